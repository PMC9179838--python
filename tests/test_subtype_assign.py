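"""Centroid correlation, assignment rules, ER filter, collapse, agreement."""

import itertools

import numpy as np
import pandas as pd
import pytest

from tnbckit import (
    CentroidSignature,
    ScalingSpec,
    agreement_class,
    assign_all,
    assign_subtype,
    collapse_lehmann,
    correlate_centroids,
    er_positive_filter,
    simulate_from_signature,
)
from tnbckit.subtype_assign import UNCLASSIFIED, AssignmentResult

from .conftest import make_matrix


@pytest.fixture
def toy_signature():
    rng = np.random.default_rng(0)
    genes = [f"g{i}" for i in range(20)]
    centroids = pd.DataFrame(
        rng.normal(7, 1, size=(20, 3)), index=genes, columns=["A", "B", "C"]
    )
    return CentroidSignature(centroids)


class TestCorrelateCentroids:
    def test_sample_equal_to_centroid_correlates_one(self, toy_signature):
        m = make_matrix(
            toy_signature.centroids[["A", "B"]].to_numpy(),
            genes=toy_signature.gene_ids,
            samples=["sa", "sb"],
        )
        r = correlate_centroids(m, toy_signature)
        assert r.loc["sa", "A"] == pytest.approx(1.0)
        assert r.loc["sb", "B"] == pytest.approx(1.0)

    def test_positive_affine_transform_invariance(self, toy_signature):
        rng = np.random.default_rng(1)
        base = rng.normal(7, 1, size=(20, 5))
        m1 = make_matrix(base, genes=toy_signature.gene_ids)
        m2 = make_matrix(3.0 + 1.7 * base, genes=toy_signature.gene_ids)
        r1 = correlate_centroids(m1, toy_signature)
        r2 = correlate_centroids(m2, toy_signature)
        np.testing.assert_allclose(r1.to_numpy(), r2.to_numpy(), atol=1e-12)

    def test_missing_signature_genes_dropped_pairwise(self, toy_signature):
        rng = np.random.default_rng(2)
        genes = toy_signature.gene_ids[:12]  # 40% missing
        m = make_matrix(rng.normal(size=(12, 4)), genes=genes)
        r = correlate_centroids(m, toy_signature)
        assert r.shape == (4, 3)
        assert np.isfinite(r.to_numpy()).all()

    def test_more_than_half_missing_errors(self, toy_signature):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(5, 4)), genes=toy_signature.gene_ids[:5])
        with pytest.raises(ValueError, match="missing"):
            correlate_centroids(m, toy_signature)

    def test_constant_profile_becomes_unclassified(self, toy_signature):
        vals = np.ones((20, 2))
        vals[:, 1] = toy_signature.centroids["A"]
        m = make_matrix(vals, genes=toy_signature.gene_ids, samples=["flat", "ok"])
        table = assign_all(m, toy_signature)
        assert table.loc["flat", "label"] == UNCLASSIFIED
        assert table.loc["flat", "reason"] == "undefined_correlations"
        assert table.loc["ok", "label"] == "A"

    def test_noisy_samples_recover_generating_centroid(self, toy_signature):
        m, truth = simulate_from_signature(toy_signature, n_per_subtype=100, noise_sd=0.5, seed=4)
        table = assign_all(m, toy_signature, min_r=0.0)
        accuracy = float((table["label"] == truth).mean())
        assert accuracy >= 0.95


class TestAssignSubtype:
    def test_argmax_and_margin(self):
        res = assign_subtype({"A": 0.8, "B": 0.2})
        assert res.label == "A"
        assert res.margin == pytest.approx(0.6)

    def test_below_min_r_unclassified(self):
        res = assign_subtype({"A": 0.05, "B": 0.02}, min_r=0.1)
        assert res.label == UNCLASSIFIED
        assert res.reason == "low_correlation"

    def test_exact_tie_unclassified(self):
        res = assign_subtype({"A": 0.5, "B": 0.5})
        assert res.label == UNCLASSIFIED
        assert res.reason == "tie"

    def test_margin_rule(self):
        res = assign_subtype({"A": 0.6, "B": 0.55}, min_margin=0.1)
        assert res.label == UNCLASSIFIED
        assert res.reason == "low_margin"


class TestErPositiveFilter:
    def test_max_gene_sample_flagged(self):
        m = make_matrix([[9.0], [1.0], [2.0], [3.0]], genes=["ESR1", "a", "b", "c"])
        assert er_positive_filter(m).iloc[0]

    def test_median_level_not_flagged(self):
        m = make_matrix([[2.5], [1.0], [2.0], [4.0], [9.0]], genes=["ESR1", "a", "b", "c", "d"])
        assert not er_positive_filter(m).iloc[0]

    def test_hand_quartile_example(self):
        # sample values (2, 4, 6, 8) with ESR1 = 8: Q3 = 6.5 < 8 -> flagged
        m = make_matrix([[8.0], [2.0], [4.0], [6.0]], genes=["ESR1", "a", "b", "c"])
        vals = np.array([2.0, 4.0, 6.0, 8.0])
        assert float(np.quantile(vals, 0.75)) == pytest.approx(6.5)
        assert er_positive_filter(m).iloc[0]

    def test_across_sample_reference(self):
        vals = np.array([[1.0, 2.0, 3.0, 10.0], [5.0, 5.0, 5.0, 5.0]])
        m = make_matrix(vals, genes=["ESR1", "x"])
        flags = er_positive_filter(m, reference="across_sample")
        assert flags.tolist() == [False, False, False, True]

    def test_missing_er_gene_errors(self, random_matrix):
        with pytest.raises(ValueError, match="ESR1"):
            er_positive_filter(random_matrix)


class TestCollapseLehmann:
    @staticmethod
    def result(label, corrs):
        return AssignmentResult("s", dict(corrs), label, 0.1)

    def test_retained_label_passes_through(self):
        corrs = {"BL1": 0.9, "BL2": 0.1, "M": 0.1, "MSL": 0.1, "IM": 0.1, "LAR": 0.1}
        assert collapse_lehmann(self.result("BL1", corrs)).collapsed_label == "BL1"

    def test_im_moves_to_best_retained(self):
        corrs = {"BL1": 0.4, "BL2": 0.1, "M": 0.3, "LAR": 0.0, "IM": 0.8, "MSL": 0.2}
        assert collapse_lehmann(self.result("IM", corrs)).collapsed_label == "BL1"

    def test_msl_tie_among_retained_unclassified(self):
        corrs = {"BL1": 0.4, "BL2": 0.4, "M": 0.1, "LAR": 0.0, "IM": 0.2, "MSL": 0.8}
        assert collapse_lehmann(self.result("MSL", corrs)).collapsed_label == UNCLASSIFIED

    def test_unclassified_propagates(self):
        corrs = {"BL1": 0.1, "BL2": 0.1, "M": 0.1, "LAR": 0.1, "IM": 0.1, "MSL": 0.1}
        assert collapse_lehmann(self.result(UNCLASSIFIED, corrs)).collapsed_label == UNCLASSIFIED

    def test_never_outputs_dropped_subtypes(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            corrs = dict(zip(["BL1", "BL2", "M", "MSL", "IM", "LAR"], rng.uniform(-1, 1, 6)))
            label = max(corrs, key=corrs.get)
            out = collapse_lehmann(self.result(label, corrs))
            assert out.collapsed_label not in ("IM", "MSL")

    def test_missing_subtype_correlation_errors(self):
        with pytest.raises(ValueError, match="missing"):
            collapse_lehmann(self.result("BL1", {"BL1": 0.5, "BL2": 0.1}))


class TestAgreementClass:
    @pytest.mark.parametrize(
        "labels,expected",
        [(("A", "A", "A"), "identical"), (("A", "B", "C"), "different"), (("A", "A", "B"), "partial")],
    )
    def test_enumerated_triples(self, labels, expected):
        assert agreement_class(*labels) == expected

    def test_symmetric_under_permutation(self):
        for triple in [("A", "A", "B"), ("A", "B", "C"), ("X", "X", "X")]:
            classes = {agreement_class(*p) for p in itertools.permutations(triple)}
            assert len(classes) == 1

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError, match="non-missing"):
            agreement_class("A", None, "B")


class TestScalingSensitivity:
    def test_heterogeneous_scales_flip_assignments_without_scaling(self):
        # 10 'loud' genes on a 10x scale where the centroids disagree one
        # way, 30 quiet genes where they disagree independently: without
        # scaling the loud block dominates Pearson r, with standardization
        # the quiet block carries 3x the weight, so some samples flip label
        rng = np.random.default_rng(7)
        n_genes, n = 40, 120
        loud = slice(0, 10)
        quiet_pattern_a = rng.choice([-1.0, 1.0], size=30)
        quiet_pattern_b = rng.choice([-1.0, 1.0], size=30)
        c_a = np.concatenate([np.full(10, 1.0), quiet_pattern_a])
        c_b = np.concatenate([np.full(10, -1.0), quiet_pattern_b])
        c_a[0], c_b[0] = 0.9, -0.9  # keep centroid columns non-constant blocks
        data = rng.normal(0, 1, size=(n_genes, n))
        data[loud] *= 10.0
        genes = [f"g{i}" for i in range(n_genes)]
        m = make_matrix(data, genes=genes)
        sig_none = CentroidSignature(
            pd.DataFrame({"A": c_a, "B": c_b}, index=genes), ScalingSpec("none")
        )
        sig_std = CentroidSignature(
            pd.DataFrame({"A": c_a, "B": c_b}, index=genes), ScalingSpec("standard")
        )
        lab_none = assign_all(m, sig_none, min_r=-1.0)["label"]
        lab_std = assign_all(m, sig_std, min_r=-1.0)["label"]
        assert (lab_none != lab_std).any()

    def test_centroid_matched_data_agrees_across_scaling(self, toy_signature):
        m, truth = simulate_from_signature(toy_signature, n_per_subtype=50, noise_sd=0.2, seed=8)
        lab_none = assign_all(m, toy_signature, min_r=-1.0)["label"]
        sig_std = CentroidSignature(toy_signature.centroids, ScalingSpec("standard"))
        lab_std = assign_all(m, sig_std, min_r=-1.0)["label"]
        agree = float((lab_none == lab_std).mean())
        assert agree > 0.95
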