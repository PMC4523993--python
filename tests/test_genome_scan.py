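"""Scan workflow: MAF filter, effective tests, Šidák threshold, LD
pruning, box assignment, direction calls and marked variance."""

import numpy as np
import pandas as pd
import pytest

from imprintscan import genome_scan as gs, simulate
from imprintscan.data import Dataset
from imprintscan.genome_scan import (
    BOX_ADDITIVE,
    BOX_IMPRINTED,
    ScanConfig,
    assign_box,
    classify_direction,
    effective_tests,
    haplotype_correlation,
    heritability_report,
    maf_filter,
    marked_variance,
    percent_decrease,
    prune_clusters,
    sidak_threshold,
)


def _dataset_from_haplotypes(mat, pat):
    n, m = mat.shape
    phen = pd.DataFrame({"id": [f"i{k}" for k in range(n)],
                         "trait": np.zeros(n)})
    markers = pd.DataFrame({"marker": [f"m{j}" for j in range(m)],
                            "chrom": ["1"] * m,
                            "pos": np.arange(m, dtype=float)})
    return Dataset(maternal=mat.astype(np.int8), paternal=pat.astype(np.int8),
                   markers=markers, phenotypes=phen)


class TestMafFilter:
    def _ds(self, freqs, n=200, seed=0):
        rng = np.random.default_rng(seed)
        mat = (rng.random((n, len(freqs))) < np.array(freqs)).astype(np.int8)
        pat = (rng.random((n, len(freqs))) < np.array(freqs)).astype(np.int8)
        return _dataset_from_haplotypes(mat, pat)

    def test_rare_and_monomorphic_removed(self):
        n = 1000
        mat = np.zeros((n, 3), dtype=np.int8)
        pat = np.zeros((n, 3), dtype=np.int8)
        mat[:30, 0] = 1              # p_hat = 0.015 -> MAF 0.015, removed
        mat[:, 1] = 1; pat[:, 1] = 1  # monomorphic A1, removed
        mat[:300, 2] = 1; pat[:100, 2] = 1  # p_hat = 0.2, kept
        ds = _dataset_from_haplotypes(mat, pat)
        assert list(maf_filter(ds, 0.05)) == [2]

    def test_exact_threshold_retained(self):
        """The rule is 'remove MAF strictly below', so MAF == 0.05 stays."""
        n = 1000
        mat = np.zeros((n, 1), dtype=np.int8)
        pat = np.zeros((n, 1), dtype=np.int8)
        mat[:100, 0] = 1  # allele count 100 / 2000 = 0.05 exactly
        ds = _dataset_from_haplotypes(mat, pat)
        assert list(maf_filter(ds, 0.05)) == [0]

    def test_bad_threshold(self):
        ds = self._ds([0.5])
        with pytest.raises(ValueError):
            maf_filter(ds, 0.7)


class TestEffectiveTests:
    def test_uncorrelated_markers_count_fully(self):
        assert effective_tests([np.eye(7)]) == pytest.approx(7.0)

    def test_perfect_block_counts_once(self):
        m = 5
        assert effective_tests([np.ones((m, m))]) == pytest.approx(1.0)

    def test_blocks_sum_and_match_direct_eigendecomposition(self):
        R = np.full((3, 3), 0.5)
        np.fill_diagonal(R, 1.0)
        lam = np.linalg.eigvalsh(R)
        expected = np.sum((lam >= 1) + (lam - np.floor(lam)))
        assert effective_tests([R, R]) == pytest.approx(2 * expected)

    def test_non_psd_rejected(self):
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            effective_tests([R])

    def test_bad_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            effective_tests([np.array([[2.0, 0.0], [0.0, 1.0]])])


class TestSidak:
    def test_single_test_is_alpha(self):
        assert sidak_threshold(0.05, 1) == pytest.approx(0.05)

    def test_closed_form_at_500(self):
        assert sidak_threshold(0.05, 500) == pytest.approx(1.0259e-4, rel=1e-3)

    def test_reference_genomewide_threshold(self):
        """Back-solving the published per-test threshold 1.316e-5 implies
        ~3,898 effective tests; plugging that back must reproduce it."""
        m_eff = np.log(1 - 0.05) / np.log(1 - 1.316e-5)
        assert m_eff == pytest.approx(3898, rel=1e-3)
        assert sidak_threshold(0.05, m_eff) == pytest.approx(1.316e-5, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sidak_threshold(0.0, 10)
        with pytest.raises(ValueError):
            sidak_threshold(0.05, 0.5)


class TestBoxesAndDirection:
    def test_box_partition_rules(self):
        assert assign_box(True, False, True) == BOX_IMPRINTED
        assert assign_box(True, False, False) == BOX_ADDITIVE
        assert assign_box(False, True, False) == "none"  # dominance only
        assert assign_box(False, False, False) == "none"

    @pytest.mark.parametrize(
        "alpha,i,expect",
        [
            (2.51e-3, 6.20e-3, "maternal"),
            (2.11e-3, 4.18e-3, "maternal"),
            (-1.36e-3, 4.59e-3, "paternal"),
            (1.05e-3, -4.36e-3, "paternal"),
            (-1.82e-3, 4.00e-3, "paternal"),
        ],
    )
    def test_direction_reference_calls(self, alpha, i, expect):
        assert classify_direction(alpha, i) == expect

    def test_zero_estimate_gives_na(self):
        with pytest.warns(UserWarning):
            assert classify_direction(0.0, 1.0) == "n/a"


class TestPruning:
    def _results(self, n, box, pvals):
        return pd.DataFrame(
            {
                "marker": [f"m{j}" for j in range(n)],
                "chrom": ["1"] * n,
                "pos": np.arange(n, dtype=float),
                "index": np.arange(n),
                "p_hat": [0.5] * n,
                "alpha_hat": [1.0] * n,
                "i_hat": [1.0] * n,
                "p_additive": pvals,
                "p_imprinting": pvals,
                "box": box,
            }
        )

    def test_duplicate_markers_collapse(self):
        rng = np.random.default_rng(0)
        col = (rng.random((300, 1)) < 0.5).astype(np.int8)
        mat = np.hstack([col, col])
        pat_col = (rng.random((300, 1)) < 0.5).astype(np.int8)
        ds = _dataset_from_haplotypes(mat, np.hstack([pat_col, pat_col]))
        res = prune_clusters(
            self._results(2, [BOX_ADDITIVE] * 2, [1e-6, 1e-7]), ds, 0.99)
        assert res["retained"].sum() == 1
        # representative is the smaller p-value
        assert res.loc[res["retained"], "marker"].iloc[0] == "m1"

    def test_uncorrelated_all_retained(self):
        rng = np.random.default_rng(1)
        mat = (rng.random((500, 3)) < 0.5).astype(np.int8)
        pat = (rng.random((500, 3)) < 0.5).astype(np.int8)
        ds = _dataset_from_haplotypes(mat, pat)
        res = prune_clusters(
            self._results(3, [BOX_IMPRINTED] * 3, [1e-6] * 3), ds, 0.99)
        assert res["retained"].all()
        assert res["cluster"].nunique() == 3

    def test_transitive_chain_forms_one_cluster(self):
        """a-b and b-c exceed the r2 threshold but a-c does not; connected
        components still merge all three."""
        rng = np.random.default_rng(2)
        n = 1000  # 2000 haplotypes
        a_m = (rng.random((n, 1)) < 0.5).astype(np.int8)
        a_p = (rng.random((n, 1)) < 0.5).astype(np.int8)
        def flip(x, k, lo):  # flip k maternal entries starting at lo
            y = x.copy()
            y[lo:lo + k, 0] ^= 1
            return y
        b_m, b_p = flip(a_m, 4, 0), a_p.copy()
        c_m, c_p = flip(b_m, 4, 500), b_p.copy()
        ds = _dataset_from_haplotypes(np.hstack([a_m, b_m, c_m]),
                                      np.hstack([a_p, b_p, c_p]))
        r2 = haplotype_correlation(ds) ** 2
        assert r2[0, 1] > 0.99 and r2[1, 2] > 0.99 and r2[0, 2] < 0.99
        res = prune_clusters(
            self._results(3, [BOX_IMPRINTED] * 3, [1e-8, 1e-6, 1e-7]), ds, 0.99)
        assert res["cluster"].nunique() == 1
        assert res["retained"].sum() == 1
        assert res.loc[res["retained"], "marker"].iloc[0] == "m0"

    def test_boxes_prune_independently(self):
        rng = np.random.default_rng(3)
        col = (rng.random((400, 1)) < 0.5).astype(np.int8)
        mat = np.hstack([col, col])  # perfectly correlated pair
        pat = np.hstack([col, col])
        ds = _dataset_from_haplotypes(mat, pat)
        res = prune_clusters(
            self._results(2, [BOX_IMPRINTED, BOX_ADDITIVE], [1e-6, 1e-6]),
            ds, 0.99)
        # different boxes: both survive despite r2 = 1
        assert res["retained"].sum() == 2


class TestMarkedVariance:
    def _row(self, box, p, alpha, i=np.nan, retained=True):
        return {
            "marker": "m", "p_hat": p, "alpha_hat": alpha, "i_hat": i,
            "box": box, "retained": retained,
        }

    def test_single_additive_marker(self):
        res = pd.DataFrame([self._row(BOX_ADDITIVE, 0.5, 0.01)])
        rep = marked_variance(res)
        assert rep.snp_without == pytest.approx(5e-5)
        assert rep.snp_with == pytest.approx(5e-5)

    def test_imprinted_marker_with_zero_i_matches_additive_formula(self):
        res1 = pd.DataFrame([self._row(BOX_IMPRINTED, 0.3, 0.02, 0.0)])
        res2 = pd.DataFrame([self._row(BOX_ADDITIVE, 0.3, 0.02)])
        assert marked_variance(res1).snp_with == pytest.approx(
            marked_variance(res2).snp_with)

    def test_adding_markers_never_decreases(self):
        rows = [self._row(BOX_ADDITIVE, 0.4, 0.01),
                self._row(BOX_IMPRINTED, 0.2, 0.005, 0.01)]
        one = marked_variance(pd.DataFrame(rows[:1]))
        both = marked_variance(pd.DataFrame(rows))
        assert both.snp_with >= one.snp_with
        assert both.snp_without >= one.snp_without - 1e-18

    def test_unretained_markers_excluded(self):
        res = pd.DataFrame([self._row(BOX_ADDITIVE, 0.5, 0.01,
                                      retained=False)])
        with pytest.warns(UserWarning, match="no retained"):
            rep = marked_variance(res)
        assert rep.snp_with == 0.0

    def test_unpruned_results_rejected(self):
        res = pd.DataFrame([{"box": BOX_ADDITIVE}])
        with pytest.raises(ValueError, match="prune"):
            marked_variance(res)


class TestHeritabilityReport:
    def test_pedigree_only_when_no_markers(self):
        assert heritability_report(0.0, 2.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            heritability_report(0.0, 0.0, 0.0, 0.0)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            heritability_report(-1e-4, 1.0, 1.0, 1.0)

    def test_percent_decrease(self):
        assert percent_decrease(2.0, 1.0) == pytest.approx(50.0)
        with pytest.raises(ValueError):
            percent_decrease(0.0, 1.0)


class TestScanIntegration:
    def test_scan_finds_planted_effects(self, small_validation):
        res, info = gs.scan(small_validation, ScanConfig())
        truth = small_validation.truth["effects"]
        assert info["n_markers_scanned"] == len(
            maf_filter(small_validation, 0.05))
        # partition: boxes are exclusive labels
        assert set(res["box"]) <= {BOX_IMPRINTED, BOX_ADDITIVE, "none"}
        # strongest additive locus should be found
        strongest = truth.loc[truth.a.abs().idxmax(), "locus"]
        row = res[res["index"] == strongest].iloc[0]
        assert row.sig_additive
        # imprinting-significant implies box1 even if also additive
        both = res[res.sig_imprinting & res.sig_additive]
        assert (both.box == BOX_IMPRINTED).all()

    def test_direction_only_for_box1(self, small_validation):
        res, _ = gs.scan(small_validation, ScanConfig())
        assert (res.loc[res.box != BOX_IMPRINTED, "direction"] == "n/a").all()
        assert res.loc[res.box == BOX_IMPRINTED, "direction"].isin(
            ["maternal", "paternal", "n/a"]).all()

    def test_model9_estimates_match_full_model(self, small_validation):
        """The dominance and imprinting codes are orthogonal under HWE, so
        i-hat from the no-dominance model tracks i-hat from the full model."""
        res6, _ = gs.scan(small_validation, ScanConfig(use_model9=False))
        res9, _ = gs.scan(small_validation, ScanConfig(use_model9=True))
        ok = np.isfinite(res6.i_hat) & np.isfinite(res9.i_hat)
        slope = np.polyfit(res6.i_hat[ok], res9.i_hat[ok], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)

    def test_wrong_model_reestimation_collapses_imprinting_share(self):
        """Strongly imprinted loci lose most of their marked variance when
        re-estimated under an additive-only model."""
        spec = simulate.SimulationSpec(
            n_individuals=2500, n_loci=30, n_additive=8, n_dominance=2,
            n_imprinting=6, seed=21)
        ds = simulate.make_validation_dataset(spec)
        res, info = gs.scan(ds, ScanConfig())
        res = prune_clusters(res, ds)
        rep = marked_variance(res)
        if rep.snp_box1 == 0:
            pytest.skip("no imprinted marker detected in this replicate")
        wrong = gs.reestimate_marked_variance(
            ds, res, BOX_IMPRINTED, (gs.mm.ADDITIVE,))
        assert wrong < rep.snp_box1
        assert percent_decrease(rep.snp_box1, wrong) > 30.0
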