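"""Silencing screen: L-shape detector, correlation screen, candidates, validation."""

import numpy as np
import pandas as pd
import pytest

from methscreen.io import AlignedCohort, BetaMatrix, ExpressionMatrix, ProbeAnnotation, align_cohort
from methscreen.screen import LShapeConfig, SilencingScreen, lshape_classify


class TestLShapeClassify:
    def test_two_corner_cells_score_two(self, rng):
        """20 points top-left + 20 bottom-right: score (2*20+2*20)/40 = 2."""
        x = np.concatenate([rng.uniform(0.0, 0.3, 20), rng.uniform(0.7, 1.0, 20)])
        y = np.concatenate([rng.uniform(0.7, 1.0, 20), rng.uniform(0.0, 0.3, 20)])
        # anchor the min-max range to the unit square
        x[0], x[-1], y[0], y[-1] = 0.0, 1.0, 1.0, 0.0
        res = lshape_classify(x, y)
        assert res.score == pytest.approx(2.0)
        assert res.flag
        assert res.counts[0, 0] == 20 and res.counts[2, 2] == 20

    def test_uniform_random_points_not_flagged(self):
        flagged = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            res = lshape_classify(r.random(40), r.random(40))
            flagged += res.flag
        assert flagged / 40 <= 0.05

    def test_all_points_top_right_rejected(self, rng):
        x = rng.uniform(0.8, 1.0, 30)
        y = rng.uniform(0.8, 1.0, 30)
        x[0], y[0] = 0.0, 0.0  # keep normalisation from collapsing the grid
        x[1], y[1] = 1.0, 1.0
        res = lshape_classify(x, y)
        assert not res.flag

    def test_below_min_points_untested(self, rng):
        res = lshape_classify(rng.random(5), rng.random(5))
        assert not res.tested and not res.flag

    def test_constant_axis_untested(self):
        res = lshape_classify(np.full(20, 0.5), np.linspace(0, 1, 20))
        assert not res.tested

    def test_duplication_invariance(self, rng):
        x, y = rng.random(25), rng.random(25)
        once = lshape_classify(x, y)
        twice = lshape_classify(np.tile(x, 2), np.tile(y, 2))
        assert twice.score == pytest.approx(once.score)
        assert twice.flag == once.flag
        np.testing.assert_array_equal(twice.counts, 2 * once.counts)

    def test_boundary_point_goes_to_lower_cell(self):
        """A point exactly on a cut belongs to the lower-beta / lower-expression cell."""
        x = np.concatenate([[0.0, 1.0, 1 / 3], np.zeros(12)])
        y = np.concatenate([[0.0, 1.0, 1.0], np.linspace(0, 1, 12)])
        res = lshape_classify(x, y)
        # the (1/3, 1.0) point must be counted in column 0 (top-left), not column 1
        assert res.counts[0, 0] >= 2

    def test_missing_pairs_dropped(self, rng):
        x = np.concatenate([rng.random(20), [np.nan]])
        y = np.concatenate([rng.random(20), [0.5]])
        assert lshape_classify(x, y).n == 20

    def test_config_validation(self):
        with pytest.raises(ValueError):
            LShapeConfig(x_cuts=(0.5, 0.4))
        with pytest.raises(ValueError):
            LShapeConfig(weight_matrix=np.zeros((2, 2)))


def _make_cohort(meth: pd.DataFrame, expr: pd.DataFrame) -> AlignedCohort:
    return AlignedCohort(meth=meth, expr=expr, n_genes_annotated=meth.shape[1],
                         n_genes_retained=meth.shape[1])


class TestCorrelationScreen:
    def _null_cohort(self, rng, n_genes=50, n=30):
        genes = [f"G{i}" for i in range(n_genes)]
        samples = [f"S{i}" for i in range(n)]
        meth = pd.DataFrame(rng.random((n, n_genes)), index=samples, columns=genes)
        expr = pd.DataFrame(rng.normal(size=(n, n_genes)), index=samples, columns=genes)
        return _make_cohort(meth, expr)

    def test_planted_positive_gene_never_flagged(self, rng):
        c = self._null_cohort(rng)
        c.expr["G0"] = 5 + 10 * c.meth["G0"]  # strong positive association
        res = SilencingScreen(c).fit()
        assert not res.table.loc["G0", "sig_neg"]
        assert res.table.loc["G0", "q"] is not None

    def test_planted_negative_gene_flagged(self, rng):
        c = self._null_cohort(rng)
        c.expr["G1"] = 5 - 10 * c.meth["G1"] + rng.normal(0, 0.5, 30)
        res = SilencingScreen(c).fit()
        assert res.table.loc["G1", "sig_neg"]
        assert res.table.loc["G1", "candidate"]

    def test_bh_over_whole_universe_is_order_invariant(self, rng):
        c = self._null_cohort(rng)
        res1 = SilencingScreen(c).fit()
        perm = rng.permutation(c.meth.columns)
        c2 = _make_cohort(c.meth[perm], c.expr[perm])
        res2 = SilencingScreen(c2).fit()
        q1 = res1.table["q"].sort_index()
        q2 = res2.table["q"].sort_index()
        pd.testing.assert_series_equal(q1, q2)

    def test_short_genes_reported_untested(self, rng):
        c = self._null_cohort(rng, n_genes=5, n=30)
        c.meth.loc[c.meth.index[3:], "G0"] = np.nan  # only 3 complete pairs
        res = SilencingScreen(c).fit()
        assert not res.table.loc["G0", "tested"]
        assert np.isnan(res.table.loc["G0", "q"])
        assert res.n_tested == 4

    def test_empty_cohort_rejected(self):
        empty = _make_cohort(pd.DataFrame(index=["S1"]), pd.DataFrame(index=["S1"]))
        with pytest.raises(ValueError):
            SilencingScreen(empty)

    def test_candidates_are_union_and_l_only_disjoint(self, small_screen):
        t = small_screen.table
        assert (t["candidate"] == (t["sig_neg"] | t["lshape_flag"])).all()
        assert not (t["l_only"] & t["sig_neg"]).any()
        assert small_screen.n_candidates == small_screen.n_sig_neg + small_screen.n_l_only

    def test_empty_lshape_set_candidates_equal_correlation_hits(self, rng):
        c = self._null_cohort(rng)
        cfg = LShapeConfig(score_threshold=1e9)  # unreachable
        res = SilencingScreen(c, lshape_config=cfg).fit()
        assert res.n_candidates == res.n_sig_neg


class TestRecoveryOnSyntheticCohort:
    def test_planted_classes_recovered(self, small_study, small_screen):
        truth = small_study.gene_classes
        t = small_screen.table
        mono = truth.index[truth == "monotone"]
        assert t.loc[mono, "sig_neg"].mean() >= 0.9
        lsh = truth.index[truth == "lshape"]
        misses = [g for g in lsh if not t.loc[g, "sig_neg"]]
        if misses:
            assert np.mean([t.loc[g, "lshape_flag"] for g in misses]) >= 0.5
        null = truth.index[truth == "null"]
        assert t.loc[null, "candidate"].mean() < 0.1


class TestCrossCohortValidation:
    def test_validation_on_synthetic_tumors(self, small_study, small_screen):
        cohort2 = align_cohort(
            small_study.beta_tumor,
            small_study.expr_tumor,
            small_study.probes,
            samples=small_study.annot_tumor.analysis_samples(),
        )
        val = small_screen.validate(cohort2)
        truth = small_study.gene_classes
        planted = [g for g in val.table.index if truth[g] != "null"]
        assert val.table.loc[planted, "validated"].mean() >= 0.85
        assert 0 < val.availability_fraction <= 1

    def test_unavailable_candidates_counted_separately(self, rng):
        genes = [f"G{i}" for i in range(20)]
        samples = [f"S{i}" for i in range(30)]
        meth = pd.DataFrame(rng.random((30, 20)), index=samples, columns=genes)
        expr = pd.DataFrame(5 - 8 * meth.to_numpy() + rng.normal(0, 0.5, (30, 20)),
                            index=samples, columns=genes)
        res = SilencingScreen(_make_cohort(meth, expr)).fit()
        assert res.n_candidates > 0
        # cohort 2 lacks half the genes
        keep = genes[::2]
        meth2 = pd.DataFrame(rng.random((30, len(keep))), index=samples, columns=keep)
        expr2 = pd.DataFrame(5 - 8 * meth2.to_numpy() + rng.normal(0, 0.5, (30, len(keep))),
                             index=samples, columns=keep)
        val = res.validate(_make_cohort(meth2, expr2))
        assert val.n_available == len([g for g in res.candidates if g in keep])
        assert val.availability_fraction < 1

    def test_no_candidates_rejected(self, rng):
        genes = [f"G{i}" for i in range(10)]
        samples = [f"S{i}" for i in range(30)]
        meth = pd.DataFrame(rng.random((30, 10)), index=samples, columns=genes)
        expr = pd.DataFrame(rng.normal(size=(30, 10)), index=samples, columns=genes)
        res = SilencingScreen(_make_cohort(meth, expr)).fit()
        if res.n_candidates == 0:
            with pytest.raises(ValueError):
                res.validate(_make_cohort(meth, expr))


class TestPerProbeMode:
    def test_most_significant_probe_represents_gene(self, rng):
        samples = [f"S{i}" for i in range(30)]
        beta = BetaMatrix(pd.DataFrame(
            {"cgA": rng.random(30), "cgB": rng.random(30)}, index=samples))
        # expression tracks cgB only
        expr = ExpressionMatrix(pd.DataFrame(
            {"G1": 5 - 8 * beta.values["cgB"] + rng.normal(0, 0.3, 30)}, index=samples))
        probes = ProbeAnnotation(pd.DataFrame({
            "probe_id": ["cgA", "cgB"], "gene_symbol": ["G1", "G1"],
            "chromosome": "chr1", "position": [0, 500]}))
        cohort = align_cohort(beta, expr, probes, mode="per-probe")
        res = SilencingScreen(cohort).fit()
        assert res.table.loc["G1", "sig_neg"]
        # gene-level p comes from the better probe, so it must be tiny
        assert res.table.loc["G1", "p"] < 1e-4

    def test_summary_renders(self, small_screen):
        s = small_screen.summary()
        assert "candidates" in s and "genes tested" in s
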