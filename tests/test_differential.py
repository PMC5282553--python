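"""Age/diet contrasts, segment scans, LOESS smoothing, factorial ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methgrad as mg
from methgrad.errors import InvalidArgumentError, InvalidDesignError
from .conftest import make_count_table


def _age_setup(locus, seed=1):
    ds = mg.simulate_scenario("AGE-1", seed=seed, locus=locus)
    dm = mg.compute_density(ds.counts)
    return ds, dm


class TestSiteContrast:
    def test_identical_groups_give_zero_delta_p_one(self):
        meth = [[50, 50, 50, 50]]
        total = [[100, 100, 100, 100]]
        dm = mg.compute_density(make_count_table(meth, total))
        from methgrad.density import validate_annotation
        annot = validate_annotation(pd.DataFrame({
            "sample": ["s0", "s1", "s2", "s3"], "mouse": list("abcd"),
            "segment": 1, "age": ["P60", "P60", "P6", "P6"]}))
        prof = mg.site_contrast(dm, annot, group_by="age", group_a="P60",
                                group_b="P6", segments=[1])
        row = prof.table.iloc[0]
        assert row.delta == 0.0 and row.p == 1.0

    def test_welch_matches_hand_computed_example(self):
        # closed-form Welch t on a 3 vs 3 worked example
        a = np.array([0.20, 0.30, 0.40])
        b = np.array([0.50, 0.60, 0.90])
        meth = [(np.concatenate([a, b]) * 1000).astype(int)]
        total = [[1000] * 6]
        dm = mg.compute_density(make_count_table(meth, total))
        from methgrad.density import validate_annotation
        annot = validate_annotation(pd.DataFrame({
            "sample": [f"s{j}" for j in range(6)],
            "mouse": list("abcdef"), "segment": 1,
            "age": ["P60"] * 3 + ["P6"] * 3}))
        prof = mg.site_contrast(dm, annot, group_by="age", group_a="P60",
                                group_b="P6", segments=[1])
        row = prof.table.iloc[0]
        a, b = dm.values.iloc[0, :3].to_numpy(), dm.values.iloc[0, 3:].to_numpy()
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 3 + vb / 3
        t_oracle = (a.mean() - b.mean()) / math.sqrt(se2)
        df_oracle = se2 ** 2 / ((va / 3) ** 2 / 2 + (vb / 3) ** 2 / 2)
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df_oracle)
        assert row.delta == pytest.approx(a.mean() - b.mean(), abs=1e-12)
        assert row.p == pytest.approx(p_oracle, abs=1e-10)
        t_sp, p_sp = stats.ttest_ind(a, b, equal_var=False)
        assert row.p == pytest.approx(p_sp, abs=1e-10)

    def test_antisymmetry(self, small_locus):
        ds, dm = _age_setup(small_locus)
        ab = mg.site_contrast(dm, ds.annotation, group_by="age",
                              group_a="P60", group_b="P6", segments=[1, 3, 7])
        ba = mg.site_contrast(dm, ds.annotation, group_by="age",
                              group_a="P6", group_b="P60", segments=[1, 3, 7])
        np.testing.assert_allclose(ab.table.delta, -ba.table.delta,
                                   atol=1e-12)
        np.testing.assert_allclose(ab.table.p, ba.table.p, atol=1e-12,
                                   equal_nan=True)

    def test_missing_segment_rejected(self, small_locus):
        ds, dm = _age_setup(small_locus)
        with pytest.raises(InvalidDesignError):
            mg.site_contrast(dm, ds.annotation, group_by="age",
                             group_a="P60", group_b="P6", segments=[9])

    def test_aging_shift_recovery_over_seeds(self, full_locus):
        # planted +30/+18/+12 pp gains recovered within +-2 pp (10 seeds)
        c1 = full_locus.cluster("C1")
        acc = {1: [], 3: [], 7: []}
        for seed in range(1, 11):
            ds, dm = _age_setup(full_locus, seed=seed)
            prof = mg.site_contrast(dm, ds.annotation, group_by="age",
                                    group_a="P60", group_b="P6",
                                    segments=[1, 3, 7])
            t = prof.table
            for seg in acc:
                sub = t[t.segment == seg].reset_index(drop=True)
                acc[seg].append(sub.iloc[list(c1.members)].delta.mean())
        assert np.mean(acc[7]) == pytest.approx(0.30, abs=0.02)
        assert np.mean(acc[1]) == pytest.approx(0.18, abs=0.02)
        assert np.mean(acc[3]) == pytest.approx(0.12, abs=0.02)

    def test_proportion_test_variant(self, small_locus):
        ds, dm = _age_setup(small_locus)
        prof = mg.site_contrast(dm, ds.annotation, group_by="age",
                                group_a="P60", group_b="P6", segments=[7],
                                test="proportion", counts=ds.counts)
        c1 = small_locus.cluster("C1")
        sub = prof.table.reset_index(drop=True).iloc[list(c1.members)]
        assert (sub.p < 1e-6).all()  # pooled-read test is very powerful


class TestBetweenSegmentScan:
    def test_self_pair_rejected(self, small_locus):
        ds, dm = _age_setup(small_locus)
        with pytest.raises(InvalidDesignError):
            mg.between_segment_scan(dm, ds.annotation, [(3, 3)])

    def test_infant_no_gradient_no_hits(self, full_locus):
        ds, dm = _age_setup(full_locus, seed=5)
        scan = mg.between_segment_scan(dm, ds.annotation, [(1, 3), (3, 7)],
                                       selector={"age": "P6"})
        assert int(scan.significant.sum()) == 0

    def test_adult_gradient_hits_planted_cluster(self, grad_dataset):
        ds = grad_dataset
        dm = mg.compute_density(ds.counts)
        scan = mg.between_segment_scan(dm, ds.annotation, [(3, 9)],
                                       selector={"age": "P60"})
        c1 = ds.locus.cluster("C1")
        sub = scan[scan.segment_a == 3].reset_index(drop=True)
        hits = sub.iloc[list(c1.members)]
        # planted inverse gradient: segment 9 sits ~42 pp above segment 3
        assert hits.significant.mean() > 0.5
        assert (hits.delta < 0).all()


def _naive_loess(x, y, span, degree):
    """Independent textbook LOESS (per-point weighted polyfit, tricube)."""
    n = len(x)
    k = min(n, max(math.ceil(span * n), degree + 2))
    out = np.empty(n)
    for i in range(n):
        d = np.sort(np.abs(x - x[i]))
        dmax = d[k - 1]
        if dmax == 0:
            sel = np.abs(x - x[i]) == 0
            out[i] = y[sel].mean()
            continue
        sel = np.argsort(np.abs(x - x[i]), kind="stable")[:k]
        w = np.maximum((1 - (np.abs(x[sel] - x[i]) / dmax) ** 3) ** 3, 1e-9)
        X = np.vander(x[sel] - x[i], degree + 1)
        WX = X * w[:, None]
        beta = np.linalg.solve(X.T @ WX, WX.T @ y[sel])
        out[i] = beta[-1]
    return out


class TestLoess:
    def test_reproduces_linear_data_exactly(self):
        x = np.linspace(0, 100, 37)
        y = 3.0 - 0.25 * x
        fitted = mg.loess_smooth(x, y, span=0.3, degree=1)
        np.testing.assert_allclose(fitted, y, atol=1e-9)

    def test_reproduces_constant(self):
        x = np.arange(20, dtype=float)
        fitted = mg.loess_smooth(x, np.full(20, 0.7), span=0.5)
        np.testing.assert_allclose(fitted, 0.7, atol=1e-12)

    @pytest.mark.parametrize("span", [0.2, 0.3, 0.6, 1.0])
    def test_matches_independent_implementation(self, span):
        rng = np.random.default_rng(4)
        x = np.sort(rng.uniform(0, 10, 60))
        y = np.sin(x) + rng.normal(0, 0.2, 60)
        got = mg.loess_smooth(x, y, span=span, degree=1)
        want = _naive_loess(x, y, span, 1)
        np.testing.assert_allclose(got, want, atol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mg.loess_smooth([1.0, 2.0], [1.0, 2.0], degree=1)

    def test_invalid_span_rejected(self):
        with pytest.raises(InvalidArgumentError):
            mg.loess_smooth(np.arange(10.0), np.arange(10.0), span=0.0)

    def test_delta_profile_smoothing(self, full_locus):
        ds, dm = _age_setup(full_locus, seed=2)
        prof = mg.site_contrast(dm, ds.annotation, group_by="age",
                                group_a="P60", group_b="P6",
                                segments=[1, 3, 7]).smooth(span=0.3)
        assert set(prof.smoothed) == {1, 3, 7}
        curve7 = prof.smoothed[7]
        c1 = full_locus.cluster("C1")
        in_cluster = curve7[(curve7.pos >= c1.start) & (curve7.pos <= c1.end)]
        # the smoothed adult-minus-infant curve peaks at the planted cluster
        assert in_cluster.fitted.mean() > curve7.fitted.median()


class TestFactorialAnova:
    @staticmethod
    def _annot(n_per_cell, diets=("LAC+", "lac-"), segments=(7, 8)):
        from methgrad.density import validate_annotation
        rows = []
        for d in diets:
            for s in segments:
                for j in range(n_per_cell):
                    rows.append({"sample": f"{d}{s}m{j}", "mouse": f"m{d}{j}",
                                 "segment": s, "diet": d})
        return validate_annotation(pd.DataFrame(rows))

    def test_identical_cell_means_give_zero_f(self):
        annot = self._annot(3)
        rng = np.random.default_rng(0)
        base = np.tile([0.1, 0.2, 0.3], 4)
        vals = pd.Series(base, index=annot.index)
        res = mg.factorial_region_anova(vals, annot)
        for term in ("diet", "segment", "diet:segment"):
            F, _ = res.term(term)
            assert F == pytest.approx(0.0, abs=1e-10)

    def test_balanced_two_way_matches_hand_computed_ss(self):
        # closed-form balanced two-way ANOVA with interaction
        annot = self._annot(2)
        y = pd.Series([1.0, 2.0, 2.0, 3.0, 2.0, 3.0, 5.0, 6.0],
                      index=annot.index)
        df = pd.DataFrame({"y": y, "a": annot.diet, "b": annot.segment})
        gm = y.mean()
        ma = df.groupby("a").y.mean()
        mb = df.groupby("b").y.mean()
        mab = df.groupby(["a", "b"]).y.mean()
        n, r_lev, c_lev = 2, 2, 2
        ss_a = n * c_lev * ((ma - gm) ** 2).sum()
        ss_b = n * r_lev * ((mb - gm) ** 2).sum()
        ss_ab = n * sum((mab[a, b] - ma[a] - mb[b] + gm) ** 2
                        for a in ma.index for b in mb.index)
        ss_err = sum((row.y - mab[row.a, row.b]) ** 2
                     for row in df.itertuples())
        ms_err = ss_err / (len(y) - r_lev * c_lev)
        res = mg.factorial_region_anova(y, annot)
        assert res.term("diet")[0] == pytest.approx(ss_a / ms_err, abs=1e-8)
        assert res.term("segment")[0] == pytest.approx(ss_b / ms_err,
                                                       abs=1e-8)
        assert res.term("diet:segment")[0] == pytest.approx(
            (ss_ab / 1) / ms_err, abs=1e-8)

    def test_empty_cell_rejected(self):
        annot = self._annot(2)
        vals = pd.Series(np.arange(8.0), index=annot.index)
        vals = vals[~((annot.diet == "lac-") & (annot.segment == 8))]
        with pytest.raises(InvalidDesignError, match="empty design cell"):
            mg.factorial_region_anova(vals, annot)

    def test_diet_cluster_interaction_detectable(self, full_locus):
        # DIET-1 exon-12-like cluster: diet effect at segments 7/8 only
        ds = mg.simulate_scenario("DIET-1", seed=3, locus=full_locus)
        dm = mg.saturation_filter(mg.compute_density(ds.counts))
        c1 = full_locus.cluster("C1")
        agg = mg.aggregate_sites(dm, c1.members)
        res = mg.factorial_region_anova(agg, ds.annotation)
        F, p = res.term("diet")
        assert p < 0.05


class TestDietRecovery:
    def test_planted_decreases_recovered_with_sign(self, full_locus):
        # all four cluster x segment decreases, correct sign in >=90% of seeds
        combos = {("C1", 7): 0.052, ("C1", 8): 0.047,
                  ("C2", 8): 0.036, ("C3", 8): 0.064}
        correct = {k: 0 for k in combos}
        est = {k: [] for k in combos}
        seeds = range(1, 11)
        for seed in seeds:
            ds = mg.simulate_scenario("DIET-1", seed=seed, locus=full_locus)
            dm = mg.saturation_filter(mg.compute_density(ds.counts))
            prof = mg.site_contrast(dm, ds.annotation, group_by="diet",
                                    group_a="lac-", group_b="LAC+",
                                    segments=[7, 8])
            t = prof.table
            for (cid, seg), planted in combos.items():
                members = full_locus.cluster(cid).members
                sub = t[t.segment == seg].reset_index(drop=True)
                d = sub.iloc[list(members)].delta.mean()
                est[(cid, seg)].append(d)
                correct[(cid, seg)] += d > 0
        for k, planted in combos.items():
            assert correct[k] >= 0.9 * len(list(seeds))
            assert np.mean(est[k]) == pytest.approx(planted, abs=0.02)
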