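"""Genotype QC, group construction, Kaplan-Meier, log-rank and odds ratios."""

import numpy as np
import pandas as pd
import pytest

from netsnp.genotypes import MISSING
from netsnp.simulate import SimConfig, gen_genotypes_and_clinical
from netsnp.survival import (
    GenotypeGroups,
    QCParams,
    build_groups,
    km_estimate,
    logistic_or,
    logrank_test,
    map_to_central,
    qc_genotypes,
    results_to_frame,
    screen,
)
from netsnp.ld import TagLink

from conftest import matrix_from_dosage


def groups_of(labels: dict[str, str], rsid="rsX") -> GenotypeGroups:
    sizes: dict[str, int] = {}
    for lab in labels.values():
        sizes[lab] = sizes.get(lab, 0) + 1
    return GenotypeGroups(rsid, labels, False, sizes)


def two_group_data(spec):
    """spec: list of (group, time, event) -> (times, events, groups)."""
    times = pd.Series({f"s{i}": t for i, (_, t, _) in enumerate(spec)}, dtype=float)
    events = pd.Series({f"s{i}": e for i, (_, _, e) in enumerate(spec)})
    labels = {f"s{i}": g for i, (g, _, _) in enumerate(spec)}
    return times, events, groups_of(labels)


def logrank_oracle_2group(times, events, labels, group):
    """Per-event-time hypergeometric tabulation of the 2-group statistic."""
    o_minus_e, v = 0.0, 0.0
    for t in sorted({ti for ti, ei in zip(times, events) if ei}):
        n = sum(ti >= t for ti in times)
        n1 = sum(ti >= t and l == group for ti, l in zip(times, labels))
        d = sum(ti == t and ei for ti, ei in zip(times, events))
        d1 = sum(ti == t and ei and l == group for ti, ei, l in zip(times, events, labels))
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / v


class TestQcGenotypes:
    def test_high_missing_snp_dropped(self):
        d = np.array([[0, 1, MISSING, MISSING, 1, 2, 0, 1, 1, 0],
                      [0, 1, 2, 1, 1, 2, 0, 1, 1, 0]])
        g = matrix_from_dosage(d, ["hi_miss", "ok"])
        out, rep = qc_genotypes(g, QCParams(confidence_min=None, min_sample_snr=None,
                                            max_missing_rate=0.05, min_maf=0.0))
        assert out.snps == ["ok"]
        assert rep.n_snps_dropped_missing == 1

    def test_low_maf_snp_dropped(self):
        d = np.vstack([np.r_[1, np.zeros(49, int)], np.tile([0, 1, 2, 1, 0], 10)])
        g = matrix_from_dosage(d, ["rare", "common"])
        out, rep = qc_genotypes(g, QCParams(confidence_min=None, min_sample_snr=None,
                                            max_missing_rate=1.0, min_maf=0.05))
        assert out.snps == ["common"]
        assert rep.n_snps_dropped_maf == 1

    def test_low_confidence_call_masked_but_snp_retained(self):
        d = np.tile([0, 1, 2, 1, 0], (1, 4))
        conf = np.ones_like(d, dtype=float)
        conf[0, 0] = 0.90
        g = matrix_from_dosage(d, ["rs1"], confidence=conf)
        out, rep = qc_genotypes(g, QCParams(confidence_min=0.95, min_sample_snr=None,
                                            max_missing_rate=0.5, min_maf=0.0))
        assert rep.n_calls_masked == 1
        assert out.dosage[0, 0] == MISSING
        assert out.snps == ["rs1"]

    def test_low_snr_samples_dropped(self):
        d = np.tile([0, 1, 2, 1, 0, 1], (1, 1))
        g = matrix_from_dosage(d, ["rs1"])
        snr = pd.Series({s: (2.0 if s == "s0" else 10.0) for s in g.samples})
        out, rep = qc_genotypes(g, QCParams(confidence_min=None, min_sample_snr=5.0,
                                            max_missing_rate=1.0, min_maf=0.0), snr)
        assert rep.n_samples_dropped_snr == 1
        assert "s0" not in out.samples

    def test_all_snps_removed_is_error(self):
        g = matrix_from_dosage(np.array([[0, 0, 0, 1]]), ["rs1"])
        with pytest.raises(ValueError, match="all SNPs"):
            qc_genotypes(g, QCParams(confidence_min=None, min_sample_snr=None, min_maf=0.4))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            QCParams(max_missing_rate=-0.1)
        with pytest.raises(ValueError):
            QCParams(merge_homo_freq=0.7)
        with pytest.raises(ValueError):
            QCParams(alpha=0.0)


class TestBuildGroups:
    def test_rare_homozygote_merged(self):
        d = np.r_[np.zeros(70, int), np.ones(25, int), np.full(5, 2)]
        g = matrix_from_dosage(d[None, :], ["rs1"])
        grp = build_groups(g, "rs1", merge_homo_freq=0.10)
        assert grp.merged
        assert grp.group_sizes == {"hom_major": 70, "merged_het_homminor": 30}

    def test_common_homozygote_not_merged(self):
        d = np.r_[np.zeros(50, int), np.ones(30, int), np.full(20, 2)]
        g = matrix_from_dosage(d[None, :], ["rs1"])
        grp = build_groups(g, "rs1", merge_homo_freq=0.10)
        assert not grp.merged
        assert grp.group_sizes == {"hom_major": 50, "het": 30, "hom_minor": 20}

    def test_absent_homozygote_class_no_merge_event(self):
        d = np.r_[np.zeros(95, int), np.ones(5, int)]
        g = matrix_from_dosage(d[None, :], ["rs1"])
        grp = build_groups(g, "rs1", merge_homo_freq=0.10)
        assert not grp.merged
        assert grp.group_sizes == {"hom_major": 95, "het": 5}

    def test_eleven_of_209_homozygotes_merge(self):
        # a 209-sample cohort with an 11-strong minor homozygote class
        d = np.r_[np.zeros(148, int), np.ones(50, int), np.full(11, 2)]
        g = matrix_from_dosage(d[None, :], ["rs1"])
        grp = build_groups(g, "rs1", merge_homo_freq=0.10)
        assert grp.merged  # 11/209 = 5.3% < 10%
        assert grp.group_sizes == {"hom_major": 148, "merged_het_homminor": 61}

    def test_major_minor_by_allele_frequency(self):
        # alt allele is the common one: dosage 2 is the major homozygote
        d = np.r_[np.full(70, 2), np.ones(25, int), np.zeros(5, int)]
        g = matrix_from_dosage(d[None, :], ["rs1"])
        grp = build_groups(g, "rs1", merge_homo_freq=0.10)
        assert grp.group_sizes["hom_major"] == 70
        assert grp.merged

    def test_missing_samples_excluded(self):
        d = np.array([[0, 0, 1, 1, 2, 2, MISSING]])
        g = matrix_from_dosage(d, ["rs1"])
        grp = build_groups(g, "rs1", merge_homo_freq=0.0)
        assert sum(grp.group_sizes.values()) == 6


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survivor(self):
        times, events, grp = two_group_data([("a", 1, 1), ("a", 2, 1), ("a", 3, 1)])
        (c,) = km_estimate(times, events, grp)
        assert list(c.event_times) == [1, 2, 3]
        assert c.survival == pytest.approx([2 / 3, 1 / 3, 0.0])

    def test_hand_computed_censored_example(self):
        # times {1, 2+, 3}: S = 2/3 on [1,3), then 2/3 * (1 - 1/1) = 0
        times, events, grp = two_group_data([("a", 1, 1), ("a", 2, 0), ("a", 3, 1)])
        (c,) = km_estimate(times, events, grp)
        assert list(c.event_times) == [1, 3]
        assert c.survival == pytest.approx([2 / 3, 0.0])

    def test_all_censored_survival_stays_one(self):
        times, events, grp = two_group_data([("a", 1, 0), ("a", 2, 0)])
        (c,) = km_estimate(times, events, grp)
        assert c.event_times.size == 0
        assert c.survival_at(5.0) == 1.0

    def test_confidence_band_brackets_estimate(self, rng):
        n = 80
        times = pd.Series(rng.exponential(12, n), index=[f"s{i}" for i in range(n)])
        events = pd.Series((rng.random(n) < 0.7).astype(int), index=times.index)
        grp = groups_of({s: "a" for s in times.index})
        (c,) = km_estimate(times, events, grp)
        assert np.all(c.ci_lower <= c.survival + 1e-12)
        assert np.all(c.survival <= c.ci_upper + 1e-12)
        assert np.all((c.ci_lower >= 0) & (c.ci_upper <= 1))
        assert np.all(np.diff(c.survival) <= 1e-12)  # nonincreasing

    def test_matches_lifelines_product_limit(self, rng):
        from lifelines import KaplanMeierFitter

        n = 60
        t = rng.exponential(10, n)
        e = (rng.random(n) < 0.6).astype(int)
        times = pd.Series(t, index=[f"s{i}" for i in range(n)])
        events = pd.Series(e, index=times.index)
        grp = groups_of({s: "a" for s in times.index})
        (c,) = km_estimate(times, events, grp)
        kmf = KaplanMeierFitter().fit(t, e)
        ours = [c.survival_at(et) for et in c.event_times]
        ref = kmf.survival_function_at_times(c.event_times).to_numpy()
        assert np.allclose(ours, ref, atol=1e-12)

    def test_invariant_under_sample_reordering(self, rng):
        spec = [("a", float(t), int(e)) for t, e in zip(rng.integers(1, 20, 30), rng.random(30) < 0.7)]
        times, events, grp = two_group_data(spec)
        (c1,) = km_estimate(times, events, grp)
        perm = rng.permutation(times.index)
        (c2,) = km_estimate(times.loc[perm], events.loc[perm], grp)
        assert np.array_equal(c1.event_times, c2.event_times)
        assert np.allclose(c1.survival, c2.survival)


class TestLogrank:
    def test_identical_groups_give_null_result(self):
        spec = [("a", 1, 1), ("b", 1, 1), ("a", 2, 1), ("b", 2, 1), ("a", 3, 1), ("b", 3, 1)]
        times, events, grp = two_group_data(spec)
        chi2, df, p, _ = logrank_test(times, events, grp)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_matches_hypergeometric_oracle_on_toy_set(self):
        spec = [("a", 1, 1), ("a", 3, 0), ("a", 5, 1), ("b", 2, 1), ("b", 4, 1), ("b", 6, 0)]
        times, events, grp = two_group_data(spec)
        chi2, df, p, _ = logrank_test(times, events, grp)
        t = [x[1] for x in spec]
        e = [x[2] for x in spec]
        l = [x[0] for x in spec]
        assert chi2 == pytest.approx(logrank_oracle_2group(t, e, l, "a"), abs=1e-9)

    def test_no_events_flagged_with_p_one(self):
        spec = [("a", 1, 0), ("a", 2, 0), ("b", 1, 0), ("b", 3, 0)]
        times, events, grp = two_group_data(spec)
        chi2, df, p, flagged = logrank_test(times, events, grp)
        assert (chi2, p, flagged) == (0.0, 1.0, True)

    def test_three_group_df(self, rng):
        labels = {f"s{i}": lab for i, lab in enumerate(["hom_major"] * 5 + ["het"] * 5 + ["hom_minor"] * 5)}
        times = pd.Series(rng.exponential(10, 15), index=labels.keys())
        events = pd.Series(1, index=times.index)
        chi2, df, p, _ = logrank_test(times, events, groups_of(labels))
        assert df == 2

    def test_null_rejection_rate_within_binomial_band(self, rng):
        reps, n, alpha = 400, 60, 0.05
        hits = 0
        t = rng.exponential(12, n)
        e = (rng.random(n) < 0.7).astype(int)
        idx = [f"s{i}" for i in range(n)]
        times = pd.Series(t, index=idx)
        events = pd.Series(e, index=idx)
        for _ in range(reps):
            labels = dict(zip(idx, rng.permutation(["a"] * (n // 2) + ["b"] * (n // 2))))
            _, _, p, _ = logrank_test(times, events, groups_of(labels))
            hits += p < alpha
        from scipy.stats import binom

        lo, hi = binom.ppf([0.025, 0.975], reps, alpha)
        assert lo <= hits <= hi


class TestLogisticOr:
    def test_equals_cross_product_ratio(self):
        # 2x2 cells (a,b,c,d) = (10,20,30,5): OR = 10*5 / (20*30)
        labels, events = {}, {}
        i = 0
        for lab, ev, cnt in [("het", 1, 10), ("het", 0, 20), ("hom_major", 1, 30), ("hom_major", 0, 5)]:
            for _ in range(cnt):
                labels[f"s{i}"] = lab
                events[f"s{i}"] = ev
                i += 1
        (res,) = logistic_or(groups_of(labels), pd.Series(events))
        assert res.odds_ratio == pytest.approx((10 * 5) / (20 * 30), abs=1e-6)
        assert res.estimable

    def test_identical_event_rates_give_unit_or(self):
        labels = {f"s{i}": ("het" if i < 20 else "hom_major") for i in range(40)}
        events = pd.Series({s: (1 if int(s[1:]) % 2 else 0) for s in labels})
        (res,) = logistic_or(groups_of(labels), events)
        assert res.odds_ratio == pytest.approx(1.0, abs=1e-6)
        assert res.p_value == pytest.approx(1.0, abs=1e-6)

    def test_zero_cell_flagged_non_estimable(self):
        labels = {f"s{i}": ("het" if i < 10 else "hom_major") for i in range(20)}
        events = pd.Series({s: (1 if labels[s] == "het" else 0) for s in labels})
        results = logistic_or(groups_of(labels), events)
        assert all(not r.estimable for r in results)

    def test_merged_groups_yield_single_contrast(self):
        labels = {f"s{i}": ("merged_het_homminor" if i < 15 else "hom_major") for i in range(40)}
        g = GenotypeGroups("rs1", labels, True, {"merged_het_homminor": 15, "hom_major": 25})
        events = pd.Series({s: int(i % 3 == 0) for i, s in enumerate(labels)})
        results = logistic_or(g, events)
        assert len(results) == 1
        assert results[0].contrast == "merged_het_homminor"


class TestScreen:
    def _world(self, seed, hr, n=300, n_snps=5):
        cfg = SimConfig(seed=seed, n_samples=n, n_snps=n_snps, missing_rate=0.0,
                        effect_snp=("rs00001", hr) if hr else None)
        gm, clin, _ = gen_genotypes_and_clinical(cfg)
        return gm, clin

    def test_strong_effect_detected(self):
        gm, clin = self._world(seed=42, hr=3.0)
        params = QCParams(confidence_min=None, min_sample_snr=None)
        results, _ = screen({"rs00001"}, gm, clin, params)
        assert len(results) == 1
        assert results[0].significant

    def test_empty_intersection_warns(self):
        gm, clin = self._world(seed=1, hr=None)
        with pytest.warns(UserWarning, match="no array SNPs"):
            results, untestable = screen({"absent"}, gm, clin, QCParams())
        assert results == [] and untestable == []

    def test_monomorphic_snp_listed_untestable(self):
        d = np.vstack([np.zeros(50, int), np.tile([0, 1, 2, 1, 0], 10)])
        gm = matrix_from_dosage(d, ["mono", "ok"])
        idx = gm.samples
        clin = pd.DataFrame({"time": np.arange(1, 51, dtype=float), "event": 1}, index=pd.Index(idx, name="sample"))
        results, untestable = screen({"mono", "ok"}, gm, clin, QCParams(confidence_min=None, min_sample_snr=None))
        assert untestable == ["mono"]
        assert [r.rsid for r in results] == ["ok"]

    def test_result_sheet_schema(self):
        gm, clin = self._world(seed=9, hr=None, n=120)
        params = QCParams(confidence_min=None, min_sample_snr=None)
        results, _ = screen(set(gm.snps), gm, clin, params)
        sheet = results_to_frame(results, [TagLink("rs00001", "cen1", 0.9)])
        assert {"SurvivalMarker", "logrank_p", "hetero_or", "homo_or", "significant",
                "tagged_central", "logrank_p_bh"} <= set(sheet.columns)
        tagged = sheet.loc[sheet["SurvivalMarker"] == "rs00001", "tagged_central"].iloc[0]
        assert tagged == "cen1"


class TestMapToCentral:
    @staticmethod
    def _sig(rsid):
        g = GenotypeGroups(rsid, {}, False, {"hom_major": 1, "het": 1})
        from netsnp.survival import SurvivalResult

        return SurvivalResult(rsid, g, [], 1.0, 1, 0.01, [], True)

    def test_direct_and_tagged_accounting(self):
        # 8 direct central hits + 10 significant tags resolving to 18
        # distinct central SNPs disjoint from the 8 -> 26 total
        direct_ids = [f"c{i}" for i in range(8)]
        tag_ids = [f"t{i}" for i in range(10)]
        tagged_ids = [f"tc{i}" for i in range(18)]
        central = set(direct_ids) | set(tagged_ids)
        results = [self._sig(r) for r in direct_ids + tag_ids]
        links = []
        for i, t in enumerate(tag_ids):
            links.append(TagLink(t, tagged_ids[2 * i % 18], 0.9))
            links.append(TagLink(t, tagged_ids[(2 * i + 1) % 18], 0.9))
        direct, tagged, total = map_to_central(results, links, central)
        assert len(direct) == 8
        assert len(tagged) == 18
        assert total == 26

    def test_self_tagging_central_counted_once(self):
        central = {"c1"}
        results = [self._sig("c1")]
        links = [TagLink("c1", "c1", 1.0)]
        direct, tagged, total = map_to_central(results, links, central)
        assert total == 1

    def test_no_significant_snps(self):
        direct, tagged, total = map_to_central([], [], {"c1"})
        assert (direct, tagged, total) == (set(), set(), 0)
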