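"""Survival screening of SNPs: QC, genotype groups, Kaplan-Meier, log-rank,
logistic odds ratios, and tag-to-central back-mapping.

Per SNP the samples are split by genotype (major homozygote / heterozygote /
minor homozygote); when the rarer homozygote class falls below a frequency
cutoff (default 10% of called samples) it is merged with the heterozygotes,
which keeps the Kaplan-Meier estimate of a tiny group from dominating the
test.  Group survival differences are tested with the k-group log-rank
statistic and nominal p-values; odds ratios for the observed-death indicator
come from logistic regression with the major homozygote as reference.

The Kaplan-Meier product-limit estimate, Greenwood variance and log-scale
confidence bands are computed here from the risk-set table; the log-rank
test is delegated to lifelines and the logistic fit to statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix
from .ld import TagLink

__all__ = [
    "QCParams",
    "QCReport",
    "GenotypeGroups",
    "KMCurve",
    "OddsRatio",
    "SurvivalResult",
    "load_clinical",
    "qc_genotypes",
    "build_groups",
    "km_estimate",
    "logrank_test",
    "logistic_or",
    "screen",
    "map_to_central",
    "results_to_frame",
]

Z95 = stats.norm.ppf(0.975)


@dataclass
class QCParams:
    """Quality-control and analysis thresholds.

    All four genotype-QC thresholds are user-visible parameters and are
    echoed in the QC report, so no run hides the values it used.
    """

    confidence_min: float | None = 0.95
    max_missing_rate: float = 0.05
    min_maf: float = 0.05
    min_sample_snr: float | None = 5.0
    merge_homo_freq: float = 0.10
    alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.confidence_min is not None and not 0 <= self.confidence_min <= 1:
            raise ValueError("confidence_min must be in [0,1]")
        if not 0 <= self.merge_homo_freq <= 0.5:
            raise ValueError("merge_homo_freq must be in [0, 0.5]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")


@dataclass
class QCReport:
    params: QCParams
    n_calls_masked: int = 0
    n_samples_dropped_snr: int = 0
    n_snps_dropped_missing: int = 0
    n_snps_dropped_maf: int = 0
    n_snps_in: int = 0
    n_snps_out: int = 0

    def to_frame(self) -> pd.DataFrame:
        p = self.params
        rows = [
            ("confidence_min", p.confidence_min, "calls_masked", self.n_calls_masked),
            ("min_sample_snr", p.min_sample_snr, "samples_dropped", self.n_samples_dropped_snr),
            ("max_missing_rate", p.max_missing_rate, "snps_dropped", self.n_snps_dropped_missing),
            ("min_maf", p.min_maf, "snps_dropped", self.n_snps_dropped_maf),
        ]
        return pd.DataFrame(rows, columns=["step", "threshold", "removed_kind", "n_removed"])


@dataclass
class GenotypeGroups:
    rsid: str
    assignment: dict[str, str]  # sample -> group label (called samples only)
    merged: bool
    group_sizes: dict[str, int]

    @property
    def labels(self) -> list[str]:
        canonical = ("hom_major", "het", "merged_het_homminor", "hom_minor")
        out = [g for g in canonical if self.group_sizes.get(g, 0) > 0]
        out += sorted(g for g in self.group_sizes if g not in canonical and self.group_sizes[g] > 0)
        return out

    @property
    def testable(self) -> bool:
        return len(self.labels) >= 2


@dataclass
class KMCurve:
    group: str
    n: int
    event_times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) just after each event time
    greenwood_se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function lookup; S = 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def median(self) -> float:
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else float("inf")


@dataclass
class OddsRatio:
    contrast: str  # "het" | "hom_minor" | "merged_het_homminor"
    odds_ratio: float | None
    p_value: float | None
    estimable: bool = True
    note: str = ""


@dataclass
class SurvivalResult:
    rsid: str
    groups: GenotypeGroups
    curves: list[KMCurve]
    logrank_chi2: float
    logrank_df: int
    logrank_p: float
    odds_ratios: list[OddsRatio]
    significant: bool
    no_events: bool = False


def load_clinical(path: str | Path) -> pd.DataFrame:
    """Clinical TSV: sample, time, event(0/1), optional snr."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    need = {"sample", "time", "event"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: clinical table needs columns {sorted(need)}")
    if (df["time"] < 0).any():
        raise ValueError(f"{path}: negative follow-up time")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    df["event"] = df["event"].astype(int)
    return df.set_index("sample")


def qc_genotypes(
    g: GenotypeMatrix,
    params: QCParams,
    sample_snr: pd.Series | dict | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Genotype QC in a fixed order.

    1. calls with confidence below ``confidence_min`` become missing;
    2. samples with signal-to-noise ratio below ``min_sample_snr`` dropped;
    3. SNPs with missing-call rate above ``max_missing_rate`` dropped;
    4. SNPs with minor-allele frequency below ``min_maf`` dropped.
    """
    report = QCReport(params=params, n_snps_in=g.n_snps)
    dosage = g.dosage.copy()

    if params.confidence_min is not None and g.confidence is not None:
        low = (g.confidence < params.confidence_min) & (dosage != MISSING)
        report.n_calls_masked = int(low.sum())
        dosage[low] = MISSING

    samples = list(g.samples)
    if params.min_sample_snr is not None and sample_snr is not None:
        snr = pd.Series(sample_snr)
        keep_mask = np.array(
            [not (s in snr.index and snr[s] < params.min_sample_snr) for s in samples]
        )
        report.n_samples_dropped_snr = int((~keep_mask).sum())
        samples = [s for s, k in zip(samples, keep_mask) if k]
        dosage = dosage[:, keep_mask]
        conf = g.confidence[:, keep_mask] if g.confidence is not None else None
    else:
        conf = g.confidence

    n_samp = len(samples)
    if n_samp == 0:
        raise ValueError("all samples removed by QC")

    missing_rate = (dosage == MISSING).sum(axis=1) / n_samp
    keep1 = missing_rate <= params.max_missing_rate
    report.n_snps_dropped_missing = int((~keep1).sum())

    keep2 = keep1.copy()
    for i in np.nonzero(keep1)[0]:
        row = dosage[i]
        called = row[row != MISSING]
        if called.size == 0:
            keep2[i] = False
            continue
        p_alt = called.sum() / (2 * called.size)
        if min(p_alt, 1 - p_alt) < params.min_maf:
            keep2[i] = False
    report.n_snps_dropped_maf = int(keep1.sum() - keep2.sum())

    kept = np.nonzero(keep2)[0]
    if kept.size == 0:
        raise ValueError("all SNPs removed by QC")
    snps = [g.snps[i] for i in kept]
    out = GenotypeMatrix(
        samples=samples,
        snps=snps,
        dosage=dosage[kept],
        alleles={r: g.alleles[r] for r in snps},
        confidence=None if conf is None else conf[kept],
    )
    report.n_snps_out = out.n_snps
    return out, report


def build_groups(g: GenotypeMatrix, rsid: str, merge_homo_freq: float = 0.10) -> GenotypeGroups:
    """Genotype groups with rare-homozygote merging.

    Major/minor is decided by allele frequency among called samples (tie:
    the alt allele is minor, so the merged class is deterministic).  If the
    rarer homozygote class frequency is below ``merge_homo_freq`` it is
    merged with the heterozygotes.
    """
    d = g.row(rsid)
    called_idx = np.nonzero(d != MISSING)[0]
    if called_idx.size == 0:
        raise ValueError(f"{rsid}: no called genotypes")
    called = d[called_idx]
    p_alt = called.sum() / (2 * called.size)
    # dosage counts the alt allele; relabel so 0 = major homozygote
    alt_is_minor = p_alt <= 0.5
    label_of = (
        {0: "hom_major", 1: "het", 2: "hom_minor"}
        if alt_is_minor
        else {2: "hom_major", 1: "het", 0: "hom_minor"}
    )
    assignment = {g.samples[j]: label_of[int(d[j])] for j in called_idx}
    sizes = {lab: 0 for lab in ("hom_major", "het", "hom_minor")}
    for lab in assignment.values():
        sizes[lab] += 1
    n_called = called.size
    merged = 0 < sizes["hom_minor"] and sizes["hom_minor"] / n_called < merge_homo_freq
    if merged:
        assignment = {
            s: ("merged_het_homminor" if lab in ("het", "hom_minor") else lab)
            for s, lab in assignment.items()
        }
        sizes = {
            "hom_major": sizes["hom_major"],
            "merged_het_homminor": sizes["het"] + sizes["hom_minor"],
        }
    sizes = {k: v for k, v in sizes.items() if v > 0}
    return GenotypeGroups(rsid=rsid, assignment=assignment, merged=merged, group_sizes=sizes)


def _km_one_group(times: np.ndarray, events: np.ndarray, label: str) -> KMCurve:
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order].astype(bool)
    event_times = np.unique(t[e])
    n = t.size
    surv, se, lo, hi = [], [], [], []
    s = 1.0
    gw = 0.0  # running sum d / (n (n - d))
    for et in event_times:
        at_risk = int((t >= et).sum())
        d = int(((t == et) & e).sum())
        s *= 1.0 - d / at_risk
        if at_risk > d:
            gw += d / (at_risk * (at_risk - d))
            # log-scale CI: S * exp(+-z * se(log S)), clipped to [0,1]
            se_log = np.sqrt(gw)
            lo.append(max(0.0, s * np.exp(-Z95 * se_log)))
            hi.append(min(1.0, s * np.exp(Z95 * se_log)))
        else:  # S hit zero; variance of log S diverges
            gw = np.inf
            lo.append(0.0)
            hi.append(0.0 if s == 0.0 else 1.0)
        surv.append(s)
        se.append(s * np.sqrt(gw) if np.isfinite(gw) else 0.0)
    return KMCurve(
        group=label,
        n=n,
        event_times=event_times.astype(float),
        survival=np.array(surv),
        greenwood_se=np.array(se),
        ci_lower=np.array(lo),
        ci_upper=np.array(hi),
    )


def km_estimate(
    times: pd.Series, events: pd.Series, groups: GenotypeGroups
) -> list[KMCurve]:
    """Product-limit survival estimate per genotype group.

    Greenwood's formula gives the variance; 0.95 bands use the log(S)
    transform and are clipped to [0, 1].
    """
    curves = []
    for label in groups.labels:
        members = [s for s, lab in groups.assignment.items() if lab == label and s in times.index]
        if not members:
            raise ValueError(f"{groups.rsid}: group {label} has no samples with clinical data")
        curves.append(
            _km_one_group(
                times.loc[members].to_numpy(float),
                events.loc[members].to_numpy(int),
                label,
            )
        )
    return curves


def logrank_test(
    times: pd.Series, events: pd.Series, groups: GenotypeGroups
) -> tuple[float, int, float, bool]:
    """k-group log-rank test; returns (chi2, df, p, no_events_flag)."""
    samples = [s for s in groups.assignment if s in times.index]
    labels = [groups.assignment[s] for s in samples]
    if len(set(labels)) < 2:
        raise ValueError(f"{groups.rsid}: needs >=2 non-empty groups")
    t = times.loc[samples].to_numpy(float)
    e = events.loc[samples].to_numpy(int)
    df = len(set(labels)) - 1
    if e.sum() == 0:
        return 0.0, df, 1.0, True
    res = multivariate_logrank_test(t, np.asarray(labels), e)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(chi2):
        return 0.0, df, 1.0, True
    return chi2, df, p, False


def logistic_or(groups: GenotypeGroups, events: pd.Series) -> list[OddsRatio]:
    """Odds ratios for observed death vs the major-homozygote reference.

    Indicator-coded logistic regression; with a merged group there is a
    single contrast.  A zero cell (no deaths or no survivors in a group)
    makes the fit separate, so that contrast is flagged non-estimable
    instead of reporting a diverged coefficient.
    """
    import statsmodels.api as sm

    samples = [s for s in groups.assignment if s in events.index]
    lab = pd.Series({s: groups.assignment[s] for s in samples})
    y = events.loc[samples].astype(int)
    contrasts = [l for l in groups.labels if l != "hom_major"]
    if "hom_major" not in groups.group_sizes:
        return [OddsRatio(c, None, None, False, "no reference group") for c in contrasts]
    out: list[OddsRatio] = []
    # per-group event tables decide estimability up front
    table = pd.crosstab(lab, y).reindex(columns=[0, 1], fill_value=0)
    bad = set(table.index[(table == 0).any(axis=1)])
    est_contrasts = [c for c in contrasts if c not in bad and "hom_major" not in bad]
    if est_contrasts:
        keep = lab.isin(est_contrasts + ["hom_major"])
        X = pd.get_dummies(lab[keep], dtype=float)[est_contrasts]
        X = sm.add_constant(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.Logit(y[keep.index[keep]], X).fit(disp=0)
                params, pvals = fit.params, fit.pvalues
            except Exception:
                params = pvals = None
        for c in contrasts:
            if c in est_contrasts and params is not None and np.isfinite(params[c]):
                out.append(OddsRatio(c, float(np.exp(params[c])), float(pvals[c])))
            else:
                out.append(OddsRatio(c, None, None, False, "fit failed" if c in est_contrasts else "zero cell"))
    else:
        out = [OddsRatio(c, None, None, False, "zero cell") for c in contrasts]
    return out


def screen(
    snps_on_array: set[str],
    g: GenotypeMatrix,
    clinical: pd.DataFrame,
    params: QCParams,
) -> tuple[list[SurvivalResult], list[str]]:
    """Per-SNP survival screen over the array/QC-passed intersection.

    Returns (results, untestable_rsids).  ``significant`` is a nominal
    log-rank test at ``params.alpha``; no multiplicity correction is
    applied (a Benjamini-Hochberg column is added downstream for the user).
    """
    present = sorted(snps_on_array & set(g.snps))
    if not present:
        warnings.warn("no array SNPs found in the genotype matrix", stacklevel=2)
        return [], []
    common = [s for s in g.samples if s in clinical.index]
    gm = g.subset_samples(common)
    times = clinical.loc[common, "time"]
    events = clinical.loc[common, "event"]
    results: list[SurvivalResult] = []
    untestable: list[str] = []
    for rsid in present:
        groups = build_groups(gm, rsid, params.merge_homo_freq)
        if not groups.testable:
            untestable.append(rsid)
            continue
        curves = km_estimate(times, events, groups)
        chi2, df, p, no_events = logrank_test(times, events, groups)
        ors = logistic_or(groups, events)
        results.append(
            SurvivalResult(
                rsid=rsid,
                groups=groups,
                curves=curves,
                logrank_chi2=chi2,
                logrank_df=df,
                logrank_p=p,
                odds_ratios=ors,
                significant=bool(p < params.alpha),
                no_events=no_events,
            )
        )
    return results, untestable


def map_to_central(
    results: list[SurvivalResult],
    links: list[TagLink],
    central: set[str],
) -> tuple[set[str], set[str], int]:
    """Resolve significant array SNPs to the central SNPs they represent.

    direct = significant SNPs that are themselves central; tagged = central
    SNPs reached through tag links from significant SNPs.  The total counts
    each central SNP once however it was reached.
    """
    sig = {r.rsid for r in results if r.significant}
    direct = sig & central
    by_tag: dict[str, set[str]] = {}
    for link in links:
        by_tag.setdefault(link.tag, set()).add(link.central)
    tagged: set[str] = set()
    for rsid in sig:
        tagged |= by_tag.get(rsid, set())
    tagged &= central
    return direct, tagged, len(direct | tagged)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1] if p.size else p


def results_to_frame(
    results: list[SurvivalResult], links: list[TagLink] | None = None
) -> pd.DataFrame:
    """Spreadsheet-style result sheet mirroring the survival-marker schema."""
    by_tag: dict[str, set[str]] = {}
    for link in links or []:
        by_tag.setdefault(link.tag, set()).add(link.central)
    rows = []
    for r in results:
        ors = {o.contrast: o for o in r.odds_ratios}
        het = ors.get("het") or ors.get("merged_het_homminor")
        hom = ors.get("hom_minor")
        rows.append(
            {
                "SurvivalMarker": r.rsid,
                "group_sizes": ";".join(f"{k}={v}" for k, v in sorted(r.groups.group_sizes.items())),
                "merged": int(r.groups.merged),
                "logrank_chi2": r.logrank_chi2,
                "logrank_p": r.logrank_p,
                "hetero_or": het.odds_ratio if het else None,
                "hetero_or_p": het.p_value if het else None,
                "homo_or": hom.odds_ratio if hom else None,
                "homo_or_p": hom.p_value if hom else None,
                "significant": int(r.significant),
                "tagged_central": ";".join(sorted(by_tag.get(r.rsid, set()))),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "SurvivalMarker", "group_sizes", "merged", "logrank_chi2", "logrank_p",
            "hetero_or", "hetero_or_p", "homo_or", "homo_or_p", "significant",
            "tagged_central",
        ],
    )
    if len(df):
        df["logrank_p_bh"] = _bh_adjust(df["logrank_p"].to_numpy(float))
    else:
        df["logrank_p_bh"] = []
    return df


def plot_km(result: SurvivalResult, path: str | Path) -> None:
    """Step plot of the group KM curves with dashed 0.95 bands."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for curve in result.curves:
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t, s, where="post", label=f"{curve.group} (n={curve.n})")
        if curve.event_times.size:
            color = ax.get_lines()[-1].get_color()
            ax.step(curve.event_times, curve.ci_lower, where="post", ls="--", lw=0.8, color=color)
            ax.step(curve.event_times, curve.ci_upper, where="post", ls="--", lw=0.8, color=color)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.set_title(f"{result.rsid}  log-rank p={result.logrank_p:.3g}")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
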