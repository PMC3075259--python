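"""Aggregation of protein-effect predictor outputs into a consensus call.

Four predictors are consumed as tables, never executed: PolyPhen and
PolyPhen-2 emit categories (benign / possibly damaging / probably damaging),
SNPs3D a real-valued score (negative = deleterious), SIFT a probability
(< 0.05 = damaging).  Per SNP, each predictor's rows are reduced by that
predictor's own rule — any damaging category counts for the PolyPhens, the
minimum score for SNPs3D, the minimum probability for SIFT — and a SNP is a
consensus functional call only when every predictor with data agrees it is
damaging (strict mode additionally requires all four to have data).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "PREDICTORS",
    "POLYPHEN_CATEGORIES",
    "PredictorRow",
    "AggregatedPrediction",
    "load_predictor_table",
    "aggregate",
    "consensus_set",
    "aggregate_to_frame",
]

PREDICTORS = ("polyphen", "polyphen2", "snps3d", "sift")
POLYPHEN_CATEGORIES = {"benign", "possibly_damaging", "probably_damaging"}
_DAMAGING_CATEGORIES = {"possibly_damaging", "probably_damaging"}
SIFT_CUTOFF = 0.05  # strictly below is damaging


@dataclass(frozen=True)
class PredictorRow:
    rsid: str
    predictor: str
    value: str | float

    def __post_init__(self) -> None:
        if self.predictor not in PREDICTORS:
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if self.predictor in ("polyphen", "polyphen2"):
            if not isinstance(self.value, str) or self.value not in POLYPHEN_CATEGORIES:
                raise ValueError(
                    f"{self.rsid}: {self.predictor} value must be one of "
                    f"{sorted(POLYPHEN_CATEGORIES)}, got {self.value!r}"
                )
        else:
            if isinstance(self.value, str):
                raise ValueError(f"{self.rsid}: {self.predictor} value must be numeric")
            if self.predictor == "sift" and not 0.0 <= float(self.value) <= 1.0:
                raise ValueError(f"{self.rsid}: sift value must be in [0,1]")


@dataclass
class AggregatedPrediction:
    rsid: str
    polyphen_calls: list[str]
    polyphen2_calls: list[str]
    snps3d_min: float | None
    sift_min: float | None
    per_method_functional: dict[str, bool | None]  # None = not evaluable
    consensus_functional: bool | None


def load_predictor_table(path: str | Path, predictor: str) -> list[PredictorRow]:
    """Two-column TSV (rsid, value) for one predictor; header optional."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: predictor table needs 2 columns")
    first = str(df.iloc[0, 0]).lower()
    if first in {"rsid", "snp", "id"}:
        df = df.iloc[1:]
    rows = []
    for rsid, raw in zip(df[0], df[1]):
        value: str | float
        if predictor in ("polyphen", "polyphen2"):
            value = str(raw).strip().lower().replace(" ", "_")
        else:
            value = float(raw)
        rows.append(PredictorRow(str(rsid), predictor, value))
    return rows


def _method_flag(predictor: str, values: list) -> bool:
    if predictor in ("polyphen", "polyphen2"):
        return any(v in _DAMAGING_CATEGORIES for v in values)
    if predictor == "snps3d":
        return min(values) < 0.0  # strictly negative is deleterious
    return min(values) < SIFT_CUTOFF  # sift; boundary value is benign


def aggregate(rows: list[PredictorRow], strict: bool = True) -> list[AggregatedPrediction]:
    """One reconciled record per rsid.

    strict=True: consensus requires all four predictors present and
    damaging.  strict=False: a predictor with no row abstains (consensus
    over the predictors that have data; a SNP with no data at all gets
    consensus None).
    """
    by_rsid: dict[str, dict[str, list]] = {}
    for row in rows:
        by_rsid.setdefault(row.rsid, {}).setdefault(row.predictor, []).append(row.value)
    out: list[AggregatedPrediction] = []
    for rsid in sorted(by_rsid):
        methods = by_rsid[rsid]
        flags: dict[str, bool | None] = {}
        for p in PREDICTORS:
            flags[p] = _method_flag(p, methods[p]) if p in methods else None
        present = [v for v in flags.values() if v is not None]
        if strict:
            consensus: bool | None = len(present) == 4 and all(present)
        else:
            consensus = all(present) if present else None
        snps3d_vals = methods.get("snps3d")
        sift_vals = methods.get("sift")
        out.append(
            AggregatedPrediction(
                rsid=rsid,
                polyphen_calls=list(methods.get("polyphen", [])),
                polyphen2_calls=list(methods.get("polyphen2", [])),
                snps3d_min=min(snps3d_vals) if snps3d_vals else None,
                sift_min=min(sift_vals) if sift_vals else None,
                per_method_functional=flags,
                consensus_functional=consensus,
            )
        )
    return out


def consensus_set(agg: list[AggregatedPrediction]) -> set[str]:
    """rsids every available predictor calls damaging."""
    return {a.rsid for a in agg if a.consensus_functional}


def aggregate_to_frame(agg: list[AggregatedPrediction]) -> pd.DataFrame:
    rows = []
    for a in agg:
        rows.append(
            {
                "rsid": a.rsid,
                "polyphen": ";".join(a.polyphen_calls),
                "polyphen2": ";".join(a.polyphen2_calls),
                "snps3d_min": a.snps3d_min,
                "sift_min": a.sift_min,
                **{f"{p}_functional": a.per_method_functional[p] for p in PREDICTORS},
                "consensus_functional": a.consensus_functional,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "rsid", "polyphen", "polyphen2", "snps3d_min", "sift_min",
            *(f"{p}_functional" for p in PREDICTORS), "consensus_functional",
        ],
    )
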