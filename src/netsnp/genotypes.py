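"""Genotype matrix container and flat-file readers.

Genotypes are diploid, unphased, biallelic.  Internally each call is stored
as the dosage of the alternate allele (0, 1, 2) with -1 for missing; the
(ref, alt) allele labels per SNP are kept alongside so calls can be written
back out as "A/G" strings.  An optional per-call confidence matrix of
identical shape supports confidence-gated QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

__all__ = ["GenotypeMatrix", "MISSING", "load_genotype_tsv", "load_confidence_tsv", "load_ped_map"]


@dataclass
class GenotypeMatrix:
    """SNPs x samples dosage matrix with allele labels.

    dosage[i, j] = copies of the alt allele of SNP i carried by sample j,
    or -1 if the call is missing.
    """

    samples: list[str]
    snps: list[str]
    dosage: np.ndarray  # (n_snps, n_samples) int8
    alleles: dict[str, tuple[str, str]]  # rsid -> (ref, alt)
    confidence: np.ndarray | None = None  # (n_snps, n_samples) float, NaN ok
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.snps), len(self.samples)):
            raise ValueError("dosage shape does not match snps x samples")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != self.dosage.shape:
                raise ValueError("confidence shape does not match dosage")
        bad = set(np.unique(self.dosage)) - {-1, 0, 1, 2}
        if bad:
            raise ValueError(f"invalid dosage values {sorted(bad)}")
        self._index = {s: i for i, s in enumerate(self.snps)}
        if len(self._index) != len(self.snps):
            raise ValueError("duplicate rsids in genotype matrix")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def row(self, rsid: str) -> np.ndarray:
        try:
            return self.dosage[self._index[rsid]]
        except KeyError:
            raise KeyError(f"SNP {rsid!r} not in genotype matrix") from None

    def subset_snps(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self._index[r] for r in keep]
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=list(keep),
            dosage=self.dosage[idx].copy(),
            alleles={r: self.alleles[r] for r in keep},
            confidence=None if self.confidence is None else self.confidence[idx].copy(),
        )

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        pos = {s: j for j, s in enumerate(self.samples)}
        idx = [pos[s] for s in keep]
        return GenotypeMatrix(
            samples=list(keep),
            snps=list(self.snps),
            dosage=self.dosage[:, idx].copy(),
            alleles=dict(self.alleles),
            confidence=None if self.confidence is None else self.confidence[:, idx].copy(),
        )

    def calls_frame(self) -> pd.DataFrame:
        """Render back to "A/G"-style strings (rows = SNPs, cols = samples)."""
        out = np.empty(self.dosage.shape, dtype=object)
        for i, rsid in enumerate(self.snps):
            ref, alt = self.alleles[rsid]
            alt = alt or "."
            lookup = {0: f"{ref}/{ref}", 1: f"{ref}/{alt}", 2: f"{alt}/{alt}", -1: "./."}
            for j in range(self.n_samples):
                out[i, j] = lookup[int(self.dosage[i, j])]
        return pd.DataFrame(out, index=pd.Index(self.snps, name="rsid"), columns=self.samples)


def _parse_call(cell: str, rsid: str) -> tuple[str, str] | None:
    cell = cell.strip()
    if cell in {"./.", ".", "", "NA", "-"}:
        return None
    sep = "/" if "/" in cell else "|" if "|" in cell else None
    if sep is None:
        raise ValueError(f"{rsid}: unparseable genotype call {cell!r}")
    a, b = cell.split(sep, 1)
    if a == "." or b == ".":
        return None
    return a, b


def load_genotype_tsv(path: str | Path, confidence_path: str | Path | None = None) -> GenotypeMatrix:
    """Load the genotype TSV: rows = SNPs, columns = samples, cells "A/G".

    Allele labels per SNP are inferred from the observed calls; more than
    two distinct alleles at a locus is an error.  Ref = lexicographically
    first allele (downstream statistics do not depend on this labeling).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    samples = [str(c) for c in df.columns]
    snps = [str(r) for r in df.index]
    dosage = np.full((len(snps), len(samples)), MISSING, dtype=np.int8)
    alleles: dict[str, tuple[str, str]] = {}
    for i, rsid in enumerate(snps):
        calls = [_parse_call(str(c), rsid) for c in df.iloc[i]]
        observed = sorted({a for call in calls if call for a in call})
        if len(observed) > 2:
            raise ValueError(f"{rsid}: more than two alleles observed: {observed}")
        if len(observed) == 2:
            ref, alt = observed
        elif len(observed) == 1:
            ref, alt = observed[0], ""
        else:
            ref, alt = "", ""
        alleles[rsid] = (ref, alt)
        for j, call in enumerate(calls):
            if call is None:
                continue
            dosage[i, j] = sum(1 for a in call if alt and a == alt)
    conf = None
    if confidence_path is not None:
        conf = load_confidence_tsv(confidence_path, snps, samples)
    return GenotypeMatrix(samples, snps, dosage, alleles, conf)


def load_confidence_tsv(path: str | Path, snps: list[str], samples: list[str]) -> np.ndarray:
    """Confidence matrix of identical shape to the genotype TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.map(str)
    if list(df.index) != list(snps) or [str(c) for c in df.columns] != list(samples):
        df = df.reindex(index=snps, columns=samples)
    return df.to_numpy(dtype=float)


def load_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Minimal PLINK text PED/MAP reader.

    MAP: chrom, rsid, cM, bp.  PED: FID IID PAT MAT SEX PHENO then two
    allele columns per SNP; "0" is missing.
    """
    snps: list[str] = []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{map_path}: MAP line needs 4 fields")
            snps.append(parts[1])
    samples: list[str] = []
    raw_calls: list[list[tuple[str, str] | None]] = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * len(snps):
                raise ValueError(f"{ped_path}: PED row has wrong field count")
            samples.append(parts[1])
            geno = parts[6:]
            row = []
            for k in range(len(snps)):
                a, b = geno[2 * k], geno[2 * k + 1]
                row.append(None if a == "0" or b == "0" else (a, b))
            raw_calls.append(row)
    dosage = np.full((len(snps), len(samples)), MISSING, dtype=np.int8)
    alleles: dict[str, tuple[str, str]] = {}
    for i, rsid in enumerate(snps):
        observed = sorted({a for row in raw_calls if row[i] for a in row[i]})
        if len(observed) > 2:
            raise ValueError(f"{rsid}: more than two alleles in PED")
        ref = observed[0] if observed else ""
        alt = observed[1] if len(observed) == 2 else ""
        alleles[rsid] = (ref, alt)
        for j, row in enumerate(raw_calls):
            call = row[i]
            if call is not None:
                dosage[i, j] = sum(1 for a in call if alt and a == alt)
    return GenotypeMatrix(samples, snps, dosage, alleles)
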