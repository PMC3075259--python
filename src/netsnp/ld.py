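"""Allele frequencies, pairwise linkage disequilibrium and tag-SNP selection.

The r² statistic between two biallelic loci is D² / (pA·qA·pB·qB) with
D = p(AB) − p(A)p(B), where p(AB) is the frequency of the two-locus
haplotype carrying both index alleles.  From unphased diploid genotypes the
haplotype frequencies are not directly observable — the double heterozygote
is phase-ambiguous — so they are estimated by an EM algorithm over the 3x3
genotype table (the classical two-locus haplotype EM, as used by PLINK's
--r2).  A squared Pearson correlation of allele dosages is provided as a
fast cross-check; the two agree asymptotically under Hardy-Weinberg
equilibrium.

Tag-SNP selection keeps every (candidate, central) pair whose r² meets the
threshold; the mapping is many-to-many by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

__all__ = [
    "AlleleStats",
    "LDResult",
    "TagLink",
    "allele_stats",
    "em_haplotype_freqs",
    "pairwise_r2",
    "select_tags",
    "snp_universe",
]

EM_TOL = 1e-10
EM_MAX_ITER = 1000


@dataclass(frozen=True)
class AlleleStats:
    rsid: str
    n_called: int
    freq_ref: float
    freq_alt: float
    maf: float
    call_rate: float


@dataclass(frozen=True)
class LDResult:
    snp_a: str
    snp_b: str
    r2: float
    hap_freqs: tuple[float, float, float, float]  # (f00, f01, f10, f11)
    n_used: int
    method: str


@dataclass(frozen=True)
class TagLink:
    tag: str
    central: str
    r2: float


class MonomorphicError(ValueError):
    """Raised when a statistic is undefined because a locus has no variation."""


def allele_stats(g: GenotypeMatrix, rsid: str) -> AlleleStats:
    """Allele frequencies from called genotypes (2 alleles per diploid call)."""
    d = g.row(rsid)
    called = d[d != MISSING]
    n = called.size
    if n == 0:
        raise MonomorphicError(f"{rsid}: no called genotypes (monomorphic/uncallable)")
    freq_alt = float(called.sum()) / (2 * n)
    freq_ref = 1.0 - freq_alt
    return AlleleStats(
        rsid=rsid,
        n_called=n,
        freq_ref=freq_ref,
        freq_alt=freq_alt,
        maf=min(freq_ref, freq_alt),
        call_rate=n / g.n_samples,
    )


def _genotype_table(da: np.ndarray, db: np.ndarray) -> tuple[np.ndarray, int]:
    """3x3 cross-table of dosages over samples called at both loci."""
    keep = (da != MISSING) & (db != MISSING)
    a, b = da[keep].astype(np.int64), db[keep].astype(np.int64)
    table = np.zeros((3, 3), dtype=np.int64)
    np.add.at(table, (a, b), 1)
    return table, int(keep.sum())


def em_haplotype_freqs(table: np.ndarray) -> tuple[np.ndarray, int]:
    """Two-locus haplotype-frequency EM on a 3x3 unphased genotype table.

    Returns ((f00, f01, f10, f11), n_iterations).  f_ij is the frequency of
    the haplotype carrying allele i at the first locus and j at the second.
    Only the double heterozygote n[1,1] is phase-ambiguous; its expected
    split between cis (00/11) and trans (01/10) phases is recomputed from
    the current frequencies each iteration.  Initialised at linkage
    equilibrium, which also resolves the D = ±|D| likelihood symmetry in a
    direction-free way (r² does not depend on it).
    """
    n = table.sum()
    if n == 0:
        raise MonomorphicError("empty genotype table")
    two_n = 2.0 * n
    # marginal alt-allele frequencies
    p_a = (table[1, :].sum() + 2 * table[2, :].sum()) / two_n
    p_b = (table[:, 1].sum() + 2 * table[:, 2].sum()) / two_n
    f = np.array(
        [(1 - p_a) * (1 - p_b), (1 - p_a) * p_b, p_a * (1 - p_b), p_a * p_b]
    )  # f00 f01 f10 f11
    n_dh = table[1, 1]
    # haplotype counts fully determined by the unambiguous cells
    base = np.array(
        [
            2 * table[0, 0] + table[0, 1] + table[1, 0],
            2 * table[0, 2] + table[0, 1] + table[1, 2],
            2 * table[2, 0] + table[2, 1] + table[1, 0],
            2 * table[2, 2] + table[2, 1] + table[1, 2],
        ],
        dtype=float,
    )
    it = 0
    for it in range(1, EM_MAX_ITER + 1):
        cis = f[0] * f[3]
        trans = f[1] * f[2]
        denom = cis + trans
        x = n_dh * (cis / denom) if denom > 0 else n_dh / 2.0
        new = base + np.array([x, n_dh - x, n_dh - x, x])
        new /= two_n
        if np.max(np.abs(new - f)) < EM_TOL:
            f = new
            break
        f = new
    return f, it


def _r2_from_haps(f: np.ndarray) -> float:
    p_a = f[2] + f[3]
    p_b = f[1] + f[3]
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        raise MonomorphicError("r2 undefined (zero variance)")
    d = f[3] - p_a * p_b
    return float(min(1.0, d * d / denom))


def pairwise_r2(g: GenotypeMatrix, a: str, b: str, method: str = "em") -> LDResult:
    """Pairwise r² between two SNPs from unphased genotypes.

    method "em": haplotype-frequency EM then D²/(pA·qA·pB·qB);
    method "allelic_corr": squared Pearson correlation of allele dosages.
    Samples missing at either locus are excluded (pairwise-complete).
    """
    if method not in {"em", "allelic_corr"}:
        raise ValueError(f"unknown r2 method {method!r}")
    da, db = g.row(a), g.row(b)
    table, n_used = _genotype_table(da, db)
    # canonical orientation so r2(a,b) == r2(b,a) bit-for-bit
    flipped = b < a
    if flipped:
        table = table.T.copy()
    first, second = (b, a) if flipped else (a, b)
    two_n = 2 * n_used if n_used else 0
    for name, margin in ((first, table.sum(axis=1)), (second, table.sum(axis=0))):
        alt = margin[1] + 2 * margin[2]
        if n_used == 0 or alt == 0 or alt == two_n:
            raise MonomorphicError(f"{name}: r2 undefined (zero variance)")
    f, _ = em_haplotype_freqs(table)
    if method == "em":
        r2 = _r2_from_haps(f)
    else:
        keep = (da != MISSING) & (db != MISSING)
        r = np.corrcoef(da[keep].astype(float), db[keep].astype(float))[0, 1]
        r2 = float(r * r)
    if flipped:  # hap freqs back in (a, b) orientation: swap f01 <-> f10
        f = f[[0, 2, 1, 3]]
    return LDResult(a, b, r2, tuple(float(x) for x in f), n_used, method)


def select_tags(
    central: set[str],
    candidates: set[str],
    g: GenotypeMatrix,
    threshold: float = 0.8,
    method: str = "em",
) -> tuple[list[TagLink], int]:
    """All (candidate, central) pairs with r² >= threshold.

    A SNP may appear in both sets; self-links are excluded.  Pairs whose r²
    is undefined (monomorphic, no overlapping calls) are skipped and
    counted.  Returns (links sorted by (tag, central), n_skipped).
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    present = set(g.snps)
    links: list[TagLink] = []
    skipped = 0
    for tag in sorted(candidates & present):
        for cen in sorted(central & present):
            if tag == cen:
                continue
            try:
                res = pairwise_r2(g, tag, cen, method=method)
            except MonomorphicError:
                skipped += 1
                continue
            if res.r2 >= threshold:
                links.append(TagLink(tag, cen, res.r2))
    if skipped:
        warnings.warn(f"{skipped} SNP pair(s) had undefined r2 and were skipped", stacklevel=2)
    return links, skipped


def snp_universe(central: set[str] | int, tags: set[str] | int, overlap: int | None = None):
    """Central/tag universe counts: (n_central, n_tags, n_both, n_union).

    Accepts either the actual identifier sets, or bare counts plus the
    overlap size (useful when only the set sizes are known); the union is
    then n_central + n_tags − n_both by inclusion-exclusion.
    """
    if isinstance(central, int):
        if overlap is None or not isinstance(tags, int):
            raise ValueError("count form needs n_central, n_tags and overlap")
        n_c, n_t, n_b = central, tags, overlap
    else:
        n_c, n_t = len(central), len(tags)
        n_b = len(central & tags)
    return n_c, n_t, n_b, n_c + n_t - n_b


def links_to_frame(links: list[TagLink]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "tag": [l.tag for l in links],
            "central": [l.central for l in links],
            "r2": [l.r2 for l in links],
        }
    )
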