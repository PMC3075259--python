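"""SNP consequence annotation and the central-SNP filter.

A *central SNP* is a variant in a focal gene's coding or regulatory region
(coding, splice site, UTR).  The filter works by exclusion: SNPs whose
consequence annotations are all in the exclusion set — upstream, downstream,
intronic, within a non-coding gene, or an HGMD mutation record — are dropped;
everything else is retained.  Consequence terms follow an ENSEMBL-v59-style
closed vocabulary; unknown terms are a parse error, not a silent pass.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "ConsequenceTerm",
    "EXCLUDED_TERMS",
    "SNPRecord",
    "CentralSNP",
    "load_snp_table",
    "filter_central",
    "central_snp_count_by_gene",
]


class ConsequenceTerm(enum.Enum):
    ESSENTIAL_SPLICE_SITE = "ESSENTIAL_SPLICE_SITE"
    SPLICE_SITE = "SPLICE_SITE"
    STOP_GAINED = "STOP_GAINED"
    STOP_LOST = "STOP_LOST"
    NON_SYNONYMOUS_CODING = "NON_SYNONYMOUS_CODING"
    SYNONYMOUS_CODING = "SYNONYMOUS_CODING"
    FRAMESHIFT_CODING = "FRAMESHIFT_CODING"
    FIVE_PRIME_UTR = "5PRIME_UTR"
    THREE_PRIME_UTR = "3PRIME_UTR"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    INTRONIC = "INTRONIC"
    WITHIN_NON_CODING_GENE = "WITHIN_NON_CODING_GENE"
    HGMD_MUTATION = "HGMD_MUTATION"

    @classmethod
    def parse(cls, text: str) -> "ConsequenceTerm":
        """Normalise case/spacing/underscores and look the term up."""
        norm = text.strip().upper().replace(" ", "_").replace("-", "_")
        norm = {"5_PRIME_UTR": "5PRIME_UTR", "3_PRIME_UTR": "3PRIME_UTR"}.get(norm, norm)
        for term in cls:
            if term.value == norm:
                return term
        raise ValueError(f"unknown consequence term {text!r}")


#: Default exclusion set; user-overridable in filter_central.
EXCLUDED_TERMS: frozenset[ConsequenceTerm] = frozenset(
    {
        ConsequenceTerm.UPSTREAM,
        ConsequenceTerm.DOWNSTREAM,
        ConsequenceTerm.INTRONIC,
        ConsequenceTerm.WITHIN_NON_CODING_GENE,
        ConsequenceTerm.HGMD_MUTATION,
    }
)


@dataclass
class SNPRecord:
    rsid: str
    gene: str
    chrom: str
    pos: int  # 1-based
    alleles: tuple[str, str]
    consequences: list[tuple[str, ConsequenceTerm]]  # (transcript_id, term)
    peptide_change: tuple[str, str, int] | None = None

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.pos < 1:
            raise ValueError(f"{self.rsid}: position must be >= 1")
        if self.alleles[0] == self.alleles[1]:
            raise ValueError(f"{self.rsid}: alleles must differ")
        if not self.consequences:
            raise ValueError(f"{self.rsid}: needs >=1 consequence")


@dataclass
class CentralSNP:
    record: SNPRecord
    retained_consequences: list[tuple[str, ConsequenceTerm]]

    def __post_init__(self) -> None:
        if not self.retained_consequences:
            raise ValueError(f"{self.record.rsid}: no retained consequence")

    @property
    def rsid(self) -> str:
        return self.record.rsid

    @property
    def gene(self) -> str:
        return self.record.gene


_COLUMNS = ["rsid", "gene", "chrom", "pos", "alleles", "transcript", "consequence"]


def load_snp_table(path: str | Path) -> list[SNPRecord]:
    """Load the SNP annotation TSV.

    Schema: rsid, gene, chrom, pos, alleles (REF/ALT), transcript,
    consequence (semicolon-joined terms per transcript), optional aa_change
    ("R/P:72").  Rows sharing (rsid, gene) are aggregated into one record
    with all transcript consequences, preserving file order (the first row's
    transcript is the "first transcript").  Exact duplicate
    (rsid, gene, transcript) rows are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")

    records: dict[tuple[str, str], SNPRecord] = {}
    seen_tx: set[tuple[str, str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key3 = (row.rsid, row.gene, row.transcript)
        if key3 in seen_tx:
            warnings.warn(f"{path}:{i}: duplicate row for {key3}, skipped", stacklevel=2)
            continue
        seen_tx.add(key3)
        try:
            terms = [
                (row.transcript, ConsequenceTerm.parse(t))
                for t in str(row.consequence).split(";")
                if t
            ]
        except ValueError as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
        aa = getattr(row, "aa_change", None)
        pep = None
        if isinstance(aa, str) and aa and aa.lower() != "nan":
            change, _, posn = aa.partition(":")
            ref_aa, _, alt_aa = change.partition("/")
            pep = (ref_aa, alt_aa, int(posn) if posn else -1)
        key = (row.rsid, row.gene)
        if key in records:
            records[key].consequences.extend(terms)
            if pep and records[key].peptide_change is None:
                records[key].peptide_change = pep
        else:
            ref, _, alt = str(row.alleles).partition("/")
            records[key] = SNPRecord(
                rsid=row.rsid,
                gene=row.gene,
                chrom=str(row.chrom),
                pos=int(row.pos),
                alleles=(ref, alt),
                consequences=terms,
                peptide_change=pep,
            )
    return list(records.values())


def filter_central(
    records: list[SNPRecord] | list[CentralSNP],
    mode: str = "any_transcript",
    excluded: frozenset[ConsequenceTerm] = EXCLUDED_TERMS,
) -> list[CentralSNP]:
    """Apply the consequence-exclusion filter.

    ``any_transcript``: keep a SNP iff at least one consequence on any
    transcript is outside the exclusion set.  ``first_transcript``: judge
    only the terms on the first-listed transcript.  The retained record
    carries only non-excluded terms among those considered, so filtering is
    idempotent.  Accepts CentralSNP input (uses the underlying records).
    """
    if mode not in {"any_transcript", "first_transcript"}:
        raise ValueError(f"unknown mode {mode!r}")
    out: list[CentralSNP] = []
    for rec in records:
        if isinstance(rec, CentralSNP):
            rec = rec.record
        if mode == "first_transcript":
            first_tx = rec.consequences[0][0]
            considered = [c for c in rec.consequences if c[0] == first_tx]
        else:
            considered = rec.consequences
        retained = [c for c in considered if c[1] not in excluded]
        if retained:
            out.append(CentralSNP(rec, retained))
    return out


def central_snp_count_by_gene(
    central: list[CentralSNP],
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-gene central-SNP counts plus a multi-gene report.

    An rsid annotated in two overlapping genes counts once per gene; such
    rsids are listed in the second return value so the double-counting is
    visible rather than silent.
    """
    if not central:
        return pd.Series(dtype=int, name="n_central"), pd.DataFrame(
            columns=["rsid", "genes"]
        )
    df = pd.DataFrame({"gene": [c.gene for c in central], "rsid": [c.rsid for c in central]})
    counts = df.groupby("gene")["rsid"].count().rename("n_central")
    multi = (
        df.groupby("rsid")["gene"]
        .apply(lambda g: ";".join(sorted(set(g))))
        .reset_index()
        .rename(columns={"gene": "genes"})
    )
    multi = multi[multi["genes"].str.contains(";")]
    return counts, multi.reset_index(drop=True)
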