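"""Synthetic inputs for the whole pipeline.

Everything the pipeline consumes can be generated here with controllable
statistical structure: random pathway/PPI snapshots, SNP annotation tables,
genotypes drawn from two-locus haplotype pools with an exact population r²,
per-call confidences, exponential survival with a genotype-dependent hazard,
and four predictor score tables.  One integer seed drives every
sub-generator through independently derived streams, so a single component
can be regenerated without perturbing the others.

The generator emulates structure, not content: gene names, coordinates and
allele-frequency spectra are arbitrary, and genotypes are sampled under
Hardy-Weinberg equilibrium (two independent haplotype draws per sample) —
the same assumption the EM r² estimator relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import ConsequenceTerm, EXCLUDED_TERMS
from .genotypes import MISSING, GenotypeMatrix
from .network import InteractionEdge, PathwayRecord

__all__ = [
    "SimConfig",
    "gen_network_snapshot",
    "gen_haplotype_pool",
    "gen_genotypes_and_clinical",
    "gen_snp_annotations",
    "gen_predictor_tables",
    "write_snapshot_files",
    "simulate_all",
]

_ALLELES = np.array(list("ACGT"))

# stream ids so sub-generators are independent of each other
_STREAMS = {"network": 1, "genotypes": 2, "clinical": 3, "annotation": 4, "predictors": 5}


@dataclass
class SimConfig:
    """Study conditions for the synthetic world.

    Defaults mirror a 209-sample SNP-array survival cohort with a median
    survival of about a year (time unit: months), light missingness and
    mostly high-confidence calls.
    """

    seed: int = 0
    # network snapshot
    n_genes: int = 60
    n_pathways: int = 8
    pathway_size_range: tuple[int, int] = (4, 12)
    ppi_mean_degree: float = 2.0
    # genotypes
    n_samples: int = 209
    n_snps: int = 40
    ld_pairs: list[tuple[str, str, float, float, float]] = field(default_factory=list)
    # each entry: (tag_rsid, central_rsid, target_r2, maf_a, maf_b)
    missing_rate: float = 0.02
    confidence_noise: float = 0.05
    # survival
    baseline_hazard: float = 1.0 / 12.0
    censoring_rate: float = 0.3
    effect_snp: tuple[str, float] | None = None  # (rsid, hazard ratio per minor allele)
    # annotation / predictors
    central_fraction: float = 0.5
    predictor_damaging_fraction: float = 0.2
    predictor_concordant: bool = True

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 1:
            raise ValueError("degenerate sizes")
        if not 0 <= self.missing_rate < 1 or not 0 <= self.censoring_rate < 1:
            raise ValueError("rates must be in [0,1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid pathway_size_range")
        if hi > self.n_genes:
            raise ValueError("pathway size exceeds gene universe")
        for tag, cen, r2, ma, mb in self.ld_pairs:
            if not 0 <= r2 <= 1:
                raise ValueError(f"target_r2 {r2} out of [0,1] for pair {tag}/{cen}")
            for m in (ma, mb):
                if not 0 < m <= 0.5:
                    raise ValueError(f"maf {m} out of (0, 0.5] for pair {tag}/{cen}")
        if self.effect_snp is not None and self.effect_snp[1] <= 0:
            raise ValueError("hazard_ratio must be positive")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def gen_network_snapshot(
    cfg: SimConfig,
) -> tuple[list[PathwayRecord], list[InteractionEdge], dict[str, str]]:
    """Random pathway memberships, an Erdos-Renyi-style PPI graph with the
    configured mean degree, and an accession->symbol alias table."""
    rng = cfg.rng("network")
    genes = _gene_names(cfg.n_genes)
    lo, hi = cfg.pathway_size_range
    pathways = []
    for k in range(cfg.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        pathways.append(
            PathwayRecord(f"PW{k + 1:03d}", f"pathway_{k + 1}", "custom", frozenset(members.tolist()))
        )
    edges: list[InteractionEdge] = []
    if cfg.n_genes > 1:
        p = min(1.0, cfg.ppi_mean_degree / (cfg.n_genes - 1))
        for i in range(cfg.n_genes):
            for j in range(i + 1, cfg.n_genes):
                if rng.random() < p:
                    edges.append(InteractionEdge(genes[i], genes[j], "sim"))
    aliases = {f"ACC{i + 1:05d}": g for i, g in enumerate(genes)}
    return pathways, edges, aliases


def gen_haplotype_pool(maf_a: float, maf_b: float, target_r2: float) -> np.ndarray:
    """Four haplotype frequencies (f00, f01, f10, f11) with exact r².

    Allele 1 at each locus is the minor allele (frequency = maf).  The
    coupling D is taken positive: D = sqrt(r² · pA qA pB qB), so minor
    alleles co-occur.  Infeasible (maf, r²) combinations raise with the
    attainable bound named.
    """
    for m in (maf_a, maf_b):
        if not 0 < m <= 0.5:
            raise ValueError(f"maf must be in (0, 0.5], got {m}")
    if not 0 <= target_r2 <= 1:
        raise ValueError("target_r2 must be in [0,1]")
    pa, pb = maf_a, maf_b
    qa, qb = 1 - pa, 1 - pb
    d_max = min(pa * qb, qa * pb)
    r2_max = d_max**2 / (pa * qa * pb * qb)
    if target_r2 > r2_max + 1e-12:
        raise ValueError(
            f"target_r2={target_r2} infeasible for maf ({maf_a}, {maf_b}); "
            f"maximum attainable r2 is {r2_max:.6f}"
        )
    d = min(np.sqrt(target_r2 * pa * qa * pb * qb), d_max)
    f = np.array([qa * qb + d, qa * pb - d, pa * qb - d, pa * pb + d])
    f[np.abs(f) < 1e-15] = 0.0
    return f


def _draw_pair_dosages(
    rng: np.random.Generator, f: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two unphased dosage vectors from 2n haplotype draws out of pool f."""
    haps = rng.choice(4, size=(n, 2), p=f)  # index 0..3 = (00,01,10,11)
    a = (haps // 2).sum(axis=1)  # allele at locus A is the high bit
    b = (haps % 2).sum(axis=1)
    return a.astype(np.int8), b.astype(np.int8)


def gen_genotypes_and_clinical(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame]:
    """Genotypes + confidences, clinical survival table, and the truth table.

    LD-pair SNPs are drawn as two haplotypes per sample from their pool;
    remaining SNPs are independent binomial(2, maf) draws with maf uniform
    on (0.05, 0.5).  Survival times are exponential with hazard
    baseline · HR^(minor-allele dosage at the effect SNP); censoring is an
    independent exponential tuned so the expected censored fraction equals
    ``censoring_rate``.  Missingness and sub-threshold confidences are
    injected after the hazard is computed, so a masked call never changes
    the biology.  Returns (matrix, clinical, per-SNP truth frame).
    """
    rng_g = cfg.rng("genotypes")
    rng_c = cfg.rng("clinical")
    n = cfg.n_samples
    samples = [f"S{i:04d}" for i in range(1, n + 1)]

    snp_names: list[str] = []
    rows: list[np.ndarray] = []
    truth_rows: list[dict] = []
    for tag, cen, r2, ma, mb in cfg.ld_pairs:
        pool = gen_haplotype_pool(ma, mb, r2)
        da, db = _draw_pair_dosages(rng_g, pool, n)
        for name, dos, maf in ((tag, da, ma), (cen, db, mb)):
            snp_names.append(name)
            rows.append(dos)
            truth_rows.append({"rsid": name, "maf": maf, "ld_partner": cen if name == tag else tag, "target_r2": r2})
    n_indep = cfg.n_snps - len(snp_names)
    for k in range(max(0, n_indep)):
        maf = float(rng_g.uniform(0.05, 0.5))
        snp_names.append(f"rs{len(snp_names) + 1:05d}")
        rows.append(rng_g.binomial(2, maf, size=n).astype(np.int8))
        truth_rows.append({"rsid": snp_names[-1], "maf": maf, "ld_partner": "", "target_r2": np.nan})
    dosage_true = np.vstack(rows)

    # allele letters; the stored dosage counts the minor ("alt") allele
    alleles = {}
    for name in snp_names:
        ref, alt = rng_g.choice(_ALLELES, size=2, replace=False)
        alleles[name] = (str(ref), str(alt))

    # survival from the true genotypes
    hazard = np.full(n, cfg.baseline_hazard)
    if cfg.effect_snp is not None:
        rsid, hr = cfg.effect_snp
        if rsid not in snp_names:
            raise ValueError(f"effect_snp {rsid!r} not among generated SNPs")
        dos = dosage_true[snp_names.index(rsid)].astype(float)
        hazard = cfg.baseline_hazard * hr**dos
    t_event = rng_c.exponential(1.0 / hazard)
    if cfg.censoring_rate > 0:
        c_rate = cfg.baseline_hazard * cfg.censoring_rate / (1 - cfg.censoring_rate)
        t_cens = rng_c.exponential(1.0 / c_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    snr = rng_c.normal(10.0, 2.0, size=n).clip(min=0.1)
    clinical = pd.DataFrame({"sample": samples, "time": time, "event": event, "snr": snr}).set_index("sample")

    # observation noise: missingness and per-call confidence.
    # confidence_noise is the fraction of calls whose confidence falls below
    # the conventional 0.95 acceptance threshold.
    dosage = dosage_true.copy()
    miss = rng_g.random(dosage.shape) < cfg.missing_rate
    dosage[miss] = MISSING
    low = rng_g.random(dosage.shape) < cfg.confidence_noise
    confidence = np.where(
        low,
        rng_g.uniform(0.5, 0.95, size=dosage.shape),
        rng_g.uniform(0.95, 1.0, size=dosage.shape),
    )

    gm = GenotypeMatrix(samples, snp_names, dosage, alleles, confidence)
    return gm, clinical, pd.DataFrame(truth_rows)


def gen_snp_annotations(cfg: SimConfig, genes: list[str], snps: list[str]) -> pd.DataFrame:
    """Annotation table assigning each SNP to a gene and a consequence term.

    About ``central_fraction`` of the SNPs get a retained (coding/UTR/
    splice) term; the rest get a term from the exclusion set.
    """
    rng = cfg.rng("annotation")
    retained = sorted(t.value for t in ConsequenceTerm if t not in EXCLUDED_TERMS)
    excluded = sorted(t.value for t in EXCLUDED_TERMS)
    rows = []
    for i, rsid in enumerate(snps):
        gene = genes[int(rng.integers(len(genes)))]
        central = rng.random() < cfg.central_fraction
        term = (retained if central else excluded)[int(rng.integers(len(retained) if central else len(excluded)))]
        ref, alt = rng.choice(_ALLELES, size=2, replace=False)
        rows.append(
            {
                "rsid": rsid,
                "gene": gene,
                "chrom": str(1 + i % 22),
                "pos": int(rng.integers(1, 10_000_000)),
                "alleles": f"{ref}/{alt}",
                "transcript": f"T{i + 1:04d}",
                "consequence": term,
            }
        )
    return pd.DataFrame(rows)


def gen_predictor_tables(snps: list[str], cfg: SimConfig) -> dict[str, pd.DataFrame]:
    """Four predictor tables with a configured concordantly-damaging subset.

    The first round(fraction · n) SNPs (after a seeded shuffle) are damaging
    under every predictor's rule; the rest are benign everywhere in
    concordant mode, or damaging under a random strict subset of predictors
    otherwise (so they can never reach consensus).
    """
    rng = cfg.rng("predictors")
    order = list(snps)
    rng.shuffle(order)
    n_dam = int(round(cfg.predictor_damaging_fraction * len(order)))
    damaging = set(order[:n_dam])
    tables: dict[str, list] = {p: [] for p in ("polyphen", "polyphen2", "snps3d", "sift")}
    for rsid in snps:
        if rsid in damaging:
            dam = {"polyphen", "polyphen2", "snps3d", "sift"}
        elif cfg.predictor_concordant:
            dam = set()
        else:
            k = int(rng.integers(0, 3))  # at most 2 dissenting methods
            dam = set(rng.choice(["polyphen", "polyphen2", "snps3d", "sift"], size=k, replace=False))
        for p in ("polyphen", "polyphen2"):
            cat = ("probably_damaging" if rng.random() < 0.5 else "possibly_damaging") if p in dam else "benign"
            tables[p].append({"rsid": rsid, "value": cat})
        tables["snps3d"].append(
            {"rsid": rsid, "value": round(-rng.uniform(0.1, 2.0) if "snps3d" in dam else rng.uniform(0.0, 2.0), 4)}
        )
        tables["sift"].append(
            {"rsid": rsid, "value": round(rng.uniform(0.0, 0.049) if "sift" in dam else rng.uniform(0.05, 1.0), 4)}
        )
    return {p: pd.DataFrame(rows) for p, rows in tables.items()}


def write_snapshot_files(cfg: SimConfig, outdir: str | Path) -> dict[str, str]:
    """Generate everything and write the flat files plus a truth manifest.

    Returns a manifest dict of file paths (also serialised to
    ``manifest.json`` in the output directory).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pathways, edges, aliases = gen_network_snapshot(cfg)
    with open(outdir / "pathways.gmt", "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.pathway_id, p.name, *sorted(p.members)]) + "\n")
    with open(outdir / "ppi.sif", "w") as fh:
        for e in sorted(edges, key=lambda e: e.key()):
            fh.write(f"{e.a}\t{e.source}\t{e.b}\n")
    with open(outdir / "aliases.tsv", "w") as fh:
        for acc in sorted(aliases):
            fh.write(f"{acc}\t{aliases[acc]}\n")

    gm, clinical, truth = gen_genotypes_and_clinical(cfg)
    gm.calls_frame().to_csv(outdir / "genotypes.tsv", sep="\t")
    pd.DataFrame(gm.confidence, index=pd.Index(gm.snps, name="rsid"), columns=gm.samples).round(4).to_csv(
        outdir / "confidence.tsv", sep="\t"
    )
    clinical.round(4).to_csv(outdir / "clinical.tsv", sep="\t")
    truth.to_csv(outdir / "truth_snps.tsv", sep="\t", index=False)

    genes = _gene_names(cfg.n_genes)
    ann = gen_snp_annotations(cfg, genes, gm.snps)
    ann.to_csv(outdir / "snp_annotations.tsv", sep="\t", index=False)

    preds = gen_predictor_tables(gm.snps, cfg)
    for name, df in preds.items():
        df.to_csv(outdir / f"pred_{name}.tsv", sep="\t", index=False, header=False)

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "files": {
            "pathways": "pathways.gmt",
            "ppi": "ppi.sif",
            "aliases": "aliases.tsv",
            "genotypes": "genotypes.tsv",
            "confidence": "confidence.tsv",
            "clinical": "clinical.tsv",
            "annotations": "snp_annotations.tsv",
            "predictors": {p: f"pred_{p}.tsv" for p in preds},
            "truth": "truth_snps.tsv",
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


simulate_all = write_snapshot_files
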