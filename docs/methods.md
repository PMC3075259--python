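# Methods

This note documents the statistical procedures implemented in `netsnp`, the
assumptions behind them, the parameters that matter, and what the synthetic
data generator does and does not emulate.

## Focal-gene expansion

A gene g is *focal* for a query set Q iff g shares at least one pathway with
some q ∈ Q, or the PPI snapshot contains a direct edge {g, q}. Pathway
topology is not used — membership only — and PPI edges are undirected and
deduplicated; self-loops are kept in the data model but never create focal
genes. Query genes are always present in the output, flagged `is_query`, so
both conventions (counting queries among focal genes or not) are recoverable
downstream; a query found in no snapshot is returned with empty provenance
rather than dropped, making "gene not in any database" an explicit, visible
outcome. Source-distribution counts classify non-query focal genes as
pathway-only / PPI-only / both, counting each gene once.

Accession-to-symbol aliasing is a user-supplied two-column table; matching of
pathway names is exact and case-insensitive. We deliberately avoid fuzzy
matching: determinism beats convenience in a pipeline whose outputs feed set
arithmetic.

## Central-SNP filter

The consequence vocabulary is a closed, ENSEMBL-v59-style term set; unknown
terms are a parse error, because silently passing a novel term through an
exclusion filter would invert its meaning. A SNP is *central* iff at least
one of its transcript consequences lies outside the exclusion set
{UPSTREAM, DOWNSTREAM, INTRONIC, WITHIN_NON_CODING_GENE, HGMD_MUTATION}.
Two modes exist: `any_transcript` (default) judges all transcripts;
`first_transcript` judges only the first-listed transcript, mirroring
annotation interfaces that return one transcript per SNP. The any-transcript
result is always a superset of the first-transcript result, and the filter
is idempotent because retained records carry only non-excluded terms.

## Pairwise r² by two-locus EM

For loci A and B with index alleles a, b, the four haplotype frequencies
f = (f00, f01, f10, f11) are estimated from the 3×3 unphased genotype table.
All cells except the double heterozygote decompose uniquely into haplotypes;
the n11 double heterozygotes split between cis (ab/00) and trans phase with
expected cis fraction f00·f11 / (f00·f11 + f01·f10), recomputed each
iteration (standard two-locus EM, the same estimator behind PLINK's
haplotype-based `--r2`). Numerical choices:

- initialisation at linkage equilibrium (products of observed allele
  frequencies), which also resolves the D = ±|D| likelihood symmetry
  without a tie-break since r² is sign-free;
- convergence when max |Δf| < 1e-10, cap 1000 iterations;
- samples missing at either locus are excluded pairwise (`n_used` reported);
- monomorphic loci raise an error ("r² undefined, zero variance") rather
  than returning 0 or NaN;
- the genotype table is put in a canonical orientation (lexicographic rsid
  order) before the EM so that r²(a,b) equals r²(b,a) bit-for-bit.

The allele-frequency margins of the maximum-likelihood solution equal the
observed allele frequencies (allele dosages are fully observed), which the
test suite exploits: a brute-force grid search over the single free
parameter f11 maximising the multinomial likelihood reproduces the EM r² to
1e-6 on 20-sample fixtures. The dosage-correlation estimator
(`allelic_corr`) is kept as an asymptotically equivalent cross-check under
Hardy–Weinberg equilibrium.

Tag selection evaluates every (candidate, central) pair and keeps links with
r² ≥ threshold (default 0.8, the conventional tagging cutoff; always
user-settable). The mapping is many-to-many; self-links are excluded and
undefined pairs are skipped with a warning count. Output is monotone
non-increasing in the threshold.

## Predictor aggregation

Each predictor is reduced per SNP by its own rule: PolyPhen / PolyPhen-2 are
damaging if *any* call is possibly or probably damaging (all calls are kept
in the record); SNPs3D takes the minimum score and is damaging iff strictly
negative; SIFT takes the minimum probability and is damaging iff strictly
below 0.05 (the boundary values 0.0 and 0.05 are benign). The consensus call
requires every method to agree. In strict mode (default) a SNP missing from
any predictor's table cannot reach consensus — predictor snapshots cover
different dbSNP builds, and we treat absence as "not evaluable" rather than
as non-dissent; the lenient mode (consensus over the methods with data) is a
flag.

## Survival screen

QC runs in a fixed order, and the QC report echoes every threshold used:
(1) calls with confidence < `confidence_min` (default 0.95) become missing;
(2) samples with signal-to-noise ratio < `min_sample_snr` (default 5) are
dropped; (3) SNPs with missing rate > `max_missing_rate` (default 0.05) are
dropped; (4) SNPs with MAF < `min_maf` (default 0.05) are dropped. The
confidence rule is implemented as confidence-gated call acceptance; the
alternative reading (imputing values back into low-confidence missing calls)
would require raw array intensities that a genotype table does not carry.

Genotype groups: major/minor is decided by allele frequency among called
samples (on a tie the alternate allele is deemed minor, a deterministic
tie-break). If the rarer homozygote class is below `merge_homo_freq`
(default 0.10) of called samples it is merged with the heterozygotes —
small homozygote groups otherwise produce unstable Kaplan–Meier tails. A
SNP with fewer than two non-empty groups is reported untestable, not
dropped silently.

Kaplan–Meier curves are the product-limit estimate computed from the
risk-set table, with Greenwood's variance and 0.95 bands on the log-S scale
(S·exp(±1.96·se(log S))), clipped to [0, 1]; when S reaches zero the band
collapses to zero. The implementation is checked against lifelines'
product-limit estimate in the tests. The log-rank test is delegated to
lifelines (`multivariate_logrank_test`, df = k−1); zero events across all
groups yields χ² = 0, p = 1 with a flag. Odds ratios for the observed-death
indicator use statsmodels logistic regression with indicator coding against
the major-homozygote reference; on a 2×2 table this equals the
cross-product ratio exactly, and a zero cell is reported as non-estimable
(separation) rather than as a diverged coefficient. The outcome is the bare
event indicator over follow-up — the natural coding when no other is
specified — and this assumption is surfaced here deliberately.

Significance is a nominal log-rank p < α (default 0.05), with no
multiplicity correction by design; a Benjamini–Hochberg column is emitted
alongside so users can apply one. Back-mapping partitions significant array
SNPs into direct central hits and tags, resolves tags through the link
table, and counts each central SNP once.

## Synthetic data

The generator produces every input with controllable structure from one
integer seed; sub-generators draw from independently derived streams so one
component can be regenerated without perturbing others.

- **Network snapshot**: pathway memberships drawn uniformly (sizes uniform
  in `pathway_size_range`), PPI edges Erdős–Rényi with the configured mean
  degree, plus an accession alias table.
- **Genotypes**: LD pairs are two haplotype draws per sample from a pool
  with *exact* population r² (D = +√(r²·pA qA pB qB); infeasible (MAF, r²)
  combinations are rejected with the attainable bound named); remaining
  SNPs are independent binomial(2, maf) draws with maf ~ U(0.05, 0.5).
  Hardy–Weinberg sampling is deliberate: it is the same assumption the EM
  estimator makes, keeping simulator and estimator coherent.
- **Survival**: exponential event times with hazard
  baseline · HR^(minor-allele dosage at the effect SNP), independent
  exponential censoring tuned so the expected censored fraction equals
  `censoring_rate`. Missingness and low-confidence calls are injected
  *after* the hazard is computed, so observation noise never changes the
  biology. `confidence_noise` is the fraction of calls whose confidence
  falls below the conventional 0.95 acceptance threshold.
- **Predictors**: a seeded fraction of SNPs is damaging concordantly under
  all four rules; the rest are benign everywhere (concordant mode) or
  damaging under a strict subset of methods (discordant mode), so they can
  never reach consensus.

Defaults are chosen to mirror a 209-sample SNP-array survival cohort with a
median survival of about a year (baseline hazard 1/12 per month,
censoring 0.3, missingness 0.02, 5 % low-confidence calls). What the
generator does **not** emulate: real pathway/interactome topology, genomic
coordinates, allele-frequency spectra, LD beyond designated pairs,
population structure, or non-proportional hazards. Tests passing on this
world therefore demonstrate the correctness and calibration of the
machinery (estimators recover the parameters that generated the data; null
rejection rates match α), not robustness to the messiness of real cohorts.

## Problem sizes used in the checks

The statistical acceptance checks run at sizes where the asymptotics they
invoke are comfortably valid while remaining quick: r² round-trips average
six generated pairs of n = 1000 samples per target; the log-rank null
calibration permutes group labels 2000 times on an 80-sample dataset and
compares the rejection count with the exact binomial 95 % band; screen
power uses 200 replicates at n = 300 and hazard ratio 3; the null
false-positive rate uses 1000 independent null SNPs at n = 200. The
EM-vs-grid oracle uses 20-sample fixtures, where phase ambiguity is common
enough to exercise the EM meaningfully.

## Known limitations

- LD is pairwise only; no multi-marker tagging or phasing beyond the
  two-locus EM.
- The logistic odds ratio ignores follow-up time (it models the bare death
  indicator); Cox regression is out of scope.
- Biallelic SNPs only; more than two observed alleles at a locus is an
  input error.
- The consequence vocabulary is frozen; annotation sources using other term
  sets must be mapped before loading (the exclusion list itself is
  configurable).
- Excel output is intentionally absent; all sheets are TSV.
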