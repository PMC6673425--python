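# Methods

## The model

One gene-tissue feature is a pair (gene, expression panel) with cis-eQTL
weights `w` over the SNPs of its locus. Given GWAS z-scores `Z` and the
SNP-correlation matrix `D` of the locus, the association statistic is the
LD-adjusted weighted z-score

    z_TWAS = w'Z / sqrt(w'Dw).

Its null model is `Z ~ MVN(0, D)`, under which `w'Z` has variance `w'Dw`
and z_TWAS is exactly standard normal for any fixed `w`. The two-sided
p-value is `2 * Phi_bar(|z|)` computed with the normal survival function;
a naive `1 − CDF` evaluation cancels to zero near |z| ≈ 6–8, i.e. at the
magnitude of genuine top hits, so the stable tail is load-bearing, not a
nicety. Sidedness is fixed as two-sided because the reference z/p pairs
the package reproduces are consistent only with the two-sided normal.

The genomic inflation factor is `lambda = median(z²) / q`, where
`q = 0.454936…` is the median of the 1-df chi-square; it is the only
scalar definition that maps a z-vector to a single calibration number
without distributional fitting.

## Permutation filter

A strongly associated GWAS locus with extensive LD can carry *any* gene
tested there to significance through chance co-localization of eQTLs and
GWAS signal. The filter conditions on the observed GWAS effects: entries
of `w` are re-assigned uniformly at random to the locus's SNP positions
(`Z` and `D` fixed), z_TWAS is recomputed, and extremeness is two-sided
(`|z_perm| ≥ |z_obs|`). The empirical p uses the add-one estimator
`(n_extreme + 1)/(n_perm + 1)`, which is never zero and is bounded below
by `1/(n_perm + 1)`; the default is 5000 permutations. The published
FUSION implementation does not document its exact shuffling scheme, so
the uniform position shuffle here is an explicit, documented choice.
Per-feature random streams are derived by hashing (master seed, gene,
panel), making results independent of scan order and parallel layout.

## Harmonization, alignment, regularization

Sumstats are matched to the reference panel's allele orientation: exact
match keeps z, swapped effect/other flips its sign (and re-orients the
stored alleles, making the operation idempotent), strand-ambiguous A/T
and C/G pairs are dropped by default (their orientation is undecidable
from summary data), and irreconcilable pairs are dropped, never silently
kept. All six outcome categories are counted and the counts provably
partition the input.

Each feature's (w, Z, D) is restricted to the intersection of the three
SNP sets, ordered as in the LD matrix (one source of truth). Features
retaining less than `min_overlap_fraction` (default 0.5) of their SNPs
are skipped with a logged reason — a statistic over a near-empty weight
vector is not the feature's statistic. LD matrices read from files are
projected onto the PSD cone by eigenvalue clipping at `eps = 1e-8`
(numerical floor only) followed by diagonal rescaling to 1, so `w'Dw` is
guaranteed nonnegative; features with `w'Dw ≤ 1e-10` are reported as
failed rather than dropped silently.

## DE filter and intersection

The expression profile contributes genes with fold change above 1.2 and
raw p below 0.05 (strict inequalities, matching the convention the
thresholds were printed with). The default `symmetric` mode treats
down-regulation as DE via `max(FC, 1/FC) > 1.2`, since candidate genes
of interest include depressed ones; `up_only` reads the rule literally.
Intersection with the significant features (p_TWAS < 0.05 and
permutation p < 0.05) happens at the feature level first and is then
collapsed to unique genes — for any input where a gene's panels all pass
or all fail this matches collapse-first, and feature-level-first keeps
the per-panel bookkeeping (multi-panel genes, per-panel counts) exact.
Gene matching is by case-insensitive exact symbol; alias resolution is
out of scope because no mapping resource is part of the inputs.

## Enrichment

Per term with universe size N, term size K, query size n and overlap k,
the p-value is the one-sided hypergeometric upper tail `P(X ≥ k)`
(`scipy.stats.hypergeom.sf`), verified against exact rational enumeration
for all populations up to N = 12. The EASE variant replaces k by
`max(k−1, 0)` before the tail — a conservative score that sends
single-gene overlaps to p = 1 and never falls below the plain p. The
default universe is the union of all term members; the annotation source
is user-supplied GMT, and because the annotation database behind the
published term list is proprietary and version-drifting, those printed
enrichment p-values are treated as structural examples, not reproduction
targets. Benjamini–Hochberg q-values are available but off by default;
the primary call is raw p < 0.05.

## Synthetic studies

The generator emulates the statistical structure the analysis assumes,
with planted truth:

- **LD**: AR(1), `D[i,j] = rho^|i−j|`, the minimal structure that makes
  `w'Dw ≠ w'w` (so the LD adjustment is actually exercised); positive
  definite for |rho| < 1. Default rho 0.6, 20 SNPs per locus.
- **GWAS**: `Z ~ MVN(sqrt(n) · D·beta, D)` — the standard summary-
  statistics likelihood — one draw per locus, n = 446,696 (the scale of
  the source GWAS: 40,585 cases + 406,111 controls).
- **Causal genes**: beta = `effect · w / sqrt(w'Dw)` at the feature's
  SNPs, giving `E[z_TWAS] = sqrt(n) · effect` in closed form. The default
  effect 0.01 puts causal features at E[z] ≈ 6.7, the magnitude of a
  genuine top hit. Causal genes are sampled from panel-covered genes and
  planted through their first covering panel's weights.
- **Panels**: three labels (METSIM, NTR, YFS), 40 genes each drawn from
  an 80-gene universe (one gene per locus), sparse standard-normal
  weights (30% of SNPs). 120 features total — a deliberately desk-scale
  stand-in for a transcriptome-wide panel; all counts are configurable.
- **DE table**: 20 cases / 20 controls, within-group log2 noise sd 0.5,
  truly DE genes shifted by 1.0 log2 unit with random sign (fold change
  2, comfortably above the 1.2 filter — a robustly DE transcript). A
  fixed shift rather than a random-magnitude one keeps the truth labels
  meaningful: every labelled DE gene is genuinely recoverable, so
  recovery sensitivity measures the pipeline, not the label noise. The
  DE truth set is the causal genes plus an equal number of non-causal
  decoys, so specificity is exercised too.
- **Annotations**: 50 random terms of size 5–30 plus one planted term
  exactly equal to the causal∩DE gene set; universe = all genes.
- **Harmonization fodder**: 10% of sumstats rows are stored with swapped
  alleles and negated z; the reference-allele table restores them, so a
  run without harmonization visibly degrades.

Everything is driven by one master seed; identical configs produce
byte-identical files.

What the generator does **not** emulate: individual-level genotypes,
realistic allele-frequency spectra, population structure, overlapping or
block-structured loci, probe-set-to-gene mapping, expression covariates
(age, sex, batch), or the multi-model weight training of real panels.
Passing tests therefore demonstrate the statistical machinery is correct
under the stated model, not that real-data idiosyncrasies are handled.

## Numerical and design choices

- PSD clip eps 1e-8; w'Dw tolerance 1e-10; LD symmetry/diagonal tolerance
  1e-8; permutation tie comparison uses a 1e-9 absolute slack so exact
  re-arrangements (the identity permutation, symmetric ties) always count
  as extreme.
- Duplicate sumstats SNP ids keep the first occurrence (deterministic),
  with a warning and an audit count.
- Ties in ranked outputs break alphabetically (genes) or by term id, so
  every table is reproducible byte-for-byte.
- Result-table p-values are written in scientific notation with 6
  significant digits; the round-trip preserves gene/panel identity and p
  to that precision.

## Problem sizes

The bundled analyses run at desk scale by choice: the null calibration
uses 100,000 simulated loci of 12 SNPs (12-SNP AR(0.6) LD, 5 nonzero
weights), the permutation-vs-enumeration check uses 20,000 shuffles of
3-SNP features, and the recovery study is the 120-feature default
configuration with 5000 permutations per feature. Together they complete
in seconds on one CPU.

## Known limitations

- Only one LD locus may host a feature; features spanning loci are
  skipped, not split.
- No conditional/joint analysis, colocalization, or fine-mapping on top
  of the marginal scan.
- The permutation scheme is the uniform position shuffle described
  above; alternatives (e.g. magnitude-preserving rotations) are not
  implemented.
- GMT carries no native category field; the `CATEGORY|Name` description
  convention used here is package-specific.
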