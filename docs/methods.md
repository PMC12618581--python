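# Methods

## Differential expression: fold-change-threshold test with variance moderation

Counts are library-normalized by TMM (trimmed mean of M-values): the
reference sample is the one whose 75th-percentile CPM is closest to the
mean 75th percentile; M and A statistics are computed on genes positive in
both sample and reference; both tails are trimmed (30 % on M, 5 % on A,
the standard trim fractions, exposed as arguments since nothing forces
them); the factor is 2 to the inverse-variance-weighted mean of the
surviving M values, and factors are rescaled to geometric mean 1 (enforced
to 1e-9). Reference ties break to the lowest column index.

Each (species, stage) contrast compares sexual and vegetative-control
replicates on x = log₂(CPM + 0.5); the 0.5 offset bounds the variance of
low counts at the cost of slightly attenuating large fold changes. The
test is a threshold ("TREAT"-style) test: t = max(|log₂FC| − τ, 0)/se with
τ = 1 log₂ unit, two-sided p from a t reference; when |log₂FC| ≤ τ the
statistic floors at 0 and p = 1.

With 3 replicates per condition a per-gene Welch variance has ~4 degrees
of freedom, and no effect in the design's realistic range can reach the
multiplicity-corrected significance levels (~1e-4) that genome-wide
screening demands — the per-gene variance must borrow strength across
genes, exactly as small-replicate RNA-seq practice does. The default
engine therefore moderates the pooled per-gene variance toward a lowess
mean–variance trend with an empirical-Bayes prior: prior degrees of
freedom d₀ are estimated by matching the variance of log residual
variances to trigamma(d/2) + trigamma(d₀/2) (solved by Newton iterations
on the trigamma inverse), and the posterior variance is
(d₀s₀² + ds²)/(d₀ + d) with d + d₀ total degrees of freedom (capped at
1e6 when the variances are consistent with a single shared value). The
plain Welch variant remains available (`moderate=False`). Under a
complete-null simulation the moderated test's p-values are uniform enough
that BH screening passes essentially nothing (verified in the acceptance
suite), while planted log₂FC = 3 effects are recovered genome-wide.
Externally produced DE tables (e.g. from a negative-binomial GLM engine)
can be fed to all downstream steps unchanged.

## Stage-wise testing

Per gene, stage p-values are Sidak-combined (1 − (1 − min p)^k over the k
stages tested), BH-adjusted across genes and screened at FDR α = 0.05.
For the R of m genes passing screening, stage p-values are Holm-adjusted
within the gene and confirmed at α·R/m. Both adjustments are vectorised
over the gene × stage matrix; equivalence with statsmodels'
`multipletests` is asserted in the test suite. A stage can never be
significant for a gene that failed screening.

## Marker discovery

"Expressed in a species" always means CPM strictly above 1 in at least 3
samples of that species (0.1 and 2 in the shallow-assembly preset, where
metatranscriptome coverage is far lower). Step 2 requires every expressed
member gene to be significant-up in ≥ 1 stage with no significant
downregulation anywhere — per-stage universality is deliberately not
required, since different species traverse the stages at different rates.
Ranking pools log₂FC over all significant (gene, stage, species)
observations (a species-mean-of-means variant is available); ties break
by family id so output is order-invariant.

"Negligible atlas expression" is operationalised as
max non-sexual TPM ≤ 2 OR sexual-mean/max-non-sexual ≥ 5 — a configurable
OR-rule, since the original judgement is inherently visual; every
candidate carries its max-TPM, sexual-mean and fold-separation statistics
plus a pass/fail/untestable label, so the rule is auditable. Candidates
without a member gene in the atlas species are marked untestable rather
than silently passed.

Control families must be present in ≥ 3 of the 4 reference species, be
single-copy (at most one duplication in one species), and never be
significantly upregulated during sex; each target marker is matched
greedily, in rank order, to the nearest unused eligible family by
Euclidean distance in (log₁₀(mean non-sexual TPM + 1e-3), CV) space.

## Homolog mapping

HMMER3 per-sequence tblout tables are parsed (fields 1, 3, 5, 6; domain
tables unsupported) and filtered at bit score ≥ 50 (inclusive) and
E-value < 1e-10 (strict), optionally restricted to diatom source taxa.

Midpoint rooting finds the deepest tip pair exhaustively and splits the
edge under the half-diameter point; a dangling root edge length is
discarded as meaningless. (dendropy's own `reroot_at_midpoint` roots at
the nearest node rather than the true mid-edge point in the installed
version, so the rooting is done in-package and checked against an
all-pairs path-length oracle.)

Clade selection is a deterministic surrogate for a manual judgement:
after midpoint rooting, the maximal clades containing ≥ 1 reference tip
and zero outgroup tips — and, when a support cutoff is set, with adequate
support on their subtending branch — are selected, and query tips inside
them are returned. With a support cutoff, branches on the path from the
clade root to a query must also clear the cutoff, otherwise an unreliably
attached query inside a well-supported clade would be accepted; branches
without a support value are not penalised, and the default cutoff is 0
(off) since no numeric cutoff is prescribed for the original judgement.
Multifurcations are allowed and count as clades.

## Event calling

MAG × sample cells with < 10,000 mapped reads or < 1000 genes with ≥ 1
read are discarded (strict readings of both bounds). MAG-level TPM is the
length-normalized rate scaled to 1e6 within the MAG's genes in that
sample, so marker expression is measured relative to the MAG's own
transcriptional activity and MAG abundance cancels.

Per-marker thresholds are the 95th percentile (linear interpolation
between order statistics, NumPy's default) of member-gene TPM pooled over
all vegetative samples of all reference species; per-species pooling is a
documented alternative. A marker passes in a cell when any homolog has
TPM strictly above the threshold and ≥ 2 reads; a MAG with several
homologs of one marker passes if any of them passes. A cell is an event
when SPO11-2 passes and ≥ 2 panel markers pass (panels: M1–M4 for raphid
pennates; M3 + SIG1 + DNAH9/11/17 + DNAH5/8 + DRC4 for centrics; MAGs of
other clades are excluded with a log entry). A lenient SPO11-2 mode
(≥ 1 read, no threshold) exists behind a switch because the prefilter's
stringency is ambiguous in the source protocol; the strict mode is the
default and the one exercised by the tests. The control audit applies the
identical rule with PC as positive control and C1–C4 as markers.

## Abundance association

Genus relative abundance is the fraction of total diatom reads per
sample. Signal vs non-signal samples are compared with a two-sided
Mann–Whitney U (exact when n₁n₂ ≤ 10,000 and tie-free, tie-corrected
normal approximation otherwise), Bonferroni-corrected over genera ×
amplicon regions. Groups are disjoint by default (the printed group sizes
of such analyses indicate disjoint groups); a signal-vs-all mode exists.
The effect size is the rank-biserial correlation 2U/(n₁n₂) − 1 with a
bootstrap percentile 95 % CI (10,000 resamples, seeded) — one defensible
choice among several, since no formula is canonical for this statistic.
ASV tables drop unidentified kingdoms/infrakingdoms, Metazoa,
Embryophyceae and Streptophyta, then ASVs below 1e-7 relative abundance
(the fraction form of 1e-5 %), and recompute relative abundances.

## Synthetic data: what it emulates, and what it does not

The multi-species generator plants `n_planted_markers` (default 3)
single-copy diatom-specific families among 500, present in all 4 species,
upregulated by log₂FC ~ U(3, 6) in the sexual samples of all stages;
control families stay flat. Baseline expression is log-normal (σ = 1.5 in
log₁₀ TPM — a realistic bulk dynamic range) with the background scaled so
nominal values are true TPM; counts are negative binomial with dispersion
0.1 (typical bulk overdispersion) at ~2e6 reads per library, 3 replicates
per condition. Marker vegetative baselines are 10 TPM and controls
15 TPM: low but quantifiable background, chosen because a 3-replicate
design has no power over genes with ~2 control reads, and consistent with
markers showing "low background" rather than zero vegetative expression.
The atlas generator emits 40 conditions × 3 replicates of vegetative
expression with near-silent markers (0.05 TPM) and optional leaky markers
at a configured fraction of their sexual mean, to stress the specificity
filter.

The MAG generator (20 MAGs × 40 samples, 2000 housekeeping genes per MAG,
depth log-normal around 2e5 reads with 5 % under-sequenced cells, 10 %
sexual cells) draws non-sexual marker TPM from the very log-normal
calibration distribution used for thresholding (median 100 TPM,
σ_ln = 1) — so the 95th-percentile rule has a designed ~5 % per-draw
exceedance, the hook for the control audit — and sexual-cell markers
strictly above threshold (threshold × 2^U(1, 4)). Read counts are
multinomial on TPM × length compositions, so count-derived TPM
reproduces the drawn values.

Not emulated: mapping/quantification error, within-family sequence
divergence (assignments are given, not inferred), species-correlated
library composition, batch effects, and any phylogenetic realism beyond
a reference clade with planted inside/outside queries. Passing tests
therefore demonstrate the statistical machinery and rules, not robustness
to upstream bioinformatic noise.

## Expected values of the audited quantities

The exceedance of a type-7 (linear interpolation) 95th-percentile
estimate from n pooled values by a fresh draw has expectation
E_n = (n + 1 − h)/(n + 1), h = 0.95(n − 1) + 1 — 5.64 % at the default
calibration pool of n = 140 (matching a 6 + 119 + 9 + 8 per-species
sample inventory), converging to 5 % as n grows. Because each marker's
threshold is a single quantile estimate per study, observed per-marker
rates also carry threshold-estimation variance ≈ E_n(1 − E_n)/n per
study; the acceptance checks therefore test the pooled rate against E_n
with compound variance E_n(1 − E_n)(1/n_draws + 1/(n · n_studies)) at the
99 % level. The expected false control-event rate per non-sexual cell is
P(PC passes) × P(≥ 2 of 4 controls pass) ≈ 0.056 × 0.017 ≈ 1e-3, which is
what the audit measures.

## Numerical choices and degenerate inputs

Zero-variance genes get a 1e-8 floor on the standard error; identical
groups yield log₂FC = 0 and p = 1 by the threshold-floor convention.
Zero-library samples, all-zero TPM compositions, empty p-value sets,
trees with all-zero branch lengths, empty Mann–Whitney groups and marker
families absent from every reference species all raise errors naming the
offending object. Correlations between (species, stage) cells are
reported only with ≥ 3 shared families; Pearson p-values use the t
approximation with n − 2 degrees of freedom.

## Problem sizes

The test and acceptance runs use the generators' default study sizes —
4 species × (4 stages × 3 + 3) libraries × 500 families, 2000-gene null
panels, 20 MAGs × 40 samples × ~2000 genes, 100 trees — across 20 seeds
for the recovery and audit rates; the full suite and the acceptance
script each complete in well under a minute on one CPU.

## Known limitations

The discovery step assumes families upregulated in *all* stages they are
expressed in; markers confined to one brief stage in one species are
penalised by step 2 exactly as in the original rule. The stage-wise
confirmation level α·R/m is the standard choice for the named procedure
but the original analysis does not print its confirmation level. Control
matching minimises a two-dimensional distance with equal weight on
log-mean and CV; other weightings are defensible. The clade-selection
surrogate resolves reference/outgroup conflicts deterministically and may
differ from expert manual curation on pathological topologies.
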