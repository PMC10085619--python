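# Methods

## Signature model

All fold changes are stored on the linear scale; log2 input is accepted at
the I/O boundary only and exponentiated on load, because the published
cutoffs the pipeline implements are printed on the linear scale
(1.50 / 0.67 for the signature, 2.0 / 0.5 for DEGs) and a single internal
scale avoids double-conversion bugs. Threshold comparisons are inclusive
(≥, ≤); a fold change of exactly 1 can belong to neither set by
construction (up requires > 1, down requires < 1 thresholds). Gene symbols
are upper-cased on load — mixed-case duplicates are a common artifact of
re-annotated public expression tables — and duplicated symbols are an
error by default (optionally resolved by keeping the largest |log2 FC|).

## Reversal scoring

The signed overlap table counts only genes carrying a direction in *both*
signatures: a = up∩up, b = up∩down, c = down∩up, d = down∩down. Genes
unchanged in either contrast are excluded. This construction makes
"smallest odds ratio ⇔ strongest reversal" literally true; it is an
assumption of this implementation, since connectivity-style services do
not publish their table construction. The Fisher test is two-sided by
default (one-sided options exposed); the odds ratio used for ranking
applies the Haldane–Anscombe +0.5 correction to all four cells whenever
any cell is zero, while the raw cross-ratio (possibly 0 or ∞) is reported
alongside but never ranked on.

Spearman's rho uses midranks (average ranks for ties) and defaults to the
full intersection of measured genes; a signature-restricted universe is
available because the appropriate universe is a judgment call. The p-value
is the usual t-approximation, with an optional seeded permutation p
(default 10,000 permutations) recommended below ~10 shared genes.

The composite ranking — ascending rho, ties by ascending odds ratio, then
agent id — is an artifact decision to make screens deterministic and
reproducible; no composite order is published for this class of screen.
Benjamini–Hochberg adjustment is applied across the agents of one screen,
separately for the Fisher and Spearman p-values. Agents sharing no
signature gene with the disease cannot be scored and are reported in a
separate exclusion list rather than silently dropped; every library agent
appears exactly once across ranking and exclusions.

A treatment contrast is labelled a *reversal* when rho < 0 with p below a
configurable α (default 0.05), *concordant* when rho > 0 with p < α, and
*indeterminate* otherwise.

## Fold-change estimation

FC = (mean_case + ε) / (mean_control + ε) per gene, with ε = 1 by default
and arithmetic means (geometric optional). The estimator is deliberately
minimal: the signature definitions are FC-threshold-only, so dispersion
modelling and DE p-values add nothing downstream, and the pseudocount
keeps the ratio stable for tiny control groups. Externally computed DE
tables (e.g. a DESeq2 results export with a `log2FoldChange` column) can
be imported instead. Optional library-size normalization scales each
sample to a fixed total of 10⁶ (counts per million). A fixed target —
rather than the mean library size — is what makes FC exactly invariant to
per-sample and global depth factors in the presence of the pseudocount.

## Over-representation analysis

p = P(X ≥ k) for X hypergeometric with population = universe, successes =
set members, draws = DEGs∩universe; one-sided (over-representation only),
BH across the sets of a collection. The universe defaults to the union of
the collection's sets; supplying the measured-gene universe is
recommended and supported. Weighted enrichment variants are out of scope;
the output is plain unweighted ORA.

## Synthetic data generator

The generator emulates the statistical structure the pipeline consumes,
not the full realism of RNA-seq counts:

- **Expression**: per-gene baseline log2 expression ~ Normal(5, 2); a
  `de_fraction` subset (default 10%) is shifted in cases by
  log2 FC ~ Normal(1.5, 0.5) with random sign; i.i.d. Normal(0, 0.5)
  log2 noise per sample; values exponentiated to the linear scale.
  Log-normal expression with Gaussian log-noise was chosen over
  negative-binomial counts because the downstream logic is FC-threshold
  only — FC structure, not count dispersion, is what matters here.
- **Agents** (defaults: 200 agents, 20 reversers, 20 mimickers): reversers
  draw log2 FC = −β·(disease log2 FC) + Normal(0, 0.3) with β = 0.8;
  mimickers use +β; nulls permute the disease effect magnitudes across
  genes with random signs, so they match the disease profile's marginal
  effect distribution while carrying no gene-level relationship.
- **Gene sets**: uniform draws from the universe; optionally one
  designated set over-samples a given DEG list five-fold.
- **Correlated contrasts**: a Gaussian copula plants a target Spearman
  rho, using r = 2·sin(π·ρ/6) to convert the target rank correlation to
  the Pearson correlation of the underlying bivariate normal.

All draws derive from one seed through independent named substreams, so
e.g. enlarging the agent library never perturbs the expression matrix.
No analytic form is used for a noisy reverser's expected rho; recovery
tests compare against empirical large-n runs instead.

What passing tests on these data do **not** show: robustness to count
overdispersion, outlier samples, batch effects, correlated genes, or
normalization artifacts of real expression data — none of which the
generator produces.

## Numerical and design choices

- Scoring a default screen (5,000 genes × 200 agents) takes ~1 s; the
  analysis scripts and the acceptance script use this scale throughout,
  which is ample for the planted effects to be detected with margin.
- Floating-point table outputs carry 6 significant digits; tests compare
  at stated tolerances, never string equality.
- The null calibration of the ORA test uses a transcriptome-scale universe
  (20,000 genes, 2,000 draws, sets of 1,000–2,000). At small counts the
  hypergeometric p-value is coarsely discrete and the strict-inequality
  rejection rule is visibly conservative (attained level ≈ 0.036 at a
  1,000-gene universe); at this scale the attained level is ≈ 0.045–0.047,
  close to nominal, so the calibration check measures the test rather
  than the discreteness of its support.
- Tumor measurements enforce width ≤ length by sorting with a warning,
  since the caliper formula width²·length·0.5 is not symmetric and axis
  conventions vary between labs.
- Pipeline runs are config-driven (pydantic-validated, unknown keys
  rejected, explicit seed mandatory) and write a manifest with config
  echo, versions and SHA-256 checksums; identical configs reproduce
  byte-identical outputs.

## Known limitations

- The Fisher/Spearman scoring reproduces the *method class*, not any
  proprietary screening service's exact agent ranking: contingency
  construction, sidedness, gene universe and ranking rule of such services
  are unpublished, so all four are explicit, documented options here.
- The FC estimator has no variance model; with very small groups the
  signature inherits the noise of the group means.
- ORA treats genes as exchangeable (no weighting, no gene length or
  expression bias correction).
- The generator's independence assumptions (genes i.i.d., noise i.i.d.)
  make recovery tests optimistic relative to correlated real data.
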