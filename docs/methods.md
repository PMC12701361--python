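# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of the package.

## Phenotype model

Each assay stratum (assay, cell line, batch, and LPS dose for the NF-kB
reporter) is reduced to a per-batch log2 fold change: the arithmetic mean
of raw replicate readouts for a target siRNA divided by the control-siRNA
mean, log2-transformed. Raw readouts are modeled as multiplicative
(log-normal), so the log2 transform yields an additive model. Control rows
are identically zero and are excluded from model fitting.

Per assay (and dose), log2FC is fit with a cell-means design — one fixed
coefficient per (siRNA, cell line) combination, equivalent to the full
siRNA x cell-line interaction — plus a batch random intercept, by REML
(`statsmodels MixedLM`). The coefficient is then directly the estimated
marginal mean for that combination. A `separate_lines` switch fits each
cell line on its own instead; in balanced designs the estimates coincide.

Inference uses a z (normal) reference on the marginal mean rather than
Satterthwaite or Kenward–Roger degrees of freedom. At the replicate counts
of these designs (9–21 wells per combination) the difference is a few
percent in the p value at most; the z reference keeps the implementation
library-agnostic. BH correction is applied within each assay/dose family —
the family a screen reader sees in one results panel — and a hit is
`p_adj <= alpha` (default 0.05).

Degenerate fits fall back to ordinary least squares with a logged warning:
a single batch, a batch variance estimate at the zero boundary (< 1e-8), a
non-converged optimizer, or the singular linear algebra that REML produces
when the realized batch-level variation is exactly zero. The OLS path uses
the same z reference.

One modeling caveat is intrinsic to the design rather than to the
implementation: because every target in a batch shares the control-siRNA
denominator, per-batch log2FC values are positively correlated within a
batch even when the generating batch effect is zero. The batch random
intercept absorbs exactly this shared-control noise; it is why the mixed
model is preferred over OLS even for plate designs with no visible batch
drift.

Knockdown efficiency from qPCR uses 2^-ddCt with a designated reference
gene: dCt = mean Ct(target) − mean Ct(reference) per condition, ddCt =
dCt(knockdown) − dCt(control), fold change = 2^-ddCt, percent knockdown =
100 (1 − fold change).

## Proteomic differential abundance

Samples identifying fewer than `min_proteins` proteins (default 6100) are
excluded before testing; the QC report records per-sample counts and
median log2 intensity, and groups left with fewer than two replicates are
flagged untestable.

Per protein, a one-way ANOVA spans all siRNA groups *within one cell
line* (control plus all knockdowns), pooling the within-group variance
across that background only; the two backgrounds differ enough at baseline
that pooling across them would inflate the error term. Each
knockdown-vs-control contrast gets a Tukey HSD p value: the studentized
range statistic `q = |difference| / sqrt(s2/2 (1/n1 + 1/n2))`
(Tukey–Kramer form for unbalanced groups) referred to the studentized
range distribution with k groups and the pooled error df. The studentized
range tail probability is evaluated by fixed-order Gauss–Legendre
quadrature of the classical double integral (96 nodes over the
standardized range, 48 over the scale), which agrees with an adaptive
reference to ~1e-12 and is fast enough to test thousands of proteins; at
k = 2 the exact t-distribution identity is used. log2FC is the group-mean
difference. Missing values are handled complete-case per protein
(samples missing that protein are dropped for that protein only), which
keeps all statistics invariant to sample ordering. Proteins with zero
pooled variance are flagged and excluded from BH adjustment and from the
enrichment ranking. BH families are per contrast across proteins.

## Preranked enrichment engine

The ranking statistic is the per-protein log2FC (or, for the reference
signature, the per-protein disease effect), sorted descending with stable
tie-breaking on input order (ties are logged). The running sum increments
by `|stat|^w / sum_in_set |stat|^w` at in-set genes (default weight w = 1;
w = 0 gives the unweighted Kolmogorov–Smirnov form) and decrements by
`1/(N − n)` elsewhere; the enrichment score is the signed maximum
deviation from zero, with magnitude ties between the positive and negative
extremum resolved to the positive one (within 1e-12, so the choice is not
at the mercy of floating-point summation order). The leading edge is the
in-set genes at or before the extremum (at or after, for negative scores).

The null is gene-label permutation: random same-size gene sets drawn from
the universe, shared across all terms of the same size. NES divides the
observed ES by the mean magnitude of same-sign null scores; the nominal
p value is `(1 + #same-sign null at least as extreme)/(1 + #same-sign
null)`. When no null score shares the observed sign the term is flagged
low-confidence with p = 1. BH correction spans the tested terms. Terms
are tested when `min_size <= |set ∩ universe| <= max_size` (defaults 10
and 500); a term equal to the whole universe is untestable and skipped.

Custom gene lists (microglial-subtype signatures and similar) run through
the same engine with a lower size floor and adaptive permutation
escalation: the per-size null doubles until every term has at least ten
same-sign exceedances or a cap (default 1e6) is reached. This is a plain
permutation stand-in for multilevel split-sampling p values: the target
quantity is the same and the procedure is simpler to verify, at the cost
of a larger p-value floor when the cap binds.

One behavior worth knowing: when a large fraction of the universe is
shifted in one direction (a heavily skewed ranking), the permutation null
itself shifts, and enrichment in the shifted direction is correctly judged
against that shifted null. Apparent "loss of significance" in such data is
the method working as designed, not a defect.

Ortholog translation accepts a two-column mapping and enforces
one-to-one: rows whose source or target appears more than once are dropped
and counted; unmapped genes are dropped and reported.

## Biodomain concordance and reversal

Terms are grouped into biodomains via a term→domain table (terms may carry
several domains and count in each). For each (target, cell line, domain),
the knockdown NES profile is compared to the reference profile over the
union of terms significant (adjusted p <= 0.05) in either analysis, with
the non-significant side set to zero. Zero-filling mass-produces ties, so
the correlation is Kendall tau-b (tie-corrected) with the asymptotic
normal p value; when every universe term is significant in both analyses
this reduces exactly to plain tau-b on the raw NES vectors. Domains with
fewer than `min_terms` (default 5) paired terms are skipped; zero variance
on either side yields a flagged, never-significant row. The union
universe follows the literal reading of "significant terms were compared";
an intersection mode is available for sensitivity analysis. Zero-filling
is applied symmetrically on both sides.

Protein-level support: per (target, cell line, domain), Pearson
correlation between knockdown log2FC and the reference per-protein effect
over in-domain proteins (membership via annotation to any in-domain term),
requiring at least `min_proteins_corr` (default 10) shared proteins.

BH families are kept separate for the term-level and protein-level
methods, each spanning all (target, cell line, domain) tests jointly.
Calls: `anti_correlated` (reversal) when `p_adj <= 0.05` and the statistic
is negative, `correlated` when positive, else `ns`. Note that BH controls
the false discovery *rate*: when many tests are true positives the
adjusted threshold rises and a small number of null tests can be dragged
across it. The protein-level family, with its large n per correlation, is
more exposed to this than the heavily tie-attenuated term-level family —
one reason the tier predicate below rests on the term-level calls.

Quadrant counts classify in-domain terms significant in both analyses by
NES sign pair (up/up, up/down, down/up, down/down) plus
reference-only and query-only tallies.

The sensitized-vs-baseline line characterization reuses the chain on
control-siRNA samples only: two-group differential abundance between the
lines, log2FC ranking, term and custom-list enrichment, and zero-filled
Kendall concordance against the disease reference.

## Integration and tiering

For each (assay, term), Spearman rho correlates the assay effect sizes
with the term's NES across all (siRNA, cell line) points carrying both
values — raw NES whether or not significant, since the coupling question
is about the continuous molecular response. Points pool both cell lines
(a per-line mode exists); at least `min_points` (default 8) pairs are
required; LPS-stimulated NF-kB effects are excluded because proteomes are
collected without stimulation. BH spans all (assay, term) pairs.

The scorecard tier is a deterministic predicate, printed in every report:

- **top**: >=1 phenotype hit AND >=1 term-level (Kendall) reversal AND >=1
  coupled term (a term significant in the integration family whose
  enrichment is also significant for this target);
- **supported**: hit and reversal without a coupled term;
- **phenotype_only** / **proteome_only** / **none** by elimination.

Protein-level reversals are listed on the scorecard but do not drive the
tier (see the FDR note above). Adding evidence can only promote a target.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes and
doubles as the ground-truth source for every recovery test.

- **Assay data**: readout = baseline × 2^(effect + u_batch + eps) with
  u_batch ~ N(0, batch_sd) shared by all siRNAs in a batch and eps ~
  N(0, residual_sd) per well. Defaults: 3 batches × 3 replicates,
  batch_sd 0.1, residual_sd 0.3 — the dispersion of a well-behaved
  384-well fluorescence assay on the log2 scale. Control rows are present
  in every stratum. The sensitized line can scale effect magnitudes
  (`sensitized_scale`, off by default so calibration runs are symmetric).
- **Annotation**: the gene universe is partitioned into one pool per
  domain; each term samples `genes_per_term` genes from its pool, and an
  `overlap` fraction of terms carries a second domain label. Defaults
  (2 domains × 50 terms × 20 genes over 2000 genes) keep end-to-end runs
  fast while leaving every stage non-trivially powered; they are a
  scale-down of a proteome-wide GO annotation, stated here as the
  package's standard simulation size.
- **Reference signature**: protein effect = domain mean effect (default
  +0.5 for the immune domain, −0.5 for the mitochondrial domain, log2
  units — the magnitude of a strong but realistic disease signature) +
  N(0, proteome_noise_sd); term NES/p come from running the package's own
  enrichment engine on that vector, so the signature is self-consistent
  with the scoring that consumes it.
- **Knockdown proteomes**: sample value = basal (drawn once per protein
  from N(25, 2) on the log2-intensity scale) + c(target, line) ×
  reference effect + knockdown_self_effect (default −1, i.e., ~50%
  depletion) on the targeted protein + N(0, proteome_noise_sd); 5
  replicates per group by default. Negative c is a built-in reversal.
  The sensitized line can additionally drift along the reference
  signature itself (`line_concordance`), which is what makes the
  line-vs-line characterization non-trivial.
- **Coupling**: `make_config` draws assay effects as `0.8 c + N(0, 0.15)`
  per (target, line, assay, dose), tying phenotype strength to molecular
  reversal the way a genuinely causal target would; `independent_assays`
  severs the tie and `null` zeroes everything for calibration.
- **Ct tables**: triplicate target and reference-gene Ct values; the
  knockdown condition raises the target Ct by −log2(fold).

Ground truth records as a *true hit* any (target, line, assay, dose)
whose drawn |effect| reaches `true_hit_min` (default 0.3, roughly the
smallest effect the 3 × 3 design detects with useful power) and as a
*true reversal* any (target, line, domain) with c < 0 in a domain with
nonzero reference effect.

What the generator does **not** emulate: missing-at-random protein
dropout (matrices are complete; the QC filter is exercised on constructed
fixtures), peptide-level quantification noise, plate-position effects,
assay-specific response nonlinearity, and correlated gene sets beyond the
domain structure. Passing recovery tests therefore demonstrate the
statistical machinery under the stated model, not robustness to every
artifact of real LC-MS or imaging data.

## Determinism and numerical choices

Every random stream derives from a single seed through fixed component
keys, so identical configurations produce byte-identical outputs
regardless of stage order. Permutation engines accept explicit seeds.
Ranking ties break by stable input order (logged). The studentized-range
quadrature and the ES tie-break tolerance are described above. BH
adjustment leaves NaN p values NaN and excludes them from the family.

## Sizes used by the shipped checks

The test suite and the acceptance script run everything on generated
data: 20 end-to-end screens at the default simulation size for reversal
recovery and tiering, 200 simulations per arm for phenotype power and
type-I error, 20 × 100 random gene sets for enrichment null calibration,
and 10–20 screens at 10 targets × 2 lines for integration recovery
(matching the pooled-points design of the integration correlation). These
sizes are the package's standard demonstration scale; all thresholds are
configurable.

## Known limitations

- The z reference slightly understates small-sample uncertainty relative
  to Satterthwaite-type corrections.
- Gene-label permutation ignores inter-gene correlation; NES and p values
  are calibrated under that null only.
- The asymptotic tau-b p value is approximate for very small domains
  (min_terms guards the worst of it).
- The tier predicate is a formalization choice; alternative predicates
  can be supplied by recomputing from the component tables, all of which
  are written to disk.
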