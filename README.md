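# perturbscreen

Integrated analysis of siRNA perturbation screens in cellular disease
models: statistical hit calling from batch-structured phenotype assays,
proteomic differential abundance after gene knockdown, preranked gene-set
enrichment, biodomain-wise concordance scoring against a reference disease
signature, and phenotype–proteome integration that tiers candidate
therapeutic targets.

## Who this is for

Groups running arrayed knockdown screens (e.g., siRNA panels in microglial
or neuronal cell lines) who measure both cellular phenotypes (viability,
mitochondrial membrane potential, phagocytosis, reporter assays) and
proteomic responses, and who want to ask: *which perturbations move
disease-relevant phenotypes, and do their molecular signatures reverse the
disease state?*

## The statistical core

1. **Phenotype hit calling.** Raw well readouts are reduced to per-batch
   log2 fold changes against the control siRNA within each (assay, cell
   line, batch, dose) stratum:
   `log2FC_b = log2(mean target replicates / mean control replicates)`.
   These are modeled per assay as
   `log2FC ~ siRNA x cell_line (fixed) + batch (random intercept)` by REML;
   the estimated marginal mean per (siRNA, cell line) is the effect size,
   tested against zero with a z reference and Benjamini–Hochberg correction
   within the assay. A hit is `p_adj <= 0.05`.
2. **Differential abundance.** After excluding samples identifying fewer
   than 6100 proteins, each protein is tested by one-way ANOVA across the
   siRNA groups within a cell line with Tukey HSD post hoc p values for
   every knockdown-vs-control contrast (studentized-range reference with
   pooled within-group variance), BH-adjusted per contrast.
3. **Preranked GSEA.** A from-scratch weighted running-sum enrichment
   score over the log2FC ranking, with a gene-label permutation null,
   sign-stratified NES (`NES = ES / mean |same-sign null ES|`), permutation
   p values, leading-edge genes, and BH adjustment. The same engine scores
   arbitrary custom gene lists (e.g., microglial-subtype signatures).
4. **Signature reversal.** Terms are grouped into biodomains; per domain,
   the knockdown NES profile is compared to the reference disease NES
   profile by Kendall tau-b after zero-filling terms significant in only
   one analysis. Protein-level Pearson correlations of knockdown log2FC
   against reference per-protein effects (through a one-to-one ortholog
   map) provide supporting evidence. A significantly negative correlation
   is a *reversal* — the knockdown pushes the proteome opposite to disease.
5. **Integration and tiering.** Spearman correlation of assay effect sizes
   with term NES across knockdowns links phenotypes to molecular programs
   (LPS-stimulated reporter effects are excluded because proteomes are
   collected unstimulated). Targets are tiered: **top** = phenotype hit ∧
   term-level reversal ∧ phenotype-coupled term; **supported** = hit ∧
   reversal; then phenotype_only / proteome_only / none.

A synthetic-data module generates every input with known ground truth
(batch random effects, knockdown proteomes proportional to a reference
signature with coefficient `c`, biodomain-structured gene sets, qPCR Ct
tables), so the whole chain is testable end to end with no external data.

## Worked example

```bash
perturbscreen simulate --seed 5 --n-targets 6 --out demo/inputs
perturbscreen run --config demo/inputs/run_config.yaml --out demo/run
```

The run directory contains `effect_estimates.tsv`, `differential_abundance.tsv`,
per-knockdown `gsea_*.tsv`, `term_concordance.tsv`, `integration.tsv`,
`scorecards.tsv` and `report.md`. For the seed above the report ends with:

```
## Target tiers

Tier predicate: top = phenotype hit AND signature reversal AND phenotype-coupled term; supported = hit AND reversal.

- top: g00000, g00001, g01000
- supported: (none)
- phenotype_only: g01001, g01002
- proteome_only: (none)
- none: g00002
```

The three top-tier targets are exactly the three generated with reversal
coefficient `c = -0.6` (their knockdowns reverse the reference signature
and carry coupled phenotype effects); the remaining targets were generated
null and are correctly left out of the top tier.

Library use mirrors the CLI:

```python
from perturbscreen import make_config, run_screen

res = run_screen(make_config(seed=5), n_perm=500)
print(res.scorecards[["target", "tier"]])
```

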