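"""Synthetic screen generator with known ground truth.

Emulates the statistical structure the analysis assumes: batch-structured
assay replicates with an additive batch random effect on the log2 scale
(multiplicative on raw readouts), knockdown proteomes whose per-protein
log2 fold change is a signed multiple ``c`` of a reference disease effect
plus noise (negative ``c`` = signature reversal) with the targeted protein
itself suppressed, a biodomain-structured term/gene annotation, and qPCR
Ct tables for 2^-ddCt worked examples.

Every generator derives its random stream from ``SimulationConfig.seed``
through fixed component keys, so an identical config yields byte-identical
outputs regardless of which generators are invoked or in which order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concordance import BiodomainAnnotation, ReferenceSignature
from .gsea import GeneSetCollection, preranked_gsea

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "make_config",
    "gen_biodomain_annotation",
    "gen_reference_signature",
    "gen_assay_data",
    "gen_knockdown_proteomes",
    "gen_ct_table",
    "ground_truth",
]

# fixed per-component entropy keys for seed derivation
_KEY_ANNOTATION = 101
_KEY_REFERENCE = 102
_KEY_REFERENCE_GSEA = 103
_KEY_ASSAY = 104
_KEY_PROTEOME = 105
_KEY_CT = 106
_KEY_CONFIG = 107

DEFAULT_DOMAINS = ("immune_response", "mitochondrial_metabolism")
NFKB_DOSES = ("vehicle", "LPS")


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), key)))


@dataclass
class SimulationConfig:
    """Generating parameters of one synthetic screen.

    ``assay_effects`` maps (target, cell_line, assay) or
    (target, cell_line, assay, dose) to the true log2FC of the assay
    readout; ``concordance_coeff`` maps (target, cell_line) to the signed
    multiple ``c`` of the reference effect imposed on that knockdown's
    proteome (negative = reversal).  ``domain_effect`` maps each biodomain
    to the mean reference disease effect (log2 units) of its proteins.
    """

    seed: int = 0
    n_targets: int = 6
    cell_lines: tuple[str, ...] = ("scramble", "sensitized")
    assays: tuple[str, ...] = ("viability", "mito_potential", "phagocytosis", "nfkb")
    n_batches_per_assay: int = 3
    n_replicates_per_batch: int = 3
    batch_sd: float = 0.1
    residual_sd: float = 0.3
    assay_effects: dict = field(default_factory=dict)
    n_genes: int = 2000
    n_domains: int = 2
    domain_names: tuple[str, ...] | None = None
    terms_per_domain: int = 50
    genes_per_term: int = 20
    overlap: float = 0.0
    domain_effect: dict = field(default_factory=dict)
    concordance_coeff: dict = field(default_factory=dict)
    knockdown_self_effect: float = -1.0
    proteome_noise_sd: float = 0.25
    n_proteome_replicates: int = 5
    sensitized_scale: float = 1.0
    line_effect: dict | None = None
    line_concordance: float = 0.0
    control_label: str = "siCtrl"
    targets: tuple[str, ...] = ()
    true_hit_min: float = 0.3

    def __post_init__(self) -> None:
        if self.domain_names is None:
            base = list(DEFAULT_DOMAINS) + [f"domain{k}" for k in range(3, self.n_domains + 1)]
            self.domain_names = tuple(base[: self.n_domains])
        if len(self.domain_names) != self.n_domains:
            raise ValueError("domain_names length must equal n_domains")
        if not self.targets:
            self.targets = tuple(self._default_targets())
        self.validate()

    # --- layout helpers -------------------------------------------------
    def gene_labels(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]

    def domain_pools(self) -> dict[str, list[str]]:
        genes = self.gene_labels()
        blocks = np.array_split(np.asarray(genes, dtype=object), self.n_domains)
        return {d: list(b) for d, b in zip(self.domain_names, blocks)}

    def _default_targets(self) -> list[str]:
        pools = self.domain_pools()
        out = []
        for i in range(self.n_targets):
            pool = pools[self.domain_names[i % self.n_domains]]
            out.append(pool[i // self.n_domains])
        return out

    def doses(self, assay: str) -> tuple[str, ...]:
        return NFKB_DOSES if assay == "nfkb" else ("",)

    def assay_effect(self, target: str, line: str, assay: str, dose: str = "") -> float:
        eff = self.assay_effects.get(
            (target, line, assay, dose), self.assay_effects.get((target, line, assay), 0.0)
        )
        if line == self.cell_lines[-1] and len(self.cell_lines) > 1:
            eff *= self.sensitized_scale
        return float(eff)

    def validate(self) -> None:
        for name in ("batch_sd", "residual_sd", "proteome_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.n_genes < self.n_domains * self.genes_per_term:
            raise ValueError(
                f"infeasible sizes: n_genes={self.n_genes} < "
                f"n_domains*genes_per_term={self.n_domains * self.genes_per_term}"
            )
        pool_size = self.n_genes // self.n_domains
        if self.genes_per_term > pool_size:
            raise ValueError("genes_per_term exceeds the per-domain gene pool")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")
        universe = set(self.gene_labels())
        for t in self.targets:
            if t not in universe:
                raise ValueError(f"target {t!r} is not a gene in the simulated universe")
        if self.assay_effects:
            covered = {k[0] for k in self.assay_effects}
            missing = set(self.targets) - covered
            if missing:
                raise ValueError(f"targets missing from assay_effects: {sorted(missing)}")
        if self.concordance_coeff:
            covered = {k[0] for k in self.concordance_coeff}
            missing = set(self.targets) - covered
            if missing:
                raise ValueError(f"targets missing from concordance_coeff: {sorted(missing)}")


@dataclass
class GroundTruth:
    """The generating parameters in recoverable form."""

    true_hits: set          # (target, cell_line, assay, dose)
    true_reversals: set     # (target, cell_line, domain)
    true_effects: dict

    def to_json_dict(self) -> dict:
        return {
            "true_hits": sorted(list(t) for t in self.true_hits),
            "true_reversals": sorted(list(t) for t in self.true_reversals),
            "true_effects": {
                k: {"|".join(map(str, key)) if isinstance(key, tuple) else str(key): v
                    for key, v in d.items()}
                for k, d in self.true_effects.items()
            },
        }


def make_config(
    seed: int = 0,
    n_targets: int = 6,
    n_reversal: int = 3,
    c_reversal: float = -0.6,
    assay_coupling: float = 0.8,
    assay_noise_sd: float = 0.15,
    independent_assays: bool = False,
    null: bool = False,
    **overrides,
) -> SimulationConfig:
    """Build a screen config with coupled phenotype and proteome effects.

    The first ``n_reversal`` targets receive concordance coefficient
    ``c_reversal`` in both cell lines (their knockdown proteomes reverse the
    reference signature); the rest are null (c = 0).  Assay effects are
    drawn once per (target, line, assay, dose) as
    ``assay_coupling * c + Normal(0, assay_noise_sd)``;
    ``independent_assays=True`` severs the coupling (effects drawn from the
    same marginal noise for every target); ``null=True`` zeroes every
    generating effect for calibration runs.
    """
    cfg = SimulationConfig(seed=seed, n_targets=n_targets, **overrides)
    if not cfg.domain_effect:
        signs = [1.0 if d == "immune_response" else -1.0 for d in cfg.domain_names]
        cfg.domain_effect = {d: 0.0 if null else 0.5 * s for d, s in zip(cfg.domain_names, signs)}
    rng = _rng(seed, _KEY_CONFIG)
    c_map, eff_map = {}, {}
    for i, t in enumerate(cfg.targets):
        c = c_reversal if (i < n_reversal and not null) else 0.0
        for line in cfg.cell_lines:
            c_map[(t, line)] = c
            for assay in cfg.assays:
                for dose in cfg.doses(assay):
                    noise = rng.normal(0.0, assay_noise_sd)
                    if null:
                        eff = 0.0
                    elif independent_assays:
                        eff = noise
                    else:
                        eff = assay_coupling * c + noise
                    eff_map[(t, line, assay, dose)] = float(eff)
    cfg.concordance_coeff = c_map
    cfg.assay_effects = eff_map
    cfg.validate()
    return cfg


def gen_biodomain_annotation(cfg: SimulationConfig) -> tuple[GeneSetCollection, BiodomainAnnotation]:
    """Biodomain-structured gene sets over the simulated universe.

    The gene universe is partitioned into one pool per domain; each term
    samples ``genes_per_term`` genes from its domain's pool without
    replacement.  A fraction ``overlap`` of terms per domain additionally
    carries the next domain's label (terms are otherwise unique per domain).
    """
    rng = _rng(cfg.seed, _KEY_ANNOTATION)
    pools = cfg.domain_pools()
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    term_to_domain: dict[str, tuple[str, ...]] = {}
    idx = 0
    for di, domain in enumerate(cfg.domain_names):
        pool = np.asarray(pools[domain], dtype=object)
        n_multi = int(round(cfg.overlap * cfg.terms_per_domain))
        for j in range(cfg.terms_per_domain):
            term = f"T{idx:04d}"
            idx += 1
            genes = rng.choice(pool, size=cfg.genes_per_term, replace=False)
            sets[term] = tuple(sorted(genes))
            descriptions[term] = f"synthetic term {j} of {domain}"
            labels = [domain]
            if j < n_multi and cfg.n_domains > 1:
                labels.append(cfg.domain_names[(di + 1) % cfg.n_domains])
            term_to_domain[term] = tuple(labels)
    gene_domain = {g: d for d, genes in pools.items() for g in genes}
    return GeneSetCollection(sets, descriptions), BiodomainAnnotation(term_to_domain, gene_domain)


def gen_reference_signature(
    cfg: SimulationConfig,
    collection: GeneSetCollection,
    annotation: BiodomainAnnotation,
    n_perm: int = 1000,
    min_size: int = 10,
    max_size: int = 500,
    alpha: float = 0.05,
) -> ReferenceSignature:
    """Reference disease signature: protein effects plus their enrichment.

    Each protein's effect is its domain's mean effect plus
    ``Normal(0, proteome_noise_sd)``; the term-level reference NES/p come
    from running the enrichment engine on that effect vector, so the
    signature is self-consistent with the engine that scores knockdowns.
    """
    rng = _rng(cfg.seed, _KEY_REFERENCE)
    genes = cfg.gene_labels()
    effects = np.array(
        [cfg.domain_effect.get(annotation.gene_domain.get(g), 0.0) for g in genes], dtype=float
    )
    effects = effects + rng.normal(0.0, cfg.proteome_noise_sd, size=len(genes))
    protein_effect = pd.Series(effects, index=genes, name="effect")
    enrich = preranked_gsea(
        protein_effect,
        collection,
        n_perm=n_perm,
        seed=_rng(cfg.seed, _KEY_REFERENCE_GSEA),
        min_size=min_size,
        max_size=max_size,
    )
    return ReferenceSignature(
        protein_effect=protein_effect,
        term_nes=enrich.set_index("term")["nes"],
        term_sig=enrich.set_index("term")["p_adj"],
        enrichment=enrich,
    )


def gen_assay_data(cfg: SimulationConfig, baseline: float = 1000.0) -> pd.DataFrame:
    """Well-level assay readouts with batch and replicate noise.

    readout = baseline * 2^(true_effect + u_batch + eps), with the batch
    intercept u_batch ~ N(0, batch_sd) shared by every siRNA in the batch
    (log-normal multiplicative noise, so the log2 transform recovers the
    additive model the analysis fits).  Control siRNA rows (true effect 0)
    are present in every stratum.
    """
    rng = _rng(cfg.seed, _KEY_ASSAY)
    sirnas = [cfg.control_label] + list(cfg.targets)
    rows = []
    for assay in cfg.assays:
        for dose in cfg.doses(assay):
            for line in cfg.cell_lines:
                for b in range(cfg.n_batches_per_assay):
                    batch = f"{assay}_b{b + 1}"
                    u = rng.normal(0.0, cfg.batch_sd)
                    for sirna in sirnas:
                        eff = 0.0 if sirna == cfg.control_label else cfg.assay_effect(sirna, line, assay, dose)
                        for rep in range(1, cfg.n_replicates_per_batch + 1):
                            eps = rng.normal(0.0, cfg.residual_sd)
                            rows.append(
                                (assay, line, sirna, batch, rep, dose,
                                 baseline * 2.0 ** (eff + u + eps))
                            )
    return pd.DataFrame(
        rows, columns=["assay", "cell_line", "sirna", "batch", "replicate", "dose", "value"]
    )


def gen_knockdown_proteomes(
    cfg: SimulationConfig,
    reference: ReferenceSignature,
    annotation: BiodomainAnnotation,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Protein-by-sample log2 intensity matrix for every knockdown group.

    Sample value = basal(protein) + group mean + Normal(0, proteome_noise_sd);
    the group mean for (target t, line l) is c(t, l) * reference_effect plus
    ``knockdown_self_effect`` on the targeted protein.  Basal abundances are
    drawn once per protein from a wide normal on the log2-intensity scale.
    """
    genes = cfg.gene_labels()
    universe = set(genes)
    for t in cfg.targets:
        if t not in universe:
            raise ValueError(f"target {t!r} not in the simulated gene universe")
    rng = _rng(cfg.seed, _KEY_PROTEOME)
    basal = rng.normal(25.0, 2.0, size=len(genes))
    ref = reference.protein_effect.loc[genes].to_numpy(dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    sirnas = [cfg.control_label] + list(cfg.targets)

    line_shift = {line: np.zeros(len(genes)) for line in cfg.cell_lines}
    if len(cfg.cell_lines) > 1:
        shift = np.zeros(len(genes))
        if cfg.line_effect:
            shift += np.array(
                [cfg.line_effect.get(annotation.gene_domain.get(g), 0.0) for g in genes],
                dtype=float,
            )
        if cfg.line_concordance:
            # the sensitized line drifts along the disease signature itself
            shift += cfg.line_concordance * ref
        line_shift[cfg.cell_lines[-1]] = shift

    columns, meta_rows, data = [], [], []
    for line in cfg.cell_lines:
        for sirna in sirnas:
            group_mean = line_shift[line].copy()
            if sirna != cfg.control_label:
                c = float(cfg.concordance_coeff.get((sirna, line), 0.0))
                group_mean = group_mean + c * ref
                group_mean[gene_pos[sirna]] += cfg.knockdown_self_effect
            for rep in range(1, cfg.n_proteome_replicates + 1):
                sample = f"{line}.{sirna}.r{rep}"
                columns.append(sample)
                meta_rows.append((sample, line, sirna, rep))
                data.append(basal + group_mean + rng.normal(0.0, cfg.proteome_noise_sd, size=len(genes)))
    matrix = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    matrix.index.name = "protein"
    meta = pd.DataFrame(meta_rows, columns=["sample", "cell_line", "sirna", "replicate"])
    return matrix, meta


def gen_ct_table(
    cfg: SimulationConfig,
    knockdown_fold: float = 0.25,
    ct_noise_sd: float = 0.0,
    reference_gene: str = "Gapdh",
    target_base_ct: float = 22.0,
    reference_base_ct: float = 18.0,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Triplicate qPCR Ct values under control and knockdown conditions.

    Knockdown raises the target's Ct by ``-log2(knockdown_fold)`` cycles
    while the reference gene is unchanged, so 2^-ddCt recovers
    ``knockdown_fold`` exactly at zero noise.
    """
    if knockdown_fold <= 0:
        raise ValueError("knockdown_fold must be positive")
    rng = _rng(cfg.seed, _KEY_CT)
    delta = -np.log2(knockdown_fold)
    rows = []
    for target in cfg.targets:
        for condition in ("control", "knockdown"):
            shift = delta if condition == "knockdown" else 0.0
            for rep in range(1, n_replicates + 1):
                rows.append((target, target, condition, rep,
                             target_base_ct + shift + rng.normal(0.0, ct_noise_sd)))
                rows.append((target, reference_gene, condition, rep,
                             reference_base_ct + rng.normal(0.0, ct_noise_sd)))
    return pd.DataFrame(rows, columns=["target", "gene", "condition", "replicate", "ct"])


def ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """Derive the recoverable ground truth from the generating parameters.

    A true hit is any (target, line, assay, dose) whose generating |effect|
    reaches ``cfg.true_hit_min``; a true reversal is any (target, line,
    domain) with c < 0 in a domain whose mean reference effect is nonzero.
    """
    hits = set()
    for t in cfg.targets:
        for line in cfg.cell_lines:
            for assay in cfg.assays:
                for dose in cfg.doses(assay):
                    if abs(cfg.assay_effect(t, line, assay, dose)) >= cfg.true_hit_min:
                        hits.add((t, line, assay, dose))
    reversals = set()
    for (t, line), c in cfg.concordance_coeff.items():
        if c < 0:
            for d, eff in cfg.domain_effect.items():
                if eff != 0.0:
                    reversals.add((t, line, d))
    return GroundTruth(
        true_hits=hits,
        true_reversals=reversals,
        true_effects={
            "assay_effects": dict(cfg.assay_effects),
            "concordance_coeff": dict(cfg.concordance_coeff),
            "domain_effect": dict(cfg.domain_effect),
        },
    )
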