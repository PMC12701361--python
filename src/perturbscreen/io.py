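"""Readers/writers for the pipeline's file formats and the run configuration.

Tabular data travel as TSV with a header row, gene sets as GMT
(term <TAB> description <TAB> gene...), manifests and ground truth as JSON.
All formats are line-oriented and diff-able so runs can be checksummed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging

import pandas as pd
import yaml

from .concordance import BiodomainAnnotation, ReferenceSignature
from .gsea import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_tsv",
    "write_tsv",
    "read_biodomain_annotation",
    "write_biodomain_annotation",
    "read_reference_signature",
    "write_reference_signature",
    "RunConfig",
    "file_checksum",
]


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line, >= 3 tab-separated fields.

    Duplicate genes within a line are dropped with a warning; duplicate
    term names are an error, as are lines with fewer than three fields.
    """
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields (need >= 3)")
            term, desc, genes = fields[0], fields[1], fields[2:]
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term name {term!r}")
            seen, unique = set(), []
            for g in genes:
                if g and g not in seen:
                    seen.add(g)
                    unique.append(g)
            if len(unique) < len([g for g in genes if g]):
                logger.warning("%s:%d: duplicate genes in term %s deduplicated", path, lineno, term)
            sets[term] = tuple(unique)
            descriptions[term] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for term, genes in collection.sets.items():
            desc = collection.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *genes]) + "\n")


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_tsv(df: pd.DataFrame, path, index: bool = False, float_format: str = "%.10g") -> None:
    df.to_csv(path, sep="\t", index=index, float_format=float_format)


def write_biodomain_annotation(annotation: BiodomainAnnotation, path) -> None:
    rows = [
        {"term": term, "domain": d}
        for term, labels in annotation.term_to_domain.items()
        for d in labels
    ]
    write_tsv(pd.DataFrame(rows, columns=["term", "domain"]), path)


def read_biodomain_annotation(path) -> BiodomainAnnotation:
    df = read_tsv(path, dtype=str)
    if not {"term", "domain"} <= set(df.columns):
        raise ValueError(f"{path}: biodomain table needs columns term, domain")
    mapping: dict[str, tuple[str, ...]] = {}
    for term, grp in df.groupby("term", sort=False):
        mapping[term] = tuple(dict.fromkeys(grp["domain"]))
    return BiodomainAnnotation(mapping)


def write_reference_signature(reference: ReferenceSignature, term_path, protein_path) -> None:
    terms = pd.DataFrame(
        {"term": reference.term_nes.index,
         "nes": reference.term_nes.to_numpy(),
         "p_adj": reference.term_sig.loc[reference.term_nes.index].to_numpy()}
    )
    write_tsv(terms, term_path)
    prots = reference.protein_effect.rename("effect").rename_axis("protein").reset_index()
    write_tsv(prots, protein_path)


def read_reference_signature(term_path, protein_path) -> ReferenceSignature:
    terms = read_tsv(term_path)
    prots = read_tsv(protein_path)
    for cols, path, df in ((["term", "nes", "p_adj"], term_path, terms),
                           (["protein", "effect"], protein_path, prots)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
    return ReferenceSignature(
        protein_effect=prots.set_index("protein")["effect"].astype(float),
        term_nes=terms.set_index("term")["nes"].astype(float),
        term_sig=terms.set_index("term")["p_adj"].astype(float),
    )


@dataclasses.dataclass
class RunConfig:
    """Paths, thresholds and flags for one orchestrated pipeline run.

    Thresholds default to the analysis' standard values: alpha 0.05
    everywhere, >= 6100 identified proteins per sample for proteomic QC,
    gene-set sizes in [10, 500], >= 5 paired terms per domain correlation,
    and >= 8 points per phenotype-term correlation.
    """

    assays: str = ""
    matrix: str = ""
    sample_meta: str = ""
    gene_sets: str = ""
    biodomains: str = ""
    reference_terms: str = ""
    reference_proteins: str = ""
    orthologs: str = ""
    control: str = "siCtrl"
    alpha: float = 0.05
    min_proteins: int = 6100
    min_size: int = 10
    max_size: int = 500
    min_terms: int = 5
    min_points: int = 8
    min_proteins_corr: int = 10
    n_perm: int = 1000
    seed: int = 0
    separate_lines: bool = False
    per_line_integration: bool = False
    universe: str = "union"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("min_proteins", "min_size", "max_size", "min_terms",
                     "min_points", "min_proteins_corr", "n_perm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.max_size < self.min_size:
            raise ValueError("max_size must be >= min_size")
        if self.universe not in ("union", "intersection"):
            raise ValueError("universe must be 'union' or 'intersection'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
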