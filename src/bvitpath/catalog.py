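"""B-vitamin pathway gene catalogs and transporter annotations.

Eight biosynthetic pathways (one per B-vitamin) are described by MetaCyc
pathway identifiers and an ordered set of reference genes (UniProt-style
accessions plus optional symbols).  Completeness of a gene set against a
catalog, and hence complementarity between genomes, is always judged
relative to these definitions.

Pathways for B1, B2, B3 and B5 require every catalog gene to count as
complete; B6, B7, B9 and B12 use a relaxed 85 % threshold because one or
two of their genes are routinely missed by annotation in metagenome
assemblies.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

__all__ = [
    "VITAMIN_CODES",
    "METACYC_IDS",
    "DEFAULT_THRESHOLDS",
    "PathwayDefinition",
    "TransporterRecord",
    "load_pathway_definitions",
    "write_pathway_definitions",
    "default_pathway_definitions",
    "load_transporters",
    "default_transporters",
    "get_threshold",
    "get_pathway",
]

#: The eight B-vitamins, in conventional order.
VITAMIN_CODES = ("B1", "B2", "B3", "B5", "B6", "B7", "B9", "B12")

#: MetaCyc pathway identifier for each vitamin's biosynthesis pathway.
METACYC_IDS = {
    "B1": "THISYN-PWY",
    "B2": "RIBOSYN2-PWY",
    "B3": "PYRIDNUCSYN-PWY",
    "B5": "PANTO-PWY",
    "B6": "PYRIDOXSYN-PWY",
    "B7": "BIOTIN-BIOSYNTHESIS-PWY",
    "B9": "FOLSYN-PWY",
    "B12": "PWY-5507",
}

#: Default pathway-completeness thresholds.  Full completeness for the
#: four pathways whose genes are reliably annotated; 85 % for the four
#: whose catalogs contain genes that are frequently undetected.
DEFAULT_THRESHOLDS = {
    "B1": 1.0,
    "B2": 1.0,
    "B3": 1.0,
    "B5": 1.0,
    "B6": 0.85,
    "B7": 0.85,
    "B9": 0.85,
    "B12": 0.85,
}

_CATALOG_COLUMNS = [
    "vitamin_code",
    "metacyc_id",
    "gene_accession",
    "gene_symbol",
    "threshold_override",
]


class CatalogError(ValueError):
    """Raised when a pathway catalog violates its invariants."""


@dataclass(frozen=True)
class PathwayDefinition:
    """Reference gene set for one B-vitamin biosynthesis pathway.

    Parameters
    ----------
    vitamin_code : str
        One of ``B1, B2, B3, B5, B6, B7, B9, B12``.
    metacyc_id : str
        MetaCyc pathway identifier.
    gene_refs : tuple of str
        Ordered, duplicate-free reference gene accessions.
    gene_symbols : dict
        Optional accession -> symbol map (informational only; gene
        identity is accession string equality).
    completeness_threshold : float
        Fraction of ``gene_refs`` required for the pathway to count as
        complete, in (0, 1].
    """

    vitamin_code: str
    metacyc_id: str
    gene_refs: tuple[str, ...]
    gene_symbols: dict[str, str] = field(default_factory=dict)
    completeness_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.vitamin_code not in VITAMIN_CODES:
            raise CatalogError(f"unknown vitamin_code {self.vitamin_code!r}")
        if not self.gene_refs:
            raise CatalogError(f"{self.vitamin_code}: gene_refs must be non-empty")
        seen: set[str] = set()
        for acc in self.gene_refs:
            if acc in seen:
                raise CatalogError(
                    f"{self.vitamin_code}: duplicate gene accession {acc!r}"
                )
            seen.add(acc)
        if not (0.0 < self.completeness_threshold <= 1.0):
            raise CatalogError(
                f"{self.vitamin_code}: completeness_threshold must be in (0, 1], "
                f"got {self.completeness_threshold}"
            )
        if self.metacyc_id != METACYC_IDS[self.vitamin_code]:
            raise CatalogError(
                f"{self.vitamin_code}: metacyc_id {self.metacyc_id!r} does not "
                f"match the expected {METACYC_IDS[self.vitamin_code]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_refs)


@dataclass(frozen=True)
class TransporterRecord:
    """A vitamin transporter used as a producer/consumer plausibility check.

    ``role`` is ``precursor_uptake`` for transporters that import pathway
    precursors (e.g. panS for pantothenate) or ``product_transport`` for
    transporters of the finished vitamin (e.g. panF).
    """

    symbol: str
    vitamin_code: str
    role: str
    gene_ref: str

    def __post_init__(self) -> None:
        if self.role not in ("precursor_uptake", "product_transport"):
            raise CatalogError(f"invalid transporter role {self.role!r}")
        if self.vitamin_code not in VITAMIN_CODES:
            raise CatalogError(f"unknown vitamin_code {self.vitamin_code!r}")


def load_pathway_definitions(path: str | Path) -> list[PathwayDefinition]:
    """Load pathway definitions from a catalog TSV.

    The file is tab-delimited with a header row and columns
    ``vitamin_code, metacyc_id, gene_accession, gene_symbol,
    threshold_override``.  Gene order within a vitamin follows file order;
    thresholds default to :data:`DEFAULT_THRESHOLDS` unless every row of a
    vitamin carries the same ``threshold_override``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _CATALOG_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise CatalogError(f"catalog file missing columns: {missing}")
    if "gene_symbol" not in df.columns:
        df["gene_symbol"] = ""
    if "threshold_override" not in df.columns:
        df["threshold_override"] = ""

    defs: list[PathwayDefinition] = []
    # preserve first-appearance order of vitamins
    for vit in df["vitamin_code"].drop_duplicates():
        if vit not in VITAMIN_CODES:
            raise CatalogError(f"unknown vitamin_code {vit!r} in catalog file")
        rows = df[df["vitamin_code"] == vit]
        accessions = list(rows["gene_accession"])
        dup = {a for a in accessions if accessions.count(a) > 1}
        if dup:
            raise CatalogError(
                f"{vit}: duplicate gene accession {sorted(dup)[0]!r} in catalog file"
            )
        metacyc = rows["metacyc_id"].iloc[0]
        overrides = {v for v in rows["threshold_override"] if v != ""}
        if len(overrides) > 1:
            raise CatalogError(f"{vit}: conflicting threshold overrides {overrides}")
        threshold = (
            float(next(iter(overrides))) if overrides else DEFAULT_THRESHOLDS[vit]
        )
        symbols = {
            acc: sym
            for acc, sym in zip(rows["gene_accession"], rows["gene_symbol"])
            if sym
        }
        defs.append(
            PathwayDefinition(
                vitamin_code=vit,
                metacyc_id=metacyc,
                gene_refs=tuple(accessions),
                gene_symbols=symbols,
                completeness_threshold=threshold,
            )
        )
    return defs


def write_pathway_definitions(
    defs: Iterable[PathwayDefinition], path: str | Path
) -> None:
    """Write definitions back to the catalog TSV dialect (round-trip safe)."""
    rows = []
    for d in defs:
        override = (
            ""
            if d.completeness_threshold == DEFAULT_THRESHOLDS[d.vitamin_code]
            else repr(d.completeness_threshold)
        )
        for acc in d.gene_refs:
            rows.append(
                {
                    "vitamin_code": d.vitamin_code,
                    "metacyc_id": d.metacyc_id,
                    "gene_accession": acc,
                    "gene_symbol": d.gene_symbols.get(acc, ""),
                    "threshold_override": override,
                }
            )
    pd.DataFrame(rows, columns=_CATALOG_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def default_pathway_definitions() -> list[PathwayDefinition]:
    """The bundled reference catalog (synthetic stand-in; see its file header)."""
    ref = importlib.resources.files("bvitpath.data").joinpath(
        "synthetic_pathway_catalog.tsv"
    )
    with importlib.resources.as_file(ref) as p:
        return load_pathway_definitions(p)


def load_transporters(path: str | Path) -> list[TransporterRecord]:
    """Load transporter records from a TSV with columns
    ``symbol, vitamin_code, role, gene_accession``."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = [
        TransporterRecord(
            symbol=r.symbol,
            vitamin_code=r.vitamin_code,
            role=r.role,
            gene_ref=r.gene_accession,
        )
        for r in df.itertuples()
    ]
    seen: set[tuple[str, str]] = set()
    for rec in records:
        key = (rec.vitamin_code, rec.role)
        if key in seen:
            raise CatalogError(f"duplicate transporter for {key}")
        seen.add(key)
    return records


def default_transporters() -> list[TransporterRecord]:
    """Pantothenate transporters: panS (precursor uptake) and panF (product)."""
    return [
        TransporterRecord("panS", "B5", "precursor_uptake", "Q8DR59"),
        TransporterRecord("panF", "B5", "product_transport", "P16256"),
    ]


def get_pathway(
    defs: Iterable[PathwayDefinition], vitamin_code: str
) -> PathwayDefinition:
    """Return the definition for ``vitamin_code`` or raise ``KeyError``."""
    for d in defs:
        if d.vitamin_code == vitamin_code:
            return d
    raise KeyError(f"no pathway definition for vitamin {vitamin_code!r}")


def get_threshold(defs: Iterable[PathwayDefinition], vitamin_code: str) -> float:
    """Completeness threshold of one vitamin's pathway."""
    return get_pathway(defs, vitamin_code).completeness_threshold


def with_threshold(d: PathwayDefinition, threshold: float) -> PathwayDefinition:
    """Copy of ``d`` with a different completeness threshold."""
    return replace(d, completeness_threshold=threshold)
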