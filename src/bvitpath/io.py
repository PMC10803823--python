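"""Readers and writers for the pipeline's table dialects.

All tables are UTF-8, tab-delimited, LF-terminated, '.' decimal.  The
profiler reader understands MetaPhlAn-style merged tables (pipe-delimited,
rank-prefixed lineages; values on the 0-100 percent scale); similarity
hits use the standard 12-column tabular dialect.  Every writer emits a
deterministic row order so identical inputs give byte-identical files.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .complement import ComplementarityPair, MagGeneSet, MagRecord, pairs_to_frame
from .orthologs import HitRecord, OrthologAssignment
from .quant import GeneAbundanceMatrix
from .taxa import AbundanceTable, CoreSelectionResult

__all__ = [
    "species_from_lineage",
    "read_metaphlan_merged",
    "read_hits_outfmt6",
    "write_hits_outfmt6",
    "read_gene_matrix",
    "write_gene_matrix",
    "read_known_list",
    "write_known_list",
    "read_mag_tables",
    "write_mag_tables",
    "write_core_selection",
    "write_pairs",
    "read_annotation_labels",
    "write_assignments",
    "write_run_manifest",
]

_RANK_ORDER = "kpcofgst"
_SEGMENT = re.compile(r"^([a-z])__(.*)$")


def species_from_lineage(lineage: str) -> str | None:
    """Extract the species name from a rank-prefixed, pipe-delimited lineage.

    Returns None unless the lineage ends at species level (has an ``s__``
    segment and no ``t__`` strain segment); underscores in the species
    segment become spaces.
    """
    ranks = []
    names = {}
    for seg in lineage.split("|"):
        m = _SEGMENT.match(seg.strip())
        if not m:
            return None
        ranks.append(m.group(1))
        names[m.group(1)] = m.group(2)
    if "".join(ranks) != _RANK_ORDER[: len(ranks)]:
        return None
    if "s" not in names or "t" in names:
        return None
    return names["s"].replace("_", " ")


def read_metaphlan_merged(path: str | Path) -> AbundanceTable:
    """Read a merged profiler table into a species-level relative table.

    Keeps only species-level rows; values are percentages (0-100) and are
    rescaled to fractions.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    lineage_col = df.columns[0]
    rows = []
    index = []
    for i, lineage in enumerate(df[lineage_col]):
        sp = species_from_lineage(str(lineage))
        if sp is None:
            continue
        vals = df.iloc[i, 1:]
        numeric = pd.to_numeric(vals, errors="coerce")
        if numeric.isna().any():
            bad = numeric.index[numeric.isna()][0]
            raise ValueError(
                f"non-numeric abundance at row {i + 2}, column {bad!r}"
            )
        rows.append(numeric / 100.0)
        index.append(sp)
    if not rows:
        raise ValueError(f"no species-level rows in {path}")
    values = pd.DataFrame(rows, index=index)
    values.columns = [str(c) for c in df.columns[1:]]
    # tables with an unclassified remainder leave species shares summing
    # below 1; renormalize over reported species in that case
    sums = values.sum(axis=0)
    if not ((sums - 1.0).abs() < 1e-6).all():
        values = values.div(sums, axis=1)
    return AbundanceTable(values=values, unit="relative")


_OUTFMT6_COLS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def read_hits_outfmt6(path: str | Path) -> list[HitRecord]:
    """Parse a headerless 12-column tabular hits file."""
    hits: list[HitRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(fields)}"
                )
            hits.append(
                HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
    return hits


def write_hits_outfmt6(hits: Iterable[HitRecord], path: str | Path) -> None:
    """Write hits in the 12-column dialect (unused columns zero-filled)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for h in hits:
            fields = [
                h.query_id, h.subject_id, repr(h.percent_identity),
                str(h.alignment_length), "0", "0", "0", "0", "0", "0",
                repr(h.evalue), repr(h.bitscore),
            ]
            fh.write("\t".join(fields) + "\n")


def read_gene_matrix(
    path: str | Path, lengths_path: str | Path | None = None
) -> GeneAbundanceMatrix:
    """Gene count matrix TSV (first column gene id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    lengths = {}
    if lengths_path is not None:
        ldf = pd.read_csv(lengths_path, sep="\t", index_col=0)
        lengths = {str(g): int(v) for g, v in ldf.iloc[:, 0].items()}
    return GeneAbundanceMatrix(counts=df.astype(float), lengths=lengths)


def write_gene_matrix(matrix: GeneAbundanceMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="gene_id", lineterminator="\n")


def read_known_list(path: str | Path) -> pd.DataFrame:
    """Known-biosynthesizer list: species, evidence, eight vitamin booleans."""
    df = pd.read_csv(path, sep="\t")
    from .catalog import VITAMIN_CODES

    for v in VITAMIN_CODES:
        if v in df.columns:
            df[v] = df[v].astype(bool)
    return df


def write_known_list(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Species-by-sample values with the unit tag in the index label."""
    table.values.to_csv(
        path, sep="\t", index_label=f"species[{table.unit}]", lineterminator="\n"
    )


def read_abundance_table(path: str | Path) -> AbundanceTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    label = str(df.index.name or "")
    df.index.name = None
    unit = "counts"
    m = re.search(r"\[(\w+)\]", label)
    if m:
        unit = m.group(1)
    return AbundanceTable(values=df.astype(float), unit=unit)


def read_mag_tables(
    quality_path: str | Path,
    genes_path: str | Path,
    coverage_path: str | Path,
) -> tuple[list[MagRecord], list[MagGeneSet]]:
    """Assemble MAG records from quality, gene and coverage TSVs.

    quality: mag_id, completeness, contamination, taxonomy;
    genes: mag_id, vitamin_code, gene_accession (transporter rows use
    vitamin_code ``transporter`` and the symbol in gene_accession);
    coverage: mag_id, sample, coverage.
    """
    qual = pd.read_csv(quality_path, sep="\t", dtype={"mag_id": str})
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    cov = pd.read_csv(coverage_path, sep="\t", dtype={"mag_id": str, "sample": str})

    coverage: dict[str, dict[str, float]] = {}
    for r in cov.itertuples():
        coverage.setdefault(r.mag_id, {})[r.sample] = float(r.coverage)

    present: dict[str, dict[str, set[str]]] = {}
    transporters: dict[str, set[str]] = {}
    for r in genes.itertuples():
        if r.vitamin_code == "transporter":
            transporters.setdefault(r.mag_id, set()).add(r.gene_accession)
        else:
            present.setdefault(r.mag_id, {}).setdefault(r.vitamin_code, set()).add(
                r.gene_accession
            )

    records = [
        MagRecord(
            mag_id=r.mag_id,
            completeness=float(r.completeness),
            contamination=float(r.contamination),
            taxonomy=str(getattr(r, "taxonomy", "")),
            coverage=coverage.get(r.mag_id, {}),
        )
        for r in qual.itertuples()
    ]
    gene_sets = [
        MagGeneSet(
            mag_id=r.mag_id,
            present={v: frozenset(g) for v, g in present.get(r.mag_id, {}).items()},
            transporters=frozenset(transporters.get(r.mag_id, set())),
        )
        for r in qual.itertuples()
    ]
    return records, gene_sets


def write_mag_tables(
    records: Iterable[MagRecord],
    gene_sets: Iterable[MagGeneSet],
    quality_path: str | Path,
    genes_path: str | Path,
    coverage_path: str | Path,
) -> None:
    records = sorted(records, key=lambda r: r.mag_id)
    gene_sets = sorted(gene_sets, key=lambda g: g.mag_id)
    pd.DataFrame(
        [
            {
                "mag_id": r.mag_id,
                "completeness": r.completeness,
                "contamination": r.contamination,
                "taxonomy": r.taxonomy,
            }
            for r in records
        ]
    ).to_csv(quality_path, sep="\t", index=False, lineterminator="\n")
    gene_rows = []
    for g in gene_sets:
        for vit in sorted(g.present):
            for acc in sorted(g.present[vit]):
                gene_rows.append(
                    {"mag_id": g.mag_id, "vitamin_code": vit, "gene_accession": acc}
                )
        for t in sorted(g.transporters):
            gene_rows.append(
                {"mag_id": g.mag_id, "vitamin_code": "transporter", "gene_accession": t}
            )
    pd.DataFrame(
        gene_rows, columns=["mag_id", "vitamin_code", "gene_accession"]
    ).to_csv(genes_path, sep="\t", index=False, lineterminator="\n")
    cov_rows = [
        {"mag_id": r.mag_id, "sample": s, "coverage": v}
        for r in records
        for s, v in sorted(r.coverage.items())
    ]
    pd.DataFrame(cov_rows, columns=["mag_id", "sample", "coverage"]).to_csv(
        coverage_path, sep="\t", index=False, lineterminator="\n"
    )


def write_core_selection(
    results: Iterable[CoreSelectionResult], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "species": r.species,
                "mra": r.mra,
                "prevalence": r.prevalence,
                "selected": r.selected,
            }
            for r in results
        ]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_pairs(pairs: Iterable[ComplementarityPair], path: str | Path) -> None:
    frame = pairs_to_frame(pairs).sort_values(
        ["sample", "vitamin_code", "mag_a", "mag_b"]
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_annotation_labels(path: str | Path) -> dict[str, str]:
    """Annotation labels TSV: gene_id, reference_gene (or symbol)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_assignments(
    assignments: Iterable[OrthologAssignment], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {"gene_id": a.gene_id, "reference_gene": a.reference_gene,
             "evidence": a.evidence}
            for a in sorted(assignments, key=lambda a: a.gene_id)
        ]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_run_manifest(params: Mapping[str, object], path: str | Path) -> None:
    """Resolved parameter set as sorted key=value lines."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in sorted(params):
            fh.write(f"{key}={params[key]}\n")
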