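"""Gene-abundance normalization and median-based pathway abundance.

The abundance of a B-vitamin biosynthesis pathway in a sample is the
median of the normalized abundances of all the pathway's reference genes
in that sample.  Catalog genes with no assigned predicted gene enter the
median as 0 by default, so the full catalog is the denominator; the
``detected_only`` alternative drops them instead.  When several predicted
genes map to the same reference gene their abundances are summed
(gene-family semantics).

Normalization is counts-per-million (``cpm``) or a length-aware
TPM-style variant (``length_cpm``) that divides by gene length in kb
before rescaling the sample to one million.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .catalog import PathwayDefinition
from .orthologs import OrthologAssignment

__all__ = [
    "GeneAbundanceMatrix",
    "PathwayAbundanceProfile",
    "normalize",
    "pathway_abundance",
    "pathway_abundance_table",
]


@dataclass
class GeneAbundanceMatrix:
    """Genes-by-samples abundance matrix with optional gene lengths (bases)."""

    counts: pd.DataFrame
    lengths: dict[str, int] = field(default_factory=dict)
    method: str = "raw"

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.lengths:
            missing = [g for g in self.counts.index if g not in self.lengths]
            if missing:
                raise ValueError(f"lengths missing for genes: {missing[:5]}")
            if any(v <= 0 for v in self.lengths.values()):
                raise ValueError("gene lengths must be positive")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class PathwayAbundanceProfile:
    sample: str
    vitamin_code: str
    abundance: float
    n_genes_detected: int
    method: str = "raw"


def normalize(matrix: GeneAbundanceMatrix, method: str = "cpm") -> GeneAbundanceMatrix:
    """Normalize each sample to counts-per-million.

    ``cpm`` scales each column to sum to 1e6.  ``length_cpm`` first divides
    each gene by its length in kilobases and then rescales the column to
    1e6 (TPM-style), so longer genes are down-weighted.
    """
    totals = matrix.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"zero-total sample(s): {list(zero.index)}")
    if method == "cpm":
        values = matrix.counts.div(totals, axis=1) * 1e6
    elif method == "length_cpm":
        if not matrix.lengths:
            raise ValueError("length_cpm requires gene lengths")
        kb = pd.Series(matrix.lengths).reindex(matrix.counts.index) / 1000.0
        rate = matrix.counts.div(kb, axis=0)
        values = rate.div(rate.sum(axis=0), axis=1) * 1e6
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return GeneAbundanceMatrix(counts=values, lengths=dict(matrix.lengths), method=method)


def _reference_gene_series(
    normalized: GeneAbundanceMatrix,
    assignments: Iterable[OrthologAssignment],
    pathway: PathwayDefinition,
    sample: str,
) -> np.ndarray:
    """Per-reference-gene abundance in one sample (summed over assigned genes)."""
    col = normalized.counts[sample]
    totals = {ref: 0.0 for ref in pathway.gene_refs}
    for a in assignments:
        if a.reference_gene in totals and a.gene_id in col.index:
            totals[a.reference_gene] += float(col[a.gene_id])
    return np.array([totals[ref] for ref in pathway.gene_refs])


def pathway_abundance(
    normalized: GeneAbundanceMatrix,
    assignments: Iterable[OrthologAssignment],
    pathway: PathwayDefinition,
    sample: str,
    detected_only: bool = False,
) -> PathwayAbundanceProfile:
    """Median normalized abundance over a pathway's reference genes.

    Undetected reference genes contribute 0 unless ``detected_only``;
    the even-length median is the midpoint of the central pair.
    """
    if sample not in normalized.counts.columns:
        raise KeyError(f"sample {sample!r} not in matrix")
    if not pathway.gene_refs:
        raise ValueError("pathway has no reference genes")
    series = _reference_gene_series(normalized, assignments, pathway, sample)
    n_detected = int((series > 0).sum())
    if detected_only:
        detected = series[series > 0]
        abundance = float(np.median(detected)) if detected.size else 0.0
    else:
        abundance = float(np.median(series))
    return PathwayAbundanceProfile(
        sample=sample,
        vitamin_code=pathway.vitamin_code,
        abundance=abundance,
        n_genes_detected=n_detected,
        method=normalized.method,
    )


def pathway_abundance_table(
    normalized: GeneAbundanceMatrix,
    assignments: Iterable[OrthologAssignment],
    defs: Sequence[PathwayDefinition],
    samples: Sequence[str] | None = None,
    detected_only: bool = False,
) -> pd.DataFrame:
    """Pathway abundance for every (sample, vitamin) combination.

    Rows ordered by (sample, vitamin in catalog order); columns
    ``sample, vitamin_code, abundance, n_genes_detected, method``.
    """
    assignments = list(assignments)
    if samples is None:
        samples = normalized.samples
    rows = [
        pathway_abundance(normalized, assignments, d, s, detected_only)
        for s in samples
        for d in defs
    ]
    return pd.DataFrame(
        [
            {
                "sample": r.sample,
                "vitamin_code": r.vitamin_code,
                "abundance": r.abundance,
                "n_genes_detected": r.n_genes_detected,
                "method": r.method,
            }
            for r in rows
        ]
    )
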