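"""Reciprocal-best-hit ortholog assignment of predicted genes to pathway genes.

Predicted genes are linked to reference pathway genes by two evidence
streams: functional-annotation labels (exact, normalized symbol match) and
reciprocal best hits (RBH) over tabular similarity searches.  A gene pair
is an RBH when each member is the other's top-scoring hit in opposing
searches; ties are broken by percent identity and then lexicographically so
runs are reproducible.  The two streams are merged; where they disagree the
annotation label wins and the conflict is logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

__all__ = [
    "HitRecord",
    "OrthologAssignment",
    "best_hit_per_query",
    "reciprocal_best_hits",
    "merge_evidence",
    "kmer_similarity",
    "normalize_symbol",
]


@dataclass(frozen=True)
class HitRecord:
    """One row of a tabular similarity search (12-column dialect)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    bitscore: float
    evalue: float

    def __post_init__(self) -> None:
        if not self.query_id or not self.subject_id:
            raise ValueError("hit record ids must be non-empty")
        if self.bitscore < 0:
            raise ValueError(f"negative bitscore {self.bitscore}")
        if self.evalue < 0:
            raise ValueError(f"negative evalue {self.evalue}")


@dataclass(frozen=True)
class OrthologAssignment:
    """A predicted gene assigned to a reference pathway gene.

    ``evidence`` is ``annotation``, ``rbh`` or ``both``.
    """

    gene_id: str
    reference_gene: str
    evidence: str


def best_hit_per_query(
    hits: Iterable[HitRecord], max_evalue: float | None = None
) -> dict[str, HitRecord]:
    """Top-scoring hit for each query.

    Maximal bitscore wins; ties broken by higher percent identity, then by
    lexicographically smallest subject id.  ``max_evalue``, when given,
    drops hits above that e-value before selection.
    """
    best: dict[str, HitRecord] = {}
    for h in hits:
        if max_evalue is not None and h.evalue > max_evalue:
            continue
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) > _hit_rank(cur):
            best[h.query_id] = h
    return best


def _hit_rank(h: HitRecord) -> tuple[float, float, _ReverseStr]:
    return (h.bitscore, h.percent_identity, _ReverseStr(h.subject_id))


class _ReverseStr(str):
    """String with reversed ordering, so max() prefers the smaller id."""

    def __lt__(self, other: str) -> bool:  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other: str) -> bool:
        return str.__lt__(self, other)


def reciprocal_best_hits(
    forward: Iterable[HitRecord],
    reverse: Iterable[HitRecord],
    max_evalue: float | None = None,
) -> list[tuple[str, str]]:
    """Reciprocal best hits between predicted genes and reference genes.

    ``forward`` has predicted genes as queries against the reference set;
    ``reverse`` swaps the roles.  A pair ``(g, r)`` is returned iff ``r``
    is g's best hit and ``g`` is r's best hit.  Output sorted by gene id.
    """
    fwd = best_hit_per_query(forward, max_evalue)
    rev = best_hit_per_query(reverse, max_evalue)
    pairs = [
        (g, h.subject_id)
        for g, h in fwd.items()
        if (back := rev.get(h.subject_id)) is not None and back.subject_id == g
    ]
    return sorted(pairs)


def merge_evidence(
    rbh: Iterable[tuple[str, str]],
    annotation_labels: Mapping[str, str],
) -> list[OrthologAssignment]:
    """Union RBH pairs with annotation-label assignments.

    Agreement yields evidence ``both``.  When the two streams assign the
    same gene to different references, the annotation wins and the
    conflict is logged.
    """
    rbh_map = dict(rbh)
    out: list[OrthologAssignment] = []
    for gene, ref in sorted(annotation_labels.items()):
        if gene in rbh_map and rbh_map[gene] == ref:
            out.append(OrthologAssignment(gene, ref, "both"))
        else:
            if gene in rbh_map:
                logger.warning(
                    "ortholog conflict for %s: annotation=%s rbh=%s; keeping annotation",
                    gene,
                    ref,
                    rbh_map[gene],
                )
            out.append(OrthologAssignment(gene, ref, "annotation"))
    for gene, ref in sorted(rbh_map.items()):
        if gene not in annotation_labels:
            out.append(OrthologAssignment(gene, ref, "rbh"))
    return sorted(out, key=lambda a: a.gene_id)


_PUNCT = re.compile(r"[^a-z0-9]")


def normalize_symbol(symbol: str) -> str:
    """Lowercase a gene symbol and strip punctuation, for label matching."""
    return _PUNCT.sub("", symbol.lower())


def kmer_similarity(seq_a: str, seq_b: str, k: int) -> float:
    """Shared k-mer fraction between two residue strings.

    Returns |shared k-mers| / |k-mers of the shorter sequence|, a crude
    alignment-free similarity in [0, 1] used by the simulator to score
    sequence pairs without an aligner.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq_a) < k or len(seq_b) < k:
        raise ValueError("sequence shorter than k")
    kmers_a = {seq_a[i : i + k] for i in range(len(seq_a) - k + 1)}
    kmers_b = {seq_b[i : i + k] for i in range(len(seq_b) - k + 1)}
    # min() keeps the score symmetric when equal-length sequences differ
    # in their number of distinct k-mers
    return len(kmers_a & kmers_b) / min(len(kmers_a), len(kmers_b))
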