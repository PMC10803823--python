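"""MAG filtering, pathway completeness and pairwise metabolic complementarity.

Metagenome-assembled genomes (MAGs) rarely carry a complete B-vitamin
pathway on their own, which raises the question of whether pairs of
genomes co-occurring in a sample could jointly complete one.  This module
applies the standard quality gate (contamination <= 5 %, completeness
>= 90 %, either violation discards the bin), restricts to MAGs with
non-zero coverage in a sample, and enumerates all unordered MAG pairs
whose combined reference-gene sets reach the pathway's completeness
threshold.  A pair is *strict* when neither member reaches the threshold
alone — true complementarity rather than piggy-backing on an already
complete genome.

Transporter presence serves as a plausibility check on producer/consumer
roles: a precursor-uptake transporter (panS for pantothenate) is
consistent with a partial or complete pathway, while a transporter of the
finished vitamin (panF) is expected only alongside a complete pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .catalog import PathwayDefinition, TransporterRecord

__all__ = [
    "MagRecord",
    "MagGeneSet",
    "ComplementarityPair",
    "filter_mags",
    "mags_in_sample",
    "pathway_completeness",
    "enumerate_complementary_pairs",
    "summarize_pairs",
    "transporter_consistency",
    "pairs_to_frame",
]


@dataclass(frozen=True)
class MagRecord:
    """Quality and per-sample coverage of one genome bin."""

    mag_id: str
    completeness: float
    contamination: float
    taxonomy: str = ""
    coverage: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.completeness <= 100):
            raise ValueError(f"{self.mag_id}: completeness must be in [0, 100]")
        if self.contamination < 0:
            raise ValueError(f"{self.mag_id}: contamination must be >= 0")
        if any(v < 0 for v in self.coverage.values()):
            raise ValueError(f"{self.mag_id}: coverage values must be >= 0")


@dataclass(frozen=True)
class MagGeneSet:
    """Reference pathway genes and transporters found in one MAG."""

    mag_id: str
    present: Mapping[str, frozenset[str]] = field(default_factory=dict)
    transporters: frozenset[str] = frozenset()

    def genes(self, vitamin_code: str) -> frozenset[str]:
        return frozenset(self.present.get(vitamin_code, frozenset()))


@dataclass(frozen=True)
class ComplementarityPair:
    """A sample-scoped MAG pair that jointly completes a pathway.

    ``strict`` means neither MAG reaches the completeness threshold alone.
    """

    sample: str
    vitamin_code: str
    mag_a: str
    mag_b: str
    c_a: float
    c_b: float
    c_union: float
    strict: bool


def filter_mags(
    records: Iterable[MagRecord],
    max_contamination: float = 5.0,
    min_completeness: float = 90.0,
) -> list[MagRecord]:
    """Quality gate: discard a MAG if either bound is violated.

    Boundaries are kept: contamination exactly 5 % or completeness
    exactly 90 % passes.
    """
    return [
        r
        for r in records
        if r.contamination <= max_contamination and r.completeness >= min_completeness
    ]


def mags_in_sample(records: Iterable[MagRecord], sample: str) -> list[str]:
    """MAG ids with non-zero coverage in ``sample``, sorted."""
    records = list(records)
    if not any(sample in r.coverage for r in records):
        raise KeyError(f"sample {sample!r} not in any coverage map")
    return sorted(r.mag_id for r in records if r.coverage.get(sample, 0.0) > 0)


def pathway_completeness(genes: MagGeneSet, pathway: PathwayDefinition) -> float:
    """Fraction of the pathway's reference genes present in the MAG."""
    present = genes.genes(pathway.vitamin_code) & set(pathway.gene_refs)
    return len(present) / pathway.n_genes


def enumerate_complementary_pairs(
    mags: Sequence[MagGeneSet],
    pathway: PathwayDefinition,
    sample: str,
    strict_only: bool = False,
) -> list[ComplementarityPair]:
    """All unordered MAG pairs whose union completes the pathway.

    ``mags`` should already be restricted to the sample (quality-filtered,
    non-zero coverage).  A pair qualifies when the union of its reference
    genes reaches the pathway's completeness threshold; ``strict_only``
    keeps only pairs where neither MAG qualifies alone.  Output sorted by
    (mag_a, mag_b) with each pair id-canonicalized.
    """
    thr = pathway.completeness_threshold
    refs = set(pathway.gene_refs)
    n = pathway.n_genes
    out: list[ComplementarityPair] = []
    for ga, gb in combinations(sorted(mags, key=lambda m: m.mag_id), 2):
        a = ga.genes(pathway.vitamin_code) & refs
        b = gb.genes(pathway.vitamin_code) & refs
        c_union = len(a | b) / n
        if c_union < thr:
            continue
        c_a, c_b = len(a) / n, len(b) / n
        strict = c_a < thr and c_b < thr
        if strict_only and not strict:
            continue
        out.append(
            ComplementarityPair(
                sample=sample,
                vitamin_code=pathway.vitamin_code,
                mag_a=ga.mag_id,
                mag_b=gb.mag_id,
                c_a=c_a,
                c_b=c_b,
                c_union=c_union,
                strict=strict,
            )
        )
    return out


def summarize_pairs(
    pairs: Iterable[ComplementarityPair], samples: Sequence[str]
) -> tuple[dict[str, float], dict[str, set[str]]]:
    """Per-vitamin sample fractions and per-sample vitamin sets.

    Returns ``(vitamin -> fraction of samples with >= 1 qualifying pair,
    sample -> set of vitamins with >= 1 pair)``; the latter supports
    upset-style combination summaries across samples.
    """
    per_sample: dict[str, set[str]] = {s: set() for s in samples}
    for p in pairs:
        per_sample.setdefault(p.sample, set()).add(p.vitamin_code)
    vitamins = sorted({p for s in per_sample.values() for p in s})
    n = len(samples)
    fractions = {
        v: (sum(v in per_sample[s] for s in samples) / n if n else 0.0)
        for v in vitamins
    }
    return fractions, per_sample


def transporter_consistency(
    genes: MagGeneSet,
    pathway: PathwayDefinition,
    transporters: Iterable[TransporterRecord],
) -> dict:
    """Check transporter presence against the MAG's pathway status.

    Status is ``complete`` (completeness >= threshold), ``absent``
    (completeness 0) or ``partial``.  A precursor-uptake transporter is
    consistent with partial or complete pathways; a product transporter
    only with a complete one.  Transporters absent from the MAG yield no
    flag.
    """
    c = pathway_completeness(genes, pathway)
    if c >= pathway.completeness_threshold:
        status = "complete"
    elif c == 0:
        status = "absent"
    else:
        status = "partial"
    flags: dict[str, str] = {}
    for t in transporters:
        if t.vitamin_code != pathway.vitamin_code:
            raise ValueError(
                f"transporter {t.symbol} is for {t.vitamin_code}, "
                f"pathway is {pathway.vitamin_code}"
            )
        if t.symbol not in genes.transporters:
            continue
        if t.role == "precursor_uptake":
            ok = status in ("partial", "complete")
        else:  # product_transport
            ok = status == "complete"
        flags[t.symbol] = "consistent" if ok else "inconsistent"
    return {"pathway_status": status, "flags": flags}


def pairs_to_frame(pairs: Iterable[ComplementarityPair]) -> pd.DataFrame:
    """Pairs as a DataFrame in the output TSV column order."""
    return pd.DataFrame(
        [
            {
                "sample": p.sample,
                "vitamin_code": p.vitamin_code,
                "mag_a": p.mag_a,
                "mag_b": p.mag_b,
                "c_a": p.c_a,
                "c_b": p.c_b,
                "c_union": p.c_union,
                "strict": p.strict,
            }
            for p in pairs
        ],
        columns=[
            "sample",
            "vitamin_code",
            "mag_a",
            "mag_b",
            "c_a",
            "c_b",
            "c_union",
            "strict",
        ],
    )
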