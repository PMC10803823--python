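"""Species prevalence, mean relative abundance and core-biosynthesizer selection.

Prevalence of a species is the fraction of samples in which it is present
(abundance > 0).  Mean relative abundance (MRA) is the arithmetic mean of
its per-sample relative abundance over *all* samples, zeros included, so
prevalence and MRA share a denominator.  A known B-vitamin biosynthesizer
with MRA >= 0.1 % and prevalence >= 50 % counts as having "modest or
higher" abundance and prevalence — the core-selection rule applied
throughout downstream comparisons.

Gut species abundances are heavy-tailed; :func:`skewness_test` quantifies
that with the adjusted moment skewness statistic g1 and a bootstrap
p-value obtained by resampling from a symmetrized version of the sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "CoreSelectionResult",
    "to_relative",
    "prevalence",
    "mean_relative_abundance",
    "select_core_biosynthesizers",
    "skewness_test",
    "normalize_species_name",
    "collapse_strains_to_species",
    "summarize_curated_list",
]


@dataclass
class AbundanceTable:
    """Taxa-by-samples abundance matrix with per-sample metadata.

    ``values`` is a DataFrame indexed by species name with sample-id
    columns; ``unit`` is ``"counts"`` or ``"relative"`` (columns summing
    to 1 over reported taxa).  ``sample_metadata`` is indexed by sample id
    and may carry cohort, location, lifestyle, diet, country, age, gender.
    """

    values: pd.DataFrame
    unit: str = "counts"
    sample_metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "relative"):
            raise ValueError(f"unknown unit tag {self.unit!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate taxa names: {dups}")
        if self.unit == "relative":
            sums = self.values.sum(axis=0).to_numpy()
            if not np.allclose(sums[sums > 0], 1.0, atol=1e-9):
                raise ValueError("relative-abundance columns must sum to 1")

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


@dataclass(frozen=True)
class CoreSelectionResult:
    species: str
    mra: float
    prevalence: float
    selected: bool


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Column-normalize counts to relative abundances (idempotent)."""
    if table.unit == "relative":
        logger.info("table already in relative units; returned unchanged")
        return table
    sums = table.values.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    return replace(table, values=table.values.div(sums, axis=1), unit="relative")


def prevalence(table: AbundanceTable, species: str) -> float:
    """Fraction of samples where ``species`` has abundance > 0."""
    if species not in table.values.index:
        raise KeyError(f"species {species!r} not in table")
    row = table.values.loc[species]
    return float((row > 0).sum() / len(row))


def mean_relative_abundance(table: AbundanceTable, species: str) -> float:
    """Mean of the species' relative abundance over all samples (zeros in)."""
    if table.unit != "relative":
        raise ValueError("table is in counts; call to_relative first")
    if species not in table.values.index:
        raise KeyError(f"species {species!r} not in table")
    return float(table.values.loc[species].mean())


def normalize_species_name(name: str) -> str:
    """Case-insensitive species-name key with underscores/spaces unified."""
    return " ".join(name.replace("_", " ").split()).lower()


def select_core_biosynthesizers(
    table: AbundanceTable,
    known: set[str] | list[str],
    mra_cutoff: float = 0.001,
    prev_cutoff: float = 0.5,
) -> list[CoreSelectionResult]:
    """Select known biosynthesizers with modest-or-higher abundance/prevalence.

    Both thresholds are inclusive.  Known species absent from the table
    are reported with zero MRA and prevalence, unselected.  Species-name
    matching is case-insensitive with underscores and spaces unified.
    """
    if not known:
        raise ValueError("known species set must be non-empty")
    if table.unit != "relative":
        raise ValueError("table is in counts; call to_relative first")
    by_key = {normalize_species_name(t): t for t in table.values.index}
    out = []
    for sp in sorted(set(known)):
        taxon = by_key.get(normalize_species_name(sp))
        if taxon is None:
            out.append(CoreSelectionResult(sp, 0.0, 0.0, False))
            continue
        m = mean_relative_abundance(table, taxon)
        p = prevalence(table, taxon)
        out.append(
            CoreSelectionResult(sp, m, p, m >= mra_cutoff and p >= prev_cutoff)
        )
    return out


def skewness_test(
    values: list[float] | np.ndarray, n_boot: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Moment skewness g1 with a symmetrized-bootstrap two-sided p-value.

    g1 = m3 / m2^(3/2) with biased central moments.  The null of symmetry
    is emulated by resampling (with replacement) from the sample pooled
    with its reflection about the mean; the p-value is the fraction of
    bootstrap |g1*| >= |g1| (with the +1 continuity adjustment).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(x) == 0:
        raise ValueError("skewness undefined for constant input")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")

    def g1(a: np.ndarray) -> float:
        c = a - a.mean()
        m2 = np.mean(c**2)
        m3 = np.mean(c**3)
        return float(m3 / m2**1.5) if m2 > 0 else 0.0

    stat = g1(x)
    rng = np.random.default_rng(seed)
    sym = np.concatenate([x, 2 * x.mean() - x])
    boots = rng.choice(sym, size=(n_boot, x.size), replace=True)
    cb = boots - boots.mean(axis=1, keepdims=True)
    m2b = np.mean(cb**2, axis=1)
    m3b = np.mean(cb**3, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        g1b = np.where(m2b > 0, m3b / m2b**1.5, 0.0)
    p = (np.sum(np.abs(g1b) >= abs(stat)) + 1) / (n_boot + 1)
    return stat, float(p)


# ---------------------------------------------------------------------------
# Curated-list bookkeeping (known biosynthesizers with vitamin profiles)

_STRAIN_MARKERS = ("subsp.", "str.", "strain", "serovar", "bv.", "pv.")


def collapse_strains_to_species(names: list[str]) -> list[str]:
    """Collapse strain-level names to unique binomial species names.

    A species is the first two whitespace-separated tokens of the name;
    trailing strain designators (``subsp.``, ``str.``, serial numbers …)
    are dropped.  Output is sorted and duplicate-free.
    """
    species = set()
    for name in names:
        tokens = name.replace("_", " ").split()
        if len(tokens) >= 2:
            species.add(f"{tokens[0]} {tokens[1]}")
        elif tokens:
            species.add(tokens[0])
    return sorted(species)


def summarize_curated_list(df: pd.DataFrame) -> dict:
    """Summary counts over a curated biosynthesizer list.

    ``df`` has columns ``species`` (species or strain names), ``evidence``
    in {experimental, computational, both} and eight boolean vitamin
    columns ``B1 … B12``.  Returns species-level counts: total species
    after strain collapse, species with all eight pathways (count and
    share), and per-evidence-class counts (a species inherits the
    strongest evidence among its strains: both > experimental alone +
    computational alone merged to both).
    """
    from .catalog import VITAMIN_CODES

    vits = list(VITAMIN_CODES)
    work = df.copy()
    work["_species"] = [
        collapse_strains_to_species([n])[0] for n in work["species"]
    ]
    # union vitamin capability over strains of one species
    caps = work.groupby("_species")[vits].any()
    ev = work.groupby("_species")["evidence"].agg(set)

    def species_evidence(classes: set[str]) -> str:
        if "both" in classes or {"experimental", "computational"} <= classes:
            return "both"
        return next(iter(classes))

    ev_class = ev.map(species_evidence)
    n_species = len(caps)
    n_all_eight = int(caps.all(axis=1).sum())
    return {
        "n_species": n_species,
        "n_all_eight_vitamins": n_all_eight,
        "share_all_eight_vitamins": n_all_eight / n_species if n_species else 0.0,
        "n_experimental_only": int((ev_class == "experimental").sum()),
        "n_computational_only": int((ev_class == "computational").sum()),
        "n_both": int((ev_class == "both").sum()),
    }
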