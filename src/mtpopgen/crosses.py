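"""Recombination analysis of homozygous mating-locus crosses.

A :class:`CrossTable` holds progeny × marker genotype calls coded by
parental origin ("A"/"B"), with "both" flagging diploid or aneuploid
progeny (both parental alleles present at a marker) and "NA" for missing
scores.  The analysis mirrors classical two-point mapping: exclude
diploids, count recombinants between a marker pair, convert to map
distance (cM = 100 × recombination fraction, no mapping function — at the
few-percent frequencies involved, interference corrections are
negligible), and test observed recombinant counts against a physical
expectation expressed in kb per cM with a two-class chi-squared
goodness-of-fit test (1 df, no continuity correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, LabelingError

GENOTYPES = ("A", "B", "both", "NA")


@dataclass(frozen=True)
class CrossTable:
    """Progeny × marker genotype calls with marker positions in kb."""

    genotypes: pd.DataFrame  # rows progeny, columns markers
    positions_kb: dict[str, float]
    phenotypes: pd.DataFrame | None = None
    n_excluded: int = 0

    def __post_init__(self):
        markers = list(self.genotypes.columns)
        missing = [m for m in markers if m not in self.positions_kb]
        if missing:
            raise LabelingError(f"markers without positions: {missing}")
        pos = [self.positions_kb[m] for m in markers]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise LabelingError("marker order must match increasing kb positions")
        bad = set(np.unique(self.genotypes.values)) - set(GENOTYPES)
        if bad:
            raise LabelingError(f"unknown genotype codes {sorted(bad)}")

    @property
    def markers(self) -> list[str]:
        return list(self.genotypes.columns)

    @property
    def n_progeny(self) -> int:
        return len(self.genotypes)

    def to_tsv(self, path):
        out = self.genotypes.copy()
        if self.phenotypes is not None:
            out = out.join(self.phenotypes)
        out.insert(0, "progeny", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, positions_kb: dict[str, float]) -> "CrossTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        df = df.set_index("progeny")
        marker_cols = [c for c in df.columns if c in positions_kb]
        pheno_cols = [c for c in df.columns if c not in positions_kb]
        phenos = df[pheno_cols] if pheno_cols else None
        return cls(df[marker_cols], positions_kb, phenos)


@dataclass(frozen=True)
class RecombinationResult:
    n_recombinant: int
    n_total_scored: int
    n_excluded: int
    frequency: float
    cM: float


@dataclass(frozen=True)
class ChiSquaredResult:
    observed: float
    expected: float
    n: int
    statistic: float
    p: float


def exclude_diploids(table: CrossTable) -> CrossTable:
    """Drop progeny scored "both" at any marker; genotypes of survivors
    are untouched and the exclusion count is recorded."""
    diploid = (table.genotypes == "both").any(axis=1)
    return replace(
        table,
        genotypes=table.genotypes.loc[~diploid],
        phenotypes=None if table.phenotypes is None else table.phenotypes.loc[~diploid],
        n_excluded=table.n_excluded + int(diploid.sum()),
    )


def recombination_frequency(
    table: CrossTable, markerA: str, markerB: str
) -> RecombinationResult:
    """Recombinants between two markers among haploid progeny.

    A progeny is recombinant when its alleles at the two markers derive
    from different parents.  Progeny missing either call are dropped with
    a warning; diploids should be excluded beforehand (any remaining
    "both" call raises).
    """
    for m in (markerA, markerB):
        if m not in table.genotypes.columns:
            raise LabelingError(f"unknown marker {m!r}")
    g = table.genotypes[[markerA, markerB]]
    if (g == "both").any().any():
        raise LabelingError("diploid progeny present; run exclude_diploids first")
    missing = (g == "NA").any(axis=1)
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} progeny missing a genotype at "
            f"{markerA}/{markerB}; dropped",
            stacklevel=2,
        )
    g = g.loc[~missing]
    n = len(g)
    if n == 0:
        raise DegenerateInputError("no scorable progeny")
    rec = int((g[markerA] != g[markerB]).sum())
    freq = rec / n
    return RecombinationResult(rec, n, table.n_excluded, freq, 100.0 * freq)


def expected_recombinants(region_kb: float, kb_per_cM: float, n: int) -> float:
    """Expected recombinant count for a region under a kb-per-cM baseline:
    n × (region_kb / kb_per_cM) / 100."""
    if region_kb < 0 or kb_per_cM <= 0 or n <= 0:
        raise DegenerateInputError("region_kb >= 0, kb_per_cM > 0, n > 0 required")
    return n * (region_kb / kb_per_cM) / 100.0


def chi_squared_test(
    observed: float, region_kb: float, kb_per_cM: float, n: int
) -> ChiSquaredResult:
    """Two-class goodness-of-fit of observed recombinants vs expectation.

    statistic = (O−E)²/E + ((n−O)−(n−E))²/(n−E), 1 df, upper-tail p.
    """
    expected = expected_recombinants(region_kb, kb_per_cM, n)
    if expected <= 0:
        raise DegenerateInputError("expected count must be positive")
    if expected >= n:
        raise DegenerateInputError("expected count reaches the sample size")
    statistic = (observed - expected) ** 2 / expected + (
        (n - observed) - (n - expected)
    ) ** 2 / (n - expected)
    p = float(stats.chi2.sf(statistic, df=1))
    return ChiSquaredResult(observed, expected, n, statistic, p)


@dataclass(frozen=True)
class CrossoverInterval:
    """One origin switch, between ``left`` and ``right`` scored markers.

    ``ambiguous`` is True when unscored markers lie inside the interval,
    so the breakpoint is only localized to the wider range.
    """

    progeny: str
    left: str
    right: str
    ambiguous: bool


def assign_crossover_intervals(table: CrossTable) -> dict[str, list[CrossoverInterval]]:
    """Minimal-crossover breakpoint intervals per progeny.

    For each progeny the parental-origin sequence over the ordered markers
    is scanned; every switch between consecutive *scored* markers yields
    one interval.  This is the fewest-switches interpretation consistent
    with the genotypes.
    """
    markers = table.markers
    if len(markers) < 3:
        raise LabelingError("need at least 3 ordered markers")
    out: dict[str, list[CrossoverInterval]] = {}
    for progeny, row in table.genotypes.iterrows():
        calls = [(m, row[m]) for m in markers if row[m] in ("A", "B")]
        intervals = []
        for (m1, g1), (m2, g2) in zip(calls, calls[1:]):
            if g1 != g2:
                adjacent = markers.index(m2) - markers.index(m1) == 1
                intervals.append(CrossoverInterval(str(progeny), m1, m2, not adjacent))
        out[str(progeny)] = intervals
    return out
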