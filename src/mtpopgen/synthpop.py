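"""Synthetic two-mating-type panels and cross progeny.

This generator stands in for wild-isolate sequence panels (two haplotype
groups with fixed inter-group differences, group-private and pool-wide
polymorphism, and optional planted gene-conversion tracts) and for the
progeny of homozygous crosses (marker-by-marker inheritance with
interval-wise recombination fractions and a diploid-contamination rate).

It sprinkles sites parametrically instead of simulating genealogies: the
pipeline's tests need exact control over which sites are fixed, shared or
segregating — and over carrier counts, so that tract frequencies like
ψ = 1/3 are constructible — not coalescent realism.  Within-group minor
allele counts default to the neutral frequency spectrum P(c) ∝ 1/c, under
which the two standard estimators of θ agree in expectation and Tajima's
D is centred on zero.

Everything is reproducible bit-for-bit from the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignio import AnnotationBlock, LabeledAlignment
from .crosses import CrossTable
from .errors import SpecError

_OTHER_BASE = {"A": "G", "C": "T", "G": "A", "T": "C"}
BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ConversionPlant:
    """A gene-conversion tract to plant after panel generation.

    ``recipient_indices`` index into the recipient group's member list;
    the donor group's allele is copied into those members over ``k``
    consecutive informative (fixed-difference) sites nearest ``location``
    (a 1-based alignment position).
    """

    recipient_indices: tuple[int, ...]
    donor_group: str
    k: int
    location: int


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of a synthetic two-group isolate panel.

    Defaults emulate the study design this generator mirrors: 7 + 6
    isolates.  ``theta_within`` sprinkles group-private biallelic
    polymorphism, ``theta_shared`` pool-wide polymorphism (the panmictic
    autosomal regime), ``delta_fixed`` fixed inter-group differences (the
    rearranged-domain regime).  Site classes are disjoint by construction.
    """

    n_plus: int = 7
    n_minus: int = 6
    L: int = 3000
    group_plus: str = "MT+"
    group_minus: str = "MT-"
    region_layout: tuple[AnnotationBlock, ...] | None = None
    theta_within: float = 0.005
    theta_shared: float = 0.0
    delta_fixed: float = 0.0
    minor_allele_spectrum: str = "neutral"  # or "uniform"
    conversion_plants: tuple[ConversionPlant, ...] = ()
    seed: int = 0

    def __post_init__(self):
        for name in ("theta_within", "theta_shared", "delta_fixed"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SpecError(f"{name} must be a probability, got {v}")
        if self.n_plus < 1 or self.n_minus < 1 or self.L < 1:
            raise SpecError("group sizes and length must be positive")
        if self.minor_allele_spectrum not in ("neutral", "uniform"):
            raise SpecError(f"unknown spectrum {self.minor_allele_spectrum!r}")


@dataclass(frozen=True)
class CrossSpec:
    """Parameters of a simulated cross: ordered markers with kb positions,
    per-interval recombination fractions, progeny count, diploid rate."""

    markers: tuple[str, ...]
    positions_kb: tuple[float, ...]
    rf_per_interval: tuple[float, ...]
    n_progeny: int
    diploid_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.markers) != len(self.positions_kb):
            raise SpecError("one kb position per marker required")
        if len(self.rf_per_interval) != len(self.markers) - 1:
            raise SpecError("need one recombination fraction per interval")
        if any(not 0.0 <= rf <= 0.5 for rf in self.rf_per_interval):
            raise SpecError("recombination fractions must lie in [0, 0.5]")
        if any(
            b <= a for a, b in zip(self.positions_kb, self.positions_kb[1:])
        ):
            raise SpecError("marker positions must increase")
        if not 0.0 <= self.diploid_rate <= 1.0:
            raise SpecError("diploid_rate must be a probability")


def _draw_carrier_count(rng, n: int, spectrum: str) -> int:
    """Minor-allele carrier count in 1..n//2.

    "neutral" uses the folded neutral spectrum P(c) ∝ 1/c + 1/(n−c)
    (single term at c = n/2), equivalent for symmetric statistics to the
    unfolded 1/j spectrum, under which θ_π and θ_W agree in expectation.
    Capping at n//2 keeps the group's majority allele ancestral, so
    within-group variation never fabricates informative sites.
    """
    counts = np.arange(1, n // 2 + 1)
    if spectrum == "neutral":
        w = np.array(
            [1.0 / c + (1.0 / (n - c) if c != n - c else 0.0) for c in counts]
        )
        return int(rng.choice(counts, p=w / w.sum()))
    return int(rng.choice(counts))


def simulate_panel(spec: PanelSpec, *, return_truth: bool = False):
    """Generate a labeled two-group panel from a :class:`PanelSpec`.

    Pipeline: ancestral sequence → fixed inter-group differences at rate
    ``delta_fixed`` → group-private polymorphism at rate ``theta_within``
    per group → pool-wide polymorphism at rate ``theta_shared`` → planted
    conversion tracts copying donor alleles into recipients.  With
    ``return_truth`` the planted site coordinates (1-based) come back too.
    """
    rng = np.random.default_rng(spec.seed)
    plus = [f"plus{i + 1}" for i in range(spec.n_plus)]
    minus = [f"minus{i + 1}" for i in range(spec.n_minus)]
    taxa = plus + minus
    groups = {t: spec.group_plus for t in plus}
    groups.update({t: spec.group_minus for t in minus})
    L = spec.L
    ancestral = rng.choice(BASES, size=L)
    matrix = np.tile(ancestral, (len(taxa), 1))
    minus_rows = slice(spec.n_plus, len(taxa))
    plus_rows = slice(0, spec.n_plus)

    u = rng.random(L)
    fixed = u < spec.delta_fixed
    free = ~fixed
    fixed_sites = np.flatnonzero(fixed)
    for col in fixed_sites:
        matrix[minus_rows, col] = _OTHER_BASE[str(ancestral[col])]

    truth = {
        "fixed_sites": (fixed_sites + 1).tolist(),
        "within_plus": [],
        "within_minus": [],
        "shared": [],
        "plants": [],
    }

    def _sprinkle(row_slice, rate, key):
        nonlocal free
        if rate <= 0:
            return
        rows = np.arange(len(taxa))[row_slice]
        if len(rows) < 2:
            return
        hit = (rng.random(L) < rate) & free
        free = free & ~hit
        for col in np.flatnonzero(hit):
            c = _draw_carrier_count(rng, len(rows), spec.minor_allele_spectrum)
            carriers = rng.choice(rows, size=c, replace=False)
            current = str(matrix[rows[0], col])
            matrix[carriers, col] = _OTHER_BASE[current]
            truth[key].append(int(col) + 1)

    _sprinkle(plus_rows, spec.theta_within, "within_plus")
    _sprinkle(minus_rows, spec.theta_within, "within_minus")
    _sprinkle(slice(0, len(taxa)), spec.theta_shared, "shared")

    for plant in spec.conversion_plants:
        positions = _plant_tract(spec, matrix, fixed_sites, plant, plus, minus)
        truth["plants"].append(positions)

    aln = LabeledAlignment.from_sequences(
        {t: "".join(matrix[i]) for i, t in enumerate(taxa)},
        groups,
        list(spec.region_layout) if spec.region_layout else None,
    )
    return (aln, truth) if return_truth else aln


def _plant_tract(spec, matrix, fixed_sites, plant, plus, minus):
    if plant.donor_group == spec.group_plus:
        donor_row, rec_members = 0, minus
        rec_offset = spec.n_plus
    elif plant.donor_group == spec.group_minus:
        donor_row, rec_members = spec.n_plus, plus
        rec_offset = 0
    else:
        raise SpecError(f"unknown donor group {plant.donor_group!r}")
    if len(fixed_sites) < plant.k:
        raise SpecError(
            f"plant of {plant.k} sites exceeds {len(fixed_sites)} informative sites"
        )
    bad = [i for i in plant.recipient_indices if i >= len(rec_members)]
    if bad:
        raise SpecError(f"recipient indices out of range: {bad}")
    nearest = int(np.argmin(np.abs(fixed_sites - (plant.location - 1))))
    start = min(max(0, nearest), len(fixed_sites) - plant.k)
    cols = fixed_sites[start: start + plant.k]
    for i in plant.recipient_indices:
        matrix[rec_offset + i, cols] = matrix[donor_row, cols]
    return (cols + 1).tolist()


def simulate_cross(spec: CrossSpec) -> CrossTable:
    """Generate haploid progeny marker-by-marker from a :class:`CrossSpec`.

    Each progeny starts at a random parental origin and switches between
    consecutive markers with the interval's recombination fraction;
    diploid progeny (probability ``diploid_rate``) are scored "both" at
    every marker.
    """
    rng = np.random.default_rng(spec.seed)
    n_m = len(spec.markers)
    rows = []
    for _ in range(spec.n_progeny):
        if rng.random() < spec.diploid_rate:
            rows.append(["both"] * n_m)
            continue
        origin = "A" if rng.random() < 0.5 else "B"
        calls = [origin]
        for rf in spec.rf_per_interval:
            if rng.random() < rf:
                origin = "A" if origin == "B" else "B"
            calls.append(origin)
        rows.append(calls)
    genotypes = pd.DataFrame(
        rows,
        index=[f"p{i + 1}" for i in range(spec.n_progeny)],
        columns=list(spec.markers),
    )
    genotypes.index.name = "progeny"
    return CrossTable(genotypes, dict(zip(spec.markers, spec.positions_kb)))


def fixture_conversion_panel() -> LabeledAlignment:
    """Deterministic fixture with the structure of the published
    polymorphism tables for the rearranged-domain genes.

    7 MT+ and 6 MT− isolates over 400 bp of non-coding sequence: twelve
    fixed inter-group differences, of which four consecutive ones carry
    the MT+ allele in two of the six MT− isolates (CC1952 and CC2931 — a
    shared conversion tract with ψ = 1/3 per site, p = (1/3)⁴ ≈ 0.012),
    plus group-private polymorphism that leaves MT+ less diverse than MT−.
    """
    L = 400
    plus = [f"plus{i}" for i in range(1, 8)]
    minus = ["CC1952", "CC2931", "minus3", "minus4", "minus5", "minus6"]
    base = ("ACGT" * (L // 4 + 1))[:L]
    seqs = {t: list(base) for t in plus + minus}

    fixed_positions = [30 * i for i in range(1, 13)]  # 30, 60, ..., 360
    for pos in fixed_positions:
        col = pos - 1
        for t in minus:
            seqs[t][col] = _OTHER_BASE[base[col]]
    # conversion tract: sites 150, 180, 210, 240 revert to the MT+ allele
    # in CC1952 and CC2931
    for pos in (150, 180, 210, 240):
        col = pos - 1
        for t in ("CC1952", "CC2931"):
            seqs[t][col] = base[col]
    # group-private polymorphism: MT− carries more than MT+
    for pos, carriers in (
        (75, ("minus3", "minus4", "minus5")),
        (255, ("CC1952", "minus6")),
        (345, ("minus4", "minus5", "minus6")),
    ):
        col = pos - 1
        for t in carriers:
            seqs[t][col] = _OTHER_BASE[base[col]]
    seqs["plus2"][95 - 1] = _OTHER_BASE[base[95 - 1]]

    groups = {t: "MT+" for t in plus}
    groups.update({t: "MT-" for t in minus})
    return LabeledAlignment.from_sequences(
        {t: "".join(s) for t, s in seqs.items()},
        groups,
        [AnnotationBlock(1, L, "intron")],
    )
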