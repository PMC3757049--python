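"""Diversity and differentiation statistics for two-group panels.

Implements the classical sample statistics used to contrast mating-type
haplotype groups against autosomal controls:

* nucleotide diversity π (average pairwise difference per analyzed site),
  with a seeded site-bootstrap standard deviation;
* Tajima's D from the number of segregating sites and the mean number of
  pairwise differences;
* between-group differentiation: d_XY (Jukes–Cantor corrected mean
  between-group distance), net divergence d_A, and the Hudson–Slatkin–
  Maddison F_ST = 1 − Hw/Hb, which — unlike variance-component
  estimators — can legitimately go negative in panmictic panels.

All statistics operate on a :class:`~mtpopgen.alignio.SiteMask`, so the
caller decides whether "silent", "ungapped" or any custom site class is
analyzed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .alignio import LabeledAlignment, SiteMask, silent_mask, ungapped_mask
from .errors import (
    DegenerateInputError,
    GroupingError,
    InsufficientSampleError,
    SaturationError,
)

BOOTSTRAP_REPS = 1000


@dataclass(frozen=True)
class DiversityResult:
    pi: float
    pi_sd: float
    n_sequences: int
    n_sites: int
    n_segregating: int


@dataclass(frozen=True)
class TajimaResult:
    d_statistic: float
    theta_pi: float
    theta_w: float
    defined: bool


@dataclass(frozen=True)
class DifferentiationResult:
    d_xy: float
    d_a: float
    fst: float
    fst_defined: bool
    pi_within_1: float
    pi_within_2: float


def _pairwise_diff_matrix(rows: np.ndarray) -> np.ndarray:
    """Counts of differing columns for every pair of rows (n, n)."""
    n = rows.shape[0]
    diff = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        neq = rows[i + 1:] != rows[i]
        diff[i, i + 1:] = neq.sum(axis=1)
    return diff + diff.T


def _mean_pairwise_diff(rows: np.ndarray) -> float:
    """Mean number of differing columns over all unordered pairs."""
    n = rows.shape[0]
    diff = _pairwise_diff_matrix(rows)
    return float(diff[np.triu_indices(n, k=1)].mean())


def nucleotide_diversity(
    aln: LabeledAlignment,
    mask: SiteMask,
    *,
    bootstrap_reps: int = BOOTSTRAP_REPS,
    seed: int | None = None,
) -> DiversityResult:
    """π over masked columns, with a site-bootstrap standard deviation.

    π = [2 / (n(n−1))] Σ_{i<j} diff(i, j) / |mask|.  The SD resamples
    masked columns with replacement ``bootstrap_reps`` times; pass a seed
    for reproducibility (the SD is 0.0 when ``bootstrap_reps == 0``).
    """
    if aln.n_taxa < 2:
        raise InsufficientSampleError("need at least 2 sequences for pi")
    if len(mask) == 0:
        raise DegenerateInputError("empty site mask")
    rows = aln.matrix[:, mask.columns]
    n_seg = int((rows != rows[0]).any(axis=0).sum())
    pi = _mean_pairwise_diff(rows) / len(mask)
    pi_sd = 0.0
    if bootstrap_reps:
        rng = np.random.default_rng(seed)
        reps = np.empty(bootstrap_reps)
        L = rows.shape[1]
        for r in range(bootstrap_reps):
            cols = rng.integers(0, L, size=L)
            reps[r] = _mean_pairwise_diff(rows[:, cols]) / L
        pi_sd = float(reps.std(ddof=1))
    return DiversityResult(pi, pi_sd, aln.n_taxa, len(mask), n_seg)


def _tajima_constants(n: int):
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(aln: LabeledAlignment, mask: SiteMask) -> TajimaResult:
    """Tajima's D over masked columns.

    Uses total (not per-site) pairwise differences and the standard
    constants; when S = 0 the statistic is flagged undefined rather than
    returned as NaN.
    """
    n = aln.n_taxa
    if n < 4:
        raise InsufficientSampleError(f"Tajima's D needs n >= 4, got {n}")
    if len(mask) == 0:
        raise DegenerateInputError("empty site mask")
    rows = aln.matrix[:, mask.columns]
    S = int((rows != rows[0]).any(axis=0).sum())
    if S == 0:
        return TajimaResult(float("nan"), 0.0, 0.0, defined=False)
    a1, e1, e2 = _tajima_constants(n)
    k = _mean_pairwise_diff(rows)
    theta_w = S / a1
    variance = e1 * S + e2 * S * (S - 1)
    d = (k - theta_w) / math.sqrt(variance)
    return TajimaResult(d, k, theta_w, defined=True)


def jukes_cantor(p: float) -> float:
    """JC69 correction −(3/4)·ln(1 − 4p/3) of a p-distance."""
    if p >= 0.75:
        raise SaturationError(f"p-distance {p} is beyond the JC69 domain")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def differentiation(
    aln: LabeledAlignment,
    mask: SiteMask,
    group1: str,
    group2: str,
) -> DifferentiationResult:
    """d_XY, d_A and Hudson F_ST between two labeled groups.

    d_XY applies the JC correction to the *mean* between-group p-distance
    (not to each pair); d_A = d_XY − (JC(π₁) + JC(π₂))/2; and
    F_ST = 1 − Hw/Hb with Hw = (π₁ + π₂)/2 and Hb the uncorrected mean
    between-group p-distance.  Hb = Hw = 0 leaves F_ST undefined
    (``fst_defined`` False) instead of raising.
    """
    rows1 = aln.group_rows(group1)[:, mask.columns]
    rows2 = aln.group_rows(group2)[:, mask.columns]
    if rows1.shape[0] < 2 or rows2.shape[0] < 2:
        raise GroupingError("both groups need at least 2 sequences")
    if len(mask) == 0:
        raise DegenerateInputError("empty site mask")
    L = len(mask)
    pi1 = _mean_pairwise_diff(rows1) / L
    pi2 = _mean_pairwise_diff(rows2) / L
    between = np.zeros((rows1.shape[0], rows2.shape[0]), dtype=np.int64)
    for i in range(rows1.shape[0]):
        between[i] = (rows2 != rows1[i]).sum(axis=1)
    hb = float(between.mean()) / L
    hw = 0.5 * (pi1 + pi2)
    d_xy = jukes_cantor(hb)
    d_a = d_xy - 0.5 * (jukes_cantor(pi1) + jukes_cantor(pi2))
    if hb == 0.0:
        return DifferentiationResult(d_xy, d_a, float("nan"), False, pi1, pi2)
    return DifferentiationResult(d_xy, d_a, 1.0 - hw / hb, True, pi1, pi2)


def subsample_statistic(
    aln: LabeledAlignment,
    taxa_subset: list[str],
    statistic=nucleotide_diversity,
    *,
    mask_kind: str = "silent",
    **kwargs,
):
    """Recompute a statistic on a taxon subset, masks re-derived on the subset.

    This is the sampling-bias control: e.g. π_sil recomputed for the same
    three isolates available at another locus.  ``mask_kind`` is "silent",
    "ungapped" or "all".
    """
    if len(taxa_subset) < 2:
        raise InsufficientSampleError("subset must hold at least 2 taxa")
    sub = aln.restrict(taxa_subset)
    mask = _mask_by_kind(sub, mask_kind)
    return statistic(sub, mask, **kwargs)


def _mask_by_kind(aln: LabeledAlignment, kind: str) -> SiteMask:
    if kind == "silent":
        return silent_mask(aln)
    if kind == "ungapped":
        return ungapped_mask(aln)
    if kind == "all":
        return SiteMask(np.arange(aln.length), "all")
    raise ValueError(f"unknown mask kind {kind!r}")
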