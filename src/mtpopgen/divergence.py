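"""Pairwise divergence of duplicate genes: T3P distance, NG86 dN/dS, CAI.

Tools for comparing a locus copy against its progenitor (e.g. a gene
translocated into a mating locus versus its autosomal source):

* :func:`tamura3p` — Tamura 3-parameter nucleotide distance, which extends
  Kimura's two-parameter model with a GC-content term, plus a seeded
  site-bootstrap standard error and the aligned/indel/substitution counts
  usually printed alongside divergence bars;
* :func:`ng86_dnds` — Nei–Gojobori (1986) synonymous and non-synonymous
  rates with fractional site counting, minimal-pathway averaging for
  multi-difference codons, and Jukes–Cantor correction;
* :func:`cai` — codon adaptation index, the geometric mean of relative
  synonymous-codon adaptiveness against a reference usage table.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np

from .alignio import translate_codon
from .errors import CodingError, FrameError, SaturationError

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
_GAPPY = {"-", "N"}
BASES = "ACGT"


@dataclass(frozen=True)
class DistanceResult:
    d: float
    se: float
    n_aligned: int
    n_indels: int
    n_substitutions: int


@dataclass(frozen=True)
class CodonDivergenceResult:
    dN: float
    dS: float
    dn_ds: float
    ratio_defined: bool
    sites_syn: float
    sites_nonsyn: float


@dataclass(frozen=True)
class CAIResult:
    cai: float
    n_codons_scored: int


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def _t3p_from_counts(P: float, Q: float, theta: float) -> float:
    h = 2.0 * theta * (1.0 - theta)
    arg1 = 1.0 - P / h - Q if h > 0 else float("nan")
    arg2 = 1.0 - 2.0 * Q
    if h <= 0 or arg1 <= 0 or arg2 <= 0:
        raise SaturationError(
            f"T3P undefined for P={P:.4f}, Q={Q:.4f}, theta={theta:.4f}"
        )
    return -h * math.log(arg1) - 0.5 * (1.0 - h) * math.log(arg2)


def _t3p_arrays(a: np.ndarray, b: np.ndarray) -> float:
    n = a.size
    neq = a != b
    ts = sum(1 for x, y in zip(a[neq], b[neq]) if _is_transition(x, y))
    tv = int(neq.sum()) - ts
    gc = np.isin(a, ("G", "C")).sum() + np.isin(b, ("G", "C")).sum()
    theta = gc / (2.0 * n)
    return _t3p_from_counts(ts / n, tv / n, theta)


def tamura3p(
    seqA: str,
    seqB: str,
    bootstrap_reps: int = 1000,
    seed: int | None = None,
) -> DistanceResult:
    """Tamura 3-parameter distance between two aligned sequences.

    Gapped columns are dropped pairwise; θ is the mean GC fraction of the
    two sequences over the analyzed columns jointly.  ``se`` is the
    standard deviation of the distance over site-bootstrap replicates
    (replicates that saturate are skipped); indels are counted as events
    (one maximal gap run = one indel) for reporting only.
    """
    if len(seqA) != len(seqB):
        raise FrameError("aligned pair must have equal length")
    a = np.array(list(seqA.upper()), dtype="U1")
    b = np.array(list(seqB.upper()), dtype="U1")
    ok = ~(np.isin(a, list(_GAPPY)) | np.isin(b, list(_GAPPY)))
    if not ok.any():
        raise SaturationError("no analyzable columns")
    n_indels = _count_indel_events(a, b)
    aa, bb = a[ok], b[ok]
    n_subs = int((aa != bb).sum())
    d = _t3p_arrays(aa, bb)
    se = 0.0
    if bootstrap_reps:
        rng = np.random.default_rng(seed)
        L = aa.size
        reps = []
        for _ in range(bootstrap_reps):
            cols = rng.integers(0, L, size=L)
            try:
                reps.append(_t3p_arrays(aa[cols], bb[cols]))
            except SaturationError:
                continue
        if len(reps) > 1:
            se = float(np.std(reps, ddof=1))
    return DistanceResult(d, se, int(ok.sum()), n_indels, n_subs)


def _count_indel_events(a: np.ndarray, b: np.ndarray) -> int:
    gap = (a == "-") ^ (b == "-")  # gap in exactly one sequence
    return int(np.diff(np.concatenate(([0], gap.view(np.int8)))).clip(min=0).sum())


# -- NG86 dN/dS -------------------------------------------------------------


def _codon_sites(codon: str) -> tuple[float, float]:
    """Fractional (synonymous, nonsynonymous) site counts of one codon.

    Each position contributes the fraction of its three possible changes
    that are synonymous; changes creating a stop codon count as
    non-synonymous.
    """
    aa = translate_codon(codon)
    syn = 0.0
    for pos in range(3):
        for alt in BASES:
            if alt == codon[pos]:
                continue
            mutant = codon[:pos] + alt + codon[pos + 1:]
            if translate_codon(mutant) == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _codon_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, pathway-averaged.

    All orders of the single-base changes turning c1 into c2 are
    enumerated; pathways passing through a stop codon are discarded (all
    pathways are kept if every one is blocked).
    """
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nsyn = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if translate_codon(nxt) == "*" and nxt != c2:
                blocked = True
            if translate_codon(nxt) == translate_codon(cur):
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        paths.append((syn, nsyn, blocked))
    open_paths = [(s, n) for s, n, blk in paths if not blk]
    if not open_paths:
        open_paths = [(s, n) for s, n, _ in paths]
    syn = sum(p[0] for p in open_paths) / len(open_paths)
    nsyn = sum(p[1] for p in open_paths) / len(open_paths)
    return syn, nsyn


def ng86_dnds(cdsA: str, cdsB: str) -> CodonDivergenceResult:
    """Nei–Gojobori dN and dS for a codon-aligned pair of CDS.

    Site counts are averaged over the two sequences; codon pairs
    containing a gap or N are skipped; p-distances are Jukes–Cantor
    corrected separately.  When dS = 0 the ratio is flagged undefined.
    """
    if len(cdsA) != len(cdsB):
        raise FrameError("codon-aligned pair must have equal length")
    if len(cdsA) % 3:
        raise FrameError(f"length {len(cdsA)} is not a multiple of 3")
    A, B = cdsA.upper(), cdsB.upper()
    sitesA = sitesB = 0.0
    Sd = Nd = 0.0
    for i in range(0, len(A), 3):
        c1, c2 = A[i: i + 3], B[i: i + 3]
        if any(ch in _GAPPY for ch in c1 + c2):
            continue
        for c, name in ((c1, "first"), (c2, "second")):
            if translate_codon(c) == "*" and i + 3 < len(A):
                raise CodingError(f"internal stop codon {c} in {name} sequence")
        s1, _ = _codon_sites(c1)
        s2, _ = _codon_sites(c2)
        sitesA += s1
        sitesB += s2
        ds, dn = _codon_differences(c1, c2)
        Sd += ds
        Nd += dn
    S_sites = 0.5 * (sitesA + sitesB)
    n_analyzed = sum(
        1
        for i in range(0, len(A), 3)
        if not any(ch in _GAPPY for ch in A[i: i + 3] + B[i: i + 3])
    )
    N_sites = 3.0 * n_analyzed - S_sites
    if n_analyzed == 0:
        raise CodingError("no analyzable codons")
    pS = Sd / S_sites if S_sites > 0 else 0.0
    pN = Nd / N_sites if N_sites > 0 else 0.0
    dS = _jc(pS)
    dN = _jc(pN)
    if dS > 0:
        return CodonDivergenceResult(dN, dS, dN / dS, True, S_sites, N_sites)
    return CodonDivergenceResult(dN, dS, float("nan"), False, S_sites, N_sites)


def _jc(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p} beyond the JC69 domain")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


# -- codon adaptation index -------------------------------------------------

_EXCLUDED_CODONS = {"ATG", "TGG"} | {
    c for c in ("".join(t) for t in itertools.product(BASES, repeat=3))
    if translate_codon(c) == "*"
}


def relative_adaptiveness(codon_usage: dict[str, float]) -> dict[str, float]:
    """w(codon) = usage / max usage within its synonymous family."""
    families: dict[str, list[str]] = {}
    for c in ("".join(t) for t in itertools.product(BASES, repeat=3)):
        aa = translate_codon(c)
        if aa != "*":
            families.setdefault(aa, []).append(c)
    w = {}
    for aa, codons in families.items():
        peak = max(codon_usage.get(c, 0.0) for c in codons)
        for c in codons:
            w[c] = codon_usage.get(c, 0.0) / peak if peak > 0 else 0.0
    return w


def cai(
    cds: str, codon_usage: dict[str, float], *, zero_usage_epsilon: float = 0.01
) -> CAIResult:
    """Codon adaptation index of a CDS against a reference usage table.

    CAI = exp[(1/L′) Σ ln w], scored over all codons except Met, Trp and
    stops (whose families admit no choice).  Codons with zero reference
    usage get w floored at ``zero_usage_epsilon`` with a warning.
    """
    if len(cds) % 3:
        raise FrameError(f"CDS length {len(cds)} is not a multiple of 3")
    w = relative_adaptiveness(codon_usage)
    log_sum = 0.0
    scored = 0
    seq = cds.upper()
    for i in range(0, len(seq), 3):
        codon = seq[i: i + 3]
        if any(ch in _GAPPY for ch in codon) or codon in _EXCLUDED_CODONS:
            continue
        if translate_codon(codon) == "*":
            continue
        wc = w.get(codon, 0.0)
        if wc <= 0.0:
            warnings.warn(
                f"codon {codon} has zero reference usage; w floored at "
                f"{zero_usage_epsilon}",
                stacklevel=2,
            )
            wc = zero_usage_epsilon
        log_sum += math.log(wc)
        scored += 1
    if scored == 0:
        raise CodingError("no scorable codons in CDS")
    return CAIResult(math.exp(log_sum / scored), scored)


def read_codon_usage(path) -> dict[str, float]:
    """Read a codon-usage TSV (codon<TAB>count-or-frequency)."""
    usage = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            codon, value = line.split("\t")
            usage[codon.upper().replace("U", "T")] = float(value)
    return usage
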