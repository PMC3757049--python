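"""Parsimony-splits networks: weighted, weakly compatible split systems.

A split is an unordered bipartition of the taxa.  The parsimony-splits
method scores a candidate non-trivial split A|B by the minimum, over all
quartets a, a′ ∈ A, b, b′ ∈ B, of

    s(aa′|bb′) − min(s(ab|a′b′), s(ab′|a′b))

where s(xy|zw) counts alignment columns at which x and y share a state, z
and w share a state, and the two states differ.  Subtracting the smaller
of the two cross-pairings lets a pair of equally supported conflicting
characters yield both splits — the boxes that make these networks more
informative than trees — while on homoplasy-free tree data the index
still returns exactly the generating tree's splits.  At most two of the
three pairings of any quartet can score positive under this index, so
accepted splits always form a weakly compatible system (no three splits
restrict to the three conflicting 2|2 bipartitions of any four taxa).  Candidate splits are
enumerated exhaustively — at panel sizes of a dozen-odd taxa the
2^(n−1) − n − 1 candidates are trivially affordable and easy to verify.

Identical sequences are collapsed to one node before analysis and
re-expanded in the output; node sizes record how many isolates each node
carries.  Bootstrap support is the fraction of site-resampling replicates
whose split set contains the split.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .alignio import GAP_CHARS, LabeledAlignment
from .errors import SizeError

MAX_EXHAUSTIVE_TAXA = 20


@dataclass(frozen=True)
class Split:
    """Taxon bipartition with a count-valued weight and optional support."""

    side_a: frozenset
    side_b: frozenset
    weight: int = 0
    bootstrap: float | None = None

    @staticmethod
    def canonical(side_a, side_b, weight=0, bootstrap=None) -> "Split":
        a, b = frozenset(side_a), frozenset(side_b)
        if a & b or not a or not b:
            raise ValueError("split sides must be disjoint and non-empty")
        if sorted(a) > sorted(b):
            a, b = b, a
        return Split(a, b, weight, bootstrap)

    @property
    def bipartition(self) -> tuple:
        return (self.side_a, self.side_b)

    def is_trivial(self) -> bool:
        return min(len(self.side_a), len(self.side_b)) == 1


@dataclass
class SplitSystem:
    """A set of splits over common taxa, including all trivial splits."""

    taxa: list[str]
    splits: list[Split]
    node_sizes: dict[str, int] = field(default_factory=dict)

    def nontrivial(self) -> list[Split]:
        return [s for s in self.splits if not s.is_trivial()]

    def contains_bipartition(self, side: set) -> bool:
        side = frozenset(side)
        other = frozenset(self.taxa) - side
        return any({s.side_a, s.side_b} == {side, other} for s in self.splits)

    def is_weakly_compatible(self) -> bool:
        """Bandelt–Dress weak compatibility, by exhaustive quadruple check.

        Equivalent to the triple-wise condition: the system is weakly
        compatible iff no four taxa exist on which three splits restrict
        to the three distinct conflicting 2|2 bipartitions.
        """
        nts = self.nontrivial()
        if len(nts) < 3:
            return True
        for quad in itertools.combinations(self.taxa, 4):
            patterns = set()
            for s in nts:
                p = _quartet_pattern(s, quad)
                if p is not None:
                    patterns.add(p)
            if len(patterns) == 3:
                return False
        return True


def _quartet_pattern(split: Split, quad: tuple) -> int | None:
    """Which 2|2 bipartition (0, 1 or 2) a split induces on four taxa."""
    inside = [t in split.side_a for t in quad]
    if sum(inside) != 2:
        return None
    if inside[0] == inside[1]:
        return 0  # q0q1 | q2q3
    if inside[0] == inside[2]:
        return 1  # q0q2 | q1q3
    return 2  # q0q3 | q1q2


# -- column preparation -----------------------------------------------------


def _ungapped_matrix(aln: LabeledAlignment) -> np.ndarray:
    keep = ~np.isin(aln.matrix, list(GAP_CHARS)).any(axis=0)
    return aln.matrix[:, keep]


def _collapse_identical(taxa: list[str], matrix: np.ndarray):
    """Group identical rows; the first taxon of each class represents it."""
    classes: list[list[int]] = []
    for i in range(matrix.shape[0]):
        for cls in classes:
            if (matrix[i] == matrix[cls[0]]).all():
                cls.append(i)
                break
        else:
            classes.append([i])
    reps = [cls[0] for cls in classes]
    rep_taxa = [taxa[i] for i in reps]
    members = {taxa[cls[0]]: [taxa[i] for i in cls] for cls in classes}
    return rep_taxa, matrix[reps], members


# -- quartet scoring --------------------------------------------------------


def _quartet_counts(rows: np.ndarray) -> tuple[int, int, int]:
    """(s(01|23), s(02|13), s(03|12)) for a 4-row character matrix."""
    r0, r1, r2, r3 = rows
    s0 = int(((r0 == r1) & (r2 == r3) & (r0 != r2)).sum())
    s1 = int(((r0 == r2) & (r1 == r3) & (r0 != r1)).sum())
    s2 = int(((r0 == r3) & (r1 == r2) & (r0 != r1)).sum())
    return s0, s1, s2


def quartet_support(aln: LabeledAlignment, a: str, a2: str, b: str, b2: str):
    """Column-count support for the three pairings of four taxa.

    Returns (s(a a2|b b2), s(a b|a2 b2), s(a b2|a2 b)) over ungapped
    columns.
    """
    names = [a, a2, b, b2]
    if len(set(names)) != 4:
        raise ValueError("four distinct taxa required")
    keep = ~np.isin(aln.matrix, list(GAP_CHARS)).any(axis=0)
    rows = np.vstack([aln.row(t)[keep] for t in names])
    return _quartet_counts(rows)


def _pairing_index(i: int, j: int, quad: tuple[int, int, int, int]) -> int:
    """Index of the pairing that joins i and j within the sorted quartet."""
    w, x, y, z = quad
    pair = {i, j}
    if pair == {w, x} or pair == {y, z}:
        return 0
    if pair == {w, y} or pair == {x, z}:
        return 1
    return 2


def _split_weight(A: tuple[int, ...], B: tuple[int, ...], qs) -> int:
    """min over quartets of s(aa′|bb′) − min(cross pairings); early exit ≤ 0."""
    weight = None
    for i, j in itertools.combinations(A, 2):
        for k, l in itertools.combinations(B, 2):
            quad = tuple(sorted((i, j, k, l)))
            counts = qs[quad]
            own_idx = _pairing_index(i, j, quad)
            own = counts[own_idx]
            others = [c for idx, c in enumerate(counts) if idx != own_idx]
            w = own - min(others)
            if weight is None or w < weight:
                weight = w
                if weight <= 0:
                    return weight
    return weight


def parsimony_splits(
    aln: LabeledAlignment,
    *,
    collapse_identical: bool = True,
    max_taxa: int = MAX_EXHAUSTIVE_TAXA,
) -> SplitSystem:
    """Exhaustive parsimony-splits system of an alignment.

    Gapped columns are dropped (complete deletion), identical sequences
    are collapsed to one node, every candidate non-trivial split of the
    collapsed taxa is scored, and positive-weight splits are kept.
    Trivial splits are always included, weighted by the taxon's count of
    private states.  Output splits are re-expanded to the full taxon set.
    """
    matrix = _ungapped_matrix(aln)
    taxa = list(aln.taxa)
    if collapse_identical:
        rep_taxa, matrix, members = _collapse_identical(taxa, matrix)
    else:
        rep_taxa, members = taxa, {t: [t] for t in taxa}
    n = len(rep_taxa)
    if n > max_taxa:
        raise SizeError(
            f"{n} distinct sequences exceed the exhaustive-enumeration guard "
            f"({max_taxa}); sub-sample the panel"
        )
    splits = _splits_of_matrix(rep_taxa, matrix, members, set(taxa))
    sizes = {t: len(members[t]) for t in rep_taxa}
    return SplitSystem(taxa, splits, sizes)


def _candidate_sides(n: int):
    """Non-trivial candidate sides containing index 0 (one per bipartition)."""
    rest = range(1, n)
    for size in range(1, n - 2):
        for combo in itertools.combinations(rest, size):
            yield (0, *combo)


def _expanded(rep_side: set, expand: dict) -> set:
    out = set()
    for t in rep_side:
        out.update(expand[t])
    return out


def _trivial_splits(rep_taxa, matrix, expand, all_taxa: set) -> list[Split]:
    splits = []
    for i, t in enumerate(rep_taxa):
        others = np.delete(matrix, i, axis=0)
        private = int(
            ((matrix[i] != others).all(axis=0)).sum()
        ) if others.size else 0
        side = _expanded({t}, expand)
        splits.append(Split.canonical(side, all_taxa - side, weight=private))
    return splits


def bootstrap_splits(
    aln: LabeledAlignment,
    reps: int = 1000,
    seed: int | None = None,
    *,
    collapse_identical: bool = True,
) -> SplitSystem:
    """Site-bootstrap support for the parsimony splits of a panel.

    Identical sequences are collapsed before resampling; support of each
    original split is the fraction of replicates whose split set contains
    the same bipartition.  Seed-reproducible.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = parsimony_splits(aln, collapse_identical=collapse_identical)
    matrix = _ungapped_matrix(aln)
    taxa = list(aln.taxa)
    if collapse_identical:
        rep_taxa, matrix, members = _collapse_identical(taxa, matrix)
    else:
        rep_taxa, members = taxa, {t: [t] for t in taxa}
    rng = np.random.default_rng(seed)
    L = matrix.shape[1]
    hits = {s.bipartition: 0 for s in base.splits}
    rep_aln_taxa = rep_taxa
    for _ in range(reps):
        cols = rng.integers(0, L, size=L)
        boot = _splits_of_matrix(rep_aln_taxa, matrix[:, cols], members, set(taxa))
        found = {s.bipartition for s in boot}
        for bip in hits:
            if bip in found:
                hits[bip] += 1
    supported = [
        Split(s.side_a, s.side_b, s.weight, hits[s.bipartition] / reps)
        for s in base.splits
    ]
    return SplitSystem(base.taxa, supported, base.node_sizes)


def _splits_of_matrix(rep_taxa, matrix, members, all_taxa):
    """Split set of a (possibly resampled) collapsed character matrix."""
    n = len(rep_taxa)
    expand = {t: members[t] for t in rep_taxa}
    splits = _trivial_splits(rep_taxa, matrix, expand, all_taxa)
    if n >= 4:
        qs = {
            quad: _quartet_counts(matrix[list(quad)])
            for quad in itertools.combinations(range(n), 4)
        }
        for split_a in _candidate_sides(n):
            split_b = tuple(i for i in range(n) if i not in split_a)
            w = _split_weight(split_a, split_b, qs)
            if w > 0:
                side_a = _expanded({rep_taxa[i] for i in split_a}, expand)
                splits.append(Split.canonical(side_a, all_taxa - side_a, weight=w))
    return splits


# -- export -----------------------------------------------------------------


def write_nexus(system: SplitSystem, path):
    """Write a NEXUS file with Taxa and Splits blocks (viewer-compatible)."""
    taxa = system.taxa
    index = {t: i + 1 for i, t in enumerate(taxa)}
    with open(path, "w") as fh:
        fh.write("#nexus\n\nBEGIN Taxa;\n")
        fh.write(f"DIMENSIONS ntax={len(taxa)};\nTAXLABELS\n")
        for i, t in enumerate(taxa, 1):
            fh.write(f"[{i}] '{t}'\n")
        fh.write(";\nEND;\n\nBEGIN Splits;\n")
        fh.write(f"DIMENSIONS ntax={len(taxa)} nsplits={len(system.splits)};\n")
        fh.write("FORMAT labels=no weights=yes confidences=yes;\nMATRIX\n")
        for k, s in enumerate(system.splits, 1):
            side = sorted(index[t] for t in s.side_a)
            conf = 0.0 if s.bootstrap is None else round(100.0 * s.bootstrap)
            ids = " ".join(str(i) for i in side)
            fh.write(f"[{k}]\t{s.weight}\t{conf}\t{ids},\n")
        fh.write(";\nEND;\n")


def splits_to_tsv(system: SplitSystem, path):
    import pandas as pd

    rows = [
        {
            "side_a": ",".join(sorted(s.side_a)),
            "side_b": ",".join(sorted(s.side_b)),
            "weight": s.weight,
            "bootstrap": "" if s.bootstrap is None else f"{s.bootstrap:.3f}",
        }
        for s in system.splits
    ]
    pd.DataFrame(rows, columns=["side_a", "side_b", "weight", "bootstrap"]).to_csv(
        path, sep="\t", index=False
    )
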