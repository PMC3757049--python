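"""Labeled multiple alignments and site-class masks.

An alignment panel couples equal-length sequences (FASTA), a taxon → group
sample sheet (e.g. "MT+" / "MT-" / "autosomal"), and a per-column annotation
of region class (exon/intron/UTR/intergenic) with reading frame for exons.
Every downstream statistic consumes a :class:`SiteMask` built here, so the
gap policy (complete deletion: any column holding '-' or 'N' in any sequence
is dropped) and the synonymy rule live in one place.

Coordinates in every file and report are 1-based inclusive; internally
columns are 0-based numpy indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Data.CodonTable import standard_dna_table

from .errors import AlignmentError, AnnotationError, LabelingError

VALID_REGIONS = ("exon", "intron", "UTR", "intergenic")
GAP_CHARS = ("-", "N")

_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"


def translate_codon(codon: str) -> str | None:
    """Amino acid (or '*' for stop) for a codon; None if ambiguous/gapped."""
    return _CODON_TO_AA.get(codon.upper())


@dataclass(frozen=True)
class AnnotationBlock:
    """One annotated region, 1-based inclusive coordinates.

    ``frame`` is the codon position (0, 1 or 2) of the block's first column
    and is defined iff ``region == "exon"``.
    """

    start: int
    end: int
    region: str
    frame: int | None = None

    def __post_init__(self):
        if self.region not in VALID_REGIONS:
            raise AnnotationError(f"unknown region class {self.region!r}")
        if self.start < 1 or self.end < self.start:
            raise AnnotationError(
                f"bad block coordinates {self.start}..{self.end} (1-based inclusive)"
            )
        if (self.region == "exon") != (self.frame is not None):
            raise AnnotationError("frame must be given iff region is exon")
        if self.frame is not None and self.frame not in (0, 1, 2):
            raise AnnotationError(f"frame must be 0, 1 or 2, got {self.frame}")


@dataclass
class LabeledAlignment:
    """Aligned sequences with group labels and per-column region annotation."""

    taxa: list[str]
    group_of: dict[str, str]
    matrix: np.ndarray  # (n_taxa, L) of single uppercase characters
    region: np.ndarray  # (L,) region class per column
    codon_start: np.ndarray  # (L,) column index of codon start, -1 if none

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype="U1")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.taxa):
            raise AlignmentError("matrix shape does not match taxon list")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon identifiers")
        missing = [t for t in self.taxa if t not in self.group_of]
        if missing:
            raise LabelingError(f"taxa without group label: {missing}")
        if self.region.shape != (self.length,) or self.codon_start.shape != (self.length,):
            raise AnnotationError("annotation arrays do not span the alignment")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_sequences(
        cls,
        sequences: dict[str, str],
        group_of: dict[str, str],
        blocks: list[AnnotationBlock] | None = None,
    ) -> "LabeledAlignment":
        taxa = list(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(f"sequences of unequal length: {sorted(lengths)}")
        (L,) = lengths
        matrix = np.array([list(sequences[t].upper()) for t in taxa], dtype="U1")
        region, codon_start = _annotate_columns(L, blocks)
        unknown = [t for t in taxa if t not in group_of]
        if unknown:
            raise LabelingError(f"no group label for taxa {unknown}")
        labels = {t: group_of[t] for t in taxa}
        return cls(taxa, labels, matrix, region, codon_start)

    # -- basic queries -----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for t in self.taxa:
            g = self.group_of[t]
            if g not in seen:
                seen.append(g)
        return seen

    def members(self, group: str) -> list[str]:
        return [t for t in self.taxa if self.group_of[t] == group]

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.matrix[self.taxa.index(taxon)]
        except ValueError:
            raise LabelingError(f"unknown taxon {taxon!r}") from None

    def group_rows(self, group: str) -> np.ndarray:
        idx = [i for i, t in enumerate(self.taxa) if self.group_of[t] == group]
        return self.matrix[idx]

    def restrict(self, taxa_subset: list[str]) -> "LabeledAlignment":
        """Sub-panel on a taxon subset; annotation is carried over."""
        unknown = [t for t in taxa_subset if t not in self.taxa]
        if unknown:
            raise LabelingError(f"unknown taxa {unknown}")
        idx = [self.taxa.index(t) for t in taxa_subset]
        return LabeledAlignment(
            list(taxa_subset),
            {t: self.group_of[t] for t in taxa_subset},
            self.matrix[idx].copy(),
            self.region.copy(),
            self.codon_start.copy(),
        )


def _annotate_columns(L: int, blocks: list[AnnotationBlock] | None):
    """Expand annotation blocks to per-column region/codon arrays.

    Columns not covered by any block default to "intergenic".  A codon is
    attached to a column only when the full triplet lies inside one exon
    block; truncated codons at block edges stay unattached (codon_start -1)
    and are never classed as silent.
    """
    region = np.full(L, "intergenic", dtype="U10")
    codon_start = np.full(L, -1, dtype=np.int64)
    if blocks is None:
        return region, codon_start
    covered = np.zeros(L, dtype=bool)
    for b in blocks:
        if b.end > L:
            raise AnnotationError(f"block {b.start}..{b.end} exceeds alignment length {L}")
        s, e = b.start - 1, b.end  # 0-based half-open
        if covered[s:e].any():
            raise AnnotationError(f"overlapping annotation at {b.start}..{b.end}")
        covered[s:e] = True
        region[s:e] = b.region
        if b.region == "exon":
            for i in range(s, e):
                pos = (b.frame + (i - s)) % 3
                start = i - pos
                if start >= s and start + 3 <= e:
                    codon_start[i] = start
    return region, codon_start


# -- file I/O ---------------------------------------------------------------


def read_alignment(fasta_path, samplesheet_path, annotation_path=None) -> LabeledAlignment:
    """Read FASTA + sample sheet (+ optional annotation) into a panel.

    The sample sheet is a two-column TSV ``taxon<TAB>group``; the annotation
    file is a TSV ``start<TAB>end<TAB>region<TAB>frame`` with 1-based
    inclusive coordinates and frame "." outside exons.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {fasta_path}")
    sequences = {r.id: str(r.seq) for r in records}
    group_of = read_samplesheet(samplesheet_path)
    unknown = [t for t in sequences if t not in group_of]
    if unknown:
        raise LabelingError(f"FASTA ids missing from sample sheet: {unknown}")
    blocks = read_annotation(annotation_path) if annotation_path is not None else None
    return LabeledAlignment.from_sequences(sequences, group_of, blocks)


def read_samplesheet(path) -> dict[str, str]:
    group_of: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LabelingError(f"bad sample-sheet line: {line!r}")
            group_of[parts[0]] = parts[1]
    return group_of


def read_annotation(path) -> list[AnnotationBlock]:
    blocks = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise AnnotationError(f"bad annotation line: {line!r}")
            start, end, region, frame = parts
            blocks.append(
                AnnotationBlock(
                    int(start), int(end), region, None if frame == "." else int(frame)
                )
            )
    return blocks


def write_alignment(aln: LabeledAlignment, fasta_path, samplesheet_path, annotation_path=None):
    """Write the panel back to FASTA + sample sheet (+ annotation)."""
    records = [
        SeqRecord(Seq("".join(aln.matrix[i])), id=t, description="")
        for i, t in enumerate(aln.taxa)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(samplesheet_path, "w") as fh:
        for t in aln.taxa:
            fh.write(f"{t}\t{aln.group_of[t]}\n")
    if annotation_path is not None:
        with open(annotation_path, "w") as fh:
            for blk in annotation_blocks(aln):
                frame = "." if blk.frame is None else str(blk.frame)
                fh.write(f"{blk.start}\t{blk.end}\t{blk.region}\t{frame}\n")


def annotation_blocks(aln: LabeledAlignment) -> list[AnnotationBlock]:
    """Recover maximal annotation blocks from the per-column arrays."""
    blocks: list[AnnotationBlock] = []
    L = aln.length
    i = 0
    while i < L:
        reg = str(aln.region[i])
        j = i
        while j + 1 < L and str(aln.region[j + 1]) == reg:
            j += 1
        if reg == "exon":
            cs = int(aln.codon_start[i: j + 1].max())
            # Codon starts inside one block share the same grid (mod 3), so
            # any of them recovers the first column's codon position.
            frame = (i - cs) % 3 if cs >= 0 else 0
            blocks.append(AnnotationBlock(i + 1, j + 1, reg, frame))
        elif reg != "intergenic":
            blocks.append(AnnotationBlock(i + 1, j + 1, reg))
        i = j + 1
    return blocks


# -- site masks -------------------------------------------------------------


@dataclass(frozen=True)
class SiteMask:
    """Ordered subset of alignment columns (0-based internally)."""

    columns: np.ndarray
    kind: str

    def __post_init__(self):
        cols = np.asarray(self.columns, dtype=np.int64)
        object.__setattr__(self, "columns", cols)
        if cols.size and not np.all(np.diff(cols) > 0):
            raise AlignmentError("mask columns must be strictly increasing")

    def __len__(self) -> int:
        return int(self.columns.size)

    @property
    def positions(self) -> np.ndarray:
        """1-based column positions, for reports."""
        return self.columns + 1

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("position\n")
            for p in self.positions:
                fh.write(f"{p}\n")


def ungapped_mask(aln: LabeledAlignment) -> SiteMask:
    """Complete-deletion mask: drop any column with '-' or 'N' anywhere.

    'N' is treated like a gap: a miscalled base would otherwise fabricate
    polymorphism.
    """
    bad = np.zeros(aln.length, dtype=bool)
    for ch in GAP_CHARS:
        bad |= (aln.matrix == ch).any(axis=0)
    return SiteMask(np.flatnonzero(~bad), "ungapped")


def silent_mask(aln: LabeledAlignment) -> SiteMask:
    """Silent sites: ungapped non-coding columns plus synonymous exon columns.

    An exon column is synonymous iff every observed base at that column
    leaves the amino acid unchanged in every sequence's codon context
    (codons containing gaps are excluded from the contexts; strict rule).
    """
    ung = ungapped_mask(aln).columns
    keep = []
    for col in ung:
        reg = str(aln.region[col])
        if reg != "exon":
            keep.append(col)
            continue
        cs = int(aln.codon_start[col])
        if cs < 0:
            # Truncated codon at an exon-block edge: synonymy cannot be
            # assessed, so the column is excluded (frame-less exon blocks
            # are already rejected when the annotation is parsed).
            continue
        if _column_is_synonymous(aln, col, cs):
            keep.append(col)
    return SiteMask(np.asarray(keep, dtype=np.int64), "silent")


def _column_is_synonymous(aln: LabeledAlignment, col: int, cs: int) -> bool:
    observed = {b for b in aln.matrix[:, col] if b not in GAP_CHARS}
    pos = col - cs
    for i in range(aln.n_taxa):
        codon = "".join(aln.matrix[i, cs: cs + 3])
        if any(c in GAP_CHARS for c in codon):
            continue
        aa = translate_codon(codon)
        if aa is None:
            continue
        for b in observed:
            mutant = codon[:pos] + b + codon[pos + 1:]
            if translate_codon(mutant) != aa:
                return False
    return True
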