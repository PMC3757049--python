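"""Polymorphism tables and gene-conversion tract detection.

The polymorphism table is the machine-readable form of the classic
"polymorphic positions" figure: every segregating ungapped column of a
two-group panel, plus insertion/deletion polymorphisms collapsed to single
events, each classified by region, substitution type (synonymous /
non-synonymous for exonic sites) and group specificity.

Tract detection follows Betrán's logic: among *informative* sites — sites
(nearly) fixed for different alleles between the two haplotype groups — a
run of two or more consecutive sites at which the same subset of recipient
isolates carries the donor group's allele is a candidate conversion tract.
Its probability is ∏ψ_i where ψ_i is the frequency of the donor-typical
pattern within the recipient group at site i; the manual criterion
ψ = 1/3 over k = 4 sites gives 0.33⁴ ≈ 0.012.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import prod

import numpy as np
import pandas as pd

from .alignio import LabeledAlignment, ungapped_mask, _column_is_synonymous
from .errors import GroupingError

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class PolymorphismTable:
    """Per-site polymorphism catalogue for a two-group panel.

    ``df`` is indexed by 1-based alignment position with one allele column
    per taxon plus ``region``, ``styp`` (S/N/""), ``klass`` and ``indel``.
    """

    df: pd.DataFrame
    group1: str
    group2: str
    members1: tuple[str, ...]
    members2: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def taxa(self) -> tuple[str, ...]:
        return self.members1 + self.members2

    def to_tsv(self, path):
        out = self.df.copy()
        out.insert(0, "position", out.index)
        out.rename(columns={"styp": "typ", "region": "dom", "klass": "class"}).to_csv(
            path, sep="\t", index=False
        )


@dataclass(frozen=True)
class ConversionTract:
    """A candidate gene-conversion tract, donor_group → recipient_group."""

    recipient_group: str
    donor_group: str
    recipient_taxa: tuple[str, ...]
    sites: tuple[int, ...]  # 1-based positions, consecutive informative sites
    psi_per_site: tuple[float, ...]
    p_value: float


def _classify_site(alleles1: set[str], alleles2: set[str], g1: str, g2: str) -> str:
    """Mutually exclusive specificity classes for a segregating site."""
    if len(alleles1) == 1 and len(alleles2) == 1:
        return "fixed"
    if len(alleles2) == 1:  # group 1 segregates
        (a2,) = alleles2
        return f"segregating-within-{g1}" if a2 in alleles1 else f"{g1}-specific"
    if len(alleles1) == 1:
        (a1,) = alleles1
        return f"segregating-within-{g2}" if a1 in alleles2 else f"{g2}-specific"
    return "shared"


def build_polymorphism_table(
    aln: LabeledAlignment, group1: str | None = None, group2: str | None = None
) -> PolymorphismTable:
    """List and classify all segregating sites of a two-group panel.

    Substitution (SNP) sites are ungapped segregating columns; indel
    polymorphisms are reported as single events (one row per maximal run of
    gap columns with an identical gapped-taxon set), with alleles coded
    "-" (deletion) / "+" (presence).
    """
    groups = aln.groups
    if group1 is None or group2 is None:
        if len(groups) < 2:
            raise GroupingError("panel has fewer than two groups")
        group1, group2 = groups[0], groups[1]
    m1, m2 = aln.members(group1), aln.members(group2)
    if not m1 or not m2:
        raise GroupingError(f"empty group among ({group1!r}, {group2!r})")
    taxa = m1 + m2
    rows = np.vstack([aln.row(t) for t in taxa])
    n1 = len(m1)

    records = []
    # SNP sites over ungapped columns
    for col in ungapped_mask(aln).columns:
        alleles = rows[:, col]
        if (alleles == alleles[0]).all():
            continue
        a1, a2 = set(alleles[:n1]), set(alleles[n1:])
        reg = str(aln.region[col])
        styp = ""
        if reg == "exon":
            cs = int(aln.codon_start[col])
            if cs >= 0:
                styp = "S" if _column_is_synonymous(aln, int(col), cs) else "N"
        records.append(
            {
                "position": int(col) + 1,
                **{t: alleles[i] for i, t in enumerate(taxa)},
                "region": reg,
                "styp": styp,
                "klass": _classify_site(a1, a2, group1, group2),
                "indel": False,
            }
        )
    # Indel events: maximal runs of gap columns sharing a gapped-taxon set
    records.extend(_indel_events(aln, rows, taxa, n1, group1, group2))
    df = pd.DataFrame.from_records(records)
    if len(df):
        df = df.sort_values("position").set_index("position")
    else:
        df = pd.DataFrame(
            columns=[*taxa, "region", "styp", "klass", "indel"],
            index=pd.Index([], name="position"),
        )
    return PolymorphismTable(df, group1, group2, tuple(m1), tuple(m2))


def _indel_events(aln, rows, taxa, n1, group1, group2):
    has_gap = (rows == "-").any(axis=0)
    records = []
    col = 0
    L = rows.shape[1]
    while col < L:
        if not has_gap[col]:
            col += 1
            continue
        gapped = frozenset(np.flatnonzero(rows[:, col] == "-"))
        end = col
        while end + 1 < L and has_gap[end + 1] and frozenset(
            np.flatnonzero(rows[:, end + 1] == "-")
        ) == gapped:
            end += 1
        if len(gapped) < len(taxa):  # all-gap runs are not polymorphisms
            alleles = np.array(
                ["-" if i in gapped else "+" for i in range(len(taxa))]
            )
            a1, a2 = set(alleles[:n1]), set(alleles[n1:])
            records.append(
                {
                    "position": col + 1,
                    **{t: alleles[i] for i, t in enumerate(taxa)},
                    "region": str(aln.region[col]),
                    "styp": "",
                    "klass": _classify_site(a1, a2, group1, group2),
                    "indel": True,
                }
            )
        col = end + 1
    return records


def _majority(alleles: np.ndarray) -> tuple[str, float]:
    """Majority allele and its frequency; lexicographic tie-break."""
    values, counts = np.unique(alleles, return_counts=True)
    best = counts.max()
    winner = min(values[counts == best])
    return str(winner), best / alleles.size


def informative_sites(table: PolymorphismTable, min_fixation: float = 1.0) -> list[int]:
    """Sites whose group-majority alleles differ, each at frequency ≥ min_fixation.

    ``min_fixation = 1.0`` demands fully fixed differences; values < 1 admit
    the "nearly fixed" sites through which conversion tracts are visible
    (a converted site is by construction not fixed in the recipient group).
    Indel events never qualify.
    """
    out = []
    for pos, row in table.df.iterrows():
        if row["indel"]:
            continue
        a1 = np.array([row[t] for t in table.members1])
        a2 = np.array([row[t] for t in table.members2])
        maj1, f1 = _majority(a1)
        maj2, f2 = _majority(a2)
        if maj1 != maj2 and f1 >= min_fixation - 1e-12 and f2 >= min_fixation - 1e-12:
            out.append(int(pos))
    return out


def detect_tracts(
    table: PolymorphismTable,
    informative: list[int],
    alpha: float = DEFAULT_ALPHA,
) -> list[ConversionTract]:
    """Scan both directions for runs of switched informative sites.

    For each recipient group, a maximal run of ≥ 2 consecutive informative
    sites at which one fixed subset of recipients carries the donor group's
    majority allele is reported iff ∏ψ_i ≤ alpha.  Runs with changing
    carrier sets are split at the change, so each reported tract names one
    recipient subset.
    """
    tracts: list[ConversionTract] = []
    pairs = [
        (table.group1, table.members1, table.group2, table.members2),
        (table.group2, table.members2, table.group1, table.members1),
    ]
    for rec_group, rec_members, don_group, don_members in pairs:
        carrier_sets: list[frozenset[str]] = []
        for pos in informative:
            row = table.df.loc[pos]
            donor_allele, _ = _majority(np.array([row[t] for t in don_members]))
            carrier_sets.append(
                frozenset(t for t in rec_members if row[t] == donor_allele)
            )
        i = 0
        while i < len(informative):
            if not carrier_sets[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(informative) and carrier_sets[j + 1] == carrier_sets[i]:
                j += 1
            if j > i:  # run length >= 2
                psi = len(carrier_sets[i]) / len(rec_members)
                psis = tuple([psi] * (j - i + 1))
                p = prod(psis)
                if p <= alpha:
                    tracts.append(
                        ConversionTract(
                            rec_group,
                            don_group,
                            tuple(sorted(carrier_sets[i])),
                            tuple(informative[i: j + 1]),
                            psis,
                            p,
                        )
                    )
            i = j + 1
    return tracts


def tracts_to_tsv(tracts: list[ConversionTract], path):
    rows = [
        {
            "recipient_group": t.recipient_group,
            "donor_group": t.donor_group,
            "recipient_taxa": ",".join(t.recipient_taxa),
            "start": t.sites[0],
            "end": t.sites[-1],
            "k": len(t.sites),
            "psi": ",".join(f"{x:.6g}" for x in t.psi_per_site),
            "p_value": t.p_value,
        }
        for t in tracts
    ]
    pd.DataFrame(
        rows,
        columns=[
            "recipient_group",
            "donor_group",
            "recipient_taxa",
            "start",
            "end",
            "k",
            "psi",
            "p_value",
        ],
    ).to_csv(path, sep="\t", index=False)
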