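import numpy as np
import pytest

from mtpopgen.alignio import AnnotationBlock, LabeledAlignment

BASES = "ACGT"


def random_alignment(
    rng: np.random.Generator,
    n_plus: int = 3,
    n_minus: int = 3,
    L: int = 60,
    gap_rate: float = 0.0,
    div: float = 0.15,
    blocks=None,
) -> LabeledAlignment:
    """Random panel mutated from a shared ancestor, for oracle tests.

    ``div`` is the per-taxon per-site mutation probability; kept well
    below the Jukes–Cantor saturation point so corrected distances exist.
    """
    taxa = [f"p{i}" for i in range(n_plus)] + [f"m{i}" for i in range(n_minus)]
    groups = {t: ("MT+" if t.startswith("p") else "MT-") for t in taxa}
    ancestral = rng.choice(list(BASES), size=L)
    seqs = {}
    for t in taxa:
        chars = ancestral.copy()
        hit = rng.random(L) < div
        for col in np.flatnonzero(hit):
            choices = [b for b in BASES if b != chars[col]]
            chars[col] = rng.choice(choices)
        if gap_rate:
            gap = rng.random(L) < gap_rate
            chars = np.where(gap, "-", chars)
        seqs[t] = "".join(chars)
    return LabeledAlignment.from_sequences(seqs, groups, blocks)


@pytest.fixture
def rng():
    return np.random.default_rng(20130829)


@pytest.fixture
def toy_two_group():
    """3 + 3 panel with two fixed differences and one private variant."""
    seqs = {
        "p1": "AAAACCCCGGGG",
        "p2": "AAAACCCCGGGG",
        "p3": "AAAACCCCGGGT",
        "m1": "AATACCGCGGGG",
        "m2": "AATACCGCGGGG",
        "m3": "AATACCGCGGGG",
    }
    groups = {t: ("MT+" if t.startswith("p") else "MT-") for t in seqs}
    return LabeledAlignment.from_sequences(seqs, groups)


@pytest.fixture
def coding_block():
    return [AnnotationBlock(1, 12, "exon", 0)]
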