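import itertools
import math

import numpy as np
import pytest

from mtpopgen.alignio import LabeledAlignment, SiteMask, ungapped_mask
from mtpopgen.errors import (
    DegenerateInputError,
    GroupingError,
    InsufficientSampleError,
)
from mtpopgen.popstats import (
    differentiation,
    jukes_cantor,
    nucleotide_diversity,
    subsample_statistic,
    tajimas_d,
)
from mtpopgen.synthpop import PanelSpec, simulate_panel
from conftest import random_alignment


def _aln(seqs, groups=None):
    groups = groups or {t: "G" for t in seqs}
    return LabeledAlignment.from_sequences(seqs, groups)


def _full_mask(aln):
    return SiteMask(np.arange(aln.length), "all")


def brute_force_pi(aln, mask):
    """π by exhaustive enumeration of all sequence pairs."""
    cols = mask.columns
    diffs = [
        (aln.matrix[i, cols] != aln.matrix[j, cols]).sum()
        for i, j in itertools.combinations(range(aln.n_taxa), 2)
    ]
    return float(np.mean(diffs)) / len(mask)


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        aln = _aln({"a": "ACGT" * 10, "b": "ACGT" * 10})
        assert nucleotide_diversity(aln, _full_mask(aln), bootstrap_reps=0).pi == 0.0

    def test_single_pair_two_differences(self):
        s = "A" * 100
        t = "A" * 50 + "C" + "A" * 24 + "G" + "A" * 24
        aln = _aln({"a": s, "b": t})
        res = nucleotide_diversity(aln, _full_mask(aln), bootstrap_reps=0)
        assert res.pi == pytest.approx(0.02)
        assert res.n_segregating == 2

    def test_matches_exhaustive_pair_oracle(self, rng):
        for _ in range(5):
            aln = random_alignment(rng, n_plus=3, n_minus=2, L=50)
            mask = ungapped_mask(aln)
            res = nucleotide_diversity(aln, mask, bootstrap_reps=0)
            assert res.pi == pytest.approx(brute_force_pi(aln, mask), abs=1e-12)

    def test_empty_mask_rejected(self):
        aln = _aln({"a": "AC", "b": "AC"})
        with pytest.raises(DegenerateInputError):
            nucleotide_diversity(aln, SiteMask(np.array([], dtype=int), "all"))

    def test_bootstrap_sd_reproducible(self, rng):
        aln = random_alignment(rng, L=40)
        mask = ungapped_mask(aln)
        r1 = nucleotide_diversity(aln, mask, bootstrap_reps=100, seed=42)
        r2 = nucleotide_diversity(aln, mask, bootstrap_reps=100, seed=42)
        assert r1.pi_sd == r2.pi_sd and r1.pi_sd > 0


class TestTajimasD:
    def test_no_segregation_undefined(self):
        aln = _aln({t: "ACGT" * 5 for t in "abcd"})
        assert not tajimas_d(aln, _full_mask(aln)).defined

    def test_small_sample_rejected(self):
        aln = _aln({"a": "ACGT", "b": "ACGA", "c": "ACGT"})
        with pytest.raises(InsufficientSampleError):
            tajimas_d(aln, _full_mask(aln))

    def test_four_sequence_hand_computation(self):
        # S = 3 singleton sites among n = 4; constants derived from scratch
        seqs = {
            "a": "CAAAAAAAAA",
            "b": "ACAAAAAAAA",
            "c": "AACAAAAAAA",
            "d": "AAAAAAAAAA",
        }
        aln = _aln(seqs)
        res = tajimas_d(aln, _full_mask(aln))
        n, S = 4, 3
        a1 = 1 + 1 / 2 + 1 / 3
        a2 = 1 + 1 / 4 + 1 / 9
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1, e2 = c1 / a1, c2 / (a1**2 + a2)
        k = np.mean(
            [
                (np.array(list(seqs[x])) != np.array(list(seqs[y]))).sum()
                for x, y in itertools.combinations("abcd", 2)
            ]
        )
        expected = (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert res.d_statistic == pytest.approx(expected, abs=1e-12)

    def test_neutral_panels_centre_on_zero(self):
        ds = []
        for s in range(200):
            aln = simulate_panel(
                PanelSpec(n_plus=13, n_minus=1, L=1500, theta_within=0.01, seed=s)
            )
            sub = aln.restrict(aln.members("MT+"))
            res = tajimas_d(sub, ungapped_mask(sub))
            if res.defined:
                ds.append(res.d_statistic)
        assert abs(np.mean(ds)) < 0.3


def brute_force_differentiation(aln, mask, g1, g2):
    """All quantities by exhaustive pairwise distances."""
    cols = mask.columns
    m1, m2 = aln.members(g1), aln.members(g2)
    L = len(mask)

    def p_dist(x, y):
        return float((aln.row(x)[cols] != aln.row(y)[cols]).sum()) / L

    pi1 = np.mean([p_dist(x, y) for x, y in itertools.combinations(m1, 2)])
    pi2 = np.mean([p_dist(x, y) for x, y in itertools.combinations(m2, 2)])
    hb = np.mean([p_dist(x, y) for x in m1 for y in m2])
    d_xy = jukes_cantor(hb)
    d_a = d_xy - 0.5 * (jukes_cantor(pi1) + jukes_cantor(pi2))
    fst = 1 - 0.5 * (pi1 + pi2) / hb
    return d_xy, d_a, fst, pi1, pi2


class TestDifferentiation:
    def test_fixed_differences_give_fst_one(self):
        seqs = {
            "p1": "AAAA", "p2": "AAAA", "m1": "AAGA", "m2": "AAGA",
        }
        groups = {"p1": "MT+", "p2": "MT+", "m1": "MT-", "m2": "MT-"}
        aln = LabeledAlignment.from_sequences(seqs, groups)
        res = differentiation(aln, _full_mask(aln), "MT+", "MT-")
        assert res.fst == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, toy_two_group, rng):
        for aln in [toy_two_group] + [
            random_alignment(rng, n_plus=3, n_minus=3, L=60) for _ in range(4)
        ]:
            mask = ungapped_mask(aln)
            res = differentiation(aln, mask, "MT+", "MT-")
            d_xy, d_a, fst, pi1, pi2 = brute_force_differentiation(
                aln, mask, "MT+", "MT-"
            )
            assert res.d_xy == pytest.approx(d_xy, abs=1e-12)
            assert res.d_a == pytest.approx(d_a, abs=1e-12)
            assert res.fst == pytest.approx(fst, abs=1e-12)

    def test_net_divergence_identity(self, rng):
        aln = random_alignment(rng, n_plus=4, n_minus=3, L=80)
        mask = ungapped_mask(aln)
        res = differentiation(aln, mask, "MT+", "MT-")
        assert res.d_a == pytest.approx(
            res.d_xy
            - 0.5 * (jukes_cantor(res.pi_within_1) + jukes_cantor(res.pi_within_2)),
            abs=1e-15,
        )

    def test_symmetric_under_group_relabeling(self, toy_two_group):
        mask = ungapped_mask(toy_two_group)
        a = differentiation(toy_two_group, mask, "MT+", "MT-")
        b = differentiation(toy_two_group, mask, "MT-", "MT+")
        assert a.fst == pytest.approx(b.fst) and a.d_xy == pytest.approx(b.d_xy)

    def test_single_member_group_rejected(self):
        aln = _aln(
            {"a": "ACGT", "b": "ACGA", "c": "ACGT"},
            {"a": "MT+", "b": "MT+", "c": "MT-"},
        )
        with pytest.raises(GroupingError):
            differentiation(aln, _full_mask(aln), "MT+", "MT-")

    def test_panmictic_null_near_zero(self):
        fsts = []
        for s in range(100):
            aln = simulate_panel(
                PanelSpec(L=1500, theta_shared=0.01, theta_within=0.0, seed=s)
            )
            res = differentiation(aln, ungapped_mask(aln), "MT+", "MT-")
            if res.fst_defined:
                fsts.append(res.fst)
        assert abs(np.mean(fsts)) < 0.15

    def test_fst_increases_with_fixed_differentiation(self):
        means = []
        for delta in (0.0005, 0.002, 0.008):
            vals = []
            for s in range(30):
                aln = simulate_panel(
                    PanelSpec(
                        L=2000, delta_fixed=delta, theta_within=0.004, seed=1000 + s
                    )
                )
                res = differentiation(aln, ungapped_mask(aln), "MT+", "MT-")
                vals.append(res.fst)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestSubsample:
    def test_full_subset_is_identity(self, toy_two_group):
        full = nucleotide_diversity(
            toy_two_group, ungapped_mask(toy_two_group), bootstrap_reps=0
        )
        sub = subsample_statistic(
            toy_two_group, toy_two_group.taxa, mask_kind="ungapped", bootstrap_reps=0
        )
        assert sub.pi == full.pi

    def test_two_identical_sequences(self, toy_two_group):
        res = subsample_statistic(
            toy_two_group, ["p1", "p2"], mask_kind="ungapped", bootstrap_reps=0
        )
        assert res.pi == 0.0

    def test_random_subsets_match_direct_recomputation(self, rng):
        aln = random_alignment(rng, n_plus=4, n_minus=4, L=50, gap_rate=0.05)
        for _ in range(5):
            subset = list(rng.choice(aln.taxa, size=3, replace=False))
            via_api = subsample_statistic(
                aln, subset, mask_kind="ungapped", bootstrap_reps=0
            )
            sub = aln.restrict(subset)
            direct = nucleotide_diversity(sub, ungapped_mask(sub), bootstrap_reps=0)
            assert via_api.pi == pytest.approx(direct.pi, abs=1e-15)
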