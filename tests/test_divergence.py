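import itertools
import math

import numpy as np
import pytest

from mtpopgen.alignio import translate_codon
from mtpopgen.divergence import (
    cai,
    ng86_dnds,
    relative_adaptiveness,
    tamura3p,
)
from mtpopgen.errors import CodingError, FrameError, SaturationError

BASES = "ACGT"


def _pair_with_counts(L, n_ts, n_tv, gc_pairs):
    """Build an aligned pair with exact transition/transversion/GC counts.

    ``gc_pairs`` columns are (G, G): identical strong-base columns; the
    rest are (A, A) identical weak columns, with the first ``n_ts``
    mutated A->G (transition) and the next ``n_tv`` mutated A->T
    (transversion) in the second sequence.
    """
    a = ["G"] * gc_pairs + ["A"] * (L - gc_pairs)
    b = list(a)
    weak = list(range(gc_pairs, L))
    for i in weak[:n_ts]:
        b[i] = "G"
    for i in weak[n_ts: n_ts + n_tv]:
        b[i] = "T"
    return "".join(a), "".join(b)


class TestTamura3P:
    def test_identical_sequences(self):
        res = tamura3p("ACGT" * 50, "ACGT" * 50, bootstrap_reps=0)
        assert res.d == pytest.approx(0.0)
        assert res.n_substitutions == 0

    def test_reduces_to_k2p_at_half_gc(self):
        # 200 columns, theta exactly 0.5, P = 0.05, Q = 0.02
        L, n_ts, n_tv = 200, 10, 4
        # GC content: seq a has gc_pairs G's; seq b gains n_ts G's.
        # Choose gc_pairs so (2*gc + n_ts) / (2L) = 0.5 -> gc = (L - n_ts/... )
        gc = (L - n_ts) // 2  # 2*95 + 10 = 200 = L -> theta = 200/400 = 0.5
        a, b = _pair_with_counts(L, n_ts, n_tv, gc)
        res = tamura3p(a, b, bootstrap_reps=0)
        P, Q = n_ts / L, n_tv / L
        k2p = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert res.d == pytest.approx(k2p, abs=1e-12)

    def test_matches_closed_form(self):
        # 300 sites with P = 0.05, Q = 0.02 and a known theta
        L, n_ts, n_tv, gc = 300, 15, 6, 100
        a, b = _pair_with_counts(L, n_ts, n_tv, gc)
        res = tamura3p(a, b, bootstrap_reps=0)
        P, Q = n_ts / L, n_tv / L
        theta = (2 * gc + n_ts) / (2 * L)
        h = 2 * theta * (1 - theta)
        expected = -h * math.log(1 - P / h - Q) - 0.5 * (1 - h) * math.log(1 - 2 * Q)
        assert res.d == pytest.approx(expected, abs=1e-12)
        assert res.n_aligned == L and res.n_substitutions == n_ts + n_tv

    def test_symmetric(self):
        a, b = _pair_with_counts(120, 8, 3, 30)
        assert tamura3p(a, b, bootstrap_reps=0).d == pytest.approx(
            tamura3p(b, a, bootstrap_reps=0).d, abs=1e-15
        )

    def test_monotone_in_transitions(self):
        ds = []
        for n_ts in (2, 6, 12):
            a, b = _pair_with_counts(200, n_ts, 4, 60)
            ds.append(tamura3p(a, b, bootstrap_reps=0).d)
        assert ds[0] < ds[1] < ds[2]

    def test_indels_counted_as_events_and_excluded(self):
        a = "AAAAAAAAGGGG"
        b = "AA--AAAAGG-G"
        res = tamura3p(a, b, bootstrap_reps=0)
        assert res.n_indels == 2
        assert res.n_aligned == 9
        assert res.d == pytest.approx(0.0)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            tamura3p("AAAA" * 30, "GGGG" * 30, bootstrap_reps=0)

    def test_bootstrap_se_reproducible_and_shrinks(self):
        a1, b1 = _pair_with_counts(150, 9, 3, 50)
        a2, b2 = _pair_with_counts(600, 36, 12, 200)
        r1 = tamura3p(a1, b1, bootstrap_reps=200, seed=7)
        r1b = tamura3p(a1, b1, bootstrap_reps=200, seed=7)
        r2 = tamura3p(a2, b2, bootstrap_reps=200, seed=7)
        assert r1.se == r1b.se and r1.se > 0
        assert r2.se < r1.se  # ~1/sqrt(L)


def brute_force_ng86(c1, c2):
    """Pathway-enumeration oracle for a single codon pair."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diff):
        cur, syn, nsyn, blocked = c1, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if translate_codon(nxt) == "*" and nxt != c2:
                blocked = True
            if translate_codon(nxt) == translate_codon(cur):
                syn += 1
            else:
                nsyn += 1
            cur = nxt
        results.append((syn, nsyn, blocked))
    keep = [(s, n) for s, n, blk in results if not blk] or [
        (s, n) for s, n, _ in results
    ]
    return (
        sum(s for s, _ in keep) / len(keep),
        sum(n for _, n in keep) / len(keep),
    )


class TestNG86:
    def test_identical_cds(self):
        cds = "ATGTTTACGGAT"
        res = ng86_dnds(cds, cds)
        assert res.dN == 0.0 and res.dS == 0.0
        assert not res.ratio_defined

    def test_synonymous_only_difference(self):
        a = "ATG" + "TTT" + "ACG" * 28
        b = "ATG" + "TTC" + "ACG" * 28
        res = ng86_dnds(a, b)
        assert res.dN == 0.0
        assert res.dS > 0.0

    def test_site_counts_sum_to_three_per_codon(self):
        a = "ATGTTTACGGAT" + "GGC" * 10
        b = "ATGTTCACGGAC" + "GGC" * 10
        res = ng86_dnds(a, b)
        assert res.sites_syn + res.sites_nonsyn == pytest.approx(3 * 14)

    def test_multi_difference_codons_match_pathway_oracle(self):
        # two codon pairs differing at two positions each
        pairs = [("TTT", "TTT")] * 16 + [("TTA", "CTC"), ("GGA", "GCC")] + [
            ("AAA", "AAA"),
            ("CCC", "CCC"),
        ]
        a = "".join(p[0] for p in pairs)
        b = "".join(p[1] for p in pairs)
        res = ng86_dnds(a, b)
        Sd = Nd = 0.0
        sA = sB = 0.0
        for c1, c2 in pairs:
            ds, dn = brute_force_ng86(c1, c2)
            Sd += ds
            Nd += dn
            for c, acc in ((c1, "A"), (c2, "B")):
                syn = 0.0
                for pos in range(3):
                    for alt in BASES:
                        if alt != c[pos]:
                            mut = c[:pos] + alt + c[pos + 1:]
                            if translate_codon(mut) == translate_codon(c):
                                syn += 1 / 3
                if acc == "A":
                    sA += syn
                else:
                    sB += syn
        S_sites = 0.5 * (sA + sB)
        N_sites = 3 * len(pairs) - S_sites
        pS, pN = Sd / S_sites, Nd / N_sites
        assert res.dS == pytest.approx(-0.75 * math.log(1 - 4 * pS / 3), abs=1e-12)
        assert res.dN == pytest.approx(-0.75 * math.log(1 - 4 * pN / 3), abs=1e-12)

    def test_cross_check_against_biopython(self):
        try:
            from Bio.Align import PairwiseAligner  # noqa: F401
            from Bio.Align.analysis import calculate_dn_ds
            from Bio.Align import Alignment
        except ImportError:
            pytest.skip("biopython dN/dS analysis module unavailable")
        a = "ATGTTTACGGATCTAAAAGGG" + "GCT" * 20
        b = "ATGTTCACGGAACTAAGAGGA" + "GCT" * 20
        aln = Alignment([a, b], np.array([[0, len(a)], [0, len(b)]]))
        dn, ds = calculate_dn_ds(aln, method="NG86")
        res = ng86_dnds(a, b)
        assert res.dN == pytest.approx(dn, abs=1e-6)
        assert res.dS == pytest.approx(ds, abs=1e-6)

    def test_frame_and_stop_errors(self):
        with pytest.raises(FrameError):
            ng86_dnds("ATGT", "ATGT")
        with pytest.raises(CodingError):
            ng86_dnds("ATGTAAACG", "ATGTAAACG")


class TestCAI:
    USAGE = {
        "TTT": 20.0, "TTC": 10.0,
        "GGU".replace("U", "T"): 5.0, "GGC": 10.0, "GGA": 2.0, "GGG": 1.0,
        "ATG": 25.0, "TGG": 8.0,
    }

    def test_family_maximal_codons_give_one(self):
        res = cai("TTTGGC", self.USAGE)
        assert res.cai == pytest.approx(1.0)
        assert res.n_codons_scored == 2

    def test_single_codon_half_usage(self):
        res = cai("TTC", self.USAGE)
        assert res.cai == pytest.approx(0.5)

    def test_met_trp_and_stops_excluded(self):
        res = cai("ATGTTTTGGTAA", self.USAGE)
        assert res.n_codons_scored == 1  # only TTT is scored

    def test_matches_log_sum_oracle(self, rng):
        usage = {
            "".join(c): float(rng.integers(1, 50))
            for c in itertools.product(BASES, repeat=3)
        }
        w = relative_adaptiveness(usage)
        codons = [
            "".join(rng.choice(list(BASES), size=3)) for _ in range(50)
        ]
        codons = [
            c for c in codons
            if translate_codon(c) != "*" and c not in ("ATG", "TGG")
        ]
        cds = "".join(codons)
        res = cai(cds, usage)
        expected = math.exp(np.mean([math.log(w[c]) for c in codons]))
        assert res.cai == pytest.approx(expected, abs=1e-12)
        assert res.n_codons_scored == len(codons)

    def test_zero_usage_floored_with_warning(self):
        usage = dict(self.USAGE)
        usage["GGG"] = 0.0
        with pytest.warns(UserWarning):
            res = cai("GGG", usage, zero_usage_epsilon=0.01)
        assert res.cai == pytest.approx(0.01)
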