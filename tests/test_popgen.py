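"""Diversity indices, Tajima's D and Nei-Gojobori Ka/Ks."""

import math
from itertools import combinations

import numpy as np
import pytest

from mitodui.core import default_code
from mitodui.popgen import (
    HaplotypeSet,
    concatenate,
    diversity_stats,
    nei_gojobori_kaks,
    region_summary,
    tajima_constants,
    tajimas_d,
)
from mitodui.simulate import CoalescentConfig, simulate_haplotypes


def brute_force_diversity(rows):
    """Independent oracle: direct definitions over clean columns."""
    cols = [
        j
        for j in range(len(rows[0]))
        if all(r[j] in "ACGT" for r in rows)
    ]
    n = len(rows)
    L = len(cols)
    S = sum(len({r[j] for r in rows}) > 1 for j in cols)
    haps = {"".join(r[j] for j in cols) for r in rows}
    from collections import Counter

    counts = Counter("".join(r[j] for j in cols) for r in rows)
    hd = n / (n - 1) * (1 - sum((c / n) ** 2 for c in counts.values()))
    diffs = [
        sum(a[j] != b[j] for j in cols) for a, b in combinations(rows, 2)
    ]
    pi = sum(diffs) / len(diffs) / L
    a1 = sum(1 / i for i in range(1, n))
    return n, len(haps), S, hd, S / (a1 * L), pi


class TestDiversity:
    def test_toy_example(self):
        hs = HaplotypeSet("toy", ["AAA", "AAT", "ATT"])
        n, h, S, hd, theta, pi = diversity_stats(hs)
        assert (n, h, S) == (3, 3, 2)
        assert hd == pytest.approx(1.0)
        assert pi == pytest.approx(4 / 3 / 3)

    def test_all_distinct_hd_one(self):
        rng = np.random.default_rng(0)
        rows = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(18)]
        assert len(set(rows)) == 18
        *_, hd, _, _ = (*diversity_stats(HaplotypeSet("x", rows))[:3],
                        *diversity_stats(HaplotypeSet("x", rows))[3:])
        assert hd == pytest.approx(1.0)

    def test_theta_closed_form(self):
        # N=4, S=3, L=100 -> theta = 3 / ((1 + 1/2 + 1/3) * 100)
        rows = ["A" * 100 for _ in range(4)]
        rows[1] = "T" + rows[1][1:]
        rows[2] = rows[2][:50] + "G" + rows[2][51:]
        rows[3] = rows[3][:99] + "C"
        _, _, S, _, theta, _ = diversity_stats(HaplotypeSet("x", rows))
        assert S == 3
        assert theta == pytest.approx(3 / ((1 + 0.5 + 1 / 3) * 100))

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 6))
            L = int(rng.integers(4, 11))
            rows = ["".join(rng.choice(list("ACGT-"), p=[0.3, 0.25, 0.2, 0.2, 0.05],
                                       size=L)) for _ in range(n)]
            if not any(all(r[j] in "ACGT" for r in rows) for j in range(L)):
                continue
            got = diversity_stats(HaplotypeSet("r", rows))
            expected = brute_force_diversity(rows)
            assert got[:3] == expected[:3]
            for g, e in zip(got[3:], expected[3:]):
                assert g == pytest.approx(e)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        rows = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(6)]
        a = diversity_stats(HaplotypeSet("x", rows))
        b = diversity_stats(HaplotypeSet("x", rows[::-1]))
        assert a == b

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            diversity_stats(HaplotypeSet("x", ["ACGT"]))


class TestTajima:
    def test_zero_numerator_gives_zero(self):
        # 4 sequences, 1 singleton mutation: pi*L = 2/4... construct and verify
        # directly that D's sign follows pi*L - S/a1
        rows = ["AAAA", "AAAT", "AAAA", "AAAA"]
        D, _, _ = tajimas_d(HaplotypeSet("x", rows))
        cst = tajima_constants(4)
        # one singleton: pi*L = (3 pairs differ)/6 = 0.5; S/a1 = 1/1.8333
        expected = (0.5 - 1 / cst["a1"]) / math.sqrt(cst["e1"] + 0)
        assert D == pytest.approx(expected)

    def test_no_segregating_sites_is_nan(self):
        D, sig, p = tajimas_d(HaplotypeSet("x", ["ACGT"] * 5))
        assert math.isnan(D) and not sig

    def test_fixed_alignment_against_transcribed_constants(self):
        """An independent transcription of the published constants on a
        fixed 5 x 20 alignment."""
        rows = [
            "ACGTACGTACGTACGTACGT",
            "ACGTACGTACGTACGTACGA",
            "ACGTACGAACGTACGTACGT",
            "ACGTACGTACGTTCGTACGT",
            "ACCTACGTACGTACGTACGT",
        ]
        D, _, _ = tajimas_d(HaplotypeSet("x", rows))
        n, L = 5, 20
        a1 = sum(1 / i for i in range(1, n))
        a2 = sum(1 / i**2 for i in range(1, n))
        b1 = (n + 1) / (3 * (n - 1))
        b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
        c1 = b1 - 1 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1 * a1 + a2)
        S = 4
        k = np.mean([sum(x != y for x, y in zip(a, b))
                     for a, b in combinations(rows, 2)])
        expected = (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))
        assert D == pytest.approx(expected)

    def test_mean_near_zero_under_neutrality(self):
        Ds = []
        for i in range(200):
            hs, _ = simulate_haplotypes(
                CoalescentConfig(n_samples=18, sequence_length=500,
                                 theta_per_site=0.02, seed=9000 + i)
            )
            D, _, _ = tajimas_d(hs)
            if not math.isnan(D):
                Ds.append(D)
        assert abs(np.mean(Ds)) < 0.15

    def test_significance_flags_extreme_d(self):
        # strongly negative D: many singletons spread over distinct rows
        n, L = 20, 400
        rows = [["A"] * L for _ in range(n)]
        k = 0
        for j in range(60):
            rows[k % n][j] = "T"
            k += 1
        hs = HaplotypeSet("x", ["".join(r) for r in rows])
        D, sig, p = tajimas_d(hs)
        assert D < 0
        assert 0 <= p <= 1


class TestNeiGojobori:
    def test_identical_sequences(self):
        hs = HaplotypeSet("x", ["ATGTTTAAA"] * 3)
        res = nei_gojobori_kaks(hs, bootstrap_reps=20, seed=0)
        assert res["Ka"] == 0.0 and res["Ks"] == 0.0
        assert res["Ka_SE"] == 0.0 and res["Ks_SE"] == 0.0

    def test_single_codon_example(self):
        # TTT (Phe) vs TTA (Leu), table 5: one nonsynonymous difference,
        # 2.5 nonsynonymous sites -> pN = 0.4
        hs = HaplotypeSet("x", ["TTT", "TTA"])
        res = nei_gojobori_kaks(hs, bootstrap_reps=0, seed=0)
        assert res["Ks"] == 0.0
        assert res["Ka"] == pytest.approx(-0.75 * math.log(1 - 4 / 3 * 0.4))

    def test_synonymous_only_pair(self):
        # TTA vs TTG both Leu: one synonymous difference over several codons
        hs = HaplotypeSet("x", ["TTATTATTA", "TTGTTATTA"])
        res = nei_gojobori_kaks(hs, bootstrap_reps=0, seed=0)
        assert res["Ka"] == 0.0
        assert res["Ks"] > 0.0

    def test_saturation_flagged_as_nan(self):
        code = default_code()
        # maximally different codons across many sites push pN >= 0.75
        hs = HaplotypeSet("x", ["ATGATGATGATG", "CCCCCCCCCCCC"])
        res = nei_gojobori_kaks(hs, bootstrap_reps=0, seed=0)
        assert math.isnan(res["Ka"])

    def test_omega_one_ratio_near_unity(self):
        ratios = []
        for i in range(30):
            hs, _ = simulate_haplotypes(
                CoalescentConfig(n_samples=6, sequence_length=1500,
                                 theta_per_site=0.1, omega=1.0, seed=300 + i)
            )
            res = nei_gojobori_kaks(hs, bootstrap_reps=0, seed=0)
            if res["Ks"] > 0 and not math.isnan(res["Ka_over_Ks"]):
                ratios.append(res["Ka_over_Ks"])
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.15)

    def test_purifying_selection_detected(self):
        below = 0
        total = 40
        for i in range(total):
            hs, _ = simulate_haplotypes(
                CoalescentConfig(n_samples=6, sequence_length=600,
                                 theta_per_site=0.03, omega=0.1, seed=700 + i)
            )
            res = nei_gojobori_kaks(hs, bootstrap_reps=0, seed=0)
            if not math.isnan(res["Ka_over_Ks"]) and res["Ka_over_Ks"] < 1:
                below += 1
        assert below / total >= 0.9


class TestRegionSummary:
    def test_concatenation_equals_manual(self):
        rng = np.random.default_rng(3)

        def mkset(region, L):
            rows = []
            base = "".join(rng.choice(list("ACGT"), size=L))
            for _ in range(5):
                rows.append(
                    "".join(
                        c if rng.random() > 0.02
                        else "ACGT"[int(rng.integers(0, 4))]
                        for c in base
                    )
                )
            return HaplotypeSet(region, rows)

        sets = [mkset("r1", 30), mkset("r2", 60), mkset("r3", 27)]
        joined = concatenate(sets)
        manual = HaplotypeSet(
            "manual",
            ["".join(s.rows[i] for s in sets) for i in range(5)],
        )
        assert diversity_stats(joined)[:3] == diversity_stats(manual)[:3]

    def test_s_additive_across_regions(self):
        a = HaplotypeSet("a", ["AAA", "AAT", "AAA"])
        b = HaplotypeSet("b", ["CCC", "CCC", "GCC"])
        Sa = diversity_stats(a)[2]
        Sb = diversity_stats(b)[2]
        Sj = diversity_stats(concatenate([a, b]))[2]
        assert Sj == Sa + Sb

    def test_summary_row_fields(self):
        hs, _ = simulate_haplotypes(
            CoalescentConfig(n_samples=8, sequence_length=300,
                             theta_per_site=0.02, seed=11)
        )
        row = region_summary(hs, bootstrap_reps=50, seed=0)
        assert row.N == 8
        assert row.h <= row.N
        assert 0 <= row.hd <= 1
        assert row.S <= 300
        assert row.theta_per_sequence == pytest.approx(
            row.theta_per_site * row.L_used
        )

    def test_theta_pi_estimator_recovery(self):
        thetas, pis = [], []
        for i in range(200):
            hs, _ = simulate_haplotypes(
                CoalescentConfig(n_samples=18, sequence_length=800,
                                 theta_per_site=0.02, seed=5000 + i)
            )
            _, _, _, _, th, pi = diversity_stats(hs)
            thetas.append(th)
            pis.append(pi)
        assert np.mean(thetas) == pytest.approx(0.02, rel=0.10)
        assert np.mean(pis) == pytest.approx(0.02, rel=0.10)
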