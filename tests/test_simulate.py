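"""Synthetic-data generators: truth records, determinism, recovery hooks."""

import math

import numpy as np
import pytest

from mitodui.core import classify_sites, translate, extract_feature_sequence
from mitodui.popgen import diversity_stats, tajima_constants
from mitodui.simulate import (
    CoalescentConfig,
    MitoPairConfig,
    QpcrSimConfig,
    simulate_haplotypes,
    simulate_mitogenome_pair,
    simulate_ngs_counts,
    simulate_qpcr_dataset,
)
from mitodui.skew import genome_wide_index, windowed_index


class TestMitogenomePair:
    def test_default_structure(self):
        gf, gm, alns = simulate_mitogenome_pair(MitoPairConfig(seed=0))
        assert gf.length == 18_113
        assert gm.length == 24_347
        assert gm.get_feature("atp8").span == 885
        assert gf.get_feature("atp8").span == 369
        assert any(f.category == "repeat_region" for f in gm.features)
        assert not any(f.category == "repeat_region" for f in gf.features)
        # 13 proteins + 2 rRNA + 23 tRNA in both genomes
        for g in (gf, gm):
            cats = [f.category for f in g.features]
            assert cats.count("protein") == 13
            assert cats.count("rRNA") == 2
            assert cats.count("tRNA") == 23

    def test_relocated_small_subunit_rrna(self):
        gf, gm, _ = simulate_mitogenome_pair(MitoPairConfig(seed=0))

        def order(g):
            feats = sorted(g.features, key=lambda f: f.start)
            return [f.name for f in feats]

        of, om = order(gf), order(gm)
        # F: srRNA directly after nad1; M: after the large rRNA / repeat region
        assert of[of.index("nad1") + 1] == "rrnS"
        assert om[om.index("nad1") + 1] != "rrnS"
        assert om.index("rrnL") < om.index("rrnS")

    def test_cds_translate_cleanly(self):
        gf, gm, _ = simulate_mitogenome_pair(MitoPairConfig(seed=1))
        for g in (gf, gm):
            for f in g.proteins():
                aa = translate(extract_feature_sequence(g, f))
                assert "*" not in aa

    def test_zero_divergence_identical_alignments(self):
        _, _, alns = simulate_mitogenome_pair(MitoPairConfig(divergence=0.0, seed=2))
        for aln in alns.values():
            assert aln.rows[0] == aln.rows[1]

    def test_divergence_target_out_of_range(self):
        with pytest.raises(ValueError):
            simulate_mitogenome_pair(MitoPairConfig(divergence=0.9, seed=0))

    def test_skew_profile_realised(self):
        cfg = MitoPairConfig(
            seed=3, skew_profile={"NCR": (0.3, 0.0, 0.35)}
        )
        gf, _, _ = simulate_mitogenome_pair(cfg)
        ncr = gf.get_feature("NCR")
        sub = gf.sequence.residues[ncr.start : ncr.end]
        a, t = sub.count("A"), sub.count("T")
        assert (a - t) / (a + t) == pytest.approx(0.3, abs=0.05)

    def test_determinism(self):
        a = simulate_mitogenome_pair(MitoPairConfig(seed=9))
        b = simulate_mitogenome_pair(MitoPairConfig(seed=9))
        assert a[0].sequence.residues == b[0].sequence.residues
        assert a[1].sequence.residues == b[1].sequence.residues


class TestCoalescent:
    def test_tiny_theta_no_variation(self):
        hs, truth = simulate_haplotypes(
            CoalescentConfig(n_samples=10, sequence_length=500,
                             theta_per_site=1e-9, seed=0)
        )
        assert truth["S"] == 0
        assert len(set(hs.rows)) == 1

    def test_watterson_expectation(self):
        # E[S] = theta * L * a1
        a1 = tajima_constants(18)["a1"]
        expected = 0.02 * 1317 * a1
        Ss = []
        for i in range(400):
            _, truth = simulate_haplotypes(
                CoalescentConfig(n_samples=18, sequence_length=1317,
                                 theta_per_site=0.02, seed=10_000 + i)
            )
            Ss.append(truth["S"])
        assert np.mean(Ss) == pytest.approx(expected, rel=0.05)

    def test_s_matches_diversity_stats(self):
        hs, truth = simulate_haplotypes(
            CoalescentConfig(n_samples=12, sequence_length=900,
                             theta_per_site=0.02, seed=77)
        )
        assert diversity_stats(hs)[2] == truth["S"]

    def test_matches_msprime_reference(self):
        """Cross-check mean segregating sites against an independent
        coalescent implementation."""
        msprime = pytest.importorskip("msprime")
        n, L, theta = 12, 800, 0.02
        ours = []
        for i in range(300):
            _, truth = simulate_haplotypes(
                CoalescentConfig(n_samples=n, sequence_length=L,
                                 theta_per_site=theta, seed=20_000 + i)
            )
            ours.append(truth["S"])
        ref = []
        for i, ts in enumerate(
            msprime.sim_ancestry(samples=n, ploidy=1, sequence_length=L,
                                 num_replicates=300, random_seed=42)
        ):
            # with population size 1 and ploidy 1, pairwise coalescence rate
            # is 1 and branch time matches our scaling: per-site rate theta/2
            mts = msprime.sim_mutations(
                ts, rate=theta / 2, random_seed=100 + i,
                model=msprime.InfiniteSites(),
            )
            ref.append(mts.num_sites)
        assert np.mean(ours) == pytest.approx(np.mean(ref), rel=0.08)

    def test_codon_mode_in_frame_and_stop_free(self):
        hs, truth = simulate_haplotypes(
            CoalescentConfig(n_samples=6, sequence_length=300,
                             theta_per_site=0.05, omega=0.5, seed=5)
        )
        assert truth["mode"] == "codon"
        code = hs.code
        for row in hs.rows:
            assert len(row) % 3 == 0
            for i in range(0, len(row), 3):
                assert not code.is_stop(row[i : i + 3])

    def test_determinism(self):
        a, _ = simulate_haplotypes(CoalescentConfig(seed=123))
        b, _ = simulate_haplotypes(CoalescentConfig(seed=123))
        assert a.rows == b.rows


class TestQpcrSim:
    def test_shapes_and_truth(self):
        dil, samp, truth = simulate_qpcr_dataset(QpcrSimConfig(seed=0))
        assert set(dil.target) == {"F_cox1", "M_nad1", "nuclear_atpa"}
        # 3 experiments x 7 decades x 3 replicates per target
        assert (dil.groupby("target").size() == 63).all()
        assert samp.sample_id.nunique() == 18
        assert len(truth.somatic_f) == 18
        assert np.allclose(
            truth.male_m, truth.intercept + truth.slope * truth.somatic_f
        )

    def test_female_contamination_in_planted_range(self):
        _, _, truth = simulate_qpcr_dataset(QpcrSimConfig(seed=1))
        assert (truth.female_fm_ratio >= 300).all()
        assert (truth.female_fm_ratio <= 10_000).all()

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            QpcrSimConfig(sigma_cq=-0.1)

    def test_determinism(self):
        d1, s1, _ = simulate_qpcr_dataset(QpcrSimConfig(seed=4))
        d2, s2, _ = simulate_qpcr_dataset(QpcrSimConfig(seed=4))
        assert d1.equals(d2) and s1.equals(s2)


class TestNgsCounts:
    def test_equal_ratio_equal_lengths(self):
        totals = []
        for i in range(50):
            rm, rf = simulate_ngs_counts(1.0, 20_000, 20_000, 10_000, seed=i)
            totals.append(rm)
        assert np.mean(totals) == pytest.approx(5000, rel=0.02)

    def test_zero_reads_errors(self):
        with pytest.raises(ValueError):
            simulate_ngs_counts(1.0, 20_000, 20_000, 0)

    def test_determinism(self):
        assert simulate_ngs_counts(31.05, 24_347, 18_113, 10**6, seed=5) == \
            simulate_ngs_counts(31.05, 24_347, 18_113, 10**6, seed=5)
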