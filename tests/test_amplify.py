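"""Competitive PCR kinetics, blocker occupancy, LoD experiments."""

from dataclasses import replace

import numpy as np
import pytest

from qprobe.amplify import (PCRConfig, TemplateMix, allele_efficiency,
                            amplify_trajectory, blocker_occupancy,
                            lod_experiment, resolve_efficiencies, simulate_pcr)
from qprobe.thermo import ThermoConfig, nn_duplex_params, reverse_complement

PRIMER = "GCAGTCCATGGACTTGACCA"


def primer_tm(tcfg):
    return nn_duplex_params(PRIMER, reverse_complement(PRIMER), tcfg).tm


class TestAlleleEfficiency:
    def test_perfect_match_well_below_tm_reaches_e_max(self, tcfg):
        cfg = PCRConfig(anneal_temp=primer_tm(tcfg) - 15.0)
        eff = allele_efficiency(PRIMER, reverse_complement(PRIMER), cfg, tcfg)
        assert eff == pytest.approx(cfg.e_max, rel=0.01)

    def test_three_prime_terminal_mismatch_applies_penalty(self, tcfg):
        """Efficiency = penalty x (e_max * theta of the mismatched duplex)."""
        from qprobe.thermo import fraction_bound
        template = reverse_complement(PRIMER)
        # mutate the template base paired with the primer's 3' terminus
        bad = "T" + template[1:] if template[0] != "T" else "G" + template[1:]
        cfg = PCRConfig(anneal_temp=primer_tm(tcfg) - 15.0,
                        extension_mismatch_penalty=0.05)
        eff = allele_efficiency(PRIMER, bad, cfg, tcfg)
        params = nn_duplex_params(PRIMER, bad, tcfg)
        assert len(PRIMER) - 1 in params.mismatch_positions
        expected = 0.05 * cfg.e_max * fraction_bound(params, cfg.anneal_temp, tcfg)
        assert eff == pytest.approx(expected, abs=1e-9)

    def test_hot_annealing_kills_extension(self, tcfg):
        cfg = PCRConfig(anneal_temp=primer_tm(tcfg) + 30.0)
        eff = allele_efficiency(PRIMER, reverse_complement(PRIMER), cfg, tcfg)
        assert eff < 0.01 * cfg.e_max


class TestBlockerOccupancy:
    def test_zero_concentration_zero_occupancy(self, ex19del, tcfg):
        bl = ex19del.assay.blocker
        cfg = PCRConfig(anneal_temp=60.0, blocker_conc=0.0)
        assert blocker_occupancy(bl.blocker_seq, ex19del.reference, cfg, tcfg) == 0.0

    def test_saturating_blocker_occupies_wild_not_deleted(self, ex19del, tcfg):
        bl = ex19del.assay.blocker
        ps = ex19del.assay.primers
        cfg = PCRConfig(anneal_temp=bl.tm - 10.0, blocker_conc=1e-6)
        occ_wild = blocker_occupancy(bl.blocker_seq, ps.wild_template, cfg, tcfg)
        occ_del = blocker_occupancy(bl.blocker_seq, ps.mutant_template, cfg, tcfg)
        assert occ_wild > 0.95
        assert occ_del < occ_wild

    def test_occupancy_monotone_in_concentration(self, ex19del, tcfg):
        bl = ex19del.assay.blocker
        cfg0 = PCRConfig(anneal_temp=bl.tm - 2.0)
        occs = [blocker_occupancy(bl.blocker_seq, ex19del.reference,
                                  replace(cfg0, blocker_conc=c), tcfg)
                for c in (1e-12, 1e-10, 1e-8, 1e-6)]
        assert all(b >= a for a, b in zip(occs, occs[1:]))


class TestTrajectory:
    def test_zero_cycles_returns_input_pool(self):
        mix = TemplateMix(wild_copies=900, mutant_copies=100)
        res = amplify_trajectory(mix, {"wild": 0.9, "mutant": 0.9},
                                 PCRConfig(cycles=0))
        assert res.trajectory.shape == (1, 2)
        assert res.final_fraction_mutant == pytest.approx(0.1, abs=1e-15)

    def test_fixed_efficiency_closed_form(self):
        """Copy ratio changes by exactly (1.9/1.5)^10 in ten cycles."""
        mix = TemplateMix(wild_copies=1000.0, mutant_copies=1000.0)
        cfg = PCRConfig(cycles=10, saturation_capacity=1e30)
        res = amplify_trajectory(mix, {"wild": 0.5, "mutant": 0.9}, cfg)
        w, m = res.trajectory[-1]
        assert m / w == pytest.approx((1.9 / 1.5) ** 10, rel=1e-12)

    def test_equal_efficiencies_preserve_composition(self):
        mix = TemplateMix(wild_copies=997, mutant_copies=3)
        cfg = PCRConfig(cycles=45)
        res = amplify_trajectory(mix, {"wild": 0.8, "mutant": 0.8}, cfg)
        assert abs(res.final_fraction_mutant - mix.mutant_fraction) <= 1e-12

    def test_copies_never_decrease(self):
        mix = TemplateMix(wild_copies=100, mutant_copies=10)
        res = amplify_trajectory(mix, {"wild": 0.9, "mutant": 0.7},
                                 PCRConfig(cycles=45))
        assert np.all(np.diff(res.trajectory, axis=0) >= -1e-9)

    def test_saturation_below_input_flags_immediate_plateau(self):
        mix = TemplateMix(wild_copies=1e6, mutant_copies=0)
        cfg = PCRConfig(cycles=5, saturation_capacity=1e3)
        res = amplify_trajectory(mix, {"wild": 0.9, "mutant": 0.9}, cfg)
        assert res.flags
        assert np.all(res.trajectory[:, 0] == 1e6)

    def test_zero_templates_rejected(self):
        with pytest.raises(ValueError):
            amplify_trajectory(TemplateMix(0, 0), {"wild": 0.9, "mutant": 0.9},
                               PCRConfig())

    def test_stochastic_mean_matches_deterministic(self):
        """Mean of 1000 binomial trajectories tracks the expectation."""
        mix = TemplateMix(wild_copies=200, mutant_copies=50)
        eff = {"wild": 0.8, "mutant": 0.6}
        cfg_det = PCRConfig(cycles=10, saturation_capacity=1e30)
        det = amplify_trajectory(mix, eff, cfg_det).trajectory
        cfg_sto = replace(cfg_det, stochastic=True)
        rng = np.random.default_rng(99)
        trajs = np.stack([amplify_trajectory(mix, eff, cfg_sto, rng).trajectory
                          for _ in range(1000)])
        mean = trajs.mean(axis=0)
        se = trajs.std(axis=0, ddof=1) / np.sqrt(trajs.shape[0])
        mask = se > 0
        assert np.all(np.abs(mean[mask] - det[mask]) <= 3.0 * se[mask])

    def test_seeded_stochastic_runs_are_reproducible(self):
        mix = TemplateMix(wild_copies=500, mutant_copies=5)
        cfg = PCRConfig(cycles=30, stochastic=True, seed=42)
        a = amplify_trajectory(mix, {"wild": 0.9, "mutant": 0.95}, cfg)
        b = amplify_trajectory(mix, {"wild": 0.9, "mutant": 0.95}, cfg)
        assert np.array_equal(a.trajectory, b.trajectory)


class TestModes:
    def test_standard_mode_preserves_fraction(self, t790m, tcfg):
        mix = TemplateMix.from_fraction(0.03)
        res = simulate_pcr(mix, t790m.assay.primers, PCRConfig(mode="standard"),
                           tcfg)
        assert res.final_fraction_mutant == pytest.approx(mix.mutant_fraction,
                                                          abs=1e-12)

    def test_mbp_enriches_every_fraction(self, t790m, tcfg):
        cfg = PCRConfig(mode="MBP")
        for f in np.arange(0.05, 1.0, 0.05):
            mix = TemplateMix(wild_copies=1500 * (1 - f), mutant_copies=1500 * f)
            res = simulate_pcr(mix, t790m.assay.primers, cfg, tcfg)
            assert res.final_fraction_mutant > mix.mutant_fraction

    def test_mbp_mode_requires_mbp_primer_set(self, ex19del, tcfg):
        with pytest.raises(ValueError):
            simulate_pcr(TemplateMix(100, 100), ex19del.assay.primers,
                         PCRConfig(mode="MBP"), tcfg)

    def test_wip_suppresses_wild_amplification(self, ex19del, tcfg):
        cfg = PCRConfig(mode="WIP")
        eff = resolve_efficiencies(ex19del.assay.primers, cfg, tcfg,
                                   ex19del.assay.blocker)
        assert eff["mutant"] > 10 * eff["wild"]

    def test_wip_mode_requires_blocker(self, ex19del, tcfg):
        with pytest.raises(ValueError):
            simulate_pcr(TemplateMix(100, 100), ex19del.assay.primers,
                         PCRConfig(mode="WIP"), tcfg)


class TestLoD:
    def test_blank_only_ladder_flags_undefined(self, t790m):
        rep = lod_experiment(t790m.assay, [0.0], 3, seed=1)
        assert rep.lod is None
        assert rep.flags

    def test_pure_mutant_level_always_detected(self, t790m):
        rep = lod_experiment(t790m.assay, [1.0, 0.0], 3, seed=1)
        assert rep.rates[rep.levels.index(1.0)] == 1.0

    def test_ladder_must_include_blank(self, t790m):
        with pytest.raises(ValueError):
            lod_experiment(t790m.assay, [0.1, 0.01], 3, seed=1)

    def test_reruns_with_same_seed_identical(self, t790m):
        ladder = [0.01, 0.003, 0.0]
        a = lod_experiment(t790m.assay, ladder, 5, seed=3)
        b = lod_experiment(t790m.assay, ladder, 5, seed=3)
        assert a.detections == b.detections
        assert a.lod == b.lod

    def test_wip_blank_never_calls_mutant(self, ex19del):
        """Blocker present, zero mutant copies: no false positives."""
        rep = lod_experiment(ex19del.assay, [0.001, 0.0], 30, seed=11,
                             cfg=PCRConfig(mode="WIP", stochastic=True))
        assert rep.blank_false_positives == 0
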