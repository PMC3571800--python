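"""Nearest-neighbor thermodynamics: summation, Tm, occupancy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from qprobe.errors import AlignmentError, SequenceError
from qprobe.thermo import (DuplexParams, R, ThermoConfig, duplex_params_at,
                           fraction_bound, melting_temp, nn_duplex_params,
                           reverse_complement)

BASES = "ACGT"


def random_duplex(rng, length=None, max_tm=72.0, cfg=None):
    """Random probe/perfect-target pair from the designable Tm domain."""
    cfg = cfg or ThermoConfig()
    while True:
        n = length or rng.integers(12, 31)
        probe = "".join(rng.choice(list(BASES), size=n))
        target = reverse_complement(probe)
        p = duplex_params_at(probe, target, 0, cfg)
        if p.stable and p.tm <= max_tm:
            return probe, target, p


class TestNNSummation:
    def test_hand_summed_octamer(self, tcfg):
        """dH/dS of ACGTCAGC equal an independent by-hand table summation.

        The expected values are summed here from the unified
        nearest-neighbor parameters written out explicitly (doublet
        stacks + duplex initiation + one A/T terminal penalty).
        """
        stacks = {  # dH kcal/mol, dS cal/(mol K), unified WC set
            "AC": (-8.4, -22.4), "CG": (-10.6, -27.2), "GT": (-8.4, -22.4),
            "TC": (-8.2, -22.2), "CA": (-8.5, -22.7), "AG": (-7.8, -21.0),
            "GC": (-9.8, -24.4),
        }
        seq = "ACGTCAGC"
        dh = 0.2 + 2.2  # init + 5' A/T terminal (3' end is G/C: 0)
        ds = -5.7 + 6.9
        for i in range(len(seq) - 1):
            h, s = stacks[seq[i:i + 2]]
            dh += h
            ds += s
        p = nn_duplex_params(seq, reverse_complement(seq), tcfg)
        assert p.dh == pytest.approx(dh, abs=1e-9)
        assert p.ds == pytest.approx(ds, abs=1e-9)
        assert p.n_mismatches == 0

    def test_perfect_match_tm_agrees_with_biopython(self, tcfg):
        """Cross-check the whole Tm path against Biopython's Tm_NN."""
        from Bio.Seq import Seq
        from Bio.SeqUtils import MeltingTemp as mt
        seq = "ACGTTGCAAGGTCCAT"
        p = nn_duplex_params(seq, reverse_complement(seq), tcfg)
        ref = mt.Tm_NN(Seq(seq), nn_table=mt.DNA_NN4,
                       dnac1=tcfg.strand_conc * 1e9, dnac2=0,
                       Na=tcfg.monovalent_salt * 1000, saltcorr=5)
        assert p.tm == pytest.approx(ref, abs=0.05)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text(alphabet=BASES, min_size=8, max_size=30))
    def test_duplex_symmetry(self, seq):
        """dH/dS are invariant under swapping probe and target strands."""
        cfg = ThermoConfig()
        target = reverse_complement(seq)
        a = nn_duplex_params(seq, target, cfg)
        b = nn_duplex_params(target, seq, cfg)
        assert a.dh == pytest.approx(b.dh, abs=1e-12)
        assert a.ds == pytest.approx(b.ds, abs=1e-12)

    def test_single_internal_mismatch_lowers_tm(self, tcfg):
        """A mismatched 16-mer melts strictly below its perfect duplex."""
        rng = np.random.default_rng(5)
        for _ in range(100):
            probe, target, p0 = random_duplex(rng, length=16)
            pos = int(rng.integers(0, 16))
            ti = 15 - pos
            wrong = rng.choice([b for b in BASES if b != target[ti]])
            mutated = target[:ti] + wrong + target[ti + 1:]
            p1 = duplex_params_at(probe, mutated, 0, tcfg)
            assert p1.n_mismatches == 1
            assert p1.tm < p0.tm

    def test_mismatch_limit_enforced(self, tcfg):
        probe = "ACGTACGTACGTACGT"
        target = reverse_complement(probe)
        flip = str.maketrans("ACGT", "CATG")  # guaranteed non-complementary
        bad = target[:4].translate(flip) + target[4:]  # 4 mismatches
        with pytest.raises(AlignmentError):
            duplex_params_at(probe, bad, 0, tcfg)

    def test_alignment_search_finds_footprint(self, tcfg):
        rng = np.random.default_rng(11)
        probe, _, _ = random_duplex(rng, length=20)
        pad5 = "".join(rng.choice(list(BASES), size=37))
        pad3 = "".join(rng.choice(list(BASES), size=55))
        target = pad5 + reverse_complement(probe) + pad3
        p = nn_duplex_params(probe, target, tcfg)
        assert p.alignment_offset == 37
        assert p.n_mismatches == 0

    def test_unalignable_probe_raises(self, tcfg):
        with pytest.raises(AlignmentError):
            nn_duplex_params("ACGTACGTACGTACGTACGT", "A" * 60, tcfg)

    def test_non_acgt_rejected(self, tcfg):
        with pytest.raises(SequenceError):
            nn_duplex_params("ACGTN", "ACGTACGTAC", tcfg)

    def test_tm_finite_and_in_range(self, tcfg):
        """Any 6-60mer duplex melts within [-20, 120] degC at defaults."""
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(6, 61))
            probe = "".join(rng.choice(list(BASES), size=n))
            p = duplex_params_at(probe, reverse_complement(probe), 0, tcfg)
            assert p.stable
            assert -20.0 <= p.tm <= 120.0


class TestMeltingTemp:
    def test_closed_form_equimolar(self):
        """Tm for dH=-60, dS=-170 at 1 uM, equimolar, 1 M salt.

        Independent closed-form evaluation:
        Tm = -60000 / (-170 + R ln(1e-6 / 4)) - 273.15 = 26.5367 degC.
        """
        params = DuplexParams(dh=-60.0, ds=-170.0, tm=0.0, n_mismatches=0,
                              alignment_offset=0, n_bp=20)
        cfg = ThermoConfig(excess_convention="equimolar", monovalent_salt=1.0,
                           strand_conc=1e-6)
        assert melting_temp(params, cfg) == pytest.approx(26.5367, abs=1e-3)

    def test_tm_monotone_in_concentration(self, tcfg):
        rng = np.random.default_rng(2)
        _, _, p = random_duplex(rng, length=18)
        tms = [melting_temp(p, ThermoConfig(strand_conc=c))
               for c in (1e-8, 1e-7, 1e-6, 1e-5)]
        assert all(a < b for a, b in zip(tms, tms[1:]))

    def test_lower_salt_lowers_tm(self, tcfg):
        rng = np.random.default_rng(3)
        _, _, p = random_duplex(rng, length=18)
        hi = melting_temp(p, ThermoConfig(monovalent_salt=1.0))
        lo = melting_temp(p, ThermoConfig(monovalent_salt=0.05))
        assert lo < hi

    def test_unstable_duplex_yields_nan_sentinel(self):
        params = DuplexParams(dh=5.0, ds=-1.0, tm=0.0, n_mismatches=0,
                              alignment_offset=0, n_bp=8)
        assert math.isnan(melting_temp(params, ThermoConfig()))


class TestFractionBound:
    def test_half_occupancy_at_tm(self, tcfg):
        rng = np.random.default_rng(4)
        for _ in range(10):
            _, _, p = random_duplex(rng)
            assert fraction_bound(p, p.tm, tcfg) == pytest.approx(0.5, abs=1e-9)

    def test_half_occupancy_at_tm_equimolar(self):
        cfg = ThermoConfig(excess_convention="equimolar")
        rng = np.random.default_rng(6)
        probe, target, _ = random_duplex(rng, length=20)
        p = duplex_params_at(probe, target, 0, cfg)
        assert fraction_bound(p, p.tm, cfg) == pytest.approx(0.5, abs=1e-9)

    def test_sigmoid_limits(self, tcfg):
        rng = np.random.default_rng(7)
        _, _, p = random_duplex(rng, length=20)
        assert fraction_bound(p, p.tm - 40.0, tcfg) > 0.99
        assert fraction_bound(p, p.tm + 40.0, tcfg) < 0.01

    def test_monotone_nonincreasing_on_grid(self, tcfg):
        rng = np.random.default_rng(8)
        _, _, p = random_duplex(rng)
        grid = np.arange(20.0, 95.0, 0.1)
        theta = fraction_bound(p, grid, tcfg)
        assert np.all(np.diff(theta) <= 1e-15)

    def test_matches_mass_action_root(self, tcfg):
        """theta agrees with a brute-force two-state equilibrium solve.

        Probe in excess at CT: solve K(T)*CT*(1-theta) = theta for theta
        by root finding, independently of the closed form.
        """
        rng = np.random.default_rng(9)
        _, _, p = random_duplex(rng, length=20)
        grid = np.arange(p.tm - 12.0, p.tm + 12.0, 0.1)
        ds_corr = p.ds + 0.368 * (p.n_bp - 1) * math.log(tcfg.monovalent_salt)
        for t in grid:
            tk = t + 273.15
            k = math.exp(-(p.dh * 1000.0 - tk * ds_corr) / (R * tk))
            root = brentq(lambda x: k * tcfg.strand_conc * (1 - x) - x,
                          0.0, 1.0, xtol=1e-14)
            assert fraction_bound(p, float(t), tcfg) == pytest.approx(root, abs=1e-9)


def test_probe_shortening_widens_tm_gap(tcfg):
    """Median match-mismatch Tm gap shrinks as probes grow 12 -> 30 nt."""
    rng = np.random.default_rng(12)
    medians = []
    for n in (12, 18, 24, 30):
        gaps = []
        while len(gaps) < 60:
            probe, target, p0 = random_duplex(rng, length=n, max_tm=90.0)
            pos = n // 2
            ti = n - 1 - pos
            wrong = rng.choice([b for b in BASES if b != target[ti]])
            p1 = duplex_params_at(probe, target[:ti] + wrong + target[ti + 1:],
                                  0, tcfg)
            if p1.stable:
                gaps.append(p0.tm - p1.tm)
        medians.append(float(np.median(gaps)))
    assert all(a >= b for a, b in zip(medians, medians[1:]))
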