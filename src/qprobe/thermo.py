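"""Nearest-neighbor duplex thermodynamics and two-state melting.

Stability of probe-target, primer-template and blocker-template duplexes is
modeled as a sum of nearest-neighbor stack, initiation and mismatch
contributions (unified Watson-Crick set plus published internal-mismatch
doublet parameters, taken from Biopython's tables).  A duplex is summarized
by its enthalpy/entropy pair, from which the two-state melting temperature

    Tm = dH / (dS + R ln(CT / x)) - 273.15

and the equilibrium occupancy (fraction of target bound by probe) at any
temperature follow.  ``x`` encodes the strand-concentration convention:
1 when the probe is in large excess over the target (the usual situation
for a detection probe read against amplicon), 4 for equimolar strands.

Model limits, by construction:

* at most three non-Watson-Crick pairs per duplex; beyond that the
  two-state description is not trustworthy and an :class:`AlignmentError`
  is raised instead of extrapolating;
* terminal mismatches are treated as unstacked ends (the terminal doublet
  and that end's initiation term contribute nothing) -- a conservative
  accounting under which any terminal substitution is destabilizing;
* doublets in which both pairs are mismatched (adjacent mismatches)
  contribute nothing;
* dangling ends, fluorophore effects, hairpins and divalent ions are out
  of scope; a single monovalent salt correction is applied to dS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Union

import numpy as np
from Bio.SeqUtils import MeltingTemp as _mt

from .errors import AlignmentError, SequenceError

#: Gas constant, cal/(mol*K).
R = 1.987204258640832

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Available nearest-neighbor parameter sets (Watson-Crick table,
#: internal-mismatch table).  Values are (dH kcal/mol, dS cal/(mol*K)).
NN_TABLES = {
    "santalucia2004": (_mt.DNA_NN4, _mt.DNA_IMM1),
    "santalucia1998": (_mt.DNA_NN3, _mt.DNA_IMM1),
}

MAX_MISMATCHES = 3


def reverse_complement(seq: str) -> str:
    try:
        return "".join(_COMPLEMENT[b] for b in reversed(seq))
    except KeyError as exc:
        raise SequenceError(f"non-ACGT character in sequence: {exc.args[0]!r}") from None


def _validate(seq: str, what: str) -> None:
    if not seq or any(b not in _COMPLEMENT for b in seq):
        bad = next((b for b in seq), "")
        bad = next((b for b in seq if b not in _COMPLEMENT), bad)
        raise SequenceError(f"{what} must be non-empty uppercase ACGT (got {bad!r})")


@dataclass(frozen=True)
class ThermoConfig:
    """Thermodynamic model settings.

    monovalent_salt is the monovalent cation concentration in mol/L
    (1.0 is the reference condition of the parameter tables); strand_conc
    is the total oligo concentration CT in mol/L.
    """

    nn_table_id: str = "santalucia2004"
    monovalent_salt: float = 1.0
    strand_conc: float = 2e-6
    excess_convention: str = "probe_excess"  # or "equimolar"

    def __post_init__(self) -> None:
        if self.nn_table_id not in NN_TABLES:
            raise ValueError(f"unknown nn_table_id {self.nn_table_id!r}; "
                             f"choose from {sorted(NN_TABLES)}")
        if self.monovalent_salt <= 0 or self.strand_conc <= 0:
            raise ValueError("monovalent_salt and strand_conc must be > 0")
        if self.excess_convention not in ("probe_excess", "equimolar"):
            raise ValueError("excess_convention must be 'probe_excess' or 'equimolar'")

    @property
    def conc_divisor(self) -> float:
        """x in Tm = dH / (dS + R ln(CT/x))."""
        return 1.0 if self.excess_convention == "probe_excess" else 4.0


@dataclass(frozen=True)
class DuplexParams:
    """Summed thermodynamics of one probe-target duplex.

    dh: kcal/mol (negative for a stable duplex); ds: cal/(mol*K);
    tm: melting temperature (deg C) at the config's concentration and salt,
    NaN when no stable duplex forms; alignment_offset: 0-based position of
    the footprint's leftmost base on the target (the probe 3' end pairs
    there -- the duplex is antiparallel); n_bp: footprint length;
    mismatch_positions: probe indices (5'->3') of non-Watson-Crick pairs.
    """

    dh: float
    ds: float
    tm: float
    n_mismatches: int
    alignment_offset: int
    n_bp: int
    mismatch_positions: tuple[int, ...] = field(default=())

    @property
    def stable(self) -> bool:
        return math.isfinite(self.tm)


def _lookup_doublet(p2: str, q2: str, wc: dict, imm: dict):
    key = f"{p2}/{q2}"
    for table in (wc, imm):
        if key in table:
            return table[key]
        if key[::-1] in table:
            return table[key[::-1]]
    return None


def _sum_duplex(probe: str, paired: str, cfg: ThermoConfig) -> tuple[float, float, tuple[int, ...]]:
    """Sum stacks + initiation for ``probe`` against the bases ``paired``.

    ``paired`` lists the target base opposite each probe base, in probe
    order (i.e. the complementary strand read 3'->5').
    """
    wc, imm = NN_TABLES[cfg.nn_table_id]
    n = len(probe)
    mism = tuple(i for i in range(n) if _COMPLEMENT[probe[i]] != paired[i])
    mset = set(mism)
    dh, ds = wc["init"]
    for end in (0, n - 1):
        if end not in mset:
            ih, is_ = wc["init_A/T"] if probe[end] in "AT" else wc["init_G/C"]
            dh += ih
            ds += is_
    for i in range(n - 1):
        a, b = i in mset, (i + 1) in mset
        if not a and not b:
            h, s = _lookup_doublet(probe[i:i + 2], paired[i:i + 2], wc, {})
        elif a and b:
            h, s = 0.0, 0.0  # adjacent mismatches: no published stack
        elif (a and i == 0) or (b and i + 1 == n - 1):
            h, s = 0.0, 0.0  # terminal mismatch: unstacked end
        else:
            got = _lookup_doublet(probe[i:i + 2], paired[i:i + 2], wc, imm)
            h, s = got if got is not None else (0.0, 0.0)
        dh += h
        ds += s
    return dh, ds, mism


def _salt_corrected_ds(params_ds: float, n_bp: int, cfg: ThermoConfig) -> float:
    # SantaLucia (1998) entropic monovalent correction.
    return params_ds + 0.368 * (n_bp - 1) * math.log(cfg.monovalent_salt)


def _tm_from_dh_ds(dh: float, ds: float, n_bp: int, cfg: ThermoConfig) -> float:
    ds_corr = _salt_corrected_ds(ds, n_bp, cfg)
    denom = ds_corr + R * math.log(cfg.strand_conc / cfg.conc_divisor)
    if dh >= 0 or denom >= 0:
        return float("nan")  # no melting in range
    return dh * 1000.0 / denom - 273.15


def duplex_params_at(probe: str, target: str, offset: int,
                     cfg: ThermoConfig) -> DuplexParams:
    """Duplex parameters for ``probe`` laid at a known footprint.

    ``offset`` is the 0-based start of the footprint on ``target`` (both
    5'->3'); the probe anneals antiparallel, so probe base i pairs with
    target base ``offset + len(probe) - 1 - i``.
    """
    _validate(probe, "probe")
    _validate(target, "target")
    n = len(probe)
    if not 6 <= n <= 60:
        raise ValueError(f"probe length must be in [6, 60], got {n}")
    if offset < 0 or offset + n > len(target):
        raise AlignmentError("footprint extends beyond the target")
    window = target[offset:offset + n]
    paired = window[::-1]
    dh, ds, mism = _sum_duplex(probe, paired, cfg)
    if len(mism) > MAX_MISMATCHES:
        raise AlignmentError(
            f"{len(mism)} mismatches at offset {offset} exceed the "
            f"{MAX_MISMATCHES}-mismatch limit of the two-state model")
    tm = _tm_from_dh_ds(dh, ds, n, cfg)
    return DuplexParams(dh=dh, ds=ds, tm=tm, n_mismatches=len(mism),
                        alignment_offset=offset, n_bp=n,
                        mismatch_positions=mism)


def nn_duplex_params(probe: str, target: str, cfg: ThermoConfig) -> DuplexParams:
    """Best-footprint duplex parameters of ``probe`` on ``target``.

    Slides the probe along the target (antiparallel) and keeps the
    footprint with the fewest mismatches (ties: leftmost).  Raises
    :class:`AlignmentError` when no footprint has at most three
    mismatches.
    """
    _validate(probe, "probe")
    _validate(target, "target")
    n = len(probe)
    if not 6 <= n <= 60:
        raise ValueError(f"probe length must be in [6, 60], got {n}")
    if n > len(target):
        raise AlignmentError("probe longer than target")
    rc = reverse_complement(probe)
    best_off, best_mm = -1, n + 1
    for off in range(len(target) - n + 1):
        mm = sum(1 for a, b in zip(rc, target[off:off + n]) if a != b)
        if mm < best_mm:
            best_off, best_mm = off, mm
            if mm == 0:
                break
    if best_mm > MAX_MISMATCHES:
        raise AlignmentError(
            f"no footprint with <= {MAX_MISMATCHES} mismatches "
            f"(best has {best_mm})")
    return duplex_params_at(probe, target, best_off, cfg)


def best_partial_duplex(oligo: str, target: str, cfg: ThermoConfig,
                        min_len: int = 6) -> DuplexParams:
    """Best duplex of ``oligo`` or one of its end-anchored fragments.

    Tries the full oligo first; if it cannot be aligned within the
    mismatch budget (e.g. a junction-spanning oligo on a template carrying
    a deletion), falls back to the most stable prefix or suffix of length
    >= ``min_len`` that aligns.  This models the partially-hybridized
    state of a wild-matched oligo on a deletion allele.  Raises
    :class:`AlignmentError` when nothing aligns.
    """
    try:
        return nn_duplex_params(oligo, target, cfg)
    except AlignmentError:
        pass
    best: DuplexParams | None = None
    n = len(oligo)
    for length in range(min(n - 1, 60), min_len - 1, -1):
        for frag in (oligo[:length], oligo[n - length:]):
            try:
                cand = nn_duplex_params(frag, target, cfg)
            except AlignmentError:
                continue
            if cand.n_mismatches > 0:
                continue  # fragments must match exactly to be credible
            if best is None or (cand.tm > best.tm if cand.stable else False):
                best = cand
        if best is not None and best.stable:
            # longer exact fragments dominate shorter ones; stop early
            break
    if best is None:
        raise AlignmentError("no end-anchored fragment of the oligo aligns")
    return best


def melting_temp(params: DuplexParams, cfg: ThermoConfig) -> float:
    """Two-state Tm (deg C); NaN signals no melting in range."""
    return _tm_from_dh_ds(params.dh, params.ds, params.n_bp, cfg)


def fraction_bound(params: DuplexParams,
                   t: Union[float, np.ndarray],
                   cfg: ThermoConfig) -> Union[float, np.ndarray]:
    """Equilibrium occupancy theta of the target by the probe at ``t`` degC.

    Probe-excess convention: theta = K*CT / (1 + K*CT), the classic
    pseudo-first-order binding isotherm, which equals 1/2 at the Tm
    defined with x = 1.  Equimolar convention: the exact root of the
    two-state mass-action quadratic, 1/2 at the Tm defined with x = 4.
    Continuous and non-increasing in temperature.
    """
    t_arr = np.asarray(t, dtype=float)
    t_kelvin = t_arr + 273.15
    ds_corr = _salt_corrected_ds(params.ds, params.n_bp, cfg)
    # ln K, K in 1/M
    ln_k = -(params.dh * 1000.0 - t_kelvin * ds_corr) / (R * t_kelvin)
    if cfg.excess_convention == "probe_excess":
        z = np.clip(ln_k + math.log(cfg.strand_conc), -700, 700)
        theta = 1.0 / (1.0 + np.exp(-z))
    else:
        # b = K * CT / 2 ; theta = ((2b+1) - sqrt(4b+1)) / (2b)
        ln_b = np.clip(ln_k + math.log(cfg.strand_conc / 2.0), -700, 700)
        b = np.exp(ln_b)
        with np.errstate(divide="ignore", invalid="ignore"):
            theta = np.where(
                b > 1e-12,
                ((2.0 * b + 1.0) - np.sqrt(4.0 * b + 1.0)) / (2.0 * b),
                b,  # small-b limit: theta ~ b
            )
    if np.ndim(t) == 0:
        return float(theta)
    return theta
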