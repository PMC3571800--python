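"""Cycle-by-cycle competitive PCR and limit-of-detection experiments.

Three amplification modes share one update rule,

    N_a(c+1) = N_a(c) * (1 + E_a * s(c)),    s(c) = max(0, 1 - N_tot/K),

with a logistic shared-resource saturation (both alleles draw on the same
reagent pool of capacity K) and per-allele efficiencies E_a resolved from
primer/blocker thermodynamics at the annealing temperature:

standard   one allele-neutral primer pair; E identical for both alleles,
           so amplification preserves the template composition;
MBP        wild and mutant primers compete for the same 3' site; each
           template is extended by whichever primer wins, at e_max *
           theta(anneal) times the 3'-terminal mismatch penalty when the
           terminal base does not pair -- the longer mutant primer plus a
           mutant-optimal annealing temperature biases every cycle toward
           the mutant allele;
WIP        an allele-neutral pair plus a non-extendable wild-matching
           blocker whose equilibrium occupancy of a template scales that
           template's efficiency by (1 - occupancy); the blocker pairs
           fully only with wild template, so wild amplification is
           suppressed.

In stochastic mode the per-cycle duplications are binomial draws with the
same expectation.  The limit-of-detection experiment runs the full
pipeline (PCR -> melt curve -> somatic call) over a mutant-fraction
dilution ladder and reports the lowest fraction detected in >= 95% of
replicates with zero blank false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import AlignmentError
from .genotype import CallingConfig, call_sample
from .signal import NoiseConfig, TemperatureGrid, simulate_melt_curve
from .thermo import (DuplexParams, ThermoConfig, best_partial_duplex,
                     fraction_bound, reverse_complement)

#: Default template input per reaction (copies) -- the genome-equivalent
#: scale of a small purified-DNA or plasma input, at which the rarest
#: dilution levels carry only a handful of mutant molecules.
DEFAULT_TEMPLATE_COPIES = 1_500


@dataclass(frozen=True)
class TemplateMix:
    """Wild/mutant template copy numbers entering PCR."""

    wild_copies: float
    mutant_copies: float

    def __post_init__(self) -> None:
        if self.wild_copies < 0 or self.mutant_copies < 0:
            raise ValueError("copy numbers must be >= 0")

    @property
    def total(self) -> float:
        return self.wild_copies + self.mutant_copies

    @property
    def mutant_fraction(self) -> float:
        return self.mutant_copies / self.total if self.total > 0 else 0.0

    @classmethod
    def from_fraction(cls, mutant_fraction: float,
                      total: float = DEFAULT_TEMPLATE_COPIES) -> "TemplateMix":
        if not 0 <= mutant_fraction <= 1:
            raise ValueError("mutant_fraction must lie in [0, 1]")
        mutant = round(mutant_fraction * total)
        return cls(wild_copies=total - mutant, mutant_copies=mutant)


@dataclass(frozen=True)
class PCRConfig:
    """Kinetic parameters of the cycle simulator (committed defaults)."""

    cycles: int = 45
    mode: str = "standard"  # standard | MBP | WIP
    anneal_temp: Optional[float] = None  # None: take from the primer set
    e_max: float = 0.95
    saturation_capacity: float = 1e12
    extension_mismatch_penalty: float = 0.90
    blocker_conc: float = 2.5e-9
    seed: int = 0
    stochastic: bool = False

    def __post_init__(self) -> None:
        if self.cycles < 0:
            raise ValueError("cycles must be >= 0")
        if not 0 < self.e_max <= 1:
            raise ValueError("e_max must lie in (0, 1]")
        if not 0 <= self.extension_mismatch_penalty <= 1:
            raise ValueError("extension_mismatch_penalty must lie in [0, 1]")
        if self.mode not in ("standard", "MBP", "WIP"):
            raise ValueError("mode must be standard, MBP or WIP")
        if self.saturation_capacity <= 0 or self.blocker_conc < 0:
            raise ValueError("invalid capacity or blocker concentration")


@dataclass
class AmplificationResult:
    """Per-cycle allele trajectories and the final pool composition."""

    trajectory: np.ndarray  # shape (cycles+1, 2): [:, 0]=wild, [:, 1]=mutant
    final_fraction_mutant: float
    effective_efficiencies: dict[str, float]
    flags: list[str] = field(default_factory=list)

    @property
    def final_pool(self) -> dict[str, float]:
        w, m = self.trajectory[-1]
        tot = w + m
        return {"wild": w / tot, "mutant": m / tot} if tot > 0 else {"wild": 0.0, "mutant": 0.0}


def _duplex_on_template(oligo: str, template: str,
                        tcfg: ThermoConfig) -> DuplexParams:
    """Duplex of an oligo on whichever strand of the template it binds.

    Full alignments on either strand take precedence (fewest mismatches,
    then higher Tm); only when the oligo cannot be laid down whole --
    e.g. a junction-spanning blocker on a deletion allele -- does the
    best end-anchored partial duplex stand in.
    """
    from .thermo import nn_duplex_params
    full: list[DuplexParams] = []
    for tgt in (template, reverse_complement(template)):
        try:
            full.append(nn_duplex_params(oligo, tgt, tcfg))
        except AlignmentError:
            pass
    if full:
        return min(full, key=lambda p: (p.n_mismatches,
                                        -(p.tm if p.stable else -1e9)))
    partial: list[DuplexParams] = []
    for tgt in (template, reverse_complement(template)):
        try:
            partial.append(best_partial_duplex(oligo, tgt, tcfg))
        except AlignmentError:
            pass
    if not partial:
        raise AlignmentError("oligo does not align to either template strand")
    return max(partial, key=lambda p: (p.n_bp, p.tm if p.stable else -1e9))


def allele_efficiency(primer: str, template: str, cfg: PCRConfig,
                      thermo_cfg: Optional[ThermoConfig] = None) -> float:
    """Per-cycle extension efficiency of one primer on one template.

    efficiency = e_max * theta(anneal_temp) * penalty, where the 3'
    terminal-mismatch penalty applies when the primer's last base does
    not pair with the template.  Unalignable primers extend nothing.
    """
    tcfg = thermo_cfg if thermo_cfg is not None else ThermoConfig()
    if cfg.anneal_temp is None:
        raise ValueError("cfg.anneal_temp must be set (or resolved from a primer set)")
    try:
        params = _duplex_on_template(primer, template, tcfg)
    except AlignmentError:
        return 0.0
    theta = fraction_bound(params, cfg.anneal_temp, tcfg)
    penalty = 1.0
    if len(primer) - 1 in params.mismatch_positions or params.n_bp < len(primer):
        penalty = cfg.extension_mismatch_penalty
    return float(cfg.e_max * theta * penalty)


def blocker_occupancy(blocker: str, template: str, cfg: PCRConfig,
                      thermo_cfg: Optional[ThermoConfig] = None) -> float:
    """Equilibrium occupancy of the template by the blocker at annealing.

    Mass-action binding at the blocker concentration: K*C / (1 + K*C).
    On a template carrying a deletion under the blocker footprint only a
    flank fragment can pair, so the occupancy collapses.
    """
    tcfg = thermo_cfg if thermo_cfg is not None else ThermoConfig()
    if cfg.blocker_conc <= 0:
        return 0.0
    if cfg.anneal_temp is None:
        raise ValueError("cfg.anneal_temp must be set")
    try:
        params = _duplex_on_template(blocker, template, tcfg)
    except AlignmentError:
        return 0.0
    conc_cfg = replace(tcfg, strand_conc=cfg.blocker_conc,
                       excess_convention="probe_excess")
    return float(fraction_bound(params, cfg.anneal_temp, conc_cfg))


def resolve_efficiencies(primers, cfg: PCRConfig,
                         thermo_cfg: Optional[ThermoConfig] = None,
                         blocker=None) -> dict[str, float]:
    """Per-allele per-cycle efficiencies for the configured mode."""
    tcfg = thermo_cfg if thermo_cfg is not None else ThermoConfig()
    if cfg.anneal_temp is None:
        if cfg.mode == "standard" and primers.mode == "MBP":
            # unbiased PCR ignores the allele-specific primers; anneal at
            # the shared primer's own optimum instead of the mutant one
            p = _duplex_on_template(primers.reverse, primers.wild_template, tcfg)
            cfg = replace(cfg, anneal_temp=p.tm - 5.0)
        else:
            cfg = replace(cfg, anneal_temp=primers.anneal_temp)
    templates = {"wild": primers.wild_template, "mutant": primers.mutant_template}
    eff: dict[str, float] = {}
    for allele, template in templates.items():
        if cfg.mode == "standard":
            eff[allele] = allele_efficiency(primers.reverse, template, cfg, tcfg)
        elif cfg.mode == "MBP":
            eff[allele] = max(
                allele_efficiency(primers.forward_wild, template, cfg, tcfg),
                allele_efficiency(primers.forward_mutant, template, cfg, tcfg))
        else:  # WIP
            base = allele_efficiency(primers.forward_wild, template, cfg, tcfg)
            occ = 0.0
            if blocker is not None:
                seq = blocker if isinstance(blocker, str) else blocker.blocker_seq
                occ = blocker_occupancy(seq, template, cfg, tcfg)
            eff[allele] = base * (1.0 - occ)
    return eff


def amplify_trajectory(mix: TemplateMix, efficiencies: Mapping[str, float],
                       cfg: PCRConfig,
                       rng: Optional[np.random.Generator] = None) -> AmplificationResult:
    """Run the cycle recursion for fixed per-allele efficiencies."""
    if mix.total <= 0:
        raise ValueError("total template copies must be > 0")
    for e in efficiencies.values():
        if not 0 <= e <= 1:
            raise ValueError("efficiencies must lie in [0, 1]")
    flags: list[str] = []
    if mix.total > cfg.saturation_capacity:
        flags.append("initial copies exceed saturation capacity: immediate plateau")
    e_vec = np.array([efficiencies["wild"], efficiencies["mutant"]], dtype=float)
    stochastic = cfg.stochastic
    if stochastic and rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = (np.array([mix.wild_copies, mix.mutant_copies], dtype=np.int64)
         if stochastic else
         np.array([mix.wild_copies, mix.mutant_copies], dtype=float))
    traj = np.empty((cfg.cycles + 1, 2), dtype=float)
    traj[0] = n
    realized = np.zeros(2)
    for c in range(cfg.cycles):
        s = max(0.0, 1.0 - float(n.sum()) / cfg.saturation_capacity)
        p = np.clip(e_vec * s, 0.0, 1.0)
        dn = rng.binomial(n, p) if stochastic else n * p
        n = n + dn
        traj[c + 1] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            realized += np.where(traj[c] > 0, dn / traj[c], 0.0)
    total = float(n.sum())
    eff_real = realized / cfg.cycles if cfg.cycles else realized
    return AmplificationResult(
        trajectory=traj,
        final_fraction_mutant=float(n[1] / total) if total > 0 else 0.0,
        effective_efficiencies={"wild": float(eff_real[0]),
                                "mutant": float(eff_real[1])},
        flags=flags)


def simulate_pcr(mix: TemplateMix, primers, cfg: PCRConfig,
                 thermo_cfg: Optional[ThermoConfig] = None, blocker=None,
                 rng: Optional[np.random.Generator] = None) -> AmplificationResult:
    """Competitive PCR of a wild/mutant template mix with a primer set."""
    if cfg.mode == "WIP" and blocker is None:
        raise ValueError("WIP mode requires a blocker")
    if cfg.mode == "MBP" and primers.mode != "MBP":
        raise ValueError("MBP mode requires an MBP primer set "
                         "(wild + mutant allele-specific primers)")
    eff = resolve_efficiencies(primers, cfg, thermo_cfg, blocker)
    return amplify_trajectory(mix, eff, cfg, rng)


@dataclass
class LoDReport:
    """Per-level detection rates and the resulting limit of detection."""

    levels: list[float]          # mutant fractions, descending, incl. 0
    detections: list[int]
    replicates: int
    rates: list[float]
    blank_false_positives: int
    lod: Optional[float]         # mutant fraction, None when undefined
    flags: list[str]
    seed: int
    detection_rate_threshold: float = 0.95
    calibrated: bool = False


def lod_experiment(bundle, ladder: Sequence[float], replicates: int,
                   seed: int, cfg: Optional[PCRConfig] = None,
                   noise: Optional[NoiseConfig] = None,
                   thermo_cfg: Optional[ThermoConfig] = None,
                   calling: Optional[CallingConfig] = None,
                   grid: Optional[TemperatureGrid] = None,
                   total_copies: float = DEFAULT_TEMPLATE_COPIES,
                   calibration=None) -> LoDReport:
    """Dilution-ladder limit-of-detection experiment.

    For every mutant fraction in ``ladder`` (which must include the 0
    blank) runs ``replicates`` independent PCR -> melt -> somatic-call
    pipelines and scores detections.  LoD is the lowest fraction whose
    detection rate, and that of every higher fraction, reaches 95%,
    provided the blanks produced zero false positives; otherwise the LoD
    is undefined and flagged.  Replicate randomness derives from one
    master seed: child k of ``numpy.random.SeedSequence(seed).spawn``
    drives replicate k of the flattened level x replicate grid.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    ladder = sorted(set(float(x) for x in ladder), reverse=True)
    if 0.0 not in ladder:
        raise ValueError("ladder must include the 0 (blank) level")
    cfg = cfg if cfg is not None else PCRConfig(mode=bundle.mode, stochastic=True)
    noise = noise if noise is not None else NoiseConfig()
    tcfg = thermo_cfg if thermo_cfg is not None else getattr(bundle, "thermo", None) or ThermoConfig()
    calling = calling if calling is not None else CallingConfig()
    grid = grid if grid is not None else TemperatureGrid()
    blocker = getattr(bundle, "blocker", None)
    eff = resolve_efficiencies(bundle.primers, cfg, tcfg, blocker)
    children = np.random.SeedSequence(seed).spawn(len(ladder) * replicates)
    detections: list[int] = []
    for i, level in enumerate(ladder):
        mix = TemplateMix.from_fraction(level, total=total_copies)
        hits = 0
        for r in range(replicates):
            rng = np.random.default_rng(children[i * replicates + r])
            if mix.total > 0:
                amp = amplify_trajectory(mix, eff, cfg, rng)
                pool = amp.final_pool
            else:
                pool = {"wild": 1.0, "mutant": 0.0}
            curve = simulate_melt_curve(bundle.probe, pool, noise=noise,
                                        grid=grid, thermo_cfg=tcfg, rng=rng)
            call = call_sample(curve, bundle, mode="somatic",
                               cfg=calling, calibration=calibration)
            hits += int(call.call == "mutant_detected")
        detections.append(hits)
    rates = [d / replicates for d in detections]
    blank_fp = detections[ladder.index(0.0)]
    flags: list[str] = []
    lod: Optional[float] = None
    if blank_fp > 0:
        flags.append("blank false positives observed: LoD undefined")
    else:
        for level, rate in zip(ladder, rates):
            if level == 0.0:
                continue
            if rate >= 0.95:
                lod = level
            else:
                break
        if lod is None:
            flags.append("no ladder level reached the 95% detection rate")
    return LoDReport(levels=ladder, detections=detections,
                     replicates=replicates, rates=rates,
                     blank_false_positives=blank_fp, lod=lod, flags=flags,
                     seed=seed, calibrated=calibration is not None)
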