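"""Assay design: quenching probes, allele-biased primers, wild-type blockers.

The design rules implemented here are the ones that make the detection
chemistry work:

* the quenching probe carries its fluorophore on a terminal cytosine and
  that cytosine must pair with a guanine on the target, so only windows
  whose (labeled) terminus forms a C:G pair are candidates;
* probes are kept short to widen the Tm gap between perfect match and
  mismatch, but not so short that the mismatch peak falls off the melt
  grid -- candidates are scored by delta-Tm subject to a mismatch-Tm
  floor;
* for mutation-biased PCR the wild and mutant primers both terminate 3'
  on the variant base, the mutant primer is extended at its 5' end so it
  out-competes the wild primer at an annealing temperature set just below
  the mutant primer's Tm;
* amplicons are targeted at ~100 bp for brief, efficient PCR;
* the wild-inhibition blocker is a wild-sequence fragment spanning the
  deletion junction, with enough flank to melt well above the annealing
  temperature so it occupies wild template while PCR anneals.

Coordinates are 0-based against the plus strand; deletions are half-open
intervals; probe and primer sequences are stored 5'->3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from .errors import DesignInfeasibleError
from .genotype import AssayExpectation
from .thermo import (DuplexParams, ThermoConfig, duplex_params_at,
                     reverse_complement)

Allele = Literal["wild", "mutant"]


@dataclass(frozen=True)
class VariantDef:
    """A single-nucleotide variant or deletion on the reference.

    snv: ``position`` (0-based), ``ref_base`` -> ``alt_base``.
    deletion: half-open interval [``start``, ``end``).
    """

    kind: Literal["snv", "deletion"]
    position: Optional[int] = None
    ref_base: Optional[str] = None
    alt_base: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind == "snv":
            if self.position is None or self.ref_base is None or self.alt_base is None:
                raise ValueError("snv requires position, ref_base, alt_base")
            if self.ref_base == self.alt_base:
                raise ValueError("alt_base must differ from ref_base")
        elif self.kind == "deletion":
            if self.start is None or self.end is None or not self.end > self.start:
                raise ValueError("deletion requires end > start")
        else:
            raise ValueError("kind must be 'snv' or 'deletion'")

    @property
    def span(self) -> tuple[int, int]:
        """Half-open reference interval affected by the variant."""
        if self.kind == "snv":
            return (self.position, self.position + 1)
        return (self.start, self.end)

    def apply(self, reference: str) -> str:
        """Mutant sequence obtained by applying the variant to ``reference``."""
        if self.kind == "snv":
            if self.position >= len(reference):
                raise ValueError("variant position outside reference")
            if reference[self.position] != self.ref_base:
                raise ValueError(
                    f"reference base {reference[self.position]!r} at "
                    f"{self.position} does not match declared {self.ref_base!r}")
            return (reference[:self.position] + self.alt_base
                    + reference[self.position + 1:])
        if self.end > len(reference):
            raise ValueError("deletion interval outside reference")
        return reference[:self.start] + reference[self.end:]


@dataclass(frozen=True)
class DesignConfig:
    """Tunable design rules with their committed defaults."""

    probe_length_range: tuple[int, int] = (14, 32)
    tm_mismatch_floor: float = 45.0
    tm_match_ceiling: float = 72.0
    #: junction-spanning deletion probes are long; their match duplex may
    #: melt hotter since no single-mismatch thermodynamics is involved
    tm_match_ceiling_deletion: float = 78.0
    labeled_end_preference: str = "3prime"
    extension_length_delta: int = 4
    anneal_offset: float = 5.0
    primer_length_bounds: tuple[int, int] = (18, 28)
    primer_tm_target: float = 62.0
    amplicon_target: int = 100
    amplicon_tol_frac: float = 0.25
    flank_min: int = 8
    blocker_margin: float = 5.0
    blocker_max_len: int = 40
    probe_tol: float = 2.0
    #: required ratio of the match/mismatch Tm gap to the mean analytic
    #: half-height width of the two melt peaks; below ~1 a heterozygote
    #: melts as a single merged peak
    resolvability_factor: float = 1.2


@dataclass
class ProbeAssay:
    """A designed quenching-probe assay with its melt expectations."""

    probe_seq: str
    labeled_end: Literal["5prime", "3prime"]
    strand: Literal["plus", "minus"]
    probe_matches: Allele
    expectation: AssayExpectation
    duplexes: dict[str, DuplexParams]
    footprint_start: int  # plus-strand start of the probe footprint
    assay_id: str = ""

    def __post_init__(self) -> None:
        end_base = self.probe_seq[-1] if self.labeled_end == "3prime" else self.probe_seq[0]
        if end_base != "C":
            raise ValueError("labeled terminal base of the probe must be C "
                             "(guanine-quenching geometry)")
        if not self.expectation.tm_match > self.expectation.tm_mismatch:
            raise ValueError("tm_match must exceed tm_mismatch")


@dataclass
class PrimerSet:
    """Primers for one assay; allele-specific forwards only in MBP mode."""

    mode: Literal["MBP", "flanking"]
    forward_wild: str
    forward_mutant: str
    reverse: str
    anneal_temp: float
    amplicon_length: int
    amplicon_span: tuple[int, int]
    wild_template: str
    mutant_template: str
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode == "MBP" and "no bias configured" not in self.flags:
            if not len(self.forward_mutant) > len(self.forward_wild):
                raise ValueError("mutant primer must be longer than wild primer")

    @property
    def shared_primer(self) -> str:
        return self.reverse


@dataclass
class BlockerDesign:
    """Wild-matching blocker fragment spanning a deletion junction."""

    blocker_seq: str
    flank_left: int
    flank_right: int
    tm: float
    tm_margin_over_primer: float
    span: tuple[int, int]


def _peak_fwhm(params: DuplexParams) -> float:
    """Analytic half-height width (degC) of a two-state melt peak.

    d(theta)/dT is logistic-shaped with rate kappa = |dH|/(R T^2); its
    full width at half height is 2*ln(3+2*sqrt(2))/kappa ~ 3.53/kappa.
    """
    t_k = params.tm + 273.15 if params.stable else 333.0
    kappa = abs(params.dh) * 1000.0 / (1.987204258640832 * t_k * t_k)
    return 3.53 / kappa


def _resolvable(match: DuplexParams, mm: DuplexParams, factor: float) -> bool:
    """Would a 50/50 mixture of the two duplexes show two melt peaks?"""
    mean_width = 0.5 * (_peak_fwhm(match) + _peak_fwhm(mm))
    return (match.tm - mm.tm) >= factor * mean_width


def _snv_mismatch_duplex(probe: str, other_seq: str, strand: str, a: int,
                         length: int, tcfg: ThermoConfig) -> DuplexParams:
    if strand == "plus":
        return duplex_params_at(probe, other_seq, a, tcfg)
    rc = reverse_complement(other_seq)
    return duplex_params_at(probe, rc, len(other_seq) - a - length, tcfg)


def _deletion_mismatch_duplex(probe: str, strand: str, a: int, length: int,
                              s: int, e: int, mutant_seq: str,
                              tcfg: ThermoConfig) -> Optional[DuplexParams]:
    """Best flank sub-duplex of a junction-spanning probe on the deletion allele.

    On the deletion allele the probe's central bases have no partner; the
    most stable state is the longer flank hybridized contiguously, which
    is what gives the deletion its low-temperature peak.
    """
    fl = s - a            # wild plus-strand bases left of the junction
    fr = a + length - e   # and right of it
    dlen = e - s
    best: Optional[DuplexParams] = None
    cands = []
    if fl >= 6:
        if strand == "plus":   # probe = revcomp(window): left flank = suffix
            cands.append((probe[length - fl:], mutant_seq, a))
        else:                  # probe = window: left flank = prefix
            cands.append((probe[:fl], reverse_complement(mutant_seq),
                          len(mutant_seq) - s))
    if fr >= 6:
        if strand == "plus":   # right flank = prefix, lands at junction
            cands.append((probe[:fr], mutant_seq, s))
        else:
            cands.append((probe[length - fr:], reverse_complement(mutant_seq),
                          len(mutant_seq) - (s + fr)))
    for frag, target, off in cands:
        try:
            p = duplex_params_at(frag, target, off, tcfg)
        except Exception:
            continue
        if p.n_mismatches:
            continue
        if best is None or (p.tm > best.tm if p.stable else False):
            best = p
    return best


def _area_captures(match: DuplexParams, mm: DuplexParams,
                   tcfg: ThermoConfig) -> tuple[float, float]:
    """Window-area capture coefficients of the two pure melt components.

    Each coefficient is the chord-baseline area a pure-allele melt curve
    (noise-free, default grid and smoothing) deposits in its own Tm
    window.  Dividing measured window areas by these normalizes away the
    sharp-vs-broad asymmetry of the two transitions.
    """
    from .genotype import window_chord_area
    from .signal import (NoiseConfig, simulate_melt_curve,
                         smooth_and_differentiate)
    caps = []
    for params in (match, mm):
        curve = simulate_melt_curve({"x": params}, {"x": 1.0},
                                    noise=NoiseConfig.zero(),
                                    thermo_cfg=tcfg)
        dcurve = smooth_and_differentiate(curve)
        caps.append(max(window_chord_area(dcurve, params.tm, 3.0), 1e-6))
    return caps[0], caps[1]


def design_qprobe(reference: str, variant: VariantDef, probe_matches: Allele,
                  thermo_cfg: Optional[ThermoConfig] = None,
                  cfg: Optional[DesignConfig] = None) -> ProbeAssay:
    """Enumerate and score candidate quenching probes; return the best.

    Candidates are windows on either strand, at either labeled end, whose
    labeled terminus is a C pairing a target G and whose footprint covers
    the variant (or spans the deletion junction).  The winner maximizes
    delta-Tm(match - mismatch) subject to the mismatch-Tm floor, with a
    deterministic tie-break: shortest probe, then lowest start
    coordinate, then plus strand, then the preferred labeled end.
    """
    tcfg = thermo_cfg if thermo_cfg is not None else ThermoConfig()
    cfg = cfg if cfg is not None else DesignConfig()
    lmin, lmax = cfg.probe_length_range
    if not (10 <= lmin <= lmax <= 35):
        raise ValueError("probe_length_range must lie within [10, 35]")
    wild_seq = reference
    mutant_seq = variant.apply(reference)
    matched_seq = wild_seq if probe_matches == "wild" else mutant_seq
    other_seq = mutant_seq if probe_matches == "wild" else wild_seq
    if variant.kind == "deletion" and probe_matches == "mutant":
        raise DesignInfeasibleError(
            "deletion assays require a wild-matched probe (the junction "
            "only exists as a contiguous footprint on the wild sequence)")
    s, e = variant.span
    n_ref = len(matched_seq)
    rc_matched = reverse_complement(matched_seq)

    label_order = (["3prime", "5prime"]
                   if cfg.labeled_end_preference == "3prime"
                   else ["5prime", "3prime"])
    no_cg_terminus = True
    candidates = []
    for length in range(lmin, lmax + 1):
        # windows [a, a+length) strictly spanning the variant/junction
        a_lo = max(0, s - length + 1) if variant.kind == "snv" else max(0, e + 1 - length)
        a_hi = min(n_ref - length, s - 1) if variant.kind == "deletion" else min(n_ref - length, s)
        for a in range(a_lo, a_hi + 1):
            window = matched_seq[a:a + length]
            for strand in ("plus", "minus"):
                probe = reverse_complement(window) if strand == "plus" else window
                for label in label_order:
                    end_base = probe[-1] if label == "3prime" else probe[0]
                    if end_base != "C":
                        continue
                    no_cg_terminus = False
                    if strand == "plus":
                        match = duplex_params_at(probe, matched_seq, a, tcfg)
                    else:
                        match = duplex_params_at(probe, rc_matched,
                                                 n_ref - a - length, tcfg)
                    ceiling = (cfg.tm_match_ceiling if variant.kind == "snv"
                               else cfg.tm_match_ceiling_deletion)
                    if not match.stable or match.tm > ceiling:
                        continue
                    if variant.kind == "snv":
                        mm = _snv_mismatch_duplex(probe, other_seq, strand,
                                                  a, length, tcfg)
                    else:
                        mm = _deletion_mismatch_duplex(probe, strand, a, length,
                                                       s, e, other_seq, tcfg)
                    if mm is None or not mm.stable:
                        continue
                    if mm.tm < cfg.tm_mismatch_floor or mm.tm >= match.tm:
                        continue
                    if variant.kind == "snv" and not _resolvable(
                            match, mm, cfg.resolvability_factor):
                        continue
                    candidates.append((-(match.tm - mm.tm), length, a,
                                       0 if strand == "plus" else 1,
                                       label_order.index(label),
                                       probe, strand, label, match, mm))
    if not candidates:
        if no_cg_terminus:
            raise DesignInfeasibleError(
                "no candidate window offers a labeled-C/target-G terminus "
                "around the variant")
        raise DesignInfeasibleError(
            "no candidate probe satisfies the Tm constraints "
            f"(mismatch floor {cfg.tm_mismatch_floor} degC, match ceiling "
            f"{cfg.tm_match_ceiling} degC)")
    candidates.sort(key=lambda c: c[:5])
    _, length, a, _, _, probe, strand, label, match, mm = candidates[0]
    cap_match, cap_mismatch = _area_captures(match, mm, tcfg)
    expectation = AssayExpectation(tm_match=match.tm, tm_mismatch=mm.tm,
                                   probe_matches=probe_matches,
                                   tol=cfg.probe_tol,
                                   area_capture_match=cap_match,
                                   area_capture_mismatch=cap_mismatch)
    duplexes = ({"wild": match, "mutant": mm} if probe_matches == "wild"
                else {"wild": mm, "mutant": match})
    return ProbeAssay(probe_seq=probe, labeled_end=label, strand=strand,
                      probe_matches=probe_matches, expectation=expectation,
                      duplexes=duplexes, footprint_start=a,
                      assay_id=f"qp_{probe_matches}_{strand}_{a}_{length}")


def forward_primer_duplex(primer: str, template: str, end: int,
                          tcfg: ThermoConfig) -> DuplexParams:
    """Duplex of a plus-strand forward primer on its (minus-strand) template.

    ``end`` is the exclusive plus-strand coordinate of the primer 3' end.
    """
    return duplex_params_at(primer, reverse_complement(template),
                            len(template) - end, tcfg)


def _pick_primer(template: str, end: int, bounds: tuple[int, int],
                 tm_target: float, tcfg: ThermoConfig):
    """Forward primer ending (3') at plus-strand position ``end`` - 1."""
    best = None
    for length in range(bounds[0], bounds[1] + 1):
        start = end - length
        if start < 0:
            break
        seq = template[start:end]
        p = forward_primer_duplex(seq, template, end, tcfg)
        if not p.stable:
            continue
        key = (abs(p.tm - tm_target), length)
        if best is None or key < best[0]:
            best = (key, seq, p)
    if best is None:
        raise DesignInfeasibleError("no stable forward primer at the required site")
    return best[1], best[2]


def _pick_reverse(template: str, amp_start: int, amp_target: int,
                  tol: int, bounds: tuple[int, int], tm_target: float,
                  tcfg: ThermoConfig, min_end: int):
    best = None
    for amp_end in range(max(min_end, amp_start + amp_target - tol),
                         min(len(template), amp_start + amp_target + tol) + 1):
        for length in range(bounds[0], bounds[1] + 1):
            if amp_end - length < amp_start:
                continue
            seq = reverse_complement(template[amp_end - length:amp_end])
            p = duplex_params_at(seq, template, amp_end - length, tcfg)
            if not p.stable:
                continue
            key = (abs(amp_end - amp_start - amp_target),
                   abs(p.tm - tm_target), amp_end, length)
            if best is None or key < best[0]:
                best = (key, seq, p, amp_end)
    if best is None:
        raise DesignInfeasibleError(
            f"cannot place a shared reverse primer within +/-{tol} bp of the "
            f"{amp_target} bp amplicon target")
    return best[1], best[2], best[3]


def design_mbp_primers(reference: str, variant: VariantDef,
                       thermo_cfg: Optional[ThermoConfig] = None,
                       cfg: Optional[DesignConfig] = None) -> PrimerSet:
    """Competitive wild/mutant primer pair with a shared reverse primer.

    Both allele-specific primers terminate 3' on the variant base; the
    mutant primer is 5'-extended by ``extension_length_delta`` so it
    melts higher, and annealing is set ``anneal_offset`` degC below the
    mutant primer's Tm -- optimal for the mutant primer, marginal for the
    wild one.
    """
    tcfg = thermo_cfg if thermo_cfg is not None else ThermoConfig()
    cfg = cfg if cfg is not None else DesignConfig()
    if variant.kind != "snv":
        raise ValueError("mutation-biased primers require an snv variant")
    pos = variant.position
    wild_seq = reference
    mutant_seq = variant.apply(reference)
    wild_primer, _ = _pick_primer(wild_seq, pos + 1, cfg.primer_length_bounds,
                                  cfg.primer_tm_target, tcfg)
    lw = len(wild_primer)
    lm = lw + cfg.extension_length_delta
    if pos + 1 - lm < 0:
        raise DesignInfeasibleError("reference too short 5' of the variant "
                                    "for the extended mutant primer")
    mutant_primer = mutant_seq[pos + 1 - lm:pos + 1]
    p_mut = forward_primer_duplex(mutant_primer, mutant_seq, pos + 1, tcfg)
    anneal = p_mut.tm - cfg.anneal_offset
    amp_start = pos + 1 - lm
    tol = int(round(cfg.amplicon_tol_frac * cfg.amplicon_target))
    reverse, _, amp_end = _pick_reverse(
        wild_seq, amp_start, cfg.amplicon_target, tol,
        cfg.primer_length_bounds, cfg.primer_tm_target, tcfg,
        min_end=pos + 1 + cfg.primer_length_bounds[0])
    flags = []
    if cfg.extension_length_delta == 0 and cfg.anneal_offset == 0:
        flags.append("no bias configured")
    return PrimerSet(mode="MBP", forward_wild=wild_primer,
                     forward_mutant=mutant_primer, reverse=reverse,
                     anneal_temp=anneal, amplicon_length=amp_end - amp_start,
                     amplicon_span=(amp_start, amp_end),
                     wild_template=wild_seq, mutant_template=mutant_seq,
                     flags=flags)


def design_flanking_primers(reference: str, variant: VariantDef,
                            thermo_cfg: Optional[ThermoConfig] = None,
                            cfg: Optional[DesignConfig] = None) -> PrimerSet:
    """Allele-neutral primer pair flanking the variant (standard / WIP PCR).

    Primer footprints avoid the variant itself (and, for deletions, leave
    ``flank_min`` bp of clearance for the blocker on the extension path),
    so both alleles amplify with identical efficiency.
    """
    tcfg = thermo_cfg if thermo_cfg is not None else ThermoConfig()
    cfg = cfg if cfg is not None else DesignConfig()
    s, e = variant.span
    fwd_end = s - (cfg.flank_min + 1 if variant.kind == "deletion" else 1)
    if fwd_end < cfg.primer_length_bounds[0]:
        raise DesignInfeasibleError("no room for a forward primer 5' of the variant")
    fwd, p_fwd = _pick_primer(reference, fwd_end, cfg.primer_length_bounds,
                              cfg.primer_tm_target, tcfg)
    amp_start = fwd_end - len(fwd)
    tol = int(round(cfg.amplicon_tol_frac * cfg.amplicon_target))
    min_end = e + (cfg.flank_min if variant.kind == "deletion" else 1) \
        + cfg.primer_length_bounds[0]
    reverse, p_rev, amp_end = _pick_reverse(
        reference, amp_start, cfg.amplicon_target, tol,
        cfg.primer_length_bounds, cfg.primer_tm_target, tcfg, min_end=min_end)
    anneal = min(p_fwd.tm, p_rev.tm) - cfg.anneal_offset
    return PrimerSet(mode="flanking", forward_wild=fwd, forward_mutant=fwd,
                     reverse=reverse, anneal_temp=anneal,
                     amplicon_length=amp_end - amp_start,
                     amplicon_span=(amp_start, amp_end),
                     wild_template=reference,
                     mutant_template=variant.apply(reference))


def design_wip_blocker(reference: str, variant: VariantDef,
                       primer_set: PrimerSet,
                       thermo_cfg: Optional[ThermoConfig] = None,
                       cfg: Optional[DesignConfig] = None) -> BlockerDesign:
    """Wild-sequence blocker spanning the deletion junction.

    Flanks grow symmetrically from ``flank_min`` until the blocker melts
    at least ``blocker_margin`` degC above the annealing temperature, so
    it occupies wild template during annealing; on the deletion allele
    only a flank fragment can pair, which melts far lower.  The blocker
    sits between the primers (extension-path placement).
    """
    tcfg = thermo_cfg if thermo_cfg is not None else ThermoConfig()
    cfg = cfg if cfg is not None else DesignConfig()
    if variant.kind != "deletion":
        raise ValueError("wild-inhibition blockers target deletion variants")
    s, e = variant.span
    if not (0 <= s and e <= len(reference)):
        raise DesignInfeasibleError("deletion interval outside the reference")
    lo_bound, hi_bound = primer_set.amplicon_span
    fl = fr = cfg.flank_min
    grow_left = True
    while True:
        start, end = s - fl, e + fr
        if start < lo_bound or end > hi_bound:
            raise DesignInfeasibleError(
                "blocker would overrun a primer footprint before reaching "
                "the required Tm margin")
        seq = reference[start:end]
        if len(seq) > cfg.blocker_max_len:
            raise DesignInfeasibleError(
                f"Tm margin {cfg.blocker_margin} degC unattainable within "
                f"{cfg.blocker_max_len} nt")
        params = forward_primer_duplex(seq, reference, end, tcfg)
        margin = params.tm - primer_set.anneal_temp
        if params.stable and margin >= cfg.blocker_margin:
            return BlockerDesign(blocker_seq=seq, flank_left=fl, flank_right=fr,
                                 tm=params.tm, tm_margin_over_primer=margin,
                                 span=(start, end))
        if grow_left:
            fl += 1
        else:
            fr += 1
        grow_left = not grow_left
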