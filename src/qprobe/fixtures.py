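"""Seeded synthetic fixtures emulating the platform's assay catalog.

Every fixture is a synthetic reference locus (no real genomic sequence)
named after a catalog entry, with the named variant class embedded at its
center and a full assay designed against it by :mod:`qprobe.design`:
quenching probe, primer set (mutation-biased for point mutations,
allele-neutral flanking plus a wild-type blocker for deletions) and truth
samples.  Regeneration with the same seed is byte-identical.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .design import (BlockerDesign, DesignConfig, PrimerSet, ProbeAssay,
                     VariantDef, design_flanking_primers, design_mbp_primers,
                     design_qprobe, design_wip_blocker)
from .errors import CatalogError, DesignInfeasibleError
from .thermo import ThermoConfig

REFERENCE_LENGTH = 400
_CENTER = REFERENCE_LENGTH // 2


@dataclass(frozen=True)
class LocusSpec:
    kind: str                  # 'snv' | 'deletion'
    ref_base: str = ""
    alt_base: str = ""
    deletion_length: int = 0   # in-frame: multiple of 3
    description: str = ""


#: Synthetic stand-ins for assay catalog entries.  Variant classes match
#: the named mutation; the surrounding sequence is random.
CATALOG: dict[str, LocusSpec] = {
    "EGFR_T790M": LocusSpec("snv", "C", "T",
                            description="EGFR exon 20 c.2369C>T (T790M), synthetic locus"),
    "EGFR_ex19del": LocusSpec("deletion", deletion_length=15,
                              description="EGFR exon 19 in-frame deletion (15 nt), synthetic locus"),
    "JAK2_V617F": LocusSpec("snv", "G", "T",
                            description="JAK2 c.1849G>T (V617F), synthetic locus"),
    "KRAS_G12D": LocusSpec("snv", "G", "A",
                           description="KRAS codon 12 c.35G>A (G12D), synthetic locus"),
    "BRAF_V600E": LocusSpec("snv", "T", "A",
                            description="BRAF c.1799T>A (V600E), synthetic locus"),
}


@dataclass
class AssayBundle:
    """Everything needed to simulate and call one assay."""

    probe: ProbeAssay
    primers: PrimerSet
    blocker: Optional[BlockerDesign]
    mode: str                   # default PCR mode: MBP | WIP | standard
    thermo: ThermoConfig

    @property
    def expectation(self):
        return self.probe.expectation

    @property
    def duplexes(self):
        return self.probe.duplexes


@dataclass
class FixtureBundle:
    locus_name: str
    reference: str
    reference_id: str
    variant: VariantDef
    assay: AssayBundle
    truth: list[dict]
    seed: int
    attempts: int = 1


def _random_sequence(rng: np.random.Generator, length: int,
                     gc: float = 0.5) -> str:
    p_gc, p_at = gc / 2.0, (1.0 - gc) / 2.0
    return "".join(rng.choice(np.array(list("ACGT")),
                              size=length,
                              p=[p_at, p_gc, p_gc, p_at]))


def _truth_samples(kind: str) -> list[dict]:
    germline = [
        {"sample_id": "g_wild", "mode": "germline",
         "pool": {"wild": 1.0, "mutant": 0.0}, "genotype": "wild_hom"},
        {"sample_id": "g_het", "mode": "germline",
         "pool": {"wild": 0.5, "mutant": 0.5}, "genotype": "heterozygous"},
        {"sample_id": "g_mut", "mode": "germline",
         "pool": {"wild": 0.0, "mutant": 1.0}, "genotype": "mutant_hom"},
    ]
    somatic = [
        {"sample_id": "s_blank", "mode": "somatic", "mutant_fraction": 0.0,
         "genotype": "wild_only"},
        {"sample_id": "s_1pct", "mode": "somatic", "mutant_fraction": 0.01,
         "genotype": "mutant_detected"},
        {"sample_id": "s_10pct", "mode": "somatic", "mutant_fraction": 0.10,
         "genotype": "mutant_detected"},
    ]
    return germline + somatic


def generate_fixture(locus_name: str, seed: int,
                     thermo_cfg: Optional[ThermoConfig] = None,
                     design_cfg: Optional[DesignConfig] = None,
                     max_attempts: int = 25) -> FixtureBundle:
    """Deterministically generate the named fixture.

    Draws a random reference, embeds the variant class of the catalog
    entry at the center and designs the assay; references for which the
    design is infeasible (e.g. no labeled-C terminus in reach) are
    redrawn from the same seeded stream, so the result is still a pure
    function of (locus_name, seed).
    """
    if locus_name not in CATALOG:
        raise CatalogError(
            f"unknown locus {locus_name!r}; valid ids: {sorted(CATALOG)}")
    spec = CATALOG[locus_name]
    tcfg = thermo_cfg if thermo_cfg is not None else ThermoConfig()
    dcfg = design_cfg if design_cfg is not None else DesignConfig()
    ss = np.random.SeedSequence([abs(int(seed)) % (2 ** 63),
                                 zlib.crc32(locus_name.encode())])
    rng = np.random.default_rng(ss)
    last_err: Exception | None = None
    for attempt in range(1, max_attempts + 1):
        ref = _random_sequence(rng, REFERENCE_LENGTH)
        if spec.kind == "snv":
            pos = _CENTER
            ref = ref[:pos] + spec.ref_base + ref[pos + 1:]
            variant = VariantDef(kind="snv", position=pos,
                                 ref_base=spec.ref_base, alt_base=spec.alt_base)
            probe_matches = "mutant"
        else:
            s = _CENTER
            e = s + spec.deletion_length
            # GC-rich patch on the left flank keeps the junction probe's
            # partial duplex (the deletion allele's peak) on the melt grid
            patch = _random_sequence(rng, 14, gc=0.75)
            ref = ref[:s - 14] + patch + ref[s:]
            variant = VariantDef(kind="deletion", start=s, end=e)
            probe_matches = "wild"
        try:
            probe = design_qprobe(ref, variant, probe_matches, tcfg, dcfg)
            if spec.kind == "snv":
                primers = design_mbp_primers(ref, variant, tcfg, dcfg)
                blocker = None
                mode = "MBP"
            else:
                primers = design_flanking_primers(ref, variant, tcfg, dcfg)
                blocker = design_wip_blocker(ref, variant, primers, tcfg, dcfg)
                mode = "WIP"
        except DesignInfeasibleError as err:
            last_err = err
            continue
        assay = AssayBundle(probe=probe, primers=primers, blocker=blocker,
                            mode=mode, thermo=tcfg)
        return FixtureBundle(locus_name=locus_name, reference=ref,
                             reference_id=f"{locus_name}_synthetic",
                             variant=variant, assay=assay,
                             truth=_truth_samples(spec.kind), seed=seed,
                             attempts=attempt)
    raise DesignInfeasibleError(
        f"no designable reference for {locus_name} in {max_attempts} draws "
        f"(last error: {last_err})")
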