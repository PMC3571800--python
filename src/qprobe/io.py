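"""File formats and configuration: melt-curve CSV, assay JSON, run config.

Formats are deliberately diff-friendly: JSON for configurations and assay
bundles, CSV for melt curves (header ``temperature_C,<sample_id>,...``),
TSV for calls and LoD reports.  Every serialized artifact carries the
package version and a configuration hash so deterministic runs can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .amplify import LoDReport, PCRConfig
from .design import BlockerDesign, DesignConfig, PrimerSet, ProbeAssay, VariantDef
from .errors import ParseError
from .fixtures import AssayBundle
from .genotype import AssayExpectation, CallingConfig, GenotypeCall
from .signal import MeltCurve, NoiseConfig
from .thermo import DuplexParams, ThermoConfig

log = logging.getLogger("qprobe")


# ---------------------------------------------------------------------------
# melt-curve CSV

def write_melt_csv(curves: Sequence[MeltCurve], path) -> None:
    """Write curves sharing one temperature grid to a single CSV."""
    if not curves:
        raise ValueError("no curves to write")
    t0 = curves[0].temperatures
    for c in curves[1:]:
        if len(c.temperatures) != len(t0) or np.any(np.abs(c.temperatures - t0) > 1e-9):
            raise ValueError("all curves in one CSV must share the temperature grid")
    data = {"temperature_C": t0}
    for i, c in enumerate(curves):
        sid = str(c.meta.get("sample_id", f"sample_{i + 1}"))
        data[sid] = c.fluorescence
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def read_melt_csv(path) -> list[MeltCurve]:
    """Read a melt-curve CSV back into one curve per sample column.

    Non-monotone temperature columns and ragged rows are parse errors
    that name the offending line (1-based, header = line 1); a
    header-only file yields an empty list with a logged warning.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if "temperature_C" not in df.columns:
        raise ParseError(f"{path}: line 1: header must start with 'temperature_C'")
    if df.empty:
        log.warning("%s: header-only melt CSV, no curves", path)
        return []
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ParseError(f"{path}: line {row + 2}: ragged or non-numeric row")
    t = df["temperature_C"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise ParseError(f"{path}: line {int(bad[0]) + 3}: temperature not "
                         "strictly increasing")
    curves = []
    for col in df.columns:
        if col == "temperature_C":
            continue
        curves.append(MeltCurve(temperatures=t,
                                fluorescence=df[col].to_numpy(float),
                                meta={"sample_id": col, "source": str(path)}))
    return curves


# ---------------------------------------------------------------------------
# run configuration

@dataclasses.dataclass
class RunConfig:
    """All tunable parameters of a run, version-stamped."""

    thermo: ThermoConfig = dataclasses.field(default_factory=ThermoConfig)
    noise: NoiseConfig = dataclasses.field(default_factory=NoiseConfig)
    pcr: PCRConfig = dataclasses.field(default_factory=PCRConfig)
    calling: CallingConfig = dataclasses.field(default_factory=CallingConfig)
    design: DesignConfig = dataclasses.field(default_factory=DesignConfig)
    version: str = __version__

    def to_dict(self) -> dict:
        d = {name: dataclasses.asdict(getattr(self, name))
             for name in ("thermo", "noise", "pcr", "calling", "design")}
        d["version"] = self.version
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub):
            sub = dict(sub)
            for k, v in sub.items():
                if isinstance(v, list):
                    sub[k] = tuple(v)
            return klass(**sub)
        return cls(thermo=build(ThermoConfig, d["thermo"]),
                   noise=build(NoiseConfig, d["noise"]),
                   pcr=build(PCRConfig, d["pcr"]),
                   calling=build(CallingConfig, d["calling"]),
                   design=build(DesignConfig, d["design"]),
                   version=d.get("version", __version__))

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def write_run_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2, sort_keys=True) + "\n")


def read_run_config(path) -> RunConfig:
    return RunConfig.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# assay bundle JSON

def _duplex_to_dict(p: DuplexParams) -> dict:
    d = dataclasses.asdict(p)
    d["mismatch_positions"] = list(p.mismatch_positions)
    return d


def _duplex_from_dict(d: dict) -> DuplexParams:
    d = dict(d)
    d["mismatch_positions"] = tuple(d["mismatch_positions"])
    return DuplexParams(**d)


def write_assay_json(bundle: AssayBundle, path,
                     reference: Optional[str] = None,
                     variant: Optional[VariantDef] = None,
                     extra_meta: Optional[dict] = None) -> None:
    probe = bundle.probe
    doc = {
        "format": "qprobe-assay",
        "version": __version__,
        "mode": bundle.mode,
        "thermo": dataclasses.asdict(bundle.thermo),
        "probe": {
            "probe_seq": probe.probe_seq,
            "labeled_end": probe.labeled_end,
            "strand": probe.strand,
            "probe_matches": probe.probe_matches,
            "footprint_start": probe.footprint_start,
            "assay_id": probe.assay_id,
            "expectation": dataclasses.asdict(probe.expectation),
            "duplexes": {a: _duplex_to_dict(p) for a, p in probe.duplexes.items()},
        },
        "primers": dataclasses.asdict(bundle.primers),
        "blocker": dataclasses.asdict(bundle.blocker) if bundle.blocker else None,
    }
    if reference is not None:
        doc["reference"] = reference
    if variant is not None:
        doc["variant"] = dataclasses.asdict(variant)
    if extra_meta:
        doc["meta"] = extra_meta
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_assay_json(path) -> AssayBundle:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "qprobe-assay":
        raise ParseError(f"{path}: not a qprobe assay bundle")
    p = doc["probe"]
    expectation = AssayExpectation(**p["expectation"])
    probe = ProbeAssay(
        probe_seq=p["probe_seq"], labeled_end=p["labeled_end"],
        strand=p["strand"], probe_matches=p["probe_matches"],
        expectation=expectation,
        duplexes={a: _duplex_from_dict(d) for a, d in p["duplexes"].items()},
        footprint_start=p["footprint_start"], assay_id=p["assay_id"])
    pr = dict(doc["primers"])
    pr["amplicon_span"] = tuple(pr["amplicon_span"])
    primers = PrimerSet(**pr)
    blocker = None
    if doc.get("blocker"):
        b = dict(doc["blocker"])
        b["span"] = tuple(b["span"])
        blocker = BlockerDesign(**b)
    thermo = ThermoConfig(**doc["thermo"])
    return AssayBundle(probe=probe, primers=primers, blocker=blocker,
                       mode=doc["mode"], thermo=thermo)


def load_variant(doc_or_path) -> VariantDef:
    doc = doc_or_path
    if not isinstance(doc, dict):
        doc = json.loads(Path(doc_or_path).read_text())
    return VariantDef(**doc["variant"])


# ---------------------------------------------------------------------------
# calls / LoD reports

def write_calls_tsv(calls: Sequence[tuple[str, str, GenotypeCall]], path) -> None:
    """Write calls as TSV rows of (sample_id, assay_id, call record)."""
    rows = []
    for sample_id, assay_id, call in calls:
        rows.append({
            "sample_id": sample_id,
            "assay_id": assay_id,
            "call": call.call,
            "tm_peaks": ";".join(f"{p.tm:.2f}" for p in call.peaks_used),
            "mutant_fraction_estimate": (
                "" if call.mutant_fraction_estimate is None
                else f"{call.mutant_fraction_estimate:.4f}"),
            "confidence": f"{call.confidence:.3f}",
            "reason": call.reason or "",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_lod_report(report: LoDReport, tsv_path, json_path,
                     config_hash: str = "") -> None:
    pd.DataFrame({
        "level": report.levels,
        "replicates": [report.replicates] * len(report.levels),
        "detections": report.detections,
        "rate": report.rates,
    }).to_csv(tsv_path, sep="\t", index=False)
    summary = {
        "lod": report.lod,
        "lod_percent": None if report.lod is None else 100.0 * report.lod,
        "calibrated": report.calibrated,
        "seed": report.seed,
        "blank_false_positives": report.blank_false_positives,
        "flags": report.flags,
        "version": __version__,
        "config_hash": config_hash,
    }
    Path(json_path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence) pairs."""
    from Bio import SeqIO
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: Sequence[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
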