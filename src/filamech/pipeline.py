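"""Batch analysis: dispatch traces by protocol and aggregate a cohort report."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import kinetics, wlc
from .binding import binomial_error
from .config import RunConfig
from .trace import TimeTrace, read_trace


@dataclass
class CohortReport:
    """Per-trace results plus cohort aggregates and provenance.

    Aggregate counts always equal the sum of per-trace outcomes, including
    excluded, failed and unclassified traces.
    """

    per_trace: list[dict] = field(default_factory=list)
    aggregates: dict = field(default_factory=dict)
    manifest: list[dict] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_trace": self.per_trace,
            "aggregates": self.aggregates,
            "manifest": self.manifest,
            "provenance": self.provenance,
        }


def read_manifest(path: str | Path) -> list[dict]:
    """Manifest TSV with at least `path` and `protocol` columns."""
    df = pd.read_csv(path, sep="\t")
    for col in ("path", "protocol"):
        if col not in df.columns:
            raise ValueError(f"manifest lacks required column {col!r}")
    base = Path(path).parent
    rows = df.to_dict("records")
    for row in rows:
        row["path"] = str((base / row["path"]).resolve())
    return rows


def analyze_assembly(trace: TimeTrace, config: RunConfig) -> dict:
    """Full kinetic readout of one constant-force assembly/compaction trace."""
    windows = config.windows
    out: dict = {}
    out["t_nucl_s"] = kinetics.detect_nucleation(trace, windows)
    regions = kinetics.propose_regions(trace, windows)
    flush = trace.metadata.get("flush_start_s", 0.0)
    _, baseline_sd = kinetics.baseline_stats(trace, flush) if flush else (0.0, None)
    if regions["formation"] is not None:
        out["formation_rate_nm_s"] = kinetics.formation_rate(
            trace, regions["formation"], windows, baseline_sd=baseline_sd)
    else:
        out["formation_rate_nm_s"] = None
    if regions["compaction"] is not None:
        out["compaction_rate_nm_s"] = kinetics.compaction_rate(
            trace, regions["compaction"], windows)
        if baseline_sd:
            out["ruptures"] = kinetics.detect_ruptures(
                trace.slice_time(*regions["compaction"]), baseline_sd, windows)
    else:
        out["compaction_rate_nm_s"] = None
    bare = trace.metadata.get("bare_extension_nm")
    if bare is None and flush:
        bare, _ = kinetics.baseline_stats(trace, flush, filtered=True)
    if bare is not None:
        out["class_label"] = kinetics.classify_trace(
            trace, bare, floor_frac=config.classify_floor_frac, windows=windows)
    return out


def analyze_ramp(trace: TimeTrace, config: RunConfig) -> dict:
    curve = wlc.ForceExtensionCurve(trace.extension, trace.force)
    fit = wlc.fit_wlc_integrated(curve, kbt=config.kbt)
    ruptures = wlc.extract_rupture_forces(curve, config.wlc_jump_threshold)
    return {
        "lp_nm": fit.lp,
        "lc_nm": fit.lc,
        "accepted": fit.accepted,
        "residual_norm": fit.residual_norm,
        "rupture_forces_pN": ruptures,
    }


def analyze_rotation(trace: TimeTrace, config: RunConfig) -> dict:
    coilable, pos, neg = kinetics.coilability_check(
        trace, slope_sigma=config.coilable_slope_sigma)
    return {"coilable": coilable, "pos_slope_nm_per_turn": pos,
            "neg_slope_nm_per_turn": neg}


_DISPATCH = {
    "assembly": analyze_assembly,
    "compaction": analyze_assembly,
    "ramp": analyze_ramp,
    "rotation": analyze_rotation,
}


def run_pipeline(manifest: list[dict], config: RunConfig | None = None
                 ) -> CohortReport:
    """Analyze every manifest entry; per-trace failures never abort the cohort."""
    config = config or RunConfig()
    report = CohortReport(manifest=list(manifest), provenance=config.stamp())
    for entry in manifest:
        row = {"path": entry.get("path"), "protocol": entry.get("protocol")}
        try:
            trace = (entry["trace"] if "trace" in entry
                     else read_trace(entry["path"]))
            handler = _DISPATCH.get(entry["protocol"])
            if handler is None:
                raise ValueError(f"unknown protocol {entry['protocol']!r}")
            row.update(handler(trace, config))
            row["error"] = None
        except Exception as exc:  # noqa: BLE001 - isolation is the contract
            row["error"] = f"{type(exc).__name__}: {exc}"
        report.per_trace.append(row)
    report.aggregates = _aggregate(report.per_trace)
    return report


def _mean_sd(values: list) -> dict:
    vals = [v for v in values if v is not None]
    return {
        "n": len(vals),
        "n_excluded": len(values) - len(vals),
        "mean": float(np.mean(vals)) if vals else None,
        "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
    }


def _aggregate(rows: list[dict]) -> dict:
    agg: dict = {"n_traces": len(rows),
                 "n_failed": sum(1 for r in rows if r.get("error"))}
    kin = [r for r in rows if r["protocol"] in ("assembly", "compaction")
           and not r.get("error")]
    if kin:
        waits = [r.get("t_nucl_s") for r in kin]
        agg["t_nucl_s"] = _mean_sd(waits)
        detected = [w for w in waits if w is not None]
        agg["k_nucl_per_s"] = (1.0 / float(np.mean(detected))
                               if detected else None)
        agg["formation_rate_nm_s"] = _mean_sd(
            [r.get("formation_rate_nm_s") for r in kin])
        agg["compaction_rate_nm_s"] = _mean_sd(
            [r.get("compaction_rate_nm_s") for r in kin])
        labels = [r.get("class_label") for r in kin if r.get("class_label")]
        if labels:
            n_all = len(labels)
            fractions = {}
            for lab in kinetics.CLASS_LABELS:
                fe = binomial_error(labels.count(lab), n_all)
                fractions[lab] = {"count": fe.n_i, "fraction": fe.f_rel,
                                  "sigma": fe.delta_f}
            agg["class_fractions"] = fractions
    ramps = [r for r in rows if r["protocol"] == "ramp" and not r.get("error")]
    if ramps:
        acc = [r for r in ramps if r.get("accepted")]
        agg["wlc"] = {
            "n_accepted": len(acc),
            "n_rejected": len(ramps) - len(acc),
            "lp_nm": _mean_sd([r["lp_nm"] for r in acc]),
            "lc_nm": _mean_sd([r["lc_nm"] for r in acc]),
        }
        forces = [f for r in ramps for f in r.get("rupture_forces_pN", [])]
        if forces:
            agg["rupture_force_pN"] = _mean_sd(forces)
    return agg
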