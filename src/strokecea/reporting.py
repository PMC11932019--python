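"""Tabular outputs and run manifests.

Everything the pipeline produces is written as plain CSV/JSON: per-cycle
traces, Table-2-style comparison blocks, tornado tables, PSA draw tables and
acceptability curves. Each command also writes a run manifest (command,
configuration hash, seed, software version, output list) so deterministic
runs can be reproduced bit-exactly.

Internal computation is kept at full precision; the human-readable summary
rounds to whole CNY and two-decimal QALYs/life-years.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .dsa import TornadoRow
from .markov import ArmResult, CEResult, CycleTrace
from .params import ParameterSet
from .psa import CEACCurve, PSAResult

__all__ = [
    "RunManifest",
    "config_hash",
    "ce_result_frame",
    "write_ce_result",
    "write_trace",
    "write_tornado",
    "write_psa",
    "format_summary",
]


def config_hash(params: ParameterSet) -> str:
    """Stable hash of the fully resolved parameter set."""
    payload = json.dumps(params.to_flat(), sort_keys=True, default=float)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int | None
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    version: str = __version__
    outputs: list[str] = field(default_factory=list)

    def add(self, path: Path) -> Path:
        self.outputs.append(str(path))
        return path

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=2) + "\n")
        return path


def _round(x: float | None, ndigits: int) -> float | None:
    return None if x is None else round(x, ndigits)


def ce_result_frame(result: CEResult) -> pd.DataFrame:
    """Comparison block: one row per arm plus the increments."""

    def arm_row(arm: ArmResult) -> dict:
        return {
            "total_cost_cny": arm.total_cost,
            "total_qaly": arm.total_qaly,
            "total_ly": arm.total_ly,
            "total_ly_undiscounted": arm.total_ly_undisc,
        }

    rows = {
        "standard": arm_row(result.standard),
        "tenecteplase": arm_row(result.tenecteplase),
    }
    rows["increment"] = {
        "total_cost_cny": result.delta_cost,
        "total_qaly": result.delta_qaly,
        "total_ly": result.delta_ly,
        "total_ly_undiscounted": (result.tenecteplase.total_ly_undisc
                                  - result.standard.total_ly_undisc),
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def format_summary(result: CEResult) -> str:
    """Rounded human-readable block (whole CNY, 2-decimal QALY/LY)."""
    lines = []
    for name, arm in (("Standard treatment", result.standard),
                      ("Tenecteplase", result.tenecteplase)):
        lines.append(
            f"{name:<20} cost {arm.total_cost:>10,.0f} CNY   "
            f"QALY {arm.total_qaly:5.2f}   LY {arm.total_ly:5.2f}"
        )
    lines.append(
        f"{'Increment':<20} cost {result.delta_cost:>10,.0f} CNY   "
        f"QALY {result.delta_qaly:5.2f}   LY {result.delta_ly:5.2f}"
    )
    icer = "undefined" if result.icer is None else f"{result.icer:,.0f} CNY/QALY"
    lines.append(f"ICER: {icer}   [{result.classification}]")
    return "\n".join(lines)


def write_ce_result(result: CEResult, out_dir: Path, stem: str,
                    manifest: RunManifest | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = ce_result_frame(result)
    csv_path = out_dir / f"{stem}.csv"
    frame.to_csv(csv_path, index_label="arm")
    json_path = out_dir / f"{stem}.json"
    json_path.write_text(json.dumps(result.summary(), indent=2, default=float) + "\n")
    if manifest is not None:
        manifest.add(csv_path)
        manifest.add(json_path)
    return csv_path


def write_trace(trace: CycleTrace, path: Path,
                manifest: RunManifest | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    occ = {f"occ_mrs{i}": trace.occupancy[:, i] for i in range(7)}
    pd.DataFrame({
        "cycle": trace.cycle, "age": trace.age, **occ,
        "cost": trace.cost, "cost_disc": trace.cost_disc,
        "qaly": trace.qaly, "qaly_disc": trace.qaly_disc,
        "ly": trace.ly, "ly_disc": trace.ly_disc,
    }).to_csv(path, index=False)
    if manifest is not None:
        manifest.add(path)
    return path


def write_tornado(rows: Sequence[TornadoRow], path: Path,
                  manifest: RunManifest | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame([{
        "parameter": r.parameter, "low": r.low, "high": r.high,
        "icer_low": r.icer_low, "icer_high": r.icer_high,
        "classification_low": r.classification_low,
        "classification_high": r.classification_high,
        "span": r.span, "dominance_flagged": r.dominance_flagged,
    } for r in rows]).to_csv(path, index=False)
    if manifest is not None:
        manifest.add(path)
    return path


def write_psa(psa: PSAResult, curve: CEACCurve, out_dir: Path,
              manifest: RunManifest | None = None) -> list[Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    draws_path = out_dir / "psa_draws.csv"
    psa.to_frame().to_csv(draws_path, index_label="draw")
    paths.append(draws_path)
    ceac_path = out_dir / "ceac.csv"
    curve.to_frame().to_csv(ceac_path, index=False)
    paths.append(ceac_path)
    summary = {
        "n_draws": psa.n_draws,
        "seed": psa.seed,
        "wtp_threshold": psa.wtp_threshold,
        "quadrant_fractions": psa.quadrant_fractions(),
        "classification_fractions": psa.classification_fractions(),
        "fraction_below_wtp": psa.fraction_below_wtp(),
        "ceac_crossover": curve.crossover,
        "median_icer": float(np.nanmedian(psa.icer)),
    }
    summary_path = out_dir / "psa_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    paths.append(summary_path)
    if manifest is not None:
        for p in paths:
            manifest.add(p)
    return paths
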