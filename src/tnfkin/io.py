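"""Trace CSV dialect, titration tables, run configuration and JSON reports.

On-disk units are SI throughout (seconds, mol/L); the report layer converts
to conventional display units (k_on in 1e6 M^-1 s^-1, k_off in 1e-5 s^-1,
K_D in pM) so that pM/nM ambiguity never enters a computation.

Trace files are delimited text with a header row and columns ``time_s,
signal, phase, conc_M, replicate_id[, scavenger]``; one trace per
(phase, conc_M, replicate_id, scavenger) group, time relative to phase
start.  Unknown columns are preserved through a read/write round trip.
Reports are versioned JSON including the seed, a config echo and input-file
checksums, so every report can be regenerated from what it names.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .errors import DataError, SchemaError
from .models import KineticFit, Phase, Trace

__all__ = [
    "REPORT_SCHEMA_VERSION",
    "RunConfig",
    "read_traces",
    "write_traces",
    "read_titration",
    "write_report",
    "read_report",
    "kinetics_display_units",
]

REPORT_SCHEMA_VERSION = "1"

_MANDATORY = ("time_s", "signal", "phase", "conc_M", "replicate_id")


class RunConfig(BaseModel):
    """Validated run configuration with explicit defaults.

    All thresholds that the analyses draw narratively (class boundaries,
    detection limits, model-selection level) live here so a report echoes
    exactly the lines it was drawn with.
    """

    seed: int = 1
    sigma: float = Field(0.01, ge=0, description="additive noise sd, signal units")
    concs_M: list[float] = Field(
        default_factory=lambda: [1e-9, 2e-9, 4e-9, 8e-9],
        description="analyte concentration series",
    )
    assoc_T: float = 260.0
    dissoc_T: float = 18_000.0
    mono_T: float = 2000.0
    panel_T: float = 4200.0
    dt_mono: float = 2.0
    dt_assoc: float = 1.0
    dt_dissoc: float = 6.0
    dt_panel: float = 10.0
    model_alpha: float = Field(0.05, gt=0, lt=1)
    detection_noise_factor: float = Field(
        5.0, description="amplitude below this multiple of noise sd → no decay"
    )
    strong_max_ratio: float = Field(
        0.054, description="k_mono/k_free below this → strong stabilization"
    )
    moderate_max_ratio: float = Field(
        0.20, description="k_mono/k_free below this → moderate stabilization"
    )
    residual_offset_ratio: float = Field(
        0.1, description="dissociation offset/amplitude above this → residual complex"
    )
    bound_ratio: float = Field(
        0.1, description="fitted kd below this fraction of rt → bound-only result"
    )
    n_boot: int = Field(1000, gt=0)
    molar_mass_g_mol: float = 17_500.0


# ---------------------------------------------------------------------------
# traces

def read_traces(path: str | Path) -> list[Trace]:
    """Read the trace CSV dialect into grouped, time-sorted traces.

    Raises :class:`SchemaError` for a missing mandatory column and
    :class:`DataError` (with line diagnostics) for malformed values.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    if "scavenger" not in df.columns:
        df["scavenger"] = None

    bad = df.index[df["conc_M"] < 0]
    if len(bad):
        lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
        raise DataError(f"{path}: negative conc_M at line(s) {lines}")
    try:
        phases = df["phase"].map(Phase)
    except ValueError as exc:
        raise DataError(f"{path}: unknown phase label ({exc})") from exc
    df = df.assign(phase=phases)

    extra_cols = [c for c in df.columns if c not in _MANDATORY + ("scavenger",)]
    traces: list[Trace] = []
    keys = ["phase", "conc_M", "replicate_id", "scavenger"]
    for (phase, conc, rid, scav), grp in df.groupby(keys, dropna=False, sort=False):
        grp = grp.sort_values("time_s")
        t = grp["time_s"].to_numpy(dtype=float)
        if np.any(np.diff(t) <= 0):
            raise DataError(
                f"{path}: duplicate/non-monotone time_s in trace "
                f"({phase.value}, {conc}, {rid})"
            )
        traces.append(
            Trace(
                t=t,
                y=grp["signal"].to_numpy(dtype=float),
                phase=phase,
                conc=float(conc),
                replicate_id=str(rid),
                scavenger=None if pd.isna(scav) else str(scav),
                extra={c: grp[c].to_numpy() for c in extra_cols},
            )
        )
    return traces


def write_traces(traces: Iterable[Trace], path: str | Path) -> None:
    """Write traces in the CSV dialect (inverse of :func:`read_traces`)."""
    frames = []
    for tr in traces:
        d = {
            "time_s": tr.t,
            "signal": tr.y,
            "phase": tr.phase.value,
            "conc_M": tr.conc,
            "replicate_id": tr.replicate_id,
            "scavenger": tr.scavenger,
        }
        d.update(tr.extra)
        frames.append(pd.DataFrame(d))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_titration(path: str | Path) -> pd.DataFrame:
    """Read a titration table (columns ``conc_M``, ``response``)."""
    df = pd.read_csv(path)
    for col in ("conc_M", "response"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    if (df["conc_M"] < 0).any():
        raise DataError(f"{path}: negative titrant concentration")
    return df[["conc_M", "response"] + [c for c in df.columns
                                        if c not in ("conc_M", "response")]]


# ---------------------------------------------------------------------------
# reports

def _jsonable(obj: Any) -> Any:
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, BaseModel):
        return _jsonable(obj.model_dump())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if isinstance(obj, Phase):
        return obj.value
    return obj


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_report(
    results: Any,
    path: str | Path,
    config: Optional[RunConfig] = None,
    inputs: Sequence[str | Path] = (),
    seed: Optional[int] = None,
) -> dict:
    """Write a versioned JSON report with full provenance.

    The report embeds the schema version, the seed, a config echo, and
    SHA-256 checksums of the input files it was computed from.  Rereading
    reproduces all numbers bit-exactly (floats round-trip via JSON repr).
    """
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": seed if seed is not None else (config.seed if config else None),
        "config": _jsonable(config) if config is not None else None,
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        "results": _jsonable(results),
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc


def read_report(path: str | Path) -> dict:
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise SchemaError(f"{path}: unsupported report schema version")
    return doc


def kinetics_display_units(fit: KineticFit) -> dict:
    """Convert a kinetic fit to conventional display units.

    k_on in 1e6 M^-1 s^-1, k_off in 1e-5 s^-1, K_D in pM — the layout used
    in kinetic-constant tables.
    """
    return {
        "k_on_1e6_per_M_s": fit.k_on / 1e6,
        "se_k_on_1e6_per_M_s": fit.se_k_on / 1e6,
        "k_off_1e-5_per_s": fit.k_off / 1e-5,
        "se_k_off_1e-5_per_s": fit.se_k_off / 1e-5,
        "kd_pM": fit.kd / 1e-12,
        "se_kd_pM": fit.se_kd / 1e-12,
    }
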