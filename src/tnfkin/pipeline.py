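"""Orchestrated workflows: monomerization, binding kinetics, titration, panel.

Each workflow chains normalization, fitting and classification into a
report-shaped result object.  Outputs are pure functions of (inputs, config,
seed); rerunning reproduces a report bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, FitError, FlatTraceError
from .fitting import (
    AssociationFit,
    DissociationFit,
    ExpFit,
    GlobalFitSpec,
    TitrationResult,
    fit_biexp_global,
    fit_monomerization,
    fit_titration,
    global_fit_association,
    global_fit_dissociation,
    kinetics_report,
    select_decay_model,
)
from .io import RunConfig
from .models import KineticFit, Phase, SizeRefs, Trace, mono_exp
from .sizing import MEASURED_REFS, compare_to_reference, trimer_fraction

__all__ = [
    "MonomerizationReport",
    "KineticsReport",
    "PanelRow",
    "StabilizationPanel",
    "run_monomerization",
    "run_kinetics",
    "run_titration",
    "run_stabilization_panel",
]


@dataclass(frozen=True)
class MonomerizationReport:
    """Replicate-averaged trimer-decay rate and size interpretation."""

    k_mean: Optional[float]  # s^-1; None when nothing decays
    k_sem: Optional[float]
    n_used: int
    per_replicate: tuple  # ExpFit per successful replicate
    excluded: tuple  # (replicate_id, reason)
    verdict: str  # "monomerization" | "no monomerization"
    dh_start_nm: Optional[float] = None
    dh_end_nm: Optional[float] = None
    start_state: Optional[str] = None
    end_state: Optional[str] = None
    fraction_trajectory: Optional[tuple] = None  # (t, trimer fraction)


@dataclass(frozen=True)
class KineticsReport:
    """Rate constants for one assay orientation, with decay-shape routing."""

    fit: KineticFit
    route: str  # "mono" | "bi"
    k_fast: Optional[float] = None  # only on the biphasic route
    residual_complex: bool = False  # dissociation did not reach baseline
    ambiguous_model: bool = False


@dataclass(frozen=True)
class PanelRow:
    label: str
    k_mono: Optional[float]  # None → below detection
    se_k: Optional[float]
    suppression_factor: Optional[float]  # k_free / k_mono; None when full
    below_detection: bool
    klass: str  # full_suppression | strong | moderate | weak


@dataclass(frozen=True)
class StabilizationPanel:
    rows: tuple  # PanelRow, ordered by increasing k_mono
    k_free: float


# ---------------------------------------------------------------------------

def run_monomerization(
    traces: Sequence[Trace],
    config: RunConfig = RunConfig(),
    dh_start: Optional[float] = None,
    dh_end: Optional[float] = None,
    refs: SizeRefs = MEASURED_REFS,
) -> MonomerizationReport:
    """Fit replicate monomerization traces and summarize the transition.

    Each replicate is fitted independently with a single exponential; the
    summary reports mean ± SEM of the rate over the replicates that
    converged, excluding failures with a logged reason.  Optional start/end
    hydrodynamic diameters are classified against the reference end states
    and turned into a trimer-fraction trajectory
    ``f(t) = f_end + (f_start - f_end) e^{-k t}``.
    """
    traces = list(traces)
    if not traces:
        raise DataError("no monomerization traces given")
    fits: list[ExpFit] = []
    excluded: list[tuple[str, str]] = []
    for tr in traces:
        try:
            fits.append(fit_monomerization(tr))
        except FlatTraceError:
            excluded.append((tr.replicate_id, "flat trace (no resolvable decay)"))
        except FitError as exc:
            excluded.append((tr.replicate_id, f"fit failed: {exc}"))
    if fits:
        ks = np.array([f.k for f in fits])
        k_mean = float(ks.mean())
        k_sem = float(ks.std(ddof=1) / math.sqrt(len(ks))) if len(ks) > 1 else 0.0
        verdict = "monomerization"
    else:
        k_mean = k_sem = None
        verdict = "no monomerization"

    dh_s = dh_e = None
    state_s = state_e = None
    trajectory = None
    if dh_start is not None and dh_end is not None:
        dh_s, dh_e = float(dh_start), float(dh_end)
        state_s = compare_to_reference(dh_s, refs).state
        state_e = compare_to_reference(dh_e, refs).state
        if k_mean is not None:
            f_start = trimer_fraction(dh_s, refs)
            f_end = trimer_fraction(dh_e, refs)
            t = traces[0].t
            frac = f_end + (f_start - f_end) * np.exp(-k_mean * t)
            trajectory = (tuple(t.tolist()), tuple(frac.tolist()))
    return MonomerizationReport(
        k_mean=k_mean,
        k_sem=k_sem,
        n_used=len(fits),
        per_replicate=tuple(fits),
        excluded=tuple(excluded),
        verdict=verdict,
        dh_start_nm=dh_s,
        dh_end_nm=dh_e,
        start_state=state_s,
        end_state=state_e,
        fraction_trajectory=trajectory,
    )


def run_kinetics(
    assoc_traces: Sequence[Trace],
    dissoc_traces: Sequence[Trace],
    config: RunConfig = RunConfig(),
    spec: GlobalFitSpec = GlobalFitSpec(),
) -> KineticsReport:
    """Full kinetic analysis of one concentration series.

    Dissociation curves are first screened for a biphasic shape (overlapping
    trimer decay and scavenger release).  On the mono route, a global
    single-exponential fit yields the shared ``k_off``; on the biphasic
    route the slow rate of a shared bi-exponential fit is assigned to
    scavenger dissociation and used as ``k_off``, with the fast rate
    reported alongside.  The shared ``k_off`` then anchors the global
    association fit for ``k_on``, and K_D = k_off/k_on.

    A dissociation curve whose fitted offset stays a sizable fraction of its
    amplitude (signal not returning to baseline within the run) is flagged
    ``residual_complex`` — the signature of interlinked multivalent
    complexes with very slow release.
    """
    assoc_traces, dissoc_traces = list(assoc_traces), list(dissoc_traces)
    if not assoc_traces or not dissoc_traces:
        raise DataError("need both association and dissociation traces")

    selections = [select_decay_model(tr, alpha=config.model_alpha)
                  for tr in dissoc_traces]
    n_bi = sum(s.decision == "bi" for s in selections)
    ambiguous = any(s.ambiguous for s in selections)
    biphasic = n_bi > len(selections) / 2

    k_fast = None
    if biphasic:
        bi = fit_biexp_global(dissoc_traces)
        k_fast = bi.k_fast
        # slow rate = scavenger dissociation; per-curve slow rates for SEM
        per_trace = []
        for tr in dissoc_traces:
            sel = fit_biexp_global([tr])
            per_trace.append(sel.k_slow)
        dissoc = DissociationFit(
            k_off=bi.k_slow,
            se_k_off=0.0,
            amplitudes=bi.a_slow,
            offsets=bi.y0,
            per_trace_k_off=tuple(per_trace),
            rss=bi.rss,
        )
    else:
        dissoc = global_fit_dissociation(dissoc_traces, spec)

    assoc = global_fit_association(assoc_traces, dissoc.k_off, spec)
    fit = kinetics_report(assoc, dissoc)

    residual = False
    for A, y0 in zip(dissoc.amplitudes, dissoc.offsets):
        total = abs(A) + abs(y0)
        if total > 0 and abs(y0) / total > config.residual_offset_ratio:
            residual = True
    return KineticsReport(
        fit=fit,
        route="bi" if biphasic else "mono",
        k_fast=k_fast,
        residual_complex=residual,
        ambiguous_model=ambiguous,
    )


def run_titration(
    tables: Sequence[pd.DataFrame],
    rts: Sequence[float],
    config: RunConfig = RunConfig(),
) -> list[TitrationResult]:
    """Fit one depletion-corrected isotherm per receptor concentration.

    Each table pairs with the fixed total receptor concentration it was
    acquired at.  Depletion-limited titrations (K_D well below rt) come back
    as upper bounds.  Note the 1:1 isotherm is an approximation for
    multivalent partners: it underestimates the steepness of the true dose
    response, so point estimates should be read as effective affinities.
    """
    tables, rts = list(tables), list(rts)
    if len(tables) != len(rts):
        raise DataError("need exactly one table per receptor concentration")
    out = []
    for tab, rt in zip(tables, rts):
        if len(tab) == 0:
            raise DataError("empty titration table")
        out.append(
            fit_titration(
                tab,
                rt,
                n_boot=config.n_boot,
                seed=config.seed,
                bound_ratio=config.bound_ratio,
            )
        )
    return out


def _average_replicates(traces: Sequence[Trace]) -> Trace:
    t0 = traces[0].t
    for tr in traces[1:]:
        if len(tr) != len(t0) or not np.allclose(tr.t, t0):
            raise DataError("replicate traces must share one time grid")
    y = np.mean([tr.y for tr in traces], axis=0)
    return Trace(
        t=t0,
        y=y,
        phase=traces[0].phase,
        conc=traces[0].conc,
        replicate_id="mean",
        scavenger=traces[0].scavenger,
    )


def run_stabilization_panel(
    traces: Sequence[Trace],
    k_free: Optional[float] = None,
    config: RunConfig = RunConfig(),
    control_label: str = "buffer",
) -> StabilizationPanel:
    """Scavenger comparison: per-scavenger trimer-decay rate and class.

    Traces are grouped by scavenger label, replicates averaged point-wise
    before fitting (per-replicate fits are retained for the SEM).  The free
    decay rate comes from the buffer control unless passed explicitly; the
    control is required for suppression factors.

    Classification: a trace whose fitted amplitude is below
    ``detection_noise_factor`` × the residual noise sd over the full record
    has no detectable decay → ``full_suppression``.  Otherwise the rate
    relative to the free rate sets the class: below ``strong_max_ratio`` →
    strong, below ``moderate_max_ratio`` → moderate, else weak.  Rows are
    ordered by increasing rate (full suppression first), so class order and
    rate order agree by construction.
    """
    groups: dict[str, list[Trace]] = {}
    for tr in traces:
        groups.setdefault(tr.scavenger or control_label, []).append(tr)

    if k_free is None:
        if control_label not in groups:
            raise DataError(
                f"no {control_label!r} control and no k_free given: "
                "suppression factors undefined"
            )
        ctrl = _average_replicates(
            sorted(groups[control_label], key=lambda tr: tr.replicate_id)
        )
        k_free = fit_monomerization(ctrl).k

    rows = []
    for label in sorted(groups):
        # fixed replicate order so results are independent of input ordering
        reps = sorted(groups[label], key=lambda tr: tr.replicate_id)
        mean_tr = _average_replicates(reps)
        try:
            fit = fit_monomerization(mean_tr,
                                     flat_factor=config.detection_noise_factor)
        except FlatTraceError:
            rows.append(
                PanelRow(label, None, None, None, True, "full_suppression")
            )
            continue
        # per-replicate rates for the SEM
        rep_ks = []
        for r in reps:
            try:
                rep_ks.append(fit_monomerization(r).k)
            except FitError:
                pass
        se = (
            float(np.std(rep_ks, ddof=1) / math.sqrt(len(rep_ks)))
            if len(rep_ks) > 1
            else fit.se_k
        )
        ratio = fit.k / k_free
        if ratio < config.strong_max_ratio:
            klass = "strong"
        elif ratio < config.moderate_max_ratio:
            klass = "moderate"
        else:
            klass = "weak"
        rows.append(
            PanelRow(
                label=label,
                k_mono=fit.k,
                se_k=se,
                suppression_factor=k_free / fit.k,
                below_detection=False,
                klass=klass,
            )
        )
    rows.sort(key=lambda r: (-math.inf if r.k_mono is None else r.k_mono, r.label))
    return StabilizationPanel(rows=tuple(rows), k_free=float(k_free))
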