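"""Nonlinear least-squares estimators for the kinetic and equilibrium models.

The procedures mirror standard biosensor practice:

* dissociation curves of a concentration series are fitted globally with one
  shared ``k_off`` and free per-curve amplitude/offset;
* the shared ``k_off`` is then fixed while the association curves are fitted
  globally for one shared ``k_on`` through ``k_obs = c*k_on + k_off``;
* biphasic dissociation (overlapping trimer decay and scavenger release) is
  fitted with shared fast/slow rates and per-curve amplitudes;
* solution titrations are fitted with the depletion-corrected isotherm at a
  fixed, known total receptor concentration, with residual-bootstrap
  confidence intervals.

All rates are optimized in log space (trust-region reflective least
squares), which enforces positivity and conditions the problem well when
rates span 1e-5 … 1e-2 s^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from .errors import FitError, FlatTraceError, IdentifiabilityWarning
from .models import (
    BiExpFit,
    EquilibriumSpec,
    ExpFit,
    KineticFit,
    Phase,
    Trace,
    equilibrium_bound_fraction,
    kd_from_rates,
    kd_standard_error,
    mono_exp,
)

__all__ = [
    "GlobalFitSpec",
    "DissociationFit",
    "AssociationFit",
    "BiExpGlobalFit",
    "ModelSelection",
    "TitrationResult",
    "normalize_trace",
    "fit_monomerization",
    "fit_dissociation_single",
    "global_fit_dissociation",
    "global_fit_association",
    "fit_biexp_global",
    "select_decay_model",
    "fit_titration",
    "kinetics_report",
]

_LOGK_BOUNDS = (-30.0, 5.0)


@dataclass(frozen=True)
class GlobalFitSpec:
    """Which parameters are shared across curves in a global fit."""

    share_k_off: bool = True
    share_k_on: bool = True
    amplitudes_free: bool = True
    offsets_free: bool = True


@dataclass(frozen=True)
class DissociationFit:
    k_off: float
    se_k_off: float
    amplitudes: tuple
    offsets: tuple
    per_trace_k_off: tuple = ()
    rss: float = 0.0


@dataclass(frozen=True)
class AssociationFit:
    k_on: float
    se_k_on: float
    amplitudes: tuple
    offsets: tuple
    k_obs: tuple = ()
    rss: float = 0.0


@dataclass(frozen=True)
class BiExpGlobalFit:
    k_fast: float
    k_slow: float
    a_fast: tuple
    a_slow: tuple
    y0: tuple
    rss: float = 0.0
    effective_mono: bool = False  # one component's amplitude below noise floor

    def as_biexp(self, i: int = 0) -> BiExpFit:
        return BiExpFit(self.k_fast, self.k_slow, self.a_fast[i],
                        self.a_slow[i], self.y0[i])


@dataclass(frozen=True)
class ModelSelection:
    """Outcome of the mono- vs bi-exponential comparison for one trace."""

    decision: str  # "mono" | "bi"
    ambiguous: bool
    aicc_mono: float
    aicc_bi: float
    f_stat: float
    p_value: float
    mono_fit: Optional[ExpFit] = None
    bi_fit: Optional[BiExpGlobalFit] = None


@dataclass(frozen=True)
class TitrationResult:
    """Solution-equilibrium affinity from a depletion-corrected isotherm fit."""

    kd: float  # mol/L (point estimate; upper bound if is_bound)
    amplitude: float
    y0: float
    rt: float
    ci_low: float
    ci_high: float
    ci_level: float
    is_bound: bool = False  # True → report "K_D < kd_upper", not a point value
    kd_upper: float = math.nan

    def __str__(self) -> str:  # pragma: no cover - convenience only
        if self.is_bound:
            return f"K_D < {self.kd_upper * 1e12:.1f} pM (depletion-limited)"
        return (
            f"K_D = {self.kd * 1e12:.1f} pM "
            f"[{self.ci_low * 1e12:.1f}, {self.ci_high * 1e12:.1f}]"
        )


# ---------------------------------------------------------------------------
# helpers

def _cov_from_result(res) -> Optional[np.ndarray]:
    J = res.jac
    dof = J.shape[0] - J.shape[1]
    if dof <= 0:
        return None
    s2 = 2.0 * res.cost / dof
    JtJ = J.T @ J
    try:
        cov = np.linalg.inv(JtJ)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(JtJ)
    return cov * s2


def _resid_sd(res) -> float:
    n = res.fun.size
    return float(np.sqrt(2.0 * res.cost / max(n, 1)))


def _check_converged(res, what: str) -> None:
    if not res.success:
        raise FitError(f"{what}: optimizer did not converge ({res.message})")


def _rate_guess_from_halflife(t: np.ndarray, y: np.ndarray) -> float:
    """Crude k from the time at which the approach to plateau is half done."""
    y_inf, y_0 = y[-1], y[0]
    if y_inf == y_0:
        return 1.0 / max(t[-1] - t[0], 1.0)
    half = 0.5 * (y_0 + y_inf)
    idx = np.argmin(np.abs(y - half))
    t_half = max(t[idx] - t[0], (t[1] - t[0]))
    return math.log(2.0) / t_half


# ---------------------------------------------------------------------------
# normalization

def normalize_trace(
    trace: Trace,
    mode: str = "initial_value",
    baseline_window: Optional[tuple[float, float]] = None,
) -> Trace:
    """Divide a trace by a reference level so repeated runs are comparable.

    ``baseline`` mode divides by the mean over ``baseline_window`` (seconds,
    inclusive; defaults to the first 5% of the trace), ``initial_value`` mode
    by ``y(t0)``.  Idempotent: normalizing twice equals normalizing once.
    """
    if mode not in ("baseline", "initial_value"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    if mode == "initial_value":
        ref = trace.y[0]
    else:
        if baseline_window is None:
            t_cut = trace.t[0] + 0.05 * (trace.t[-1] - trace.t[0])
            mask = trace.t <= t_cut
        else:
            lo, hi = baseline_window
            mask = (trace.t >= lo) & (trace.t <= hi)
            if not np.any(mask):
                raise ValueError("baseline window contains no points")
        ref = float(np.mean(trace.y[mask]))
    if ref == 0:
        raise FlatTraceError("normalizer is zero; cannot normalize trace")
    return Trace(
        t=trace.t,
        y=trace.y / ref,
        phase=trace.phase,
        conc=trace.conc,
        replicate_id=trace.replicate_id,
        scavenger=trace.scavenger,
        extra=trace.extra,
    )


# ---------------------------------------------------------------------------
# mono-exponential fits

def _fit_exp_core(
    t: np.ndarray, y: np.ndarray, sign: float, flat_factor: float = 5.0
) -> tuple[float, float, float, float, float]:
    """Fit y = sign*A*exp(-k t) + y0; returns (k, A, y0, se_k, resid_sd).

    ``sign = -1`` is the rising monomerization form, ``sign = +1`` the
    falling dissociation form.
    """
    y0_init = float(y[-1])
    # model y(0) = sign*A + y0  →  A = (y(0) - y0)/sign
    A_init = float((y[0] - y[-1]) / sign)
    A_init = A_init if A_init != 0 else 1e-3
    k_init = _rate_guess_from_halflife(t, y)

    def resid(theta):
        k, A, y0 = math.exp(theta[0]), theta[1], theta[2]
        return sign * A * np.exp(-k * t) + y0 - y

    res = least_squares(
        resid,
        x0=[math.log(max(k_init, 1e-12)), A_init, y0_init],
        bounds=([_LOGK_BOUNDS[0], -np.inf, -np.inf],
                [_LOGK_BOUNDS[1], np.inf, np.inf]),
        method="trf",
        x_scale="jac",
    )
    _check_converged(res, "exponential fit")
    logk, A_hat, y0_hat = res.x
    k_hat = math.exp(logk)
    sd = _resid_sd(res)
    scale = max(1.0, float(np.max(np.abs(y))))
    # signal change the fit claims *within the record*: a near-flat trace can
    # hide behind a huge asymptote amplitude paired with a vanishing rate
    realized = abs(A_hat) * (1.0 - math.exp(-k_hat * (t[-1] - t[0])))
    if realized <= max(flat_factor * sd, 1e-9 * scale):
        raise FlatTraceError(
            "amplitude indistinguishable from noise; no decay resolvable"
        )
    if logk < _LOGK_BOUNDS[0] + 1e-6 or logk > _LOGK_BOUNDS[1] - 1e-6:
        raise FitError("rate constant pinned at parameter boundary")
    cov = _cov_from_result(res)
    se_k = k_hat * math.sqrt(cov[0, 0]) if cov is not None else 0.0
    return k_hat, float(A_hat), float(y0_hat), se_k, sd


def fit_monomerization(trace: Trace, flat_factor: float = 5.0) -> ExpFit:
    """Single-exponential fit of a trimer-decay trace (``-A e^{-kt} + y0``).

    Raises :class:`FlatTraceError` when the fitted amplitude is below
    ``flat_factor`` times the residual noise sd (a flat trace must not yield
    a spurious tiny rate) and :class:`FitError` on non-convergence or a
    boundary-pinned rate.
    """
    if trace.phase is not Phase.MONOMERIZATION and trace.phase is not Phase.STABILIZATION:
        raise ValueError("fit_monomerization expects a monomerization-type trace")
    if len(trace) < 5:
        raise ValueError("need at least 5 points")
    k, A, y0, se_k, _ = _fit_exp_core(trace.t, trace.y, sign=-1.0,
                                      flat_factor=flat_factor)
    return ExpFit(k=k, A=A, y0=y0, se_k=se_k)


def fit_dissociation_single(trace: Trace) -> ExpFit:
    """Per-curve dissociation fit ``y = A e^{-k_off t} + y0``."""
    if trace.phase is not Phase.DISSOCIATION:
        raise ValueError("expected a dissociation-phase trace")
    k, A, y0, se_k, _ = _fit_exp_core(trace.t, trace.y, sign=+1.0)
    return ExpFit(k=k, A=A, y0=y0, se_k=se_k)


# ---------------------------------------------------------------------------
# global fits

def global_fit_dissociation(
    traces: Sequence[Trace], spec: GlobalFitSpec = GlobalFitSpec()
) -> DissociationFit:
    """One shared ``k_off`` over all dissociation curves, free A/y0 per curve.

    Minimizes the pooled residual sum of squares.  Also fits each curve
    individually, so the spread of per-curve ``k_off`` values (SEM) can be
    reported alongside the pooled estimate.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces given")
    for tr in traces:
        if tr.phase is not Phase.DISSOCIATION:
            raise ValueError("all traces must be dissociation phase")
    if len(traces) == 1:
        warnings.warn(
            "single trace: global fit degenerates to a per-curve fit",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    singles = [fit_dissociation_single(tr) for tr in traces]
    n = len(traces)

    def unpack(theta):
        k = math.exp(theta[0])
        A = theta[1 : 1 + n]
        y0 = theta[1 + n : 1 + 2 * n]
        return k, A, y0

    def resid(theta):
        k, A, y0 = unpack(theta)
        return np.concatenate(
            [A[i] * np.exp(-k * tr.t) + y0[i] - tr.y for i, tr in enumerate(traces)]
        )

    k_init = float(np.exp(np.mean([math.log(s.k) for s in singles])))
    x0 = [math.log(k_init)] + [s.A for s in singles] + [s.y0 for s in singles]
    res = least_squares(resid, x0=x0, method="trf", x_scale="jac")
    _check_converged(res, "global dissociation fit")
    k_off, A_hat, y0_hat = unpack(res.x)
    cov = _cov_from_result(res)
    se = k_off * math.sqrt(cov[0, 0]) if cov is not None else 0.0
    return DissociationFit(
        k_off=k_off,
        se_k_off=se,
        amplitudes=tuple(float(a) for a in A_hat),
        offsets=tuple(float(v) for v in y0_hat),
        per_trace_k_off=tuple(s.k for s in singles),
        rss=float(2.0 * res.cost),
    )


def global_fit_association(
    traces: Sequence[Trace],
    k_off: float,
    spec: GlobalFitSpec = GlobalFitSpec(),
) -> AssociationFit:
    """One shared ``k_on`` over the association series, with ``k_off`` fixed.

    Each curve at analyte concentration ``c`` follows
    ``y = -A e^{-(c k_on + k_off) t} + y0``; the previously determined
    ``k_off`` enters the observed rate but is not re-fitted.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces given")
    for tr in traces:
        if tr.phase is not Phase.ASSOCIATION:
            raise ValueError("all traces must be association phase")
        if tr.conc <= 0:
            raise ValueError("association traces require conc > 0")
    concs = np.array([tr.conc for tr in traces])
    if len(traces) > 1 and np.allclose(concs, concs[0], rtol=1e-12, atol=0.0):
        warnings.warn(
            "all concentrations equal: k_on and k_off trade off",
            IdentifiabilityWarning,
            stacklevel=2,
        )
    n = len(traces)

    def unpack(theta):
        k_on = math.exp(theta[0])
        A = theta[1 : 1 + n]
        y0 = theta[1 + n : 1 + 2 * n]
        return k_on, A, y0

    def resid(theta):
        k_on, A, y0 = unpack(theta)
        out = []
        for i, tr in enumerate(traces):
            k_obs = tr.conc * k_on + k_off
            out.append(-A[i] * np.exp(-k_obs * tr.t) + y0[i] - tr.y)
        return np.concatenate(out)

    # initial k_on from the fastest curve's half-rise
    k_obs_init = max(
        _rate_guess_from_halflife(tr.t, tr.y) for tr in traces
    )
    k_on_init = max((k_obs_init - k_off) / concs.max(), 1.0)
    A_init = [float(tr.y[-1] - tr.y[0]) or 1e-3 for tr in traces]
    y0_init = [float(tr.y[-1]) for tr in traces]
    res = least_squares(
        resid,
        x0=[math.log(k_on_init)] + A_init + y0_init,
        method="trf",
        x_scale="jac",
    )
    _check_converged(res, "global association fit")
    k_on, A_hat, y0_hat = unpack(res.x)
    cov = _cov_from_result(res)
    se = k_on * math.sqrt(cov[0, 0]) if cov is not None else 0.0
    return AssociationFit(
        k_on=k_on,
        se_k_on=se,
        amplitudes=tuple(float(a) for a in A_hat),
        offsets=tuple(float(v) for v in y0_hat),
        k_obs=tuple(float(tr.conc * k_on + k_off) for tr in traces),
        rss=float(2.0 * res.cost),
    )


def fit_biexp_global(traces: Sequence[Trace]) -> BiExpGlobalFit:
    """Shared fast/slow rates, per-curve amplitudes and offsets.

    The fast component captures decay of unprotected trimer, the slow one
    scavenger dissociation.  Initialization is multi-start: ``k_slow`` is
    seeded from a mono-exponential fit of the trace tails (last 25%),
    ``k_fast`` from the early-phase residual, plus bracketing perturbations;
    the start with the lowest residual sum of squares wins.  Rates are
    ordered ``k_fast > k_slow`` after the fit.  If one component's pooled
    amplitude falls below the noise floor the result is flagged
    ``effective_mono``.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces given")
    for tr in traces:
        if tr.phase is not Phase.DISSOCIATION:
            raise ValueError("all traces must be dissociation phase")
    n = len(traces)

    # --- heuristic rate seeds from the first trace
    tr0 = traces[0]
    m = len(tr0)
    tail = slice(int(0.75 * m), m)
    try:
        k_slow_init, A_tail, y0_tail, _, _ = _fit_exp_core(
            tr0.t[tail], tr0.y[tail], sign=+1.0
        )
    except FitError:
        k_slow_init = 0.5 * _rate_guess_from_halflife(tr0.t, tr0.y)
        y0_tail = float(tr0.y[-1])
        A_tail = float(tr0.y[0] - y0_tail) or 1e-3
    early = slice(0, max(int(0.25 * m), 6))
    resid_early = tr0.y[early] - (
        A_tail * np.exp(-k_slow_init * tr0.t[early]) + y0_tail
    )
    try:
        k_fast_init, _, _, _, _ = _fit_exp_core(
            tr0.t[early], resid_early, sign=+1.0
        )
    except FitError:
        k_fast_init = 20.0 * k_slow_init
    k_fast_init = max(k_fast_init, 2.0 * k_slow_init)

    def unpack(theta):
        kf, ks = math.exp(theta[0]), math.exp(theta[1])
        af = theta[2 : 2 + n]
        aslow = theta[2 + n : 2 + 2 * n]
        y0 = theta[2 + 2 * n : 2 + 3 * n]
        return kf, ks, af, aslow, y0

    def resid(theta):
        kf, ks, af, aslow, y0 = unpack(theta)
        return np.concatenate(
            [
                -af[i] * np.exp(-kf * tr.t)
                - aslow[i] * np.exp(-ks * tr.t)
                + y0[i]
                - tr.y
                for i, tr in enumerate(traces)
            ]
        )

    amp_tot = [float(tr.y[-1] - tr.y[0]) or 1e-3 for tr in traces]
    starts = []
    for mult in (1.0, 5.0, 0.2):
        starts.append(
            [math.log(k_fast_init * mult), math.log(k_slow_init)]
            + [0.5 * a for a in amp_tot]  # note sign: -a*exp form
            + [0.5 * a for a in amp_tot]
            + [float(tr.y[-1]) for tr in traces]
        )
    best = None
    for x0 in starts:
        try:
            res = least_squares(resid, x0=x0, method="trf", x_scale="jac")
        except Exception:  # singular start; try the next one
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        raise FitError("bi-exponential global fit did not converge")
    kf, ks, af, aslow, y0 = unpack(best.x)
    if kf < ks:  # enforce ordering by swapping components
        kf, ks = ks, kf
        af, aslow = aslow, af
    sd = _resid_sd(best)
    eff_mono = (
        float(np.max(np.abs(af))) <= max(3.0 * sd, 1e-12)
        or float(np.max(np.abs(aslow))) <= max(3.0 * sd, 1e-12)
        or kf / ks < 1.0 + 1e-6
    )
    return BiExpGlobalFit(
        k_fast=float(kf),
        k_slow=float(ks),
        a_fast=tuple(float(a) for a in af),
        a_slow=tuple(float(a) for a in aslow),
        y0=tuple(float(v) for v in y0),
        rss=float(2.0 * best.cost),
        effective_mono=bool(eff_mono),
    )


# ---------------------------------------------------------------------------
# model selection

def _aicc(rss: float, n: int, p: int) -> float:
    if n - p - 1 <= 0:
        return math.inf
    return n * math.log(max(rss, 1e-300) / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1)


def select_decay_model(trace: Trace, alpha: float = 0.05) -> ModelSelection:
    """Decide mono- vs bi-exponential decay for one dissociation trace.

    Fits both forms and compares them with the small-sample-corrected
    information criterion (AICc) *and* an F-test on residual sums of squares
    (nested models, 2 extra parameters).  The bi-exponential is accepted only
    when both agree at level ``alpha``; disagreement is flagged ambiguous and
    the simpler model retained.  An unidentifiable second component (rate
    ratio → 1 or amplitude below noise) always yields mono.
    """
    if len(trace) < 10:
        raise ValueError("need at least 10 points for model selection")
    n = len(trace)
    mono = fit_dissociation_single(trace)
    rss_mono = float(np.sum((mono.A * np.exp(-mono.k * trace.t) + mono.y0 - trace.y) ** 2))
    try:
        bi = fit_biexp_global([trace])
    except FitError:
        return ModelSelection("mono", False, _aicc(rss_mono, n, 3), math.inf,
                              0.0, 1.0, mono_fit=mono, bi_fit=None)
    rss_bi = bi.rss
    aicc_mono = _aicc(rss_mono, n, 3)
    aicc_bi = _aicc(rss_bi, n, 5)
    if rss_bi <= 0 or n <= 5:
        f_stat, p_value = math.inf, 0.0
    else:
        f_stat = ((rss_mono - rss_bi) / 2.0) / (rss_bi / (n - 5))
        f_stat = max(f_stat, 0.0)
        p_value = float(stats.f.sf(f_stat, 2, n - 5))
    bi_wins_aicc = aicc_bi < aicc_mono
    bi_wins_f = p_value < alpha
    if bi.effective_mono:
        decision, ambiguous = "mono", False
    elif bi_wins_aicc and bi_wins_f:
        decision, ambiguous = "bi", False
    elif not bi_wins_aicc and not bi_wins_f:
        decision, ambiguous = "mono", False
    else:
        decision, ambiguous = "mono", True
    return ModelSelection(decision, ambiguous, aicc_mono, aicc_bi, f_stat,
                          p_value, mono_fit=mono, bi_fit=bi)


# ---------------------------------------------------------------------------
# titration

def _titration_model(lt: np.ndarray, rt: float, kd: float, A: float, y0: float) -> np.ndarray:
    # vectorized depletion-corrected bound fraction (stable quadratic root)
    kd = max(kd, 0.0)
    s = rt + lt + kd
    disc = np.sqrt(s * s - 4.0 * rt * lt)
    b = np.where(lt > 0, 2.0 * lt / (s + disc), 0.0)
    return y0 + A * (1.0 - np.minimum(b, 1.0))


def fit_titration(
    points: pd.DataFrame,
    rt: float,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
    bound_ratio: float = 0.1,
) -> TitrationResult:
    """Fit the depletion-corrected isotherm to a solution titration table.

    ``points`` must have columns ``conc_M`` (total titrant) and ``response``
    (normalized free-receptor readout).  The total receptor concentration
    ``rt`` is fixed and known.  Least squares over (kd, A, y0) with kd > 0
    via log-parameterization; confidence intervals by seeded residual
    bootstrap with leverage-adjusted residuals and studentized
    (bootstrap-t) intervals on the log-K_D scale — at a dozen design points
    the plain percentile interval is noticeably anti-conservative.

    When the titration is depletion-limited — the fitted K_D is small
    compared to ``rt`` (below ``bound_ratio * rt``) or the transition is not
    bracketed by the grid — only an upper bound on K_D can be supported and
    the result is flagged ``is_bound`` with ``kd_upper`` set.
    """
    if rt <= 0:
        raise ValueError("rt must be positive")
    if len(points) == 0:
        raise ValueError("empty titration table")
    if len(points) < 6:
        raise ValueError("need at least 6 titration points")
    lt = np.asarray(points["conc_M"], dtype=float)
    y = np.asarray(points["response"], dtype=float)
    order = np.argsort(lt)
    lt, y = lt[order], y[order]

    # midpoint of the transition sits near rt + kd
    A_init = float(y[0] - y[-1]) or 1.0
    y0_init = float(y[-1])
    half = y0_init + 0.5 * A_init
    idx = int(np.argmin(np.abs(y - half)))
    kd_init = max(lt[idx] - rt, 0.05 * rt)

    def resid(theta, yy):
        kd, A, y0 = math.exp(theta[0]), theta[1], theta[2]
        return _titration_model(lt, rt, kd, A, y0) - yy

    res = least_squares(
        resid,
        x0=[math.log(kd_init), A_init, y0_init],
        args=(y,),
        bounds=([-45.0, -np.inf, -np.inf], [0.0, np.inf, np.inf]),
        method="trf",
        x_scale="jac",
    )
    _check_converged(res, "titration fit")
    logkd_hat = float(res.x[0])
    kd_hat = math.exp(logkd_hat)
    A_hat, y0_hat = float(res.x[1]), float(res.x[2])

    def _se_logkd(res_) -> float:
        Jb = res_.jac
        nb, pb = Jb.shape
        if nb <= pb:
            return math.nan
        s2 = 2.0 * res_.cost / (nb - pb)
        try:
            covb = np.linalg.inv(Jb.T @ Jb) * s2
        except np.linalg.LinAlgError:
            return math.nan
        return math.sqrt(max(covb[0, 0], 0.0))

    se_log_hat = _se_logkd(res)

    # residual bootstrap, warm-started at the point estimate; raw residuals
    # from a p-parameter fit are deflated, so use leverage-adjusted residuals
    # r_i / sqrt(1 - h_ii), centered (linearized hat matrix from the jacobian)
    fitted = _titration_model(lt, rt, kd_hat, A_hat, y0_hat)
    resids = y - fitted
    J = res.jac
    try:
        h = np.einsum("ij,ij->i", J @ np.linalg.inv(J.T @ J), J)
        h = np.clip(h, 0.0, 0.99)
        resids = resids / np.sqrt(1.0 - h)
    except np.linalg.LinAlgError:
        pass
    resids = resids - resids.mean()
    rng = np.random.default_rng(seed)
    kd_samples = np.empty(n_boot)
    t_stats = []
    idx_boot = rng.integers(0, len(resids), size=(n_boot, len(resids)))
    for b in range(n_boot):
        y_b = fitted + resids[idx_boot[b]]
        # warm-started, unbounded LM refit (positivity via log-parameterization)
        res_b = least_squares(resid, x0=res.x, args=(y_b,), method="lm")
        kd_samples[b] = math.exp(min(res_b.x[0], 0.0))
        se_b = _se_logkd(res_b)
        if math.isfinite(se_b) and se_b > 0:
            t_stats.append((res_b.x[0] - logkd_hat) / se_b)
    a = 0.5 * (1.0 - ci_level)
    if len(t_stats) >= 50 and math.isfinite(se_log_hat) and se_log_hat > 0:
        t_lo, t_hi = np.quantile(t_stats, [a, 1.0 - a])
        ci_low = math.exp(logkd_hat - t_hi * se_log_hat)
        ci_high = math.exp(logkd_hat - t_lo * se_log_hat)
    else:  # too few usable resamples: fall back to percentile interval
        ci_low, ci_high = np.quantile(kd_samples, [a, 1.0 - a])

    not_bracketed = kd_hat + rt < lt[lt > 0].min() if np.any(lt > 0) else True
    depletion_limited = kd_hat < bound_ratio * rt
    is_bound = bool(depletion_limited or not_bracketed)
    kd_upper = float(max(kd_hat, ci_high)) if is_bound else math.nan
    return TitrationResult(
        kd=float(kd_hat),
        amplitude=A_hat,
        y0=y0_hat,
        rt=rt,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        ci_level=ci_level,
        is_bound=is_bound,
        kd_upper=kd_upper,
    )


# ---------------------------------------------------------------------------
# report assembly

def kinetics_report(
    assoc: AssociationFit, dissoc: DissociationFit
) -> KineticFit:
    """Assemble rate constants into a kinetic summary.

    ``K_D = k_off/k_on`` exactly; the ``k_off`` uncertainty is the standard
    error of the mean of the individually fitted per-curve ``k_off`` values
    (SEM, undefined for a single curve and then reported as 0), and the K_D
    uncertainty follows by first-order propagation.
    """
    k_offs = np.asarray(dissoc.per_trace_k_off, dtype=float)
    if k_offs.size >= 2:
        se_k_off = float(np.std(k_offs, ddof=1) / math.sqrt(k_offs.size))
    else:
        se_k_off = 0.0
    kd = kd_from_rates(assoc.k_on, dissoc.k_off)
    se_kd = kd_standard_error(assoc.k_on, dissoc.k_off, assoc.se_k_on, se_k_off)
    return KineticFit(
        k_on=assoc.k_on,
        k_off=dissoc.k_off,
        kd=kd,
        se_k_on=assoc.se_k_on,
        se_k_off=se_k_off,
        se_kd=se_kd,
        amplitudes=assoc.amplitudes,
        offsets=assoc.offsets,
    )
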