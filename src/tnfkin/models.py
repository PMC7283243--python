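"""Closed-form kinetic and equilibrium models for TNF-α oligomer dynamics.

TNF-α is bioactive as a non-covalent homotrimer of ~17.5 kDa monomers.  On a
biosensor surface under buffer flow the trimer decays into monomers with a
first-order rate constant k (mono-exponential signal change), while bound
therapeutic scavengers (IgGs, Fabs, receptor fusions) slow or suppress that
decay.  This module collects the pure closed-form pieces of the analysis:

* mono- and bi-exponential decay signals,
* pseudo-first-order association with observed rate ``k_obs = c*k_on + k_off``,
* the depletion-corrected 1:1 equilibrium binding isotherm (exact quadratic
  solution of mass action, required because both partners sit at pM levels
  comparable to the K_D),
* the switching-speed integral ("dynamic response") of a normalized
  fluorescence transition,
* small unit/derived-quantity helpers (K_D = k_off/k_on, molar → mass
  concentration).

Everything here is a pure function of its arguments; fitting lives in
:mod:`tnfkin.fitting` and simulation in :mod:`tnfkin.synthdata`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "TNFA_MONOMER_MASS_G_PER_MOL",
    "Phase",
    "Trace",
    "ExpFit",
    "BiExpFit",
    "KineticFit",
    "EquilibriumSpec",
    "SizeRefs",
    "dr_integral",
    "mono_exp",
    "dissociation_signal",
    "association_signal",
    "bi_exp",
    "equilibrium_bound_fraction",
    "kd_from_rates",
    "kd_standard_error",
    "molar_to_mass_conc",
]

#: Molar mass of the TNF-α monomer used for ng/ml conversions.  17.5 kg/mol
#: is consistent with the 10 nM ↔ 175 ng/ml pairing quoted for free TNF-α.
TNFA_MONOMER_MASS_G_PER_MOL: float = 17_500.0


class Phase(str, Enum):
    """Experimental phase a trace belongs to."""

    ASSOCIATION = "association"
    DISSOCIATION = "dissociation"
    MONOMERIZATION = "monomerization"
    STABILIZATION = "stabilization"


@dataclass(frozen=True)
class Trace:
    """One time-resolved, normalized biosensor signal.

    Parameters
    ----------
    t :
        Time in seconds, strictly increasing, length ≥ 3.
    y :
        Normalized signal (dimensionless), same length as ``t``.
    phase :
        Which experimental phase the trace records.  Time is taken relative
        to the phase start (t = 0 at injection / phase switch).
    conc :
        Analyte concentration in mol/L; 0 for buffer-only phases.
    replicate_id :
        Identifier of the replicate (e.g. detection spot).
    scavenger :
        Optional label of the TNF-α scavenger present.
    extra :
        Additional per-point columns carried through I/O untouched.
    """

    t: NDArray[np.float64]
    y: NDArray[np.float64]
    phase: Phase
    conc: float = 0.0
    replicate_id: str = "r1"
    scavenger: Optional[str] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "phase", Phase(self.phase))
        if t.ndim != 1 or y.ndim != 1 or len(t) != len(y):
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(t) < 3:
            raise ValueError("a trace needs at least 3 points")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if self.conc < 0:
            raise ValueError("concentration must be non-negative")

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class ExpFit:
    """Mono-exponential decay parameters ``y(t) = -A*exp(-k*t) + y0``."""

    k: float  # s^-1
    A: float  # signal units
    y0: float  # signal units
    se_k: float = 0.0  # s^-1

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("rate constant k must be positive")
        if self.se_k < 0:
            raise ValueError("se_k must be non-negative")


@dataclass(frozen=True)
class BiExpFit:
    """Bi-exponential decay parameters; ``k_fast > k_slow`` by convention."""

    k_fast: float  # s^-1
    k_slow: float  # s^-1
    a_fast: float
    a_slow: float
    y0: float

    def __post_init__(self) -> None:
        if not (self.k_fast > self.k_slow > 0):
            raise ValueError("require k_fast > k_slow > 0")


@dataclass(frozen=True)
class KineticFit:
    """Association/dissociation rate constants and the derived K_D.

    ``kd`` always equals ``k_off / k_on`` (enforced at construction).
    Amplitudes and offsets are per-concentration fit parameters.
    """

    k_on: float  # M^-1 s^-1
    k_off: float  # s^-1
    kd: float  # M
    se_k_on: float = 0.0
    se_k_off: float = 0.0
    se_kd: float = 0.0
    amplitudes: tuple = ()
    offsets: tuple = ()

    def __post_init__(self) -> None:
        if self.k_on <= 0 or self.k_off <= 0:
            raise ValueError("rate constants must be positive")
        if not math.isclose(self.kd * self.k_on, self.k_off, rel_tol=1e-9):
            raise ValueError("kd must equal k_off / k_on")


@dataclass(frozen=True)
class EquilibriumSpec:
    """Total concentrations and K_D for a 1:1 solution equilibrium R + L ⇌ RL."""

    rt: float  # total receptor (TNF-α), mol/L
    lt: float  # total ligand (titrant), mol/L
    kd: float  # mol/L

    def __post_init__(self) -> None:
        if self.rt < 0 or self.lt < 0 or self.kd < 0:
            raise ValueError("concentrations and kd must be non-negative")


@dataclass(frozen=True)
class SizeRefs:
    """Reference hydrodynamic diameters of the two oligomeric end states."""

    dh_trimer: float  # nm
    dh_monomer: float  # nm

    def __post_init__(self) -> None:
        if not (self.dh_trimer > self.dh_monomer > 0):
            raise ValueError("require dh_trimer > dh_monomer > 0")


def dr_integral(trace: Trace, t1: float, t2: float) -> float:
    """Switching-speed observable: integral of the normalized signal.

    Computes ``DR = ∫_{t1}^{t2} y dt`` by trapezoidal quadrature on the
    stored grid (no resampling); the window endpoints are linearly
    interpolated so the integral is additive over adjacent windows.

    Raises
    ------
    ValueError
        If ``t1 >= t2`` or the window extends outside the trace time range.
    """
    if t1 >= t2:
        raise ValueError("require t1 < t2")
    if t1 < trace.t[0] or t2 > trace.t[-1]:
        raise ValueError(
            f"window [{t1}, {t2}] outside trace range "
            f"[{trace.t[0]}, {trace.t[-1]}]"
        )
    inside = (trace.t > t1) & (trace.t < t2)
    ts = np.concatenate(([t1], trace.t[inside], [t2]))
    ys = np.concatenate(
        (
            [np.interp(t1, trace.t, trace.y)],
            trace.y[inside],
            [np.interp(t2, trace.t, trace.y)],
        )
    )
    return float(np.trapezoid(ys, ts))


def mono_exp(t: ArrayLike, k: float, A: float, y0: float) -> NDArray[np.float64]:
    """Mono-exponential signal ``y(t) = -A*exp(-k*t) + y0``.

    Starts at ``y0 - A`` and relaxes toward ``y0`` with rate ``k``; this is
    the forward model for trimer monomerization under buffer flow.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    return -A * np.exp(-k * np.asarray(t, dtype=float)) + y0


def dissociation_signal(
    t: ArrayLike, k_off: float, A: float, y0: float
) -> NDArray[np.float64]:
    """Dissociation-phase signal ``y(t) = A*exp(-k_off*t) + y0``."""
    if k_off < 0:
        raise ValueError("k_off must be non-negative")
    return A * np.exp(-k_off * np.asarray(t, dtype=float)) + y0


def association_signal(
    t: ArrayLike, c: float, k_on: float, k_off: float, A: float, y0: float
) -> NDArray[np.float64]:
    """Pseudo-first-order association signal.

    ``y(t) = -A*exp(-k_obs*t) + y0`` with observed rate
    ``k_obs = c*k_on + k_off`` — the 1:1 binding model at constant analyte
    concentration ``c``.  At ``c = 0`` this reduces to a decay with ``k_off``.
    """
    if c < 0:
        raise ValueError("c must be non-negative")
    if k_on <= 0:
        raise ValueError("k_on must be positive")
    if k_off < 0:
        raise ValueError("k_off must be non-negative")
    k_obs = c * k_on + k_off
    return -A * np.exp(-k_obs * np.asarray(t, dtype=float)) + y0


def bi_exp(t: ArrayLike, p: BiExpFit) -> NDArray[np.float64]:
    """Bi-exponential signal: two decay components sharing one offset.

    ``y(t) = -a_fast*exp(-k_fast*t) - a_slow*exp(-k_slow*t) + y0``.
    Used where trimer decay (fast) and scavenger dissociation (slow) overlap.
    """
    t = np.asarray(t, dtype=float)
    return (
        -p.a_fast * np.exp(-p.k_fast * t)
        - p.a_slow * np.exp(-p.k_slow * t)
        + p.y0
    )


def equilibrium_bound_fraction(spec: EquilibriumSpec) -> float:
    """Fraction of receptor bound at equilibrium, with depletion correction.

    Solves mass action for R + L ⇌ RL exactly (both totals comparable to
    K_D, so the free-ligand approximation is invalid):

    ``b = ((rt + lt + kd) - sqrt((rt + lt + kd)^2 - 4*rt*lt)) / (2*rt)``

    evaluated in the numerically stable form ``b = 2*lt / (s + sqrt(...))``
    to avoid cancellation when ``rt*lt`` is small.  Returns a value in
    ``[0, min(1, lt/rt)]``.

    Raises
    ------
    ValueError
        If ``rt <= 0`` (use the no-depletion limit lt/(lt+kd) explicitly
        when receptor is truly negligible).
    """
    if spec.rt <= 0:
        raise ValueError("rt must be positive; the rt→0 limit is lt/(lt+kd)")
    if spec.lt == 0:
        return 0.0
    s = spec.rt + spec.lt + spec.kd
    disc = math.sqrt(s * s - 4.0 * spec.rt * spec.lt)
    b = 2.0 * spec.lt / (s + disc)
    return min(b, 1.0)


def kd_from_rates(k_on: float, k_off: float) -> float:
    """Equilibrium dissociation constant ``K_D = k_off / k_on`` in mol/L."""
    if k_on <= 0:
        raise ValueError("k_on must be positive")
    if k_off < 0:
        raise ValueError("k_off must be non-negative")
    return k_off / k_on


def kd_standard_error(
    k_on: float, k_off: float, se_k_on: float, se_k_off: float
) -> float:
    """First-order error propagation for K_D = k_off/k_on.

    ``se_kd / kd = sqrt((se_k_on/k_on)^2 + (se_k_off/k_off)^2)``.
    """
    kd = kd_from_rates(k_on, k_off)
    if k_off == 0:
        return 0.0
    return kd * math.sqrt((se_k_on / k_on) ** 2 + (se_k_off / k_off) ** 2)


def molar_to_mass_conc(c: float, molar_mass: float = TNFA_MONOMER_MASS_G_PER_MOL) -> float:
    """Convert a molar concentration (mol/L) to mass concentration (g/L)."""
    if c < 0:
        raise ValueError("c must be non-negative")
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    return c * molar_mass
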