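"""Hydrodynamic-size interpretation of switching-speed observables.

A molecule tethered to an actuated DNA nanolever slows the lever's motion in
proportion to its hydrodynamic friction, so the switching-speed observable
(dynamic response, DR) reports the hydrodynamic diameter D_H of the cargo.
The physical DR→D_H model lives in the instrument software; here the mapping
is a user-supplied, strictly monotone calibration table interpolated with a
shape-preserving spline.  The oligomeric state is then expressed as a trimer
fraction by linear interpolation between the measured end-state diameters
(trimer ≈ 5.6 nm, monomer ≈ 3.9 nm) — an operational scale, not a
hydrodynamic model of intermediate species.

Reference diameters carry provenance labels (measured on the sensor vs
predicted from PDB crystal structures) and are never mixed silently.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .models import SizeRefs

__all__ = [
    "MEASURED_REFS",
    "PREDICTED_TRIMER_RANGE_NM",
    "PREDICTED_MONOMER_RANGE_NM",
    "CalibrationCurve",
    "ReferenceMatch",
    "dh_from_signal",
    "signal_from_dh",
    "interpolation_error",
    "trimer_fraction",
    "compare_to_reference",
]

#: End-state diameters measured on the biosensor (nm): trimer and monomer.
MEASURED_REFS = SizeRefs(dh_trimer=5.6, dh_monomer=3.9)
#: Shell-model predictions from trimeric crystal structures (3ALQ, 1TNF), nm.
PREDICTED_TRIMER_RANGE_NM: tuple[float, float] = (5.76, 6.10)
#: Shell-model predictions from monomeric crystal structures (4G3Y, 3WD5), nm.
PREDICTED_MONOMER_RANGE_NM: tuple[float, float] = (4.39, 4.44)


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone table mapping switching-speed values to D_H (nm).

    Larger switching speed means less friction, hence smaller D_H: the table
    must be strictly decreasing in D_H as DR increases.
    """

    dr: np.ndarray
    dh: np.ndarray

    def __post_init__(self) -> None:
        dr = np.asarray(self.dr, dtype=float)
        dh = np.asarray(self.dh, dtype=float)
        object.__setattr__(self, "dr", dr)
        object.__setattr__(self, "dh", dh)
        if len(dr) != len(dh) or len(dr) < 2:
            raise ValueError("need at least 2 calibration pairs")
        if not np.all(np.diff(dr) > 0):
            raise ValueError("DR values must be strictly increasing")
        if not np.all(np.diff(dh) < 0):
            raise ValueError("D_H must be strictly decreasing with DR")

    @classmethod
    def from_file(cls, path: str | Path) -> "CalibrationCurve":
        """Read a two-column delimited file (dr, dh_nm), header optional."""
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        if df.shape[1] < 2:
            raise ValueError("calibration file needs two columns (dr, dh_nm)")
        arr = df.iloc[:, :2].to_numpy(dtype=float)
        order = np.argsort(arr[:, 0])
        return cls(dr=arr[order, 0], dh=arr[order, 1])

    def _interpolator(self) -> PchipInterpolator:
        return PchipInterpolator(self.dr, self.dh)


@dataclass(frozen=True)
class ReferenceMatch:
    """Classification of a measured D_H against the reference states."""

    state: str  # "trimer" | "monomer" | "ambiguous"
    nearest_anchor_nm: float
    deviation_nm: float
    candidates: tuple  # (state, anchor_nm, deviation_nm) per end state
    within_predicted_trimer: bool
    within_predicted_monomer: bool


def dh_from_signal(dr: float, cal: CalibrationCurve) -> float:
    """Interpolate a switching-speed value to a hydrodynamic diameter (nm).

    Shape-preserving (PCHIP) monotone interpolation; extrapolation outside
    the calibrated DR range is refused.
    """
    if dr < cal.dr[0] or dr > cal.dr[-1]:
        raise ValueError(
            f"DR {dr} outside calibration range [{cal.dr[0]}, {cal.dr[-1]}]; "
            "extrapolation refused"
        )
    return float(cal._interpolator()(dr))


def signal_from_dh(dh: float, cal: CalibrationCurve) -> float:
    """Inverse of :func:`dh_from_signal` by root finding on the interpolant."""
    lo, hi = float(cal.dh[-1]), float(cal.dh[0])
    if not (lo <= dh <= hi):
        raise ValueError(f"D_H {dh} nm outside calibration range [{lo}, {hi}]")
    f = cal._interpolator()
    return float(brentq(lambda x: float(f(x)) - dh, cal.dr[0], cal.dr[-1],
                        xtol=1e-13, rtol=1e-14))


def interpolation_error(dr: float, cal: CalibrationCurve) -> float:
    """Crude local interpolation-error estimate (nm).

    Difference between the shape-preserving spline and straight linear
    interpolation; zero at the knots, largest where the table is sparse.
    """
    if dr < cal.dr[0] or dr > cal.dr[-1]:
        raise ValueError("DR outside calibration range")
    lin = float(np.interp(dr, cal.dr, cal.dh))
    return abs(float(cal._interpolator()(dr)) - lin)


def trimer_fraction(dh: float, refs: SizeRefs = MEASURED_REFS) -> float:
    """Linear position of a diameter on the monomer→trimer scale, in [0, 1].

    ``f = (dh - dh_monomer) / (dh_trimer - dh_monomer)``, clipped.  This is
    an operational fraction, not a friction model of mixed populations.
    """
    span = refs.dh_trimer - refs.dh_monomer
    f = (dh - refs.dh_monomer) / span
    return float(np.clip(f, 0.0, 1.0))


def compare_to_reference(
    dh: float, refs: SizeRefs = MEASURED_REFS, tie_tol: float = 1e-12
) -> ReferenceMatch:
    """Classify a measured D_H as trimer or monomer (measured anchors).

    The decision uses the measured end-state anchors; equidistant values are
    reported ambiguous with both candidates.  Consistency with the
    PDB-predicted ranges is reported separately and never drives the
    classification (measured and predicted references are not interchangeable).
    """
    if dh <= 0:
        raise ValueError("dh must be positive")
    d_tri = abs(dh - refs.dh_trimer)
    d_mono = abs(dh - refs.dh_monomer)
    candidates = (
        ("trimer", refs.dh_trimer, d_tri),
        ("monomer", refs.dh_monomer, d_mono),
    )
    if abs(d_tri - d_mono) <= tie_tol:
        state, nearest, dev = "ambiguous", refs.dh_trimer, d_tri
    elif d_tri < d_mono:
        state, nearest, dev = "trimer", refs.dh_trimer, d_tri
    else:
        state, nearest, dev = "monomer", refs.dh_monomer, d_mono
    return ReferenceMatch(
        state=state,
        nearest_anchor_nm=nearest,
        deviation_nm=dev,
        candidates=candidates,
        within_predicted_trimer=(
            PREDICTED_TRIMER_RANGE_NM[0] <= dh <= PREDICTED_TRIMER_RANGE_NM[1]
        ),
        within_predicted_monomer=(
            PREDICTED_MONOMER_RANGE_NM[0] <= dh <= PREDICTED_MONOMER_RANGE_NM[1]
        ),
    )
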