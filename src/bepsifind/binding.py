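"""Equilibrium Kd fitting for protein-dsRNA binding by fluorescence anisotropy.

A fluorescently labeled RNA duplex is titrated with protein; bound ligand
tumbles more slowly, raising the anisotropy r.  Because the ligand
concentration (tens of nM) is not negligible relative to the Kd, free
protein is depleted by binding and the simple hyperbola P/(P+Kd) is biased.
The fraction bound therefore uses the exact solution of the 1:1 mass-action
quadratic:

    fb = ((P + L + Kd) - sqrt((P + L + Kd)^2 - 4 P L)) / (2 L)

with P and L the *total* protein and ligand concentrations.  The observed
anisotropy is modeled as r(P) = r_free + (r_bound - r_free) * fb, and
(Kd, r_free, r_bound) are fitted per titration curve by nonlinear least
squares; replicates are fitted independently and summarized as mean +/- sd,
matching the usual "Kd = x +/- y nM, n = 3" presentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    """Raised when a titration curve cannot be fitted."""


@dataclass(frozen=True)
class BindingCurve:
    """One titration: total protein concentrations (nM) vs anisotropy, at a
    fixed total ligand concentration (nM)."""

    protein_conc: tuple[float, ...]
    anisotropy: tuple[float, ...]
    ligand_conc: float
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.protein_conc) != len(self.anisotropy):
            raise ValueError("protein_conc and anisotropy must have equal length")
        if len(self.protein_conc) < 5:
            raise ValueError("need at least 5 titration points")
        if self.ligand_conc <= 0:
            raise ValueError("ligand_conc must be > 0")
        if any(p < 0 for p in self.protein_conc):
            raise ValueError("protein concentrations must be >= 0")
        if len(set(self.protein_conc)) != len(self.protein_conc):
            raise ValueError("protein concentrations must be distinct")


@dataclass
class KdEstimate:
    """Replicate-aggregated dissociation constant (nM)."""

    kd: float
    kd_sd: float
    kds: list[float]
    r_free: float
    r_bound: float


def fraction_bound(P, L: float, Kd: float):
    """Fraction of ligand bound at total protein P, ligand L, both nM.

    Physical root of the 1:1 binding quadratic; vectorized over P.  The
    discriminant is clamped at zero as a numerical guard (it is nonnegative
    for valid inputs).
    """
    P = np.asarray(P, dtype=float)
    if L <= 0:
        raise ValueError("L must be > 0")
    if Kd < 0 or np.any(P < 0):
        raise ValueError("P and Kd must be >= 0")
    s = P + L + Kd
    disc = np.maximum(s * s - 4.0 * P * L, 0.0)
    fb = (s - np.sqrt(disc)) / (2.0 * L)
    return np.clip(fb, 0.0, 1.0)


def _anisotropy_model(P, kd, r_free, r_bound, L):
    return r_free + (r_bound - r_free) * fraction_bound(P, L, kd)


def _initial_kd(P: np.ndarray, r: np.ndarray) -> float:
    """Grid lookup: protein concentration nearest half-maximal anisotropy."""
    half = (r.min() + r.max()) / 2.0
    kd0 = float(P[np.argmin(np.abs(r - half))])
    return max(kd0, 1e-3)


def fit_curve(curve: BindingCurve, noise_floor: float = 0.002) -> tuple[float, float, float]:
    """Fit (Kd, r_free, r_bound) for one titration curve.

    Warns when the anisotropy change is below 3x the noise floor (transition
    not bracketed); raises :class:`FitError` on non-convergence.
    """
    P = np.asarray(curve.protein_conc, dtype=float)
    r = np.asarray(curve.anisotropy, dtype=float)
    span = r.max() - r.min()
    if span < 3.0 * noise_floor:
        warnings.warn(
            f"curve {curve.label or '<unnamed>'}: anisotropy change {span:.4g} "
            f"< 3x noise floor {noise_floor:.4g}; transition not bracketed",
            stacklevel=2,
        )
    p0 = (_initial_kd(P, r), float(r.min()), float(r.max()))
    try:
        popt, _ = curve_fit(
            lambda x, kd, rf, rb: _anisotropy_model(x, kd, rf, rb, curve.ligand_conc),
            P,
            r,
            p0=p0,
            bounds=([1e-9, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"curve {curve.label or '<unnamed>'}: {exc}") from exc
    kd, r_free, r_bound = map(float, popt)
    return kd, r_free, r_bound


def fit_kd(curves: list[BindingCurve], noise_floor: float = 0.002) -> KdEstimate:
    """Fit each replicate independently; report mean +/- sample sd of Kd."""
    if not curves:
        raise ValueError("need at least one titration curve")
    kds, rfs, rbs = [], [], []
    for curve in curves:
        kd, rf, rb = fit_curve(curve, noise_floor=noise_floor)
        kds.append(kd)
        rfs.append(rf)
        rbs.append(rb)
    kd_sd = float(np.std(kds, ddof=1)) if len(kds) > 1 else 0.0
    return KdEstimate(
        kd=float(np.mean(kds)),
        kd_sd=kd_sd,
        kds=kds,
        r_free=float(np.mean(rfs)),
        r_bound=float(np.mean(rbs)),
    )
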