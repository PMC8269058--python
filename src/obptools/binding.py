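"""Fluorescence ligand-binding analysis.

Two assay geometries are covered:

* **saturation** — titrating a protein solution with the fluorescent probe
  N-phenyl-1-naphthylamine (1-NPN) and fitting the one-site model
  ``F = F_max · L / (K_d + L)``;
* **competition** — titrating a protein/1-NPN mixture with a non-fluorescent
  ligand, fitting ``F = F_0 / (1 + L / IC50)`` (unit Hill slope), and
  converting the half-displacement concentration to a ligand dissociation
  constant with the Cheng–Prusoff-type correction
  ``K_d = IC50 / (1 + [probe] / K_probe)``.

Concentrations are in μM throughout; fluorescence signals are unitless.
The free probe concentration is approximated by the total probe
concentration (no free-probe correction is applied).

Tryptophan-quenching titrations (proteins whose probe spectrum shows no
blue shift) can be ingested as :class:`TitrationCurve` objects, but no
dissociation constant is derived from them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "TitrationCurve",
    "SaturationFit",
    "CompetitionFit",
    "fit_saturation",
    "fit_ic50",
    "cheng_prusoff_kd",
    "fit_competition",
    "quenching_summary",
]


@dataclass(frozen=True)
class TitrationCurve:
    """(ligand concentration, fluorescence) series from one titration."""

    ligand_conc: tuple[float, ...]  # μM, strictly increasing
    signal: tuple[float, ...]  # arbitrary fluorescence units
    protein_conc: float = 2.0  # μM

    def __post_init__(self) -> None:
        L = np.asarray(self.ligand_conc, dtype=float)
        F = np.asarray(self.signal, dtype=float)
        if L.size != F.size:
            raise ValueError("concentration and signal series differ in length")
        if L.size and (np.any(L < 0) or np.any(np.diff(L) <= 0)):
            raise ValueError("concentrations must be nonnegative and strictly "
                             "increasing")
        if not np.all(np.isfinite(F)):
            raise ValueError("signals must be finite")
        if self.protein_conc <= 0:
            raise ValueError("protein concentration must be positive")


@dataclass(frozen=True)
class SaturationFit:
    kd: float  # μM
    f_max: float  # a.u.
    residual_norm: float

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.f_max <= 0:
            raise ValueError("K_d and F_max must be positive")


@dataclass(frozen=True)
class CompetitionFit:
    ic50: float  # μM
    kd: float  # μM
    probe_conc: float  # μM
    k_probe: float  # μM
    ic50_interpolated: float | None = None  # model-free QC estimate

    def __post_init__(self) -> None:
        if min(self.ic50, self.kd, self.probe_conc, self.k_probe) <= 0:
            raise ValueError("all competition-fit quantities must be positive")
        if self.kd > self.ic50 * (1 + 1e-9):
            raise ValueError("K_d cannot exceed IC50")


def _one_site(L: np.ndarray, kd: float, f_max: float) -> np.ndarray:
    return f_max * L / (kd + L)


def fit_saturation(curve: TitrationCurve) -> SaturationFit:
    """Nonlinear least-squares fit of the one-site saturation model.

    Initialisation: K_d at the median ligand concentration, F_max at the
    maximum signal; both parameters are bounded positive.
    """
    L = np.asarray(curve.ligand_conc, dtype=float)
    F = np.asarray(curve.signal, dtype=float)
    if L.size < 4:
        raise ValueError(f"need at least 4 titration points, got {L.size}")
    if np.allclose(F, F[0]):
        raise ValueError("constant signal: no binding isotherm to fit")
    p0 = (float(np.median(L)), float(F.max()))
    try:
        popt, _ = curve_fit(
            _one_site, L, F, p0=p0,
            bounds=((1e-9, 1e-9), (np.inf, np.inf)), maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise ValueError(f"saturation fit did not converge: {exc}") from exc
    kd, f_max = map(float, popt)
    resid = float(np.linalg.norm(F - _one_site(L, kd, f_max)))
    return SaturationFit(kd=kd, f_max=f_max, residual_norm=resid)


def _competition(L: np.ndarray, ic50: float, f0: float) -> np.ndarray:
    return f0 / (1.0 + L / ic50)


def fit_ic50(curve: TitrationCurve) -> tuple[float, float, float | None]:
    """Fit ``F = F0 / (1 + L/IC50)`` to a displacement titration.

    Returns ``(ic50, f0, ic50_interpolated)`` where the last element is a
    model-free QC estimate: the reciprocal signal is linear in L for this
    model, so F0 is read off the intercept of a straight-line fit of 1/F
    and the crossing of F0/2 is located by linear interpolation of the
    measured points (None when the curve never falls below F0/2).
    """
    L = np.asarray(curve.ligand_conc, dtype=float)
    F = np.asarray(curve.signal, dtype=float)
    if L.size < 4:
        raise ValueError(f"need at least 4 titration points, got {L.size}")
    if F[-1] >= F[0]:
        raise ValueError("signal does not decrease: not a displacement curve")
    if np.any(F <= 0):
        raise ValueError("fluorescence signals must stay positive")
    # reciprocal-linear initialisation: 1/F = 1/F0 + L/(F0*IC50)
    slope, intercept = np.polyfit(L, 1.0 / F, 1)
    if intercept <= 0 or slope <= 0:
        f0_init, ic50_init = float(F[0]), float(np.median(L))
    else:
        f0_init, ic50_init = 1.0 / intercept, intercept / slope
    popt, _ = curve_fit(
        _competition, L, F, p0=(ic50_init, f0_init),
        bounds=((1e-9, 1e-9), (np.inf, np.inf)), maxfev=10000,
    )
    ic50, f0 = map(float, popt)
    half = f0 / 2.0
    crossing: float | None = None
    below = np.nonzero(F <= half)[0]
    if below.size:
        j = int(below[0])
        if j == 0:
            crossing = float(L[0])
        else:
            f1, f2 = F[j - 1], F[j]
            crossing = float(L[j - 1] + (f1 - half) * (L[j] - L[j - 1]) / (f1 - f2))
    elif ic50 > 4 * L[-1]:
        raise ValueError(
            "IC50 not reached: signal never falls to half its initial value "
            "within the titrated range and the extrapolated fit is unstable"
        )
    return ic50, f0, crossing


def cheng_prusoff_kd(ic50: float, probe_conc: float, k_probe: float) -> float:
    """Ligand dissociation constant from IC50: ``IC50 / (1 + [probe]/K_probe)``."""
    if min(ic50, probe_conc, k_probe) <= 0:
        raise ValueError("ic50, probe_conc and k_probe must all be positive")
    return ic50 / (1.0 + probe_conc / k_probe)


def fit_competition(
    curve: TitrationCurve,
    probe_conc: float = 2.0,
    k_probe: float = 3.5,
) -> CompetitionFit:
    """Fit a displacement curve and convert IC50 to the ligand K_d."""
    ic50, _, crossing = fit_ic50(curve)
    kd = cheng_prusoff_kd(ic50, probe_conc, k_probe)
    return CompetitionFit(
        ic50=ic50, kd=kd, probe_conc=probe_conc, k_probe=k_probe,
        ic50_interpolated=crossing,
    )


def quenching_summary(curve: TitrationCurve) -> dict:
    """Descriptive summary of a tryptophan-quenching titration.

    Quenching reports ligand entry but not the bound-probe concentration, so
    no dissociation constant is estimated (``kd`` is always None).
    """
    F = np.asarray(curve.signal, dtype=float)
    frac = float(1.0 - F[-1] / F[0]) if F[0] != 0 else math.nan
    return {
        "kd": None,
        "initial_signal": float(F[0]),
        "final_signal": float(F[-1]),
        "fraction_quenched": frac,
    }
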