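"""Ferrozine-assay processing and Michaelis-Menten kinetics.

The ferroxidase assay quantifies remaining Fe2+ after the enzymatic
reaction with ferrozine, whose Fe2+ complex absorbs at 560 nm
(epsilon_560 = 25,400 M^-1 cm^-1).  Oxidation rates follow from the
drop in absorbance relative to an enzyme-free control; rates across a
substrate series are fitted to the Michaelis-Menten equation

    v = Vmax * S / (K_M + S)

by unweighted nonlinear least squares, initialised from a Hanes-Woolf
linearisation (S/v regressed on S).  A unit helper converts ICP-MS
elemental contents of washed agar (ug element per g dry agar) into the
micromolar contribution to the solid growth medium.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

#: Molar extinction coefficient of the Fe2+-ferrozine complex at 560 nm.
EPSILON_560_M_CM = 25_400.0


@dataclass(frozen=True)
class AssayPoint:
    """One ferrozine-assay observation."""

    substrate_uM: float
    a560: float
    path_cm: float = 1.0
    time_min: float = 1.0
    replicate: int = 0

    def __post_init__(self):
        if self.substrate_uM < 0:
            raise ValueError("substrate_uM must be >= 0")
        if self.path_cm <= 0:
            raise ValueError("path_cm must be > 0")
        if self.time_min <= 0:
            raise ValueError("time_min must be > 0")


@dataclass
class RateSeries:
    """Initial-rate observations v(S), possibly with replicates."""

    S: np.ndarray
    v: np.ndarray
    grouping: np.ndarray | None = None
    clamped: np.ndarray | None = None  # flags set where negatives were clamped

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.S.shape != self.v.shape:
            raise ValueError("S and v must have equal lengths")
        if (self.S < 0).any():
            raise ValueError("substrate concentrations must be >= 0")


@dataclass(frozen=True)
class MMFit:
    """Fitted Michaelis-Menten constants with asymptotic standard errors."""

    km_uM: float
    vmax: float
    km_se: float
    vmax_se: float
    rss: float
    converged: bool
    n_points: int

    def predict(self, S):
        S = np.asarray(S, dtype=float)
        return self.vmax * S / (self.km_uM + S)


@dataclass(frozen=True)
class MediumSpec:
    """Elemental content of washed dry agar and the medium recipe."""

    element: str
    content_ug_per_g: float
    agar_percent_wv: float = 1.0
    molar_mass_g_mol: float = 1.0

    def __post_init__(self):
        if self.content_ug_per_g < 0:
            raise ValueError("content must be >= 0")
        if self.agar_percent_wv <= 0:
            raise ValueError("agar percentage must be > 0")
        if self.molar_mass_g_mol <= 0:
            raise ValueError("molar mass must be > 0")


def fe2_from_absorbance(a560: float, path_cm: float = 1.0) -> float:
    """Fe2+ concentration (uM) from A560 by Beer-Lambert.

    c = A / (epsilon * l), with epsilon = 25,400 M^-1 cm^-1, reported in
    micromolar.  Negative absorbances are clamped to 0 with a warning.
    """
    if path_cm <= 0:
        raise ValueError("path_cm must be > 0")
    if a560 < 0:
        warnings.warn(f"negative absorbance {a560} clamped to 0", stacklevel=2)
        return 0.0
    return a560 / (EPSILON_560_M_CM * path_cm) * 1e6


def oxidation_rate(
    a560_no_enzyme: float,
    a560_with_enzyme: float,
    time_min: float,
    path_cm: float = 1.0,
) -> tuple[float, bool]:
    """Fe2+ oxidation rate (uM min^-1) from control and sample absorbances.

    The enzyme consumes Fe2+, so the sample reads lower than the
    enzyme-free control; v = (c_control - c_sample) / t.  A sample above
    its control yields 0 with the clamp flag set.
    """
    if time_min <= 0:
        raise ValueError("time_min must be > 0")
    c_ctrl = fe2_from_absorbance(a560_no_enzyme, path_cm)
    c_samp = fe2_from_absorbance(a560_with_enzyme, path_cm)
    v = (c_ctrl - c_samp) / time_min
    if v < 0:
        return 0.0, True
    return v, False


def subtract_background(sample: RateSeries, control: RateSeries) -> RateSeries:
    """Pointwise background subtraction on matching substrate grids.

    Negative differences are clamped to 0 and flagged rather than dropped.
    """
    if sample.S.shape != control.S.shape or not np.allclose(sample.S, control.S):
        raise ValueError("sample and control substrate grids do not match")
    diff = sample.v - control.v
    clamped = diff < 0
    return RateSeries(
        S=sample.S.copy(),
        v=np.where(clamped, 0.0, diff),
        grouping=None if sample.grouping is None else sample.grouping.copy(),
        clamped=clamped,
    )


def _hanes_woolf_init(S: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """(K_M, Vmax) start values from the S/v vs S regression.

    Hanes-Woolf: S/v = S/Vmax + K_M/Vmax, so slope = 1/Vmax and
    intercept = K_M/Vmax.  Points with v <= 0 or S <= 0 are excluded.
    Falls back to (median S, max v) when the regression is degenerate.
    """
    ok = (v > 0) & (S > 0)
    fallback = (float(np.median(S[S > 0])) or 1.0, float(v.max()) or 1.0)
    if ok.sum() < 2:
        return fallback
    slope, intercept = np.polyfit(S[ok], S[ok] / v[ok], 1)
    if slope <= 0 or intercept <= 0:
        return fallback
    vmax0 = 1.0 / slope
    km0 = intercept * vmax0
    return km0, vmax0


def fit_mm(series: RateSeries, max_iter: int = 10_000) -> MMFit:
    """Fit v = Vmax*S/(K_M+S) by unweighted nonlinear least squares.

    Replicates are pooled (each observation enters the residual sum
    once).  Requires >= 3 distinct substrate levels; at least one level
    below and one above the eventual K_M estimate is recommended for a
    well-conditioned fit.  Standard errors come from the Jacobian-based
    covariance estimate.
    """
    S, v = series.S, series.v
    if len(np.unique(S)) < 3:
        raise ValueError("fit_mm requires >= 3 distinct substrate levels")
    if np.all(v == 0):
        raise ValueError("all velocities are zero; nothing to fit")

    km0, vmax0 = _hanes_woolf_init(S, v)

    def model(s, km, vmax):
        return vmax * s / (km + s)

    try:
        popt, pcov = curve_fit(
            model,
            S,
            v,
            p0=[km0, vmax0],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            xtol=1e-8,
            maxfev=max_iter,
        )
        converged = True
    except RuntimeError:
        popt = np.array([km0, vmax0])
        pcov = np.full((2, 2), np.nan)
        converged = False

    resid = v - model(S, *popt)
    with np.errstate(invalid="ignore"):
        se = np.sqrt(np.diag(pcov))
    return MMFit(
        km_uM=float(popt[0]),
        vmax=float(popt[1]),
        km_se=float(se[0]),
        vmax_se=float(se[1]),
        rss=float(np.sum(resid**2)),
        converged=converged,
        n_points=len(S),
    )


def medium_micromolar(spec: MediumSpec) -> tuple[float, float]:
    """Micromolar contribution of an agar impurity to the solid medium.

    A w/v agar percentage corresponds to (percent x 10) g dry agar per
    litre of medium; each gram carries ``content_ug_per_g`` micrograms of
    the element, so

        uM = content * (percent * 10) / molar_mass.

    Returns (value rounded to 2 significant figures, full precision).
    """
    grams_per_litre = spec.agar_percent_wv * 10.0
    micromolar = spec.content_ug_per_g * grams_per_litre / spec.molar_mass_g_mol
    if micromolar == 0:
        return 0.0, 0.0
    from math import floor, log10

    ndigits = 1 - int(floor(log10(abs(micromolar))))
    return round(micromolar, ndigits), micromolar
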