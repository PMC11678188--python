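"""Synthetic instrument data with known ground truth.

Every downstream stage (DSC reduction, spectral decomposition, van't Hoff
inference) is exercised against data generated here, so the generators are
first-class, tested code.

* ``generate_two_state_thermogram`` — the unique excess-heat-capacity
  lineshape of a two-state transition whose peak height obeys
  ``Cp_max = dHcal dHvH / (4 R Tm^2)``, plus an optional Gaussian
  pretransition, a polynomial baseline and i.i.d. Gaussian noise.
* ``generate_nitroxide_spectrum`` — a three-line first-derivative
  pseudo-Voigt stand-in for a nitroxide spectrum (isotropic hyperfine
  splitting A, per-line peak-to-peak widths).
* ``generate_two_component_series`` — a temperature series of
  two-component spectra whose mixing fractions follow a cubic
  ``ln K = a + b/T + c/T^2 + d/T^3`` law, the exact fractions returned as
  ground truth.

Default series conditions emulate the gel-fluid coexistence window of a
DPPC bilayer (300-313 K) with a pronounced sigmoidal van't Hoff plot.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

from ._constants import R_KCAL, kelvin_to_celsius
from .dsc import Thermogram
from .esr import EsrSpectrum, PopulationSeries

__all__ = [
    "ThermogramSpec",
    "NitroxideComponentModel",
    "SeriesSpec",
    "generate_two_state_thermogram",
    "generate_nitroxide_spectrum",
    "nitroxide_component_trace",
    "generate_two_component_series",
    "protonation_fraction",
    "default_thermogram_spec",
    "default_series_spec",
    "ORDERED_COMPONENT",
    "DISORDERED_COMPONENT",
]


@dataclass
class ThermogramSpec:
    """Ground truth for a synthetic DSC scan.

    ``baseline_coeffs`` are ascending polynomial coefficients in
    ``(T - Tm_main)`` (kcal mol^-1 K^-1); ``pre_width`` is the Gaussian
    sigma of the pretransition peak (K).
    """

    Tm_main: float
    dHcal: float
    dHvH: float
    T_grid: np.ndarray
    Tp_pre: float | None = None
    dHpre: float = 0.0
    pre_width: float = 0.5
    baseline_coeffs: Sequence[float] = (0.0,)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.T_grid = np.asarray(self.T_grid, dtype=float)
        if self.dHcal < 0 or self.dHvH <= 0:
            raise ValueError("dHcal must be >= 0 and dHvH > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not np.all(np.diff(self.T_grid) > 0):
            raise ValueError("T_grid must be strictly increasing")
        if not (self.T_grid[0] < self.Tm_main < self.T_grid[-1]):
            raise ValueError("T_grid must span Tm_main")


@dataclass
class NitroxideComponentModel:
    """Three-line pseudo-Voigt component: center field and isotropic
    hyperfine spacing A (gauss), per-line peak-to-peak widths (gauss),
    overall amplitude, and the Gaussian fraction of the pseudo-Voigt mix."""

    center_field: float
    hyperfine_A: float
    widths: tuple[float, float, float]
    amplitude: float = 1.0
    gauss_fraction: float = 0.5

    def __post_init__(self):
        if self.hyperfine_A <= 0:
            raise ValueError("hyperfine_A must be positive")
        if any(w <= 0 for w in self.widths):
            raise ValueError("all linewidths must be positive")
        if not 0.0 <= self.gauss_fraction <= 1.0:
            raise ValueError("gauss_fraction must lie in [0, 1]")


@dataclass
class SeriesSpec:
    """Ground truth for a two-component temperature series.

    ``vh_coeffs = (a, b, c, d)`` are the van't Hoff polynomial coefficients
    (units 1, K, K^2, K^3); ``noise_sd`` is the Gaussian noise level as a
    fraction of the maximum clean amplitude; ``model_T_drift`` optionally
    applies linear temperature drifts ``(dA_dT, dwidth_dT)`` in G/K to both
    component models around the series midpoint.
    """

    temperatures: np.ndarray
    vh_coeffs: tuple[float, float, float, float]
    ordered_model: NitroxideComponentModel
    disordered_model: NitroxideComponentModel
    Kp: float = 1.0
    model_T_drift: tuple[float, float] | None = None
    noise_sd: float = 0.0
    seed: int = 0
    field_grid: np.ndarray | None = None

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        if not np.all(np.diff(self.temperatures) > 0):
            raise ValueError("temperatures must be strictly increasing")
        if self.Kp <= 0:
            raise ValueError("Kp must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.field_grid is None:
            lo = min(m.center_field - 2.5 * m.hyperfine_A
                     for m in (self.ordered_model, self.disordered_model))
            hi = max(m.center_field + 2.5 * m.hyperfine_A
                     for m in (self.ordered_model, self.disordered_model))
            self.field_grid = np.linspace(lo, hi, 1024)
        else:
            self.field_grid = np.asarray(self.field_grid, dtype=float)


# ---------------------------------------------------------------------------
# thermograms


def generate_two_state_thermogram(spec: ThermogramSpec) -> Thermogram:
    """Synthesize a DSC scan from a two-state transition.

    ``Cp(T) = dHcal (dHvH / R T^2) K/(1+K)^2`` with
    ``K(T) = exp[-(dHvH/R)(1/T - 1/Tm)]`` integrates exactly to ``dHcal``
    and peaks at ``dHcal dHvH / (4 R Tm^2)``.
    """
    T = spec.T_grid
    lnK = -(spec.dHvH / R_KCAL) * (1.0 / T - 1.0 / spec.Tm_main)
    # K/(1+K)^2 written via sech^2 for overflow safety
    fluct = 0.25 / np.cosh(0.5 * lnK) ** 2
    cp = spec.dHcal * (spec.dHvH / (R_KCAL * T ** 2)) * fluct
    if spec.Tp_pre is not None and spec.dHpre != 0.0:
        s = spec.pre_width
        cp = cp + spec.dHpre / (s * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((T - spec.Tp_pre) / s) ** 2)
    cp = cp + np.polynomial.polynomial.polyval(
        T - spec.Tm_main, np.asarray(spec.baseline_coeffs, dtype=float))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        cp = cp + rng.normal(0.0, spec.noise_sd, T.shape)
    meta = {
        "kind": "thermogram",
        "ground_truth": {
            "Tm_main": spec.Tm_main, "dHcal": spec.dHcal,
            "dHvH": spec.dHvH, "Tp_pre": spec.Tp_pre,
            "dHpre": spec.dHpre, "noise_sd": spec.noise_sd,
            "seed": spec.seed,
        },
    }
    return Thermogram(T, cp, meta)


# ---------------------------------------------------------------------------
# nitroxide spectra


def _gaussian_deriv(t, w):
    # unit-area absorption; w is the derivative peak-to-peak width
    sig = w / 2.0
    return -(t / (sig ** 3 * np.sqrt(2.0 * np.pi))) * np.exp(
        -0.5 * (t / sig) ** 2)


def _lorentzian_deriv(t, w):
    gam = np.sqrt(3.0) / 2.0 * w
    return -(2.0 / np.pi) * gam * t / (t ** 2 + gam ** 2) ** 2


def nitroxide_component_trace(model: NitroxideComponentModel,
                              field_grid: np.ndarray) -> np.ndarray:
    """First-derivative intensity of one component on ``field_grid``."""
    B = np.asarray(field_grid, dtype=float)
    centers = (model.center_field - model.hyperfine_A, model.center_field,
               model.center_field + model.hyperfine_A)
    gf = model.gauss_fraction
    y = np.zeros_like(B)
    for B0, w in zip(centers, model.widths):
        t = B - B0
        y += gf * _gaussian_deriv(t, w) + (1 - gf) * _lorentzian_deriv(t, w)
    return model.amplitude * y


def generate_nitroxide_spectrum(model: NitroxideComponentModel, field_grid,
                                temperature_C: float | None = None,
                                label: str = "") -> EsrSpectrum:
    """Three-line first-derivative pseudo-Voigt spectrum of one component."""
    B = np.asarray(field_grid, dtype=float)
    if not np.all(np.diff(B) > 0):
        raise ValueError("field_grid must be strictly increasing")
    if (B[0] > model.center_field - 2 * model.hyperfine_A or
            B[-1] < model.center_field + 2 * model.hyperfine_A):
        raise ValueError("field_grid must span center_field +/- 2 A")
    y = nitroxide_component_trace(model, B)
    return EsrSpectrum(B, y, temperature_C=temperature_C, label=label,
                       metadata={"kind": "spectrum"})


def _unit_area(field, deriv):
    absorption = cumulative_trapezoid(deriv, field, initial=0.0)
    return deriv / np.trapezoid(absorption, field)


def _drifted(model: NitroxideComponentModel, dT: float,
             drift: tuple[float, float] | None) -> NitroxideComponentModel:
    if drift is None or dT == 0.0:
        return model
    dA, dw = drift
    return NitroxideComponentModel(
        center_field=model.center_field,
        hyperfine_A=model.hyperfine_A + dA * dT,
        widths=tuple(w + dw * dT for w in model.widths),
        amplitude=model.amplitude, gauss_fraction=model.gauss_fraction)


def vant_hoff_ln_K(T, coeffs):
    """ln K = a + b/T + c/T^2 + d/T^3."""
    a, b, c, d = coeffs
    u = 1.0 / np.asarray(T, dtype=float)
    return a + b * u + c * u ** 2 + d * u ** 3


def generate_two_component_series(spec: SeriesSpec):
    """Temperature series of ordered/disordered mixtures.

    At each temperature ``ln K`` follows the cubic law, the disordered
    fraction is ``P_dis = K/(Kp + K)`` (the probe-partition relation
    ``K = Kp P_dis/P_ord`` inverted), and the spectrum is the fraction-
    weighted sum of the two area-normalized component traces plus noise.

    Returns ``(spectra, populations)`` where ``populations`` is the exact
    ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    B = spec.field_grid
    Tmid = float(spec.temperatures.mean())
    lnK = vant_hoff_ln_K(spec.temperatures, spec.vh_coeffs)
    # P_dis/P_ord = K/Kp
    P_dis = 1.0 / (1.0 + spec.Kp * np.exp(-lnK))
    P_ord = 1.0 - P_dis
    spectra = []
    for T, po, pd_ in zip(spec.temperatures, P_ord, P_dis):
        om = _drifted(spec.ordered_model, T - Tmid, spec.model_T_drift)
        dm = _drifted(spec.disordered_model, T - Tmid, spec.model_T_drift)
        bo = _unit_area(B, nitroxide_component_trace(om, B))
        bd = _unit_area(B, nitroxide_component_trace(dm, B))
        clean = po * bo + pd_ * bd
        y = clean
        if spec.noise_sd > 0:
            y = clean + rng.normal(0.0, spec.noise_sd * np.abs(clean).max(),
                                   B.shape)
        spectra.append(EsrSpectrum(
            B.copy(), y, temperature_C=kelvin_to_celsius(float(T)),
            metadata={"kind": "spectrum", "ground_truth": {
                "P_ordered": float(po), "P_disordered": float(pd_),
                "seed": spec.seed}}))
    pops = PopulationSeries(spec.temperatures.copy(), P_ord, P_dis,
                            np.zeros_like(P_dis))
    return spectra, pops


def protonation_fraction(pH: float, pKa: float) -> float:
    """Henderson-Hasselbalch fraction of the monoprotic acid form:
    ``1/(1 + 10^(pH - pKa))``."""
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


# ---------------------------------------------------------------------------
# default study conditions


#: Broad, strongly split component emulating gel-phase (ordered) lipids.
ORDERED_COMPONENT = NitroxideComponentModel(
    center_field=3350.0, hyperfine_A=28.0, widths=(5.0, 5.0, 7.0),
    amplitude=1.0, gauss_fraction=0.3)

#: Narrow three-line component emulating fluid-phase (disordered) lipids.
DISORDERED_COMPONENT = NitroxideComponentModel(
    center_field=3350.0, hyperfine_A=15.2, widths=(1.6, 1.6, 2.2),
    amplitude=1.0, gauss_fraction=0.2)


def default_thermogram_spec(noise_sd: float = 0.0, seed: int = 0,
                            step_K: float = 0.005) -> ThermogramSpec:
    """DPPC-like main transition: Tm = 314.15 K, dHcal = 8.74 kcal/mol,
    dHvH = 2930 kcal/mol, pretransition near 307.15 K."""
    return ThermogramSpec(
        Tm_main=314.15, dHcal=8.74, dHvH=2930.0,
        T_grid=np.arange(300.0, 322.0 + step_K / 2, step_K),
        Tp_pre=307.15, dHpre=1.2, pre_width=0.6,
        baseline_coeffs=(0.0,), noise_sd=noise_sd, seed=seed)


def default_vh_coeffs(T_lo: float = 300.0, T_hi: float = 313.2):
    """Cubic van't Hoff coefficients for a DPPC-like sigmoid.

    Constructed in a centered 1/T basis so that over the coexistence
    window [T_lo, T_hi] the ln K curve runs from about -2.55 (ordered
    dominates, cold end) to about +0.85 (disordered dominates, hot end)
    with steep flanks and a mid-window plateau, the shape characteristic
    of a strongly cubic van't Hoff plot.
    """
    u_hi, u_lo = 1.0 / T_lo, 1.0 / T_hi
    u0 = 0.5 * (u_hi + u_lo)
    dmax = 0.5 * (u_hi - u_lo)
    alpha, beta_d, gamma_d, eta_d = -1.1, -0.6, 0.25, -1.1
    beta = beta_d / dmax
    gamma = gamma_d / dmax ** 2
    eta = eta_d / dmax ** 3
    d = eta
    c = gamma - 3.0 * eta * u0
    b = beta - 2.0 * gamma * u0 + 3.0 * eta * u0 ** 2
    a = alpha - beta * u0 + gamma * u0 ** 2 - eta * u0 ** 3
    return (a, b, c, d)


def default_series_spec(noise_sd: float = 0.0, seed: int = 0) -> SeriesSpec:
    """Study conditions for the synthetic coexistence series: 27
    temperatures at 0.5 K steps across 300-313 K, the default cubic
    van't Hoff law, Kp = 1, and the two default component models."""
    return SeriesSpec(
        temperatures=np.arange(300.0, 313.0 + 0.25, 0.5),
        vh_coeffs=default_vh_coeffs(),
        ordered_model=ORDERED_COMPONENT,
        disordered_model=DISORDERED_COMPONENT,
        Kp=1.0, noise_sd=noise_sd, seed=seed)
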