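"""Non-linear van't Hoff analysis of gel-fluid phase coexistence.

The equilibrium constant between lipids in the disordered and ordered
phases is obtained from spin-probe populations through the probe partition
coefficient Kp:

    K(T) = Kp * P_disordered / P_ordered

A curved van't Hoff plot, ln K vs 1/T, is fitted with a polynomial in
u = 1/T up to cubic order,

    ln K = a + b u + c u^2 + d u^3,

from which the transfer thermodynamics follow analytically (R in
cal mol^-1 K^-1, all outputs in cal-based units):

    dG(T) = -R T ln K
    dH(T) = -R (b + 2 c u + 3 d u^2)          (van't Hoff derivative)
    dS(T) = (dH - dG)/T
    dC(T) = R (2 c u^2 + 6 d u^3)             (analytic d(dH)/dT)

Special temperatures are the roots of dG (phase equilibrium, ln K = 0)
and of dS (stationary points of dG).  Entropy-enthalpy compensation is
quantified by regressing dH on dS (the slope is the compensation
temperature) and dH on T dS (slope near 1 signals compensation).
Uncertainty comes from a residual-resampling bootstrap of the polynomial
fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import f as f_dist

from ._constants import R_CAL
from .esr import PopulationSeries

__all__ = [
    "VantHoffModel",
    "ThermoCurves",
    "CompensationResult",
    "BootstrapBands",
    "ln_equilibrium_constant",
    "fit_vant_hoff",
    "select_degree",
    "thermodynamic_curves",
    "compensation_analysis",
    "bootstrap_uncertainty",
]


@dataclass
class VantHoffModel:
    """Polynomial van't Hoff model ln K = a + b u + c u^2 + d u^3, u = 1/T.

    ``coeffs`` always holds (a, b, c, d) with coefficients above ``degree``
    set to zero; ``covariance`` is the 4x4 covariance in the same raw
    basis (rows/columns of unused coefficients are zero).
    """

    Kp: float
    degree: int
    coeffs: tuple[float, float, float, float]
    covariance: np.ndarray
    T_range: tuple[float, float]
    n_points: int
    rss: float
    adj_r2: float

    def __post_init__(self):
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")
        if not self.T_range[0] < self.T_range[1]:
            raise ValueError("T_range must be a nonempty interval")

    def ln_K(self, T):
        a, b, c, d = self.coeffs
        u = 1.0 / np.asarray(T, dtype=float)
        return a + b * u + c * u ** 2 + d * u ** 3


@dataclass
class ThermoCurves:
    """dG, dH (cal/mol), dS, dC (cal mol^-1 K^-1) on a temperature grid,
    plus the special temperatures: ``("G_root", T)`` where dG = 0 and
    ``("S_zero", T)`` where dS = 0."""

    T_grid: np.ndarray
    dG: np.ndarray
    dH: np.ndarray
    dS: np.ndarray
    dC: np.ndarray
    special: list = field(default_factory=list)


@dataclass
class CompensationResult:
    slope: float            # compensation temperature, K (dH vs dS)
    intercept: float        # cal/mol
    slope_H_vs_TdS: float   # ~1 when compensation holds
    compensation_T: float


@dataclass
class BootstrapBands:
    """Percentile bands (2.5/97.5) for each curve and coefficient CIs."""

    T_grid: np.ndarray
    bands: dict           # name -> (lo, hi) arrays for dG, dH, dS, dC
    coeff_ci: np.ndarray  # (4, 2): per-coefficient percentile interval
    n_boot: int
    seed: int


# ---------------------------------------------------------------------------


def ln_equilibrium_constant(series: PopulationSeries, Kp: float = 1.0,
                            exclusion_threshold: float = 0.02) -> pd.DataFrame:
    """Van't Hoff table from a population series.

    ``ln K = ln(Kp P_disordered / P_ordered)`` for every temperature where
    both fractions are at least ``exclusion_threshold`` (the logit diverges
    outside the coexistence window); excluded rows are kept in the table
    with ``included = False``.
    """
    if Kp <= 0:
        raise ValueError("Kp must be positive")
    ok = ((series.P_ordered >= exclusion_threshold) &
          (series.P_disordered >= exclusion_threshold))
    if not ok.any():
        raise ValueError("all rows excluded; no coexistence window")
    with np.errstate(divide="ignore"):
        lnk = np.log(Kp) + np.log(series.P_disordered) - np.log(
            series.P_ordered)
    return pd.DataFrame({
        "temperature_K": series.temperature_K,
        "inv_T_K": 1.0 / series.temperature_K,
        "ln_K": lnk,
        "included": ok,
    })


def _design(u_centered, degree):
    return np.vander(u_centered, degree + 1, increasing=True)


def _raw_basis_transform(u_mean, degree):
    """Matrix T with raw = T @ centered for ln K = sum beta_k (u - u0)^k."""
    from math import comb
    T = np.zeros((degree + 1, degree + 1))
    for k in range(degree + 1):
        for j in range(k + 1):
            T[j, k] = comb(k, j) * (-u_mean) ** (k - j)
    return T


def fit_vant_hoff(table: pd.DataFrame, degree: int) -> VantHoffModel:
    """Ordinary least squares of ln K on powers of u = 1/T.

    The fit is performed in a mean-centered u basis for conditioning (u
    spans ~1e-4 K^-1) and the coefficients mapped back to the raw basis.
    """
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    sub = table[table["included"]] if "included" in table else table
    u = sub["inv_T_K"].to_numpy(dtype=float)
    y = sub["ln_K"].to_numpy(dtype=float)
    n = u.size
    if n < degree + 2:
        raise ValueError("need at least degree + 2 points")
    u0 = u.mean()
    X = _design(u - u0, degree)
    if np.linalg.matrix_rank(X) < degree + 1:
        raise ValueError("rank-deficient design (degenerate temperatures)")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    dof = n - (degree + 1)
    sigma2 = rss / dof if dof > 0 else np.nan
    cov_beta = sigma2 * np.linalg.inv(X.T @ X)
    T = _raw_basis_transform(u0, degree)
    raw = T @ beta
    cov_raw = T @ cov_beta @ T.T
    coeffs = np.zeros(4)
    coeffs[:degree + 1] = raw
    cov4 = np.zeros((4, 4))
    cov4[:degree + 1, :degree + 1] = cov_raw
    tss = float(((y - y.mean()) ** 2).sum())
    adj_r2 = 1.0 - (rss / dof) / (tss / (n - 1)) if tss > 0 and dof > 0 else np.nan
    Tk = sub["temperature_K"].to_numpy(dtype=float)
    return VantHoffModel(Kp=1.0, degree=degree, coeffs=tuple(coeffs),
                         covariance=cov4,
                         T_range=(float(Tk.min()), float(Tk.max())),
                         n_points=n, rss=rss, adj_r2=float(adj_r2))


def select_degree(table: pd.DataFrame, candidate_degrees=(1, 2, 3),
                  alpha: float = 0.01) -> int:
    """Choose the polynomial degree by incremental F-tests.

    Returns the highest candidate whose fit improves significantly
    (p < ``alpha``) on the next-lower candidate; ties (equal residuals)
    break toward the lower degree.
    """
    degrees = sorted(set(candidate_degrees))
    if len(degrees) < 2:
        raise ValueError("need at least two candidate degrees")
    fits = {k: fit_vant_hoff(table, k) for k in degrees}
    chosen = degrees[0]
    for lo, hi in zip(degrees[:-1], degrees[1:]):
        rss_lo, rss_hi = fits[lo].rss, fits[hi].rss
        n = fits[hi].n_points
        extra = hi - lo
        df2 = n - (hi + 1)
        if rss_hi >= rss_lo or df2 <= 0:
            continue
        if rss_hi == 0:
            p = 0.0
        else:
            F = ((rss_lo - rss_hi) / extra) / (rss_hi / df2)
            p = float(f_dist.sf(F, extra, df2))
        if p < alpha:
            chosen = hi
    return chosen


# ---------------------------------------------------------------------------
# thermodynamic curves


def _curves_from_coeffs(coeffs, T):
    a, b, c, d = coeffs
    u = 1.0 / T
    lnK = a + b * u + c * u ** 2 + d * u ** 3
    dG = -R_CAL * T * lnK
    dH = -R_CAL * (b + 2 * c * u + 3 * d * u ** 2)
    dS = (dH - dG) / T
    dC = R_CAL * (2 * c * u ** 2 + 6 * d * u ** 3)
    return dG, dH, dS, dC


def _bracketed_roots(f, T_lo, T_hi, mesh=0.01):
    """All sign-change roots of f on [T_lo, T_hi], located by bisection on
    a ``mesh``-kelvin scan."""
    Ts = np.arange(T_lo, T_hi + mesh / 2, mesh)
    vals = f(Ts)
    roots = []
    for i in range(len(Ts) - 1):
        v0, v1 = vals[i], vals[i + 1]
        if v0 == 0.0:
            roots.append(float(Ts[i]))
        elif v0 * v1 < 0:
            roots.append(float(brentq(f, Ts[i], Ts[i + 1])))
    if vals[-1] == 0.0:
        roots.append(float(Ts[-1]))
    return roots


def thermodynamic_curves(model: VantHoffModel, T_grid) -> ThermoCurves:
    """Evaluate dG, dH, dS, dC on ``T_grid`` (inside the model's T_range)
    and locate the special temperatures."""
    T = np.asarray(T_grid, dtype=float)
    lo, hi = model.T_range
    if T.min() < lo - 1e-9 or T.max() > hi + 1e-9:
        raise ValueError("T_grid extends outside the model's T_range")
    dG, dH, dS, dC = _curves_from_coeffs(model.coeffs, T)
    special = []

    def dS_fun(t):
        return _curves_from_coeffs(model.coeffs, np.asarray(t, dtype=float))[2]

    for r in _bracketed_roots(model.ln_K, lo, hi):
        special.append(("G_root", r))
    for r in _bracketed_roots(dS_fun, lo, hi):
        special.append(("S_zero", r))
    return ThermoCurves(T_grid=T, dG=dG, dH=dH, dS=dS, dC=dC,
                        special=special)


def compensation_analysis(curves: ThermoCurves) -> CompensationResult:
    """Entropy-enthalpy compensation regressions.

    The slope of dH on dS is the compensation temperature (K); the slope
    of dH on T dS is ~1 when |dG| is small compared with the enthalpic
    scale (compensation holds).
    """
    dS, dH, T = curves.dS, curves.dH, curves.T_grid
    if dS.size < 5:
        raise ValueError("need at least 5 grid points")
    if np.ptp(dS) < 1e-12 * max(1.0, np.abs(dS).max()):
        raise ValueError("dS is constant; compensation slope undefined")
    slope, intercept = np.polyfit(dS, dH, 1)
    tds = T * dS
    slope2 = np.polyfit(tds, dH, 1)[0] if np.ptp(tds) > 0 else np.nan
    return CompensationResult(slope=float(slope), intercept=float(intercept),
                              slope_H_vs_TdS=float(slope2),
                              compensation_T=float(slope))


def bootstrap_uncertainty(table: pd.DataFrame, model: VantHoffModel,
                          n_boot: int = 1000, seed: int = 0,
                          T_grid=None) -> BootstrapBands:
    """Residual-resampling bootstrap of the van't Hoff fit.

    Residuals of the fitted model are resampled with replacement, added to
    the fitted values, and the polynomial refitted; 2.5/97.5 percentile
    bands are reported for every thermodynamic curve and coefficient.
    Bit-reproducible for a fixed seed.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    sub = table[table["included"]] if "included" in table else table
    u = sub["inv_T_K"].to_numpy(dtype=float)
    if T_grid is None:
        T_grid = np.linspace(model.T_range[0], model.T_range[1], 101)
    T_grid = np.asarray(T_grid, dtype=float)
    yhat = model.ln_K(1.0 / u)
    resid = sub["ln_K"].to_numpy(dtype=float) - yhat
    rng = np.random.default_rng(seed)
    coefs = np.empty((n_boot, 4))
    curves = {k: np.empty((n_boot, T_grid.size)) for k in
              ("dG", "dH", "dS", "dC")}
    boot_table = sub.copy()
    for i in range(n_boot):
        boot_table = pd.DataFrame({
            "temperature_K": sub["temperature_K"].to_numpy(),
            "inv_T_K": u,
            "ln_K": yhat + rng.choice(resid, size=resid.size, replace=True),
            "included": np.ones(resid.size, dtype=bool),
        })
        m = fit_vant_hoff(boot_table, model.degree)
        coefs[i] = m.coeffs
        dG, dH, dS, dC = _curves_from_coeffs(m.coeffs, T_grid)
        curves["dG"][i], curves["dH"][i] = dG, dH
        curves["dS"][i], curves["dC"][i] = dS, dC
    bands = {k: (np.percentile(v, 2.5, axis=0), np.percentile(v, 97.5, axis=0))
             for k, v in curves.items()}
    coeff_ci = np.column_stack([np.percentile(coefs, 2.5, axis=0),
                                np.percentile(coefs, 97.5, axis=0)])
    return BootstrapBands(T_grid=T_grid, bands=bands, coeff_ci=coeff_ci,
                          n_boot=n_boot, seed=seed)
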