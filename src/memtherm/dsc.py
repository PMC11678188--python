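"""DSC thermogram processing: baseline subtraction, melting-transition
thermodynamics, and the ligand-partitioning melting-point-depression fit.

The excess heat capacity curve Cp(T) of a lipid main transition is reduced
to the standard calorimetric parameters:

* ``Tm`` — temperature of the Cp maximum (parabolically refined),
* ``dHcal`` — calorimetric enthalpy, the area under Cp over the transition,
* ``dTm_half`` — full width of the peak at half of ``Cp_max``,
* ``dS_at_Tm = dHcal / Tm`` — transition entropy,
* ``dHvH = 4 R Tm^2 Cp_max / dHcal`` — van't Hoff enthalpy from peak
  sharpness,
* ``CUS = dHvH / dHcal`` — cooperative unit size, the mean number of lipids
  melting as one unit.

A two-state ligand-partitioning model relates the depression of Tm with
drug:lipid mole ratio to the ratio of the drug's binding constants to the
fluid (KF) and gel (KG) phases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from ._constants import R_KCAL, celsius_to_kelvin, kelvin_to_celsius

__all__ = [
    "Thermogram",
    "DSCTransitionResult",
    "BindingModelResult",
    "subtract_baseline",
    "analyze_thermogram",
    "entropy_at_Tm",
    "vant_hoff_enthalpy",
    "cooperative_unit",
    "fit_tm_depression",
]


@dataclass
class Thermogram:
    """One DSC scan: temperature (K, strictly increasing) vs excess heat
    capacity (kcal mol^-1 K^-1), with free-form metadata (scan rate,
    lipid concentration, label, provenance...)."""

    temperature_K: np.ndarray
    cp: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature_K = np.asarray(self.temperature_K, dtype=float)
        self.cp = np.asarray(self.cp, dtype=float)
        if self.temperature_K.shape != self.cp.shape:
            raise ValueError("temperature and cp arrays differ in length")
        if self.temperature_K.size < 50:
            raise ValueError("a thermogram needs at least 50 points")
        if not np.all(np.diff(self.temperature_K) > 0):
            raise ValueError("temperature axis must be strictly increasing")

    @classmethod
    def from_celsius(cls, temperature_C, cp, metadata=None):
        return cls(celsius_to_kelvin(np.asarray(temperature_C, dtype=float)),
                   cp, metadata or {})

    @property
    def temperature_C(self):
        return kelvin_to_celsius(self.temperature_K)


@dataclass
class DSCTransitionResult:
    """Calorimetric parameters of a single melting endotherm.

    Temperatures are reported in Celsius, enthalpies in kcal/mol, the
    entropy in cal/(mol K), matching the conventional table layout.
    """

    Tm_C: float
    dHcal: float
    Cp_max: float
    dTm_half_C: float | None
    dS_at_Tm: float
    dHvH: float
    CUS: float
    Tp_C: float | None = None


@dataclass
class BindingModelResult:
    """Gel/fluid binding constants of a membrane-partitioning ligand from
    the Tm-depression fit, with the ratio KF/KG and its uncertainty."""

    KG: float
    KF: float
    ratio_KF_KG: float
    ratio_stderr: float | None
    covariance: np.ndarray | None
    model_id: str
    unbounded: bool = False


# ---------------------------------------------------------------------------
# baseline handling


def _window_mask(t_K, window_C):
    lo, hi = sorted(window_C)
    return (t_K >= celsius_to_kelvin(lo)) & (t_K <= celsius_to_kelvin(hi))


def subtract_baseline(raw: Thermogram, buffer: Thermogram | None = None,
                      windows=None, degree: int = 1) -> Thermogram:
    """Remove the instrumental baseline from a raw scan.

    If ``buffer`` is given, the buffer trace is interpolated onto the
    sample grid and subtracted first.  If ``windows`` (two ``(lo, hi)``
    temperature intervals in Celsius flanking the transition) are given, a
    polynomial of ``degree`` is fitted to the points inside them and
    removed.  The metadata of the returned trace records the method.
    """
    t = raw.temperature_K
    cp = raw.cp.copy()
    method = []
    if buffer is not None:
        cp = cp - np.interp(t, buffer.temperature_K, buffer.cp)
        method.append("buffer")
    if windows is not None:
        if len(windows) != 2:
            raise ValueError("windows must be two (lo, hi) intervals in Celsius")
        mask = _window_mask(t, windows[0]) | _window_mask(t, windows[1])
        if not mask.any():
            raise ValueError("baseline windows contain no data points")
        i_peak = int(np.argmax(cp))
        if mask[i_peak]:
            warnings.warn("baseline window overlaps the transition peak",
                          stacklevel=2)
        # centered abscissa keeps the Vandermonde well conditioned
        t0 = t.mean()
        coef = np.polynomial.polynomial.polyfit(t[mask] - t0, cp[mask], degree)
        cp = cp - np.polynomial.polynomial.polyval(t - t0, coef)
        method.append(f"poly{degree}")
    meta = dict(raw.metadata)
    meta["baseline"] = "+".join(method) if method else "none"
    return Thermogram(t, cp, meta)


# ---------------------------------------------------------------------------
# single-peak analysis


def _refined_peak(t, y):
    """Parabolic refinement of the discrete maximum through its 3 points.

    Returns (t_peak, y_peak). Falls back to the discrete maximum at the
    array edges.
    """
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return float(t[i]), float(y[i])
    x0, x1, x2 = t[i - 1:i + 2]
    y0, y1, y2 = y[i - 1:i + 2]
    denom = (y0 - 2 * y1 + y2)
    if denom >= 0:  # not a local max in the quadratic sense
        return float(t[i]), float(y[i])
    # assumes a locally uniform grid step, true for instrument scans
    h = 0.5 * (x2 - x0)
    delta = 0.5 * (y0 - y2) / denom
    t_pk = x1 + delta * h
    y_pk = y1 - 0.25 * (y0 - y2) * delta
    return float(t_pk), float(y_pk)


def _half_width(t, y, y_half):
    """Full width at ``y_half`` by linear interpolation on both flanks.

    Returns None when the half level is not bracketed on both sides of the
    maximum (reported missing rather than guessed).
    """
    i = int(np.argmax(y))
    left = right = None
    for j in range(i, 0, -1):
        if y[j - 1] <= y_half <= y[j]:
            frac = (y_half - y[j - 1]) / (y[j] - y[j - 1])
            left = t[j - 1] + frac * (t[j] - t[j - 1])
            break
    for j in range(i, len(y) - 1):
        if y[j + 1] <= y_half <= y[j]:
            frac = (y[j] - y_half) / (y[j] - y[j + 1])
            right = t[j] + frac * (t[j + 1] - t[j])
            break
    if left is None or right is None:
        return None
    return float(right - left)


def entropy_at_Tm(dHcal: float, Tm_K: float) -> float:
    """Transition entropy dS = dHcal/Tm in cal/(mol K).

    ``dHcal`` in kcal/mol, ``Tm_K`` in kelvin.
    """
    if Tm_K <= 0:
        raise ValueError("Tm must be positive (kelvin)")
    return 1000.0 * dHcal / Tm_K


def vant_hoff_enthalpy(Cp_max: float, Tm_K: float, dHcal: float) -> float:
    """Van't Hoff enthalpy dHvH = 4 R Tm^2 Cp_max / dHcal (kcal/mol)."""
    if dHcal == 0:
        raise ValueError("dHcal must be nonzero")
    return 4.0 * R_KCAL * Tm_K ** 2 * Cp_max / dHcal


def cooperative_unit(dHvH: float, dHcal: float) -> float:
    """Cooperative unit size CUS = dHvH/dHcal (number of molecules)."""
    if dHcal == 0:
        raise ValueError("dHcal must be nonzero")
    return dHvH / dHcal


def analyze_thermogram(processed: Thermogram, main_window,
                       pre_window=None) -> DSCTransitionResult:
    """Reduce a baseline-subtracted thermogram to its transition parameters.

    ``main_window`` and ``pre_window`` are ``(lo, hi)`` intervals in
    Celsius; the main window must contain one dominant positive peak.
    """
    t = processed.temperature_K
    cp = processed.cp
    mask = _window_mask(t, main_window)
    if mask.sum() < 5:
        raise ValueError("main window contains too few points")
    tw, cw = t[mask], cp[mask]
    if cw.max() <= 0:
        raise ValueError("no positive peak inside the main window")
    Tm_K, Cp_max = _refined_peak(tw, cw)
    dHcal = float(np.trapezoid(cw, tw))
    width = _half_width(tw, cw, Cp_max / 2.0)
    Tp_C = None
    if pre_window is not None:
        pmask = _window_mask(t, pre_window)
        if pmask.sum() >= 3 and cp[pmask].max() > 0:
            Tp_K, _ = _refined_peak(t[pmask], cp[pmask])
            Tp_C = kelvin_to_celsius(Tp_K)
    dS = entropy_at_Tm(dHcal, Tm_K)
    dHvH = vant_hoff_enthalpy(Cp_max, Tm_K, dHcal)
    return DSCTransitionResult(
        Tm_C=kelvin_to_celsius(Tm_K),
        dHcal=dHcal,
        Cp_max=Cp_max,
        dTm_half_C=width,
        dS_at_Tm=dS,
        dHvH=dHvH,
        CUS=cooperative_unit(dHvH, dHcal),
        Tp_C=Tp_C,
    )


# ---------------------------------------------------------------------------
# melting-point depression


def tm_depression_model(x, KG, KF, dHvH0, Tm0_K):
    """Predicted 1/Tm shift for drug:lipid mole ratio ``x``.

    Two-state partitioning of the ligand between gel and fluid phases:
    ``1/Tm - 1/Tm0 = (R/dHvH0) ln[(1 + KF x)/(1 + KG x)]`` — preferential
    binding to the fluid phase (KF > KG) depresses Tm.
    """
    x = np.asarray(x, dtype=float)
    return (R_KCAL / dHvH0) * (np.log1p(KF * x) - np.log1p(KG * x))


def fit_tm_depression(mole_ratios, Tm_K_values, dHvH0: float,
                      Tm0_K: float) -> BindingModelResult:
    """Fit gel/fluid binding constants to a Tm vs mole-ratio series.

    ``mole_ratios`` are drug:lipid mole ratios (0.04 for 4 mol%), the
    series must include the drug-free reference.  ``dHvH0`` is the
    transition enthalpy of the unit that carries one set of binding
    sites: pass the van't Hoff enthalpy if the whole cooperative unit
    binds one ligand, or the per-molecule calorimetric enthalpy if every
    lipid is a site (the usual case: sites scale with the cooperative
    unit, so the enthalpy per site-carrying unit is dHcal).  Returns the
    ratio KF/KG with a covariance-derived uncertainty.  A flat Tm series
    is reported as ratio 1 with the ``unbounded`` flag instead of failing.
    """
    x = np.asarray(mole_ratios, dtype=float)
    tm = np.asarray(Tm_K_values, dtype=float)
    if x.size < 3 or x.size != tm.size:
        raise ValueError("need >= 3 matched (mole_ratio, Tm) points")
    if not np.any(x == 0):
        raise ValueError("series must include the drug-free point (x = 0)")
    y = 1.0 / tm - 1.0 / Tm0_K
    model_id = "two-state-partitioning:invTm=(R/dHvH0)*ln((1+KF*x)/(1+KG*x))"
    if np.allclose(tm, tm[0]):
        return BindingModelResult(KG=1.0, KF=1.0, ratio_KF_KG=1.0,
                                  ratio_stderr=None, covariance=None,
                                  model_id=model_id, unbounded=True)

    params = lmfit.Parameters()
    # log-parametrization enforces positivity
    params.add("logKG", value=0.0, min=-20, max=20)
    params.add("logKF", value=1.0, min=-20, max=20)

    def resid(p):
        return y - tm_depression_model(x, np.exp(p["logKG"].value),
                                       np.exp(p["logKF"].value),
                                       dHvH0, Tm0_K)

    out = lmfit.minimize(resid, params, method="leastsq")
    lg, lf = out.params["logKG"], out.params["logKF"]
    KG, KF = float(np.exp(lg.value)), float(np.exp(lf.value))
    ratio = KF / KG
    stderr = None
    cov = getattr(out, "covar", None)
    if cov is not None:
        # delta method on log ratio: var(logKF - logKG)
        var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
        if var >= 0:
            stderr = float(ratio * np.sqrt(var))
    return BindingModelResult(KG=KG, KF=KF, ratio_KF_KG=float(ratio),
                              ratio_stderr=stderr, covariance=cov,
                              model_id=model_id, unbounded=False)
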