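"""Nitroxide ESR lineshape observables, two-component decomposition into
ordered/disordered populations, and the orientational order parameter.

First-derivative X-band spectra of doxyl-labelled lipids report on local
chain packing: in the fluid phase the spectrum is three narrow lines; in
the gel phase it is broad.  Inside the gel-fluid coexistence window the
spectrum is a superposition of the two, and the mixing fractions
(P_ordered, P_disordered) are the bridge to the phase-equilibrium
thermodynamics.  Populations here come from non-negative least squares on
two basis spectra scaled to unit absorption area (double integral of the
first-derivative trace), so the weights count spins.

The order parameter S = <(3 cos^2 theta - 1)/2> is evaluated over the
Boltzmann distribution of an orienting pseudopotential expanded in rank-2
(and optionally rank-4) spherical harmonics with coefficients c20, c22,
c40, c42, c44 (in units of kT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import nnls
from scipy.stats import f as f_dist

__all__ = [
    "EsrSpectrum",
    "LineshapeMetrics",
    "PopulationSeries",
    "OrderingPotential",
    "SingleComponentFit",
    "lineshape_metrics",
    "fit_single_component",
    "decompose_two_components",
    "build_population_series",
    "model_selection",
    "order_parameter",
]


@dataclass
class EsrSpectrum:
    """One first-derivative spectrum: magnetic field (gauss, strictly
    increasing) vs intensity (arbitrary units), tagged with the sample
    temperature in Celsius."""

    field_G: np.ndarray
    intensity: np.ndarray
    temperature_C: float | None = None
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.field_G = np.asarray(self.field_G, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.field_G.shape != self.intensity.shape:
            raise ValueError("field and intensity arrays differ in length")
        if self.field_G.size < 200:
            raise ValueError("a spectrum needs at least 200 points")
        if not np.all(np.diff(self.field_G) > 0):
            raise ValueError("field axis must be strictly increasing")


@dataclass
class LineshapeMetrics:
    """Model-free observables: outer hyperfine splitting 2Amax (gauss,
    absent when the outer extrema are unresolved), central-line
    peak-to-peak width dH0 (gauss), and the central zero crossing."""

    two_Amax: float | None
    dH0: float
    central_crossing: float


@dataclass
class PopulationSeries:
    """Ordered/disordered spin populations vs temperature (kelvin)."""

    temperature_K: np.ndarray
    P_ordered: np.ndarray
    P_disordered: np.ndarray
    residual_rms: np.ndarray

    def __post_init__(self):
        self.temperature_K = np.asarray(self.temperature_K, dtype=float)
        self.P_ordered = np.asarray(self.P_ordered, dtype=float)
        self.P_disordered = np.asarray(self.P_disordered, dtype=float)
        self.residual_rms = np.asarray(self.residual_rms, dtype=float)
        n = self.temperature_K.size
        if not (self.P_ordered.size == self.P_disordered.size ==
                self.residual_rms.size == n):
            raise ValueError("population series arrays differ in length")
        s = self.P_ordered + self.P_disordered
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValueError("populations must sum to 1")
        if np.any(self.P_ordered < -1e-12) or np.any(self.P_ordered > 1 + 1e-12):
            raise ValueError("populations must lie in [0, 1]")


@dataclass
class OrderingPotential:
    """Orienting pseudopotential coefficients, in units of kT.

    ``U/kT = -[c20 D^2_00 + c22 (D^2_02 + D^2_0-2) + c40 D^4_00
    + c42 (D^4_02 + D^4_0-2) + c44 (D^4_04 + D^4_0-4)]``.
    """

    c20: float
    c22: float = 0.0
    c40: float = 0.0
    c42: float = 0.0
    c44: float = 0.0
    temperature_K: float = 298.15

    def __post_init__(self):
        vals = (self.c20, self.c22, self.c40, self.c42, self.c44)
        if not np.all(np.isfinite(vals)):
            raise ValueError("potential coefficients must be finite")


# ---------------------------------------------------------------------------
# lineshape observables


def _zero_crossings(field, intensity, lo, hi, downward=True):
    """Fields of linear-interpolated zero crossings inside [lo, hi]."""
    s = intensity
    out = []
    for i in range(len(s) - 1):
        if field[i] < lo or field[i + 1] > hi:
            continue
        if downward and s[i] > 0 >= s[i + 1]:
            pass
        elif not downward and s[i] < 0 <= s[i + 1]:
            pass
        else:
            continue
        frac = s[i] / (s[i] - s[i + 1])
        out.append(field[i] + frac * (field[i + 1] - field[i]))
    return out


def lineshape_metrics(spec: EsrSpectrum) -> LineshapeMetrics:
    """Measure 2Amax, dH0 and the central crossing of one spectrum.

    The central line of a first-derivative nitroxide spectrum rises to a
    maximum, crosses zero going down, and falls to a minimum; dH0 is that
    max-to-min field separation.  2Amax is the field of the global
    high-field minimum minus the field of the global low-field maximum;
    it is reported absent when either extremum sits on the grid edge.
    """
    B, y = spec.field_G, spec.intensity
    span = B[-1] - B[0]
    lo, hi = B[0] + span / 3.0, B[-1] - span / 3.0
    crossings = _zero_crossings(B, y, lo, hi, downward=True)
    if not crossings:
        raise ValueError("no downward zero crossing in the central third")
    mid = 0.5 * (B[0] + B[-1])
    bc = min(crossings, key=lambda b: abs(b - mid))
    ic = int(np.searchsorted(B, bc))

    # flanking extrema of the central line, bounded by the neighbouring
    # zero crossings so the outer lines cannot capture the search
    left_seg = y[:ic]
    ups = _zero_crossings(B[:ic], y[:ic], B[0], bc, downward=False)
    lo_idx = int(np.searchsorted(B, ups[-1])) if ups else 0
    i_max = lo_idx + int(np.argmax(left_seg[lo_idx:]))
    downs_right = _zero_crossings(B[ic:], y[ic:], bc, B[-1], downward=False)
    hi_idx = int(np.searchsorted(B, downs_right[0])) if downs_right else len(B)
    i_min = ic + int(np.argmin(y[ic:hi_idx]))
    dH0 = float(B[i_min] - B[i_max])

    g_max = int(np.argmax(np.where(B < bc, y, -np.inf)))
    g_min = int(np.argmin(np.where(B > bc, y, np.inf)))
    if g_max in (0, len(B) - 1) or g_min in (0, len(B) - 1):
        two_Amax = None
    else:
        two_Amax = float(B[g_min] - B[g_max])
    return LineshapeMetrics(two_Amax=two_Amax, dH0=dH0,
                            central_crossing=float(bc))


# ---------------------------------------------------------------------------
# single-component fitting


@dataclass
class SingleComponentFit:
    model: "NitroxideComponentModel"
    residual_rms: float
    success: bool
    message: str = ""


def fit_single_component(spec: EsrSpectrum, init) -> SingleComponentFit:
    """Nonlinear least-squares fit of one three-line component.

    ``init`` is a :class:`~memtherm.synthetic.NitroxideComponentModel`
    starting point.  Non-convergence is returned as a flagged result, not
    raised.
    """
    from .synthetic import NitroxideComponentModel, nitroxide_component_trace

    B, y = spec.field_G, spec.intensity
    if not (B[0] <= init.center_field <= B[-1]):
        raise ValueError("initial center field outside the spectrum range")

    p = lmfit.Parameters()
    p.add("center", value=init.center_field, min=B[0], max=B[-1])
    p.add("A", value=init.hyperfine_A, min=1e-3)
    for k, w in enumerate(init.widths):
        p.add(f"w{k}", value=w, min=1e-3)
    p.add("amplitude", value=init.amplitude)
    p.add("gf", value=init.gauss_fraction, min=0.0, max=1.0)

    def resid(pars):
        m = NitroxideComponentModel(
            center_field=pars["center"].value, hyperfine_A=pars["A"].value,
            widths=(pars["w0"].value, pars["w1"].value, pars["w2"].value),
            amplitude=pars["amplitude"].value,
            gauss_fraction=pars["gf"].value)
        return nitroxide_component_trace(m, B) - y

    try:
        out = lmfit.minimize(resid, p, method="leastsq")
    except Exception as exc:  # pragma: no cover - defensive
        return SingleComponentFit(init, float(np.sqrt(np.mean(y ** 2))),
                                  False, str(exc))
    pr = out.params
    best = NitroxideComponentModel(
        center_field=pr["center"].value, hyperfine_A=pr["A"].value,
        widths=(pr["w0"].value, pr["w1"].value, pr["w2"].value),
        amplitude=pr["amplitude"].value, gauss_fraction=pr["gf"].value)
    rms = float(np.sqrt(np.mean(out.residual ** 2)))
    return SingleComponentFit(best, rms, bool(out.success),
                              out.message if not out.success else "")


# ---------------------------------------------------------------------------
# two-component decomposition


def _double_integral(field, deriv):
    """Absorption area of a first-derivative trace (double integral)."""
    absorption = cumulative_trapezoid(deriv, field, initial=0.0)
    return float(np.trapezoid(absorption, field))


def _area_normalized(field, deriv):
    area = _double_integral(field, deriv)
    if area == 0:
        raise ValueError("basis spectrum has zero absorption area")
    return deriv / area


def _resample(basis: EsrSpectrum, field):
    return np.interp(field, basis.field_G, basis.intensity, left=0.0, right=0.0)


def decompose_two_components(spec: EsrSpectrum, basis_ordered: EsrSpectrum,
                             basis_disordered: EsrSpectrum,
                             allow_shift: bool = False,
                             max_shift_G: float = 2.0):
    """Populations of two spectral components by non-negative least squares.

    Both bases are resampled onto the target grid and scaled to unit
    absorption area, so the NNLS weights are proportional to spin counts
    and ``P_i = w_i/(w_ordered + w_disordered)``.  With ``allow_shift`` the
    bases may be rigidly shifted along the field axis (bounded
    ``max_shift_G``, chosen by residual with ties broken toward the
    smallest shift).

    Returns ``(P_ordered, P_disordered, residual_rms)``.
    """
    B, y = spec.field_G, spec.intensity

    def bases_at(shift):
        bo = _area_normalized(B, _resample(basis_ordered, B - shift))
        bd = _area_normalized(B, _resample(basis_disordered, B - shift))
        return bo, bd

    bo0, bd0 = bases_at(0.0)
    cos = np.dot(bo0, bd0) / (np.linalg.norm(bo0) * np.linalg.norm(bd0))
    if cos > 0.999:
        raise ValueError("basis spectra are collinear; populations "
                         "unidentifiable")

    step = float(np.median(np.diff(B)))
    shifts = [0.0]
    if allow_shift:
        n = max(1, int(round(max_shift_G / step)))
        shifts = sorted((k * step for k in range(-n, n + 1)), key=abs)

    best = None
    for sh in shifts:
        bo, bd = bases_at(sh)
        w, rnorm = nnls(np.column_stack([bo, bd]), y)
        if best is None or rnorm < best[1] - 1e-15:
            best = (w, rnorm, sh)
    w, rnorm, _ = best
    total = w.sum()
    if total == 0:
        raise ValueError("both component weights vanished")
    rms = float(rnorm / np.sqrt(y.size))
    return float(w[0] / total), float(w[1] / total), rms


def model_selection(residual_1comp: float, residual_2comp: float,
                    n_points: int, extra_params: int = 1,
                    params_2comp: int = 2, alpha: float = 0.01) -> bool:
    """F-test on nested fits: is the two-component model justified?

    ``residual_*`` are RMS residuals of the one- and two-component fits of
    the same spectrum; returns True when the improvement is significant at
    ``alpha`` (default 0.01).
    """
    if residual_2comp >= residual_1comp:
        return False
    rss1 = n_points * residual_1comp ** 2
    rss2 = n_points * residual_2comp ** 2
    df2 = n_points - params_2comp
    if df2 <= 0:
        return False
    if rss2 == 0:
        return True
    F = ((rss1 - rss2) / extra_params) / (rss2 / df2)
    return bool(f_dist.sf(F, extra_params, df2) < alpha)


def _best_single_basis(y, bo, bd):
    """RMS of the best non-negative single-basis fit; returns (rms, which)."""
    out = []
    for which, b in (("ordered", bo), ("disordered", bd)):
        w = max(0.0, float(np.dot(b, y) / np.dot(b, b)))
        r = y - w * b
        out.append((float(np.sqrt(np.mean(r ** 2))), which))
    return min(out)


def build_population_series(spectra, basis_strategy: str = "endpoints",
                            bases=None, allow_shift: bool = False,
                            use_model_selection: bool = True,
                            alpha: float = 0.01) -> PopulationSeries:
    """Decompose a temperature series of spectra into populations.

    ``basis_strategy``: ``"endpoints"`` takes the coldest spectrum as the
    pure ordered basis and the hottest as the pure disordered one (valid
    when the series extends beyond the coexistence window on both sides);
    ``"supplied"`` uses ``bases=(ordered, disordered)``.  Temperatures
    where the one-component fit is statistically sufficient are assigned
    P = 0 or 1.  Spectra that cannot be decomposed are dropped with a
    warning.  The output is sorted by temperature.
    """
    if len(spectra) < 5:
        raise ValueError("need at least 5 temperatures")
    if any(s.temperature_C is None for s in spectra):
        raise ValueError("every spectrum needs a temperature tag")
    order = np.argsort([s.temperature_C for s in spectra])
    spectra = [spectra[i] for i in order]
    if basis_strategy == "endpoints":
        basis_o, basis_d = spectra[0], spectra[-1]
    elif basis_strategy == "supplied":
        if bases is None or len(bases) != 2:
            raise ValueError("supplied strategy needs bases=(ordered, "
                             "disordered)")
        basis_o, basis_d = bases
    else:
        raise ValueError(f"unknown basis strategy {basis_strategy!r}")

    T, Po, Pd, rms_list = [], [], [], []
    for s in spectra:
        try:
            po, pd_, rms = decompose_two_components(
                s, basis_o, basis_d, allow_shift=allow_shift)
        except ValueError as exc:
            warnings.warn(f"T={s.temperature_C} C dropped: {exc}",
                          stacklevel=2)
            continue
        if use_model_selection:
            bo = _area_normalized(s.field_G, _resample(basis_o, s.field_G))
            bd = _area_normalized(s.field_G, _resample(basis_d, s.field_G))
            rms1, which = _best_single_basis(s.intensity, bo, bd)
            if not model_selection(rms1, rms, s.field_G.size, alpha=alpha):
                po, pd_ = (1.0, 0.0) if which == "ordered" else (0.0, 1.0)
                rms = rms1
        T.append(s.temperature_C + 273.15)
        Po.append(po)
        Pd.append(pd_)
        rms_list.append(rms)
    if not T:
        raise ValueError("no spectrum could be decomposed")
    return PopulationSeries(np.array(T), np.array(Po), np.array(Pd),
                            np.array(rms_list))


# ---------------------------------------------------------------------------
# order parameter


def _wigner_terms(x, phi, pot: OrderingPotential):
    """-U/kT on the (cos theta, phi) product grid."""
    x2 = x ** 2
    d200 = 0.5 * (3.0 * x2 - 1.0)
    u = pot.c20 * d200
    if pot.c40:
        u = u + pot.c40 * 0.125 * (35.0 * x2 ** 2 - 30.0 * x2 + 3.0)
    if phi is None:
        return u
    s2 = 1.0 - x2
    u = u[:, None] * np.ones_like(phi)[None, :]
    if pot.c22:
        u = u + pot.c22 * np.sqrt(1.5) * s2[:, None] * np.cos(2 * phi)[None, :]
    if pot.c42:
        u = u + pot.c42 * (np.sqrt(10.0) / 4.0) * (
            s2 * (7.0 * x2 - 1.0))[:, None] * np.cos(2 * phi)[None, :]
    if pot.c44:
        u = u + pot.c44 * (np.sqrt(70.0) / 8.0) * (
            s2 ** 2)[:, None] * np.cos(4 * phi)[None, :]
    return u


def order_parameter(pot: OrderingPotential, quadrature_nodes: int = 256,
                    phi_nodes: int = 128) -> float:
    """Order parameter S from the Boltzmann average of (3 cos^2 theta - 1)/2.

    Gauss-Legendre quadrature in cos(theta) (``quadrature_nodes`` >= 64)
    crossed with a uniform phi rule; the phi integral is skipped when the
    potential is uniaxial (only c20/c40 nonzero).
    """
    if quadrature_nodes < 64:
        raise ValueError("quadrature_nodes must be >= 64")
    x, wx = np.polynomial.legendre.leggauss(quadrature_nodes)
    d200 = 0.5 * (3.0 * x ** 2 - 1.0)
    uniaxial = pot.c22 == 0 and pot.c42 == 0 and pot.c44 == 0
    phi = None if uniaxial else np.linspace(
        0.0, 2.0 * np.pi, phi_nodes, endpoint=False)
    minus_u = _wigner_terms(x, phi, pot)
    if not np.all(np.isfinite(minus_u)):
        raise ValueError("non-finite potential values")
    w = np.exp(minus_u - minus_u.max())
    if uniaxial:
        num = np.sum(wx * d200 * w)
        den = np.sum(wx * w)
    else:
        num = np.sum(wx[:, None] * d200[:, None] * w)
        den = np.sum(wx[:, None] * w)
    return float(num / den)
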