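"""Michaelis-Menten kinetics and the quadratic subunit-composition model.

Two layers of kinetic analysis:

* Per-molecule enzyme kinetics — the rotation rate of F1 versus substrate
  concentration follows Michaelis-Menten saturation
  ``v(S) = Vmax S / (Km + S)``; the catalytic efficiency of ATP binding
  is ``kon = 3 Vmax / Km`` (three ATP are consumed per turn).

* Across motors — each F1 variant is an alpha3-beta3-gamma complex whose
  subunits come from one of three species: thermophilic Bacillus PS3
  (T), Paracoccus denitrificans (P) or bovine mitochondria (b).  A
  variant is written as a three-letter origin triplet in alpha, beta,
  gamma order ("PbP" = alpha and gamma from P, beta from b).  Its maximum
  rate is modelled by a nine-term quadratic response surface with no
  intercept,

  ``Vmax/Vbar = a_a Va + a_b Vb + a_g Vg + a_ab Va Vb + a_ag Va Vg
                + a_bg Vb Vg + a_aa Va^2 + a_bb Vb^2 + a_gg Vg^2``,

  where each explanatory variable takes the genuine Vmax of that
  subunit's species divided by the mean of the three genuine values
  (Vbar), rendering variables, response and coefficients dimensionless.
  The fitted surface predicts Vmax over the full 3x3x3 composition
  lattice; predictions are trusted only inside the convex hull of the
  observed compositions (interpolation), since polynomials extrapolate
  poorly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from itertools import product

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial import Delaunay, QhullError

from .errors import FitError

__all__ = [
    "ORIGINS",
    "GENUINE_VMAX",
    "MMFit",
    "QuadraticFit",
    "fit_michaelis_menten",
    "catalytic_efficiency",
    "encode_composition",
    "fit_quadratic",
    "predict_vmax",
    "lattice_predictions",
    "minimality_check",
    "load_reference_compositions",
]

ORIGINS = ("T", "P", "b")

#: maximum rotation rates (rps) of the genuine motors, used to encode
#: subunit origins as dimensionless variables
GENUINE_VMAX = {"T": 189.0, "P": 338.0, "b": 786.0}

_TERM_NAMES = ("a_a", "a_b", "a_g", "a_ab", "a_ag", "a_bg", "a_aa", "a_bb", "a_gg")


def load_reference_compositions() -> pd.DataFrame:
    """The packaged table of genuine and hybrid F1 variants.

    Columns: name, alpha, beta, gamma (origin codes), vmax_rps, km_um and
    the published catalytic efficiency kon (10^7 / M / s).
    """
    with resources.files("f1rotary.data").joinpath(
        "genuine_and_hybrid_vmax.csv"
    ).open() as fh:
        return pd.read_csv(fh)


# ---------------------------------------------------------------------------
# Michaelis-Menten


@dataclass
class MMFit:
    """Michaelis-Menten fit: Vmax (rps), Km (molar), asymptotic SEs."""

    vmax: float
    km: float
    vmax_se: float
    km_se: float
    residual_ss: float


def _mm(S, vmax, km):
    return vmax * S / (km + S)


def fit_michaelis_menten(data: pd.DataFrame) -> MMFit:
    """Unweighted nonlinear least squares of rate = Vmax S / (Km + S).

    ``data`` needs columns conc_M and rate_rps with at least 3 distinct
    concentrations; a warning is issued when the concentrations do not
    bracket the fitted Km.  Initialisation: Vmax0 = max rate, Km0 = the
    concentration closest to half-maximal rate.
    """
    S = np.asarray(data["conc_M"], dtype=float)
    v = np.asarray(data["rate_rps"], dtype=float)
    if np.unique(S).size < 2:
        raise FitError("need at least 2 distinct concentrations")
    vmax0 = float(v.max())
    km0 = float(S[np.argmin(np.abs(v - vmax0 / 2.0))])
    try:
        popt, pcov = curve_fit(
            _mm, S, v, p0=(vmax0, max(km0, S.min())), maxfev=10_000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = map(float, popt)
    if vmax <= 0 or km <= 0:
        raise FitError(f"non-positive estimates Vmax={vmax}, Km={km}")
    if not (S.min() < km < S.max()):
        warnings.warn(
            "concentrations do not bracket the fitted Km; estimates may be poor",
            stacklevel=2,
        )
    se = np.sqrt(np.diag(pcov))
    rss = float(np.sum((v - _mm(S, vmax, km)) ** 2))
    return MMFit(vmax=vmax, km=km, vmax_se=float(se[0]), km_se=float(se[1]), residual_ss=rss)


def catalytic_efficiency(vmax: float, km: float) -> float:
    """ATP on-rate efficiency ``kon = 3 Vmax / Km`` (per molar per second).

    The factor 3 converts revolutions per second to ATP per second (three
    catalytic sites fire per turn).  ``vmax`` in rps, ``km`` in molar.
    """
    if km <= 0:
        raise ValueError("km must be positive")
    return 3.0 * vmax / km


# ---------------------------------------------------------------------------
# Quadratic composition model


def _validate_key(key: str) -> str:
    if len(key) != 3 or any(c not in ORIGINS for c in key):
        raise ValueError(f"composition key must be 3 characters over {ORIGINS}: {key!r}")
    return key


def encode_composition(
    key: str, genuine_vmax: dict[str, float] | None = None
) -> tuple[float, float, float]:
    """Dimensionless (Va, Vb, Vg) for an origin triplet.

    Each variable is the genuine Vmax of that subunit's origin divided by
    Vbar, the exact arithmetic mean of the three genuine values
    (437.67 rps for the defaults, quoted as ~438)."""
    _validate_key(key)
    gv = GENUINE_VMAX if genuine_vmax is None else genuine_vmax
    vbar = sum(gv[o] for o in ORIGINS) / 3.0
    return tuple(gv[c] / vbar for c in key)


def _design_row(enc: tuple[float, float, float]) -> list[float]:
    a, b, g = enc
    return [a, b, g, a * b, a * g, b * g, a * a, b * b, g * g]


@dataclass
class QuadraticFit:
    """The nine fitted coefficients and their context.

    ``coefficients`` and ``standard_errors`` are keyed by term name
    (a_a .. a_gg); ``vbar`` is the normalizer in rps; ``residuals`` are in
    rps, aligned with ``keys``; ``design`` is the n x 9 regressor matrix.
    """

    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    vbar: float
    residuals: np.ndarray
    design: np.ndarray
    keys: list[str]
    residual_ss: float  # on the dimensionless response scale
    genuine_vmax: dict[str, float] | None = None

    @property
    def coef_vector(self) -> np.ndarray:
        return np.array([self.coefficients[t] for t in _TERM_NAMES])


def _ols_no_intercept(X: np.ndarray, y: np.ndarray):
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise FitError("design matrix is rank deficient")
    resid = y - X @ coef
    rss = float(resid @ resid)
    return coef, resid, rss


def fit_quadratic(
    table: pd.DataFrame | list[tuple[str, float]],
    genuine_vmax: dict[str, float] | None = None,
) -> QuadraticFit:
    """Fit the nine-term no-intercept quadratic response surface.

    ``table`` is a (composition key, Vmax in rps) list, or a DataFrame
    with alpha/beta/gamma origin columns and vmax_rps.  The response is
    Vmax/Vbar; coefficient standard errors come from the asymptotic OLS
    covariance with ``n - 9`` residual degrees of freedom.
    """
    rows = _as_key_vmax(table)
    if len(rows) < 9:
        raise FitError("need at least 9 compositions to fit 9 coefficients")
    gv = GENUINE_VMAX if genuine_vmax is None else genuine_vmax
    vbar = sum(gv[o] for o in ORIGINS) / 3.0
    keys = [k for k, _ in rows]
    X = np.array([_design_row(encode_composition(k, gv)) for k in keys])
    y = np.array([v for _, v in rows]) / vbar
    coef, resid, rss = _ols_no_intercept(X, y)
    dof = len(rows) - X.shape[1]
    if dof > 0:
        sigma2 = rss / dof
        se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
    else:
        se = np.full(X.shape[1], np.nan)
    return QuadraticFit(
        coefficients=dict(zip(_TERM_NAMES, map(float, coef))),
        standard_errors=dict(zip(_TERM_NAMES, map(float, se))),
        vbar=vbar,
        residuals=resid * vbar,
        design=X,
        keys=keys,
        residual_ss=rss,
        genuine_vmax=None if genuine_vmax is None else dict(genuine_vmax),
    )


def _as_key_vmax(table) -> list[tuple[str, float]]:
    if isinstance(table, pd.DataFrame):
        return [
            (_validate_key(f"{r.alpha}{r.beta}{r.gamma}"), float(r.vmax_rps))
            for r in table.itertuples()
        ]
    return [(_validate_key(k), float(v)) for k, v in table]


def predict_vmax(fit: QuadraticFit, key: str) -> float:
    """Evaluate the fitted surface at a composition; returns rps."""
    row = np.array(_design_row(encode_composition(key, fit.genuine_vmax)))
    return float(row @ fit.coef_vector * fit.vbar)


def lattice_predictions(fit: QuadraticFit, observed: list[str]) -> pd.DataFrame:
    """Predictions over the 27-point composition lattice.

    Each origin triplet gets a predicted Vmax; the ``interpolated`` flag
    marks points inside the convex hull of the observed compositions'
    encoded coordinates — predictions outside it are extrapolations of a
    polynomial and should not be trusted.
    """
    if not observed:
        raise ValueError("observed composition set is empty")
    obs_pts = np.array([encode_composition(k, fit.genuine_vmax) for k in observed])
    try:
        hull = Delaunay(obs_pts)

        def inside(p):
            return bool(hull.find_simplex(np.asarray(p)[None, :]) >= 0)

    except QhullError:  # degenerate (coplanar) observed set: hull has no volume
        def inside(p):
            return any(np.allclose(p, q) for q in obs_pts)

    rows = []
    for combo in product(ORIGINS, repeat=3):
        key = "".join(combo)
        enc = encode_composition(key, fit.genuine_vmax)
        rows.append(
            {
                "key": key,
                "predicted_vmax_rps": predict_vmax(fit, key),
                "observed": key in observed,
                "interpolated": inside(enc),
            }
        )
    return pd.DataFrame(rows)


def minimality_check(
    table: pd.DataFrame | list[tuple[str, float]],
    genuine_vmax: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Is every quadratic term needed, and is a constant term absent?

    For each of the nine terms the model is refitted without it and the
    ratio of its residual sum of squares to the full model's is reported
    (ratios well above 1 mean the term is required).  A tenth row
    ("intercept") reports the fitted constant of the intercept-augmented
    model, which should be close to zero relative to the response scale.
    """
    rows = _as_key_vmax(table)
    gv = GENUINE_VMAX if genuine_vmax is None else genuine_vmax
    vbar = sum(gv[o] for o in ORIGINS) / 3.0
    X = np.array([_design_row(encode_composition(k, gv)) for k, _ in rows])
    y = np.array([v for _, v in rows]) / vbar
    _, _, rss_full = _ols_no_intercept(X, y)
    out = []
    for j, term in enumerate(_TERM_NAMES):
        Xr = np.delete(X, j, axis=1)
        _, _, rss_r = _ols_no_intercept(Xr, y)
        out.append(
            {"term": term, "rss_ratio": rss_r / rss_full if rss_full > 0 else np.inf,
             "estimate": np.nan}
        )
    Xc = np.hstack([np.ones((X.shape[0], 1)), X])
    coef_c, _, rss_c = _ols_no_intercept(Xc, y)
    out.append({"term": "intercept", "rss_ratio": rss_c / rss_full if rss_full > 0 else np.inf,
                "estimate": float(coef_c[0])})
    return pd.DataFrame(out)
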