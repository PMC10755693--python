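"""Michaelis–Menten and cofactor-activation fits for initial-rate data.

The NAD+-dependent SQase assays yield initial rates v at a grid of substrate
(SQGro, α-/β-PNPSQ) or cofactor (NAD+) concentrations.  Both follow the same
rectangular hyperbola

    v = Vmax · S / (K + S)

where K is the Michaelis constant KM for a substrate titration, or the
Michaelis activation constant KA for a cofactor titration at fixed substrate.
The primary estimator is nonlinear least squares; the Lineweaver–Burk double
reciprocal line is used only to seed the optimiser and for plotting — it is
statistically biased as an estimator.

kcat = Vmax / [E]0 and kcat/KM follow by exact arithmetic from the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclass(frozen=True)
class KineticDataset:
    """Initial-rate observations: rates at substrate (or cofactor) levels.

    ``s_values`` in mM; ``rates`` in concentration/time (or 1/s if already
    normalised by enzyme); ``e0`` is the enzyme concentration used to convert
    Vmax to kcat.
    """

    s_values: np.ndarray
    rates: np.ndarray
    e0: float | None = None
    substrate_label: str = ""

    def __post_init__(self) -> None:
        s = np.asarray(self.s_values, dtype=float)
        v = np.asarray(self.rates, dtype=float)
        if s.shape != v.shape or s.ndim != 1:
            raise ValueError("s_values and rates must be 1-D and equal length")
        if np.any(s <= 0):
            raise ValueError("all concentrations must be > 0")
        object.__setattr__(self, "s_values", s)
        object.__setattr__(self, "rates", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"S": self.s_values, "v": self.rates})

    @classmethod
    def from_csv(cls, path, e0: float | None = None,
                 substrate_label: str = "") -> "KineticDataset":
        df = pd.read_csv(path)
        return cls(df["S"].to_numpy(), df["v"].to_numpy(), e0=e0,
                   substrate_label=substrate_label)


@dataclass(frozen=True)
class MMFit:
    """Fitted hyperbolic parameters with standard errors.

    For substrate fits the constant lands in ``km``; ``fit_activation``
    aliases it into ``ka``.  kcat and kcat/KM are populated by
    ``derive_catalytic`` when an enzyme concentration is known.
    """

    vmax: float
    vmax_se: float
    km: float
    km_se: float
    residual_ss: float
    n_obs: int
    converged: bool
    status: str = "ok"
    kcat: float | None = None
    kcat_over_km: float | None = None
    ka: float | None = None
    ka_se: float | None = None

    def predict(self, s) -> np.ndarray:
        s = np.asarray(s, dtype=float)
        return self.vmax * s / (self.km + s)


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def lineweaver_burk_guess(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """(Vmax, KM) from the double-reciprocal regression; used only to seed
    the nonlinear optimiser (and for plotting)."""
    ok = v > 0
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(1.0 / s[ok], 1.0 / v[ok], 1)
        if intercept > 0 and slope > 0:
            return 1.0 / intercept, slope / intercept
    # fall back to curve-shape heuristics
    vmax0 = float(np.max(v)) * 1.2 if np.max(v) > 0 else 1.0
    km0 = float(np.median(s))
    return vmax0, km0


def fit_mm(data: KineticDataset, warn_on_span: bool = True) -> MMFit:
    """Nonlinear least-squares fit of v = Vmax·S/(KM+S).

    Standard errors come from the Jacobian-based covariance at the optimum.
    If the unconstrained path strays into negative parameters, the fit is
    redone in log-parameter space.
    """
    s, v = data.s_values, data.rates
    vmax0, km0 = lineweaver_burk_guess(s, v)
    if warn_on_span:
        if len(np.unique(s)) < 4:
            warnings.warn("fewer than 4 distinct concentrations; "
                          "KM is weakly determined", stacklevel=2)
        elif not (s.min() <= km0 / 2 and s.max() >= 2 * km0):
            warnings.warn("concentration grid does not span [KM/2, 2·KM]; "
                          "KM may be poorly determined", stacklevel=2)
    if len(s) < 2:
        raise ValueError("need at least 2 observations to fit 2 parameters")

    status, converged = "ok", True
    try:
        popt, pcov = curve_fit(
            _mm, s, v, p0=[vmax0, km0], method="lm",
            maxfev=500 * 4, xtol=1e-12, ftol=1e-12, gtol=1e-10,
        )
        if np.any(popt <= 0):
            raise RuntimeError("negative parameter path")
    except RuntimeError:
        # log-parameter fallback keeps Vmax, KM positive by construction
        def mm_log(x, lv, lk):
            return np.exp(lv) * x / (np.exp(lk) + x)

        try:
            plog, pcov_log = curve_fit(
                mm_log, s, v, p0=[np.log(max(vmax0, 1e-12)),
                                  np.log(max(km0, 1e-12))],
                method="lm", maxfev=500 * 4, xtol=1e-12, ftol=1e-12,
            )
            popt = np.exp(plog)
            jac = np.diag(popt)  # delta method: d(exp)/dx = exp
            pcov = jac @ pcov_log @ jac
            status = "log-fallback"
        except RuntimeError:
            popt = np.array([vmax0, km0])
            pcov = np.full((2, 2), np.nan)
            status, converged = "not converged", False

    resid = v - _mm(s, *popt)
    with np.errstate(invalid="ignore"):
        ses = np.sqrt(np.diag(pcov))
    return MMFit(
        vmax=float(popt[0]), vmax_se=float(ses[0]),
        km=float(popt[1]), km_se=float(ses[1]),
        residual_ss=float(resid @ resid), n_obs=len(s),
        converged=converged, status=status,
    )


def fit_activation(data: KineticDataset, **kwargs) -> MMFit:
    """Fit v = Vmax·A/(KA+A) for a cofactor titration at fixed substrate.

    Same estimator and contract as :func:`fit_mm`; the constant is reported
    in the ``ka`` field.
    """
    if len(np.unique(data.s_values)) < 2:
        raise ValueError("activation fit needs at least 2 distinct "
                         "cofactor concentrations")
    base = fit_mm(data, **kwargs)
    return MMFit(
        vmax=base.vmax, vmax_se=base.vmax_se,
        km=base.km, km_se=base.km_se,
        residual_ss=base.residual_ss, n_obs=base.n_obs,
        converged=base.converged, status=base.status,
        ka=base.km, ka_se=base.km_se,
    )


def derive_catalytic(fit: MMFit, e0: float) -> MMFit:
    """kcat = Vmax/e0 and kcat/KM by exact arithmetic; returns a new MMFit."""
    if e0 <= 0:
        raise ValueError("enzyme concentration must be > 0")
    kcat = fit.vmax / e0
    return MMFit(
        vmax=fit.vmax, vmax_se=fit.vmax_se, km=fit.km, km_se=fit.km_se,
        residual_ss=fit.residual_ss, n_obs=fit.n_obs,
        converged=fit.converged, status=fit.status,
        kcat=kcat, kcat_over_km=kcat / fit.km,
        ka=fit.ka, ka_se=fit.ka_se,
    )
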