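"""Two-site cis-trans exchange kinetics from 1H-1H EXSY build-up curves.

Slow conformational exchange between the cis and trans prolyl conformers of a
peptide produces off-diagonal cross-peaks in a 2D EXSY spectrum.  For a
two-site system with forward (cis->trans) rate ``k_ct`` and reverse
(trans->cis) rate ``k_tc``, the ratio of the cis->trans cross-peak volume to
the trans-trans diagonal volume follows

    I_ct / I_tt = {1 - exp[-(k_ct + k_tc) t_mix]} k_tc
                  / {k_ct + k_tc exp[-(k_ct + k_tc) t_mix]}

which is independent of the (shared) auto-relaxation rate because relaxation
decay cancels in the ratio.  Fitting this build-up curve over a series of
mixing times yields both rate constants and the total exchange rate
``k_ex = k_ct + k_tc``.

This module provides the ratio model, the standard error propagation for the
cross/diagonal volume ratio, construction of ratio tables from volume series,
Levenberg-Marquardt estimation of the exchange rates (with positivity enforced
by fitting log-rates), and a simple 2D-Gaussian lineshape fitter for
extracting peak volumes from spectral intensity grids.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import leastsq

logger = logging.getLogger(__name__)

__all__ = [
    "MixingSeries",
    "ExchangeFitResult",
    "PeakVolume2D",
    "InsufficientDataError",
    "exsy_ratio_model",
    "propagate_ratio_error",
    "build_ratio_series",
    "fit_exchange",
    "monte_carlo_errors",
    "extract_peak_volume",
    "equilibrium_cis_fraction",
    "read_mixing_series",
]

#: Mixing times (seconds) of the pseudo-3D EXSY experiment used throughout
#: as the default sampling schedule.
DEFAULT_MIXING_TIMES_S: tuple[float, ...] = (
    0.0125, 0.025, 0.050, 0.075, 0.100, 0.150, 0.200,
    0.250, 0.300, 0.350, 0.400, 0.500, 0.600,
)


class InsufficientDataError(ValueError):
    """Raised when fewer usable data points than free parameters + 1 exist."""


@dataclass(frozen=True)
class MixingSeries:
    """A mixing-time series of diagonal (trans-trans) and cross (cis->trans)
    peak volumes with their errors.

    Mixing times are in seconds, strictly positive and strictly increasing.
    """

    t_mix: np.ndarray
    I_tt: np.ndarray
    I_ct: np.ndarray
    sigma_tt: np.ndarray
    sigma_ct: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("t_mix", "I_tt", "I_ct", "sigma_tt", "sigma_ct"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t_mix.size
        for name in ("I_tt", "I_ct", "sigma_tt", "sigma_ct"):
            if getattr(self, name).size != n:
                raise ValueError(f"{name} length {getattr(self, name).size} != t_mix length {n}")
        if np.any(self.t_mix <= 0):
            raise ValueError("mixing times must be strictly positive")
        if np.any(np.diff(self.t_mix) <= 0):
            raise ValueError("mixing times must be strictly increasing")
        if np.any(self.I_tt < 0) or np.any(self.I_ct < 0):
            raise ValueError("peak volumes must be non-negative")
        if np.any(self.sigma_tt < 0) or np.any(self.sigma_ct < 0):
            raise ValueError("volume errors must be non-negative")

    def __len__(self) -> int:
        return int(self.t_mix.size)


@dataclass(frozen=True)
class ExchangeFitResult:
    """Fitted exchange rates. ``k_ex = k_ct + k_tc`` by definition."""

    k_ct: float
    k_tc: float
    k_ex: float
    se_k_ct: float
    se_k_tc: float
    se_k_ex: float
    residual_ss: float
    n_points: int
    converged: bool
    # covariance of (k_ct, k_tc) on the rate scale, for downstream propagation
    cov_rates: np.ndarray | None = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class PeakVolume2D:
    """A 2D lineshape-fit peak volume: ``volume = 2*pi*A*width1*width2``.

    ``volume_error`` is NaN when the fit failed.
    """

    center_dim1: float
    center_dim2: float
    width_dim1: float
    width_dim2: float
    volume: float
    volume_error: float

    @property
    def ok(self) -> bool:
        return np.isfinite(self.volume_error)


def exsy_ratio_model(t_mix, k_ct: float, k_tc: float):
    """Cross/diagonal intensity ratio of the two-site exchange model.

    Parameters
    ----------
    t_mix : float or array
        Mixing time(s) in seconds, >= 0.
    k_ct, k_tc : float
        cis->trans and trans->cis rate constants in s^-1, > 0.

    Returns
    -------
    The ratio I_ct/I_tt, in [0, k_tc/k_ct), strictly increasing in ``t_mix``.
    """
    if not (k_ct > 0 and k_tc > 0):
        raise ValueError(f"rate constants must be positive, got k_ct={k_ct}, k_tc={k_tc}")
    t = np.asarray(t_mix, dtype=float)
    if np.any(t < 0):
        raise ValueError("mixing time must be non-negative")
    e = np.exp(-(k_ct + k_tc) * t)
    out = (1.0 - e) * k_tc / (k_ct + k_tc * e)
    return out if out.ndim else float(out)


def propagate_ratio_error(I_tt, sigma_tt, I_ct, sigma_ct):
    """Standard error of the ratio CT/T from volume errors dT and dCT.

    Uses the algebraically equivalent finite form

        sqrt[(dCT/T)^2 + (CT*dT/T^2)^2]

    which equals ``sqrt[(dT/T)^2 + (dCT/CT)^2] * CT/T`` whenever CT > 0 and
    stays finite (reducing to dCT/T) at CT = 0, so the shortest mixing time
    never yields an undefined error bar.
    """
    T = np.asarray(I_tt, dtype=float)
    CT = np.asarray(I_ct, dtype=float)
    dT = np.asarray(sigma_tt, dtype=float)
    dCT = np.asarray(sigma_ct, dtype=float)
    if np.any(T == 0):
        raise ZeroDivisionError("diagonal volume I_tt is zero; the ratio error is undefined")
    out = np.sqrt((dCT / T) ** 2 + (CT * dT / T**2) ** 2)
    return out if out.ndim else float(out)


def build_ratio_series(series: MixingSeries) -> pd.DataFrame:
    """Build the (t_mix, ratio, ratio_error) table from a volume series.

    Raises if any diagonal volume is zero, naming the offending mixing time.
    """
    zero = series.I_tt == 0
    if np.any(zero):
        t_bad = series.t_mix[zero][0]
        raise ZeroDivisionError(
            f"diagonal volume I_tt is zero at t_mix = {t_bad:g} s; ratio undefined"
        )
    ratio = series.I_ct / series.I_tt
    err = propagate_ratio_error(series.I_tt, series.sigma_tt, series.I_ct, series.sigma_ct)
    return pd.DataFrame(
        {"t_mix": series.t_mix, "ratio": ratio, "ratio_error": np.atleast_1d(err)}
    )


def _slope_based_init(t: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Heuristic start: initial slope ~ k_tc, plateau ~ k_tc/k_ct."""
    r_inf = max(float(np.max(r)), 1e-6)
    k_tc0 = float(np.clip(r[0] / t[0], 1e-3, 1e4))
    k_ct0 = float(np.clip(k_tc0 / r_inf, 1e-3, 1e4))
    return k_ct0, k_tc0


def fit_exchange(
    ratio_table: pd.DataFrame,
    weighted: bool | None = None,
    init: tuple[float, float] | None = None,
    se_method: str = "covariance",
    n_mc: int = 200,
    seed: int | None = None,
) -> ExchangeFitResult:
    """Fit the two-site exchange model to a (t_mix, ratio, ratio_error) table.

    Levenberg-Marquardt least squares on log(k_ct), log(k_tc), which enforces
    positivity.  When ``weighted`` (default: automatically on iff every
    ratio_error is finite and positive) residuals are divided by the supplied
    errors and the parameter covariance is taken at face value; otherwise the
    covariance is scaled by the reduced chi-square.

    ``se_method='monte_carlo'`` replaces the covariance-based standard errors
    by the spread of ``n_mc`` parametric-bootstrap refits (requires errors).
    """
    t = np.asarray(ratio_table["t_mix"], dtype=float)
    r = np.asarray(ratio_table["ratio"], dtype=float)
    err = (
        np.asarray(ratio_table["ratio_error"], dtype=float)
        if "ratio_error" in ratio_table
        else None
    )
    keep = np.isfinite(t) & np.isfinite(r)
    if err is not None:
        keep &= np.isfinite(err)
    t, r = t[keep], r[keep]
    if err is not None:
        err = err[keep]
    n = t.size
    if n < 3:
        raise InsufficientDataError(
            f"need at least 3 finite data points to fit two rates, got {n}"
        )
    if weighted is None:
        weighted = err is not None and bool(np.all(err > 0))
    if weighted and (err is None or np.any(err <= 0)):
        raise ValueError("weighted fit requires strictly positive ratio errors")

    def residuals(p: np.ndarray) -> np.ndarray:
        m = exsy_ratio_model(t, np.exp(p[0]), np.exp(p[1]))
        res = m - r
        return res / err if weighted else res

    if init is not None:
        starts = [tuple(init)]
    else:
        k0 = 1.0 / float(np.median(t))
        starts = [(k0, k0), _slope_based_init(t, r)]

    popt = cov_log = None
    converged = False
    for k_ct0, k_tc0 in starts:
        p0 = np.log([k_ct0, k_tc0])
        sol, cov_x, infodict, _, ier = leastsq(
            residuals, p0, full_output=True, ftol=1e-12, xtol=1e-12, maxfev=5000
        )
        if ier in (1, 2, 3, 4):
            popt, cov_log, converged = sol, cov_x, True
            if cov_x is not None and np.all(np.isfinite(cov_x)):
                break  # keep looking for a start that also yields a covariance
        if popt is None:
            popt, cov_log = sol, cov_x  # best effort for the flagged result

    k_ct, k_tc = float(np.exp(popt[0])), float(np.exp(popt[1]))
    res = residuals(popt)
    rss = float(np.dot(res, res))

    if cov_log is not None and not np.all(np.isfinite(cov_log)):
        cov_log = None
    if converged and cov_log is not None:
        if not weighted:
            dof = max(n - 2, 1)
            cov_log = cov_log * (rss / dof)
        jac = np.diag([k_ct, k_tc])  # d(k)/d(log k) = k
        cov_rates = jac @ cov_log @ jac
        se_k_ct = float(np.sqrt(max(cov_rates[0, 0], 0.0)))
        se_k_tc = float(np.sqrt(max(cov_rates[1, 1], 0.0)))
        se_k_ex = float(np.sqrt(max(cov_rates.sum(), 0.0)))
    else:
        cov_rates = None
        se_k_ct = se_k_tc = se_k_ex = float("nan")

    result = ExchangeFitResult(
        k_ct=k_ct,
        k_tc=k_tc,
        k_ex=k_ct + k_tc,
        se_k_ct=se_k_ct,
        se_k_tc=se_k_tc,
        se_k_ex=se_k_ex,
        residual_ss=rss,
        n_points=int(n),
        converged=converged,
        cov_rates=cov_rates,
    )
    if se_method == "monte_carlo" and converged:
        se = monte_carlo_errors(
            pd.DataFrame({"t_mix": t, "ratio": r, "ratio_error": err}),
            result,
            n_draws=n_mc,
            seed=seed,
        )
        result = ExchangeFitResult(
            k_ct=k_ct, k_tc=k_tc, k_ex=k_ct + k_tc,
            se_k_ct=se["k_ct"], se_k_tc=se["k_tc"], se_k_ex=se["k_ex"],
            residual_ss=rss, n_points=int(n), converged=True, cov_rates=cov_rates,
        )
    elif se_method not in ("covariance", "monte_carlo"):
        raise ValueError(f"unknown se_method {se_method!r}")
    return result


def monte_carlo_errors(
    ratio_table: pd.DataFrame,
    fit: ExchangeFitResult,
    n_draws: int = 200,
    seed: int | None = None,
) -> dict[str, float]:
    """Parametric-bootstrap standard errors for the fitted rates.

    Draws synthetic ratio tables from N(model, ratio_error) around the fitted
    curve and refits each; returns the sample standard deviations.
    """
    if "ratio_error" not in ratio_table or np.any(ratio_table["ratio_error"] <= 0):
        raise ValueError("Monte-Carlo errors require strictly positive ratio errors")
    rng = np.random.default_rng(seed)
    t = np.asarray(ratio_table["t_mix"], dtype=float)
    err = np.asarray(ratio_table["ratio_error"], dtype=float)
    model = exsy_ratio_model(t, fit.k_ct, fit.k_tc)
    draws = []
    for _ in range(n_draws):
        r_sim = model + rng.normal(scale=err)
        tab = pd.DataFrame({"t_mix": t, "ratio": r_sim, "ratio_error": err})
        try:
            f = fit_exchange(tab, weighted=True, init=(fit.k_ct, fit.k_tc))
        except Exception:  # pragma: no cover - pathological draws
            continue
        if f.converged:
            draws.append((f.k_ct, f.k_tc, f.k_ex))
    arr = np.asarray(draws)
    sd = arr.std(axis=0, ddof=1)
    return {"k_ct": float(sd[0]), "k_tc": float(sd[1]), "k_ex": float(sd[2])}


def equilibrium_cis_fraction(fit: ExchangeFitResult) -> float:
    """Equilibrium cis population k_tc/(k_ct + k_tc) implied by detailed balance.

    Equals R_inf/(1 + R_inf) where R_inf = k_tc/k_ct is the long-mixing-time
    limit of the cross/diagonal ratio.
    """
    if not fit.converged:
        raise ValueError("cis fraction requires a converged fit")
    return fit.k_tc / (fit.k_ct + fit.k_tc)


def _gauss2d(params: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    amp, c1, c2, lw1, lw2, base = params
    w1, w2 = np.exp(lw1), np.exp(lw2)
    return amp * np.exp(-0.5 * (((ii - c1) / w1) ** 2 + ((jj - c2) / w2) ** 2)) + base


def extract_peak_volume(
    grid: np.ndarray,
    guess: tuple[float, float],
    window: int | tuple[int, int],
) -> PeakVolume2D:
    """Fit one 2D Gaussian (plus flat baseline) in a window and integrate it.

    ``guess`` is an approximate (row, col) peak center; ``window`` the
    half-width of the fitting box in grid points per dimension.  The volume is
    the analytic integral 2*pi*amplitude*width1*width2 and its error comes
    from the fit covariance.  On failure the result carries NaN
    ``volume_error`` and a warning is logged.
    """
    grid = np.asarray(grid, dtype=float)
    if isinstance(window, (int, np.integer)):
        window = (int(window), int(window))
    r0, c0 = int(round(guess[0])), int(round(guess[1]))
    rlo, rhi = r0 - window[0], r0 + window[0] + 1
    clo, chi = c0 - window[1], c0 + window[1] + 1
    if rlo < 0 or clo < 0 or rhi > grid.shape[0] or chi > grid.shape[1]:
        raise ValueError("fitting window extends outside the grid")
    sub = grid[rlo:rhi, clo:chi]
    ii, jj = np.meshgrid(
        np.arange(rlo, rhi, dtype=float), np.arange(clo, chi, dtype=float), indexing="ij"
    )

    base0 = float(np.median(sub))
    amp0 = float(sub.max() - base0)
    w0 = max(window[0] / 4.0, 1.0)
    p0 = np.array([amp0 if amp0 > 0 else 1.0, guess[0], guess[1],
                   np.log(w0), np.log(w0), base0])

    def residuals(p: np.ndarray) -> np.ndarray:
        return (_gauss2d(p, ii, jj) - sub).ravel()

    sol, cov_x, infodict, _, ier = leastsq(
        residuals, p0, full_output=True, ftol=1e-12, xtol=1e-12, maxfev=5000
    )
    amp, c1, c2, lw1, lw2, _ = sol
    w1, w2 = float(np.exp(lw1)), float(np.exp(lw2))
    volume = float(2.0 * np.pi * amp * w1 * w2)
    failed = ier not in (1, 2, 3, 4) or cov_x is None or amp <= 0
    if failed:
        logger.warning("2D lineshape fit failed (ier=%s, amplitude=%.3g)", ier, amp)
        return PeakVolume2D(float(c1), float(c2), w1, w2, volume, float("nan"))
    res = residuals(sol)
    dof = max(res.size - sol.size, 1)
    cov = cov_x * float(np.dot(res, res)) / dof
    # delta method on V = 2*pi*A*exp(lw1)*exp(lw2): dV = V*(dA/A, 0, 0, dlw1, dlw2, 0)
    g = np.array([volume / amp, 0.0, 0.0, volume, volume, 0.0])
    vol_var = float(g @ cov @ g)
    return PeakVolume2D(
        float(c1), float(c2), w1, w2, volume, float(np.sqrt(max(vol_var, 0.0)))
    )


def read_mixing_series(path, label: str | None = None) -> MixingSeries:
    """Read a mixing series from CSV/TSV.

    Required columns: ``t_mix_ms``, ``I_tt``, ``I_ct``; optional ``sigma_tt``,
    ``sigma_ct`` (default 0).  Mixing times are milliseconds in files and
    converted to seconds here.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"t_mix_ms", "I_tt", "I_ct"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    n = len(df)
    return MixingSeries(
        t_mix=df["t_mix_ms"].to_numpy(dtype=float) / 1000.0,
        I_tt=df["I_tt"].to_numpy(dtype=float),
        I_ct=df["I_ct"].to_numpy(dtype=float),
        sigma_tt=df.get("sigma_tt", pd.Series(np.zeros(n))).to_numpy(dtype=float),
        sigma_ct=df.get("sigma_ct", pd.Series(np.zeros(n))).to_numpy(dtype=float),
        label=label if label is not None else str(path),
    )
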