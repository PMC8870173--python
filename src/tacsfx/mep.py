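"""MEP trial-series analysis: Tukey-fence outlier screening, gap
interpolation, and the local linear trend (LLT) state-space model.

Peak-to-peak MEP amplitudes fluctuate strongly from stimulus to stimulus.
The pipeline therefore (1) excludes outliers beyond the Tukey fences
Q1 − k·IQR / Q3 + k·IQR (k = 1.5), (2) linearly interpolates the removed
trials, and (3) fits the local linear trend model

    y_t     = μ_t + ε_t,             ε_t ~ N(0, σ²_obs)
    μ_{t+1} = μ_t + ν_t + ξ_t,       ξ_t ~ N(0, σ²_level)
    ν_{t+1} = ν_t + ζ_t,             ζ_t ~ N(0, σ²_slope)

where μ_t is the underlying excitability level and ν_t its slope, both
Gaussian random walks. Disturbance variances are estimated by maximizing the
marginal likelihood (prediction-error decomposition of the Kalman filter with
diffuse initialization); smoothed state trajectories come from fixed-interval
(RTS) smoothing. A random-walk Metropolis sampler over log-variances with
half-normal priors on the disturbance SDs is available as a fully Bayesian
alternative.

The model/results split follows the statsmodels convention:
``LocalLinearTrend(y).fit()`` returns a :class:`LocalLinearTrendResults`
carrying estimates, uncertainties and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .simulate import MepSeries
from .spectral import InputError, PipelineError

__all__ = [
    "OutlierReport",
    "tukey_fences",
    "interpolate_gaps",
    "LocalLinearTrend",
    "LocalLinearTrendResults",
    "fit_llt",
    "normalize_mep",
]

DIFFUSE_KAPPA = 1e7  # prior variance of the (unknown) initial level & slope
_N_DIFFUSE = 2  # prediction-error terms dropped from the likelihood


# ---------------------------------------------------------------------------
# outlier screening and interpolation
# ---------------------------------------------------------------------------


@dataclass
class OutlierReport:
    """Which trials the Tukey fences excluded and how they were refilled."""

    excluded: np.ndarray  # 0-based positions flagged as outliers
    lower_fence: float
    upper_fence: float
    interpolated: np.ndarray = field(default_factory=lambda: np.array([], int))
    extended: np.ndarray = field(default_factory=lambda: np.array([], int))

    @property
    def n_excluded(self) -> int:
        return self.excluded.size


def tukey_fences(amplitudes: np.ndarray, k: float = 1.5) -> OutlierReport:
    """Flag values outside [Q1 − k·IQR, Q3 + k·IQR].

    Quartiles use the linear-interpolation convention between order
    statistics (numpy's default, R type 7); the hinge convention is isolated
    here so it can be swapped if needed. ``k = inf`` flags nothing.
    """
    x = np.asarray(amplitudes, dtype=float)
    if x.size < 4:
        raise InputError("Tukey fences need at least 4 observations")
    if not np.all(np.isfinite(x)):
        raise InputError("amplitudes must be finite")
    q1, q3 = np.percentile(x, [25.0, 75.0])
    iqr = q3 - q1
    lower, upper = q1 - k * iqr, q3 + k * iqr
    if math.isinf(k):
        excluded = np.array([], dtype=int)
    else:
        excluded = np.flatnonzero((x < lower) | (x > upper))
    return OutlierReport(excluded=excluded, lower_fence=lower, upper_fence=upper)


def interpolate_gaps(
    amplitudes: np.ndarray, excluded: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Refill excluded trials from their retained neighbours.

    Interior gaps are linearly interpolated between the nearest retained
    trials; gaps before the first (after the last) retained trial take that
    trial's value, since linear interpolation is undefined beyond the ends.

    Returns ``(filled, interpolated_idx, extended_idx)``.
    """
    x = np.asarray(amplitudes, dtype=float)
    excluded = np.asarray(excluded, dtype=int)
    keep = np.setdiff1d(np.arange(x.size), excluded)
    if keep.size < 2:
        raise PipelineError(
            f"only {keep.size} trial(s) retained — cannot interpolate"
        )
    filled = x.copy()
    filled[excluded] = np.interp(excluded, keep, x[keep])
    interior = excluded[(excluded > keep[0]) & (excluded < keep[-1])]
    edge = np.setdiff1d(excluded, interior)
    return filled, interior, edge


def clean_series(
    amplitudes: np.ndarray, k: float = 1.5
) -> tuple[np.ndarray, OutlierReport]:
    """Tukey-fence screening followed by gap interpolation."""
    report = tukey_fences(amplitudes, k=k)
    if report.n_excluded:
        filled, interior, edge = interpolate_gaps(amplitudes, report.excluded)
        report.interpolated, report.extended = interior, edge
    else:
        filled = np.asarray(amplitudes, dtype=float).copy()
    return filled, report


# ---------------------------------------------------------------------------
# Kalman filter / smoother (scalar-unrolled for the 2-state LLT)
# ---------------------------------------------------------------------------


def _filter(y, var_obs, var_level, var_slope, kappa=DIFFUSE_KAPPA):
    """Kalman filter for the LLT; returns per-step quantities.

    State is (μ, ν); covariances are carried as (p11, p12, p22). The initial
    state is diffuse: mean zero, variance ``kappa`` on both components.
    """
    n = len(y)
    # predicted state and cov at t (before seeing y_t)
    ap = np.empty((n, 2))
    Pp = np.empty((n, 3))
    # filtered state and cov at t (after seeing y_t)
    af = np.empty((n, 2))
    Pf = np.empty((n, 3))
    v = np.empty(n)
    F = np.empty(n)

    mu, nu = 0.0, 0.0
    p11, p12, p22 = kappa, 0.0, kappa
    loglik = 0.0
    for t in range(n):
        ap[t] = mu, nu
        Pp[t] = p11, p12, p22
        vt = y[t] - mu
        Ft = p11 + var_obs
        v[t], F[t] = vt, Ft
        k1, k2 = p11 / Ft, p12 / Ft
        mu += k1 * vt
        nu += k2 * vt
        f11 = p11 - p11 * p11 / Ft
        f12 = p12 - p11 * p12 / Ft
        f22 = p22 - p12 * p12 / Ft
        af[t] = mu, nu
        Pf[t] = f11, f12, f22
        if t >= _N_DIFFUSE:
            loglik += -0.5 * (math.log(2 * math.pi) + math.log(Ft) + vt * vt / Ft)
        # time update: a = T a, P = T P T' + Q
        mu, nu = mu + nu, nu
        p11 = f11 + 2 * f12 + f22 + var_level
        p12 = f12 + f22
        p22 = f22 + var_slope
    return loglik, ap, Pp, af, Pf, v, F


def _loglike(y, var_obs, var_level, var_slope, kappa=DIFFUSE_KAPPA):
    """Marginal log-likelihood only (fast path for the optimizer)."""
    n = len(y)
    mu, nu = 0.0, 0.0
    p11, p12, p22 = kappa, 0.0, kappa
    loglik = 0.0
    log2pi = math.log(2 * math.pi)
    for t in range(n):
        vt = y[t] - mu
        Ft = p11 + var_obs
        k1, k2 = p11 / Ft, p12 / Ft
        mu += k1 * vt
        nu += k2 * vt
        f11 = p11 - p11 * p11 / Ft
        f12 = p12 - p11 * p12 / Ft
        f22 = p22 - p12 * p12 / Ft
        if t >= _N_DIFFUSE:
            loglik += -0.5 * (log2pi + math.log(Ft) + vt * vt / Ft)
        mu, nu = mu + nu, nu
        p11 = f11 + 2 * f12 + f22 + var_level
        p12 = f12 + f22
        p22 = f22 + var_slope
    return loglik


def _smooth(y, var_obs, var_level, var_slope, kappa=DIFFUSE_KAPPA):
    """Fixed-interval (RTS) smoother; returns smoothed means and covariances."""
    loglik, ap, Pp, af, Pf, _, _ = _filter(y, var_obs, var_level, var_slope, kappa)
    n = len(y)
    T = np.array([[1.0, 1.0], [0.0, 1.0]])
    a_s = np.empty((n, 2))
    P_s = np.empty((n, 2, 2))

    def mat(p):
        return np.array([[p[0], p[1]], [p[1], p[2]]])

    a_s[-1] = af[-1]
    P_s[-1] = mat(Pf[-1])
    for t in range(n - 2, -1, -1):
        Pft = mat(Pf[t])
        Ppt1 = mat(Pp[t + 1])
        # pseudoinverse: the predicted covariance degenerates to rank < 2
        # when disturbance variances are (numerically) zero
        J = Pft @ T.T @ np.linalg.pinv(Ppt1, hermitian=True)
        a_s[t] = af[t] + J @ (a_s[t + 1] - ap[t + 1])
        P_s[t] = Pft + J @ (P_s[t + 1] - Ppt1) @ J.T
    return loglik, a_s, P_s


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class FitError(RuntimeError):
    pass


class LocalLinearTrend:
    """Local linear trend model for an evenly spaced amplitude series.

    Parameters
    ----------
    endog : array-like
        The (complete, outlier-cleaned) observation series, μV.
    kappa : float
        Diffuse prior variance for the initial level and slope.

    Use :meth:`from_series` to run Tukey-fence screening + interpolation on a
    raw :class:`~tacsfx.simulate.MepSeries` first.
    """

    def __init__(self, endog, kappa: float = DIFFUSE_KAPPA):
        y = np.asarray(endog, dtype=float)
        if y.ndim != 1 or y.size < 5:
            raise InputError("endog must be a 1-d series of length >= 5")
        if not np.all(np.isfinite(y)):
            raise InputError("endog contains non-finite values")
        self.endog = y
        self.nobs = y.size
        self.kappa = float(kappa)
        self.outlier_report: OutlierReport | None = None
        self.series_meta: dict = {}

    @classmethod
    def from_series(cls, series: MepSeries, tukey_k: float = 1.5, **kwargs):
        """Build the model from a raw MEP series after outlier cleaning."""
        filled, report = clean_series(series.amplitude, k=tukey_k)
        model = cls(filled, **kwargs)
        model.outlier_report = report
        model.series_meta = {
            "condition": series.condition,
            "phase": series.phase,
            "session": series.session,
        }
        return model

    # -- likelihood ---------------------------------------------------------

    def loglike(self, var_obs: float, var_level: float, var_slope: float) -> float:
        """Marginal log-likelihood at the given disturbance variances."""
        if min(var_obs, var_level, var_slope) < 0:
            raise InputError("variances must be nonnegative")
        return _loglike(self.endog, var_obs, var_level, var_slope, self.kappa)

    def smooth(self, var_obs: float, var_level: float, var_slope: float):
        """Smoothed states at fixed variances (no estimation).

        Returns a :class:`LocalLinearTrendResults`.
        """
        loglik, a_s, P_s = _smooth(
            self.endog, var_obs, var_level, var_slope, self.kappa
        )
        return LocalLinearTrendResults(
            model=self,
            var_obs=var_obs,
            var_level=var_level,
            var_slope=var_slope,
            loglik=loglik,
            level=a_s[:, 0],
            slope=a_s[:, 1],
            level_sd=np.sqrt(np.maximum(P_s[:, 0, 0], 0.0)),
            slope_sd=np.sqrt(np.maximum(P_s[:, 1, 1], 0.0)),
            method="fixed",
        )

    # -- estimation ---------------------------------------------------------

    def _start_points(self) -> list[np.ndarray]:
        s2 = float(np.var(np.diff(self.endog)))
        if s2 <= 0:
            s2 = 1.0
        props = [
            (0.5, 0.25, 0.01),
            (0.9, 0.05, 0.001),
            (0.1, 0.5, 0.05),
        ]
        return [np.log(np.array(p) * s2) for p in props]

    def fit(
        self,
        method: str = "mle",
        maxiter: int = 600,
        n_starts: int = 3,
        seed: int | None = None,
        mcmc_draws: int = 2000,
        mcmc_burn: int = 500,
    ) -> "LocalLinearTrendResults":
        """Estimate the disturbance variances and smooth the states.

        ``method="mle"`` maximizes the marginal likelihood over
        log-variances with Nelder–Mead from ``n_starts`` starting points.
        ``method="mcmc"`` runs random-walk Metropolis over log-variances with
        half-normal priors on the SDs and smooths at the posterior medians.
        """
        if method == "mcmc":
            return self._fit_mcmc(seed=seed, draws=mcmc_draws, burn=mcmc_burn)
        if method != "mle":
            raise InputError(f"unknown method {method!r}")
        y = self.endog

        def neg_loglike(theta):
            th = np.clip(theta, -40.0, 40.0)
            return -_loglike(y, *np.exp(th), self.kappa)

        best = None
        for x0 in self._start_points()[:n_starts]:
            res = optimize.minimize(
                neg_loglike,
                x0,
                method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise FitError("variance estimation did not converge")
        var_obs, var_level, var_slope = np.exp(np.clip(best.x, -40.0, 40.0))
        out = self.smooth(var_obs, var_level, var_slope)
        out.method = "mle"
        out.converged = bool(best.success) or best.fun < np.inf
        return out

    def _fit_mcmc(self, seed, draws, burn, step: float = 0.35):
        rng = np.random.default_rng(seed)
        y = self.endog
        tau = max(float(np.std(y)), 1e-6)  # half-normal prior scale on SDs

        def logpost(theta):
            th = np.clip(theta, -40.0, 40.0)
            var = np.exp(th)
            sd = np.sqrt(var)
            # half-normal prior on sd, plus Jacobian d(sd)/d(log var) = sd/2
            logprior = float(np.sum(-0.5 * (sd / tau) ** 2 + np.log(sd / 2.0)))
            return _loglike(y, *var, self.kappa) + logprior

        theta = self._start_points()[0]
        lp = logpost(theta)
        samples = np.empty((draws, 3))
        accept = 0
        for i in range(draws):
            prop = theta + step * rng.standard_normal(3)
            lp_prop = logpost(prop)
            if math.log(rng.random()) < lp_prop - lp:
                theta, lp = prop, lp_prop
                accept += 1
            samples[i] = theta
        kept = np.exp(samples[burn:])
        var_obs, var_level, var_slope = np.median(kept, axis=0)
        out = self.smooth(var_obs, var_level, var_slope)
        out.method = "mcmc"
        out.mcmc_samples = kept
        out.mcmc_accept_rate = accept / draws
        return out


@dataclass
class LocalLinearTrendResults:
    """Smoothed trajectories and estimated hyperparameters of an LLT fit."""

    model: LocalLinearTrend
    var_obs: float
    var_level: float
    var_slope: float
    loglik: float
    level: np.ndarray
    slope: np.ndarray
    level_sd: np.ndarray
    slope_sd: np.ndarray
    method: str = "mle"
    converged: bool = True
    mcmc_samples: np.ndarray | None = None
    mcmc_accept_rate: float | None = None

    @property
    def params(self) -> dict[str, float]:
        return {
            "var_obs": self.var_obs,
            "var_level": self.var_level,
            "var_slope": self.var_slope,
        }

    def normalized(self, baseline_mean: float, tolerance: float = 1e-6) -> np.ndarray:
        """Per-trial NP = (level_t − R)/R against a baseline mean R."""
        return normalize_mep(self.level, baseline_mean, tolerance)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trial": np.arange(1, self.level.size + 1),
                "level": self.level,
                "level_sd": self.level_sd,
                "slope": self.slope,
                "slope_sd": self.slope_sd,
            }
        )

    def plot(self, ax=None):
        """Raw amplitudes with the smoothed level ± 2 SD band (matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.arange(1, self.level.size + 1)
        ax.plot(t, self.model.endog, "o-", alpha=0.4, label="observed")
        ax.plot(t, self.level, lw=2, label="smoothed level")
        ax.fill_between(
            t,
            self.level - 2 * self.level_sd,
            self.level + 2 * self.level_sd,
            alpha=0.2,
            lw=0,
        )
        ax.set_xlabel("trial")
        ax.set_ylabel("MEP amplitude (uV)")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            "Local Linear Trend Results",
            "=" * 46,
            f"Observations:        {self.model.nobs}",
            f"Method:              {self.method}",
            f"Log-likelihood:      {self.loglik:.4f}",
            "-" * 46,
            f"{'parameter':<16}{'estimate':>14}",
            f"{'var_obs (uV^2)':<16}{self.var_obs:>14.4f}",
            f"{'var_level (uV^2)':<16}{self.var_level:>14.4f}",
            f"{'var_slope':<16}{self.var_slope:>14.6f}",
            "-" * 46,
            f"final level:         {self.level[-1]:.2f} "
            f"(sd {self.level_sd[-1]:.2f}) uV",
            f"final slope:         {self.slope[-1]:.3f} "
            f"(sd {self.slope_sd[-1]:.3f}) uV/trial",
        ]
        rep = self.model.outlier_report
        if rep is not None:
            lines.append(
                f"outliers excluded:   {rep.n_excluded} "
                f"(fences [{rep.lower_fence:.1f}, {rep.upper_fence:.1f}])"
            )
        return "\n".join(lines)


def fit_llt(
    series: MepSeries | np.ndarray, tukey_k: float = 1.5, **fit_kwargs
) -> LocalLinearTrendResults:
    """Convenience: outlier-clean (for a MepSeries) and fit the LLT by MLE."""
    if isinstance(series, MepSeries):
        model = LocalLinearTrend.from_series(series, tukey_k=tukey_k)
    else:
        model = LocalLinearTrend(series)
    return model.fit(**fit_kwargs)


def normalize_mep(
    levels: np.ndarray, baseline_mean: float, tolerance: float = 1e-6
) -> np.ndarray:
    """Per-trial baseline-relative change NP_t = (level_t − R)/R.

    Negative values indicate amplitudes below the pre-stimulation baseline
    (stronger inhibition); positive values indicate facilitation.
    """
    if baseline_mean <= tolerance:
        raise PipelineError(
            f"baseline mean {baseline_mean!r} is at or below tolerance {tolerance}"
        )
    return (np.asarray(levels, dtype=float) - baseline_mean) / baseline_mean
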