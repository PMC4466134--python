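"""Regression models behind the EINS analysis, as scikit-learn style estimators.

Four 1-D regressions carry the whole analysis:

* :class:`GaussianElasticModel` — the Gaussian (Debye-Waller) approximation
  S(Q, w=0) = I0 * exp(-<u2> Q^2 / 6), fitted as a weighted linear regression
  of ln S on Q^2. <u2> is the full three-dimensional amplitude relative to the
  reference temperature; the per-atom displacement scale is <u2>/6.
* :class:`BimodalElasticModel` — the two-population mixture
  S = I0 * [a1 exp(-<u2>_1 Q^2/6) + a2 exp(-<u2>_2 Q^2/6)] with fixed
  fractions (methyl vs non-methyl non-exchangeable hydrogens) and the
  ordering constraint <u2>_1 >= <u2>_2.
* :class:`EinsteinOscillatorModel` — the low-temperature harmonic law
  <u2>(T)/3 = (h nu / 2 k) [coth(h nu / 2 kB T) - 1], fitted to an MSD-vs-T
  series relative to the reference temperature.
* :class:`PiecewiseLinearModel` — continuous piecewise-linear regression with
  0..max_breakpoints hinge breakpoints chosen by exhaustive search over the
  observed abscissae and model order selected by BIC; used to locate
  slope-change transitions (methyl-group activation, the 240 K dynamical
  transition) in summed elastic intensities.

All estimators follow the sklearn contract: ``fit(X, y, sample_weight)`` with
X of shape (n, 1), ``predict(X)``, ``get_params``/``set_params``, and fitted
attributes with trailing underscores, so they compose with sklearn pipelines
and model selection. Sample weights are inverse-variance weights.
"""

from __future__ import annotations

import itertools
import math
from typing import Tuple

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .constants import K_B, M2_TO_A2, PER_PS_TO_PER_S, PLANCK_H

__all__ = [
    "oscillator_msd",
    "GaussianElasticModel",
    "BimodalElasticModel",
    "EinsteinOscillatorModel",
    "PiecewiseLinearModel",
]


def oscillator_msd(force_constant_k, frequency_nu, temperature):
    """Einstein-oscillator mean square displacement <u2>(T) in AA^2.

    Implements <u2>/3 = (h nu / 2k) [coth(h nu / 2 kB T) - 1] with h Planck's
    constant, k the force constant (N/m) and nu the mean frequency (1/ps).
    The bracketed "-1" removes the zero-point term, so <u2>(0) = 0. Uses
    coth(x) - 1 = 2/(exp(2x) - 1) for numerical stability at large x.
    """
    k = float(force_constant_k)
    nu = float(frequency_nu)
    if k <= 0 or nu <= 0:
        raise ValueError("force constant and frequency must be positive")
    t = np.asarray(temperature, dtype=float)
    if np.any(t < 0):
        raise ValueError("temperature must be >= 0")
    h_nu = PLANCK_H * nu * PER_PS_TO_PER_S  # J
    prefactor = 3.0 * h_nu / (2.0 * k) * M2_TO_A2  # AA^2
    with np.errstate(divide="ignore", over="ignore"):
        x = np.where(t > 0, h_nu / (2.0 * K_B * np.maximum(t, 1e-300)), np.inf)
        bracket = 2.0 / np.expm1(2.0 * x)  # coth(x) - 1; -> 0 as x -> inf
    out = prefactor * np.where(t > 0, bracket, 0.0)
    return out if out.ndim else float(out)


def _as_column(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2 or X.shape[1] != 1:
        raise ValueError("X must have shape (n_samples, 1)")
    return X


def _weights(sample_weight, n) -> np.ndarray:
    """Inverse-variance weights; fall back to unit weights when absent/degenerate."""
    if sample_weight is None:
        return np.ones(n)
    w = np.asarray(sample_weight, dtype=float)
    if w.shape != (n,):
        raise ValueError("sample_weight has wrong shape")
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("sample_weight must be finite and non-negative")
    if not np.any(w > 0):
        return np.ones(n)
    return w


class GaussianElasticModel(RegressorMixin, BaseEstimator):
    """Debye-Waller fit: ln S = ln I0 - (<u2>/6) Q^2, by closed-form WLS.

    ``fit`` takes X = Q^2 (1/AA^2, column vector) and y = normalised elastic
    intensity S; ``sample_weight`` are inverse-variance weights of ln S.
    If no weights are given, parameter variances are scaled by the residual
    variance; with true counting weights they are reported unscaled.

    Attributes
    ----------
    msd_ : float
        <u2> in AA^2 (full 3-D amplitude relative to the reference scan).
    msd_stderr_, i0_, i0_stderr_, slope_, intercept_ : floats
    n_points_ : int
    """

    def __init__(self, min_points: int = 3):
        self.min_points = min_points

    def fit(self, X, y, sample_weight=None):
        q2 = _as_column(X)[:, 0]
        s = np.asarray(y, dtype=float)
        if s.shape != q2.shape:
            raise ValueError("X and y length mismatch")
        if np.any(s <= 0):
            raise ValueError("elastic intensities must be positive for the log fit")
        if q2.size < self.min_points:
            raise ValueError(
                f"need at least {self.min_points} points, got {q2.size}"
            )
        w = _weights(sample_weight, q2.size)
        ly = np.log(s)

        sw = w.sum()
        xm = (w * q2).sum() / sw
        ym = (w * ly).sum() / sw
        sxx = (w * (q2 - xm) ** 2).sum()
        if sxx <= 0:
            raise ValueError("degenerate Q^2 design (no spread)")
        sxy = (w * (q2 - xm) * (ly - ym)).sum()
        slope = sxy / sxx
        intercept = ym - slope * xm

        var_slope = 1.0 / sxx
        var_intercept = 1.0 / sw + xm**2 / sxx
        if sample_weight is None:
            resid = ly - (intercept + slope * q2)
            dof = max(q2.size - 2, 1)
            s2 = float((w * resid**2).sum() / dof)
            var_slope *= s2
            var_intercept *= s2

        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.msd_ = float(-6.0 * slope)
        self.msd_stderr_ = float(6.0 * math.sqrt(var_slope))
        self.i0_ = float(math.exp(intercept))
        self.i0_stderr_ = float(self.i0_ * math.sqrt(var_intercept))
        self.n_points_ = int(q2.size)
        return self

    def predict(self, X):
        check_is_fitted(self, "msd_")
        q2 = _as_column(X)[:, 0]
        return self.i0_ * np.exp(-self.msd_ * q2 / 6.0)


def _bimodal_s(q2, i0, a1, u1, u2):
    return i0 * (a1 * np.exp(-u1 * q2 / 6.0) + (1 - a1) * np.exp(-u2 * q2 / 6.0))


class BimodalElasticModel(RegressorMixin, BaseEstimator):
    """Two-population elastic fit with fixed (or free) population fractions.

    Parametrised as (I0, <u2>_2, delta[, a1]) with <u2>_1 = <u2>_2 + delta,
    delta >= 0, which enforces the ordering <u2>_1 >= <u2>_2 (population 1 is
    the mobile methyl class) and prevents label swapping. Solved by bounded
    trust-region least squares from a Gaussian-fit-derived start.

    Parameters
    ----------
    a1 : float
        Methyl population fraction (a2 = 1 - a1). Default 0.26.
    free_fractions : bool
        If true, a1 is fitted within [0, 1] as well.
    """

    _MAX_U2 = 60.0  # AA^2, generous bound for relative MSDs of hydrated powders

    def __init__(self, a1: float = 0.26, free_fractions: bool = False):
        self.a1 = a1
        self.free_fractions = free_fractions

    def fit(self, X, y, sample_weight=None):
        q2 = _as_column(X)[:, 0]
        s = np.asarray(y, dtype=float)
        if s.shape != q2.shape:
            raise ValueError("X and y length mismatch")
        if not 0 <= self.a1 <= 1:
            raise ValueError("a1 must lie in [0, 1]")
        w = _weights(sample_weight, q2.size)
        sw = np.sqrt(w)

        # start from the single-Gaussian solution on the same window
        try:
            g = GaussianElasticModel().fit(
                q2[:, None][s > 0], s[s > 0], sample_weight=None
            )
            u_start, i0_start = max(g.msd_, 1e-3), min(max(g.i0_, 1e-3), 5.0)
        except ValueError:
            u_start, i0_start = 0.5, 1.0

        free_a1 = bool(self.free_fractions)
        a1_eff = max(self.a1, 1e-3)
        # theta = [i0, u2, delta, (a1)]; multistart guards against convergence
        # to the collapsed (u1 = u2) saddle when a separated minimum exists
        starts = [
            (0.5 * u_start, 1.5 * u_start),
            (0.25 * u_start, min(u_start / a1_eff, self._MAX_U2 / 2)),
            (0.9 * u_start, 0.2 * u_start),
            (0.05 * u_start, min(3.0 * u_start, self._MAX_U2 / 2)),
        ]
        lo, hi = [1e-6, 0.0, 0.0], [10.0, self._MAX_U2, self._MAX_U2]
        if free_a1:
            lo.append(0.0)
            hi.append(1.0)

        def resid(theta):
            i0, u2, d = theta[:3]
            a1 = theta[3] if free_a1 else self.a1
            return sw * (_bimodal_s(q2, i0, a1, u2 + d, u2) - s)

        res = None
        for u2_0, d_0 in starts:
            theta0 = [i0_start, u2_0, d_0]
            if free_a1:
                theta0.append(float(np.clip(self.a1, 1e-3, 1 - 1e-3)))
            cand = least_squares(
                resid, theta0, bounds=(lo, hi), method="trf",
                ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=2000,
            )
            if res is None or cand.cost < res.cost:
                res = cand
        self.converged_ = bool(res.success)
        self.status_message_ = str(res.message)

        i0, u2, d = res.x[:3]
        a1 = float(res.x[3]) if free_a1 else float(self.a1)
        self.i0_ = float(i0)
        self.msd2_ = float(u2)
        self.msd1_ = float(u2 + d)
        self.a1_ = a1
        self.a2_ = 1.0 - a1
        self.cost_ = float(res.cost)
        # ordering bound active => collapsed solution: the two-population split
        # is unidentified at this temperature (Jacobian singular along the
        # u1 <-> u2 exchange direction)
        self.separated_ = bool(d > 1e-4)

        # stderr from the Jacobian; propagate var(u1) = var(u2) + var(d) + 2 cov
        stderr = np.full(res.x.size, np.nan)
        cov = None
        try:
            jtj = res.jac.T @ res.jac
            dof = max(q2.size - res.x.size, 1)
            s2 = 2.0 * res.cost / dof if sample_weight is None else 1.0
            cov = np.linalg.pinv(jtj) * s2
            stderr = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
        self.i0_stderr_ = float(stderr[0])
        self.msd2_stderr_ = float(stderr[1])
        if cov is not None:
            v1 = cov[1, 1] + cov[2, 2] + 2.0 * cov[1, 2]
            self.msd1_stderr_ = float(math.sqrt(max(v1, 0.0)))
        else:
            self.msd1_stderr_ = float("nan")
        self.a1_stderr_ = float(stderr[3]) if free_a1 else 0.0

        if not self.separated_ and cov is not None:
            # Only the population average u_avg = u2 + a1*d is identified here.
            # Quote each population at u_avg with an uncertainty that spans the
            # interval of equally good solutions (u1 in [u_avg, u_avg/a1],
            # u2 in [0, u_avg]) on top of the measurement error of u_avg.
            u_avg = float(u2 + a1 * d)
            var_avg = cov[1, 1] + (a1**2) * cov[2, 2] + 2.0 * a1 * cov[1, 2]
            sigma_avg = math.sqrt(max(var_avg, 0.0))
            a1_safe = max(a1, 1e-3)
            self.msd1_stderr_ = sigma_avg + 0.5 * u_avg * (1.0 / a1_safe - 1.0)
            self.msd2_stderr_ = sigma_avg + 0.5 * u_avg
        return self

    def predict(self, X):
        check_is_fitted(self, "msd1_")
        q2 = _as_column(X)[:, 0]
        return _bimodal_s(q2, self.i0_, self.a1_, self.msd1_, self.msd2_)


class EinsteinOscillatorModel(RegressorMixin, BaseEstimator):
    """Low-temperature harmonic fit of an MSD-vs-T series.

    Fits <u2>_model(T) = u2_osc(k, nu, T) - u2_osc(k, nu, T_ref), i.e. the
    oscillator law referenced to the normalisation temperature, since measured
    MSDs are displacements relative to the reference scan (zero at T_ref).
    A multistart grid over (k, nu) in [0.1, 50] N/m x [0.1, 20] 1/ps guards
    against local minima.

    ``fit`` takes X = temperature (K) and y = <u2> (AA^2); ``sample_weight``
    are inverse-variance weights.

    Attributes
    ----------
    force_constant_k_ : float   fitted k in N/m
    frequency_nu_ : float       fitted nu in 1/ps
    k_stderr_, nu_stderr_ : floats
    """

    _BOUNDS = ((1e-3, 1e-3), (500.0, 200.0))

    def __init__(
        self,
        reference_temperature: float = 20.0,
        n_starts: int = 5,
        k_grid: Tuple[float, float] = (0.1, 50.0),
        nu_grid: Tuple[float, float] = (0.1, 20.0),
        min_points: int = 5,
    ):
        self.reference_temperature = reference_temperature
        self.n_starts = n_starts
        self.k_grid = k_grid
        self.nu_grid = nu_grid
        self.min_points = min_points

    def _model(self, k, nu, t):
        return oscillator_msd(k, nu, t) - oscillator_msd(
            k, nu, self.reference_temperature
        )

    def fit(self, X, y, sample_weight=None):
        t = _as_column(X)[:, 0]
        u2 = np.asarray(y, dtype=float)
        if u2.shape != t.shape:
            raise ValueError("X and y length mismatch")
        if t.size < self.min_points:
            raise ValueError(f"need at least {self.min_points} points")
        if np.allclose(u2, 0.0):
            raise ValueError("all-zero MSD series: oscillator parameters unidentifiable")
        w = _weights(sample_weight, t.size)
        sw = np.sqrt(w)

        def resid(theta):
            return sw * (self._model(theta[0], theta[1], t) - u2)

        ks = np.geomspace(*self.k_grid, self.n_starts)
        nus = np.geomspace(*self.nu_grid, self.n_starts)
        best = None
        for k0, nu0 in itertools.product(ks, nus):
            res = least_squares(
                resid, [k0, nu0], bounds=self._BOUNDS, method="trf",
                ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=1000,
            )
            if best is None or res.cost < best.cost - 1e-300 or (
                res.cost < best.cost * (1 + 1e-10) and res.success and not best.success
            ):
                if best is None or res.cost < best.cost:
                    best = res
        res = best
        self.converged_ = bool(res.success)
        self.force_constant_k_ = float(res.x[0])
        self.frequency_nu_ = float(res.x[1])
        self.cost_ = float(res.cost)

        stderr = np.full(2, np.nan)
        try:
            jtj = res.jac.T @ res.jac
            dof = max(t.size - 2, 1)
            s2 = 2.0 * res.cost / dof if sample_weight is None else 1.0
            cov = np.linalg.pinv(jtj) * s2
            stderr = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            pass
        self.k_stderr_ = float(stderr[0])
        self.nu_stderr_ = float(stderr[1])
        return self

    def predict(self, X):
        check_is_fitted(self, "force_constant_k_")
        t = _as_column(X)[:, 0]
        return self._model(self.force_constant_k_, self.frequency_nu_, t)


class PiecewiseLinearModel(RegressorMixin, BaseEstimator):
    """Continuous piecewise-linear regression with BIC-selected breakpoints.

    Fits y = b0 + b1*x + sum_j c_j * max(0, x - tau_j) for every candidate
    breakpoint set drawn from the observed x values (exhaustive search,
    0..max_breakpoints breaks, at least ``min_segment`` points strictly on
    each side of every break), and keeps the break count minimising the
    modified BIC  n ln(RSS/n) + p ln(n)  with p = 2 + break_penalty * n_breaks.
    The default break_penalty = 3 charges each break its slope-change and
    location parameters plus one extra ln(n) location term (changepoint-BIC in
    the spirit of Zhang & Siegmund), which compensates the selection effect of
    scanning every candidate position; plain BIC over-detects on series of
    this length.

    Attributes
    ----------
    breakpoints_ : list of float
    segment_slopes_ : list of float   slope of each consecutive segment
    bic_ : float                      score of the selected model
    n_breakpoints_ : int
    """

    def __init__(
        self,
        max_breakpoints: int = 2,
        min_segment: int = 3,
        break_penalty: float = 3.0,
    ):
        self.max_breakpoints = max_breakpoints
        self.min_segment = min_segment
        self.break_penalty = break_penalty

    @staticmethod
    def _design(x, taus):
        cols = [np.ones_like(x), x]
        cols += [np.maximum(0.0, x - tau) for tau in taus]
        return np.column_stack(cols)

    def fit(self, X, y, sample_weight=None):
        x = _as_column(X)[:, 0]
        yv = np.asarray(y, dtype=float)
        if yv.shape != x.shape:
            raise ValueError("X and y length mismatch")
        order = np.argsort(x)
        x, yv = x[order], yv[order]
        w = _weights(sample_weight, x.size)[order]
        sw = np.sqrt(w)
        n = x.size
        if n < 2 * self.min_segment + 2:
            raise ValueError("too few points for breakpoint search")

        # candidate breaks: interior observed x with min_segment points per side
        lo, hi = self.min_segment, n - self.min_segment
        candidates = x[lo:hi]
        scale = max(float(np.max(np.abs(yv))), 1e-12)
        rss_floor = n * (1e-9 * scale) ** 2

        best = None  # (bic, taus, beta, rss)
        for n_br in range(self.max_breakpoints + 1):
            for taus in itertools.combinations(candidates, n_br):
                if len(set(taus)) < n_br:
                    continue
                A = self._design(x, taus) * sw[:, None]
                beta, *_ = np.linalg.lstsq(A, yv * sw, rcond=None)
                rss = float(np.sum((A @ beta - yv * sw) ** 2))
                p = 2 + self.break_penalty * n_br
                bic = n * math.log(max(rss, rss_floor) / n) + p * math.log(n)
                if best is None or bic < best[0] - 1e-12:
                    best = (bic, list(taus), beta, rss)

        bic, taus, beta, rss = best
        self.breakpoints_ = [float(t) for t in taus]
        self.bic_ = float(bic)
        self.rss_ = float(rss)
        self.n_breakpoints_ = len(taus)
        self._beta = beta
        slopes = [float(beta[1])]
        for j in range(len(taus)):
            slopes.append(slopes[-1] + float(beta[2 + j]))
        self.segment_slopes_ = slopes
        return self

    def predict(self, X):
        check_is_fitted(self, "breakpoints_")
        x = _as_column(X)[:, 0]
        return self._design(x, self.breakpoints_) @ self._beta
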