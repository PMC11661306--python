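"""Longitudinal reporting-fatigue dynamics.

The observation model for a participant's contact total at repeat ``r`` is

    Y ~ NegBinomial(lambda, phi),
    log lambda = beta0 + x'beta + tau(t) + rho(r),

with ``tau`` a zero-mean Gaussian process over calendar time (Matérn-3/2
kernel) capturing the pandemic trend, and ``rho`` the fatigue term, for
which four interchangeable forms are supported:

* ``independent`` — a free effect per repeat count r >= 1 (no functional
  form assumed);
* ``identical`` — a single shared effect for every r >= 1;
* ``gp`` — a squared-exponential GP over standardized repeat counts;
* ``hill`` — the three-parameter Hill dose-response
  rho(r) = -gamma * e^zeta r^eta / (1 + e^zeta r^eta),
  a saturating curve with rho(0) = 0 and asymptote -gamma, where
  repeat participation plays the role of the dose and under-reporting
  the response.

All variants anchor rho(0) = 0, so fatigue is identified as a contrast
against first-time participants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import WaveDataset
from .sampling import (
    NegBinLogLik,
    PosteriorSummary,
    exponential_lp,
    half_cauchy_lp,
    half_normal_lp,
    inv_gamma_lp,
    log_jac,
    normal_lp,
    run_mcmc,
)

VARIANTS = ("independent", "identical", "gp", "hill")


@dataclass(frozen=True)
class HillParams:
    """Hill dose-response parameters: asymptote scale ``gamma`` > 0,
    log half-saturation ``zeta``, shape ``eta`` > 0."""

    gamma: float
    zeta: float
    eta: float

    def __post_init__(self):
        if not (np.isfinite(self.gamma) and np.isfinite(self.zeta) and np.isfinite(self.eta)):
            raise ValueError("Hill parameters must be finite")
        if self.gamma < 0 or self.eta <= 0:
            raise ValueError("require gamma >= 0 and eta > 0")


@dataclass(frozen=True)
class KernelParams:
    """GP kernel parameters; ``amplitude`` is the variance at zero distance."""

    amplitude: float
    lengthscale: float

    def __post_init__(self):
        if self.amplitude <= 0 or self.lengthscale <= 0:
            raise ValueError("kernel parameters must be positive")


def hill_effect(r, params: HillParams):
    """Log-scale fatigue effect rho(r) = -gamma e^zeta r^eta / (1 + e^zeta r^eta).

    Vectorized over ``r``; rho(0) = 0 exactly and rho -> -gamma as r grows.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("repeat counts must be >= 0")
    with np.errstate(divide="ignore"):
        log_t = np.where(r > 0, params.zeta + params.eta * np.log(np.maximum(r, 1e-300)), -np.inf)
    t = np.exp(log_t)
    out = -params.gamma * t / (1.0 + t)
    return float(out) if out.ndim == 0 else out


def percent_reduction(rho):
    """Percent change in expected contacts implied by a log-scale effect."""
    out = 100.0 * (np.exp(np.asarray(rho, dtype=float)) - 1.0)
    return float(out) if out.ndim == 0 else out


def matern32(t, t2, params: KernelParams):
    """Matérn-3/2 kernel sigma (1 + sqrt3 d / l) exp(-sqrt3 d / l).

    The amplitude enters linearly, acting as the variance at distance zero.
    """
    d = np.abs(np.asarray(t, dtype=float) - np.asarray(t2, dtype=float))
    s = np.sqrt(3.0) * d / params.lengthscale
    out = params.amplitude * (1.0 + s) * np.exp(-s)
    return float(out) if out.ndim == 0 else out


def squared_exponential(t, t2, params: KernelParams):
    """SE kernel sigma exp(-d^2 / (2 l^2)); amplitude linear, as for Matérn."""
    d = np.asarray(t, dtype=float) - np.asarray(t2, dtype=float)
    out = params.amplitude * np.exp(-0.5 * (d / params.lengthscale) ** 2)
    return float(out) if out.ndim == 0 else out


def standardize_repeats(r_values, ddof: int = 1) -> np.ndarray:
    """Center and scale repeat counts to zero mean, unit (sample) sd."""
    arr = np.asarray(r_values, dtype=float)
    sd = arr.std(ddof=ddof)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot standardize constant repeat counts")
    return (arr - arr.mean()) / sd


@dataclass
class FatigueModelSpec:
    """Configuration of the longitudinal fit: fatigue variant, maximum
    repeat count R, and which tested-block columns join the design."""

    variant: str = "hill"
    max_repeats: int | None = None
    tested_columns: tuple[str, ...] = ()

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")


# ---------------------------------------------------------------------------
# model internals


def _matern_corr(dist: np.ndarray, ell: np.ndarray) -> np.ndarray:
    """(m, D, D) Matérn-3/2 correlation for per-walker lengthscales."""
    s = np.sqrt(3.0) * dist[None, :, :] / ell[:, None, None]
    return (1.0 + s) * np.exp(-s)


def _se_corr(dist: np.ndarray, ell: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * (dist[None, :, :] / ell[:, None, None]) ** 2)


def _whitened_gp(z: np.ndarray, sigma: np.ndarray, corr: np.ndarray) -> np.ndarray:
    """Draw-specific GP values L z with K = sigma * corr + jitter.

    z: (m, D); sigma: (m,); corr: (m, D, D) -> (m, D).
    """
    m, D = z.shape
    K = sigma[:, None, None] * corr
    K[:, np.arange(D), np.arange(D)] += (1e-8 + 1e-6 * sigma)[:, None]
    L = np.linalg.cholesky(K)
    return np.einsum("mij,mj->mi", L, z)


class LongitudinalModel:
    """Vectorized log posterior for the longitudinal fatigue model."""

    def __init__(self, panel: WaveDataset, spec: FatigueModelSpec):
        self.spec = spec
        rec = panel.records
        mask_u = np.array(panel.schema.estimable_mask("always_in"))
        X = panel.U[:, mask_u]
        self.x_names = [n for n, m in zip(panel.schema.column_names("always_in"), mask_u) if m]
        if spec.tested_columns:
            names_v = panel.schema.column_names("tested")
            idx = [names_v.index(c) for c in spec.tested_columns]
            X = np.hstack([X, panel.V[:, idx]])
            self.x_names += list(spec.tested_columns)
        self.X = X
        self.y = panel.y
        self.loglik = NegBinLogLik(self.y)

        dates = panel.dates
        lo, hi = dates.min(), dates.max()
        span = max(hi - lo, 1.0)
        t_std = (dates - lo) / span
        self.t_unique, self.date_idx = np.unique(t_std, return_inverse=True)
        self.date_dist = np.abs(self.t_unique[:, None] - self.t_unique[None, :])

        r = panel.r
        self.R = int(spec.max_repeats if spec.max_repeats is not None else r.max())
        if r.max() > self.R:
            raise ValueError("records contain repeat counts above max_repeats")
        self.r_idx = r
        self.r_grid = np.arange(self.R + 1, dtype=float)
        if spec.variant == "gp" and self.R >= 2:
            self.r_std = standardize_repeats(np.arange(1, self.R + 1))
            self.r_dist = np.abs(self.r_std[:, None] - self.r_std[None, :])

        self.k_beta = X.shape[1]
        self.D = len(self.t_unique)
        self.n_rho = {"independent": self.R, "identical": 1, "gp": self.R + 2,
                      "hill": 3}[spec.variant]
        # layout: b0 | z_beta (k) | log sigma_beta | log phi_inv |
        #         log sigma_tau | log ell_tau | z_tau (D) | rho block
        self.dim = 1 + self.k_beta + 1 + 1 + 2 + self.D + self.n_rho

    def initial_point(self) -> np.ndarray:
        x0 = np.zeros(self.dim)
        x0[0] = np.log(self.y.mean() + 0.1)
        x0[1 + self.k_beta] = np.log(0.5)           # sigma_beta
        off = 1 + self.k_beta + 2
        x0[off] = np.log(0.1)                        # sigma_tau (variance)
        x0[off + 1] = np.log(0.25)                   # ell_tau
        return x0

    def _split(self, T: np.ndarray):
        k, D = self.k_beta, self.D
        i = 0
        b0 = T[:, i]; i += 1
        z_beta = T[:, i:i + k]; i += k
        log_sb = T[:, i]; i += 1
        log_phi_inv = T[:, i]; i += 1
        log_st = T[:, i]; i += 1
        log_lt = T[:, i]; i += 1
        z_tau = T[:, i:i + D]; i += D
        rho_raw = T[:, i:]
        return b0, z_beta, log_sb, log_phi_inv, log_st, log_lt, z_tau, rho_raw

    def _rho_grid(self, rho_raw: np.ndarray) -> tuple[np.ndarray, float]:
        """Fatigue values on the grid 0..R per walker: (m, R+1), plus
        the log prior of the variant's parameters."""
        m = rho_raw.shape[0]
        grid = np.zeros((m, self.R + 1))
        variant = self.spec.variant
        if variant == "independent":
            grid[:, 1:] = rho_raw
            lp = normal_lp(rho_raw).sum(axis=1)
        elif variant == "identical":
            grid[:, 1:] = rho_raw[:, [0]]
            lp = normal_lp(rho_raw[:, 0])
        elif variant == "gp":
            z = rho_raw[:, :self.R]
            sig = np.exp(rho_raw[:, self.R])
            ell = np.exp(rho_raw[:, self.R + 1])
            corr = _se_corr(self.r_dist, ell)
            grid[:, 1:] = _whitened_gp(z, sig, corr)
            lp = (normal_lp(z).sum(axis=1)
                  + inv_gamma_lp(sig, 5.0, 1.0) + log_jac(rho_raw[:, self.R])
                  + inv_gamma_lp(ell, 5.0, 1.0) + log_jac(rho_raw[:, self.R + 1]))
        else:  # hill
            gamma = np.exp(rho_raw[:, 0])
            zeta = rho_raw[:, 1]
            eta = np.exp(rho_raw[:, 2])
            with np.errstate(divide="ignore"):
                logr = np.log(self.r_grid[1:])
            grid[:, 1:] = -gamma[:, None] * expit(zeta[:, None] + eta[:, None] * logr[None, :])
            lp = (half_normal_lp(gamma, 1.0) + log_jac(rho_raw[:, 0])
                  + normal_lp(zeta)
                  + exponential_lp(eta, 1.0) + log_jac(rho_raw[:, 2]))
        return grid, lp

    def log_post(self, T: np.ndarray) -> np.ndarray:
        T = np.atleast_2d(T)
        b0, z_beta, log_sb, log_phi_inv, log_st, log_lt, z_tau, rho_raw = self._split(T)
        sb = np.exp(log_sb)
        beta = sb[:, None] * z_beta
        phi_inv = np.exp(log_phi_inv)
        phi = 1.0 / phi_inv
        sig_t = np.exp(log_st)
        ell_t = np.exp(log_lt)

        corr = _matern_corr(self.date_dist, ell_t)
        tau = _whitened_gp(z_tau, sig_t, corr)  # (m, D)
        rho_grid, lp_rho = self._rho_grid(rho_raw)

        eta_lin = (b0[None, :]
                   + self.X @ beta.T
                   + tau.T[self.date_idx, :]
                   + rho_grid.T[self.r_idx, :])  # (n, m)
        ll = self.loglik(eta_lin, phi)

        lp = (normal_lp(b0, 0.0, 10.0)
              + normal_lp(z_beta).sum(axis=1)
              + half_cauchy_lp(sb) + log_jac(log_sb)
              + exponential_lp(phi_inv) + log_jac(log_phi_inv)
              + inv_gamma_lp(sig_t, 5.0, 1.0) + log_jac(log_st)
              + inv_gamma_lp(ell_t, 5.0, 1.0) + log_jac(log_lt)
              + normal_lp(z_tau).sum(axis=1)
              + lp_rho)
        return ll + lp

    def constrain(self, T: np.ndarray) -> dict[str, np.ndarray]:
        b0, z_beta, log_sb, log_phi_inv, log_st, log_lt, z_tau, rho_raw = self._split(T)
        sb = np.exp(log_sb)
        out = {
            "beta0": b0,
            "beta": sb[:, None] * z_beta,
            "sigma_beta": sb,
            "phi": np.exp(-log_phi_inv),
            "sigma_tau": np.exp(log_st),
            "ell_tau": np.exp(log_lt),
        }
        sig_t = np.exp(log_st)
        ell_t = np.exp(log_lt)
        corr = _matern_corr(self.date_dist, ell_t)
        out["tau"] = _whitened_gp(z_tau, sig_t, corr)
        grid, _ = self._rho_grid(rho_raw)
        out["rho_grid"] = grid
        if self.spec.variant == "hill":
            out["gamma"] = np.exp(rho_raw[:, 0])
            out["zeta"] = rho_raw[:, 1]
            out["eta"] = np.exp(rho_raw[:, 2])
        return out


def fit_longitudinal_model(panel: WaveDataset, spec: FatigueModelSpec, seed: int,
                           **mcmc_kwargs) -> PosteriorSummary:
    """Fit the longitudinal negative-binomial fatigue model to a panel.

    The panel must span multiple calendar dates and contain repeat counts
    up to ``spec.max_repeats``.  Returns posterior draws for the fixed
    effects, overdispersion, the calendar GP at each unique date and the
    fatigue curve on the grid r = 0..R (block ``rho_grid``), plus the Hill
    parameters when that variant is used.
    """
    if len(np.unique(panel.dates)) < 2:
        raise ValueError("panel must span multiple calendar dates")
    model = LongitudinalModel(panel, spec)
    return run_mcmc(model, seed, label=f"longitudinal[{spec.variant}]", **mcmc_kwargs)


def reduction_curve(summary: PosteriorSummary, r_grid=None) -> pd.DataFrame:
    """Percent reduction in contact intensity per repeat count.

    Returns one row per r with the posterior median and central 95%
    interval of 100 (e^rho(r) - 1).  r = 0 is the identifiability anchor
    (exact zero, zero-width interval).
    """
    grid_draws = summary.stacked("rho_grid")  # (draws, R+1)
    R = grid_draws.shape[1] - 1
    rs = np.arange(R + 1) if r_grid is None else np.asarray(r_grid, dtype=int)
    if np.any(rs > R):
        raise ValueError("requested repeat counts beyond fitted grid")
    pct = 100.0 * (np.exp(grid_draws[:, rs]) - 1.0)
    qs = np.percentile(pct, [2.5, 50, 97.5], axis=0)
    return pd.DataFrame({
        "r": rs,
        "median": qs[1],
        "lower95": qs[0],
        "upper95": qs[2],
    })
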