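"""Bayesian variable selection with regularized horseshoe (RHS) priors.

Two selection stages operate on single survey waves:

* **contact-intensity determinants** — a Poisson log-linear model on
  first-time participants, with hierarchical normal effects for the
  always-in covariates (age group, sex, household size) and RHS priors on
  the 16-column tested block (employment, symptoms, day of week, urban
  type).  A tested feature is selected when its posterior median effect
  falls outside (log 0.95, log 1.05) = (-0.0513, 0.0488), i.e. changes
  baseline intensity by more than 5%;

* **reporting-fatigue determinants** — a Poisson model on repeating
  participants whose linear predictor is offset by plug-in posterior
  medians from a refit of the intensity model (standard-normal priors on
  the previously selected features), plus per-category fatigue effects
  gamma over the 33-column fatigue block.  Each gamma is constrained
  non-positive through a negative half-RHS prior whose half-normal scale
  carries the (1 - 2/pi)^-1 variance-matching adjustment; a category is
  selected when its median effect reduces intensity by more than 5%
  (median < log 0.95).

Final feature sets are unions of per-wave selections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import WaveDataset
from .sampling import (
    PosteriorSummary,
    gamma_lp,
    half_cauchy_lp,
    half_normal_lp,
    half_student_t_lp,
    log_jac,
    normal_lp,
    poisson_loglik,
    run_mcmc,
)

#: +-5% change thresholds on the log scale
SELECT_LOWER = float(np.log(0.95))
SELECT_UPPER = float(np.log(1.05))

_HALF_VAR_ADJ = 1.0 / (1.0 - 2.0 / np.pi)


def rhs_epsilon0(p0: float, P: int, n: int) -> float:
    """Reference global scale p0 / (P - p0) * n^(-1/2) for the RHS prior.

    ``p0`` is the prior guess of the number of non-zero coefficients among
    the ``P`` tested ones, ``n`` the sample size.
    """
    if not (0 < p0 < P):
        raise ValueError("require 0 < p0 < P")
    if n <= 0:
        raise ValueError("sample size must be positive")
    return p0 / (P - p0) / np.sqrt(n)


def half_rhs_scale(eps: float, zeta_tilde: float) -> float:
    """Half-normal scale of the sign-constrained RHS slab component.

    The squared scale is (1 - 2/pi)^-1 eps^2 zeta_tilde^2; the inflation
    makes the variance of the negative half-normal equal eps^2 zeta_tilde^2,
    the variance of the corresponding unconstrained RHS normal.
    """
    if eps < 0 or zeta_tilde < 0:
        raise ValueError("eps and zeta_tilde must be non-negative")
    return float(np.sqrt(_HALF_VAR_ADJ) * eps * zeta_tilde)


@dataclass(frozen=True)
class RHSConfig:
    """RHS hyperparameters: local/slab/global degrees of freedom
    (nu1, nu2, nu3), slab scale s^2, and the prior guess p0 of non-zero
    coefficients (default: half the tested block)."""

    nu1: float = 3.0
    nu2: float = 2.0
    nu3: float = 4.0
    s2: float = 2.0
    p0: float | None = None  # default K/2, resolved at fit time

    def __post_init__(self):
        if min(self.nu1, self.nu2, self.nu3, self.s2) <= 0:
            raise ValueError("RHS hyperparameters must be positive")

    def resolve_p0(self, K: int) -> float:
        p0 = K / 2.0 if self.p0 is None else float(self.p0)
        if not (0 < p0 < K):
            raise ValueError(f"p0 must lie strictly between 0 and {K}")
        return p0


@dataclass
class SelectionResult:
    """Outcome of one selection stage: the selected feature set plus the
    per-feature posterior medians and percent changes from baseline."""

    selected: set[str]
    table: pd.DataFrame  # feature, median, percent_change, selected
    thresholds: tuple[float, float]
    provenance: dict[str, set[str]] = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return self.table["feature"].tolist()


def _zeta_tilde_sq(zeta_sq, eps_sq, c_sq):
    return c_sq * zeta_sq / (c_sq + eps_sq * zeta_sq)


class _IntensitySelectionModel:
    """Poisson GLM, hierarchical always-in effects, RHS tested effects.

    Unconstrained layout:
    b0 | z_alpha (Ka) | log sigma_alpha | b (K) | log zeta (K) | log eps | log c2
    with beta_k = eps * zeta_tilde_k * b_k (non-centered RHS).
    """

    def __init__(self, data: WaveDataset, config: RHSConfig,
                 beta_prior: str = "rhs", tested_subset=None):
        rec = data.records
        first = rec["repeat_count"].to_numpy() == 0
        self.mask_u = np.array(data.schema.estimable_mask("always_in"))
        mask_v = np.array(data.schema.estimable_mask("tested"))
        self.v_names_all = data.schema.column_names("tested")
        if tested_subset is not None:
            keep = np.array([n in set(tested_subset) for n in self.v_names_all])
            mask_v = mask_v & keep
        self.mask_v = mask_v
        self.U = data.U[first][:, self.mask_u]
        self.V = data.V[first][:, mask_v]
        self.y = data.y[first]
        self.n = len(self.y)
        self.Ka = self.U.shape[1]
        self.K = self.V.shape[1]
        self.beta_prior = beta_prior
        self.config = config
        if beta_prior == "rhs":
            p0 = config.resolve_p0(self.K)
            self.eps0 = rhs_epsilon0(p0, self.K, self.n)
            self.dim = 1 + self.Ka + 1 + self.K + self.K + 1 + 1
        else:
            self.dim = 1 + self.Ka + 1 + self.K
        self.u_names = [n for n, m in zip(data.schema.column_names("always_in"),
                                          self.mask_u) if m]
        self.v_names = [n for n, m in zip(self.v_names_all, mask_v) if m]

    def initial_point(self) -> np.ndarray:
        x0 = np.zeros(self.dim)
        x0[0] = np.log(self.y.mean() + 0.1)
        x0[1 + self.Ka] = np.log(0.5)
        if self.beta_prior == "rhs":
            i = 2 + self.Ka + self.K
            x0[i:i + self.K] = 0.0                      # log zeta
            x0[i + self.K] = np.log(self.eps0)          # log eps
            x0[i + self.K + 1] = np.log(self.config.s2)  # log c2
        return x0

    def _split(self, T):
        Ka, K = self.Ka, self.K
        i = 0
        b0 = T[:, i]; i += 1
        z_a = T[:, i:i + Ka]; i += Ka
        log_sa = T[:, i]; i += 1
        b = T[:, i:i + K]; i += K
        if self.beta_prior != "rhs":
            return b0, z_a, log_sa, b, None, None, None
        log_z = T[:, i:i + K]; i += K
        log_e = T[:, i]; i += 1
        log_c2 = T[:, i]
        return b0, z_a, log_sa, b, log_z, log_e, log_c2

    def _beta(self, b, log_z, log_e, log_c2):
        if self.beta_prior != "rhs":
            return b, 0.0
        zeta_sq = np.exp(2 * log_z)
        eps = np.exp(log_e)
        c_sq = np.exp(log_c2)
        zt_sq = _zeta_tilde_sq(zeta_sq, (eps**2)[:, None], c_sq[:, None])
        beta = b * eps[:, None] * np.sqrt(zt_sq)
        cfg = self.config
        lp = (half_student_t_lp(np.exp(log_z), cfg.nu1).sum(axis=1) + log_jac(log_z).sum(axis=1)
              + half_student_t_lp(eps, cfg.nu3, self.eps0) + log_jac(log_e)
              + gamma_lp(c_sq, cfg.nu2, cfg.nu2 * cfg.s2 / 2.0) + log_jac(log_c2))
        return beta, lp

    def log_post(self, T):
        T = np.atleast_2d(T)
        b0, z_a, log_sa, b, log_z, log_e, log_c2 = self._split(T)
        sa = np.exp(log_sa)
        alpha = sa[:, None] * z_a
        beta, lp_rhs = self._beta(b, log_z, log_e, log_c2)
        eta = b0[None, :] + self.U @ alpha.T + self.V @ beta.T
        ll = poisson_loglik(self.y, eta)
        lp = (normal_lp(b0, 0.0, 100.0)
              + normal_lp(z_a).sum(axis=1)
              + half_cauchy_lp(sa) + log_jac(log_sa)
              + normal_lp(b).sum(axis=1)
              + lp_rhs)
        return ll + lp

    def constrain(self, T):
        b0, z_a, log_sa, b, log_z, log_e, log_c2 = self._split(T)
        sa = np.exp(log_sa)
        beta, _ = self._beta(b, log_z, log_e, log_c2)
        # embed into full block widths, reference columns at zero
        m = T.shape[0]
        alpha_full = np.zeros((m, len(self.mask_u)))
        alpha_full[:, self.mask_u] = sa[:, None] * z_a
        beta_full = np.zeros((m, len(self.mask_v)))
        beta_full[:, self.mask_v] = beta
        out = {"beta0": b0, "alpha": alpha_full, "beta": beta_full, "sigma_alpha": sa}
        if self.beta_prior == "rhs":
            out["eps"] = np.exp(log_e)
            out["c2"] = np.exp(log_c2)
        return out


class _FatigueSelectionModel:
    """Poisson model on repeaters with plug-in offset and negative
    half-RHS fatigue effects over the 33-column block.

    Layout: log s (L) | log zeta (L) | log eps | log c2, with
    gamma_l = -adj * eps * zeta_tilde_l * s_l, s_l ~ half-Normal(0,1).
    """

    def __init__(self, data: WaveDataset, offset: np.ndarray, config: RHSConfig):
        rec = data.records
        rep = rec["repeat_count"].to_numpy() > 0
        if not rep.any():
            raise ValueError("fatigue selection requires repeating participants")
        self.W = data.W[rep]
        self.y = data.y[rep]
        self.offset = np.asarray(offset)[rep]
        self.n = len(self.y)
        self.L = self.W.shape[1]
        self.config = config
        p0 = config.resolve_p0(self.L)
        self.eps0 = rhs_epsilon0(p0, self.L, self.n)
        self.w_names = None  # set by caller
        self.dim = 2 * self.L + 2

    def initial_point(self) -> np.ndarray:
        x0 = np.zeros(self.dim)
        x0[:self.L] = np.log(0.5)
        x0[2 * self.L] = np.log(self.eps0)
        x0[2 * self.L + 1] = np.log(self.config.s2)
        return x0

    def _gamma(self, T):
        L = self.L
        s = np.exp(T[:, :L])
        zeta_sq = np.exp(2 * T[:, L:2 * L])
        eps = np.exp(T[:, 2 * L])
        c_sq = np.exp(T[:, 2 * L + 1])
        zt = np.sqrt(_zeta_tilde_sq(zeta_sq, (eps**2)[:, None], c_sq[:, None]))
        gamma = -np.sqrt(_HALF_VAR_ADJ) * eps[:, None] * zt * s
        cfg = self.config
        lp = (half_normal_lp(s).sum(axis=1) + log_jac(T[:, :L]).sum(axis=1)
              + half_student_t_lp(np.sqrt(zeta_sq), cfg.nu1).sum(axis=1)
              + log_jac(T[:, L:2 * L]).sum(axis=1)
              + half_student_t_lp(eps, cfg.nu3, self.eps0) + log_jac(T[:, 2 * L])
              + gamma_lp(c_sq, cfg.nu2, cfg.nu2 * cfg.s2 / 2.0) + log_jac(T[:, 2 * L + 1]))
        return gamma, lp

    def log_post(self, T):
        T = np.atleast_2d(T)
        gamma, lp = self._gamma(T)
        eta = self.offset[:, None] + self.W @ gamma.T
        return poisson_loglik(self.y, eta) + lp

    def constrain(self, T):
        gamma, _ = self._gamma(T)
        return {"gamma": gamma, "eps": np.exp(T[:, 2 * self.L]),
                "c2": np.exp(T[:, 2 * self.L + 1])}


# ---------------------------------------------------------------------------
# public fits


def fit_intensity_selection_model(data: WaveDataset, config: RHSConfig | None = None,
                                  seed: int = 0, **mcmc_kwargs) -> PosteriorSummary:
    """RHS variable-selection fit for contact-intensity determinants.

    Uses first-time participants only.  The returned summary's ``beta``
    block spans the full 16-column tested block (reference columns pinned
    at zero); feature names are in ``summary.meta['beta_names']``.
    """
    config = config or RHSConfig()
    model = _IntensitySelectionModel(data, config, beta_prior="rhs")
    if model.n == 0:
        raise ValueError("no first-time participants in data")
    summary = run_mcmc(model, seed, label="intensity-selection", **mcmc_kwargs)
    summary.meta["beta_names"] = model.v_names_all
    summary.meta["alpha_names"] = data.schema.column_names("always_in")
    return summary


def fit_intensity_refit_model(data: WaveDataset, selected: set[str] | None = None,
                              seed: int = 0, **mcmc_kwargs) -> PosteriorSummary:
    """Refit of the intensity model with standard-normal priors on the
    selected tested features, providing plug-in medians for the fatigue
    stage.  ``selected=None`` keeps every (non-reference) tested column."""
    model = _IntensitySelectionModel(data, RHSConfig(), beta_prior="normal",
                                     tested_subset=selected)
    summary = run_mcmc(model, seed, label="intensity-refit", **mcmc_kwargs)
    summary.meta["beta_names"] = model.v_names_all
    summary.meta["alpha_names"] = data.schema.column_names("always_in")
    return summary


def plugin_offset(data: WaveDataset, refit: PosteriorSummary) -> np.ndarray:
    """Linear predictor offset beta0_hat + U alpha_hat + V beta_hat from
    posterior medians of the refit model, for every record in ``data``."""
    b0 = refit.median("beta0")
    alpha = refit.median("alpha")
    beta = refit.median("beta")
    return b0 + data.U @ alpha + data.V @ beta


def fit_fatigue_selection_model(data: WaveDataset, plugin: PosteriorSummary | np.ndarray,
                                config: RHSConfig | None = None, seed: int = 0,
                                **mcmc_kwargs) -> PosteriorSummary:
    """Negative half-RHS selection fit for reporting-fatigue determinants.

    ``plugin`` is either the refit summary (medians are plugged in) or a
    precomputed per-record offset.  Only repeating participants enter the
    likelihood; all gamma draws are non-positive by construction.
    """
    config = config or RHSConfig()
    offset = plugin if isinstance(plugin, np.ndarray) else plugin_offset(data, plugin)
    model = _FatigueSelectionModel(data, offset, config)
    summary = run_mcmc(model, seed, label="fatigue-selection", **mcmc_kwargs)
    summary.meta["gamma_names"] = data.schema.column_names("fatigue")
    return summary


# ---------------------------------------------------------------------------
# selection rules


def _selection_table(names, medians, lower, upper, rule):
    sel = rule(np.asarray(medians))
    table = pd.DataFrame({
        "feature": names,
        "median": medians,
        "percent_change": 100.0 * (np.exp(medians) - 1.0),
        "selected": sel,
    })
    return SelectionResult(
        selected=set(table.loc[table["selected"], "feature"]),
        table=table,
        thresholds=(lower, upper),
    )


def select_features(summary: PosteriorSummary, lower: float = SELECT_LOWER,
                    upper: float = SELECT_UPPER) -> SelectionResult:
    """Select tested features whose posterior median effect lies strictly
    outside (lower, upper); defaults are the +-5% thresholds."""
    names = summary.meta["beta_names"]
    medians = summary.median("beta")
    return _selection_table(names, medians, lower, upper,
                            lambda m: (m < lower) | (m > upper))


def select_fatigue_features(summary: PosteriorSummary,
                            threshold: float = SELECT_LOWER) -> SelectionResult:
    """Select fatigue categories whose median reduction exceeds 5%
    (median effect < log 0.95)."""
    names = summary.meta["gamma_names"]
    medians = summary.median("gamma")
    return _selection_table(names, medians, threshold, np.inf,
                            lambda m: m < threshold)


def union_across_waves(results: list[SelectionResult],
                       labels: list[str] | None = None) -> SelectionResult:
    """Final selected set = union of per-wave selections."""
    if not results:
        raise ValueError("no selection results to combine")
    universe = results[0].features
    for res in results[1:]:
        if res.features != universe:
            raise ValueError("selection results have mismatched feature universes")
    labels = labels or [f"wave{i}" for i in range(len(results))]
    selected = set().union(*(r.selected for r in results))
    table = results[0].table[["feature"]].copy()
    for lab, res in zip(labels, results):
        table[f"median_{lab}"] = res.table["median"].to_numpy()
    table["selected"] = [f in selected for f in table["feature"]]
    return SelectionResult(
        selected=selected,
        table=table,
        thresholds=results[0].thresholds,
        provenance={lab: set(res.selected) for lab, res in zip(labels, results)},
    )
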