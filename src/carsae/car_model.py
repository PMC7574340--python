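"""Bayesian binomial spatial mixed models with CAR random effects.

The model
---------
For region r with N_r assessed children of whom y_r are vulnerable,

    y_r ~ Binomial(N_r, p_r),
    logit(p_r) = alpha + X_r' beta + u_r + v_r  (+ log e_r, optional offset),

where u is a spatially *structured* random effect with a conditional
autoregressive (CAR) prior over the region adjacency graph and v is an
iid Gaussian *unstructured* effect capturing region-specific
overdispersion. The structured prior is the Leroux family: the full
conditional of u_j given its neighbours is

    u_j | u_-j ~ N( rho * sum_i w_ji u_i / (rho * d_j + 1 - rho),
                    tau_u^2 / (rho * d_j + 1 - rho) ),

with d_j = sum_i w_ji the neighbour count. rho = 1 recovers the
intrinsic CAR (ICAR) of the Besag-York-Mollié model — each effect is
normal around the plain neighbour mean with variance tau_u^2 / d_j —
and rho = 0 gives independent N(0, tau_u^2) effects.

Fitting is Metropolis-within-Gibbs: random-walk Metropolis for the
fixed effects and for each u_r and v_r (single-site moves executed in
vectorised blocks over a graph colouring, so no two simultaneously
updated effects are neighbours), conjugate inverse-gamma draws for the
variance parameters, and Metropolis on logit(rho) for the Leroux
variant. Proposal scales adapt during burn-in only, then freeze, so the
retained chain satisfies detailed balance.

A Gaussian-response BYM smoother (`gaussian_car_smooth`) built on the
same prior structure, fully conjugate so it needs no tuning, is used to
impute spatially smooth covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx
from scipy import sparse

from carsae.geography import RegionGraph
from carsae.direct_estimation import coefficient_of_variation

__all__ = [
    "ModelConfig",
    "RegionDataset",
    "PosteriorSamples",
    "SmallAreaEstimates",
    "car_full_conditional",
    "sample_tau2_structured",
    "log_posterior",
    "run_mcmc",
    "posterior_prevalence",
    "gaussian_car_smooth",
]

VARIANTS = ("leroux", "bym", "icar_only", "iid_only")


@dataclass(frozen=True)
class ModelConfig:
    """Model variant, hyperpriors and MCMC controls.

    The gamma(shape, rate) hyperpriors sit on the random-effect
    *precisions* 1/tau_u^2 and 1/tau_v^2 (equivalently inverse-gamma on
    the variances); the defaults shape 1 with rates 0.5 (structured)
    and 0.01 (unstructured) are weakly informative. ``beta_prior_sd``
    is the sd of the zero-mean normal prior on the intercept and fixed
    effects, intended for a standardized covariate scale.
    """

    variant: str = "leroux"
    alpha_u: float = 1.0
    beta_u: float = 0.5
    alpha_v: float = 1.0
    beta_v: float = 0.01
    beta_prior_sd: float = 10.0
    n_iterations: int = 50_000
    burn_in: int = 10_000
    thinning: int = 10
    seed: int = 0
    offset_enabled: bool = False

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        for name in ("alpha_u", "beta_u", "alpha_v", "beta_v", "beta_prior_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.burn_in < self.n_iterations:
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def has_structured(self) -> bool:
        return self.variant in ("leroux", "bym", "icar_only")

    @property
    def has_unstructured(self) -> bool:
        return self.variant in ("leroux", "bym", "iid_only")

    @property
    def rho_fixed(self) -> float | None:
        """Fixed value of the Leroux mixing parameter, or None if sampled."""
        if self.variant in ("bym", "icar_only"):
            return 1.0
        if self.variant == "iid_only":
            return 0.0
        return None

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        """Load a config from a YAML mapping of field names to values."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config YAML must be a mapping")
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class RegionDataset:
    """Per-region counts, covariates and missingness flags.

    ``covariate`` may be a vector (single covariate) or (n, p) matrix;
    an intercept column is always added internally. ``response_missing``
    marks regions whose y is suppressed/invalid: they are excluded from
    the likelihood but remain in the spatial graph. ``offset`` is
    log(e_r), the log expected count, used only when the model config
    enables it.
    """

    region_ids: tuple
    N: np.ndarray
    y: np.ndarray
    covariate: np.ndarray
    offset: np.ndarray | None = None
    response_missing: np.ndarray | None = None
    covariate_missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.region_ids)
        N = np.asarray(self.N, dtype=float)
        y = np.asarray(self.y, dtype=float)
        X = np.asarray(self.covariate, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if N.shape != (n,) or y.shape != (n,) or X.shape[0] != n:
            raise ValueError("inconsistent lengths in RegionDataset")
        rm = (
            np.zeros(n, dtype=bool)
            if self.response_missing is None
            else np.asarray(self.response_missing, dtype=bool)
        )
        cm = (
            np.zeros(n, dtype=bool)
            if self.covariate_missing is None
            else np.asarray(self.covariate_missing, dtype=bool)
        )
        valid = ~rm
        if np.any(y[valid] < 0) or np.any(y[valid] > N[valid]):
            raise ValueError("need 0 <= y <= N for non-missing responses")
        object.__setattr__(self, "N", N)
        object.__setattr__(self, "y", np.where(rm, np.nan, y))
        object.__setattr__(self, "covariate", X)
        object.__setattr__(self, "response_missing", rm)
        object.__setattr__(self, "covariate_missing", cm)
        if self.offset is not None:
            off = np.asarray(self.offset, dtype=float)
            if off.shape != (n,):
                raise ValueError("offset length mismatch")
            object.__setattr__(self, "offset", off)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def design_matrix(self) -> np.ndarray:
        """Covariate matrix with a leading intercept column."""
        X = self.covariate
        if np.isnan(X).any():
            raise ValueError(
                "covariate contains missing values; impute before fitting"
            )
        return np.column_stack([np.ones(self.n_regions), X])

    def observed_mask(self) -> np.ndarray:
        """Regions contributing to the binomial likelihood."""
        return (~self.response_missing) & (self.N > 0)


@dataclass(frozen=True)
class PosteriorSamples:
    """Retained MCMC draws; ``coef`` column 0 is the intercept."""

    coef: np.ndarray          # (draws, 1 + p)
    u: np.ndarray             # (draws, n)
    v: np.ndarray             # (draws, n)
    tau2_u: np.ndarray        # (draws,)
    tau2_v: np.ndarray        # (draws,)
    rho: np.ndarray           # (draws,)
    acceptance_rates: dict
    seed: int

    @property
    def n_draws(self) -> int:
        return self.coef.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"coef{k}": self.coef[:, k] for k in range(self.coef.shape[1])}
        cols.update(tau2_u=self.tau2_u, tau2_v=self.tau2_v, rho=self.rho)
        return pd.DataFrame(cols)


@dataclass(frozen=True)
class SmallAreaEstimates:
    """Posterior summaries of per-region prevalence."""

    region_ids: tuple
    mean: np.ndarray
    sd: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    cv: np.ndarray
    provenance: np.ndarray    # str array: fitted | plug-in | imputed-covariate

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.mean,
                "sd": self.sd,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "cv": self.cv,
                "provenance": self.provenance,
            },
            index=pd.Index(self.region_ids, name="region_id"),
        )


# ---------------------------------------------------------------------------
# CAR prior pieces

def car_full_conditional(
    u: np.ndarray, j: int, graph: RegionGraph, tau2_u: float, rho: float
) -> tuple[float, float]:
    """Mean and variance of u_j given the other effects (Leroux family).

    rho = 1 gives the ICAR conditional (neighbour mean, tau_u^2/degree);
    rho = 0 gives independence (mean 0, variance tau_u^2). Continuous in
    rho in between.
    """
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    d_j = float(graph.neighbor_counts[j])
    if d_j == 0 and rho == 1:
        raise ValueError(
            f"ICAR conditional undefined for isolated region {graph.region_ids[j]!r}"
        )
    s = float(graph.W[j] @ u)
    denom = rho * d_j + (1.0 - rho)
    return rho * s / denom, tau2_u / denom


def _structure_eigvals(graph: RegionGraph) -> np.ndarray:
    """Eigenvalues of the graph Laplacian D - W (ascending)."""
    D = np.diag(graph.neighbor_counts.astype(float))
    return np.linalg.eigvalsh(D - graph.W)


def _car_quadform(u: np.ndarray, graph: RegionGraph, rho: float) -> float:
    """Q(u) = u' [rho (D - W) + (1 - rho) I] u, the CAR prior quadratic form."""
    Wu = graph.W @ u
    pairwise = float(u @ (graph.neighbor_counts * u) - u @ Wu)  # u'(D-W)u
    return rho * pairwise + (1.0 - rho) * float(u @ u)


def sample_tau2_structured(
    u: np.ndarray,
    graph: RegionGraph,
    rho: float,
    alpha: float,
    beta: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Conjugate Gibbs draw(s) of the structured variance tau_u^2 at fixed u.

    The full conditional of the precision 1/tau_u^2 is
    gamma(alpha + rank/2, beta + Q(u)/2) with Q the CAR quadratic form
    u'[rho(D-W) + (1-rho)I]u and rank the effective dimension (n minus
    one per connected component when rho = 1, else n). Equivalently
    tau_u^2 is inverse-gamma with the same shape and rate.
    """
    n = graph.n_regions
    n_comp = nx.number_connected_components(nx.from_numpy_array(np.asarray(graph.W)))
    rank = n - n_comp if rho == 1.0 else n
    Q = _car_quadform(np.asarray(u, dtype=float), graph, rho)
    prec = rng.gamma(alpha + 0.5 * rank, 1.0 / (beta + 0.5 * Q), size=size)
    return 1.0 / prec


def _car_logdet(eigvals: np.ndarray, rho: float, n_components: int) -> tuple[float, int]:
    """Log pseudo-determinant of rho(D-W) + (1-rho)I and its rank.

    At rho = 1 the Laplacian has one zero eigenvalue per connected
    component; those directions are dropped (improper ICAR prior).
    """
    vals = rho * eigvals + (1.0 - rho)
    if rho == 1.0:
        vals = np.sort(vals)[n_components:]
    return float(np.sum(np.log(vals))), vals.size


# ---------------------------------------------------------------------------
# Joint log posterior (used by tests and by the rho update)

def _binom_loglik(y, N, eta):
    """Binomial log likelihood up to the binomial coefficient."""
    return float(np.sum(y * eta - N * np.logaddexp(0.0, eta)))


def log_posterior(
    state: dict,
    data: RegionDataset,
    graph: RegionGraph,
    config: ModelConfig,
    *,
    eigvals: np.ndarray | None = None,
) -> float:
    """Joint log density of all parameters given the data, up to a constant.

    ``state`` maps: coef (intercept-first vector), u, v, tau2_u, tau2_v,
    rho. Terms for effects absent from the configured variant are
    ignored.
    """
    X = data.design_matrix()
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite covariate")
    coef = np.asarray(state["coef"], dtype=float)
    u = np.asarray(state.get("u", np.zeros(data.n_regions)), dtype=float)
    v = np.asarray(state.get("v", np.zeros(data.n_regions)), dtype=float)
    eta = X @ coef + u + v
    if config.offset_enabled and data.offset is not None:
        eta = eta + data.offset
    obs = data.observed_mask()
    lp = _binom_loglik(data.y[obs], data.N[obs], eta[obs])

    # fixed-effect prior
    lp += float(-0.5 * np.sum(coef**2) / config.beta_prior_sd**2)

    if config.has_structured:
        tau2_u = float(state["tau2_u"])
        rho = float(state.get("rho", config.rho_fixed if config.rho_fixed is not None else 1.0))
        if eigvals is None:
            eigvals = _structure_eigvals(graph)
        n_comp = nx.number_connected_components(nx.from_numpy_array(np.asarray(graph.W)))
        logdet, rank = _car_logdet(eigvals, rho, n_comp)
        Q = _car_quadform(u, graph, rho)
        lp += 0.5 * logdet - 0.5 * rank * np.log(tau2_u) - Q / (2 * tau2_u)
        # gamma(shape, rate) prior on the precision 1/tau2_u
        prec = 1.0 / tau2_u
        lp += (config.alpha_u - 1) * np.log(prec) - config.beta_u * prec
    if config.has_unstructured:
        tau2_v = float(state["tau2_v"])
        n = data.n_regions
        lp += -0.5 * n * np.log(tau2_v) - float(np.sum(v**2)) / (2 * tau2_v)
        prec = 1.0 / tau2_v
        lp += (config.alpha_v - 1) * np.log(prec) - config.beta_v * prec
    return float(lp)


# ---------------------------------------------------------------------------
# Sampler internals

def _color_blocks(graph: RegionGraph) -> list[np.ndarray]:
    """Partition regions into independent sets (greedy graph colouring).

    Within a block no two regions are neighbours, so their single-site
    full conditionals do not depend on each other and the Metropolis
    moves can be executed simultaneously as one vectorised update.
    """
    g = nx.from_numpy_array(np.asarray(graph.W))
    coloring = nx.greedy_color(g, strategy="largest_first")
    n_colors = max(coloring.values()) + 1 if coloring else 1
    return [
        np.array([i for i, c in coloring.items() if c == col], dtype=np.intp)
        for col in range(n_colors)
    ]


class _Adapter:
    """Per-parameter random-walk scales, tuned during burn-in only.

    Targets an acceptance rate around 0.4 (the usual 30-50 % band for
    single-site random-walk Metropolis), frozen afterwards.
    """

    def __init__(self, shape, init=0.5, target=0.4, every=50):
        self.scale = np.full(shape, float(init))
        self.acc = np.zeros(shape)
        self.n = 0
        self.target = target
        self.every = every
        self.frozen = False
        self.total_acc = np.zeros(shape)
        self.total_n = 0

    def record(self, accepted):
        self.acc = self.acc + accepted
        self.n += 1
        self.total_acc = self.total_acc + accepted
        self.total_n += 1
        if not self.frozen and self.n >= self.every:
            rate = self.acc / self.n
            self.scale = self.scale * np.exp(np.clip(rate - self.target, -0.5, 0.5))
            self.acc = np.zeros_like(self.acc)
            self.n = 0

    @property
    def rate(self):
        return self.total_acc / max(self.total_n, 1)


def run_mcmc(
    data: RegionDataset, graph: RegionGraph, config: ModelConfig
) -> PosteriorSamples:
    """Fit the spatial binomial mixed model by Metropolis-within-Gibbs.

    Identical seed and inputs give identical draws. Regions with
    missing responses stay in the graph: their random effects are drawn
    from the prior conditionals while contributing nothing to the
    likelihood.
    """
    n = data.n_regions
    if graph.n_regions != n:
        raise ValueError("graph and dataset disagree on region count")
    X = data.design_matrix()
    p = X.shape[1]
    obs = data.observed_mask()
    if not obs.any():
        raise ValueError("no region with an observed response")
    y = np.where(obs, np.nan_to_num(data.y), 0.0)
    N = np.where(obs, data.N, 0.0)
    off = (
        data.offset
        if (config.offset_enabled and data.offset is not None)
        else np.zeros(n)
    )
    deg = graph.neighbor_counts.astype(float)
    if config.has_structured and config.rho_fixed == 1.0 and np.any(deg == 0):
        bad = [rid for rid, d in zip(graph.region_ids, deg) if d == 0]
        raise ValueError(f"ICAR variant undefined for isolated regions {bad}")

    Ws = sparse.csr_matrix(np.asarray(graph.W, dtype=float))
    eigvals = _structure_eigvals(graph) if config.has_structured else None
    n_comp = (
        nx.number_connected_components(nx.from_numpy_array(np.asarray(graph.W)))
        if config.has_structured
        else 0
    )
    blocks = _color_blocks(graph) if config.has_structured else []

    rng = np.random.default_rng(config.seed)

    # --- initial state: crude logit fit
    pooled = max(y.sum(), 0.5) / max(N.sum(), 1.0)
    coef = np.zeros(p)
    coef[0] = np.log(pooled / (1 - pooled))
    u = np.zeros(n)
    v = np.zeros(n)
    tau2_u = 0.1
    tau2_v = 0.1
    rho = config.rho_fixed if config.rho_fixed is not None else 0.5

    # proposal geometry for the fixed effects from a quick IRLS fit
    coef_chol = _irls_proposal_chol(X[obs], y[obs], N[obs], off[obs], coef)

    adapt_coef = _Adapter((), init=1.0)
    adapt_u = _Adapter(n, init=0.5)
    adapt_v = _Adapter(n, init=0.5)
    adapt_rho = _Adapter((), init=0.5)

    eta_fix = X @ coef + off

    def loglik_region(eta_r, idx):
        return y[idx] * eta_r - N[idx] * np.logaddexp(0.0, eta_r)

    n_keep = (config.n_iterations - config.burn_in) // config.thinning
    out_coef = np.empty((n_keep, p))
    out_u = np.empty((n_keep, n))
    out_v = np.empty((n_keep, n))
    out_t2u = np.empty(n_keep)
    out_t2v = np.empty(n_keep)
    out_rho = np.empty(n_keep)
    kept = 0

    for it in range(config.n_iterations):
        in_burn = it < config.burn_in
        if not in_burn:
            adapt_coef.frozen = adapt_u.frozen = adapt_v.frozen = adapt_rho.frozen = True

        # --- fixed effects: joint random-walk Metropolis
        prop = coef + adapt_coef.scale * (coef_chol @ rng.standard_normal(p))
        eta_prop = X @ prop + off
        cur_ll = _binom_loglik(y[obs], N[obs], (eta_fix + u + v)[obs])
        new_ll = _binom_loglik(y[obs], N[obs], (eta_prop + u + v)[obs])
        logr = (
            new_ll
            - cur_ll
            + (-0.5 * np.sum(prop**2) + 0.5 * np.sum(coef**2)) / config.beta_prior_sd**2
        )
        if np.log(rng.random()) < logr:
            coef = prop
            eta_fix = eta_prop
            adapt_coef.record(1.0)
        else:
            adapt_coef.record(0.0)

        # --- structured effects u: colour-blocked single-site Metropolis
        if config.has_structured:
            acc_u = np.zeros(n)
            for idx in blocks:
                Wu = Ws @ u
                denom = rho * deg[idx] + (1.0 - rho)
                m = rho * Wu[idx] / denom
                u_cur = u[idx]
                u_new = u_cur + adapt_u.scale[idx] * rng.standard_normal(idx.size)
                eta_base = eta_fix[idx] + v[idx]
                dll = loglik_region(eta_base + u_new, idx) - loglik_region(
                    eta_base + u_cur, idx
                )
                dlp = -denom / (2 * tau2_u) * ((u_new - m) ** 2 - (u_cur - m) ** 2)
                accept = np.log(rng.random(idx.size)) < dll + dlp
                u[idx] = np.where(accept, u_new, u_cur)
                acc_u[idx] = accept
            if config.rho_fixed == 1.0:
                u -= u.mean()  # ICAR sum-to-zero identifiability constraint
            adapt_u.record(acc_u)

            # conjugate draw for tau2_u (inverse-gamma via gamma on precision)
            Q = _car_quadform(u, graph, rho)
            rank = n - n_comp if rho == 1.0 else n
            prec = rng.gamma(config.alpha_u + 0.5 * rank, 1.0 / (config.beta_u + 0.5 * Q))
            tau2_u = 1.0 / float(prec)

            # Leroux mixing parameter: Metropolis on logit(rho)
            if config.rho_fixed is None:
                zeta = np.log(rho / (1 - rho))
                zeta_new = zeta + adapt_rho.scale * rng.standard_normal()
                rho_new = 1.0 / (1.0 + np.exp(-zeta_new))
                ld_cur, _ = _car_logdet(eigvals, rho, n_comp)
                ld_new, _ = _car_logdet(eigvals, rho_new, n_comp)
                Q_new = _car_quadform(u, graph, rho_new)
                # uniform(0,1) prior on rho; Jacobian of the logit transform
                logr = (
                    0.5 * (ld_new - ld_cur)
                    - (Q_new - Q) / (2 * tau2_u)
                    + np.log(rho_new * (1 - rho_new))
                    - np.log(rho * (1 - rho))
                )
                if np.log(rng.random()) < logr:
                    rho = float(rho_new)
                    adapt_rho.record(1.0)
                else:
                    adapt_rho.record(0.0)

        # --- unstructured effects v: independent single-site Metropolis
        if config.has_unstructured:
            v_new = v + adapt_v.scale * rng.standard_normal(n)
            eta_base = eta_fix + u
            dll = np.where(
                obs,
                y * (eta_base + v_new)
                - N * np.logaddexp(0.0, eta_base + v_new)
                - (y * (eta_base + v) - N * np.logaddexp(0.0, eta_base + v)),
                0.0,
            )
            dlp = -(v_new**2 - v**2) / (2 * tau2_v)
            accept = np.log(rng.random(n)) < dll + dlp
            v = np.where(accept, v_new, v)
            adapt_v.record(accept.astype(float))

            prec = rng.gamma(
                config.alpha_v + 0.5 * n, 1.0 / (config.beta_v + 0.5 * float(v @ v))
            )
            tau2_v = 1.0 / prec

        if not in_burn and (it - config.burn_in) % config.thinning == 0 and kept < n_keep:
            out_coef[kept] = coef
            out_u[kept] = u
            out_v[kept] = v
            out_t2u[kept] = tau2_u
            out_t2v[kept] = tau2_v
            out_rho[kept] = rho
            kept += 1

    return PosteriorSamples(
        coef=out_coef[:kept],
        u=out_u[:kept],
        v=out_v[:kept],
        tau2_u=out_t2u[:kept],
        tau2_v=out_t2v[:kept],
        rho=out_rho[:kept],
        acceptance_rates={
            "coef": float(np.mean(adapt_coef.rate)),
            "u": float(np.mean(adapt_u.rate)) if config.has_structured else np.nan,
            "v": float(np.mean(adapt_v.rate)) if config.has_unstructured else np.nan,
            "rho": float(np.mean(adapt_rho.rate)) if config.rho_fixed is None else np.nan,
        },
        seed=config.seed,
    )


def _irls_proposal_chol(X, y, N, off, coef0):
    """Cholesky factor of the logistic-GLM covariance, for the coef proposal.

    A few iteratively-reweighted-least-squares steps at the crude start
    give the local curvature; the Metropolis proposal uses its Cholesky
    so correlated fixed effects are proposed along the right directions.
    """
    p = X.shape[1]
    coef = coef0.copy()
    for _ in range(8):
        eta = X @ coef + off
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(N * mu * (1 - mu), 1e-10)
        z = eta - off + (y - N * mu) / w
        XtW = X.T * w
        H = XtW @ X
        try:
            coef_new = np.linalg.solve(H, XtW @ z)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(coef_new)):
            break
        if np.max(np.abs(coef_new - coef)) < 1e-8:
            coef = coef_new
            break
        coef = coef_new
    eta = X @ coef + off
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(N * mu * (1 - mu), 1e-10)
    H = (X.T * w) @ X
    try:
        cov = np.linalg.inv(H)
        return np.linalg.cholesky((cov + cov.T) / 2)
    except np.linalg.LinAlgError:
        return np.eye(p) * 0.05


def posterior_prevalence(
    samples: PosteriorSamples,
    data: RegionDataset,
    config: ModelConfig,
    *,
    level: float = 0.95,
) -> SmallAreaEstimates:
    """Posterior summaries of p_r = inverse-logit(eta_r) per retained draw.

    Per draw the linear predictor combines the fixed effects with that
    draw's random effects; the prevalence is summarised by the posterior
    mean, sd, central credible interval and percent CV.
    """
    if samples.n_draws == 0:
        raise ValueError("empty posterior sample")
    X = data.design_matrix()
    eta = samples.coef @ X.T + samples.u + samples.v  # (draws, n)
    if config.offset_enabled and data.offset is not None:
        eta = eta + data.offset
    p = 1.0 / (1.0 + np.exp(-eta))
    mean = p.mean(axis=0)
    sd = p.std(axis=0, ddof=1) if samples.n_draws > 1 else np.zeros(data.n_regions)
    a = (1 - level) / 2
    lo, hi = np.quantile(p, [a, 1 - a], axis=0)
    cv = coefficient_of_variation(mean, sd)
    return SmallAreaEstimates(
        region_ids=tuple(data.region_ids),
        mean=mean,
        sd=sd,
        ci_low=lo,
        ci_high=hi,
        cv=cv,
        provenance=np.array(["fitted"] * data.n_regions, dtype=object),
    )


# ---------------------------------------------------------------------------
# Gaussian BYM smoother (for covariate imputation)

def gaussian_car_smooth(
    values,
    graph: RegionGraph,
    *,
    n_iterations: int = 3000,
    burn_in: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Spatially smooth a partially observed field with a Gaussian BYM model.

    Fits  z_r ~ N(alpha + u_r + v_r, sigma^2)  on the observed entries,
    u ICAR over the graph and v iid, all full conditionals conjugate
    (pure Gibbs). Returns the posterior mean of alpha + u_r + v_r for
    every region, so missing entries get a neighbour-informed
    prediction.
    """
    z = np.asarray(values, dtype=float)
    n = graph.n_regions
    if z.shape != (n,):
        raise ValueError("values length must match the graph")
    obs = ~np.isnan(z)
    if obs.sum() < 2:
        raise ValueError("need at least 2 observed values to smooth")
    deg = graph.neighbor_counts.astype(float)
    if np.any(deg == 0):
        raise ValueError("graph has isolated regions; remove them first")
    Ws = sparse.csr_matrix(np.asarray(graph.W, dtype=float))
    blocks = _color_blocks(graph)
    rng = np.random.default_rng(seed)

    zo = z[obs]
    alpha = float(zo.mean())
    scale0 = float(zo.std(ddof=1)) if obs.sum() > 1 else 1.0
    scale0 = scale0 if scale0 > 0 else 1.0
    u = np.zeros(n)
    v = np.zeros(n)
    sigma2 = max(scale0**2, 1e-12)
    tau2_u = max(scale0**2, 1e-12)
    tau2_v = max(scale0**2, 1e-12)
    a0, b0 = 1.0, 0.01  # weak gamma priors on all three precisions
    obs_f = obs.astype(float)

    mu_sum = np.zeros(n)
    kept = 0
    for it in range(n_iterations):
        resid = z - alpha - v  # NaN at unobserved entries; masked below
        # u | rest — colour-blocked conjugate normal draws
        for idx in blocks:
            Wu = Ws @ u
            prior_prec = deg[idx] / tau2_u
            prior_mean = Wu[idx] / deg[idx]
            like_prec = obs_f[idx] / sigma2
            like_mean = np.where(obs[idx], np.nan_to_num(resid[idx]), 0.0)
            post_prec = prior_prec + like_prec
            post_mean = (prior_prec * prior_mean + like_prec * like_mean) / post_prec
            u[idx] = post_mean + rng.standard_normal(idx.size) / np.sqrt(post_prec)
        shift = u.mean()
        u -= shift
        alpha += shift

        # v | rest
        like_prec = obs_f / sigma2
        post_prec = 1.0 / tau2_v + like_prec
        num = like_prec * np.where(obs, np.nan_to_num(z - alpha - u), 0.0)
        v = num / post_prec + rng.standard_normal(n) / np.sqrt(post_prec)

        # alpha | rest (flat prior)
        r = z - u - v
        post_var = sigma2 / obs.sum()
        alpha = float(np.nanmean(r[obs]) + rng.standard_normal() * np.sqrt(post_var))

        # variance components
        err = z[obs] - alpha - u[obs] - v[obs]
        sigma2 = 1.0 / rng.gamma(a0 + 0.5 * obs.sum(), 1.0 / (b0 + 0.5 * float(err @ err)))
        Q = _car_quadform(u, graph, 1.0)
        tau2_u = 1.0 / rng.gamma(a0 + 0.5 * (n - 1), 1.0 / (b0 + 0.5 * Q))
        tau2_v = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * float(v @ v)))

        if it >= burn_in:
            mu_sum += alpha + u + v
            kept += 1
    return mu_sum / kept
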