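"""Bayesian two-source (or k-source) stable-isotope diet mixing model.

Estimates the proportions of end-member food sources (here ice algae and
pelagic POM) in consumer diets from δ¹³C/δ¹⁵N signatures.  The model for
consumer ``i`` and isotope ``d`` is

    X_id = Σ_j p_j (S_jd + C_jd) + ε_id,
    S_jd ~ Normal(μ_jd, ω_jd),   source signature
    C_jd ~ Normal(λ_d, τ_d),     trophic enrichment factor
    ε_id ~ Normal(0, σ_d),       residual
    p    ~ Dirichlet(α),

so marginally X_id | p ~ Normal(Σ_j p_j (μ_jd + λ_d),
sqrt(Σ_j p_j² (ω_jd² + τ_d²) + σ_d²)).  Source and TEF uncertainty are
marginalised analytically (same marginal likelihood, fewer parameters);
the diet proportions and per-isotope residual spreads are sampled with an
adaptive random-walk Metropolis on additive-log-ratio-transformed
proportions, which keeps the simplex constraint implicit.

:class:`DietMixingModel` is a scikit-learn-style estimator: configure in
``__init__``, call :meth:`~DietMixingModel.fit` on an ``(n_consumers,
n_isotopes)`` signature array, read fitted attributes (``draws_``,
``summary_``, ``diagnostics_``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import IsotopeRecord

__all__ = [
    "SourceSpec",
    "TEFSpec",
    "MixingModelSpec",
    "DietPosterior",
    "DietMixingModel",
    "fit_mixing_model",
    "summarise_posterior",
    "read_sources_table",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

#: Default per-isotope trophic enrichment, ‰ per trophic level, in the
#: package-wide isotope order (δ13C, δ15N).
DEFAULT_TEF_MEAN = (1.0, 3.8)


@dataclass(frozen=True)
class SourceSpec:
    """An end-member food source: per-isotope mean ± SD (‰)."""

    name: str
    mean: tuple[float, ...]
    sd: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", tuple(float(m) for m in self.mean))
        object.__setattr__(self, "sd", tuple(float(s) for s in self.sd))
        if len(self.mean) != len(self.sd):
            raise ValueError(f"source {self.name!r}: mean/sd length mismatch")
        if any(s < 0 for s in self.sd):
            raise ValueError(f"source {self.name!r}: sd must be >= 0")


@dataclass(frozen=True)
class TEFSpec:
    """Trophic enrichment factor: per-isotope mean ± SD (‰ per level)."""

    mean: tuple[float, ...] = DEFAULT_TEF_MEAN
    sd: tuple[float, ...] = (0.0, 0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", tuple(float(m) for m in self.mean))
        object.__setattr__(self, "sd", tuple(float(s) for s in self.sd))
        if len(self.mean) != len(self.sd):
            raise ValueError("TEF mean/sd length mismatch")
        if any(s < 0 for s in self.sd):
            raise ValueError("TEF sd must be >= 0")


@dataclass(frozen=True)
class MixingModelSpec:
    """Bundle of sources, TEF and priors defining one mixing model."""

    sources: tuple[SourceSpec, ...]
    tef: TEFSpec = TEFSpec()
    dirichlet_alpha: tuple[float, ...] | None = None
    residual_sd_prior: float | str | None = "empirical"

    def __post_init__(self) -> None:
        object.__setattr__(self, "sources", tuple(self.sources))
        if len(self.sources) < 2:
            raise ValueError("a mixing model requires at least 2 sources")
        if self.dirichlet_alpha is not None:
            alpha = tuple(float(a) for a in self.dirichlet_alpha)
            if len(alpha) != len(self.sources):
                raise ValueError("dirichlet_alpha length must match sources")
            if any(a <= 0 for a in alpha):
                raise ValueError("dirichlet_alpha must be positive elementwise")
            object.__setattr__(self, "dirichlet_alpha", alpha)


@dataclass
class DietPosterior:
    """MCMC draws of diet-proportion vectors with summaries/diagnostics.

    ``draws`` has shape (n_retained_draws, n_sources); every row is a
    simplex vector.  ``residual_draws`` is ``None`` when the residual term
    was disabled.  ``summaries`` are recomputable from the draws with
    :func:`summarise_posterior`.
    """

    draws: np.ndarray
    source_names: tuple[str, ...]
    residual_draws: np.ndarray | None
    chains: int
    seed: int
    diagnostics: dict = field(default_factory=dict)
    summaries: pd.DataFrame | None = None

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


class DietMixingModel(BaseEstimator):
    """Scikit-learn-style estimator for the Bayesian diet mixing model.

    Parameters
    ----------
    sources : sequence of SourceSpec
        End-member signatures; their order defines the proportion-vector
        order.  At least two are required.
    tef : TEFSpec
        Trophic enrichment factor added to every source.
    dirichlet_alpha : sequence of float, optional
        Prior concentration per source (default: all ones, uniform on the
        simplex).
    residual_sd_prior : float, "empirical" or None
        Scale of the half-normal prior on the per-isotope residual SD.
        ``"empirical"`` sets the scale from the consumer SD per isotope;
        ``None`` or ``0`` disables the residual term (σ fixed at 0, valid
        only when source/TEF SDs are positive).
    chains, iterations, burn_in, thin : int / float
        MCMC configuration; ``iterations`` is per chain, ``burn_in`` a
        fraction (< 1) or an absolute iteration count.
    random_state : int
        Seed for the sampler.  Identical seed and configuration give
        identical draws.

    Attributes
    ----------
    posterior_ : DietPosterior
    draws_ : ndarray of shape (n_retained, n_sources)
    residual_draws_ : ndarray or None
    summary_ : DataFrame with per-source mean/median/credible interval
    diagnostics_ : dict with per-parameter R-hat and effective sample size
    """

    def __init__(
        self,
        sources: Sequence[SourceSpec] = (),
        tef: TEFSpec = TEFSpec(),
        dirichlet_alpha: Sequence[float] | None = None,
        residual_sd_prior: float | str | None = "empirical",
        chains: int = 4,
        iterations: int = 10_000,
        burn_in: float = 0.5,
        thin: int = 1,
        random_state: int | None = None,
        rhat_threshold: float = 1.1,
    ) -> None:
        self.sources = sources
        self.tef = tef
        self.dirichlet_alpha = dirichlet_alpha
        self.residual_sd_prior = residual_sd_prior
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.random_state = random_state
        self.rhat_threshold = rhat_threshold

    # ------------------------------------------------------------------

    def fit(self, X, y=None):
        """Sample the posterior of the diet proportions given consumers.

        ``X`` is an ``(n_consumers, n_isotopes)`` array of δ signatures,
        or a sequence of :class:`~isotroph.core.IsotopeRecord` (isotope
        order δ¹³C, δ¹⁵N).
        """
        X = _as_signature_array(X)
        sources = tuple(self.sources)
        if len(sources) < 2:
            raise ValueError("a mixing model requires at least 2 sources")
        n_iso = X.shape[1]
        mu = np.array([s.mean for s in sources], dtype=float)
        omega = np.array([s.sd for s in sources], dtype=float)
        lam = np.asarray(self.tef.mean, dtype=float)
        tau = np.asarray(self.tef.sd, dtype=float)
        if mu.shape[1] != n_iso or lam.shape[0] != n_iso:
            raise ValueError(
                "isotope dimensions of consumers, sources and TEF must agree: "
                f"consumers have {n_iso}, sources {mu.shape[1]}, TEF {lam.shape[0]}"
            )
        if X.shape[0] < 1:
            raise ValueError("at least one consumer record is required")

        k = len(sources)
        alpha = (
            np.ones(k)
            if self.dirichlet_alpha is None
            else np.asarray(self.dirichlet_alpha, dtype=float)
        )
        if alpha.shape[0] != k or np.any(alpha <= 0):
            raise ValueError("dirichlet_alpha must be positive with one entry per source")

        # Half-normal residual prior scale; None/0 fixes sigma at 0.
        if self.residual_sd_prior == "empirical":
            emp = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(n_iso)
            sigma_scale = np.maximum(np.nan_to_num(emp, nan=1.0), 1e-3)
        elif self.residual_sd_prior in (None, 0, 0.0):
            sigma_scale = None
        else:
            sigma_scale = np.full(n_iso, float(self.residual_sd_prior))

        src_mean = mu + lam  # TEF-corrected source means, (k, D)
        src_var = omega**2 + tau**2
        if sigma_scale is None and np.any(src_var.sum(axis=0) == 0):
            raise ValueError(
                "residual term disabled but some isotope has zero source/TEF "
                "variance; the likelihood would be degenerate"
            )

        seed = (
            int(self.random_state)
            if self.random_state is not None
            else int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
        )
        burn = (
            int(self.burn_in * self.iterations)
            if 0 < self.burn_in < 1
            else int(self.burn_in)
        )
        if not 0 <= burn < self.iterations:
            raise ValueError("burn_in must leave at least one retained iteration")

        chain_p, chain_sigma = _run_chains(
            X,
            src_mean,
            src_var,
            alpha,
            sigma_scale,
            chains=int(self.chains),
            iterations=int(self.iterations),
            burn=burn,
            thin=int(self.thin),
            seed=seed,
        )

        diagnostics = _diagnostics(
            chain_p, chain_sigma, [s.name for s in sources], self.rhat_threshold
        )
        draws = chain_p.reshape(-1, k)
        residual = None if chain_sigma is None else chain_sigma.reshape(-1, n_iso)

        posterior = DietPosterior(
            draws=draws,
            source_names=tuple(s.name for s in sources),
            residual_draws=residual,
            chains=int(self.chains),
            seed=seed,
            diagnostics=diagnostics,
        )
        posterior.summaries = summarise_posterior(posterior)

        self.n_features_in_ = n_iso
        self.posterior_ = posterior
        self.draws_ = draws
        self.residual_draws_ = residual
        self.summary_ = posterior.summaries
        self.diagnostics_ = diagnostics
        return self


# ----------------------------------------------------------------------
# sampler internals


def _as_signature_array(X) -> np.ndarray:
    if len(X) and isinstance(X[0], IsotopeRecord):
        X = [(r.d13c, r.d15n) for r in X]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("consumer signatures must be finite")
    return X


def _softmax_from_alr(z: np.ndarray) -> np.ndarray:
    """Inverse additive-log-ratio transform (reference = last source)."""
    full = np.append(z, 0.0)
    full -= full.max()
    e = np.exp(full)
    return e / e.sum()


def _log_posterior(z, log_sigma, X, src_mean, src_var, alpha, sigma_scale):
    p = _softmax_from_alr(z)
    if np.any(p <= 0):
        return -np.inf, p, None
    # Dirichlet(alpha) density + ALR Jacobian sum(log p) = sum(alpha*log p)
    lp = float(np.dot(alpha, np.log(p)))
    mu_mix = p @ src_mean
    var_mix = (p**2) @ src_var
    if log_sigma is not None:
        sigma = np.exp(log_sigma)
        var_mix = var_mix + sigma**2
        # half-normal prior on sigma, plus log-Jacobian of the log transform
        lp += float(-0.5 * np.sum((sigma / sigma_scale) ** 2) + np.sum(log_sigma))
    if np.any(var_mix <= 0):
        return -np.inf, p, None
    resid = X - mu_mix
    n = X.shape[0]
    lp += float(
        -0.5 * np.sum(resid**2 / var_mix)
        - 0.5 * n * np.sum(np.log(var_mix))
        - 0.5 * n * X.shape[1] * _LOG_2PI
    )
    sigma_out = None if log_sigma is None else np.exp(log_sigma)
    return lp, p, sigma_out


def _run_chains(X, src_mean, src_var, alpha, sigma_scale, *, chains, iterations,
                burn, thin, seed):
    k = src_mean.shape[0]
    n_iso = X.shape[1]
    with_sigma = sigma_scale is not None
    n_keep = len(range(burn, iterations, thin))
    chain_p = np.empty((chains, n_keep, k))
    chain_sigma = np.empty((chains, n_keep, n_iso)) if with_sigma else None

    ss = np.random.SeedSequence(seed)
    for c, child in enumerate(ss.spawn(chains)):
        rng = np.random.default_rng(child)
        z = rng.normal(0.0, 0.5, size=k - 1)
        log_sigma = (
            np.log(np.maximum(sigma_scale, 1e-3)) - np.log(2.0)
            + rng.normal(0.0, 0.2, size=n_iso)
            if with_sigma
            else None
        )
        dim = (k - 1) + (n_iso if with_sigma else 0)
        scale = 2.4 / np.sqrt(dim)

        lp, p, sigma = _log_posterior(
            z, log_sigma, X, src_mean, src_var, alpha, sigma_scale
        )
        accepted = 0
        kept = 0
        for it in range(iterations):
            step = rng.normal(0.0, scale, size=dim)
            z_new = z + step[: k - 1]
            ls_new = log_sigma + step[k - 1:] if with_sigma else None
            lp_new, p_new, sigma_new = _log_posterior(
                z_new, ls_new, X, src_mean, src_var, alpha, sigma_scale
            )
            if np.log(rng.random()) < lp_new - lp:
                z, log_sigma, lp, p, sigma = z_new, ls_new, lp_new, p_new, sigma_new
                accepted += 1
            # Robbins-Monro scale adaptation during burn-in only, so the
            # retained draws come from a fixed-kernel Markov chain.
            if it < burn and (it + 1) % 50 == 0:
                rate = accepted / 50.0
                scale *= float(np.exp(0.5 * (rate - 0.30)))
                accepted = 0
            if it >= burn and (it - burn) % thin == 0:
                chain_p[c, kept] = p
                if with_sigma:
                    chain_sigma[c, kept] = sigma
                kept += 1
    return chain_p, chain_sigma


def _diagnostics(chain_p, chain_sigma, names, rhat_threshold):
    import arviz as az

    data = {f"p[{name}]": chain_p[:, :, j] for j, name in enumerate(names)}
    if chain_sigma is not None:
        for d in range(chain_sigma.shape[2]):
            data[f"sigma[{d}]"] = chain_sigma[:, :, d]
    idata = az.convert_to_dataset({k: v for k, v in data.items()})
    rhat = {k: float(v) for k, v in az.rhat(idata).items()}
    ess = {k: float(v) for k, v in az.ess(idata).items()}
    finite_rhat = [v for v in rhat.values() if np.isfinite(v)]
    converged = all(v <= rhat_threshold for v in finite_rhat)
    if not converged:
        warnings.warn(
            f"MCMC may not have converged: max R-hat = {max(finite_rhat):.3f} "
            f"> {rhat_threshold}",
            stacklevel=2,
        )
    return {"rhat": rhat, "ess": ess, "converged": converged}


# ----------------------------------------------------------------------
# functional wrappers


def fit_mixing_model(
    consumers: Iterable[IsotopeRecord] | np.ndarray,
    spec: MixingModelSpec,
    *,
    chains: int = 4,
    iterations: int = 10_000,
    burn_in: float = 0.5,
    thin: int = 1,
    seed: int | None = None,
) -> DietPosterior:
    """Fit the mixing model for one consumer group; thin wrapper over
    :class:`DietMixingModel`."""
    model = DietMixingModel(
        sources=spec.sources,
        tef=spec.tef,
        dirichlet_alpha=spec.dirichlet_alpha,
        residual_sd_prior=spec.residual_sd_prior,
        chains=chains,
        iterations=iterations,
        burn_in=burn_in,
        thin=thin,
        random_state=seed,
    )
    consumers = list(consumers) if not isinstance(consumers, np.ndarray) else consumers
    model.fit(consumers)
    return model.posterior_


def summarise_posterior(
    posterior: DietPosterior,
    probs: tuple[float, float] = (0.025, 0.975),
) -> pd.DataFrame:
    """Per-source posterior mean, median and equal-tailed credible interval.

    Means sum to 1 (to numerical precision) because every draw is a
    simplex vector.
    """
    if posterior.draws.shape[0] == 0:
        raise ValueError("cannot summarise an empty posterior")
    lo, hi = sorted(probs)
    draws = posterior.draws
    return pd.DataFrame(
        {
            "source": list(posterior.source_names),
            "mean": draws.mean(axis=0),
            "median": np.median(draws, axis=0),
            f"ci_{lo}": np.quantile(draws, lo, axis=0),
            f"ci_{hi}": np.quantile(draws, hi, axis=0),
        }
    ).set_index("source")


def read_sources_table(
    path: str | Path, delimiter: str = ","
) -> tuple[tuple[SourceSpec, ...], TEFSpec]:
    """Read a sources/TEF table: columns ``name, d13c_mean, d13c_sd,
    d15n_mean, d15n_sd``; the reserved name ``TEF`` holds the enrichment."""
    df = pd.read_csv(path, sep=delimiter, skipinitialspace=True)
    required = ["name", "d13c_mean", "d13c_sd", "d15n_mean", "d15n_sd"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {missing}")
    sources = []
    tef = TEFSpec()
    for _, row in df.iterrows():
        mean = (float(row["d13c_mean"]), float(row["d15n_mean"]))
        sd = (float(row["d13c_sd"]), float(row["d15n_sd"]))
        if str(row["name"]).strip() == "TEF":
            tef = TEFSpec(mean=mean, sd=sd)
        else:
            sources.append(SourceSpec(name=str(row["name"]).strip(), mean=mean, sd=sd))
    return tuple(sources), tef
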