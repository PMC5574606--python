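"""Diet mixing model: sampler correctness against oracles and invariants."""

import numpy as np
import pytest
from scipy.stats import norm

from isotroph.mixing import (
    DietMixingModel,
    DietPosterior,
    MixingModelSpec,
    SourceSpec,
    TEFSpec,
    fit_mixing_model,
    summarise_posterior,
)

TEF1 = TEFSpec(mean=(1.0,), sd=(0.0,))


def two_sources_1iso(sd=0.5):
    # TEF-corrected means land at -25 and -15
    return (
        SourceSpec("A", mean=(-26.0,), sd=(sd,)),
        SourceSpec("B", mean=(-16.0,), sd=(sd,)),
    )


def grid_posterior_mean(consumers, sources, tef, alpha=(1.0, 1.0), n_grid=2001):
    """Brute-force grid integration of the 2-source, 1-isotope posterior
    with the residual term disabled; independent of the MCMC code path."""
    p = np.linspace(0.0, 1.0, n_grid)[1:-1]
    m = [s.mean[0] + tef.mean[0] for s in sources]
    v = [s.sd[0] ** 2 + tef.sd[0] ** 2 for s in sources]
    mu = p * m[0] + (1 - p) * m[1]
    sd = np.sqrt(p**2 * v[0] + (1 - p) ** 2 * v[1])
    log_post = (alpha[0] - 1) * np.log(p) + (alpha[1] - 1) * np.log(1 - p)
    for x in np.atleast_1d(consumers):
        log_post += norm.logpdf(x, mu, sd)
    w = np.exp(log_post - log_post.max())
    w /= w.sum()
    return float((w * p).sum())


def fit_1iso(consumers, sources, seed=7, **kw):
    kw.setdefault("chains", 2)
    kw.setdefault("iterations", 4000)
    model = DietMixingModel(
        sources=sources, tef=TEF1, residual_sd_prior=None, random_state=seed, **kw
    )
    return model.fit(np.atleast_2d(consumers).T)


class TestSamplerAgainstOracles:
    def test_symmetric_consumer_splits_evenly(self):
        m = fit_1iso([-20.0], two_sources_1iso())
        assert m.summary_.loc["A", "mean"] == pytest.approx(0.5, abs=0.05)

    def test_consumer_at_source_mean_is_attributed_to_it(self):
        srcs = two_sources_1iso(sd=0.2)
        m = fit_1iso([-25.0], srcs)
        p_a = m.summary_.loc["A", "mean"]
        assert p_a >= 0.90
        oracle = grid_posterior_mean([-25.0], srcs, TEF1)
        assert p_a == pytest.approx(oracle, abs=0.02)

    @pytest.mark.parametrize("x", [-24.0, -21.5, -18.0])
    def test_grid_integration_agreement(self, x):
        srcs = two_sources_1iso()
        m = fit_1iso([x], srcs, seed=11)
        oracle = grid_posterior_mean([x], srcs, TEF1)
        assert m.summary_.loc["A", "mean"] == pytest.approx(oracle, abs=0.02)

    def test_prior_recovery_under_uninformative_likelihood(self):
        # an enormous fixed residual spread flattens the likelihood, so the
        # posterior should fall back to the Dirichlet prior mean
        srcs = two_sources_1iso()
        model = DietMixingModel(
            sources=srcs,
            tef=TEF1,
            dirichlet_alpha=(3.0, 1.0),
            residual_sd_prior=None,
            chains=2,
            iterations=6000,
            random_state=5,
        )
        wide = (
            SourceSpec("A", mean=(-26.0,), sd=(200.0,)),
            SourceSpec("B", mean=(-16.0,), sd=(200.0,)),
        )
        model.set_params(sources=wide)
        model.fit([[-20.0]])
        assert model.summary_.loc["A", "mean"] == pytest.approx(0.75, abs=0.05)


class TestInvariants:
    def test_simplex_closure(self):
        m = fit_1iso([-19.0], two_sources_1iso())
        assert np.all(m.draws_ >= 0)
        assert np.allclose(m.draws_.sum(axis=1), 1.0, atol=1e-12)

    def test_seed_reproducibility(self):
        a = fit_1iso([-21.0], two_sources_1iso(), seed=99)
        b = fit_1iso([-21.0], two_sources_1iso(), seed=99)
        assert np.array_equal(a.draws_, b.draws_)

    def test_label_equivariance(self):
        srcs = two_sources_1iso()
        m1 = fit_1iso([-22.0], srcs, seed=7)
        m2 = fit_1iso([-22.0], srcs[::-1], seed=7)
        # same posterior law with permuted labels, up to Monte-Carlo error
        assert m1.summary_.loc["A", "mean"] == pytest.approx(
            m2.summary_.loc["A", "mean"], abs=0.03
        )

    def test_diagnostics_present(self):
        m = fit_1iso([-20.0], two_sources_1iso())
        assert set(m.diagnostics_) == {"rhat", "ess", "converged"}
        assert all(v > 50 for v in m.diagnostics_["ess"].values())


class TestSpecAndErrors:
    def test_fewer_than_two_sources_rejected(self):
        with pytest.raises(ValueError, match="2 sources"):
            MixingModelSpec(sources=(two_sources_1iso()[0],))
        with pytest.raises(ValueError, match="2 sources"):
            DietMixingModel(sources=(two_sources_1iso()[0],)).fit([[-20.0]])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="isotope dimensions"):
            DietMixingModel(sources=two_sources_1iso(), tef=TEF1).fit([[-20.0, 9.0]])

    def test_degenerate_zero_variance_rejected(self):
        srcs = (
            SourceSpec("A", mean=(-26.0,), sd=(0.0,)),
            SourceSpec("B", mean=(-16.0,), sd=(0.0,)),
        )
        with pytest.raises(ValueError, match="residual"):
            DietMixingModel(
                sources=srcs, tef=TEF1, residual_sd_prior=None
            ).fit([[-20.0]])

    def test_bad_alpha_rejected(self):
        with pytest.raises(ValueError, match="dirichlet_alpha"):
            DietMixingModel(
                sources=two_sources_1iso(), tef=TEF1, dirichlet_alpha=(1.0, -1.0)
            ).fit([[-20.0]])

    def test_functional_wrapper_matches_estimator(self):
        spec = MixingModelSpec(
            sources=two_sources_1iso(), tef=TEF1, residual_sd_prior=None
        )
        post = fit_mixing_model(
            np.array([[-20.0]]), spec, chains=2, iterations=2000, seed=4
        )
        est = fit_1iso([-20.0], two_sources_1iso(), seed=4, iterations=2000)
        assert np.array_equal(post.draws, est.draws_)


class TestSummaries:
    def test_degenerate_draws(self):
        post = DietPosterior(
            draws=np.tile([0.6, 0.4], (200, 1)),
            source_names=("A", "B"),
            residual_draws=None,
            chains=1,
            seed=0,
        )
        s = summarise_posterior(post)
        assert s.loc["A", "mean"] == pytest.approx(0.6, abs=1e-12)
        assert s.loc["A", "ci_0.975"] - s.loc["A", "ci_0.025"] == pytest.approx(
            0.0, abs=1e-12
        )

    def test_mean_matches_column_mean_and_sums_to_one(self):
        rng = np.random.default_rng(0)
        draws = rng.dirichlet((2.0, 3.0), size=500)
        post = DietPosterior(draws, ("A", "B"), None, 1, 0)
        s = summarise_posterior(post)
        assert np.allclose(s["mean"].to_numpy(), draws.mean(axis=0), atol=1e-12)
        assert s["mean"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_empty_posterior_rejected(self):
        post = DietPosterior(np.empty((0, 2)), ("A", "B"), None, 1, 0)
        with pytest.raises(ValueError, match="empty"):
            summarise_posterior(post)
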