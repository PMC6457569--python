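"""Design matrices, latent-state conditionals, the Gibbs sampler, summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest

from edna_occupancy import (
    DesignParams,
    ModelSpec,
    TruthParams,
    build_design_matrices,
    detection_curve,
    diagnostics,
    generate_dataset,
    latent_conditionals,
    run_mcmc,
    summarize_posterior,
)
from edna_occupancy.occupancy import PosteriorDraws, _PGBlock, _RWMBlock


def tiny_tables(n_sites=4, n_samples_per=2, K=2, y=None):
    sites = pd.DataFrame(
        {
            "site_id": [f"S{i}" for i in range(n_sites)],
            "island_type": (["colony", "control"] * n_sites)[:n_sites],
        }
    )
    rows = []
    for i in range(n_sites):
        for j in range(n_samples_per):
            rows.append(
                {
                    "sample_id": f"S{i}-{j}",
                    "site_id": f"S{i}",
                    "date_days": float(i),
                    "time_min": 480.0 + 30 * (i * n_samples_per + j),
                    "water_temp_c": 20.0 + i + j,
                    "depth_cm": 10.0 + 5 * j,
                }
            )
    samples = pd.DataFrame(rows)
    n = len(samples)
    det = pd.DataFrame(
        np.full((n, K), 0 if y is None else y, dtype=int),
        columns=[f"det_{k+1}" for k in range(K)],
        index=pd.Index(samples["sample_id"], name="sample_id"),
    )
    return sites, samples, det


class TestDesignMatrices:
    def test_standardization_uses_sample_sd(self):
        sites, samples, det = tiny_tables(n_sites=1, n_samples_per=2, K=1)
        samples["time_min"] = [600.0, 660.0]
        ds = build_design_matrices(sites, samples, det, ModelSpec(p=("time",)))
        np.testing.assert_allclose(
            ds.V[:, 1], [-0.70710678, 0.70710678], atol=1e-8
        )
        mu, sd = ds.scaling["p.time"]
        assert (mu, sd) == (630.0, pytest.approx(np.sqrt(1800)))

    def test_cell_means_coding_one_hot(self):
        sites, samples, det = tiny_tables(n_sites=30)
        ds = build_design_matrices(sites, samples, det, ModelSpec(psi=("type",)))
        assert ds.X.shape == (30, 2)
        np.testing.assert_array_equal(ds.X.sum(axis=1), np.ones(30))
        assert set(ds.x_names) == {"type_colony", "type_control"}

    def test_null_model_is_all_intercepts(self):
        sites, samples, det = tiny_tables()
        ds = build_design_matrices(sites, samples, det, ModelSpec())
        for mat in (ds.X, ds.W, ds.V):
            assert mat.shape[1] == 1 and (mat == 1.0).all()

    def test_constant_covariate_rejected(self):
        sites, samples, det = tiny_tables()
        samples["depth_cm"] = 12.0
        with pytest.raises(ValueError, match="constant"):
            build_design_matrices(sites, samples, det, ModelSpec(p=("depth",)))

    def test_unknown_covariate_rejected(self):
        sites, samples, det = tiny_tables()
        with pytest.raises(KeyError):
            build_design_matrices(sites, samples, det, ModelSpec(theta=("salinity",)))


def enum_conditional_a(theta, p_j, y_j):
    """Brute force P(a=1 | z=1, y_j) by summing the joint over a."""
    def like(a):
        if a == 0:
            return 1.0 if not any(y_j) else 0.0
        return np.prod([p if y else 1 - p for p, y in zip(p_j, y_j)])

    num = theta * like(1)
    den = num + (1 - theta) * like(0)
    return num / den


def enum_conditional_z(psi, theta_ij):
    """Brute force P(z=1 | all a=0): P(a all 0|z=1) = Π(1−θ)."""
    num = psi * np.prod([1 - t for t in theta_ij])
    return num / (num + (1 - psi))


class TestLatentConditionals:
    def test_worked_examples(self):
        pz, pa = latent_conditionals(0.5, [0.5], [np.array([0.8, 0.8])], [np.array([0, 0])])
        assert pa[0] == pytest.approx(0.02 / 0.52, abs=1e-12)
        pz2, pa2 = latent_conditionals(0.5, [0.5], [np.array([0.8, 0.8])], [np.array([0, 1])])
        assert pa2[0] == 1.0
        pz3, _ = latent_conditionals(0.5, [0.5], [np.array([0.3])], [np.array([0])])
        assert pz3 == pytest.approx(1.0 / 3.0, abs=1e-12)

    def test_exhaustive_enumeration_all_small_instances(self):
        """Agreement with brute-force enumeration on every y up to 3 samples × 2 reps."""
        rng = np.random.default_rng(11)
        for n_samp in (1, 2, 3):
            for K in (1, 2):
                psi = rng.uniform(0.05, 0.95)
                theta = rng.uniform(0.05, 0.95, size=n_samp)
                p = rng.uniform(0.05, 0.95, size=(n_samp, K))
                for flat in itertools.product((0, 1), repeat=n_samp * K):
                    y = np.array(flat).reshape(n_samp, K)
                    pz, pa = latent_conditionals(psi, theta, list(p), list(y))
                    for j in range(n_samp):
                        assert pa[j] == pytest.approx(
                            enum_conditional_a(theta[j], p[j], y[j]), abs=1e-12
                        )
                    assert pz == pytest.approx(enum_conditional_z(psi, theta), abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            latent_conditionals(1.4, [0.5], [np.array([0.5])], [np.array([0])])
        with pytest.raises(ValueError):
            latent_conditionals(0.5, [1.5], [np.array([0.5])], [np.array([0])])


class TestGibbs:
    def test_degenerate_all_positive_data(self):
        sites, samples, det = tiny_tables(n_sites=10, n_samples_per=3, K=3, y=1)
        det[:] = 1
        ds = build_design_matrices(sites, samples, det, ModelSpec())
        draws = run_mcmc(ds, n_iter=5000, burn_in=500, seed=1)
        s = summarize_posterior(draws)
        for name in ("theta_bar", "p_bar"):
            assert s[name][0] > 0.9
        assert np.median(draws.psi_by_type["colony"]) > 0.9
        assert draws.z.all() and draws.a.all()

    def test_same_seed_same_chains(self):
        ds, _ = generate_dataset(DesignParams(n_pairs=5), TruthParams(), seed=3)
        d1 = run_mcmc(ds, n_iter=800, burn_in=100, seed=12)
        d2 = run_mcmc(ds, n_iter=800, burn_in=100, seed=12)
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.delta, d2.delta)
        d3 = run_mcmc(ds, n_iter=800, burn_in=100, seed=13)
        assert not np.array_equal(d1.beta, d3.beta)

    def test_hierarchy_holds_in_every_draw(self):
        ds, _ = generate_dataset(DesignParams(n_pairs=8), TruthParams(), seed=21)
        draws = run_mcmc(ds, n_iter=1500, burn_in=200, seed=4)
        # a_ij ≤ z_i in all draws; every detected sample keeps a = 1
        z_of_sample = draws.z[:, ds.sample_site]
        assert (draws.a <= z_of_sample).all()
        y_sample = np.bincount(ds.rep_sample, weights=ds.y, minlength=ds.n_samples) > 0
        assert draws.a[:, y_sample].all()

    def test_rwm_sampler_agrees_with_pg_on_posterior_location(self):
        ds, _ = generate_dataset(DesignParams(n_pairs=25), TruthParams(), seed=6)
        pg = run_mcmc(ds, n_iter=4000, burn_in=1000, seed=5, sampler="pg")
        rwm = run_mcmc(ds, n_iter=12000, burn_in=3000, seed=5, sampler="rwm")
        m_pg = np.median(pg.psi_by_type["colony"])
        m_rwm = np.median(rwm.psi_by_type["colony"])
        assert abs(m_pg - m_rwm) < 0.1

    def test_uninformative_level_falls_back_to_prior(self):
        """With no units to regress on, a block draws from its Normal prior."""
        rng = np.random.default_rng(0)
        for block in (_PGBlock(2, 1.5), _RWMBlock(2, 1.5)):
            draws = np.array(
                [block.update(np.empty((0, 2)), np.empty(0), np.zeros(2), rng) for _ in range(4000)]
            )
            assert abs(draws.mean()) < 4 * 1.5 / np.sqrt(4000 * 2)
            assert abs(draws.std(ddof=1) - 1.5) < 0.08

    def test_burn_in_must_be_smaller(self):
        ds, _ = generate_dataset(DesignParams(n_pairs=2), seed=1)
        with pytest.raises(ValueError):
            run_mcmc(ds, n_iter=100, burn_in=100)


def fake_draws(beta, alpha=None, delta=None, **kw):
    n = beta.shape[0]
    alpha = np.zeros((n, 1)) if alpha is None else alpha
    delta = np.zeros((n, 1)) if delta is None else delta
    return PosteriorDraws(
        beta=beta,
        alpha=alpha,
        delta=delta,
        z=np.zeros((n, 1), np.uint8),
        a=np.zeros((n, 1), np.uint8),
        psi_by_type={},
        theta_bar=np.zeros(n),
        p_bar=np.zeros(n),
        x_names=("intercept",),
        w_names=("intercept",),
        v_names=tuple(kw.get("v_names", ("intercept",))),
        n_iter=n,
        burn_in=0,
        seed=0,
        spec=ModelSpec(),
    )


class TestSummaries:
    def test_constant_chain(self):
        d = fake_draws(np.full((1000, 1), 0.42))
        s = summarize_posterior(d)
        assert s["beta_intercept"] == (0.42, 0.42, 0.42)

    def test_percentiles_linear_interpolation(self):
        chain = np.random.default_rng(1).permutation(np.arange(1.0, 1001.0))
        s = summarize_posterior(fake_draws(chain[:, None]))
        med, lo, hi = s["beta_intercept"]
        assert (med, lo, hi) == (500.5, pytest.approx(25.975), pytest.approx(975.025))

    def test_empty_chain_rejected(self):
        with pytest.raises(ValueError):
            summarize_posterior(fake_draws(np.empty((0, 1))))


class TestDetectionCurve:
    def test_flat_and_closed_form(self):
        n = 500
        delta = np.column_stack([np.zeros(n), np.zeros(n)])
        d = fake_draws(np.zeros((n, 1)), delta=delta, v_names=("intercept", "time"))
        curve = detection_curve(d, np.array([-1.0, 0.0, 1.0]))
        np.testing.assert_allclose(curve["p_mean"], 0.5)

        delta1 = np.column_stack([np.zeros(n), -np.ones(n)])
        d1 = fake_draws(np.zeros((n, 1)), delta=delta1, v_names=("intercept", "time"))
        curve1 = detection_curve(d1, np.array([0.0, 1.0]))
        assert curve1["p_mean"].iloc[0] == pytest.approx(0.5)
        assert curve1["p_mean"].iloc[1] == pytest.approx(1 / (1 + np.e), abs=1e-12)

    def test_monotone_for_negative_slope_posterior(self):
        rng = np.random.default_rng(3)
        n = 400
        delta = np.column_stack([rng.normal(0, 1, n), -rng.uniform(0.2, 1.5, n)])
        d = fake_draws(np.zeros((n, 1)), delta=delta, v_names=("intercept", "time"))
        curve = detection_curve(d, np.linspace(-2, 2, 21))
        assert (np.diff(curve["p_mean"]) <= 0).all()

    def test_requires_covariate_and_warns_off_grid(self):
        d = fake_draws(np.zeros((100, 1)))
        with pytest.raises(ValueError):
            detection_curve(d, np.array([0.0]))
        d2 = fake_draws(
            np.zeros((100, 1)),
            delta=np.zeros((100, 2)),
            v_names=("intercept", "time"),
        )
        with pytest.warns(UserWarning):
            detection_curve(d2, np.array([9.0]))


class TestDiagnostics:
    def test_iid_chain_has_tiny_autocorrelation(self):
        rng = np.random.default_rng(8)
        d = fake_draws(rng.normal(size=(10_000, 1)))
        diag = diagnostics(d)
        row = diag.set_index("parameter").loc["beta_intercept"]
        assert abs(row["acf_1"]) < 0.03

    def test_ar1_chain_recovers_rho(self):
        rng = np.random.default_rng(9)
        n = 20_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = 0.9 * x[t - 1] + eps[t]
        diag = diagnostics(fake_draws(x[:, None])).set_index("parameter")
        assert 0.85 <= diag.loc["beta_intercept", "acf_1"] <= 0.95

    def test_constant_chain_mcse_zero(self):
        diag = diagnostics(fake_draws(np.full((4000, 1), 1.3))).set_index("parameter")
        assert diag.loc["beta_intercept", "mcse"] == 0.0

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            diagnostics(fake_draws(np.zeros((100, 1))))
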