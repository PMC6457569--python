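"""Multi-scale Bayesian occupancy model for eDNA surveys.

The observation design has three nested levels: sites (tree islands), water
samples within sites, and PCR replicates within samples. The model is

    z_i   ~ Bernoulli(ψ_i),    logit ψ_i   = x_i'β      (site occupancy)
    a_ij  | z_i = 1 ~ Bernoulli(θ_ij),  logit θ_ij = w_ij'α  (sample occurrence)
    y_ijk | a_ij = 1 ~ Bernoulli(p_ijk), logit p_ijk = v_ijk'δ (replicate detection)

with a_ij = 0 whenever z_i = 0 and y_ijk = 0 whenever a_ij = 0. The latent
indicators z (site holds eDNA) and a (sample holds eDNA) are sampled by
Gibbs steps from their closed-form full conditionals; the logit-scale
coefficient blocks β, α, δ get conjugate normal updates via Pólya-Gamma
augmentation (or, optionally, adaptive random-walk Metropolis) under
independent Normal(0, prior_sd²) priors.

Island type enters ψ with cell-means coding — one coefficient per type and
no global intercept — so that each type's occupancy is logit⁻¹ of its own
coefficient. Numeric covariates are centred and scaled (SD with n−1) over
the units at their own level before entering the linear predictors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .polya_gamma import sample_pg, seed_pg_rng

__all__ = [
    "ModelSpec",
    "OccupancyDataset",
    "PosteriorDraws",
    "OccupancySummary",
    "build_design_matrices",
    "latent_conditionals",
    "run_mcmc",
    "summarize_posterior",
    "detection_curve",
    "diagnostics",
]

_CLIP = 35.0  # |linear predictor| bound; inert at double precision

#: covariate name -> column of the internal samples table
_SAMPLE_COLUMNS = {
    "date": "date_days",
    "time": "time_min",
    "temp": "water_temp_c",
    "depth": "depth_cm",
}

ISLAND_TYPES = ("colony", "control")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_CLIP, _CLIP)))


@dataclass(frozen=True)
class ModelSpec:
    """Covariate structure of one candidate model.

    ``psi`` lists site-level covariates ("type" triggers cell-means coding),
    ``theta`` sample-level and ``p`` replicate-level covariates; empty tuples
    mean intercept-only. ``prior_sd`` is the common prior standard deviation
    of all logit-scale coefficients.
    """

    psi: tuple[str, ...] = ()
    theta: tuple[str, ...] = ()
    p: tuple[str, ...] = ()
    prior_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.prior_sd <= 0:
            raise ValueError("prior_sd must be positive")

    @property
    def name(self) -> str:
        fmt = lambda covs: " + ".join(covs) if covs else "."
        return f"psi({fmt(self.psi)})theta({fmt(self.theta)})p({fmt(self.p)})"


@dataclass
class OccupancyDataset:
    """Ragged site → sample → replicate detection data with design matrices.

    The detection history is stored flat: ``y`` has one entry per PCR
    replicate, ``rep_sample`` maps replicates to sample indices and
    ``sample_site`` maps samples to site indices. ``X``, ``W``, ``V`` are the
    site/sample/replicate design matrices (already centred and scaled);
    ``scaling`` records the (mean, sd) used per numeric covariate so
    estimates can be mapped back to natural units.
    """

    y: np.ndarray
    rep_sample: np.ndarray
    sample_site: np.ndarray
    X: np.ndarray
    W: np.ndarray
    V: np.ndarray
    x_names: tuple[str, ...]
    w_names: tuple[str, ...]
    v_names: tuple[str, ...]
    site_ids: np.ndarray
    sample_ids: np.ndarray
    island_type: np.ndarray  # per site
    spec: ModelSpec
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    tables: dict[str, pd.DataFrame] | None = None

    @property
    def n_sites(self) -> int:
        return self.X.shape[0]

    @property
    def n_samples(self) -> int:
        return self.W.shape[0]

    @property
    def n_replicates(self) -> int:
        return self.V.shape[0]

    def validate(self) -> None:
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be binary")
        if self.rep_sample.shape[0] != self.n_replicates:
            raise ValueError("replicate index length mismatch")
        if self.sample_site.shape[0] != self.n_samples:
            raise ValueError("sample index length mismatch")
        if self.rep_sample.max(initial=-1) >= self.n_samples:
            raise ValueError("replicate points past sample table")
        if self.sample_site.max(initial=-1) >= self.n_sites:
            raise ValueError("sample points past site table")


def _standardize(values: np.ndarray, name: str, scaling: dict) -> np.ndarray:
    mu = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError(f"covariate {name!r} is constant; cannot scale")
    scaling[name] = (mu, sd)
    return (values - mu) / sd


def build_design_matrices(
    sites: pd.DataFrame,
    samples: pd.DataFrame,
    detections: pd.DataFrame,
    spec: ModelSpec,
) -> OccupancyDataset:
    """Assemble the flat detection arrays and design matrices for one model.

    Parameters
    ----------
    sites
        One row per site: ``site_id``, ``island_type``, optional numerics.
    samples
        One row per water sample: ``sample_id``, ``site_id``, ``date_days``
        (days since the first collection), ``time_min`` (minutes since
        midnight), ``water_temp_c``, ``depth_cm``. Temperatures must already
        be complete (imputed upstream).
    detections
        Indexed by ``sample_id`` with columns ``det_1..det_K`` in {0, 1}
        (the LOB-filtered replicate detection matrix).
    spec
        Covariate structure; unknown names raise ``KeyError``.
    """
    sites = sites.reset_index() if sites.index.name == "site_id" else sites
    site_ids = sites["site_id"].to_numpy()
    site_pos = {s: i for i, s in enumerate(site_ids)}
    samples = samples.sort_values("sample_id", kind="stable").reset_index(drop=True)
    sample_site = samples["site_id"].map(site_pos)
    if sample_site.isna().any():
        bad = samples.loc[sample_site.isna(), "sample_id"].iloc[0]
        raise ValueError(f"sample {bad!r} references an unknown site")
    sample_site = sample_site.to_numpy(dtype=np.int64)

    det = detections.loc[samples["sample_id"]]
    det_cols = [c for c in det.columns if c.startswith("det_")]
    if not det_cols:
        raise ValueError("detection table has no det_* columns")
    y2 = det[det_cols].to_numpy(dtype=np.int8)
    n_samples, n_rep = y2.shape
    y = y2.ravel()
    rep_sample = np.repeat(np.arange(n_samples), n_rep)

    scaling: dict[str, tuple[float, float]] = {}

    # --- site matrix ---------------------------------------------------
    x_cols, x_names = [], []
    if "type" in spec.psi:
        t = sites["island_type"].to_numpy()
        unknown = set(t) - set(ISLAND_TYPES)
        if unknown:
            raise ValueError(f"unknown island types {sorted(unknown)}")
        for level in ISLAND_TYPES:
            x_cols.append((t == level).astype(float))
            x_names.append(f"type_{level}")
    else:
        x_cols.append(np.ones(len(sites)))
        x_names.append("intercept")
    for name in spec.psi:
        if name == "type":
            continue
        if name not in sites.columns:
            raise KeyError(f"site covariate {name!r} not in sites table")
        x_cols.append(_standardize(sites[name].to_numpy(float), f"psi.{name}", scaling))
        x_names.append(name)
    X = np.column_stack(x_cols)

    # --- sample / replicate matrices ------------------------------------
    def numeric_sample_column(name: str, level: str) -> np.ndarray:
        col = _SAMPLE_COLUMNS.get(name, name)
        if col not in samples.columns:
            raise KeyError(f"covariate {name!r} (column {col!r}) not in samples table")
        vals = samples[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValueError(f"covariate {name!r} has missing values; impute first")
        return vals

    w_cols, w_names = [np.ones(n_samples)], ["intercept"]
    for name in spec.theta:
        vals = numeric_sample_column(name, "theta")
        w_cols.append(_standardize(vals, f"theta.{name}", scaling))
        w_names.append(name)
    W = np.column_stack(w_cols)

    v_cols, v_names = [np.ones(n_samples * n_rep)], ["intercept"]
    for name in spec.p:
        vals = numeric_sample_column(name, "p")
        rep_vals = np.repeat(vals, n_rep)
        v_cols.append(_standardize(rep_vals, f"p.{name}", scaling))
        v_names.append(name)
    V = np.column_stack(v_cols)

    ds = OccupancyDataset(
        y=y,
        rep_sample=rep_sample,
        sample_site=sample_site,
        X=X,
        W=W,
        V=V,
        x_names=tuple(x_names),
        w_names=tuple(w_names),
        v_names=tuple(v_names),
        site_ids=site_ids,
        sample_ids=samples["sample_id"].to_numpy(),
        island_type=sites["island_type"].to_numpy(),
        spec=spec,
        scaling=scaling,
        tables={"sites": sites, "samples": samples, "detections": det},
    )
    ds.validate()
    return ds


def latent_conditionals(
    psi_i: float,
    theta_ij: np.ndarray,
    p_ijk: Sequence[np.ndarray],
    y_i: Sequence[np.ndarray],
) -> tuple[float, np.ndarray]:
    """Full-conditional probabilities of the latent states at one site.

    Returns ``(pz, pa)`` where ``pa[j]`` is P(a_ij = 1 | z_i = 1, y_ij·):
    1 whenever the sample has a detection, else θq/(θq + 1 − θ) with
    q = Π_k (1 − p_ijk); and ``pz`` is P(z_i = 1 | a_i· = 0) =
    ψr/(ψr + 1 − ψ) with r = Π_j (1 − θ_ij) (the caller uses z = 1 with
    certainty whenever any a_ij = 1).
    """
    if not 0.0 <= psi_i <= 1.0:
        raise ValueError("psi outside [0, 1]")
    theta_ij = np.asarray(theta_ij, dtype=float)
    if ((theta_ij < 0) | (theta_ij > 1)).any():
        raise ValueError("theta outside [0, 1]")
    pa = np.empty(len(theta_ij))
    for j, (th, pj, yj) in enumerate(zip(theta_ij, p_ijk, y_i)):
        pj = np.asarray(pj, dtype=float)
        if ((pj < 0) | (pj > 1)).any():
            raise ValueError("p outside [0, 1]")
        if np.any(np.asarray(yj) == 1):
            pa[j] = 1.0
        else:
            q = np.prod(1.0 - pj)
            pa[j] = th * q / (th * q + 1.0 - th)
    r = np.prod(1.0 - theta_ij)
    pz = psi_i * r / (psi_i * r + 1.0 - psi_i)
    return float(pz), pa


@dataclass
class PosteriorDraws:
    """Post-burn-in MCMC output of one model fit."""

    beta: np.ndarray  # (n_keep, len(x_names))
    alpha: np.ndarray
    delta: np.ndarray
    z: np.ndarray  # (n_keep, n_sites) uint8
    a: np.ndarray  # (n_keep, n_samples) uint8
    psi_by_type: dict[str, np.ndarray]
    theta_bar: np.ndarray
    p_bar: np.ndarray
    x_names: tuple[str, ...]
    w_names: tuple[str, ...]
    v_names: tuple[str, ...]
    n_iter: int
    burn_in: int
    seed: int
    spec: ModelSpec
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.beta.shape[0]

    def coefficient_chains(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, chain, names in (
            ("beta", self.beta, self.x_names),
            ("alpha", self.alpha, self.w_names),
            ("delta", self.delta, self.v_names),
        ):
            for k, nm in enumerate(names):
                out[f"{prefix}_{nm}"] = chain[:, k]
        return out


class _PGBlock:
    """Conjugate Pólya-Gamma update of one logistic coefficient block."""

    def __init__(self, dim: int, prior_sd: float):
        self.prior_prec = np.eye(dim) / prior_sd**2
        self.prior_sd = prior_sd
        self.dim = dim

    def update(self, Xm, resp, coef, rng):
        if Xm.shape[0] == 0:
            return self.prior_sd * rng.standard_normal(self.dim)
        c = np.clip(Xm @ coef, -_CLIP, _CLIP)
        omega = sample_pg(c)
        prec = Xm.T @ (omega[:, None] * Xm) + self.prior_prec
        chol, low = cho_factor(prec, lower=True)
        mean = cho_solve((chol, low), Xm.T @ (resp - 0.5))
        noise = solve_triangular(chol, rng.standard_normal(self.dim), lower=True, trans="T")
        return mean + noise


class _RWMBlock:
    """Adaptive random-walk Metropolis update (target acceptance 0.44)."""

    def __init__(self, dim: int, prior_sd: float):
        self.prior_sd = prior_sd
        self.dim = dim
        self.log_step = np.log(0.5)
        self.t = 0

    def _logpost(self, coef, Xm, resp):
        eta = np.clip(Xm @ coef, -_CLIP, _CLIP)
        ll = np.sum(resp * eta - np.logaddexp(0.0, eta))
        return ll - 0.5 * np.sum(coef**2) / self.prior_sd**2

    def update(self, Xm, resp, coef, rng):
        if Xm.shape[0] == 0:
            return self.prior_sd * rng.standard_normal(self.dim)
        self.t += 1
        step = np.exp(self.log_step)
        prop = coef + step * rng.standard_normal(self.dim)
        logr = self._logpost(prop, Xm, resp) - self._logpost(coef, Xm, resp)
        accept = np.log(rng.random()) < logr
        # Robbins-Monro adaptation of the step size
        self.log_step += self.t**-0.6 * ((1.0 if accept else 0.0) - 0.44)
        return prop if accept else coef


def run_mcmc(
    dataset: OccupancyDataset,
    spec: ModelSpec | None = None,
    n_iter: int = 100_000,
    burn_in: int = 5_000,
    seed: int = 0,
    sampler: Literal["pg", "rwm"] = "pg",
) -> PosteriorDraws:
    """Fit the three-level occupancy model by Gibbs sampling.

    Each iteration updates, in fixed order: the sample-occurrence indicators
    ``a`` given ``z``, the site-occupancy indicators ``z`` given ``a``, then
    the coefficient blocks δ (on replicates of samples with a = 1), α (on
    samples of sites with z = 1) and β (on all sites). Latents start from
    the observed detections (z/a = 1 wherever anything was detected) and
    coefficients at 0. The full chains after ``burn_in`` are kept, unthinned.
    Identical seeds give identical chains.
    """
    if spec is None:
        spec = dataset.spec
    if burn_in >= n_iter:
        raise ValueError("burn_in must be smaller than n_iter")
    dataset.validate()

    y = dataset.y.astype(np.float64)
    rep_sample, sample_site = dataset.rep_sample, dataset.sample_site
    X, W, V = dataset.X, dataset.W, dataset.V
    n_sites, n_samples = dataset.n_sites, dataset.n_samples

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    seed_pg_rng(int(ss.generate_state(2)[1] % 2**31))

    any_y = np.bincount(rep_sample, weights=y, minlength=n_samples) > 0
    a = any_y.astype(np.float64)
    z = (np.bincount(sample_site, weights=a, minlength=n_sites) > 0).astype(np.float64)

    pb, pa_, pd_ = X.shape[1], W.shape[1], V.shape[1]
    beta = np.zeros(pb)
    alpha = np.zeros(pa_)
    delta = np.zeros(pd_)
    block_cls = _PGBlock if sampler == "pg" else _RWMBlock
    upd_beta = block_cls(pb, spec.prior_sd)
    upd_alpha = block_cls(pa_, spec.prior_sd)
    upd_delta = block_cls(pd_, spec.prior_sd)

    n_keep = n_iter - burn_in
    out_beta = np.empty((n_keep, pb))
    out_alpha = np.empty((n_keep, pa_))
    out_delta = np.empty((n_keep, pd_))
    out_z = np.empty((n_keep, n_sites), dtype=np.uint8)
    out_a = np.empty((n_keep, n_samples), dtype=np.uint8)
    out_theta_bar = np.empty(n_keep)
    out_p_bar = np.empty(n_keep)

    types_present = [t for t in ISLAND_TYPES if t in set(dataset.island_type)]
    psi_rows = {}
    for t in types_present:
        row = np.zeros(pb)
        for k, nm in enumerate(dataset.x_names):
            if nm == f"type_{t}":
                row[k] = 1.0
            elif nm == "intercept":
                row[k] = 1.0
        psi_rows[t] = row
    out_psi = {t: np.empty(n_keep) for t in types_present}

    for it in range(n_iter):
        psi = _sigmoid(X @ beta)
        theta = _sigmoid(W @ alpha)
        p = _sigmoid(V @ delta)

        # a | z, y  (a = 0 wherever z = 0; certain 1 wherever a detection)
        log_q = np.bincount(rep_sample, weights=np.log1p(-p), minlength=n_samples)
        q = np.exp(log_q)
        pa1 = theta * q / (theta * q + 1.0 - theta)
        draw = rng.random(n_samples)
        a = np.where(any_y, 1.0, (draw < pa1).astype(np.float64))
        a *= z[sample_site]

        # z | a  (certain 1 wherever any a = 1)
        any_a = np.bincount(sample_site, weights=a, minlength=n_sites) > 0
        log_r = np.bincount(sample_site, weights=np.log1p(-theta), minlength=n_sites)
        r = np.exp(log_r)
        pz1 = psi * r / (psi * r + 1.0 - psi)
        z = np.where(any_a, 1.0, (rng.random(n_sites) < pz1).astype(np.float64))

        # coefficient blocks: δ, α, β
        rep_mask = a[rep_sample] == 1.0
        delta = upd_delta.update(V[rep_mask], y[rep_mask], delta, rng)
        samp_mask = z[sample_site] == 1.0
        alpha = upd_alpha.update(W[samp_mask], a[samp_mask], alpha, rng)
        beta = upd_beta.update(X, z, beta, rng)

        if it >= burn_in:
            k = it - burn_in
            out_beta[k] = beta
            out_alpha[k] = alpha
            out_delta[k] = delta
            out_z[k] = z
            out_a[k] = a
            out_theta_bar[k] = _sigmoid(W @ alpha).mean()
            out_p_bar[k] = _sigmoid(V @ delta).mean()
            for t in types_present:
                out_psi[t][k] = _sigmoid(psi_rows[t] @ beta)

    return PosteriorDraws(
        beta=out_beta,
        alpha=out_alpha,
        delta=out_delta,
        z=out_z,
        a=out_a,
        psi_by_type=out_psi,
        theta_bar=out_theta_bar,
        p_bar=out_p_bar,
        x_names=dataset.x_names,
        w_names=dataset.w_names,
        v_names=dataset.v_names,
        n_iter=n_iter,
        burn_in=burn_in,
        seed=seed,
        spec=spec,
        scaling=dict(dataset.scaling),
    )


@dataclass
class OccupancySummary:
    """Posterior medians and 95% equal-tailed credible intervals."""

    table: pd.DataFrame  # parameter, median, cri_low, cri_high

    def __getitem__(self, parameter: str) -> tuple[float, float, float]:
        row = self.table.set_index("parameter").loc[parameter]
        return float(row["median"]), float(row["cri_low"]), float(row["cri_high"])


def _summary_row(name: str, chain: np.ndarray) -> dict:
    lo, med, hi = np.percentile(chain, [2.5, 50.0, 97.5])
    return {"parameter": name, "median": med, "cri_low": lo, "cri_high": hi}


def summarize_posterior(draws: PosteriorDraws) -> OccupancySummary:
    """Median and 95% CRI for every coefficient and derived probability."""
    if draws.n_draws == 0:
        raise ValueError("no post-burn-in draws to summarize")
    rows = [
        _summary_row(name, chain)
        for name, chain in draws.coefficient_chains().items()
    ]
    for t, chain in draws.psi_by_type.items():
        rows.append(_summary_row(f"psi_{t}", chain))
    rows.append(_summary_row("theta_bar", draws.theta_bar))
    rows.append(_summary_row("p_bar", draws.p_bar))
    return OccupancySummary(table=pd.DataFrame(rows))


def detection_curve(
    draws: PosteriorDraws,
    grid: np.ndarray,
    covariate: str = "time",
) -> pd.DataFrame:
    """Posterior detection probability across a standardized covariate grid.

    Evaluates logit⁻¹(δ₀ + δ_cov · t) draw by draw over ``grid`` (values on
    the standardized scale used in the fit) and returns the posterior mean
    and 95% CRI per grid point. Other detection covariates are held at 0
    (their mean).
    """
    if covariate not in draws.v_names:
        raise ValueError(f"model has no detection covariate {covariate!r}")
    grid = np.asarray(grid, dtype=float)
    if np.any(np.abs(grid) > 5.0):
        warnings.warn("detection grid extends beyond ±5 SD of the data")
    i0 = draws.v_names.index("intercept")
    i1 = draws.v_names.index(covariate)
    eta = draws.delta[:, i0][:, None] + np.outer(draws.delta[:, i1], grid)
    probs = _sigmoid(eta)
    lo, hi = np.percentile(probs, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            covariate: grid,
            "p_mean": probs.mean(axis=0),
            "cri_low": lo,
            "cri_high": hi,
        }
    )


def diagnostics(
    draws: PosteriorDraws, max_lag: int = 50, n_batches: int = 50
) -> pd.DataFrame:
    """Autocorrelation (lags 1..max_lag) and batch-means Monte Carlo SE.

    The MCSE divides the chain into ``n_batches`` equal batches and reports
    SD(batch means)/√n_batches; requires at least 50 draws per batch.
    """
    chains = draws.coefficient_chains()
    n = draws.n_draws
    if n < n_batches * 50:
        raise ValueError(
            f"need at least {n_batches * 50} draws for {n_batches}-batch diagnostics"
        )
    rows = []
    for name, c in chains.items():
        x = c - c.mean()
        denom = np.dot(x, x)
        acf = np.ones(max_lag + 1)
        if denom > 0:
            for lag in range(1, max_lag + 1):
                acf[lag] = np.dot(x[:-lag], x[lag:]) / denom
        else:
            acf[1:] = 0.0
        batch = c[: n - n % n_batches].reshape(n_batches, -1).mean(axis=1)
        mcse = float(batch.std(ddof=1) / np.sqrt(n_batches))
        row = {"parameter": name, "mcse": mcse}
        row.update({f"acf_{lag}": acf[lag] for lag in range(1, max_lag + 1)})
        rows.append(row)
    return pd.DataFrame(rows)
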