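"""End-to-end pipeline: raw CSVs in, quantification/fits/rankings out.

Stages run in a fixed order — quantify → limit-of-blank screen → detection
matrix → temperature imputation → model fits → WAIC ranking → field
summaries — and every artifact is written as CSV into the output directory,
together with a ``manifest.json`` recording the configuration, seed, library
versions, per-stage row counts and a checksum per output file. Reruns with
the same configuration are byte-identical for the deterministic stages and
chain-identical given the seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ddpcr import (
    DEFAULT_DROPLET_VOLUME_UL,
    apply_lob,
    compute_lob,
    estimate_concentration,
    inhibition_ratio,
    pool_and_select,
)
from .field import (
    design_counts,
    exclude_pairs,
    impute_temperature,
    naive_summary,
    pair_table,
    paired_concentration_test,
)
from .io import read_detections, read_neg_controls, read_replicates, read_samples, read_sites
from .occupancy import (
    ModelSpec,
    build_design_matrices,
    detection_curve,
    diagnostics,
    run_mcmc,
    summarize_posterior,
)
from .waic import compute_waic, rank_models

__all__ = ["PipelineConfig", "parse_model_string", "run_pipeline", "DEFAULT_MODELS"]

log = logging.getLogger("edna_occupancy")

#: The candidate model set compared by default.
DEFAULT_MODELS = (
    "psi(type)theta(.)p(time)",
    "psi(type)theta(.)p(.)",
    "psi(.)theta(.)p(.)",
    "psi(type)theta(date)p(.)",
    "psi(type)theta(date)p(time)",
    "psi(type)theta(.)p(time + depth)",
    "psi(type)theta(.)p(depth)",
)

_ALLOWED = {
    "psi": {"type"},
    "theta": {"date", "time", "depth", "temp"},
    "p": {"date", "time", "depth", "temp"},
}

_MODEL_RE = re.compile(
    r"^\s*(?:psi|ψ)\((?P<psi>[^)]*)\)\s*(?:theta|θ)\((?P<theta>[^)]*)\)\s*p\((?P<p>[^)]*)\)\s*$"
)


def parse_model_string(s: str, prior_sd: float = 2.0) -> ModelSpec:
    """Parse Table-style model notation like ``psi(type)theta(.)p(time + depth)``.

    ``.`` means intercept-only; covariate names are ``+``-separated. Unknown
    covariates and malformed strings raise ``ValueError`` naming the token.
    """
    m = _MODEL_RE.match(s)
    if m is None:
        raise ValueError(
            f"malformed model string {s!r}: expected psi(...)theta(...)p(...)"
        )

    def covs(level: str) -> tuple[str, ...]:
        body = m.group(level).strip()
        if body in (".", ""):
            return ()
        names = tuple(tok.strip() for tok in body.split("+"))
        for tok in names:
            if tok not in _ALLOWED[level]:
                raise ValueError(f"unknown covariate {tok!r} at level {level}")
        return names

    return ModelSpec(psi=covs("psi"), theta=covs("theta"), p=covs("p"), prior_sd=prior_sd)


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs; YAML-loadable, flag-overridable."""

    sites: str = "sites.csv"
    samples: str = "samples.csv"
    replicates: str = "replicates.csv"
    neg_controls: str = "neg_controls.csv"
    out_dir: str = "results"
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL
    lob: str | float = "auto"  # "auto" -> max over negative controls
    ipc_standard: float = 100.0
    models: tuple[str, ...] = DEFAULT_MODELS
    n_iter: int = 100_000
    burn_in: int = 5_000
    seed: int = 1
    prior_sd: float = 2.0
    sampler: str = "pg"

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("n_iter must exceed burn_in")
        for s in self.models:
            parse_model_string(s)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _slug(model: str) -> str:
    return re.sub(r"[^a-z0-9]+", "_", model.lower()).strip("_")


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the artifact directory.

    Raises on schema violations (naming the offending file); artifacts
    written before a failure are left in place.
    """
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    counts: dict[str, int] = {}

    def emit(name: str, df: pd.DataFrame, **kwargs) -> None:
        path = out / name
        df.to_csv(path, **kwargs)
        written[name] = path
        counts[name] = len(df)
        log.info("wrote %s (%d rows)", path, len(df))

    # --- quantify -------------------------------------------------------
    t0 = time.time()
    sites = read_sites(config.sites)
    samples = read_samples(config.samples)
    runs = read_replicates(config.replicates)
    controls_df = read_neg_controls(config.neg_controls)
    selected = pool_and_select(runs, config.droplet_volume)
    missing = set(samples["sample_id"]) - set(selected)
    if missing:
        raise ValueError(
            f"{config.replicates}: no replicate runs for samples {sorted(missing)[:5]}"
        )

    control_ests = {
        str(r.control_id): estimate_concentration(
            int(r.m_total), int(r.m_pos), config.droplet_volume
        )
        for r in controls_df.itertuples()
    }
    if config.lob == "auto":
        lob = compute_lob(control_ests)
    else:
        from .ddpcr import LobThreshold

        lob = LobThreshold(value=float(config.lob))
    log.info("limit of blank: %.4g copies/uL (%s)", lob.value, lob.source_control_id)

    det = apply_lob(
        {sid: est for sid, (est, _) in selected.items()},
        runs,
        lob,
        selected_runs={sid: rid for sid, (_, rid) in selected.items()},
    )

    ipc_by_sample: dict[str, float] = {}
    for r in runs:
        if r.ipc_conc is not None and r.run_id == selected[r.sample_id][1]:
            ipc_by_sample.setdefault(r.sample_id, 0.0)
            ipc_by_sample[r.sample_id] += r.ipc_conc
    quant = pd.DataFrame(
        {
            "sample_id": list(selected),
            "lambda_hat": [selected[s][0].lambda_hat for s in selected],
            "se": [selected[s][0].se for s in selected],
            "ci_low": [selected[s][0].ci_low for s in selected],
            "ci_high": [selected[s][0].ci_high for s in selected],
            "selected_run": [selected[s][1] for s in selected],
            "lob_applied": [bool(det.loc[s, "lob_applied"]) for s in selected],
            "inhibition": [
                inhibition_ratio(
                    ipc_by_sample[s] / max(1, sum(1 for r in runs if r.sample_id == s and r.run_id == selected[s][1])),
                    config.ipc_standard,
                )
                if s in ipc_by_sample
                else np.nan
                for s in selected
            ],
        }
    ).sort_values("sample_id")
    emit("quantification.csv", quant, index=False)
    emit("detections.csv", det.drop(columns=["concentration", "lob_applied"]))
    log.info("quantify stage: %.1fs", time.time() - t0)

    # --- impute + field summaries --------------------------------------
    samples = impute_temperature(samples)
    samples_out = samples.copy()
    emit("samples_imputed.csv", samples_out, index=False)

    merged = samples.merge(sites[["site_id", "pair_id", "island_type"]], on="site_id")
    merged["concentration"] = det.loc[merged["sample_id"], "concentration"].to_numpy()

    emit("table2_naive.csv", naive_summary(merged))

    pairs = pair_table(merged)
    retained, _ = exclude_pairs(pairs)
    pair_df = pd.DataFrame([asdict(p) for p in pairs])
    emit("pair_comparison.csv", pair_df, index=False)
    if len(retained) >= 2:
        mean_d, sd_d, t_stat, dof, p_val = paired_concentration_test(retained)
        pd.DataFrame(
            [{"mean_diff": mean_d, "sd_diff": sd_d, "t": t_stat, "df": dof, "p": p_val}]
        ).to_csv(out / "paired_test.csv", index=False)
        written["paired_test.csv"] = out / "paired_test.csv"
        counts["paired_test.csv"] = 1

    dc = design_counts(merged)
    emit("design_counts.csv", pd.DataFrame([dc]), index=False)

    # --- fit all models + WAIC ------------------------------------------
    results = []
    for k, model_str in enumerate(config.models):
        t0 = time.time()
        spec = parse_model_string(model_str, prior_sd=config.prior_sd)
        ds = build_design_matrices(sites, samples, det, spec)
        draws = run_mcmc(
            ds,
            n_iter=config.n_iter,
            burn_in=config.burn_in,
            seed=config.seed + k,
            sampler=config.sampler,
        )
        slug = _slug(model_str)
        emit(f"posterior_summary_{slug}.csv", summarize_posterior(draws).table, index=False)
        emit(f"diagnostics_{slug}.csv", diagnostics(draws) if draws.n_draws >= 2500 else pd.DataFrame(), index=False)
        chains = pd.DataFrame(draws.coefficient_chains())
        chains.to_csv(out / f"draws_{slug}.csv.gz", index=False, compression="gzip")
        written[f"draws_{slug}.csv.gz"] = out / f"draws_{slug}.csv.gz"
        counts[f"draws_{slug}.csv.gz"] = len(chains)
        if "time" in draws.v_names:
            grid = np.linspace(-2.0, 2.0, 41)
            emit(f"detection_curve_{slug}.csv", detection_curve(draws, grid), index=False)
        results.append((model_str, compute_waic(draws, ds)))
        log.info("fitted %s in %.1fs", model_str, time.time() - t0)

    if results:
        emit("waic_ranking.csv", rank_models(results), index=False)

    manifest = {
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "seed": config.seed,
        "row_counts": counts,
        "checksums": {name: _sha256(path) for name, path in written.items()},
        "elapsed_s": round(time.time() - t_start, 2),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
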