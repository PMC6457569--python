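"""Synthetic paired colony/control eDNA surveys with known truth.

Two generators live here:

* :func:`generate_dataset` simulates a full survey — paired colony and
  control tree islands, ~9 one-litre water samples per site, five ddPCR
  replicates per sample — from user-supplied logit-scale truth, all the way
  down to droplet counts. Parameter-recovery and model-selection tests run
  against the stored truth.
* :func:`everglades_fixture` emits a fully deterministic dataset whose
  count-level summaries (sample and site positivity, concentration extremes
  and site-total means, morning-sampling and temperature-window tallies,
  temperature-based pair exclusions) match the published field study this
  package's defaults are modelled on. It ships both as code and as frozen
  CSVs under ``fixtures/``.

Covariate emulation is deliberately simple: collection times uniform over
08:00–13:00, water temperature linear in time plus Gaussian noise, a fixed
depth per site, one collection date per island pair. Only the covariate
structure matters for exercising the model; none of it is calibrated to real
hydrology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .ddpcr import DEFAULT_DROPLET_VOLUME_UL
from .occupancy import ISLAND_TYPES, ModelSpec, OccupancyDataset, build_design_matrices

__all__ = [
    "DesignParams",
    "TruthParams",
    "SyntheticTruth",
    "DEFAULT_SEED",
    "generate_dataset",
    "everglades_fixture",
    "truth_report",
]

#: Default RNG seed (the study's publication date).
DEFAULT_SEED = 20190410

_SAMPLE_COVARIATES = ("date", "time", "depth", "temp")


@dataclass(frozen=True)
class DesignParams:
    """Sampling-design knobs of a simulated survey."""

    n_pairs: int = 15
    samples_per_site: tuple[int, int] = (8, 10)  # inclusive range
    n_replicates: int = 5
    droplets_per_reaction: tuple[int, int] = (15_000, 20_000)
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL

    def __post_init__(self) -> None:
        if self.n_pairs < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.samples_per_site
        if not 1 <= lo <= hi:
            raise ValueError("invalid samples_per_site range")
        dlo, dhi = self.droplets_per_reaction
        if not 1 <= dlo <= dhi <= 10**6:
            raise ValueError("droplet range must lie within [1, 1e6]")
        if self.droplet_volume <= 0:
            raise ValueError("droplet_volume must be positive")


@dataclass(frozen=True)
class TruthParams:
    """Logit-scale truth of the three-level hierarchy.

    ``beta`` holds one cell-means occupancy logit per island type;
    ``alpha``/``delta`` map coefficient names ("intercept" plus covariates
    among date/time/depth/temp) to values. ``occupied_concentration`` is the
    (log-mean, log-sd) of the nominal eDNA concentration (copies/μL) in
    occupied samples; ``false_amp_rate`` is the per-replicate probability of
    a spurious positive-droplet burst in eDNA-free material.
    """

    beta: dict[str, float] = field(
        default_factory=lambda: {"colony": 1.2, "control": -0.2}
    )
    alpha: dict[str, float] = field(default_factory=lambda: {"intercept": -0.5})
    delta: dict[str, float] = field(default_factory=lambda: {"intercept": 0.5})
    occupied_concentration: tuple[float, float] = (0.0, 1.0)
    false_amp_rate: float = 0.0

    def __post_init__(self) -> None:
        if set(self.beta) != set(ISLAND_TYPES):
            raise ValueError(f"beta must have one entry per island type {ISLAND_TYPES}")
        for name, coefs in (("alpha", self.alpha), ("delta", self.delta)):
            if "intercept" not in coefs:
                raise ValueError(f"{name} needs an 'intercept' entry")
            unknown = set(coefs) - {"intercept", *_SAMPLE_COVARIATES}
            if unknown:
                raise ValueError(f"unknown {name} covariates {sorted(unknown)}")
        if self.occupied_concentration[1] <= 0:
            raise ValueError("occupied_concentration scale must be positive")
        if not 0.0 <= self.false_amp_rate <= 0.05:
            raise ValueError("false_amp_rate must lie in [0, 0.05]")

    @property
    def model_spec(self) -> ModelSpec:
        covs = lambda d: tuple(k for k in d if k != "intercept")
        return ModelSpec(psi=("type",), theta=covs(self.alpha), p=covs(self.delta))


@dataclass
class SyntheticTruth:
    """Latent states and concentrations behind one simulated dataset."""

    z: np.ndarray  # per-site occupancy indicator
    a: np.ndarray  # per-sample occurrence indicator
    lambda_true: np.ndarray  # per-sample nominal concentration, copies/μL
    site_ids: np.ndarray
    sample_ids: np.ndarray
    theta_true: np.ndarray  # per-sample occurrence probability
    p_true: np.ndarray  # per-replicate detection probability (flat)
    params: TruthParams

    def __post_init__(self) -> None:
        if np.any(self.lambda_true[self.a == 0] != 0):
            raise ValueError("lambda_true must be 0 where a = 0")
        if np.any(self.lambda_true[self.a == 1] <= 0):
            raise ValueError("lambda_true must be positive where a = 1")


def _standardized(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=1)
    return (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)


def _linear_predictor(coefs: dict[str, float], columns: dict[str, np.ndarray], n: int) -> np.ndarray:
    eta = np.full(n, coefs["intercept"], dtype=float)
    for name, val in coefs.items():
        if name != "intercept":
            eta = eta + val * columns[name]
    return eta


def generate_dataset(
    design: DesignParams = DesignParams(),
    truth: TruthParams = TruthParams(),
    seed: int = DEFAULT_SEED,
) -> tuple[OccupancyDataset, SyntheticTruth]:
    """Simulate a paired survey down to droplet counts.

    Site occupancy, sample occurrence and replicate detection follow the
    logit-linear truth on covariates standardized within the generated
    dataset (matching how the model will see them). Droplet counts in
    occupied samples are Binomial(m, π) with the per-droplet probability π
    attenuated so that P(≥1 positive droplet) equals the replicate detection
    probability exactly — detections therefore arise only through the
    quantification chain. eDNA-free replicates can fire through a spurious
    burst channel with probability ``false_amp_rate``.

    Returns the assembled :class:`OccupancyDataset` (raw tables attached)
    and the :class:`SyntheticTruth`. Identical seeds give identical output.
    """
    rng = np.random.default_rng(seed)
    n_sites = 2 * design.n_pairs
    K = design.n_replicates

    # --- sites -----------------------------------------------------------
    site_rows = []
    for pr in range(1, design.n_pairs + 1):
        for typ, pre in (("colony", "C"), ("control", "T")):
            site_rows.append(
                {
                    "site_id": f"{pre}{pr:02d}",
                    "pair_id": f"P{pr:02d}",
                    "island_type": typ,
                    "area_m2": round(float(rng.uniform(200, 4000)), 1),
                    "_depth": round(float(rng.uniform(10, 100)), 1),
                    "_date": date(2017, 4, 9) + timedelta(days=pr),
                }
            )
    sites = pd.DataFrame(site_rows)

    # --- samples ---------------------------------------------------------
    lo, hi = design.samples_per_site
    n_per_site = rng.integers(lo, hi + 1, size=n_sites)
    sample_rows = []
    for i, site in sites.iterrows():
        for j in range(n_per_site[i]):
            t_min = int(rng.integers(480, 781))
            temp = round(11.0 + 0.02 * t_min + float(rng.normal(0, 3.0)), 1)
            sample_rows.append(
                {
                    "sample_id": f"{site['site_id']}-{j + 1:02d}",
                    "site_id": site["site_id"],
                    "date": site["_date"].isoformat(),
                    "time_min": t_min,
                    "water_temp_c": temp,
                    "depth_cm": site["_depth"],
                    "temp_imputed": False,
                }
            )
    samples = pd.DataFrame(sample_rows).sort_values("sample_id").reset_index(drop=True)
    d0 = pd.to_datetime(samples["date"]).min()
    samples["date_days"] = (pd.to_datetime(samples["date"]) - d0).dt.days.astype(float)
    n_samples = len(samples)

    # --- latent states ---------------------------------------------------
    site_index = {s: i for i, s in enumerate(sites["site_id"])}
    sample_site = samples["site_id"].map(site_index).to_numpy()

    psi = 1.0 / (1.0 + np.exp(-np.array([truth.beta[t] for t in sites["island_type"]])))
    z = (rng.random(n_sites) < psi).astype(np.int8)

    samp_cols = {
        "date": _standardized(samples["date_days"].to_numpy(float)),
        "time": _standardized(samples["time_min"].to_numpy(float)),
        "depth": _standardized(samples["depth_cm"].to_numpy(float)),
        "temp": _standardized(samples["water_temp_c"].to_numpy(float)),
    }
    theta = 1.0 / (1.0 + np.exp(-_linear_predictor(truth.alpha, samp_cols, n_samples)))
    a = ((rng.random(n_samples) < theta) & (z[sample_site] == 1)).astype(np.int8)

    mu, sig = truth.occupied_concentration
    lam = np.where(a == 1, rng.lognormal(mu, sig, size=n_samples), 0.0)

    # replicate-level detection probabilities (covariates repeat per sample)
    rep_cols = {k: _standardized(np.repeat(samples[_col(k)].to_numpy(float), K)) for k in _SAMPLE_COVARIATES}
    p_rep = 1.0 / (1.0 + np.exp(-_linear_predictor(truth.delta, rep_cols, n_samples * K)))

    # --- droplets --------------------------------------------------------
    dlo, dhi = design.droplets_per_reaction
    m_tot = rng.integers(dlo, dhi + 1, size=n_samples * K)
    a_rep = np.repeat(a, K)
    # π such that P(m1 = 0) = (1−π)^m = 1 − p exactly
    pi_occ = -np.expm1(np.log1p(-p_rep) / m_tot)
    m_pos = np.zeros(n_samples * K, dtype=np.int64)
    occ = a_rep == 1
    m_pos[occ] = rng.binomial(m_tot[occ], pi_occ[occ])
    if truth.false_amp_rate > 0:
        burst = (~occ) & (rng.random(n_samples * K) < truth.false_amp_rate)
        m_pos[burst] = 1 + rng.poisson(1.0, size=int(burst.sum()))

    replicates = pd.DataFrame(
        {
            "sample_id": np.repeat(samples["sample_id"].to_numpy(), K),
            "replicate_id": np.tile(np.arange(1, K + 1), n_samples),
            "run_id": 1,
            "m_total": m_tot,
            "m_pos": m_pos,
            "ipc_conc": 100.0,
        }
    )
    neg_controls = pd.DataFrame(
        {
            "control_id": [f"{t}_{i}" for t in ("field", "filtration", "extraction", "ntc") for i in (1, 2)],
            "control_type": [t for t in ("field", "filtration", "extraction", "ntc") for _ in (1, 2)],
            "m_total": 16_000,
            "m_pos": 0,
        }
    )

    det = pd.DataFrame(
        (m_pos >= 1).astype(np.int8).reshape(n_samples, K),
        columns=[f"det_{k + 1}" for k in range(K)],
        index=pd.Index(samples["sample_id"], name="sample_id"),
    )

    dataset = build_design_matrices(
        sites.drop(columns=["_depth", "_date"]), samples, det, truth.model_spec
    )
    dataset.tables.update({"replicates": replicates, "neg_controls": neg_controls})

    truth_obj = SyntheticTruth(
        z=z,
        a=a,
        lambda_true=lam,
        site_ids=sites["site_id"].to_numpy(),
        sample_ids=samples["sample_id"].to_numpy(),
        theta_true=theta,
        p_true=p_rep,
        params=truth,
    )
    return dataset, truth_obj


def _col(name: str) -> str:
    return {"date": "date_days", "time": "time_min", "temp": "water_temp_c", "depth": "depth_cm"}[name]


def truth_report(truth: SyntheticTruth, dataset: OccupancyDataset) -> pd.DataFrame:
    """Recount the stored truth into the fractions recovery tests target.

    Per island type: the true occupancy fraction (mean z), the occurrence
    fraction among samples of occupied sites (mean a | z = 1) and the mean
    replicate positivity among occurring samples (mean y | a = 1); plus an
    ``overall`` row. Fractions with an empty denominator are reported as 0.
    """
    if not np.array_equal(truth.site_ids, dataset.site_ids):
        raise ValueError("truth and dataset site ids do not match")
    if not np.array_equal(truth.sample_ids, dataset.sample_ids):
        raise ValueError("truth and dataset sample ids do not match")

    z_site = truth.z
    a_samp = truth.a
    y = dataset.y
    samp_type = dataset.island_type[dataset.sample_site]
    rep_type = samp_type[dataset.rep_sample]
    a_rep = a_samp[dataset.rep_sample]

    def frac(num_mask, den_mask):
        den = int(den_mask.sum())
        return float(num_mask[den_mask].mean()) if den else 0.0

    rows = []
    for label in (*ISLAND_TYPES, "overall"):
        s_mask = np.ones(dataset.n_sites, bool) if label == "overall" else dataset.island_type == label
        sa_mask = np.ones(dataset.n_samples, bool) if label == "overall" else samp_type == label
        r_mask = np.ones(dataset.n_replicates, bool) if label == "overall" else rep_type == label
        occ_samples = sa_mask & (z_site[dataset.sample_site] == 1)
        pos_reps = r_mask & (a_rep == 1)
        rows.append(
            {
                "stratum": label,
                "occupancy": frac(z_site.astype(float), s_mask),
                "occurrence": frac(a_samp.astype(float), occ_samples),
                "replicate_positivity": frac(y.astype(float), pos_reps),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# deterministic fixture
# ---------------------------------------------------------------------------

_FIXTURE_V = DEFAULT_DROPLET_VOLUME_UL
_COLONY_FILLER = 9.45 / 17  # ≈0.5559: 17 fillers chosen so site-total mean is 3.20
_CONTROL_POSITIVES = {  # site -> list of sample concentrations, copies/μL
    "T01": [0.26, 0.39],
    "T02": [0.333],
    "T03": [0.333],
    "T04": [0.334],
}
_NTC_CONC = 0.258  # limit of blank carried by the dirtiest no-template control


def _invert_droplets(lam: float) -> tuple[int, int]:
    """Pooled droplet counts (M, M1) whose estimate matches λ to 4 sig figs.

    Picks a small positive-droplet count near the expectation at M ≈ 85,000
    and then tunes the pooled total M (kept inside 5 wells × 15,000–20,000
    droplets) so −ln(1 − M1/M)/v lands on λ; the residual relative error is
    O(1/M), far below 4 significant figures.
    """
    u = -math.expm1(-lam * _FIXTURE_V)
    m1 = max(1, round(85_000 * u))
    m = min(100_000, max(75_000, round(m1 / u)))
    return m, m1


def _split(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def everglades_fixture() -> OccupancyDataset:
    """Deterministic 15-pair survey matching the published count summaries.

    The layout: 137 colony samples over 15 sites (two sites of 10, thirteen
    of 9) with 19 positives on 10 sites; 128 control samples (eight sites of
    9, seven of 8) with 5 positives on 4 sites. Concentrations place the
    printed extremes (0.26 and 38.29 copies/μL, both at colony site C06; the
    control extremes 0.26/0.39) and fillers chosen so that the site-total
    means print as 3.20 (colonies) and 0.11 (controls). Collection times put
    exactly 97/137 colony and 91/128 control samples before 11:00;
    temperatures put exactly 218/265 samples inside 20.3–27.8 °C and make
    exactly three pairs fail the 8 °C colony/control median screen. Droplet
    counts reproduce each positive concentration to 4 significant figures;
    the dirtiest negative control is an NTC at 0.258 copies/μL.

    Filler values (0.5559 and 0.333/0.334) are constrained only by the
    printed sums and extremes; they are otherwise arbitrary.
    """
    colony_sizes = [10, 10] + [9] * 13
    control_sizes = [9] * 8 + [8] * 7
    colony_pos = {f"C{i:02d}": 2 for i in range(1, 10)}
    colony_pos["C10"] = 1

    site_rows, sample_rows, rep_rows = [], [], []
    colony_seq = control_seq = 0
    global_idx = 0

    for pr in range(1, 16):
        for typ, pre, sizes in (
            ("colony", "C", colony_sizes),
            ("control", "T", control_sizes),
        ):
            sid = f"{pre}{pr:02d}"
            site_rows.append(
                {
                    "site_id": sid,
                    "pair_id": f"P{pr:02d}",
                    "island_type": typ,
                    "area_m2": 1000.0 + 100.0 * pr + (0.0 if typ == "colony" else 50.0),
                }
            )
            n_s = sizes[pr - 1]

            # per-site positive concentrations
            if typ == "colony":
                n_pos = colony_pos.get(sid, 0)
                concs = [38.29, 0.26] if sid == "C06" else [_COLONY_FILLER] * n_pos
            else:
                concs = _CONTROL_POSITIVES.get(sid, [])
            concs = list(concs) + [0.0] * (n_s - len(concs))

            for j, lam in enumerate(concs):
                seq = colony_seq if typ == "colony" else control_seq
                tot = 137 if typ == "colony" else 128
                before = 97 if typ == "colony" else 91
                if seq < before:
                    t_min = (480 if typ == "colony" else 482) + (seq % 35) * 5
                else:
                    t_min = (660 if typ == "colony" else 662) + ((seq - before) % 23) * 5
                if typ == "colony":
                    colony_seq += 1
                else:
                    control_seq += 1

                if pr >= 13:  # the three temperature-excluded pairs
                    temp = 21.0 if typ == "colony" else 29.5
                elif typ == "colony" and sid in [f"C{i:02d}" for i in range(3, 11)]:
                    n_cold = 2 if sid == "C10" else 3
                    temp = 19.5 if j >= n_s - n_cold else 24.0
                else:
                    temp = 24.0

                smp = f"{sid}-{j + 1:02d}"
                sample_rows.append(
                    {
                        "sample_id": smp,
                        "site_id": sid,
                        "date": (date(2017, 4, 9) + timedelta(days=pr)).isoformat(),
                        "time_min": t_min,
                        "water_temp_c": temp,
                        "depth_cm": float(15 + (global_idx % 40)),
                        "temp_imputed": False,
                    }
                )
                global_idx += 1

                if lam > 0:
                    m, m1 = _invert_droplets(lam)
                    m_tots, m_poss = _split(m, 5), _split(m1, 5)
                else:
                    m_tots, m_poss = [16_000] * 5, [0] * 5
                ipc = 2.0 if typ == "colony" else 80.0
                for k in range(5):
                    rep_rows.append(
                        {
                            "sample_id": smp,
                            "replicate_id": k + 1,
                            "run_id": 1,
                            "m_total": m_tots[k],
                            "m_pos": m_poss[k],
                            "ipc_conc": ipc,
                        }
                    )

    sites = pd.DataFrame(site_rows)
    samples = pd.DataFrame(sample_rows).sort_values("sample_id").reset_index(drop=True)
    d0 = pd.to_datetime(samples["date"]).min()
    samples["date_days"] = (pd.to_datetime(samples["date"]) - d0).dt.days.astype(float)
    replicates = pd.DataFrame(rep_rows)

    ntc_m, ntc_m1 = _invert_droplets(_NTC_CONC)
    neg_controls = pd.DataFrame(
        {
            "control_id": ["field_1", "field_2", "filtration_1", "extraction_1", "ntc_1"],
            "control_type": ["field", "field", "filtration", "extraction", "ntc"],
            "m_total": [16_000, 16_000, 16_000, 16_000, ntc_m],
            "m_pos": [0, 0, 0, 0, ntc_m1],
        }
    )

    det = (
        replicates.assign(hit=(replicates["m_pos"] >= 1).astype(np.int8))
        .pivot_table(index="sample_id", columns="replicate_id", values="hit")
        .astype(np.int8)
    )
    det.columns = [f"det_{k}" for k in det.columns]
    det = det.loc[samples["sample_id"]]

    ds = build_design_matrices(
        sites, samples, det, ModelSpec(psi=("type",), p=("time",))
    )
    ds.tables.update({"replicates": replicates, "neg_controls": neg_controls})
    return ds
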