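"""Absolute quantification from droplet digital PCR (ddPCR) partition counts.

A ddPCR reaction partitions a sample into ``m`` nanolitre-scale droplets of
volume ``v`` μL; each droplet amplifies iff it received at least one target
molecule. Under Poisson partitioning of molecules, the probability a droplet
is positive is ``1 − exp(−λ v)`` where λ is the concentration in copies/μL,
so the maximum-likelihood estimate from ``m1`` positive droplets out of ``m``
is

    λ̂ = −ln(1 − m1/m) / v

with delta-method standard error ``sqrt(m1 / (m (m − m1))) / v``.

This module also implements the limit-of-blank (LOB) screen — the highest
concentration seen in any negative control (field, filtration, extraction or
no-template control); samples at or below it are zeroed — the
highest-concentration rule for samples re-run after extra inhibitor-removal
(IRK) rounds, and the internal-positive-control (IPC) inhibition score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ReplicateRun",
    "ConcentrationEstimate",
    "LobThreshold",
    "DEFAULT_DROPLET_VOLUME_UL",
    "DEFAULT_LOB",
    "estimate_concentration",
    "pool_and_select",
    "compute_lob",
    "apply_lob",
    "inhibition_ratio",
]

#: Nominal droplet volume of the QX200 platform, μL.
DEFAULT_DROPLET_VOLUME_UL = 0.00085

#: Default limit of blank, copies/μL (highest negative-control concentration).
DEFAULT_LOB = 0.258


@dataclass(frozen=True)
class ReplicateRun:
    """One ddPCR reaction well: the raw evidence unit."""

    sample_id: str
    replicate_id: int
    run_id: int  # inhibitor-removal (IRK) round this run followed
    m_total: int
    m_pos: int
    ipc_conc: float | None = None  # internal positive control, copies/μL

    def __post_init__(self) -> None:
        if self.m_total < 1:
            raise ValueError(f"m_total must be >= 1, got {self.m_total}")
        if not 0 <= self.m_pos <= self.m_total:
            raise ValueError(
                f"m_pos must lie in [0, m_total]; got {self.m_pos}/{self.m_total}"
            )


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Pooled concentration estimate with 95% confidence interval."""

    lambda_hat: float  # copies/μL
    se: float
    ci_low: float
    ci_high: float
    m_total: int
    m_pos: int


@dataclass(frozen=True)
class LobThreshold:
    """Limit of blank: zero out any sample at or below ``value``."""

    value: float
    source_control_id: str | None = None


class SaturationError(ValueError):
    """All droplets positive: the Poisson-partition estimator diverges."""


def estimate_concentration(
    m_total: int,
    m_pos: int,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    ci_method: Literal["log-wald", "wald"] = "log-wald",
) -> ConcentrationEstimate:
    """Estimate concentration (copies/μL) from droplet counts.

    Parameters
    ----------
    m_total, m_pos
        Total and positive droplet counts (pooled over replicates upstream).
    droplet_volume
        Droplet volume in μL.
    ci_method
        ``"log-wald"`` (default) builds the 95% Wald interval on log λ̂ and
        back-transforms, which respects positivity; ``"wald"`` is the plain
        symmetric interval truncated at 0.

    Raises
    ------
    SaturationError
        If every droplet is positive (``m_pos == m_total``).
    """
    if droplet_volume <= 0:
        raise ValueError("droplet_volume must be positive")
    if m_total < 1:
        raise ValueError("m_total must be >= 1")
    if m_pos > m_total:
        raise ValueError(f"m_pos {m_pos} exceeds m_total {m_total}")
    if m_pos == m_total:
        raise SaturationError(
            f"all {m_total} droplets positive: concentration unbounded"
        )
    if m_pos == 0:
        return ConcentrationEstimate(0.0, 0.0, 0.0, 0.0, m_total, 0)

    lam = -np.log1p(-m_pos / m_total) / droplet_volume
    se = np.sqrt(m_pos / (m_total * (m_total - m_pos))) / droplet_volume
    z = 1.959963984540054  # 97.5th normal percentile
    if ci_method == "log-wald":
        half = z * se / lam
        lo, hi = lam * np.exp(-half), lam * np.exp(half)
    elif ci_method == "wald":
        lo, hi = max(0.0, lam - z * se), lam + z * se
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return ConcentrationEstimate(float(lam), float(se), float(lo), float(hi), m_total, m_pos)


def _pool_runs(
    runs: Sequence[ReplicateRun], droplet_volume: float
) -> dict[int, ConcentrationEstimate]:
    by_run: dict[int, list[ReplicateRun]] = {}
    for r in runs:
        by_run.setdefault(r.run_id, []).append(r)
    return {
        run_id: estimate_concentration(
            sum(r.m_total for r in rs), sum(r.m_pos for r in rs), droplet_volume
        )
        for run_id, rs in by_run.items()
    }


def pool_and_select(
    runs: Iterable[ReplicateRun],
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
) -> dict[str, tuple[ConcentrationEstimate, int]]:
    """Pool droplets within each run and pick the best run per sample.

    Within one run all replicate wells are pooled (Σ m_total, Σ m_pos) before
    estimation. When a sample was re-run after additional IRK treatments, the
    run with the highest pooled concentration is kept — extra inhibitor
    removal can only lose target molecules, so the largest estimate is the
    least-biased one. Ties (typically all-zero runs) go to the latest run_id.

    Returns
    -------
    Mapping ``sample_id -> (estimate, selected_run_id)``.
    """
    runs = list(runs)
    if not runs:
        raise ValueError("empty run list")
    by_sample: dict[str, list[ReplicateRun]] = {}
    for r in runs:
        by_sample.setdefault(r.sample_id, []).append(r)
    out: dict[str, tuple[ConcentrationEstimate, int]] = {}
    for sid, rs in by_sample.items():
        pooled = _pool_runs(rs, droplet_volume)
        # max λ̂, ties broken by latest run_id
        best = max(pooled, key=lambda rid: (pooled[rid].lambda_hat, rid))
        out[sid] = (pooled[best], best)
    return out


def compute_lob(
    control_estimates: dict[str, ConcentrationEstimate]
) -> LobThreshold:
    """Limit of blank: maximum pooled concentration over all negative controls."""
    if not control_estimates:
        raise ValueError("at least one negative control is required")
    worst = max(control_estimates, key=lambda cid: control_estimates[cid].lambda_hat)
    value = control_estimates[worst].lambda_hat
    return LobThreshold(value=float(value), source_control_id=worst if value > 0 else None)


def apply_lob(
    sample_estimates: dict[str, ConcentrationEstimate],
    replicate_runs: Iterable[ReplicateRun],
    lob: LobThreshold,
    selected_runs: dict[str, int] | None = None,
    level: Literal["sample", "replicate"] = "sample",
) -> pd.DataFrame:
    """Zero out sub-LOB measurements and derive the detection matrix.

    Samples whose pooled concentration is at or below ``lob.value`` are set
    to 0 and all their replicate detections forced to 0. Retained samples
    keep λ̂, and replicate ``k`` is scored detected (1) iff its well had at
    least one positive droplet. With ``level="replicate"``, each replicate is
    additionally screened against the LOB on its own single-well estimate.

    Only wells of the selected run per sample (``selected_runs``, as returned
    by :func:`pool_and_select`) enter the detection matrix.

    Returns
    -------
    DataFrame indexed by sample_id with columns ``concentration``,
    ``lob_applied`` and ``det_1..det_K``; idempotent under re-application.
    """
    reps: dict[str, list[ReplicateRun]] = {}
    for r in replicate_runs:
        if selected_runs is not None and r.run_id != selected_runs.get(r.sample_id):
            continue
        reps.setdefault(r.sample_id, []).append(r)

    rows = {}
    n_rep = max((len(v) for v in reps.values()), default=0)
    for sid, est in sample_estimates.items():
        wells = sorted(reps.get(sid, []), key=lambda r: r.replicate_id)
        zeroed = est.lambda_hat <= lob.value
        conc = 0.0 if zeroed else est.lambda_hat
        det = []
        for w in wells:
            hit = 0 if zeroed else int(w.m_pos >= 1)
            if hit and level == "replicate":
                single = estimate_concentration(w.m_total, w.m_pos)
                hit = int(single.lambda_hat > lob.value)
            det.append(hit)
        det += [0] * (n_rep - len(det))
        rows[sid] = [conc, bool(zeroed)] + det
    cols = ["concentration", "lob_applied"] + [f"det_{k+1}" for k in range(n_rep)]
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "sample_id"
    return df


def inhibition_ratio(ipc_sample: float, ipc_standard: float) -> float:
    """Fraction of the internal positive control lost to PCR inhibition.

    The IPC is spiked into every well at a known concentration; comparing its
    measured concentration in a sample with that of the uninhibited standards
    gives ``1 − ipc_sample/ipc_standard``, clamped to [0, 1]. Reported as QC
    metadata only — target detections in inhibited samples still count.
    """
    if ipc_standard <= 0:
        raise ValueError("ipc_standard must be positive")
    if ipc_sample < 0:
        raise ValueError("ipc_sample must be non-negative")
    return float(min(1.0, max(0.0, 1.0 - ipc_sample / ipc_standard)))
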