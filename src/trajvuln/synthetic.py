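"""Synthetic cohorts with the statistical structure the analysis assumes.

Emulated features of the study design: two latent pain-trajectory groups in
roughly a 44/56 split, group mean pain at the four scheduled visits matching
the published curves (transient: 0, 1.46, 0.27, 0; persistent: 0.86, 2.13,
2.23, 1.68), 0-10 rating-scale granularity (clip to bounds, round to the
nearest half point), monotone study dropout mimicking 89 -> 85 -> 73
completers, and a correlated baseline endpoint battery whose direction-
aligned composite separates the groups with a standardized mean difference
of about 0.8.

Endpoint calibration: endpoints are exchangeable-correlation Gaussians with
within-group SD 1 and a between-group shift ``delta`` applied in each
endpoint's vulnerable direction.  The composite (mean of m direction-aligned
z-scores) then has within-group SD proportional to sqrt((1+(m-1)*rho)/m) and
group mean difference proportional to ``delta`` with the same pooled-SD
scaling cancelling, so

    delta = d_target * sqrt((1 + (m-1)*rho) / m)

yields composite Cohen's d of ``d_target`` exactly in the large-n limit;
this is verified by simulation in the test suite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .cohort_io import DEFAULT_TIMEPOINTS, EndpointMatrix, LongCohort, Timepoint

__all__ = ["GeneratorConfig", "generate", "truth_table", "GROUP_LABELS"]

GROUP_LABELS = ("TP", "PP")  # transient / persistent pain phenotypes

# Study-scale defaults: 89 baseline completers, retention 85/89 at M6 and
# 73/89 at M12 (day-17 phone ratings treated as fully observed).
_DEFAULT_RETENTION = (1.0, 1.0, 85 / 89, 73 / 89)
_DEFAULT_CURVES = ((0.0, 1.46, 0.27, 0.0), (0.86, 2.13, 2.23, 1.68))


class GeneratorConfig(BaseModel):
    """Parameters of the synthetic cohort; defaults mirror the study conditions."""

    n_subjects: int = Field(default=89, ge=0)
    group_probs: tuple[float, ...] = (0.44, 0.56)
    group_mean_curves: tuple[tuple[float, ...], ...] = _DEFAULT_CURVES
    residual_sd: float = Field(default=1.0, gt=0)
    round_to: float = Field(default=0.5, ge=0)  # NRS granularity; 0 disables rounding
    n_endpoints: int = Field(default=20, ge=1)
    endpoint_group_shift: float | None = None  # None -> calibrate to composite_d_target
    composite_d_target: float = Field(default=0.8, gt=0)
    endpoint_correlation: float = Field(default=0.3, ge=0, lt=1)
    dropout_probs: tuple[float, ...] = _DEFAULT_RETENTION  # per-visit retention
    item_missing_rate: float = Field(default=0.05, ge=0, lt=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        probs = np.asarray(self.group_probs, dtype=float)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("group_probs must be a probability simplex")
        if len(self.group_mean_curves) != len(self.group_probs):
            raise ValueError("one mean curve per group required")
        T = len(DEFAULT_TIMEPOINTS)
        if any(len(c) != T for c in self.group_mean_curves):
            raise ValueError(f"each mean curve needs {T} values (one per visit)")
        ret = np.asarray(self.dropout_probs, dtype=float)
        if len(ret) != T:
            raise ValueError(f"dropout_probs needs {T} retention values")
        if np.any(ret < 0) or np.any(ret > 1) or np.any(np.diff(ret) > 1e-12):
            raise ValueError(
                "dropout_probs must be non-increasing retention probabilities in [0,1]"
            )
        return self

    @property
    def calibrated_shift(self) -> float:
        """Per-endpoint group shift producing the target composite separation."""
        if self.endpoint_group_shift is not None:
            return self.endpoint_group_shift
        m, rho = self.n_endpoints, self.endpoint_correlation
        return self.composite_d_target * float(np.sqrt((1 + (m - 1) * rho) / m))


def generate(
    config: GeneratorConfig,
    timepoints: Sequence[Timepoint] = DEFAULT_TIMEPOINTS,
) -> tuple[LongCohort, EndpointMatrix, pd.DataFrame]:
    """Draw a cohort, baseline battery and latent-group truth table.

    Same config (including seed) -> bit-identical output.  The truth frame
    (subject, group index, group label) is returned separately so pipeline
    runs cannot accidentally consume it.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    K = len(config.group_probs)
    T = len(timepoints)
    labels = [tp.label for tp in timepoints]
    subjects = [f"S{i + 1:04d}" for i in range(n)]

    groups = rng.choice(K, size=n, p=np.asarray(config.group_probs, dtype=float))

    # pain: group mean + Gaussian noise, clipped to scale, rounded to NRS grid
    curves = np.asarray(config.group_mean_curves, dtype=float)
    latent = curves[groups] + rng.normal(0.0, config.residual_sd, size=(n, T))
    pain = np.clip(latent, 0.0, 10.0)
    if config.round_to > 0:
        pain = np.round(pain / config.round_to) * config.round_to

    # monotone dropout: one uniform per subject against non-increasing retention
    u = rng.random(n)
    retained = u[:, None] < np.asarray(config.dropout_probs)[None, :]
    pain = np.where(retained, pain, np.nan)

    rows = []
    for i, sid in enumerate(subjects):
        for t, lab in enumerate(labels):
            if retained[i, t]:
                rows.append((sid, lab, pain[i, t]))
    cohort = LongCohort(
        pd.DataFrame(rows, columns=["subject", "timepoint", "pain"]),
        timepoints=tuple(timepoints),
    )

    # endpoint battery: exchangeable correlation rho on the direction-aligned
    # (vulnerability) scale, group shift for the persistent group (higher
    # latent index); raw values are the aligned ones times the direction, so
    # opposite-direction endpoints correlate negatively in raw units
    m = config.n_endpoints
    rho = config.endpoint_correlation
    common = rng.normal(size=(n, 1))
    indep = rng.normal(size=(n, m))
    aligned = np.sqrt(rho) * common + np.sqrt(1 - rho) * indep
    directions = np.where(np.arange(m) % 2 == 0, 1, -1)
    delta = config.calibrated_shift
    vulnerable = (groups == K - 1).astype(float)[:, None]
    values = (aligned + vulnerable * delta) * directions[None, :]
    if config.item_missing_rate > 0:
        mask = rng.random((n, m)) < config.item_missing_rate
        values = np.where(mask, np.nan, values)
    endpoint_ids = [f"E{e + 1:02d}" for e in range(m)]
    endpoints = EndpointMatrix(
        pd.DataFrame(values, index=subjects, columns=endpoint_ids),
        directions={e: int(d) for e, d in zip(endpoint_ids, directions)},
    )

    truth = pd.DataFrame(
        {
            "subject": subjects,
            "group": groups,
            "label": [GROUP_LABELS[g] if K == 2 else f"G{g}" for g in groups],
        }
    )
    return cohort, endpoints, truth


def truth_table(truth: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions per latent group from a truth frame."""
    if truth.empty:
        return pd.DataFrame(columns=["group", "count", "proportion"])
    counts = truth.groupby("group").size().rename("count").reset_index()
    counts["proportion"] = counts["count"] / counts["count"].sum()
    return counts
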