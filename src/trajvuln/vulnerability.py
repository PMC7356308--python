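"""Composite psychosocial-vulnerability score (average-z composite endpoint).

Each baseline endpoint is standardized against the pooled cohort (both
trajectory groups together): ``z_ie = direction_e * (x_ie - mean_e) / sd_e``
with the sample (n-1) SD.  The direction flag aligns every endpoint so that
a higher z marks a more vulnerable subject; the per-subject mean of the
available z-scores is the composite.  A subject's composite is reported
missing when fewer than a configurable fraction of endpoints (default half)
are available.

The classical average-z composite convention points the other way (worse
outcomes get smaller scores); here the sign follows the vulnerability-score
usage (higher = more vulnerable), and ``standardize(..., flip_sign=True)``
restores the opposite convention.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import EndpointMatrix

__all__ = ["ZMatrix", "CompositeScore", "standardize", "composite", "apply_frozen"]


class ZeroVarianceError(ValueError):
    """An endpoint column is constant and cannot be standardized."""


@dataclass
class ZMatrix:
    """Direction-aligned standardized endpoint scores plus the parameters used."""

    z: pd.DataFrame  # subject x endpoint
    mean: pd.Series  # pooled mean per endpoint
    sd: pd.Series  # pooled sample SD per endpoint
    directions: dict[str, int]

    def params_to_json(self, path: str | Path) -> None:
        """Freeze (mean, sd, direction) so the score can be applied to new subjects."""
        payload = {
            e: {"mean": float(self.mean[e]), "sd": float(self.sd[e]),
                "direction": self.directions[e]}
            for e in self.z.columns
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


@dataclass
class CompositeScore:
    """Per-subject vulnerability score and the number of endpoints behind it."""

    scores: pd.Series  # NaN where below the completeness threshold
    n_endpoints_used: pd.Series
    completeness_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"vulnerability": self.scores, "n_endpoints_used": self.n_endpoints_used}
        )


def standardize(matrix: EndpointMatrix, flip_sign: bool = False) -> ZMatrix:
    """Pooled z-standardization with direction alignment.

    Every endpoint must show at least two distinct non-missing values;
    a constant column raises ``ZeroVarianceError`` naming it.
    """
    x = matrix.values
    bad = [e for e in x.columns if x[e].dropna().nunique() < 2]
    if bad:
        raise ZeroVarianceError(f"constant endpoint column(s): {bad}")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    dirs = pd.Series(matrix.directions)
    sign = -1.0 if flip_sign else 1.0
    z = sign * dirs * (x - mean) / sd
    return ZMatrix(z=z, mean=mean, sd=sd, directions=dict(matrix.directions))


def apply_frozen(matrix: EndpointMatrix, params_path: str | Path) -> ZMatrix:
    """Standardize new subjects with previously exported (mean, sd, direction)."""
    payload = json.loads(Path(params_path).read_text(encoding="utf-8"))
    x = matrix.values
    missing = [e for e in x.columns if e not in payload]
    if missing:
        raise KeyError(f"endpoint(s) absent from frozen parameters: {missing}")
    mean = pd.Series({e: payload[e]["mean"] for e in x.columns})
    sd = pd.Series({e: payload[e]["sd"] for e in x.columns})
    dirs = pd.Series({e: payload[e]["direction"] for e in x.columns})
    z = dirs * (x - mean) / sd
    return ZMatrix(z=z, mean=mean, sd=sd, directions={e: int(dirs[e]) for e in x.columns})


def composite(z: ZMatrix, completeness_threshold: float = 0.5) -> CompositeScore:
    """Per-subject mean of available z-scores, missing below the completeness bar."""
    if not (0 <= completeness_threshold <= 1):
        raise ValueError("completeness_threshold must lie in [0, 1]")
    avail = z.z.notna().sum(axis=1)
    frac = avail / z.z.shape[1]
    scores = z.z.mean(axis=1, skipna=True)
    scores[frac < completeness_threshold] = np.nan
    return CompositeScore(
        scores=scores.rename("vulnerability"),
        n_endpoints_used=avail.rename("n_endpoints_used"),
        completeness_threshold=completeness_threshold,
    )
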