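"""Functional Stratification Index: cohort-normalized composite ranking.

The FSI condenses five kinetic parameters — relative confluence divergence,
log-phase slope, direction-signed divergence duration, AUC and intra-assay
CV — into one score per cell line.  Each parameter is z-scored across the
cohort (sample SD, n-1), weighted, and scaled:

    FSI_i = scale * ( w1 z(Δrel) + w2 z(slope) + w3 z(±duration)
                      + w4 z(AUC) - w5 z(CV) )

The CV term enters negatively: noisy responses are penalized.  Duration is
signed by the direction of the divergence so inhibitory lines do not earn
positive duration credit.  Because every z-score column sums to zero, the
cohort's FSI values sum to zero by construction; the score is a relative
ranking, not an absolute magnitude.  Stimulated lines come out positive,
inhibited lines negative, inert lines near zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticProfile

__all__ = ["FsiConfig", "FsiResult", "feature_vector", "fsi_scores", "rank_lines"]

FSI_PARAMETERS = ("delta_relative", "logphase_slope", "signed_duration",
                  "auc", "intra_cv")

DEFAULT_WEIGHTS = {
    "delta_relative": 0.30,
    "logphase_slope": 0.20,
    "signed_duration": 0.15,
    "auc": 0.25,
    "intra_cv": 0.10,
}


@dataclass
class FsiConfig:
    """Weights (non-negative, summing to 1) and display scale."""

    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    scale: float = 15.0

    def __post_init__(self) -> None:
        if set(self.weights) != set(FSI_PARAMETERS):
            raise ValueError(f"weights must cover exactly {FSI_PARAMETERS}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")
        total = sum(self.weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"weights must sum to 1, got {total}")


@dataclass
class FsiResult:
    cell_line: str
    z_scores: dict[str, float]
    weights: dict[str, float]
    scale: float
    fsi: float
    delta_relative: float


def feature_vector(profile: KineticProfile) -> dict[str, float]:
    """The five FSI inputs; duration is signed by the divergence direction
    and zero when no divergence was sustained."""
    sign = 0.0
    if profile.divergence_duration > 0:
        sign = math.copysign(1.0, profile.delta_relative)
    return {
        "delta_relative": profile.delta_relative,
        "logphase_slope": profile.logphase_slope,
        "signed_duration": sign * profile.divergence_duration,
        "auc": profile.auc,
        "intra_cv": profile.intra_cv,
    }


def _zscore_columns(matrix: np.ndarray) -> np.ndarray:
    z = np.zeros_like(matrix)
    for j in range(matrix.shape[1]):
        col = matrix[:, j]
        sd = col.std(ddof=1)
        if sd == 0:
            warnings.warn(
                f"FSI parameter {FSI_PARAMETERS[j]} has zero variance across "
                "the cohort; its z-scores are all zero", UserWarning,
                stacklevel=3,
            )
            continue
        z[:, j] = (col - col.mean()) / sd
    return z


def fsi_scores(cohort: list[KineticProfile],
               cfg: FsiConfig | None = None) -> list[FsiResult]:
    """Compute the FSI for every profile in a cohort (>= 2 lines)."""
    cfg = cfg or FsiConfig()
    if len(cohort) < 2:
        raise ValueError("FSI needs a cohort of >= 2 profiles")
    feats = [feature_vector(p) for p in cohort]
    matrix = np.array([[f[k] for k in FSI_PARAMETERS] for f in feats])
    z = _zscore_columns(matrix)
    signs = {k: (-1.0 if k == "intra_cv" else 1.0) for k in FSI_PARAMETERS}
    out = []
    for i, p in enumerate(cohort):
        zrow = dict(zip(FSI_PARAMETERS, z[i]))
        composite = sum(signs[k] * cfg.weights[k] * zrow[k] for k in FSI_PARAMETERS)
        out.append(FsiResult(
            cell_line=p.cell_line,
            z_scores={k: float(v) for k, v in zrow.items()},
            weights=dict(cfg.weights),
            scale=cfg.scale,
            fsi=float(cfg.scale * composite),
            delta_relative=p.delta_relative,
        ))
    return out


def rank_lines(results: list[FsiResult]) -> list[FsiResult]:
    """Descending by FSI; ties broken by delta_relative, then line name."""
    return sorted(results,
                  key=lambda r: (-r.fsi, -r.delta_relative, r.cell_line))
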