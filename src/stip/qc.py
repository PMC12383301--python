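"""Intra-assay and interbatch reproducibility QC and the compatibility matrix.

Intra-assay: the CV of final confluence across technical replicates must
stay within 8% for active (stimulatory/inhibitory) lines and 5% for neutral
ones; indeterminate calls are held to the active bound.

Interbatch (>= 2 independent formulation batches per line): the across-batch
CV of final confluence must stay below 10%, the CV of the divergence onset
below 8%, the largest pairwise difference of the treated-control Δ (final
confluence, percentage points) below 10 points, and the assigned functional
category must be concordant.  Concordance is judged over the definite
Type I/II/III calls; batches where the classifier abstains (indeterminate)
are counted and reported but, by default, do not break concordance — an
abstention is not a category inversion.  Set ``strict_concordance`` to make
any disagreement, including abstentions, fail.

The compatibility matrix tabulates the category per line x formulation and
flags rows that contain both stimulatory and inhibitory calls (inversions).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import Category, StipCall
from .kinetics import KineticProfile

__all__ = [
    "QcConfig",
    "IntraAssayVerdict",
    "BatchVerdict",
    "QcReport",
    "CompatibilityMatrix",
    "intra_assay_qc",
    "interbatch_qc_line",
    "interbatch_qc",
    "build_compatibility_matrix",
]

_DEFINITE = (Category.STIMULATORY, Category.INHIBITORY, Category.NEUTRAL)


@dataclass
class QcConfig:
    intra_cv_active: float = 8.0
    intra_cv_neutral: float = 5.0
    interbatch_final_cv: float = 10.0
    interbatch_onset_cv: float = 8.0
    interbatch_delta_max: float = 10.0   # points, on the treated-control Δ
    strict_concordance: bool = False


@dataclass
class IntraAssayVerdict:
    cell_line: str
    formulation_id: str | None
    production_batch: str
    category: str
    intra_cv: float
    bound: float
    passed: bool


@dataclass
class BatchVerdict:
    """Interbatch reproducibility verdict for one line x formulation."""

    cell_line: str
    formulation_id: str | None
    n_batches: int
    final_cv: float | None
    onset_cv: float | None
    max_delta_diff: float | None
    categories: list[str]
    n_indeterminate: int
    category_concordant: bool
    insufficient: bool
    passed: bool


@dataclass
class QcReport:
    intra_assay: list[IntraAssayVerdict] = field(default_factory=list)
    interbatch: list[BatchVerdict] = field(default_factory=list)

    @property
    def overall_pass(self) -> bool:
        return (all(v.passed for v in self.intra_assay)
                and all(v.passed for v in self.interbatch))


def _cv(values: Sequence[float]) -> float | None:
    arr = np.asarray(values, dtype=float)
    if arr.size < 2 or arr.mean() == 0:
        return None
    return float(100.0 * arr.std(ddof=1) / abs(arr.mean()))


def intra_assay_qc(profiles: Sequence[KineticProfile],
                   calls: Sequence[StipCall],
                   cfg: QcConfig | None = None) -> list[IntraAssayVerdict]:
    """Per-group intra-assay CV verdicts, bound chosen by category."""
    cfg = cfg or QcConfig()
    out = []
    for profile, call in zip(profiles, calls, strict=True):
        bound = (cfg.intra_cv_neutral if call.category is Category.NEUTRAL
                 else cfg.intra_cv_active)
        out.append(IntraAssayVerdict(
            cell_line=profile.cell_line,
            formulation_id=profile.formulation_id,
            production_batch=profile.production_batch,
            category=call.category.value,
            intra_cv=profile.intra_cv,
            bound=bound,
            passed=profile.intra_cv <= bound,
        ))
    return out


def interbatch_qc_line(profiles: Sequence[KineticProfile],
                       calls: Sequence[StipCall],
                       cfg: QcConfig | None = None) -> BatchVerdict:
    """Interbatch verdict for one line x formulation across batches."""
    cfg = cfg or QcConfig()
    if len(profiles) != len(calls) or not profiles:
        raise ValueError("need matched, non-empty profiles and calls")
    line = profiles[0].cell_line
    form = profiles[0].formulation_id
    categories = [c.category.value for c in calls]
    n_ind = sum(1 for c in calls
                if c.category not in _DEFINITE)
    definite = [c.category for c in calls if c.category in _DEFINITE]
    if cfg.strict_concordance:
        concordant = len(set(categories)) <= 1
    else:
        concordant = len(set(definite)) <= 1
    if len(profiles) < 2:
        # a single batch violates no bound; concordance is trivially true,
        # but the verdict is flagged insufficient
        return BatchVerdict(line, form, len(profiles), None, None, None,
                            categories, n_ind, concordant, True, concordant)
    finals = [p.final_confluence_mean for p in profiles]
    onsets = [p.onset_hours for p in profiles if p.onset_hours is not None]
    deltas = [p.delta_points for p in profiles]
    final_cv = _cv(finals)
    onset_cv = _cv(onsets) if len(onsets) >= 2 else None
    max_dd = float(max(abs(a - b) for i, a in enumerate(deltas)
                       for b in deltas[i + 1:]))
    passed = (concordant
              and (final_cv is None or final_cv <= cfg.interbatch_final_cv)
              and (onset_cv is None or onset_cv <= cfg.interbatch_onset_cv)
              and max_dd <= cfg.interbatch_delta_max)
    return BatchVerdict(line, form, len(profiles), final_cv, onset_cv,
                        max_dd, categories, n_ind, concordant, False, passed)


def interbatch_qc(groups: Mapping[tuple[str, str | None],
                                  tuple[Sequence[KineticProfile], Sequence[StipCall]]],
                  cfg: QcConfig | None = None) -> list[BatchVerdict]:
    """Interbatch verdicts for every (line, formulation) group.

    ``groups`` maps (cell_line, formulation_id) to the per-batch profiles
    and calls of that combination.  Verdicts are deterministic and invariant
    to batch order.
    """
    cfg = cfg or QcConfig()
    return [interbatch_qc_line(p, c, cfg) for (_, _), (p, c) in sorted(
        groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1])))]


@dataclass
class CompatibilityMatrix:
    """Category per cell line (rows) x formulation (columns)."""

    table: pd.DataFrame
    inversion_free: bool
    row_inversion_free: dict[str, bool]

    SYMBOLS = {"stimulatory": "✓", "inhibitory": "✕", "neutral": "—"}

    def rendered(self) -> pd.DataFrame:
        """Human-readable ✓/✕/— rendering (other categories abbreviated)."""
        return self.table.map(
            lambda c: self.SYMBOLS.get(c, "·" if c == "" else c[:5]))


def build_compatibility_matrix(calls: Sequence[StipCall]) -> CompatibilityMatrix:
    """Tabulate calls into a line x formulation matrix.

    Duplicate (line, formulation) calls with conflicting categories raise;
    missing combinations are left blank.  A row is inversion-free when it
    does not contain both a stimulatory and an inhibitory cell.
    """
    seen: dict[tuple[str, str | None], str] = {}
    for c in calls:
        key = (c.cell_line, c.formulation_id)
        cat = c.category.value
        if key in seen and seen[key] != cat:
            raise ValueError(
                f"conflicting duplicate calls for {key}: {seen[key]} vs {cat}")
        seen[key] = cat
    lines = sorted({k[0] for k in seen})
    forms = sorted({str(k[1]) for k in seen})
    table = pd.DataFrame("", index=lines, columns=forms, dtype=object)
    for (line, form), cat in seen.items():
        table.loc[line, str(form)] = cat
    row_free = {}
    for line in lines:
        cats = set(table.loc[line]) - {""}
        row_free[line] = not ({"stimulatory", "inhibitory"} <= cats)
    return CompatibilityMatrix(
        table=table,
        inversion_free=all(row_free.values()) if row_free else True,
        row_inversion_free=row_free,
    )
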