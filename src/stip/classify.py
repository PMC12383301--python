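"""STIP phenotype calls: the decision tree over kinetics, death and secretome.

A response is classified from its kinetic profile into stimulatory (Type I),
inhibitory (Type II) or neutral (Type III).  A cumulative cell-death signal
above the cytotoxicity threshold pre-empts any kinetic call
(``cytotoxic_confounded``): the framework only stratifies non-lethal,
structural responses.  Cytokine congruence (the IFN-γ/IL-10 ratio for active
calls, absence of analyte shifts for neutral ones) is recorded as supporting
evidence but never overrides the kinetic category — the secretome confirms
trajectories, it does not define them.

Responses whose relative divergence falls between the neutral band (<10%)
and the active threshold (>=20%), or whose divergence is too short or not
significant, are refused a type and reported as ``indeterminate`` rather
than forced into the nearest class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

from .kinetics import KineticProfile, PointwiseStats
from .plate_io import DeathTrace, CytokineSample
from . import secretome as _secretome

__all__ = [
    "Category",
    "Congruence",
    "ClassifierConfig",
    "Evidence",
    "StipCall",
    "kinetic_category",
    "death_gate",
    "secretome_congruence",
    "classify_stip",
]


class Category(str, Enum):
    STIMULATORY = "stimulatory"      # Type I
    INHIBITORY = "inhibitory"        # Type II
    NEUTRAL = "neutral"              # Type III
    INDETERMINATE = "indeterminate"
    CYTOTOXIC_CONFOUNDED = "cytotoxic_confounded"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Congruence(str, Enum):
    CONGRUENT = "congruent"
    INCONGRUENT = "incongruent"
    NOT_ASSESSED = "not_assessed"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass
class ClassifierConfig:
    """Decision thresholds of the phenotype classifier.

    class_rel : |Δ/control| defining an active (Type I/II) response (0.20).
    neutral_rel : |Δ/control| band of a neutral response (0.10).
    min_duration : hours of sustained divergence required for an active call.
    min_sig_points : number of p < alpha timepoints required.
    alpha : per-timepoint significance level.
    death_positive : percent cumulative death flagged as a positive signal.
    death_cytotoxic : percent cumulative death that confounds the call.
    ratio_high : IFN-γ/IL-10 above which an inhibitory call is congruent.
    ratio_low : IFN-γ/IL-10 below which a stimulatory call is congruent.
    neutral_cytokine_p : adjusted p below which an analyte is considered
        shifted when checking neutral congruence.
    """

    class_rel: float = 0.20
    neutral_rel: float = 0.10
    min_duration: float = 12.0
    min_sig_points: int = 5
    alpha: float = 0.05
    death_positive: float = 2.5
    death_cytotoxic: float = 5.0
    ratio_high: float = 6.0
    ratio_low: float = 3.0
    neutral_cytokine_p: float = 0.1

    def __post_init__(self) -> None:
        if not 0 < self.neutral_rel < self.class_rel:
            raise ValueError("need 0 < neutral_rel < class_rel")
        if not 0 < self.death_positive < self.death_cytotoxic:
            raise ValueError("need 0 < death_positive < death_cytotoxic")
        if not self.ratio_low < self.ratio_high:
            raise ValueError("need ratio_low < ratio_high")


@dataclass
class Evidence:
    """Audit trail of one call."""

    magnitude_pass: bool = False
    duration_pass: bool = False
    significance_pass: bool = False
    death_gate: str = "not_assessed"     # pass | cytotoxic | not_assessed
    death_positive: bool = False
    death_final: float | None = None
    congruence: str = Congruence.NOT_ASSESSED.value
    ifng_il10_ratio: float | None = None


@dataclass
class StipCall:
    """Final phenotype call for one cell line x formulation."""

    cell_line: str
    formulation_id: str | None
    category: Category
    evidence: Evidence = field(default_factory=Evidence)

    @property
    def stip_type(self) -> str | None:
        return {
            Category.STIMULATORY: "Type I",
            Category.INHIBITORY: "Type II",
            Category.NEUTRAL: "Type III",
        }.get(self.category)


def kinetic_category(profile: KineticProfile,
                     cfg: ClassifierConfig | None = None) -> Category:
    """Three-way kinetic classification with an explicit indeterminate class.

    Stimulatory: Δ/control >= +class_rel, sustained >= min_duration hours,
    significant at >= min_sig_points timepoints.  Inhibitory is the mirror
    image.  Neutral: |Δ/control| < neutral_rel with fewer than
    min_sig_points significant timepoints.  Everything else is
    indeterminate.  A tie at exactly +/-class_rel counts as active.
    """
    cfg = cfg or ClassifierConfig()
    dr = profile.delta_relative
    sustained = profile.divergence_duration >= cfg.min_duration
    significant = profile.n_sig_points >= cfg.min_sig_points
    if dr >= cfg.class_rel and sustained and significant:
        return Category.STIMULATORY
    if dr <= -cfg.class_rel and sustained and significant:
        return Category.INHIBITORY
    if abs(dr) < cfg.neutral_rel and not significant:
        return Category.NEUTRAL
    return Category.INDETERMINATE


def death_gate(death: Sequence[DeathTrace],
               cfg: ClassifierConfig | None = None) -> tuple[str, bool, float]:
    """Cytotoxicity gate on the treated group's cumulative death traces.

    Returns (status, positive_flag, final_mean): status is ``"cytotoxic"``
    iff the group-mean cumulative death at the final time exceeds
    ``death_cytotoxic``, else ``"pass"``; positive_flag reports whether the
    group mean exceeded ``death_positive`` at any time.
    """
    cfg = cfg or ClassifierConfig()
    if not death:
        return "not_assessed", False, float("nan")
    vals = np.vstack([d.values for d in death])
    mean_curve = vals.mean(axis=0)
    final = float(mean_curve[-1])
    status = "cytotoxic" if final > cfg.death_cytotoxic else "pass"
    positive = bool(np.any(mean_curve > cfg.death_positive))
    return status, positive, final


def secretome_congruence(category: Category,
                         treated: Sequence[CytokineSample],
                         control: Sequence[CytokineSample],
                         cfg: ClassifierConfig | None = None,
                         ) -> tuple[Congruence, float | None]:
    """Check whether the cytokine panel supports the kinetic category.

    Stimulatory calls are congruent when IFN-γ/IL-10 < ``ratio_low``;
    inhibitory when the ratio > ``ratio_high``; neutral when no analyte
    differs from control (Welch test, Bonferroni over the four analytes,
    adjusted p >= ``neutral_cytokine_p``).  Advisory only.
    """
    cfg = cfg or ClassifierConfig()
    if not treated:
        return Congruence.NOT_ASSESSED, None
    summary = _secretome.summarize_panel(treated, label=str(category))
    ratio = summary.ratio
    if category in (Category.STIMULATORY, Category.INHIBITORY):
        if ratio is None:
            return Congruence.NOT_ASSESSED, None
        if category is Category.STIMULATORY:
            ok = ratio < cfg.ratio_low
        else:
            ok = ratio > cfg.ratio_high
        return (Congruence.CONGRUENT if ok else Congruence.INCONGRUENT), ratio
    if category is Category.NEUTRAL:
        if not control:
            return Congruence.NOT_ASSESSED, ratio
        shifted = _secretome.analyte_shifts(treated, control,
                                            alpha=cfg.neutral_cytokine_p)
        ok = not any(shifted.values())
        return (Congruence.CONGRUENT if ok else Congruence.INCONGRUENT), ratio
    return Congruence.NOT_ASSESSED, ratio


def classify_stip(profile: KineticProfile,
                  pstats: PointwiseStats | None = None,
                  death: Sequence[DeathTrace] = (),
                  treated_panel: Sequence[CytokineSample] = (),
                  control_panel: Sequence[CytokineSample] = (),
                  cfg: ClassifierConfig | None = None) -> StipCall:
    """Full decision tree: death gate first, then kinetics, then congruence."""
    cfg = cfg or ClassifierConfig()
    ev = Evidence(
        magnitude_pass=abs(profile.delta_relative) >= cfg.class_rel,
        duration_pass=profile.divergence_duration >= cfg.min_duration,
        significance_pass=profile.n_sig_points >= cfg.min_sig_points,
    )
    status, positive, final = death_gate(death, cfg) if death else ("not_assessed", False, None)
    ev.death_gate = status
    ev.death_positive = positive
    ev.death_final = final
    if status == "cytotoxic":
        return StipCall(profile.cell_line, profile.formulation_id,
                        Category.CYTOTOXIC_CONFOUNDED, ev)
    category = kinetic_category(profile, cfg)
    congruence, ratio = secretome_congruence(category, treated_panel,
                                             control_panel, cfg)
    ev.congruence = congruence.value
    ev.ifng_il10_ratio = ratio
    return StipCall(profile.cell_line, profile.formulation_id, category, ev)
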