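"""Cytokine panel summaries, the IFN-γ/IL-10 composite marker and group tests.

Panels carry IL-6, IL-10, IFN-γ and TNF-α concentrations in pg/mL.
Samples below the assay's lower limit of detection are excluded from means.
The IFN-γ/IL-10 ratio — high under suppressive/overactivated profiles, low
under permissive/trophic ones — is the ratio of group means, which is how
the printed group ratios are reproduced to two decimals; its SD is a
first-order (delta-method) propagation and is informational only.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sstats

from .plate_io import ANALYTES, CytokineSample

__all__ = [
    "AnalyteSummary",
    "PanelSummary",
    "summarize_panel",
    "ifng_il10_ratio",
    "analyte_shifts",
    "group_compare",
]


@dataclass(frozen=True)
class AnalyteSummary:
    mean: float
    sd: float | None
    n: int


@dataclass(frozen=True)
class PanelSummary:
    """Per-analyte mean ± sample SD for one group, plus the composite ratio."""

    label: str
    analytes: Mapping[str, AnalyteSummary]
    ratio: float | None
    ratio_sd: float | None


def _above_llod(samples: Sequence[CytokineSample], analyte: str) -> np.ndarray:
    return np.array([s.concentration for s in samples
                     if s.analyte == analyte and not s.below_llod], dtype=float)


def summarize_panel(samples: Sequence[CytokineSample], label: str = "") -> PanelSummary:
    """Mean ± sample SD per analyte, excluding below-LLOD samples.

    Analytes with no above-LLOD sample are reported absent.  The ratio is
    present only when the IL-10 mean is positive.
    """
    analytes: dict[str, AnalyteSummary] = {}
    for a in ANALYTES:
        vals = _above_llod(samples, a)
        if vals.size == 0:
            continue
        sd = float(vals.std(ddof=1)) if vals.size >= 2 else None
        analytes[a] = AnalyteSummary(mean=float(vals.mean()), sd=sd, n=int(vals.size))
    ratio = ratio_sd = None
    ifng, il10 = analytes.get("IFN-γ"), analytes.get("IL-10")
    if ifng is not None and il10 is not None and il10.mean > 0:
        ratio = ifng.mean / il10.mean
        if ifng.sd is not None and il10.sd is not None:
            ratio_sd = ratio * np.hypot(ifng.sd / ifng.mean, il10.sd / il10.mean)
    return PanelSummary(label=label, analytes=analytes, ratio=ratio,
                        ratio_sd=ratio_sd)


def ifng_il10_ratio(ifng_mean: float, il10_mean: float) -> float:
    """IFN-γ/IL-10 ratio of group means (reported to 2 decimals in outputs)."""
    if il10_mean <= 0:
        raise ValueError(f"IL-10 mean must be > 0 to form the ratio, got {il10_mean}")
    return ifng_mean / il10_mean


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or b.size < 2:
        return float("nan")
    if a.std() == 0 and b.std() == 0:
        return 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
    return float(sstats.ttest_ind(a, b, equal_var=False).pvalue)


def analyte_shifts(treated: Sequence[CytokineSample],
                   control: Sequence[CytokineSample],
                   alpha: float = 0.1) -> dict[str, bool]:
    """Per-analyte Welch test treated vs control, Bonferroni over the panel.

    Returns ``{analyte: True if the adjusted p falls below alpha}``.
    """
    out: dict[str, bool] = {}
    for a in ANALYTES:
        x, y = _above_llod(treated, a), _above_llod(control, a)
        if x.size < 2 or y.size < 2:
            continue
        p_adj = min(1.0, _welch_p(x, y) * len(ANALYTES))
        out[a] = p_adj < alpha
    return out


def group_compare(groups: Mapping[str, Mapping[str, Sequence[float]]],
                  ) -> dict[str, dict]:
    """One-way ANOVA per analyte across groups, then pairwise Welch t-tests
    with a Bonferroni correction over (pairs x analytes).

    ``groups`` maps group label -> analyte -> concentration values.
    Identical zero-variance groups yield p = 1 by convention.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups to compare")
    labels = sorted(groups)
    analytes = [a for a in ANALYTES if all(a in groups[g] for g in labels)]
    n_pairs = len(list(combinations(labels, 2)))
    bonf = max(1, n_pairs * len(analytes))
    results: dict[str, dict] = {}
    for a in analytes:
        arrays = [np.asarray(groups[g][a], dtype=float) for g in labels]
        if any(x.size < 2 for x in arrays):
            raise ValueError(f"analyte {a}: every group needs >= 2 samples")
        if all(x.std() == 0 for x in arrays) and len({x.mean() for x in arrays}) == 1:
            anova_p = 1.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                anova_p = float(sstats.f_oneway(*arrays).pvalue)
            if np.isnan(anova_p):
                anova_p = 1.0
        pairwise = {}
        for (i, gi), (j, gj) in combinations(enumerate(labels), 2):
            p = _welch_p(arrays[i], arrays[j])
            pairwise[f"{gi} vs {gj}"] = min(1.0, p * bonf)
        results[a] = {"anova_p": anova_p, "pairwise_p_bonferroni": pairwise}
    return results
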