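"""Reference eight-line validation cohort.

The reported group-level kinetic metrics and cytokine summaries of the
eight-line tumor panel that this package's validation suite reproduces:
final confluence, treated-control Δ, intra-assay CV and divergence onset
per line; log-phase slope, AUC (in the reporting scale's arbitrary units),
divergence duration and composite FSI score; and the per-class cytokine
panel means.  Controls are reconstructed as final − Δ.  The reference FSI
column is used for sign and rank-order comparisons only: composite weights
are not part of the reported metrics, so FSI magnitudes are not
reproducible and are never asserted.

``n_sig_points`` encodes the reported per-line significance flags (active
lines significant, neutral lines not) rather than a measured count.
"""

from __future__ import annotations

from .kinetics import KineticProfile

__all__ = ["COHORT", "CYTOKINE_GROUPS", "CLUSTER_PARTITION",
           "FSI_RANK_ORDER", "make_profiles"]

#: line -> (category, final confluence %, Δ points vs control, intra CV %,
#:          onset h, log-phase slope %/h, AUC a.u., divergence duration h,
#:          reference FSI)
COHORT: dict[str, tuple[str, float, float, float, float | None, float,
                        float, float, float]] = {
    "BEWO":      ("stimulatory", 63.2, +34.1, 6.4, 10.0, 2.9, 428, 28, +42.3),
    "U87":       ("stimulatory", 52.6, +16.7, 5.9, 18.0, 2.4, 385, 22, +33.7),
    "LUDLU":     ("stimulatory", 49.3, +12.4, 7.1, 20.0, 1.8, 362, 18, +29.4),
    "A375":      ("inhibitory",  23.0, -21.1, 6.2, 12.0, -2.5, 219, 24, -26.1),
    "PANC-1":    ("inhibitory",  20.5, -29.5, 6.7, 22.0, -3.1, 202, 26, -28.3),
    "MCF-7":     ("neutral",     46.0, +1.6,  4.3, None, 0.3, 321, 0, +3.2),
    "HEPG2":     ("neutral",     43.2, -2.8,  4.9, None, -0.4, 308, 0, -1.6),
    "LNCAP-C42": ("neutral",     41.5, -3.1,  4.6, None, -0.5, 297, 0, -2.3),
}

#: functional group -> analyte mean pg/mL (treated); the composite
#: IFN-γ/IL-10 ratio follows from these means
CYTOKINE_GROUPS: dict[str, dict[str, float]] = {
    "stimulatory": {"IL-6": 168.5, "IFN-γ": 54.1, "IL-10": 39.2},
    "inhibitory": {"IL-6": 45.7, "IFN-γ": 83.6, "IL-10": 14.2},
    "neutral": {"IL-6": 62.3, "IFN-γ": 47.5, "IL-10": 45.2},
}

#: permissive / suppressive / inert compatibility clusters
CLUSTER_PARTITION: set[frozenset[str]] = {
    frozenset({"BEWO", "U87", "LUDLU"}),
    frozenset({"A375", "PANC-1"}),
    frozenset({"MCF-7", "HEPG2", "LNCAP-C42"}),
}

#: cohort ordered by the reference FSI column, best to worst
FSI_RANK_ORDER = ["BEWO", "U87", "LUDLU", "MCF-7", "HEPG2", "LNCAP-C42",
                  "A375", "PANC-1"]


def make_profiles() -> list[KineticProfile]:
    """Kinetic profiles rebuilt from the reference metrics.

    The control final confluence is reconstructed as final − Δ, and the
    significance flag becomes a count safely above/below the five-point
    rule (20 for significant lines, 0 for neutral ones).
    """
    profiles = []
    for line, (cat, final, delta, cv, onset, slope, auc, dur, _) in COHORT.items():
        control = final - delta
        profiles.append(KineticProfile(
            cell_line=line,
            formulation_id=None,
            production_batch="reference",
            final_confluence_mean=final,
            final_confluence_sd=0.0,
            control_final_mean=control,
            delta_points=delta,
            delta_relative=delta / control,
            onset_hours=onset,
            logphase_slope=slope,
            auc=auc,
            divergence_duration=dur,
            plateau_window=None,
            intra_cv=cv,
            n_sig_points=20 if cat != "neutral" else 0,
        ))
    return profiles
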