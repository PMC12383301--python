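import numpy as np
import pytest

from stip.classify import (Category, ClassifierConfig, Congruence,
                           classify_stip, death_gate, kinetic_category,
                           secretome_congruence)
from stip.kinetics import KineticProfile
from stip.plate_io import CytokineSample, DeathTrace
from stip.reference import COHORT, make_profiles

CFG = ClassifierConfig()


def profile(dr, duration, n_sig, line="X"):
    control = 40.0
    return KineticProfile(
        cell_line=line, formulation_id="FV-001", production_batch="B1",
        final_confluence_mean=min(100.0, control * (1 + dr)),
        final_confluence_sd=1.0, control_final_mean=control,
        delta_points=control * dr, delta_relative=dr,
        onset_hours=10.0 if duration else None, logphase_slope=1.0,
        auc=1000.0, divergence_duration=duration, plateau_window=None,
        intra_cv=5.0, n_sig_points=n_sig)


def death(final, well="A1"):
    t = np.arange(0.0, 49.0)
    return DeathTrace(well, t, final * (1 - np.exp(-t / 10)) / (1 - np.exp(-4.8)))


def panel(ifng, il10, condition="treated", line="X"):
    out = []
    for rep, jit in enumerate((-0.1, 0.0, 0.1)):   # mean-preserving jitter
        out.append(CytokineSample(f"s{rep}", line, condition, "IFN-γ",
                                  ifng + jit))
        out.append(CytokineSample(f"s{rep}", line, condition, "IL-10",
                                  max(0.0, il10 + jit if il10 > 0 else 0.0)))
    return out


class TestKineticCategory:
    @pytest.mark.parametrize("line", list(COHORT))
    def test_reference_cohort_reclassifies_exactly(self, line):
        prof = next(p for p in make_profiles() if p.cell_line == line)
        assert kinetic_category(prof, CFG).value == COHORT[line][0]

    @pytest.mark.parametrize("dr,dur,n_sig,expected", [
        (+0.25, 20, 10, Category.STIMULATORY),
        (-0.25, 20, 10, Category.INHIBITORY),
        (+0.03, 0, 0, Category.NEUTRAL),
        (+0.15, 20, 10, Category.INDETERMINATE),   # between the bands
        (+0.25, 8, 10, Category.INDETERMINATE),    # too short
        (+0.25, 20, 3, Category.INDETERMINATE),    # not significant enough
        (+0.05, 0, 10, Category.INDETERMINATE),    # small but significant
        (+0.20, 20, 5, Category.STIMULATORY),      # ties count as active
        (-0.20, 20, 5, Category.INHIBITORY),
    ])
    def test_decision_boundaries(self, dr, dur, n_sig, expected):
        assert kinetic_category(profile(dr, dur, n_sig), CFG) is expected

    def test_every_input_gets_exactly_one_category(self):
        cats = set()
        for dr in np.linspace(-0.6, 0.6, 13):
            for dur in (0, 8, 20):
                for n_sig in (0, 4, 10):
                    cats.add(kinetic_category(profile(dr, dur, n_sig), CFG))
        assert cats <= set(Category)

    def test_monotone_in_delta_relative(self):
        """Raising Δ/control never demotes a stimulatory call."""
        for dur in (12, 20, 40):
            for n_sig in (5, 20):
                seen_stim = False
                for dr in np.linspace(-0.5, 1.5, 41):
                    cat = kinetic_category(profile(dr, dur, n_sig), CFG)
                    if seen_stim:
                        assert cat is Category.STIMULATORY
                    seen_stim = seen_stim or cat is Category.STIMULATORY


class TestDeathGate:
    @pytest.mark.parametrize("final,status,positive", [
        (3.2, "pass", True),     # inhibitory line's reported maximum
        (0.0, "pass", False),
        (7.0, "cytotoxic", True),
    ])
    def test_thresholds(self, final, status, positive):
        traces = [death(final, w) for w in ("A1", "A2", "A3")]
        got_status, got_positive, got_final = death_gate(traces, CFG)
        assert got_status == status
        assert got_positive == positive
        assert got_final == pytest.approx(final, abs=0.1)

    def test_gate_precedence_over_kinetics(self):
        call = classify_stip(profile(+0.5, 30, 20),
                             death=[death(8.0, w) for w in ("A1", "A2")],
                             cfg=CFG)
        assert call.category is Category.CYTOTOXIC_CONFOUNDED
        assert call.stip_type is None

    def test_low_death_keeps_kinetic_call(self):
        call = classify_stip(profile(-0.48, 24, 20),
                             death=[death(2.8, w) for w in ("A1", "A2")],
                             cfg=CFG)
        assert call.category is Category.INHIBITORY
        assert call.evidence.death_gate == "pass"


class TestCongruence:
    def test_inhibitory_ratio_just_below_boundary_is_incongruent(self):
        """83.6/14.2 = 5.89 sits under the >6 congruence boundary."""
        got, ratio = secretome_congruence(Category.INHIBITORY,
                                          panel(83.6, 14.2), [], CFG)
        assert ratio == pytest.approx(5.89, abs=0.02)
        assert got is Congruence.INCONGRUENT

    def test_stimulatory_low_ratio_is_congruent(self):
        got, ratio = secretome_congruence(Category.STIMULATORY,
                                          panel(54.1, 39.2), [], CFG)
        assert ratio == pytest.approx(1.38, abs=0.01)
        assert got is Congruence.CONGRUENT

    def test_missing_panel_not_assessed(self):
        got, ratio = secretome_congruence(Category.STIMULATORY, [], [], CFG)
        assert got is Congruence.NOT_ASSESSED and ratio is None

    def test_zero_il10_not_assessed(self):
        got, ratio = secretome_congruence(Category.INHIBITORY,
                                          panel(50.0, 0.0), [], CFG)
        assert got is Congruence.NOT_ASSESSED

    def test_neutral_congruent_when_panels_match(self):
        treated = panel(47.5, 45.2)
        control = panel(47.5, 45.2, condition="control")
        got, _ = secretome_congruence(Category.NEUTRAL, treated, control, CFG)
        assert got is Congruence.CONGRUENT

    def test_neutral_incongruent_on_large_shift(self):
        treated = panel(150.0, 10.0)
        control = panel(47.5, 45.2, condition="control")
        got, _ = secretome_congruence(Category.NEUTRAL, treated, control, CFG)
        assert got is Congruence.INCONGRUENT

    def test_congruence_never_overrides_kinetics(self):
        call = classify_stip(profile(-0.48, 24, 20),
                             treated_panel=panel(54.1, 39.2),  # "wrong" panel
                             cfg=CFG)
        assert call.category is Category.INHIBITORY
        assert call.evidence.congruence == Congruence.INCONGRUENT.value


class TestConfigInvariants:
    @pytest.mark.parametrize("kwargs", [
        {"neutral_rel": 0.25},                  # neutral band above active
        {"death_positive": 6.0},                # positive above cytotoxic
        {"ratio_low": 7.0},                     # low boundary above high
    ])
    def test_inconsistent_thresholds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ClassifierConfig(**kwargs)
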