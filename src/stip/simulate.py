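"""Synthetic plate simulator: confluence, death and cytokine channels with
ground-truth labels.

The generator emulates the statistical structure the analysis assumes: an
8-line cohort monitored hourly for 48 h in treated/control triplicates,
with class-specific treatment effects on logistic growth, a sub-threshold
cumulative death signal, and class-conditional cytokine panels.

Growth model
------------
Controls follow a logistic curve C(t) = K / (1 + exp(-r (t - t_mid))).
Treated wells follow the control trajectory until the effect onset t0 and
thereafter the logistic law with effect-scaled parameters
(K_eff = effect_K * K, r_eff = effect_r * r), re-anchored so the trajectory
is continuous at t0:

    C(t) = K_eff / (1 + (K_eff / C(t0) - 1) exp(-r_eff (t - t0)))

which rises toward K_eff when C(t0) < K_eff and decays toward it when the
treatment caps growth below the current confluence — one mechanism covers
the sustained-rise, progressive-suppression and unchanged archetypes.

Noise
-----
Additive Gaussian well noise per timepoint (sd ``noise_sd``), clipped to
[0, 100].  A multiplicative batch factor (CV ``interbatch_cv``) is drawn
once per production batch and applied to the carrying capacity of every
well in the batch, treated and control alike: it models plate/passage-level
batch variation and is visible to interbatch QC through the across-batch
spread of final confluence, while leaving the within-batch treated/control
contrast unbiased.

Everything is driven by one integer seed; identical seeds give bit-identical
datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .plate_io import (ANALYTES, ConfluenceTrace, CytokineSample, DeathTrace,
                       PlateEntry, PlateMap)

__all__ = [
    "LineSpec",
    "SimConfig",
    "SimulatedDataset",
    "default_cohort",
    "simulate_trace",
    "simulate_plate",
    "simulate_interbatch_study",
]

#: class-conditional cytokine (mean, sd) in pg/mL for treated wells, and the
#: shared control/baseline panel; the neutral class secretes at baseline.
DEFAULT_CYTOKINES: dict[str, dict[str, tuple[float, float]]] = {
    "stimulatory": {"IL-6": (168.5, 12.4), "IFN-γ": (54.1, 9.3),
                    "IL-10": (39.2, 6.1), "TNF-α": (12.0, 3.0)},
    "inhibitory": {"IL-6": (45.7, 7.9), "IFN-γ": (83.6, 10.8),
                   "IL-10": (14.2, 3.4), "TNF-α": (10.0, 3.0)},
    "neutral": {"IL-6": (62.3, 8.5), "IFN-γ": (47.5, 6.2),
                "IL-10": (45.2, 5.9), "TNF-α": (8.0, 2.0)},
    "cytotoxic": {"IL-6": (45.7, 7.9), "IFN-γ": (83.6, 10.8),
                  "IL-10": (14.2, 3.4), "TNF-α": (10.0, 3.0)},
    "control": {"IL-6": (62.3, 8.5), "IFN-γ": (47.5, 6.2),
                "IL-10": (45.2, 5.9), "TNF-α": (8.0, 2.0)},
}

#: cumulative-death plateau (%) by class: active and neutral lines stay well
#: under the 5% cytotoxicity threshold, the cytotoxic archetype exceeds it
DEFAULT_DEATH_PLATEAU = {"stimulatory": 1.2, "inhibitory": 3.0,
                         "neutral": 1.0, "cytotoxic": 7.0, "control": 1.0}


@dataclass(frozen=True)
class LineSpec:
    """Generative parameters of one cell line.

    ``effect_K``/``effect_r`` multiply the carrying capacity and growth rate
    of treated wells from ``effect_onset`` hours onward; 1.0 means no
    treatment effect.
    """

    name: str
    true_class: str                 # stimulatory | inhibitory | neutral | cytotoxic
    control_K: float                # carrying capacity, percent confluence
    r: float = 0.25                 # growth rate, 1/h
    t_mid: float = 18.0             # inflection hour of the control curve
    effect_K: float = 1.0
    effect_r: float = 1.0
    effect_onset: float = 10.0
    death_plateau: float | None = None   # defaults by class

    def __post_init__(self) -> None:
        if self.true_class not in ("stimulatory", "inhibitory", "neutral",
                                   "cytotoxic"):
            raise ValueError(f"unknown class {self.true_class!r}")
        if not 0 < self.control_K <= 100:
            raise ValueError("control_K must be in (0, 100]")
        if not 0 <= self.effect_onset <= 48:
            raise ValueError("effect_onset must be in [0, 48]")


def default_cohort() -> list[LineSpec]:
    """The 8-line study cohort.

    Class effects are sized to the reported final-confluence contrasts
    (treated/control ratio = effect_K).  Each line's inflection hour sits
    near its effect onset and stimulated lines get a growth-rate boost so
    the treated and control trajectories separate sharply at onset, giving
    detected divergence onsets close to the reported per-line ΔT with a
    tight across-batch spread.
    """
    return [
        LineSpec("BEWO", "stimulatory", control_K=29.1, t_mid=12.0,
                 effect_K=2.172, effect_r=1.8, effect_onset=10.0),
        LineSpec("U87", "stimulatory", control_K=35.9, t_mid=18.0,
                 effect_K=1.465, effect_r=1.4, effect_onset=18.0),
        LineSpec("LUDLU", "stimulatory", control_K=36.9, t_mid=20.0,
                 effect_K=1.336, effect_r=1.4, effect_onset=20.0),
        LineSpec("A375", "inhibitory", control_K=44.1, t_mid=14.0,
                 effect_K=0.522, effect_r=0.6, effect_onset=12.0,
                 death_plateau=2.8),
        LineSpec("PANC-1", "inhibitory", control_K=50.0, t_mid=20.0,
                 effect_K=0.410, effect_r=0.8, effect_onset=22.0,
                 death_plateau=3.2),
        LineSpec("MCF-7", "neutral", control_K=44.4),
        LineSpec("HEPG2", "neutral", control_K=46.0),
        LineSpec("LNCAP-C42", "neutral", control_K=44.6),
    ]


@dataclass
class SimConfig:
    """Generative parameters for synthetic plates."""

    lines: list[LineSpec] = field(default_factory=default_cohort)
    replicates: int = 3
    batches: int = 3
    formulations: int = 5
    noise_sd: float = 1.0            # additive confluence noise, percent
    interbatch_cv: float = 5.0       # percent CV of the batch factor
    t_end: float = 48.0
    dt: float = 1.0
    death_noise_sd: float = 0.05
    death_tau: float = 16.0          # hours to ~63% of the death plateau
    cytokine_reps: int = 3
    llod: float = 2.0                # pg/mL floor below which samples flag
    cytokines: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CYTOKINES.items()})
    death_plateaus: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEATH_PLATEAU))

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.interbatch_cv < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per arm")
        if 2 * self.replicates * len(self.lines) > 96:
            raise ValueError("layout exceeds one 96-well plate")

    @property
    def grid(self) -> np.ndarray:
        return np.arange(0.0, self.t_end + self.dt / 2, self.dt)


@dataclass
class SimulatedDataset:
    """One simulated plate: every channel plus the generating truth."""

    confluence: dict[str, ConfluenceTrace]
    death: dict[str, DeathTrace]
    cytokines: list[CytokineSample]
    plate_map: PlateMap
    truth: dict[str, str]            # cell line -> true class
    formulation_id: str
    production_batch: str


def _logistic(t: np.ndarray, K: float, r: float, t_mid: float) -> np.ndarray:
    return K / (1.0 + np.exp(-r * (t - t_mid)))


def _mean_curve(line: LineSpec, arm: str, batch_factor: float,
                grid: np.ndarray) -> np.ndarray:
    K = line.control_K * batch_factor
    base = _logistic(grid, K, line.r, line.t_mid)
    if arm == "control" or (line.effect_K == 1.0 and line.effect_r == 1.0):
        return base
    t0 = line.effect_onset
    c0 = float(_logistic(np.asarray([t0]), K, line.r, line.t_mid)[0])
    K_eff = K * line.effect_K
    r_eff = line.r * line.effect_r
    post = K_eff / (1.0 + (K_eff / c0 - 1.0) * np.exp(-r_eff * (grid - t0)))
    return np.where(grid < t0, base, post)


def simulate_trace(line: LineSpec, arm: str, well_id: str,
                   rng: np.random.Generator, cfg: SimConfig,
                   batch_factor: float = 1.0) -> ConfluenceTrace:
    """One well's noisy confluence trace."""
    grid = cfg.grid
    mean = _mean_curve(line, arm, batch_factor, grid)
    noisy = mean + rng.normal(0.0, cfg.noise_sd, size=grid.shape) \
        if cfg.noise_sd > 0 else mean.copy()
    return ConfluenceTrace(well_id, grid, np.clip(noisy, 0.0, 100.0))


def _simulate_death(line: LineSpec, arm: str, well_id: str,
                    rng: np.random.Generator, cfg: SimConfig) -> DeathTrace:
    grid = cfg.grid
    if arm == "control":
        plateau = cfg.death_plateaus["control"]
    else:
        plateau = (line.death_plateau if line.death_plateau is not None
                   else cfg.death_plateaus[line.true_class])
    mean = plateau * (1.0 - np.exp(-grid / cfg.death_tau))
    noisy = mean + rng.normal(0.0, cfg.death_noise_sd, size=grid.shape)
    cum = np.maximum.accumulate(np.clip(noisy, 0.0, 100.0))
    cum[0] = min(cum[0], mean[0])
    return DeathTrace(well_id, grid, np.clip(cum, 0.0, 100.0))


def _simulate_cytokines(line: LineSpec, rng: np.random.Generator,
                        cfg: SimConfig) -> list[CytokineSample]:
    out = []
    for condition in ("treated", "control"):
        key = line.true_class if condition == "treated" else "control"
        params = cfg.cytokines[key]
        for rep in range(1, cfg.cytokine_reps + 1):
            for analyte in ANALYTES:
                mean, sd = params[analyte]
                conc = max(0.0, float(rng.normal(mean, sd)))
                out.append(CytokineSample(
                    sample_id=f"{line.name}-{condition}-{rep}",
                    cell_line=line.name,
                    condition=condition,
                    analyte=analyte,
                    concentration=conc,
                    below_llod=conc < cfg.llod,
                ))
    return out


def _well_layout(n_lines: int, replicates: int) -> Iterable[tuple[int, str, int, str]]:
    """(line index, arm, replicate, well id) over a 96-well grid, row per line."""
    rows = "ABCDEFGH"
    for i in range(n_lines):
        for rep in range(replicates):
            yield i, "treated", rep + 1, f"{rows[i % 8]}{rep + 1}"
        for rep in range(replicates):
            yield i, "control", rep + 1, f"{rows[i % 8]}{replicates + rep + 1}"


def simulate_plate(cfg: SimConfig | None = None, seed: int = 0, *,
                   formulation_id: str = "FV-001",
                   production_batch: str = "B1",
                   batch_factor: float | None = None) -> SimulatedDataset:
    """Simulate one plate (all lines, treated + control arms, one batch)."""
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(seed)
    if batch_factor is None:
        batch_factor = _draw_batch_factor(rng, cfg)
    confluence: dict[str, ConfluenceTrace] = {}
    death: dict[str, DeathTrace] = {}
    entries: dict[str, PlateEntry] = {}
    for i, arm, rep, well in _well_layout(len(cfg.lines), cfg.replicates):
        line = cfg.lines[i]
        confluence[well] = simulate_trace(line, arm, well, rng, cfg,
                                          batch_factor)
        death[well] = _simulate_death(line, arm, well, rng, cfg)
        entries[well] = PlateEntry(
            cell_line=line.name,
            condition=arm,
            formulation_id=formulation_id if arm == "treated" else None,
            production_batch=production_batch,
            replicate=rep,
        )
    cytokines = [s for line in cfg.lines
                 for s in _simulate_cytokines(line, rng, cfg)]
    return SimulatedDataset(
        confluence=confluence,
        death=death,
        cytokines=cytokines,
        plate_map=PlateMap(entries),
        truth={line.name: line.true_class for line in cfg.lines},
        formulation_id=formulation_id,
        production_batch=production_batch,
    )


def _draw_batch_factor(rng: np.random.Generator, cfg: SimConfig) -> float:
    return max(0.1, float(rng.normal(1.0, cfg.interbatch_cv / 100.0)))


def write_dataset(dataset: SimulatedDataset, out_dir) -> dict[str, "object"]:
    """Write a simulated dataset in the CSV dialects the readers accept.

    Produces confluence.csv, death.csv, plate_map.csv, cytokines.csv and
    truth.json under ``out_dir`` and returns the paths.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _wide(traces: Mapping[str, ConfluenceTrace], name: str) -> None:
        wells = sorted(traces)
        grid = traces[wells[0]].times
        lines = ["elapsed_h," + ",".join(wells)]
        for i, t in enumerate(grid):
            row = [f"{t:g}"] + [f"{traces[w].values[i]:.6f}" for w in wells]
            lines.append(",".join(row))
        p = out / name
        p.write_text("\n".join(lines) + "\n", encoding="utf-8")
        paths[name] = p

    _wide(dataset.confluence, "confluence.csv")
    _wide(dataset.death, "death.csv")

    pm_lines = ["well,cell_line,condition,formulation_id,production_batch,replicate"]
    for well, e in sorted(dataset.plate_map.entries.items()):
        pm_lines.append(",".join([well, e.cell_line, e.condition,
                                  e.formulation_id or "", e.production_batch,
                                  str(e.replicate)]))
    (out / "plate_map.csv").write_text("\n".join(pm_lines) + "\n", encoding="utf-8")
    paths["plate_map.csv"] = out / "plate_map.csv"

    cy_lines = ["sample_id,cell_line,condition,analyte,concentration_pg_ml,below_llod"]
    for s in dataset.cytokines:
        cy_lines.append(",".join([s.sample_id, s.cell_line, s.condition,
                                  s.analyte, f"{s.concentration:.4f}",
                                  str(s.below_llod)]))
    (out / "cytokines.csv").write_text("\n".join(cy_lines) + "\n", encoding="utf-8")
    paths["cytokines.csv"] = out / "cytokines.csv"

    (out / "truth.json").write_text(
        json.dumps(dataset.truth, indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8")
    paths["truth.json"] = out / "truth.json"
    return paths


def simulate_interbatch_study(cfg: SimConfig | None = None, seed: int = 0,
                              n_batches: int | None = None,
                              formulation_id: str = "FV-001",
                              ) -> list[SimulatedDataset]:
    """Independent batches with identical class truth and fresh batch factors."""
    cfg = cfg or SimConfig()
    n = n_batches if n_batches is not None else cfg.batches
    if n < 2:
        raise ValueError("an interbatch study needs >= 2 batches")
    rng = np.random.default_rng(seed)
    out = []
    for b in range(n):
        factor = _draw_batch_factor(rng, cfg)
        plate_seed = int(rng.integers(0, 2**31 - 1))
        out.append(simulate_plate(cfg, plate_seed,
                                  formulation_id=formulation_id,
                                  production_batch=f"B{b + 1}",
                                  batch_factor=factor))
    return out
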