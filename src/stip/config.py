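"""Run configuration: loading, validation, dumping and pretty-printing.

A run configuration is a YAML/JSON document with one section per analysis
stage (``kinetics``, ``classifier``, ``fsi``, ``qc``, ``cluster``, ``sim``)
plus ``seed`` and ``log_level``.  Unknown keys are rejected so typos fail
loudly; every threshold is validated by its section's dataclass invariants
at load time.  Dump-then-load reproduces the effective configuration
exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .classify import ClassifierConfig
from .cluster import ClusterConfig
from .fsi import FsiConfig
from .kinetics import KineticsConfig
from .qc import QcConfig
from .simulate import LineSpec, SimConfig

__all__ = ["RunConfig", "load_config", "dump_config", "config_hash",
           "describe_config"]

_SECTIONS = {
    "kinetics": KineticsConfig,
    "classifier": ClassifierConfig,
    "fsi": FsiConfig,
    "qc": QcConfig,
    "cluster": ClusterConfig,
    "sim": SimConfig,
}

#: plain-language meaning of the headline thresholds, keyed by section.field
_DESCRIPTIONS = {
    "classifier.class_rel": "relative confluence change defining an active response",
    "classifier.neutral_rel": "relative band within which a response is neutral",
    "classifier.min_duration": "hours of sustained divergence required for an active call",
    "classifier.min_sig_points": "timepoints with p < alpha required for an active call",
    "classifier.alpha": "per-timepoint significance level",
    "classifier.death_positive": "cumulative death (%) flagged as a positive signal",
    "classifier.death_cytotoxic": "cumulative death (%) above which the call is cytotoxicity-confounded",
    "classifier.ratio_high": "IFN-γ/IL-10 above which an inhibitory call is congruent",
    "classifier.ratio_low": "IFN-γ/IL-10 below which a stimulatory call is congruent",
    "classifier.neutral_cytokine_p": "adjusted p below which an analyte counts as shifted",
    "kinetics.onset_rel": "relative difference defining divergence onset",
    "kinetics.onset_run": "consecutive qualifying points required at onset",
    "kinetics.slope_window": "sliding-window width (h) for the log-phase slope",
    "kinetics.plateau_tol": "max |slope| (%/h) inside a plateau",
    "kinetics.plateau_min": "minimum plateau length (h)",
    "qc.intra_cv_active": "intra-assay CV bound (%) for active lines",
    "qc.intra_cv_neutral": "intra-assay CV bound (%) for neutral lines",
    "qc.interbatch_final_cv": "across-batch CV bound (%) on final confluence",
    "qc.interbatch_onset_cv": "across-batch CV bound (%) on divergence onset",
    "qc.interbatch_delta_max": "max across-batch spread (points) of the treated-control Δ",
    "fsi.scale": "multiplier mapping the weighted z-composite to the display range",
    "sim.noise_sd": "additive confluence noise (%) per well and timepoint",
    "sim.interbatch_cv": "CV (%) of the per-batch capacity factor",
}


@dataclass
class RunConfig:
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    fsi: FsiConfig = field(default_factory=FsiConfig)
    qc: QcConfig = field(default_factory=QcConfig)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    log_level: str = "INFO"


def _build_section(cls, data: dict, section: str):
    valid = {f.name for f in fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown key(s) in section {section!r}: {sorted(unknown)}")
    if cls is SimConfig and "lines" in data:
        data = dict(data)
        data["lines"] = [LineSpec(**ln) for ln in data["lines"]]
    if cls is ClusterConfig and "features" in data:
        data = dict(data)
        data["features"] = tuple(data["features"])
    if cls is SimConfig:
        for key in ("cytokines",):
            if key in data:
                data = dict(data)
                data[key] = {k: {a: tuple(v) for a, v in d.items()}
                             for k, d in data[key].items()}
    return cls(**data)


def load_config(source: str | Path | dict | None = None) -> RunConfig:
    """Build a validated RunConfig from a YAML/JSON file or a dict."""
    if source is None:
        return RunConfig()
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text(encoding="utf-8")) or {}
    else:
        data = dict(source)
    unknown = set(data) - set(_SECTIONS) - {"seed", "log_level"}
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in data:
            kwargs[name] = _build_section(cls, data[name] or {}, name)
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    if "log_level" in data:
        kwargs["log_level"] = str(data["log_level"])
    return RunConfig(**kwargs)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def dump_config(cfg: RunConfig) -> str:
    """Serialize the effective configuration to YAML."""
    return yaml.safe_dump(_to_plain(cfg), sort_keys=True, allow_unicode=True)


def config_hash(cfg: RunConfig) -> str:
    """Stable digest of the effective configuration (for run manifests)."""
    blob = json.dumps(_to_plain(cfg), sort_keys=True, ensure_ascii=False)
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:16]


def describe_config(cfg: RunConfig) -> str:
    """Human-readable listing of every threshold, marking overrides."""
    defaults = RunConfig()
    lines = []
    for section in (*_SECTIONS, "seed", "log_level"):
        if section in ("seed", "log_level"):
            val, dval = getattr(cfg, section), getattr(defaults, section)
            marker = "  (overridden)" if val != dval else ""
            lines.append(f"{section} = {val!r}{marker}")
            continue
        lines.append(f"[{section}]")
        sec, dsec = getattr(cfg, section), getattr(defaults, section)
        for f in fields(sec):
            val, dval = getattr(sec, f.name), getattr(dsec, f.name)
            marker = "  (overridden)" if _to_plain(val) != _to_plain(dval) else ""
            desc = _DESCRIPTIONS.get(f"{section}.{f.name}")
            note = f"   # {desc}" if desc else ""
            if section == "sim" and f.name in ("lines", "cytokines",
                                               "death_plateaus"):
                val = f"<{len(val)} entries>" if marker == "" else _to_plain(val)
            lines.append(f"  {f.name} = {val}{marker}{note}")
    return "\n".join(lines)
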