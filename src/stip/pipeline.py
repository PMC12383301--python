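"""End-to-end orchestration: ingest -> kinetics -> classify -> FSI -> QC ->
compatibility -> clustering -> write.

The pipeline is deterministic given its inputs and configuration; the only
stochastic stage in the package is the simulator, and it is driven entirely
by the run seed.  Logging goes to stderr with per-stage timings; result
files are never interleaved with log output.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import Category, StipCall, classify_stip
from .cluster import ClusterResult, build_feature_matrix, similarity_matrix, ward_cluster
from .config import RunConfig, config_hash
from .fsi import FsiResult, fsi_scores, rank_lines
from .kinetics import KineticProfile, compute_profile
from .plate_io import (ConfluenceTrace, CytokineSample, DeathTrace, PlateMap,
                       read_confluence_export, read_cytokines,
                       read_death_export, read_plate_map, write_results)
from .qc import (CompatibilityMatrix, QcReport, build_compatibility_matrix,
                 interbatch_qc_line, intra_assay_qc)

__all__ = ["ResultBundle", "run_analyze", "run_analyze_files"]

log = logging.getLogger("stip")


@dataclass
class ResultBundle:
    profiles: list[KineticProfile]
    calls: list[StipCall]
    line_profiles: list[KineticProfile]
    line_calls: list[StipCall]
    fsi: list[FsiResult]
    qc: QcReport
    matrix: CompatibilityMatrix
    features: pd.DataFrame
    similarity: pd.DataFrame
    clusters: ClusterResult
    metrics: pd.DataFrame


def _profile_row(p: KineticProfile, call: StipCall) -> dict:
    row = {
        "cell_line": p.cell_line,
        "formulation_id": p.formulation_id,
        "production_batch": p.production_batch,
        "category": call.category.value,
        "final_confluence_mean": p.final_confluence_mean,
        "final_confluence_sd": p.final_confluence_sd,
        "control_final_mean": p.control_final_mean,
        "delta_points": p.delta_points,
        "delta_relative": p.delta_relative,
        "onset_hours": p.onset_hours,
        "logphase_slope": p.logphase_slope,
        "auc": p.auc,
        "divergence_duration": p.divergence_duration,
        "plateau_start": p.plateau_window[0] if p.plateau_window else None,
        "plateau_end": p.plateau_window[1] if p.plateau_window else None,
        "intra_cv": p.intra_cv,
        "n_sig_points": p.n_sig_points,
    }
    return row


def _aggregate_line(profiles: Sequence[KineticProfile]) -> KineticProfile:
    """Mean of each numeric metric across a line's formulation x batch runs."""
    def m(attr):
        vals = [getattr(p, attr) for p in profiles]
        return float(np.mean(vals))

    onsets = [p.onset_hours for p in profiles if p.onset_hours is not None]
    plateaus = [p.plateau_window for p in profiles if p.plateau_window]
    return KineticProfile(
        cell_line=profiles[0].cell_line,
        formulation_id=None,
        production_batch="pooled",
        final_confluence_mean=m("final_confluence_mean"),
        final_confluence_sd=m("final_confluence_sd"),
        control_final_mean=m("control_final_mean"),
        delta_points=m("delta_points"),
        delta_relative=m("delta_relative"),
        onset_hours=float(np.mean(onsets)) if onsets else None,
        logphase_slope=m("logphase_slope"),
        auc=m("auc"),
        divergence_duration=m("divergence_duration"),
        plateau_window=(float(np.mean([p[0] for p in plateaus])),
                        float(np.mean([p[1] for p in plateaus]))) if plateaus else None,
        intra_cv=m("intra_cv"),
        n_sig_points=int(round(np.mean([p.n_sig_points for p in profiles]))),
    )


def _modal_call(calls: Sequence[StipCall]) -> StipCall:
    """Most frequent category for a line (ties: earliest in sorted order)."""
    counts: dict[Category, int] = {}
    for c in calls:
        counts[c.category] = counts.get(c.category, 0) + 1
    best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0].value))[0][0]
    winner = next(c for c in calls if c.category is best)
    return replace(winner, formulation_id=None)


def run_analyze(traces: Mapping[str, ConfluenceTrace], plate_map: PlateMap,
                death: Mapping[str, DeathTrace] | None = None,
                cytokines: Sequence[CytokineSample] = (),
                cfg: RunConfig | None = None) -> ResultBundle:
    """Run the complete analysis on in-memory inputs."""
    cfg = cfg or RunConfig()
    t_start = time.perf_counter()

    # --- kinetics + classification per treated group ----------------------
    profiles: list[KineticProfile] = []
    calls: list[StipCall] = []
    cyt_by_line: dict[tuple[str, str], list[CytokineSample]] = {}
    for s in cytokines:
        cyt_by_line.setdefault((s.cell_line, s.condition), []).append(s)

    for (line, cond, form, batch), wells in plate_map.groups().items():
        if cond != "treated":
            continue
        control_wells = plate_map.control_wells(line, batch)
        missing = [w for w in wells + control_wells if w not in traces]
        if missing:
            raise ValueError(
                f"stage kinetics: group (line={line}, formulation={form}, "
                f"batch={batch}) is missing trace(s) for wells {missing}")
        treated_tr = [traces[w] for w in wells]
        control_tr = [traces[w] for w in control_wells]
        profile, pstats = compute_profile(
            treated_tr, control_tr, cfg.kinetics,
            cell_line=line, formulation_id=form, production_batch=batch)
        death_tr = [death[w] for w in wells if death and w in death] if death else []
        call = classify_stip(profile, pstats, death_tr,
                             cyt_by_line.get((line, "treated"), []),
                             cyt_by_line.get((line, "control"), []),
                             cfg.classifier)
        profiles.append(profile)
        calls.append(call)
    if not profiles:
        raise ValueError("stage kinetics: no treated groups in the plate map")
    log.info("kinetics+classification: %d group(s) in %.2fs",
             len(profiles), time.perf_counter() - t_start)

    # --- per-line aggregation for cohort-level stages ---------------------
    by_line: dict[str, list[int]] = {}
    for i, p in enumerate(profiles):
        by_line.setdefault(p.cell_line, []).append(i)
    line_profiles = [_aggregate_line([profiles[i] for i in idx])
                     for idx in by_line.values()]
    line_calls = [_modal_call([calls[i] for i in idx])
                  for idx in by_line.values()]

    # --- FSI --------------------------------------------------------------
    t0 = time.perf_counter()
    fsi_res = rank_lines(fsi_scores(line_profiles, cfg.fsi)) \
        if len(line_profiles) >= 2 else []
    log.info("fsi: %d line(s) in %.2fs", len(fsi_res), time.perf_counter() - t0)

    # --- QC ---------------------------------------------------------------
    t0 = time.perf_counter()
    report = QcReport(intra_assay=intra_assay_qc(profiles, calls, cfg.qc))
    groups: dict[tuple[str, str | None], tuple[list, list]] = {}
    for p, c in zip(profiles, calls):
        groups.setdefault((p.cell_line, p.formulation_id), ([], []))
        groups[(p.cell_line, p.formulation_id)][0].append(p)
        groups[(p.cell_line, p.formulation_id)][1].append(c)
    for key in sorted(groups, key=lambda k: (k[0], str(k[1]))):
        ps, cs = groups[key]
        report.interbatch.append(interbatch_qc_line(ps, cs, cfg.qc))
    log.info("qc: %d interbatch group(s) in %.2fs",
             len(report.interbatch), time.perf_counter() - t0)

    # --- compatibility matrix --------------------------------------------
    matrix = build_compatibility_matrix(_dedupe_calls(profiles, calls))

    # --- clustering -------------------------------------------------------
    t0 = time.perf_counter()
    features = sim = clusters = None
    if len(line_profiles) >= 3 and fsi_res:
        features = build_feature_matrix(line_profiles, fsi_res,
                                        cfg.cluster.features)
        sim = similarity_matrix(features)
        clusters = ward_cluster(features, cfg.cluster)
        log.info("cluster: k=%d in %.2fs", clusters.selected_k,
                 time.perf_counter() - t0)

    metrics = pd.DataFrame([_profile_row(p, c) for p, c in zip(profiles, calls)])
    return ResultBundle(profiles=profiles, calls=calls,
                        line_profiles=line_profiles, line_calls=line_calls,
                        fsi=fsi_res, qc=report, matrix=matrix,
                        features=features if features is not None else pd.DataFrame(),
                        similarity=sim if sim is not None else pd.DataFrame(),
                        clusters=clusters, metrics=metrics)


def _dedupe_calls(profiles: Sequence[KineticProfile],
                  calls: Sequence[StipCall]) -> list[StipCall]:
    """One call per (line, formulation): the modal category across batches."""
    grouped: dict[tuple[str, str | None], list[StipCall]] = {}
    for c in calls:
        grouped.setdefault((c.cell_line, c.formulation_id), []).append(c)
    out = []
    for key in sorted(grouped, key=lambda k: (k[0], str(k[1]))):
        modal = _modal_call(grouped[key])
        out.append(replace(modal, formulation_id=key[1]))
    return out


def _fsi_frame(results: Sequence[FsiResult]) -> pd.DataFrame:
    rows = []
    for rank, r in enumerate(results, start=1):
        row = {"cell_line": r.cell_line, "rank": rank, "fsi": r.fsi}
        row.update({f"z_{k}": v for k, v in r.z_scores.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def _calls_payload(calls: Sequence[StipCall]) -> list[dict]:
    return [{
        "cell_line": c.cell_line,
        "formulation_id": c.formulation_id,
        "category": c.category.value,
        "stip_type": c.stip_type,
        "evidence": c.evidence,
    } for c in calls]


def write_bundle(bundle: ResultBundle, out_dir: str | Path,
                 cfg: RunConfig | None = None) -> dict[str, Path]:
    """Write every stage's outputs plus a run manifest."""
    cfg = cfg or RunConfig()
    cluster_payload = None
    if bundle.clusters is not None:
        cluster_payload = {
            "selected_k": bundle.clusters.selected_k,
            "labels": bundle.clusters.labels,
            "silhouettes": {str(k): v for k, v in
                            bundle.clusters.silhouettes.items()},
            "linkage": bundle.clusters.linkage.tolist(),
        }
    written = write_results(
        out_dir,
        metrics=bundle.metrics,
        calls=_calls_payload(_dedupe_calls(bundle.profiles, bundle.calls)),
        qc={"overall_pass": bundle.qc.overall_pass,
            "intra_assay": bundle.qc.intra_assay,
            "interbatch": bundle.qc.interbatch},
        fsi=_fsi_frame(bundle.fsi),
        matrix=bundle.matrix.table if bundle.matrix else None,
        similarity=bundle.similarity if len(bundle.similarity) else None,
        clusters=cluster_payload,
    )
    manifest = {
        "package": "stip",
        "version": __version__,
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "outputs": sorted(str(p.name) for p in written.values()),
    }
    mpath = Path(out_dir) / "run_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    written["run_manifest.json"] = mpath
    return written


def run_analyze_files(confluence: str | Path, plate_map: str | Path,
                      death: str | Path | None = None,
                      cytokines: str | Path | None = None,
                      out_dir: str | Path | None = None,
                      cfg: RunConfig | None = None) -> ResultBundle:
    """File-based front end to :func:`run_analyze`."""
    cfg = cfg or RunConfig()
    for name, p in (("confluence", confluence), ("plate map", plate_map)):
        if p is None or not Path(p).exists():
            raise FileNotFoundError(f"missing required input: {name} ({p})")
    traces = {t.well_id: t for t in read_confluence_export(confluence)}
    pmap = read_plate_map(plate_map)
    death_map = None
    if death is not None:
        death_map = {t.well_id: t for t in read_death_export(death)}
    cyt = read_cytokines(cytokines) if cytokines is not None else []
    bundle = run_analyze(traces, pmap, death_map, cyt, cfg)
    if out_dir is not None:
        write_bundle(bundle, out_dir, cfg)
    return bundle
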