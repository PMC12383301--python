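"""Reading and writing of plate-level data files.

Confluence and cell-death exports are wide CSV files: an ``elapsed_h`` time
column followed by one column per well, optionally preceded by ``#`` comment
lines.  Instrument software in some locales exports decimal commas
(``0,1`` for ``0.1``) with ``;`` as the field separator; both dialects are
supported and can be auto-detected per file.  Plate maps and cytokine tables
are ordinary point-decimal CSV.

All result tables written by :func:`write_results` use ``.`` as the decimal
separator regardless of the input dialect.
"""

from __future__ import annotations

import dataclasses
import json
import math
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "ValidationError",
    "StructuralError",
    "ConfluenceTrace",
    "DeathTrace",
    "PlateEntry",
    "PlateMap",
    "CytokineSample",
    "ANALYTES",
    "read_confluence_export",
    "read_death_export",
    "read_plate_map",
    "read_cytokines",
    "read_metrics",
    "write_results",
]

ANALYTES = ("IL-6", "IL-10", "IFN-γ", "TNF-α")

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")

#: tolerated upward jitter when checking that death traces are cumulative
DEATH_MONOTONE_TOL = 0.2


class ParseError(ValueError):
    """A cell in an input file could not be parsed as a number."""


class ValidationError(ValueError):
    """Parsed data violate a structural invariant (range, ordering, grid)."""


class StructuralError(ValueError):
    """The plate layout is inconsistent (duplicates, unmatched controls)."""


def normalize_well_id(well: str) -> str:
    """Upper-case a well coordinate and check it is within A1–H12."""
    w = well.strip().upper()
    if not _WELL_RE.match(w):
        raise ValidationError(f"invalid well id {well!r} (expected A1–H12)")
    return w


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfluenceTrace:
    """One well's confluence time course on an (approximately) hourly grid.

    Parameters
    ----------
    well_id : str
        Plate coordinate, e.g. ``"B7"``.
    times : ndarray
        Hours since treatment, strictly increasing, first value >= 0,
        spacing uniform within 10% of the median interval.
    values : ndarray
        Confluence percent, each value in [0, 100].
    """

    well_id: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v) or len(t) < 2:
            raise ValidationError(
                f"{self.well_id}: times and values must be equal-length 1-D "
                f"arrays of length >= 2 (got {len(t)} and {len(v)})"
            )
        if t[0] < 0:
            raise ValidationError(f"{self.well_id}: first time {t[0]} < 0")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise ValidationError(f"{self.well_id}: times not strictly increasing")
        med = float(np.median(dt))
        if np.any(np.abs(dt - med) > 0.1 * med):
            raise ValidationError(
                f"{self.well_id}: time grid not uniform within 10% of the "
                f"median interval ({med:g} h)"
            )
        self._check_range(v)

    def _check_range(self, v: np.ndarray) -> None:
        bad = np.where((v < 0) | (v > 100))[0]
        if bad.size:
            offenders = ", ".join(f"t={self.times[i]:g}h:{v[i]:g}" for i in bad[:5])
            raise ValidationError(
                f"{self.well_id}: {bad.size} value(s) outside [0, 100] ({offenders})"
            )

    @property
    def spacing(self) -> float:
        return float(np.median(np.diff(self.times)))

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class DeathTrace(ConfluenceTrace):
    """Cumulative dead-cell percent over time for one well.

    Values must be non-decreasing up to a smoothing tolerance of
    0.2 percentage points.
    """

    def __post_init__(self) -> None:
        super().__post_init__()
        drops = np.diff(self.values)
        if np.any(drops < -DEATH_MONOTONE_TOL):
            i = int(np.argmin(drops))
            raise ValidationError(
                f"{self.well_id}: cumulative death decreases by "
                f"{-drops[i]:.2f} points at t={self.times[i + 1]:g} h "
                f"(tolerance {DEATH_MONOTONE_TOL})"
            )


@dataclass(frozen=True)
class PlateEntry:
    """Annotation of one well in the plate map."""

    cell_line: str
    condition: str  # "treated" | "control"
    formulation_id: str | None
    production_batch: str
    replicate: int

    def __post_init__(self) -> None:
        if self.condition not in ("treated", "control"):
            raise ValidationError(
                f"condition must be 'treated' or 'control', got {self.condition!r}"
            )
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")


@dataclass(frozen=True)
class PlateMap:
    """Mapping of wells to cell line / condition / batch / replicate.

    Every treated (cell_line, formulation_id, production_batch) group must
    have a matched control group for the same cell line; replicate counts
    below 3 trigger a warning (technical triplicates are the norm), below 2
    an error.
    """

    entries: Mapping[str, PlateEntry]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        for well in self.entries:
            normalize_well_id(well)
        self._validate_groups()

    def _validate_groups(self) -> None:
        for key, wells in self.groups().items():
            if len(wells) < 2:
                raise StructuralError(
                    f"group {key} has only {len(wells)} replicate(s); >= 2 required"
                )
            if len(wells) < 3:
                warnings.warn(
                    f"group {key} has {len(wells)} replicates (< 3 technical "
                    "triplicates)", UserWarning, stacklevel=3,
                )
        controls = {
            (e.cell_line, e.production_batch)
            for e in self.entries.values()
            if e.condition == "control"
        }
        control_lines = {line for line, _ in controls}
        for line, cond, form, batch in self.groups():
            if cond != "treated":
                continue
            if (line, batch) not in controls and line not in control_lines:
                raise StructuralError(
                    f"no matched control for treated group "
                    f"(line={line}, formulation={form}, batch={batch})"
                )

    def groups(self) -> dict[tuple[str, str, str | None, str], list[str]]:
        """Wells grouped by (cell_line, condition, formulation_id, batch)."""
        out: dict[tuple[str, str, str | None, str], list[str]] = {}
        for well, e in sorted(self.entries.items()):
            key = (e.cell_line, e.condition, e.formulation_id, e.production_batch)
            out.setdefault(key, []).append(well)
        return out

    def control_wells(self, cell_line: str, production_batch: str) -> list[str]:
        """Control wells matched to a treated group, preferring same batch."""
        same_batch = [
            w for w, e in sorted(self.entries.items())
            if e.condition == "control" and e.cell_line == cell_line
            and e.production_batch == production_batch
        ]
        if same_batch:
            return same_batch
        return [
            w for w, e in sorted(self.entries.items())
            if e.condition == "control" and e.cell_line == cell_line
        ]

    @property
    def cell_lines(self) -> list[str]:
        return sorted({e.cell_line for e in self.entries.values()})


@dataclass(frozen=True)
class CytokineSample:
    """One cytokine measurement (pg/mL) for one sample."""

    sample_id: str
    cell_line: str
    condition: str
    analyte: str
    concentration: float
    below_llod: bool = False

    def __post_init__(self) -> None:
        if self.condition not in ("treated", "control"):
            raise ValidationError(f"bad condition {self.condition!r}")
        if self.analyte not in ANALYTES:
            raise ValidationError(
                f"unknown analyte {self.analyte!r}; expected one of {ANALYTES}"
            )
        if self.concentration < 0:
            raise ValidationError(
                f"{self.sample_id}: negative concentration {self.concentration}"
            )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _sniff_dialect(lines: Sequence[str]) -> str:
    """Decide between the ';'+decimal-comma and ','+decimal-point dialects."""
    for line in lines:
        if ";" in line:
            return "comma"
    return "point"


def _parse_number(cell: str, dec: str, row: int, col: str) -> float:
    s = cell.strip()
    if s == "" or s.lower() in ("na", "nan"):
        return math.nan
    if dec == ",":
        if "." in s:
            raise ParseError(
                f"row {row}, column {col!r}: {cell!r} uses a decimal point in a "
                "decimal-comma file"
            )
        s = s.replace(",", ".")
    try:
        return float(s)
    except ValueError:
        raise ParseError(
            f"row {row}, column {col!r}: non-numeric value {cell!r}"
        ) from None


def _interpolate_gaps(times: np.ndarray, values: np.ndarray, col: str,
                      max_gap: int = 2) -> np.ndarray:
    """Linearly fill runs of <= ``max_gap`` missing points; longer gaps error."""
    v = values.copy()
    isnan = np.isnan(v)
    if not isnan.any():
        return v
    # locate runs of NaN
    idx = np.where(isnan)[0]
    runs: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        if i == runs[-1][-1] + 1:
            runs[-1].append(int(i))
        else:
            runs.append([int(i)])
    for run in runs:
        if len(run) > max_gap:
            raise ValidationError(
                f"column {col!r}: {len(run)} consecutive missing values from "
                f"t={times[run[0]]:g} h (at most {max_gap} may be interpolated)"
            )
        lo, hi = run[0] - 1, run[-1] + 1
        if lo < 0 or hi >= len(v):
            raise ValidationError(
                f"column {col!r}: missing value at the {'start' if lo < 0 else 'end'} "
                "of the series cannot be interpolated"
            )
        v[run] = np.interp(times[run], [times[lo], times[hi]], [v[lo], v[hi]])
    return v


def _read_wide_export(path: str | Path, dialect: str) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    raw = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in raw.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    if not lines:
        raise ValidationError(f"{path}: no data lines")
    if dialect == "auto":
        dialect = _sniff_dialect(lines)
    if dialect == "comma":
        sep, dec = ";", ","
    elif dialect == "point":
        sep, dec = ",", "."
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    header = [h.strip() for h in lines[0].split(sep)]
    if len(header) < 2:
        raise ValidationError(f"{path}: expected a time column plus well columns")
    wells = [normalize_well_id(w) for w in header[1:]]
    if len(set(wells)) != len(wells):
        raise StructuralError(f"{path}: duplicate well columns")

    rows = []
    for r, line in enumerate(lines[1:], start=2):
        cells = line.split(sep)
        if len(cells) != len(header):
            raise ParseError(
                f"row {r}: expected {len(header)} fields, got {len(cells)}"
            )
        rows.append([_parse_number(c, dec, r, header[j]) for j, c in enumerate(cells)])
    data = np.asarray(rows, dtype=float)

    times = data[:, 0]
    if np.isnan(times).any():
        raise ValidationError(f"{path}: missing values in the time column")
    keep = times >= 0
    if not keep.all():
        warnings.warn(
            f"{path}: dropping {int((~keep).sum())} pre-treatment row(s) with "
            "negative elapsed time", UserWarning, stacklevel=2,
        )
        times, data = times[keep], data[keep]
    if np.any(np.diff(times) <= 0):
        raise ValidationError(f"{path}: time column not strictly increasing")

    columns = {}
    for j, well in enumerate(wells, start=1):
        columns[well] = _interpolate_gaps(times, data[:, j], well)
    return times, columns


def read_confluence_export(path: str | Path, dialect: str = "auto") -> list[ConfluenceTrace]:
    """Read a wide confluence CSV into one :class:`ConfluenceTrace` per well.

    ``dialect`` is ``"auto"`` (sniff per file), ``"comma"`` (``;``-separated,
    decimal comma) or ``"point"`` (``,``-separated, decimal point).
    """
    times, columns = _read_wide_export(path, dialect)
    return [ConfluenceTrace(w, times, v) for w, v in columns.items()]


def read_death_export(path: str | Path, dialect: str = "auto") -> list[DeathTrace]:
    """Read a cumulative cell-death CSV (same layout as the confluence export)."""
    times, columns = _read_wide_export(path, dialect)
    return [DeathTrace(w, times, v) for w, v in columns.items()]


_PLATE_COLS = ["well", "cell_line", "condition", "formulation_id",
               "production_batch", "replicate"]


def read_plate_map(path: str | Path) -> PlateMap:
    """Read and validate a plate map CSV."""
    df = pd.read_csv(path, dtype=str, comment="#").fillna("")
    missing = [c for c in _PLATE_COLS if c not in df.columns]
    if missing:
        raise StructuralError(f"{path}: missing plate-map columns {missing}")
    entries: dict[str, PlateEntry] = {}
    for _, row in df.iterrows():
        well = normalize_well_id(row["well"])
        if well in entries:
            raise StructuralError(f"{path}: duplicate well {well}")
        try:
            rep = int(row["replicate"])
        except ValueError:
            raise ParseError(
                f"{path}: non-integer replicate {row['replicate']!r} for well {well}"
            ) from None
        entries[well] = PlateEntry(
            cell_line=row["cell_line"].strip(),
            condition=row["condition"].strip().lower(),
            formulation_id=row["formulation_id"].strip() or None,
            production_batch=row["production_batch"].strip(),
            replicate=rep,
        )
    return PlateMap(entries)


def read_cytokines(path: str | Path) -> list[CytokineSample]:
    """Read a cytokine concentration table (CBA-style pg/mL export)."""
    df = pd.read_csv(path, comment="#")
    needed = ["sample_id", "cell_line", "condition", "analyte",
              "concentration_pg_ml", "below_llod"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise StructuralError(f"{path}: missing cytokine columns {missing}")
    def _bool(x) -> bool:
        if isinstance(x, str):
            return x.strip().lower() in ("true", "1", "yes")
        return bool(x)

    out = []
    for _, row in df.iterrows():
        out.append(CytokineSample(
            sample_id=str(row["sample_id"]),
            cell_line=str(row["cell_line"]),
            condition=str(row["condition"]).lower(),
            analyte=str(row["analyte"]),
            concentration=float(row["concentration_pg_ml"]),
            below_llod=_bool(row["below_llod"]),
        ))
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and math.isnan(obj):
        return None
    return obj


def read_metrics(path: str | Path) -> pd.DataFrame:
    """Read back a metrics.csv written by :func:`write_results`."""
    try:
        return pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame()


def write_results(out_dir: str | Path, *, metrics: pd.DataFrame | None = None,
                  calls=None, qc=None, fsi: pd.DataFrame | None = None,
                  matrix: pd.DataFrame | None = None,
                  similarity: pd.DataFrame | None = None,
                  clusters=None) -> dict[str, Path]:
    """Write the tidy result file set; absent results produce empty files.

    Returns a mapping of logical names to the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _csv(name: str, df: pd.DataFrame | None, index: bool = False) -> None:
        p = out / name
        (df if df is not None else pd.DataFrame()).to_csv(p, index=index)
        written[name] = p

    def _json(name: str, obj) -> None:
        p = out / name
        p.write_text(json.dumps(_jsonable(obj if obj is not None else {}),
                                indent=2, ensure_ascii=False) + "\n",
                     encoding="utf-8")
        written[name] = p

    _csv("metrics.csv", metrics)
    _json("calls.json", calls)
    _json("qc.json", qc)
    _csv("fsi.csv", fsi)
    _csv("compatibility.csv", matrix, index=matrix is not None)
    _csv("similarity.csv", similarity, index=similarity is not None)
    _json("cluster.json", clusters)
    return written
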