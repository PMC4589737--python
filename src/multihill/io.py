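"""Reading and writing dose-response tables; single-curve and batch runs.

The on-disk layout mirrors the tool's tabular convention: a grid whose
fields are, in order, the concentration vector, one field per replicate,
then the concentration unit and finally a title.  The grid may be
column-oriented (each field is a column; concentrations run down the
first column) or row-oriented (the transpose).  CSV is the primary
format; .xlsx is read for fidelity with spreadsheet workflows.

Response scales accepted: ``one_to_zero`` (normalized viability, the
canonical internal scale), ``hundred_to_zero`` (percent viability),
``zero_to_one`` / ``zero_to_hundred`` (inhibition scales, ascending
with dose).  All are converted to the canonical descending-from-1
scale on input and converted back on output.
"""

from __future__ import annotations

import zlib
from dataclasses import replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .fitters import FitSettings
from .objective import SCALE_TAGS, DoseResponseDataset
from .selection import CANDIDATE_ORDER, CLASS_LABELS, SelectionReport, classify, select_model

__all__ = [
    "read_dataset",
    "write_dataset",
    "write_results",
    "run_batch",
    "to_normalized",
    "from_normalized",
]

_TO_NORMALIZED = {
    "one_to_zero": lambda v: v,
    "hundred_to_zero": lambda v: v / 100.0,
    "zero_to_one": lambda v: 1.0 - v,
    "zero_to_hundred": lambda v: 1.0 - v / 100.0,
}
_FROM_NORMALIZED = {
    "one_to_zero": lambda v: v,
    "hundred_to_zero": lambda v: v * 100.0,
    "zero_to_one": lambda v: 1.0 - v,
    "zero_to_hundred": lambda v: (1.0 - v) * 100.0,
}


def to_normalized(values, scale_tag: str):
    """Convert raw effects to the canonical scale (baseline 1, descending)."""
    return _TO_NORMALIZED[scale_tag](np.asarray(values, dtype=float))


def from_normalized(values, scale_tag: str):
    """Exact inverse of :func:`to_normalized`."""
    return _FROM_NORMALIZED[scale_tag](np.asarray(values, dtype=float))


def _read_grid(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        df = pd.read_excel(path, header=None, dtype=object)
    else:
        df = pd.read_csv(path, header=None, dtype=str, skip_blank_lines=True)
    return df.to_numpy(dtype=object)


def _as_float(cell) -> Optional[float]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return np.nan
    if isinstance(cell, (int, float)):
        return float(cell)
    s = str(cell).strip()
    if s == "" or s.lower() == "nan":
        return np.nan
    try:
        return float(s)
    except ValueError:
        return None


def _axis_check(vec) -> tuple[bool, str]:
    """Is this vector a plausible concentration axis (numeric, nonnegative,
    strictly increasing)?  Returns (ok, reason-if-not)."""
    vals = []
    for cell in vec:
        v = _as_float(cell)
        if v is None or np.isnan(v):
            return False, f"non-numeric entry {cell!r}"
        vals.append(v)
    arr = np.asarray(vals)
    if arr.size < 3:
        return False, "fewer than 3 entries"
    if np.any(arr < 0):
        return False, "negative concentrations"
    if np.any(np.diff(arr) <= 0):
        return False, "not strictly increasing"
    return True, ""


def read_dataset(
    path, orientation: str = "auto", scale_tag: str = "one_to_zero"
) -> DoseResponseDataset:
    """Parse a dose-response table into a dataset on the canonical scale.

    ``orientation='auto'`` detects which axis carries the strictly
    increasing concentration vector; ambiguity (both axes qualify) is
    an error asking for an explicit orientation, as is neither axis
    qualifying.
    """
    if scale_tag not in SCALE_TAGS:
        raise ValueError(f"unknown scale_tag {scale_tag!r}; expected one of {SCALE_TAGS}")
    path = Path(path)
    grid = _read_grid(path)
    if grid.ndim != 2 or grid.size == 0:
        raise ValueError(f"{path}: empty or malformed table")

    col_ok, col_why = _axis_check(grid[:, 0])
    row_ok, row_why = _axis_check(grid[0, :])
    if orientation == "auto":
        if col_ok and row_ok:
            raise ValueError(
                f"{path}: both axes look like concentration vectors; "
                "pass orientation='row' or 'column' explicitly"
            )
        if not col_ok and not row_ok:
            raise ValueError(
                f"{path}: no monotone concentration axis found "
                f"(columns: {col_why}; rows: {row_why})"
            )
        orientation = "column" if col_ok else "row"
    elif orientation not in ("row", "column"):
        raise ValueError(f"orientation must be auto/row/column, got {orientation!r}")

    if orientation == "row":
        grid = grid.T
    p = grid.shape[0]

    # columns after the first: replicates until the first column whose
    # leading cell is non-numeric; that one is the unit, the next the title
    n_cols = grid.shape[1]
    meta_start = n_cols
    for j in range(1, n_cols):
        if _as_float(grid[0, j]) is None:
            meta_start = j
            break
    if meta_start == 1:
        raise ValueError(f"{path}: no replicate columns found")
    unit = str(grid[0, meta_start]).strip() if meta_start < n_cols else ""
    title = str(grid[0, meta_start + 1]).strip() if meta_start + 1 < n_cols else ""

    conc = np.array([_as_float(c) for c in grid[:, 0]], dtype=float)
    effects = np.empty((p, meta_start - 1))
    for j in range(1, meta_start):
        for i in range(p):
            v = _as_float(grid[i, j])
            if v is None:
                axis_note = "row" if orientation == "row" else "column"
                raise ValueError(
                    f"{path}: non-numeric effect {grid[i, j]!r} at concentration "
                    f"index {i}, replicate {j} ({axis_note}-oriented grid)"
                )
            effects[i, j - 1] = v

    return DoseResponseDataset(
        concentrations=conc,
        effects=to_normalized(effects, scale_tag),
        unit=unit,
        title=title,
        scale_tag=scale_tag,
    )


def write_dataset(dataset: DoseResponseDataset, path, orientation: str = "column") -> Path:
    """Write a dataset back to CSV in the tabular layout, converting the
    canonical effects back to the dataset's original response scale."""
    path = Path(path)
    effects = from_normalized(dataset.effects, dataset.scale_tag)
    p, n = effects.shape
    n_cols = 1 + n + 2
    grid = np.full((p, n_cols), "", dtype=object)
    grid[:, 0] = [repr(float(c)) for c in dataset.concentrations]
    for j in range(n):
        grid[:, 1 + j] = [
            "" if not np.isfinite(v) else repr(float(v)) for v in effects[:, j]
        ]
    grid[0, 1 + n] = dataset.unit or "unit"
    grid[0, 2 + n] = dataset.title or "untitled"
    if orientation == "row":
        grid = grid.T
    pd.DataFrame(grid).to_csv(path, header=False, index=False)
    return path


def _phase_columns(result, max_phases: int = 3) -> dict:
    cols = {}
    for i in range(max_phases):
        if result is not None and i < result.model.n_phases:
            ph = result.model.phases[i]
            cols[f"phase{i + 1}_role"] = ph.role.value
            cols[f"phase{i + 1}_ec50"] = ph.ec50
            cols[f"phase{i + 1}_h"] = ph.h
            cols[f"phase{i + 1}_e_inf"] = ph.e_inf
        else:
            cols[f"phase{i + 1}_role"] = ""
            cols[f"phase{i + 1}_ec50"] = np.nan
            cols[f"phase{i + 1}_h"] = np.nan
            cols[f"phase{i + 1}_e_inf"] = np.nan
    return cols


def write_results(
    report: SelectionReport, dataset: DoseResponseDataset, path_prefix
) -> dict[str, Path]:
    """Write the candidate table and a dense fitted-curve table.

    ``<prefix>_models.csv`` holds one row per candidate (parameters,
    scaling, chi-square objective F, GOF p, AIC, BIC, convergence and
    the best-model marker); ``<prefix>_curve.csv`` holds model effects
    on a dense log-concentration grid one decade beyond the tested
    range on each side, for plotting.
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    rank_of = {lab: i + 1 for i, lab in enumerate(report.ranking)}
    rows = []
    for label in CANDIDATE_ORDER:
        res = report.candidates[label]
        row = {
            "configuration": label.value,
            "phase_class": CLASS_LABELS[label],
            "rank": rank_of.get(label, np.nan),
            "best": label is report.best,
            "converged": res.converged if res is not None else False,
            "baseline_scale": res.model.baseline_scale if res is not None else np.nan,
            "f_value": res.stats.f_value if res is not None else np.nan,
            "n_obs": res.stats.n_obs if res is not None else np.nan,
            "k_params": res.stats.k_params if res is not None else np.nan,
            "gof_p": res.stats.gof_p if res is not None else np.nan,
            "aic": res.stats.aic if res is not None else np.nan,
            "bic": res.stats.bic if res is not None else np.nan,
            "flags": ";".join(report.flags.get(label, ())),
        }
        row.update(_phase_columns(res))
        rows.append(row)
    models_path = prefix.parent / (prefix.name + "_models.csv")
    pd.DataFrame(rows).to_csv(models_path, index=False)

    pos = dataset.concentrations[dataset.concentrations > 0]
    grid = np.logspace(np.log10(pos.min()) - 1.0, np.log10(pos.max()) + 1.0, 241)
    curve = {"concentration": grid}
    for label in CANDIDATE_ORDER:
        res = report.candidates[label]
        if res is not None:
            curve[label.value] = res.model(grid)
    curve_path = prefix.parent / (prefix.name + "_curve.csv")
    pd.DataFrame(curve).to_csv(curve_path, index=False)
    return {"models": models_path, "curve": curve_path}


def _curve_seed(base_seed: int, curve_id) -> int:
    return int((base_seed ^ zlib.crc32(str(curve_id).encode())) % (2**31 - 1))


def dataset_from_long(sub: pd.DataFrame, curve_id="") -> DoseResponseDataset:
    """Build a dataset from long-format rows (concentration, replicate_id, effect)."""
    pivot = sub.pivot_table(
        index="concentration", columns="replicate_id", values="effect", aggfunc="first"
    ).sort_index()
    return DoseResponseDataset(
        concentrations=pivot.index.to_numpy(dtype=float),
        effects=pivot.to_numpy(dtype=float),
        title=str(curve_id),
    )


def run_batch(
    curves: pd.DataFrame,
    settings: Optional[FitSettings] = None,
    weighting: str = "sd",
    criterion: str = "bic",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model selection for every curve in a long-format table.

    Input columns: ``curve_id, concentration, replicate_id, effect``.
    Each curve gets a deterministic seed derived from ``seed`` and its
    id, so reruns are bit-identical.  A failing curve yields a flagged
    row and never aborts the batch.  Returns the per-curve result table
    and the phase-class histogram (whose counts, including failures,
    sum to the number of input curves).
    """
    required = {"curve_id", "concentration", "replicate_id", "effect"}
    if curves is None or len(curves) == 0:
        raise ValueError("empty batch input")
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"batch input missing columns: {sorted(missing)}")
    settings = settings if settings is not None else FitSettings()

    rows = []
    for cid, sub in curves.groupby("curve_id", sort=False):
        curve_settings = replace(settings, seed=_curve_seed(seed, cid))
        try:
            ds = dataset_from_long(sub, cid)
            report = select_model(
                ds, curve_settings, weighting=weighting, criterion=criterion
            )
            best = report.best_fit
            rows.append(
                {
                    "curve_id": cid,
                    "status": "ok",
                    "best": report.best.value,
                    "phase_class": classify(report),
                    "f_value": best.stats.f_value,
                    "bic": best.stats.bic,
                    "aic": best.stats.aic,
                    "gof_p": best.stats.gof_p,
                    "n_phases": best.model.n_phases,
                    "primary_ec50": best.model.phases[0].ec50,
                    "error": "",
                }
            )
        except Exception as exc:
            rows.append(
                {
                    "curve_id": cid,
                    "status": "failed",
                    "best": "",
                    "phase_class": "failed",
                    "f_value": np.nan,
                    "bic": np.nan,
                    "aic": np.nan,
                    "gof_p": np.nan,
                    "n_phases": 0,
                    "primary_ec50": np.nan,
                    "error": str(exc),
                }
            )
    results = pd.DataFrame(rows)
    class_order = [CLASS_LABELS[lab] for lab in CANDIDATE_ORDER]
    counts = results["phase_class"].value_counts()
    hist_rows = [
        {"phase_class": cls, "count": int(counts.get(cls, 0))} for cls in class_order
    ]
    n_failed = int(counts.get("failed", 0))
    if n_failed:
        hist_rows.append({"phase_class": "failed", "count": n_failed})
    histogram = pd.DataFrame(hist_rows)
    return results, histogram
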