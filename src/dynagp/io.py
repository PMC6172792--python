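"""Matrix file formats, time transforms, plot bundles and SQLite export.

The matrix dialect is a plain TSV: a mandatory header row of time labels,
first column of unique element ids, and finite numeric cells (integers for
counts/depths).  Missing cells are an error — GP fitting handles only
complete rows, and incomplete rows belong in the rejects report upstream.
"""

from __future__ import annotations

import csv
import os
import sqlite3
import tempfile
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gp import ElementSeries, posterior_predict
from .ranking import GPTestResult

__all__ = [
    "MatrixFormatError",
    "read_matrix",
    "write_matrix",
    "read_times",
    "transform_time",
    "PlotBundle",
    "plot_data",
    "plot_gp",
    "export_sqlite",
    "write_results",
]

_KINDS = ("means", "variances", "counts", "depths")


class MatrixFormatError(ValueError):
    """A matrix file violates the TSV dialect."""


def read_matrix(path: str, kind: str = "means") -> tuple[np.ndarray, list[str], list[str]]:
    """Read a TSV matrix; returns ``(values, ids, time_labels)``.

    ``kind`` selects validation: variances must be non-negative;
    counts/depths must be non-negative integers.  Errors carry row/column
    coordinates (1-based, counting the header and id column).
    """
    if kind not in _KINDS:
        raise ValueError(f"kind must be one of {_KINDS}, got {kind!r}")
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise MatrixFormatError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 2:
        raise MatrixFormatError(f"{path}: header must have an id column and time labels")
    labels = [c.strip() for c in header[1:]]
    n = len(labels)
    ids: list[str] = []
    values = np.empty((len(rows) - 1, n))
    for r, row in enumerate(rows[1:], start=2):
        if len(row) != n + 1:
            raise MatrixFormatError(
                f"{path}: row {r} has {len(row)} fields, expected {n + 1}"
            )
        ids.append(row[0].strip())
        for c, cell in enumerate(row[1:], start=2):
            text = cell.strip()
            try:
                val = float(text)
            except ValueError:
                raise MatrixFormatError(
                    f"{path}: non-numeric cell {text!r} at row {r}, column {c}"
                ) from None
            if not np.isfinite(val):
                raise MatrixFormatError(
                    f"{path}: non-finite cell at row {r}, column {c}"
                )
            if kind in ("variances", "counts", "depths") and val < 0:
                raise MatrixFormatError(
                    f"{path}: negative {kind} value {text} at row {r}, column {c}"
                )
            if kind in ("counts", "depths") and val != int(val):
                raise MatrixFormatError(
                    f"{path}: non-integer {kind} value {text} at row {r}, column {c}"
                )
            values[r - 2, c - 2] = val
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise MatrixFormatError(f"{path}: duplicate ids {dupes}")
    if kind in ("counts", "depths"):
        values = values.astype(np.int64)
    return values, ids, labels


def write_matrix(
    path: str,
    values: np.ndarray,
    ids: list[str],
    time_labels: list[str],
    fmt: str = "%.17g",
) -> None:
    """Write a matrix in the TSV dialect (full float precision by default)."""
    values = np.atleast_2d(np.asarray(values))
    if values.shape != (len(ids), len(time_labels)):
        raise ValueError(
            f"shape {values.shape} inconsistent with {len(ids)} ids and "
            f"{len(time_labels)} time labels"
        )
    is_int = np.issubdtype(values.dtype, np.integer)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(time_labels) + "\n")
        for i, rid in enumerate(ids):
            cells = (
                [str(int(x)) for x in values[i]]
                if is_int
                else [fmt % x for x in values[i]]
            )
            fh.write(str(rid) + "\t" + "\t".join(cells) + "\n")


def read_times(spec: str) -> np.ndarray:
    """Parse a time vector from a comma-separated string or a file path.

    A file holds one time per line (or a single comma-separated line).
    """
    if os.path.exists(spec):
        with open(spec, encoding="utf-8") as fh:
            text = fh.read()
        parts = text.replace(",", "\n").split()
    else:
        parts = [p for p in spec.split(",") if p.strip()]
    try:
        t = np.array([float(p) for p in parts])
    except ValueError as exc:
        raise ValueError(f"cannot parse time points from {spec!r}: {exc}") from None
    if t.size == 0:
        raise ValueError(f"no time points found in {spec!r}")
    return t


def transform_time(
    t: np.ndarray, method: str = "identity", offset: float = 5.0
) -> np.ndarray:
    """Optionally map times through ln(offset + t).

    The log transform compresses the long tail of geometric sampling
    designs so that a stationary kernel is a reasonable model; natural
    logarithm throughout.
    """
    t = np.asarray(t, dtype=float).ravel()
    if method == "identity":
        return t.copy()
    if method == "log_offset":
        if np.any(t + offset <= 0):
            bad = float(t[np.argmax(t + offset <= 0)])
            raise ValueError(
                f"log_offset transform undefined at t={bad} with offset {offset}"
            )
        return np.log(offset + t)
    raise ValueError(f"unknown time transform {method!r}")


@dataclass(frozen=True)
class PlotBundle:
    """Everything needed to draw one fitted element."""

    id: str
    times: np.ndarray
    y: np.ndarray
    yerr: np.ndarray  # 2 * sqrt(v): error bars from the fixed variances
    grid: np.ndarray
    pred_mean: np.ndarray
    pred_sd: np.ndarray  # latent-function SD; band is mean +/- 2 * sd
    ln_bf: float


def plot_data(
    series: ElementSeries, result: GPTestResult, grid_size: int = 200
) -> PlotBundle:
    """Dense prediction grid plus observation error bars for plotting.

    The shaded band is the 2-SD region of the latent function under the
    fitted time-dependent model; error bars are 2 SDs of the fixed
    per-observation variances, as obtained upstream.
    """
    grid = np.linspace(series.times[0], series.times[-1], grid_size)
    mean, var = posterior_predict(series, result.fit_dep, grid)
    return PlotBundle(
        id=series.id,
        times=series.times.copy(),
        y=series.means.copy(),
        yerr=2.0 * np.sqrt(series.fixed_variances),
        grid=grid,
        pred_mean=mean,
        pred_sd=np.sqrt(var),
        ln_bf=result.ln_bf,
    )


def plot_gp(bundle: PlotBundle, path: str | None = None, ax=None):
    """Draw the fitted GP profile (matplotlib)."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(
        bundle.grid,
        bundle.pred_mean - 2 * bundle.pred_sd,
        bundle.pred_mean + 2 * bundle.pred_sd,
        alpha=0.25,
        color="gray",
        label="2 SD band",
    )
    ax.plot(bundle.grid, bundle.pred_mean, color="black", label="GP mean")
    ax.errorbar(
        bundle.times, bundle.y, yerr=bundle.yerr, fmt="o", color="black", capsize=3
    )
    ax.set_xlabel("time")
    ax.set_ylabel("abundance")
    ax.set_title(f"{bundle.id}  (ln BF = {bundle.ln_bf:.2f})")
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


_SCHEMA = """
CREATE TABLE results (
    id TEXT PRIMARY KEY, rank INTEGER, ln_bf REAL, posterior_prob REAL,
    lengthscale REAL, signal_variance REAL,
    noise_variance_dep REAL, noise_variance_null REAL,
    lml_dep REAL, lml_null REAL,
    lengthscale_lower_bound REAL, noise_lower_bound REAL,
    converged_dep INTEGER, converged_null INTEGER
);
CREATE TABLE series (
    id TEXT, time_index INTEGER, t REAL, y REAL, v REAL,
    pred_mean REAL, pred_sd REAL,
    FOREIGN KEY (id) REFERENCES results (id)
);
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
"""


def export_sqlite(
    table: pd.DataFrame,
    series_results: list[tuple[ElementSeries, GPTestResult]],
    path: str,
    meta: dict | None = None,
) -> None:
    """Write ranked results and per-point predictions to an SQLite file.

    The export is all-or-nothing: the database is built in a temporary file
    and atomically moved over ``path``, so a failed export never leaves a
    half-written database behind.
    """
    by_id = {s.id: (s, r) for s, r in series_results}
    table_ids = set(table["id"]) if len(table) else set()
    missing = table_ids - set(by_id)
    if missing:
        raise ValueError(f"no series/prediction data for ids {sorted(missing)}")

    bounds: dict[str, tuple[float, float]] = {
        s.id: (r.fit_dep.lengthscale_lower_bound, r.fit_dep.noise_lower_bound)
        for s, r in series_results
    }
    fd, tmp = tempfile.mkstemp(
        suffix=".sqlite", dir=os.path.dirname(os.path.abspath(path)) or "."
    )
    os.close(fd)
    try:
        con = sqlite3.connect(tmp)
        try:
            con.executescript(_SCHEMA)
            for row in table.itertuples(index=False):
                lb, nb = bounds[row.id]
                con.execute(
                    "INSERT INTO results VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                    (
                        row.id,
                        int(row.rank),
                        float(row.ln_bf),
                        float(row.posterior_prob),
                        float(row.lengthscale),
                        float(row.signal_variance),
                        float(row.noise_variance_dep),
                        float(row.noise_variance_null),
                        float(row.lml_dep),
                        float(row.lml_null),
                        lb,
                        nb,
                        int(row.converged_dep),
                        int(row.converged_null),
                    ),
                )
            for sid in sorted(table_ids):
                series, result = by_id[sid]
                mean, var = posterior_predict(series, result.fit_dep, series.times)
                sd = np.sqrt(var)
                for k in range(series.n):
                    con.execute(
                        "INSERT INTO series VALUES (?,?,?,?,?,?,?)",
                        (
                            sid,
                            k,
                            float(series.times[k]),
                            float(series.means[k]),
                            float(series.fixed_variances[k]),
                            float(mean[k]),
                            float(sd[k]),
                        ),
                    )
            for key, value in (meta or {}).items():
                con.execute("INSERT INTO meta VALUES (?,?)", (str(key), str(value)))
            con.commit()
        finally:
            con.close()
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_results(table: pd.DataFrame, path: str) -> None:
    """Write the rank table as TSV (%.10g float formatting, stable order)."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
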