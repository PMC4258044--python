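"""Long-format CSV input and JSON/TSV report output.

Input is one record per (subject, rater, replicate) with a numeric response;
the replicate column may be omitted for single-measurement designs.  Labels
are opaque strings; subjects and raters are ordered by first appearance.
"""

from __future__ import annotations

import json
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .anova import VarianceComponents, point_icc_b, point_icc_w
from .design import DataGrid, DesignSpec
from .errors import BalanceError
from .results import IntervalResult

__all__ = ["read_long_csv", "write_long_csv", "grid_to_frame", "write_report"]

DEFAULT_COLUMNS = {"subject": "subject", "rater": "rater", "replicate": "replicate", "value": "value"}


def _package_version() -> str:
    try:
        return version("icc-intervals")
    except PackageNotFoundError:  # pragma: no cover
        return "unknown"


def grid_to_frame(grid: DataGrid, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    d = grid.design
    rows = []
    for b in range(d.b0):
        for l in range(d.l0):
            for r in range(d.r0):
                rows.append(
                    {
                        cols["subject"]: grid.subject_labels[b],
                        cols["rater"]: grid.rater_labels[l],
                        cols["replicate"]: r + 1,
                        cols["value"]: grid.values[b, l, r],
                    }
                )
    return pd.DataFrame(rows)


def write_long_csv(grid: DataGrid, path: str | Path, column_map: dict[str, str] | None = None) -> None:
    grid_to_frame(grid, column_map).to_csv(path, index=False)


def read_long_csv(path: str | Path, column_map: dict[str, str] | None = None) -> DataGrid:
    """Read and validate a long-format CSV into a :class:`DataGrid`.

    Raises :class:`BalanceError` naming offending (subject, rater) pairs
    when the crossing is incomplete or uneven, and ``ValueError`` with the
    row number for non-numeric responses.
    """
    cols = {**DEFAULT_COLUMNS, **(column_map or {})}
    df = pd.read_csv(path, dtype=str)
    for key in ("subject", "rater", "value"):
        if cols[key] not in df.columns:
            raise ValueError(f"missing required column {cols[key]!r} in {path}")
    values = pd.to_numeric(df[cols["value"]], errors="coerce")
    bad = values.isna() | ~np.isfinite(values)
    if bad.any():
        row = int(bad.idxmax()) + 2  # 1-based, plus header line
        raise ValueError(f"non-numeric value in column {cols['value']!r} at line {row}")
    subjects = list(dict.fromkeys(df[cols["subject"]]))
    raters = list(dict.fromkeys(df[cols["rater"]]))
    counts = df.groupby([cols["subject"], cols["rater"]], sort=False).size()
    r0 = int(counts.max())
    missing = []
    for s in subjects:
        for r in raters:
            if counts.get((s, r), 0) != r0:
                missing.append((s, r))
    if missing:
        shown = ", ".join(f"({s}, {r})" for s, r in missing[:5])
        raise BalanceError(
            f"incomplete or unbalanced grid; offending (subject, rater) pairs: {shown}"
            + ("..." if len(missing) > 5 else "")
        )
    design = DesignSpec(b0=len(subjects), l0=len(raters), r0=r0)
    grid_values = np.empty((design.b0, design.l0, design.r0))
    s_idx = {s: i for i, s in enumerate(subjects)}
    r_idx = {r: i for i, r in enumerate(raters)}
    rep_counter: dict[tuple[str, str], int] = {}
    for row_s, row_r, val in zip(df[cols["subject"]], df[cols["rater"]], values):
        k = rep_counter.get((row_s, row_r), 0)
        grid_values[s_idx[row_s], r_idx[row_r], k] = val
        rep_counter[(row_s, row_r)] = k + 1
    return DataGrid(
        values=grid_values,
        design=design,
        subject_labels=[str(s) for s in subjects],
        rater_labels=[str(r) for r in raters],
    )


def write_report(
    results: Iterable[IntervalResult],
    design: DesignSpec,
    components: VarianceComponents | None = None,
    path: str | Path | None = None,
    fmt: str = "json",
    notes: list[str] | None = None,
) -> str:
    """Serialize interval results plus point estimates to JSON or TSV.

    The report embeds the design, the per-method Monte Carlo settings and
    seeds, and the software version, so any row can be recomputed.  Returns
    the serialized text; also writes it when ``path`` is given.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to report")
    point: dict[str, float] = {}
    if components is not None:
        point = {
            "icc_b": point_icc_b(components),
            "icc_w": point_icc_w(components),
        }
    payload = {
        "software": {"name": "icc-intervals", "version": _package_version()},
        "design": {"b0": design.b0, "l0": design.l0, "r0": design.r0},
        "notes": list(notes or []),
        "point_estimates": point,
        "intervals": [
            {
                "method": res.method,
                "level": res.level,
                "lower": res.lower,
                "upper": res.upper,
                "meta": {k: _jsonable(v) for k, v in res.meta.items()},
            }
            for res in results
        ],
    }
    if fmt == "json":
        text = json.dumps(payload, indent=2)
    elif fmt == "tsv":
        lines = ["method\tlevel\tlower\tupper\ticc_b\ticc_w\tb0\tl0\tr0\tversion"]
        for res in results:
            lines.append(
                "\t".join(
                    [
                        res.method,
                        f"{res.level:g}",
                        f"{res.lower:.6f}",
                        f"{res.upper:.6f}",
                        f"{point.get('icc_b', float('nan')):.6f}",
                        f"{point.get('icc_w', float('nan')):.6f}",
                        str(design.b0),
                        str(design.l0),
                        str(design.r0),
                        _package_version(),
                    ]
                )
            )
        text = "\n".join(lines) + "\n"
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, (str, int, float, bool)) or v is None:
        return v
    return str(v)
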