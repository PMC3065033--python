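"""Plain-text readers and writers.

Two input files drive an analysis: a square synchronization matrix (plain
ASCII, whitespace- or comma-delimited) and an electrode montage whose first
column is the electrode label followed by 2 (x, y) or 3 (x, y, z) numeric
coordinate columns.  Outputs are CSV/JSON metric reports, layout CSVs, edge
lists, and a minimal SVG rendering.

Readers reject malformed input outright — ragged rows, non-numeric cells and
duplicate labels are errors that name the offending row/column — rather than
silently coercing it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputFormatError
from .network import WeightedNetwork, default_labels

__all__ = [
    "Montage",
    "MetricReport",
    "read_sync_matrix",
    "write_sync_matrix",
    "read_montage",
    "write_montage",
    "write_metric_report",
    "read_metric_report",
    "write_layout",
    "read_layout",
    "export_edges",
    "render_svg",
]

# SVG styling constants: fixed and documented rather than configurable.
# Node circles have radius 6 in a 600x600 viewport with a 40px margin;
# the colormap ramp runs from blue (weakest edge) to red (strongest).
SVG_SIZE = 600
SVG_MARGIN = 40
SVG_NODE_RADIUS = 6


@dataclass(frozen=True)
class Montage:
    """Labelled electrode coordinates (2-D or 3-D)."""

    labels: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] not in (2, 3):
            raise InputFormatError(
                f"montage coordinates must be n x 2 or n x 3, got {coords.shape}"
            )
        labels = tuple(self.labels)
        if len(labels) != coords.shape[0]:
            raise InputFormatError("label count does not match coordinate rows")
        seen = set()
        for lab in labels:
            if lab in seen:
                raise InputFormatError(f"duplicate electrode label {lab!r}")
            seen.add(lab)
        coords = coords.copy()
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "labels", labels)

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


@dataclass
class MetricReport:
    """Container pairing global scalars with the per-vertex metric table."""

    global_metrics: dict[str, float] = field(default_factory=dict)
    vertex_metrics: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(index=pd.Index([], name="label"))
    )

    def __post_init__(self) -> None:
        if self.vertex_metrics.index.name is None:
            self.vertex_metrics.index.name = "label"


# -- delimiter handling ----------------------------------------------------


def _tokenize(lines: list[str], what: str) -> list[list[str]]:
    """Split lines on the auto-detected delimiter (whitespace, then comma)."""
    use_comma = any("," in ln for ln in lines)
    rows = []
    for idx, ln in enumerate(lines):
        if use_comma:
            toks = [t.strip() for t in ln.split(",")]
            if any(" " in t or "\t" in t for t in toks):
                raise InputFormatError(
                    f"{what}: row {idx + 1} mixes comma and whitespace delimiters"
                )
        else:
            toks = ln.split()
        if any(t == "" for t in toks):
            raise InputFormatError(f"{what}: empty field in row {idx + 1}")
        rows.append(toks)
    return rows


def _parse_float(tok: str, row: int, col: int, what: str) -> float:
    try:
        return float(tok)
    except ValueError:
        raise InputFormatError(
            f"{what}: non-numeric value {tok!r} at row {row + 1}, column {col + 1}"
        ) from None


# -- synchronization matrix ------------------------------------------------


def read_sync_matrix(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a square synchronization matrix; returns ``(matrix, n)``.

    Accepts whitespace- or comma-delimited plain ASCII with no header.
    """
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise InputFormatError(f"{path}: empty matrix file")
    rows = _tokenize(lines, str(path))
    n_cols = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != n_cols:
            raise InputFormatError(
                f"{path}: ragged row {i + 1} has {len(row)} fields, expected {n_cols}"
            )
    matrix = np.array(
        [
            [_parse_float(tok, i, j, str(path)) for j, tok in enumerate(row)]
            for i, row in enumerate(rows)
        ]
    )
    if matrix.shape[0] != matrix.shape[1]:
        raise InputFormatError(
            f"{path}: matrix is {matrix.shape[0]} x {matrix.shape[1]}, not square"
        )
    return matrix, matrix.shape[0]


def read_timeseries(path: str | Path) -> np.ndarray:
    """Read a samples-by-channels numeric block (one row per sample)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise InputFormatError(f"{path}: empty time-series file")
    rows = _tokenize(lines, str(path))
    n_cols = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != n_cols:
            raise InputFormatError(
                f"{path}: ragged row {i + 1} has {len(row)} fields, expected {n_cols}"
            )
    return np.array(
        [
            [_parse_float(tok, i, j, str(path)) for j, tok in enumerate(row)]
            for i, row in enumerate(rows)
        ]
    )


def write_sync_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a matrix as whitespace-delimited ASCII at full float precision."""
    matrix = np.asarray(matrix, dtype=float)
    with open(path, "w") as fh:
        for row in matrix:
            fh.write(" ".join(f"{x:.17g}" for x in row) + "\n")


# -- montage ---------------------------------------------------------------


def read_montage(path: str | Path) -> Montage:
    """Read an electrode montage file: label column + 2 or 3 coordinates."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()]
    lines = [ln for ln in lines if ln and not ln.startswith("#")]
    if not lines:
        raise InputFormatError(f"{path}: empty montage file")
    rows = _tokenize(lines, str(path))
    n_coord = len(rows[0]) - 1
    if n_coord not in (2, 3):
        raise InputFormatError(
            f"{path}: expected 2 or 3 coordinate columns, found {n_coord}"
        )
    labels: list[str] = []
    coords: list[list[float]] = []
    for i, row in enumerate(rows):
        if len(row) - 1 != n_coord:
            raise InputFormatError(
                f"{path}: row {i + 1} has {len(row) - 1} coordinate columns, "
                f"expected {n_coord}"
            )
        label = row[0]
        try:
            float(label)
        except ValueError:
            pass
        else:
            raise InputFormatError(
                f"{path}: row {i + 1} starts with numeric value {label!r}; "
                "the first column must be an electrode label"
            )
        if label in labels:
            raise InputFormatError(f"{path}: duplicate electrode label {label!r}")
        labels.append(label)
        coords.append(
            [_parse_float(tok, i, j + 1, str(path)) for j, tok in enumerate(row[1:])]
        )
    return Montage(tuple(labels), np.array(coords))


def write_montage(montage: Montage, path: str | Path) -> None:
    with open(path, "w") as fh:
        for label, row in zip(montage.labels, montage.coords):
            fh.write(label + " " + " ".join(f"{x:.17g}" for x in row) + "\n")


# -- metric reports --------------------------------------------------------


def _fmt(x: float) -> str:
    """Format with >= 10 significant digits; NaN marks undefined metrics."""
    if isinstance(x, float) and math.isnan(x):
        return "nan"
    return f"{float(x):.12g}"


def write_metric_report(report: MetricReport, path: str | Path, format: str = "csv") -> None:
    """Write the metric report as CSV (vertex table + ``#global`` lines) or JSON."""
    path = Path(path)
    if format == "csv":
        with open(path, "w") as fh:
            for name, value in report.global_metrics.items():
                fh.write(f"#global,{name},{_fmt(value)}\n")
            df = report.vertex_metrics
            fh.write(",".join(["label", *df.columns]) + "\n")
            for label, row in df.iterrows():
                fh.write(",".join([str(label), *(_fmt(v) for v in row)]) + "\n")
    elif format == "json":
        payload = {
            "global": {k: (None if math.isnan(v) else v) for k, v in report.global_metrics.items()},
            "vertex": [
                {"label": str(label), **{c: (None if math.isnan(row[c]) else row[c]) for c in report.vertex_metrics.columns}}
                for label, row in report.vertex_metrics.iterrows()
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
    else:
        raise InputFormatError(f"unknown report format {format!r}; use 'csv' or 'json'")


def read_metric_report(path: str | Path, format: str = "csv") -> MetricReport:
    path = Path(path)
    if format == "csv":
        global_metrics: dict[str, float] = {}
        lines = path.read_text().splitlines()
        data_lines = []
        for ln in lines:
            if ln.startswith("#global,"):
                _, name, value = ln.split(",", 2)
                global_metrics[name] = float(value)
            elif ln.strip():
                data_lines.append(ln)
        header = data_lines[0].split(",")
        records = [ln.split(",") for ln in data_lines[1:]]
        df = pd.DataFrame(records, columns=header)
        df = df.set_index("label")
        df = df.apply(pd.to_numeric)
        return MetricReport(global_metrics, df)
    if format == "json":
        payload = json.loads(path.read_text())
        vm = payload.get("vertex", [])
        if vm:
            df = pd.DataFrame(vm).set_index("label").astype(float)
        else:
            df = pd.DataFrame(index=pd.Index([], name="label"))
        gm = {
            k: (float("nan") if v is None else float(v))
            for k, v in payload.get("global", {}).items()
        }
        return MetricReport(gm, df)
    raise InputFormatError(f"unknown report format {format!r}")


# -- layouts and edges -----------------------------------------------------


def write_layout(layout, path: str | Path) -> None:
    """Write per-vertex 2-D coordinates as ``label,x,y`` CSV."""
    with open(path, "w") as fh:
        fh.write("label,x,y\n")
        for label, (x, y) in zip(layout.labels, layout.coords):
            fh.write(f"{label},{x:.17g},{y:.17g}\n")


def read_layout(path: str | Path) -> tuple[tuple[str, ...], np.ndarray]:
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].strip() != "label,x,y":
        raise InputFormatError(f"{path}: expected 'label,x,y' header")
    labels, coords = [], []
    for i, ln in enumerate(lines[1:]):
        if not ln.strip():
            continue
        parts = ln.split(",")
        if len(parts) != 3:
            raise InputFormatError(f"{path}: row {i + 2} does not have 3 fields")
        labels.append(parts[0])
        coords.append([_parse_float(parts[1], i + 1, 2, str(path)),
                       _parse_float(parts[2], i + 1, 3, str(path))])
    return tuple(labels), np.array(coords)


def export_edges(net: WeightedNetwork, path: str | Path) -> None:
    """Write the edge list as ``source,target,weight`` CSV."""
    with open(path, "w") as fh:
        fh.write("source,target,weight\n")
        for u, v, w in net.edges():
            fh.write(f"{net.labels[u]},{net.labels[v]},{w:.17g}\n")


# -- SVG rendering ---------------------------------------------------------


def _edge_colour(weight: float, style: str) -> str:
    """Stroke colour for an edge of the given weight.

    greyscale: weight 1 -> black, weight near 0 -> light grey.
    colormap: blue (weak) to red (strong) linear ramp.
    uniform: black regardless of weight.
    """
    w = min(max(float(weight), 0.0), 1.0)
    if style == "greyscale":
        level = round(230 * (1.0 - w))
        return f"rgb({level},{level},{level})"
    if style == "colormap":
        return f"rgb({round(255 * w)},0,{round(255 * (1 - w))})"
    if style == "uniform":
        return "rgb(0,0,0)"
    raise InputFormatError(f"unknown edge style {style!r}")


def render_svg(
    net: WeightedNetwork,
    layout,
    path: str | Path,
    style: str = "greyscale",
    show_labels: bool = True,
) -> None:
    """Render the network at the given layout into a standalone SVG file.

    Edge stroke encodes weight via ``style``; node circles are uniform.
    """
    if tuple(layout.labels) != tuple(net.labels):
        raise InputFormatError(
            "layout and network label sets differ; cannot render"
        )
    coords = np.asarray(layout.coords, dtype=float)
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    scale = (SVG_SIZE - 2 * SVG_MARGIN) / span.max()

    def to_px(p):
        q = (p - (lo + hi) / 2) * scale + SVG_SIZE / 2
        return q[0], SVG_SIZE - q[1]  # flip y: SVG origin is top-left

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{SVG_SIZE}" '
        f'height="{SVG_SIZE}" viewBox="0 0 {SVG_SIZE} {SVG_SIZE}">'
    ]
    for u, v, w in net.edges():
        x1, y1 = to_px(coords[u])
        x2, y2 = to_px(coords[v])
        parts.append(
            f'<line x1="{x1:.2f}" y1="{y1:.2f}" x2="{x2:.2f}" y2="{y2:.2f}" '
            f'stroke="{_edge_colour(w, style)}" stroke-width="1.5"/>'
        )
    for label, p in zip(net.labels, coords):
        x, y = to_px(p)
        parts.append(
            f'<circle cx="{x:.2f}" cy="{y:.2f}" r="{SVG_NODE_RADIUS}" '
            f'fill="rgb(60,60,60)"/>'
        )
        if show_labels:
            parts.append(
                f'<text x="{x + 8:.2f}" y="{y - 8:.2f}" font-size="10">{label}</text>'
            )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n")
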