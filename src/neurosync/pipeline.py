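"""End-to-end analysis pipeline.

``run_pipeline`` chains the full workflow — read (or simulate) a
multichannel series or a ready-made synchronization matrix, estimate
connectivity, threshold into a network, compute global and vertex metrics,
lay the network out, and export everything (report, layout CSV, edge list,
SVG, provenance JSON) into an output directory.

The :class:`RunConfig` is validated up front, before any computation, and
is serialized verbatim into the provenance record so a run can be
reproduced bit-identically from that file alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .connectivity import (
    BANDS,
    EmbeddingParams,
    TimeSeriesSet,
    WelchParams,
    connectivity_matrix,
)
from .errors import ConfigError, InputFormatError
from .io import (
    MetricReport,
    export_edges,
    read_montage,
    read_sync_matrix,
    read_timeseries,
    render_svg,
    write_layout,
    write_metric_report,
    write_sync_matrix,
)
from .layouts import bstress_layout, mds_layout, static_layout
from .metrics_global import compute_global_metrics
from .metrics_vertex import compute_vertex_metrics
from .network import threshold_network
from .synth import gen_eeg_like, gen_montage

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

_METHODS = ("msc", "rim", "pdc")
_LAYOUTS = ("static", "mds", "bstress")
_MODES = ("binary", "greyscale")
_TRANSFORMS = ("inverse", "log2")


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run."""

    # inputs: either a time-series file, a matrix file, or synthetic data
    timeseries: str | None = None
    matrix: str | None = None
    montage: str | None = None
    synthetic_channels: int | None = None

    method: str = "msc"
    band: str | None = None  # named band or "lo:hi" in Hz
    fs: float = 128.0
    threshold: float = 0.4
    mode: str = "binary"
    length_transform: str = "inverse"
    metrics: str = "degree,efficiency,betweenness,eigenvector,hubbell,subgraph,entropy"
    layout: str = "static"
    seed: int = 0
    out_dir: str = "neurosync_out"
    log_level: str = "INFO"
    # estimator knobs
    var_order: int = 2
    emb_m: int = 5
    emb_tau: int = 1
    emb_k: int = 10
    welch_nperseg: int = 256
    n_samples: int = 2048

    def validate(self) -> None:
        if self.method not in _METHODS:
            raise ConfigError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.mode not in _MODES:
            raise ConfigError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.layout not in _LAYOUTS:
            raise ConfigError(f"layout must be one of {_LAYOUTS}, got {self.layout!r}")
        if self.length_transform not in _TRANSFORMS:
            raise ConfigError(
                f"length_transform must be one of {_TRANSFORMS}, "
                f"got {self.length_transform!r}"
            )
        if not 0.0 <= self.threshold <= 1.0:
            raise ConfigError(f"threshold must lie in [0, 1], got {self.threshold}")
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        sources = [self.timeseries, self.matrix, self.synthetic_channels]
        if sum(s is not None for s in sources) != 1:
            raise ConfigError(
                "exactly one input source required: timeseries=, matrix=, or "
                "synthetic_channels="
            )
        for path in (self.timeseries, self.matrix, self.montage):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"input file does not exist: {path}")
        self.parse_band()

    def parse_band(self) -> tuple[float, float] | None:
        if self.band is None or self.band in ("", "broadband"):
            return None
        if self.band in BANDS:
            return BANDS[self.band]
        try:
            lo, hi = (float(x) for x in self.band.split(":"))
        except ValueError:
            raise ConfigError(
                f"band must be a named band {sorted(BANDS)}, 'lo:hi' in Hz, or "
                f"'broadband'; got {self.band!r}"
            ) from None
        if not 0 <= lo < hi:
            raise ConfigError(f"band limits must satisfy 0 <= lo < hi, got {self.band}")
        return lo, hi


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file into a RunConfig."""
    cfg = RunConfig()
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    for i, raw in enumerate(Path(path).read_text().splitlines()):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}: line {i + 1} is not 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key not in fields:
            raise ConfigError(f"{path}: unknown config key {key!r} on line {i + 1}")
        ftype = fields[key].type
        if value.lower() in ("none", ""):
            parsed = None
        elif "int" in str(ftype):
            parsed = int(value)
        elif "float" in str(ftype):
            parsed = float(value)
        else:
            parsed = value
        setattr(cfg, key, parsed)
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict of artifact paths."""
    config.validate()
    band = config.parse_band()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    input_hashes = {}
    for name in ("timeseries", "matrix", "montage"):
        path = getattr(config, name)
        if path is not None:
            input_hashes[name] = _sha256(Path(path))

    # ---- stage 1: obtain the synchronization matrix ----------------------
    conn_params: dict = {}
    if config.matrix is not None:
        matrix, n = read_sync_matrix(config.matrix)
        labels = None
        logger.info("stage=read_matrix n=%d sha=%s", n, input_hashes.get("matrix"))
    else:
        if config.timeseries is not None:
            raw = read_timeseries(config.timeseries)
            ts = TimeSeriesSet(raw, fs=config.fs)
        else:
            ts = gen_eeg_like(
                n_channels=config.synthetic_channels,
                n_samples=config.n_samples,
                seed=config.seed,
                fs=config.fs,
            )
        result = connectivity_matrix(
            ts,
            method=config.method,
            band=band,
            welch=WelchParams(nperseg=config.welch_nperseg),
            emb=EmbeddingParams(m=config.emb_m, tau=config.emb_tau, k=config.emb_k),
            order=config.var_order,
        )
        matrix = result.matrix
        labels = result.labels
        conn_params = result.params
        write_sync_matrix(matrix, out / "sync_matrix.txt")
        logger.info(
            "stage=connectivity method=%s pairs=%s",
            config.method, conn_params.get("n_pair_evaluations"),
        )

    # ---- stage 2: montage ------------------------------------------------
    if config.montage is not None:
        montage = read_montage(config.montage)
        if labels is None:
            labels = montage.labels
    else:
        montage = gen_montage(matrix.shape[0])
        if labels is None:
            labels = montage.labels
    if len(labels) != matrix.shape[0]:
        raise InputFormatError(
            f"montage has {len(labels)} electrodes but the matrix is "
            f"{matrix.shape[0]} x {matrix.shape[0]}"
        )

    # ---- stage 3: network ------------------------------------------------
    directed = config.method == "pdc" and config.matrix is None
    net = threshold_network(
        matrix, config.threshold, mode=config.mode, directed=directed, labels=labels
    )
    logger.info("stage=network edges=%d mode=%s", net.n_edges, net.mode)

    # ---- stage 4: metrics ------------------------------------------------
    metric_names = tuple(m.strip() for m in config.metrics.split(",") if m.strip())
    vertex_df = compute_vertex_metrics(net, metric_names, fn=config.length_transform)
    try:
        global_metrics = compute_global_metrics(net, fn=config.length_transform).as_dict()
    except Exception as exc:  # empty networks: record the failure, keep going
        logger.warning("global metrics unavailable: %s", exc)
        global_metrics = {}
    report = MetricReport(global_metrics, vertex_df)
    write_metric_report(report, out / "metrics.csv", "csv")
    write_metric_report(report, out / "metrics.json", "json")
    logger.info("stage=metrics n_vertex_metrics=%d", len(vertex_df.columns))

    # ---- stage 5: layout + rendering ------------------------------------
    if config.layout == "static":
        layout = static_layout(montage)
        layout = dataclasses.replace(layout, labels=net.labels)
    elif config.layout == "mds":
        layout = mds_layout(net, fn=config.length_transform)
    else:
        layout = bstress_layout(net, seed=config.seed)
    write_layout(layout, out / "layout.csv")
    export_edges(net, out / "edges.csv")
    style = "greyscale" if config.mode == "greyscale" else "uniform"
    render_svg(net, layout, out / "network.svg", style=style)
    logger.info("stage=layout method=%s", config.layout)

    # ---- provenance ------------------------------------------------------
    provenance = {
        "neurosync_version": __version__,
        "config": dataclasses.asdict(config),
        "input_hashes": input_hashes,
        "connectivity_params": {
            k: v for k, v in conn_params.items() if isinstance(v, (int, float, str, type(None), tuple, list))
        },
        "n_vertices": net.n_vertices,
        "n_edges": net.n_edges,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str) + "\n")
    return {
        "out_dir": str(out),
        "n_vertices": net.n_vertices,
        "n_edges": net.n_edges,
        "artifacts": sorted(p.name for p in out.iterdir()),
    }
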