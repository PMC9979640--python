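"""CSV/JSON/GraphML input and output.

All tables are plain CSV with explicit headers and units in column names;
networks are additionally exported as GraphML for standard graph tooling.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .params import Hyperparams, PhysicalParams
from .tables import (BulkSeries, CellFrame, FluxSolution, ProbeFrame,
                     TableValidationError)

log = logging.getLogger(__name__)

CELLS_REQUIRED = ["frame_index", "time_min", "cell_id", "x_um", "y_um"]
PROBES_REQUIRED = ["frame_index", "time_min", "probe_id", "x_um", "y_um", "pH", "sigma"]
BULK_REQUIRED = ["time_min", "bulk_pH"]


def _read_csv_strict(path, required, numeric):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path.name}: missing required column(s) {missing}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or coerced.isna().any():
            rows = [int(i) + 2 for i in df.index[coerced.isna()]]  # +2: header + 1-based
            raise TableValidationError(
                f"{path.name}: non-numeric or missing value in column {col!r} "
                f"at line(s) {rows[:10]}"
            )
        df[col] = coerced
    return df


def _split_frames(df, make_frame, path_name):
    frames = []
    order = df.groupby("frame_index")["time_min"].first().sort_values()
    if not order.index.is_monotonic_increasing:
        log.warning("%s: frames supplied out of time order; sorted by time", path_name)
    for fi in order.index:
        sub = df[df["frame_index"] == fi]
        t = float(sub["time_min"].iloc[0])
        frames.append(make_frame(int(fi), t, sub.reset_index(drop=True)))
    return frames


def read_cells_csv(path, params: PhysicalParams | None = None) -> list:
    """Read a cells.csv into a time-sorted list of CellFrame."""
    df = _read_csv_strict(path, CELLS_REQUIRED,
                          ["frame_index", "time_min", "x_um", "y_um"])
    if "cell_type" not in df.columns:
        df["cell_type"] = "unknown"
    frames = _split_frames(
        df, lambda fi, t, sub: CellFrame(fi, t, sub[["cell_id", "x_um", "y_um", "cell_type"]]),
        Path(path).name)
    if params is not None:
        for f in frames:
            f.validate_bounds(params.frame_size_L)
    return frames


def read_probes_csv(path) -> list:
    """Read a probes.csv into a time-sorted list of ProbeFrame.

    Schema violations (sigma <= 0, pH out of range, missing columns) raise
    with the offending rows identified.
    """
    df = _read_csv_strict(path, PROBES_REQUIRED,
                          ["frame_index", "time_min", "x_um", "y_um", "pH", "sigma"])
    bad_sigma = df.index[df["sigma"] <= 0].tolist()
    if bad_sigma:
        raise TableValidationError(
            f"{Path(path).name}: sigma must be > 0 at line(s) "
            f"{[int(i) + 2 for i in bad_sigma[:10]]}"
        )
    return _split_frames(
        df, lambda fi, t, sub: ProbeFrame(fi, t, sub[["probe_id", "x_um", "y_um", "pH", "sigma"]]),
        Path(path).name)


def read_bulk_csv(path) -> pd.DataFrame:
    return _read_csv_strict(path, BULK_REQUIRED, BULK_REQUIRED)


def read_tables(cells_path, probes_path, params: PhysicalParams | None = None):
    """Read and cross-validate the cell and probe frame series."""
    cells = read_cells_csv(cells_path, params)
    probes = read_probes_csv(probes_path)
    if [c.frame_index for c in cells] != [p.frame_index for p in probes]:
        raise TableValidationError(
            "cells and probes cover different frame_index sets "
            f"({[c.frame_index for c in cells]} vs {[p.frame_index for p in probes]})"
        )
    return cells, probes


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_experiment(outdir, experiment, bulk: BulkSeries | None = None) -> dict:
    """Write cells.csv / probes.csv / truth.csv (and bulk.csv) for an experiment."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells = pd.concat([
        cf.cells.assign(frame_index=cf.frame_index, time_min=cf.time_min)
        for cf in experiment.cell_frames
    ])[["frame_index", "time_min", "cell_id", "x_um", "y_um", "cell_type"]]
    probes = pd.concat([
        pf.probes.assign(frame_index=pf.frame_index, time_min=pf.time_min)
        for pf in experiment.probe_frames
    ])[["frame_index", "time_min", "probe_id", "x_um", "y_um", "pH", "sigma"]]
    paths = {
        "cells": outdir / "cells.csv",
        "probes": outdir / "probes.csv",
        "truth": outdir / "truth.csv",
    }
    cells.to_csv(paths["cells"], index=False)
    probes.to_csv(paths["probes"], index=False)
    experiment.truth_dataframe().to_csv(paths["truth"], index=False)
    if bulk is not None:
        paths["bulk"] = outdir / "bulk.csv"
        pd.DataFrame({"time_min": bulk.times_min, "bulk_pH": bulk.bulk_ph,
                      "bulk_efflux_mmol_gdw_h": bulk.bulk_efflux}).to_csv(
            paths["bulk"], index=False)
    return paths


def write_solution(outdir, solution: FluxSolution) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fluxes": outdir / "fluxes.csv",
        "boundary": outdir / "boundary.csv",
        "residuals": outdir / "residuals.csv",
        "diagnostics": outdir / "diagnostics.json",
    }
    solution.to_dataframe().to_csv(paths["fluxes"], index=False)
    solution.boundary_dataframe().to_csv(paths["boundary"], index=False)
    solution.residuals_dataframe().to_csv(paths["residuals"], index=False)
    with open(paths["diagnostics"], "w") as fh:
        json.dump(_jsonable(solution.diagnostics), fh, indent=2, sort_keys=True)
    return paths


def write_network_outputs(outdir, graphs, summaries) -> dict:
    """edges.csv, summary.csv and one GraphML file per frame."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for g in graphs:
        fi = g.graph.get("frame_index", -1)
        for a, b, d in g.edges(data=True):
            rows.append({"frame_index": fi, "donor_id": a, "acceptor_id": b,
                         "F_mmol_gdw_h": d["F"]})
    edges = pd.DataFrame(rows, columns=["frame_index", "donor_id",
                                        "acceptor_id", "F_mmol_gdw_h"])
    summary = pd.DataFrame([{
        "frame_index": s.frame_index, "avg_degree": s.average_degree,
        "max_degree": s.max_degree, "lcc_size": s.lcc_size,
        "n_nodes": s.n_nodes, "n_edges": s.n_edges, "leakage": s.leakage,
    } for s in summaries])
    paths = {"edges": outdir / "edges.csv", "summary": outdir / "summary.csv"}
    edges.to_csv(paths["edges"], index=False)
    summary.to_csv(paths["summary"], index=False)
    gml_dir = outdir / "graphml"
    gml_dir.mkdir(exist_ok=True)
    for g in graphs:
        p = gml_dir / f"network_frame{g.graph.get('frame_index', 0):03d}.graphml"
        nx.write_graphml(g, p)
        paths[p.stem] = p
    return paths


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a JSON config with blocks "physical", "hyper", "pipeline".

    Unknown keys raise, so typos do not silently fall back to defaults.
    """
    with open(path) as fh:
        raw = json.load(fh)
    known_blocks = {"physical", "hyper", "pipeline"}
    unknown = set(raw) - known_blocks
    if unknown:
        raise ValueError(f"config: unknown top-level block(s) {sorted(unknown)}")
    out = {}
    phys = raw.get("physical", {})
    try:
        out["physical"] = PhysicalParams(**phys)
    except TypeError as exc:
        raise ValueError(f"config block 'physical': {exc}") from exc
    hyp = raw.get("hyper", {})
    try:
        out["hyper"] = Hyperparams(**hyp)
    except TypeError as exc:
        raise ValueError(f"config block 'hyper': {exc}") from exc
    out["pipeline"] = raw.get("pipeline", {})
    return out
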