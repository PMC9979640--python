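"""Cell-to-cell proton exchange network reconstruction and graph summaries.

A diffusing proton released by an exporting cell i (u_i > 0) is absorbed by
importing cells (u_j < 0) with a probability that itself solves the Laplace
equation and therefore decays with distance. The pairwise exchange flux is

    F_{i->j} = u_i * (|u_j| / d_ij^a) / Z_i,    Z_i = sum_{k: u_k<0} |u_k| / d_ik^a

so that the out-fluxes of every donor sum exactly to u_i. The distance
exponent a defaults to 1 (monopole absorption heuristic). The boundary flux
U never enters the network; the per-frame difference between total export
and total import is reported as "leakage" — the acidification that spills
into the bulk medium.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist

from .params import PhysicalParams
from .tables import CellFrame, FluxVector

log = logging.getLogger(__name__)

#: two-sided Gaussian tail mass beyond 3 standard deviations
GAUSSIAN_3SD_TAIL = 2.0 * float(stats.norm.sf(3.0))


def pairwise_fluxes(flux: FluxVector, cells: CellFrame,
                    params: PhysicalParams | None = None,
                    distance_exponent: float = 1.0) -> nx.DiGraph:
    """Unthresholded weighted directed exchange graph for one frame.

    Nodes carry the cell flux and position; edges run from exporters to
    importers with weight F_{i->j} in the flux units of ``flux``.
    Coincident donor/acceptor positions are clamped to the minimum
    distance with a warning, mirroring the forward-model clamp.
    """
    params = params or PhysicalParams()
    if list(flux.cell_ids) != cells.cell_ids:
        raise ValueError("flux vector cell ids do not match the cell frame")
    g = nx.DiGraph(frame_index=cells.frame_index, time_min=cells.time_min,
                   threshold_used=0.0, units=flux.units)
    xy = cells.positions()
    u = flux.values
    for cid, (x, y), ui in zip(flux.cell_ids, xy, u):
        g.add_node(cid, u=float(ui), x=float(x), y=float(y))
    donors = np.where(u > 0)[0]
    acceptors = np.where(u < 0)[0]
    g.graph["leakage"] = float(u[donors].sum() - np.abs(u[acceptors]).sum())
    if len(donors) == 0 or len(acceptors) == 0:
        g.graph["no_importers"] = len(acceptors) == 0
        if len(donors) and not len(acceptors):
            log.info("frame %s: no importers; donors get no edges", cells.frame_index)
        return g
    g.graph["no_importers"] = False
    d = cdist(xy[donors], xy[acceptors])
    if np.any(d == 0.0):
        log.warning("frame %s: coincident donor/acceptor pair, distance clamped",
                    cells.frame_index)
    d = np.maximum(d, params.min_distance_um)
    w = np.abs(u[acceptors])[None, :] / d ** distance_exponent
    Z = w.sum(axis=1)
    F = u[donors][:, None] * w / Z[:, None]
    ids = cells.cell_ids
    for a, i in enumerate(donors):
        for b, j in enumerate(acceptors):
            g.add_edge(ids[i], ids[j], F=float(F[a, b]))
    return g


def threshold_graph(g: nx.DiGraph, threshold: float) -> nx.DiGraph:
    """Keep edges with F strictly above the threshold; nodes are retained."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    out = nx.DiGraph(**g.graph)
    out.graph["threshold_used"] = float(threshold)
    out.add_nodes_from(g.nodes(data=True))
    out.add_edges_from((a, b, d) for a, b, d in g.edges(data=True)
                       if d["F"] > threshold)
    return out


@dataclass
class GraphSummary:
    """Topology summary of one (usually thresholded) exchange graph."""

    frame_index: int
    n_nodes: int
    n_edges: int
    average_degree: float
    max_degree: int
    lcc_size: int
    degree_histogram: np.ndarray   # counts for k = 0 .. max_degree
    poisson_null: np.ndarray       # expected counts, same mean, same k range
    leakage: float

    def in_out_degrees(self):  # kept for completeness; set by graph_summary
        return self._in_deg, self._out_deg


def graph_summary(g: nx.DiGraph) -> GraphSummary:
    """Degrees, largest connected component and Poisson null of a graph.

    Degrees are computed on the undirected projection (exchange partners,
    regardless of direction); components likewise. The Poisson null scales
    p_k = exp(-<k>) <k>^k / k! to the node count.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph summary of an empty node set is undefined")
    und = nx.Graph()
    und.add_nodes_from(g.nodes)
    und.add_edges_from(g.edges)
    degs = np.array([d for _, d in und.degree()], dtype=int)
    kmax = int(degs.max())
    hist = np.bincount(degs, minlength=kmax + 1)
    mean_k = float(degs.mean())
    ks = np.arange(kmax + 1)
    null = g.number_of_nodes() * stats.poisson.pmf(ks, mean_k)
    lcc = max((len(c) for c in nx.connected_components(und)), default=0)
    summ = GraphSummary(
        frame_index=g.graph.get("frame_index", -1),
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        average_degree=mean_k,
        max_degree=kmax,
        lcc_size=int(lcc),
        degree_histogram=hist,
        poisson_null=null,
        leakage=float(g.graph.get("leakage", np.nan)),
    )
    summ._in_deg = dict(g.in_degree())
    summ._out_deg = dict(g.out_degree())
    return summ


def degree_poisson_gof(summary: GraphSummary):
    """Chi-square goodness of fit of the degree histogram to its Poisson null.

    Bins with expected counts below 5 are merged into their neighbours
    (tail pooled); one degree of freedom is spent on the estimated mean.
    Returns (chi2, p_value).
    """
    obs = summary.degree_histogram.astype(float)
    exp = summary.poisson_null.astype(float)
    # pool the open upper tail into the last bin
    n = obs.sum()
    exp = np.append(exp, max(n - exp.sum(), 0.0))
    obs = np.append(obs, 0.0)
    merged_o, merged_e = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(obs, exp):
        acc_o += o
        acc_e += e
        if acc_e >= 5.0:
            merged_o.append(acc_o)
            merged_e.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and merged_e:
        merged_o[-1] += acc_o
        merged_e[-1] += acc_e
    if len(merged_e) < 3:
        return np.nan, np.nan
    merged_o = np.asarray(merged_o)
    merged_e = np.asarray(merged_e) * merged_o.sum() / np.sum(merged_e)
    chi2 = float(np.sum((merged_o - merged_e) ** 2 / merged_e))
    dof = len(merged_e) - 2  # -1 normalization, -1 estimated mean
    return chi2, float(stats.chi2.sf(chi2, dof))


@dataclass
class MotifTrace:
    """Aligned time series for one donor/acceptor cell pair."""

    frame_indices: list
    times_min: list
    F: np.ndarray          # pairwise flux (either direction), 0 when no edge
    u_a: np.ndarray
    u_b: np.ndarray
    correlation: float | None  # Pearson r of |u_a| vs |u_b|; None if undefined


def motif_trace(graph_series: list, cell_pair: tuple) -> MotifTrace:
    """Follow a dipole motif (cell pair) across a series of exchange graphs.

    Reports the pairwise flux between the two cells in each frame together
    with both cells' fluxes, and the Pearson correlation between the two
    |u| series (undefined — None — for degenerate variance or fewer than
    two frames).
    """
    a, b = cell_pair
    frames, times, F, ua, ub = [], [], [], [], []
    for g in graph_series:
        fi = g.graph.get("frame_index", -1)
        for cid in (a, b):
            if cid not in g.nodes:
                raise KeyError(f"cell {cid!r} is not tracked in frame {fi}")
        frames.append(fi)
        times.append(g.graph.get("time_min", float("nan")))
        ua.append(g.nodes[a]["u"])
        ub.append(g.nodes[b]["u"])
        if g.has_edge(a, b):
            F.append(g.edges[a, b]["F"])
        elif g.has_edge(b, a):
            F.append(g.edges[b, a]["F"])
        else:
            F.append(0.0)
    ua, ub, F = np.asarray(ua), np.asarray(ub), np.asarray(F)
    corr: float | None
    if len(ua) < 2 or np.std(np.abs(ua)) == 0 or np.std(np.abs(ub)) == 0:
        corr = None
    else:
        corr = float(stats.pearsonr(np.abs(ua), np.abs(ub)).statistic)
    return MotifTrace(frames, times, F, ua, ub, corr)


@dataclass
class FluxDistribution:
    """Pooled single-cell flux histogram with a Gaussian fit overlay."""

    values: np.ndarray
    counts: np.ndarray
    bin_edges: np.ndarray
    mean: float
    sd: float
    excess_tail_fraction: float      # fraction beyond mean ± 3 fitted sd
    gaussian_tail_expectation: float  # = 2 Phi(-3) ≈ 0.0027


def flux_distribution(values, bins: int = 50) -> FluxDistribution:
    """Histogram + maximum-likelihood Gaussian fit of pooled flux values.

    The excess-tail fraction (mass beyond 3 fitted standard deviations)
    quantifies how heavy-tailed the empirical distribution is relative to
    its Gaussian approximation.
    """
    v = np.asarray(values, float).ravel()
    if len(v) < 2:
        raise ValueError("flux distribution needs at least 2 values")
    mean, sd = float(v.mean()), float(v.std())  # MLE (ddof=0)
    counts, edges = np.histogram(v, bins=bins)
    if sd == 0:
        tail = 0.0
    else:
        tail = float(np.mean(np.abs(v - mean) > 3.0 * sd))
    return FluxDistribution(values=v, counts=counts, bin_edges=edges,
                            mean=mean, sd=sd, excess_tail_fraction=tail,
                            gaussian_tail_expectation=GAUSSIAN_3SD_TAIL)
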