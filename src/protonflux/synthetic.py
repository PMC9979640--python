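"""Synthetic experiments with known ground truth.

Emulates the experimental regime the method targets: 100-200 cells and a
comparable number of pH probes in a 500 μm square field, 36 frames at 10 min
spacing, ground-truth fluxes that are even in sign, heavy-tailed (typical
magnitude 1 mmol/gdw/h, hubs at 100x, floor ~0.01 — three orders of
magnitude), AR(1) temporal evolution, and Gaussian probe noise on pH.

Scenarios
---------
uniform
    zero-mean Gaussian fluxes, independent cells.
dipoles
    cells paired at short range with opposite fluxes ±a_p(t).
hubs
    a small fraction (5%) of exporters at ~100x the typical magnitude.
crossover
    hubs whose amplitude decays over frames on top of a dipole background —
    the networked-to-sparse transition.

Because the linear monopole superposition has no saturation, an importer
close to a probe could drive the predicted concentration negative; real
uptake is diffusion-limited and cannot do that. Where a probe concentration
would fall below 5% of c0 the responsible importing cell is capped (its
whole time series scaled down) until the landscape is physical; the
per-cell factors are recorded in the experiment.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import field_model
from .params import PhysicalParams
from .tables import BulkSeries, CellFrame, FluxVector, ProbeFrame

SCENARIOS = ("uniform", "dipoles", "hubs", "crossover")

#: typical single-cell flux magnitude, mmol/gdw/h
TYPICAL_FLUX = 1.0
#: hub magnitude multiplier
HUB_FACTOR = 100.0
#: fraction of hub cells in hub-bearing scenarios
HUB_FRACTION = 0.05
#: minimum cell-cell separation, μm (cells are ~10 μm disks)
MIN_CELL_SEPARATION = 10.0
#: sigma recorded for probes when the noise level is zero (instrument floor)
SIGMA_FLOOR = 1.0e-4


class PackingError(ValueError):
    """Too many cells for the requested minimum separation."""


@dataclass
class SyntheticExperiment:
    """A generated experiment: tables, ground truth, and its provenance."""

    seed: int
    scenario: str
    noise_sigma: float
    params: PhysicalParams
    c0: float
    cell_frames: list
    probe_frames: list
    ground_truth: list           # list[FluxVector], mmol/gdw/h, U = 0
    noise_draws: list            # per frame, pH units, as added to the probes
    importer_rescale: float = 1.0
    dipole_pairs: list = field(default_factory=list)  # [(donor_id, acceptor_id)]
    hub_ids: list = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.cell_frames)

    def truth_dataframe(self) -> pd.DataFrame:
        rows = []
        for cf, fv in zip(self.cell_frames, self.ground_truth):
            for cid, u in zip(fv.cell_ids, fv.values):
                rows.append({"frame_index": cf.frame_index, "time_min": cf.time_min,
                             "cell_id": cid, "u_true_mmol_gdw_h": u})
        return pd.DataFrame(rows)


def _place_points(rng, n, L, min_sep, margin, max_tries_per_point=2000):
    pts = np.empty((n, 2))
    placed = 0
    tries = 0
    while placed < n:
        cand = margin + rng.uniform(0, L - 2 * margin, size=2)
        if placed == 0 or np.min(np.linalg.norm(pts[:placed] - cand, axis=1)) >= min_sep:
            pts[placed] = cand
            placed += 1
            tries = 0
        else:
            tries += 1
            if tries > max_tries_per_point:
                feasible = int(0.5 * (L / min_sep) ** 2)
                raise PackingError(
                    f"could not place {n} points at {min_sep} μm separation in an "
                    f"{L} μm square; roughly {feasible} are feasible"
                )
    return pts


def _place_paired_cells(rng, n, L, min_sep):
    """Cell layout where consecutive index pairs (2k, 2k+1) sit 15-35 μm apart."""
    n_pairs = n // 2
    pts = np.full((n, 2), np.nan)
    placed = []
    k = 0
    guard = 0
    while k < n:
        if k + 1 < 2 * n_pairs:   # place a pair
            a = 5.0 + rng.uniform(0, L - 10.0, size=2)
            ang = rng.uniform(0, 2 * math.pi)
            r = rng.uniform(15.0, 35.0)
            b = a + r * np.array([math.cos(ang), math.sin(ang)])
            ok = np.all((b >= 5.0) & (b <= L - 5.0))
            if ok and placed:
                dmat = np.linalg.norm(np.asarray(placed)[:, None, :] -
                                      np.stack([a, b])[None, :, :], axis=2)
                ok = dmat.min() >= min_sep
            if ok:
                pts[k], pts[k + 1] = a, b
                placed.extend([a, b])
                k += 2
                guard = 0
            else:
                guard += 1
        else:                     # leftover unpaired cell
            a = 5.0 + rng.uniform(0, L - 10.0, size=2)
            if not placed or np.min(np.linalg.norm(np.asarray(placed) - a, axis=1)) >= min_sep:
                pts[k] = a
                placed.append(a)
                k += 1
                guard = 0
            else:
                guard += 1
        if guard > 5000:
            feasible = int(0.5 * (L / min_sep) ** 2)
            raise PackingError(
                f"could not place {n} paired cells in an {L} μm square; "
                f"roughly {feasible} are feasible"
            )
    return pts


def _ar1_series(rng, base, n_frames, rho, innovation_sd):
    """AR(1) walk per cell around 0 starting from ``base`` (stationary)."""
    out = np.empty((n_frames, len(base)))
    out[0] = base
    for t in range(1, n_frames):
        out[t] = rho * out[t - 1] + math.sqrt(1 - rho**2) * rng.normal(0, innovation_sd, len(base))
    return out


def _draw_fluxes(rng, scenario, n_cells, n_frames, rho):
    """Ground-truth flux matrix (n_frames, n_cells) plus motif metadata."""
    pairs, hubs = [], []
    if scenario == "uniform":
        u = _ar1_series(rng, rng.normal(0, TYPICAL_FLUX, n_cells), n_frames,
                        rho, TYPICAL_FLUX)
    elif scenario == "dipoles":
        n_pairs = n_cells // 2
        log_amp = _ar1_series(rng, rng.normal(0, 0.5, n_pairs), n_frames, rho, 0.5)
        amp = TYPICAL_FLUX * 10.0 ** log_amp
        u = np.zeros((n_frames, n_cells))
        u[:, 0:2 * n_pairs:2] = amp
        u[:, 1:2 * n_pairs:2] = -amp
        if n_cells % 2:
            u[:, -1] = _ar1_series(rng, rng.normal(0, 0.1, 1), n_frames, rho, 0.1)[:, 0]
        u += 0.05 * TYPICAL_FLUX * rng.normal(0, 1, u.shape)
        pairs = [(2 * k, 2 * k + 1) for k in range(n_pairs)]
    elif scenario in ("hubs", "crossover"):
        n_hubs = max(1, int(round(HUB_FRACTION * n_cells)))
        hubs = list(range(n_hubs))
        if scenario == "hubs":
            u = _ar1_series(rng, rng.normal(0, TYPICAL_FLUX, n_cells), n_frames,
                            rho, TYPICAL_FLUX)
            hub_amp = HUB_FACTOR * TYPICAL_FLUX * 10.0 ** rng.normal(0, 0.15, n_hubs)
            u[:, :n_hubs] = hub_amp[None, :] * (
                1.0 + 0.05 * _ar1_series(rng, rng.normal(0, 1, n_hubs), n_frames, rho, 1.0))
        else:
            # hubs decaying into a dipole background
            rest = n_cells - n_hubs
            n_pairs = rest // 2
            log_amp = _ar1_series(rng, rng.normal(0.5, 0.3, n_pairs), n_frames, rho, 0.3)
            amp = TYPICAL_FLUX * 10.0 ** log_amp
            u = np.zeros((n_frames, n_cells))
            u[:, n_hubs:n_hubs + 2 * n_pairs:2] = amp
            u[:, n_hubs + 1:n_hubs + 2 * n_pairs:2] = -amp
            u += 0.05 * TYPICAL_FLUX * rng.normal(0, 1, u.shape)
            tau = max(n_frames / 4.0, 1.0)
            decay = np.exp(-np.arange(n_frames) / tau)
            hub_amp = HUB_FACTOR * TYPICAL_FLUX * 10.0 ** rng.normal(0, 0.15, n_hubs)
            u[:, :n_hubs] = hub_amp[None, :] * decay[:, None]
            pairs = [(n_hubs + 2 * k, n_hubs + 2 * k + 1) for k in range(n_pairs)]
    else:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    return u, pairs, hubs


def generate_experiment(scenario: str = "uniform", n_cells: int = 150,
                        n_probes: int = 150, n_frames: int = 36,
                        noise_sigma: float = 0.02, seed: int = 0,
                        params: PhysicalParams | None = None,
                        frame_interval_min: float = 10.0,
                        ar_coefficient: float = 0.999,
                        cell_step_um: float = 3.0) -> SyntheticExperiment:
    """Generate a fully specified synthetic experiment.

    Cells are placed uniformly with a 10 μm minimum separation (paired
    scenarios place partners 15-35 μm apart) and perform a small reflected
    random walk across frames; probes are static with the clamp distance
    respected at placement. Probe pH equals the forward-model prediction
    plus recorded N(0, noise_sigma) draws. Regenerating with the same seed
    reproduces every table exactly.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if min(n_cells, n_probes, n_frames) < 1:
        raise ValueError("n_cells, n_probes and n_frames must all be >= 1")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    params = params or PhysicalParams()
    rng = np.random.default_rng(seed)
    L = params.frame_size_L
    c0 = params.default_c0()

    if scenario in ("dipoles", "crossover"):
        cells0 = _place_paired_cells(rng, n_cells, L, MIN_CELL_SEPARATION)
    else:
        cells0 = _place_points(rng, n_cells, L, MIN_CELL_SEPARATION, margin=5.0)
    # probes: uniform, at least the clamp distance away from frame-0 cells
    probes_xy = np.empty((n_probes, 2))
    placed = 0
    tries = 0
    while placed < n_probes:
        cand = rng.uniform(0, L, size=2)
        if np.min(np.linalg.norm(cells0 - cand, axis=1)) >= params.min_distance_um:
            probes_xy[placed] = cand
            placed += 1
            tries = 0
        else:
            tries += 1
            if tries > 5000:
                raise PackingError("could not place probes clear of the cells")
    u_rep, pairs, hubs = _draw_fluxes(rng, scenario, n_cells, n_frames, ar_coefficient)

    # cell motion: reflected random walk, probes static
    positions = [cells0]
    for _ in range(1, n_frames):
        step = rng.normal(0, cell_step_um, size=cells0.shape)
        nxt = positions[-1] + step
        nxt = np.abs(nxt)                      # reflect at 0
        nxt = L - np.abs(L - nxt)              # reflect at L
        positions.append(nxt)

    cell_ids = [f"c{i:03d}" for i in range(n_cells)]
    probe_ids = [f"p{j:03d}" for j in range(n_probes)]
    cell_types = rng.choice(["tumor", "fibroblast"], size=n_cells)

    # positivity guard: one global rescale of the importing fluxes
    scale = field_model.native_per_reported(params)
    kernels = []
    for t in range(n_frames):
        cf = _cell_frame(t, t * frame_interval_min, cell_ids, positions[t], cell_types)
        pf_geom = _probe_frame(t, t * frame_interval_min, probe_ids, probes_xy,
                               np.full(n_probes, 7.0), np.full(n_probes, 1.0))
        kernels.append(field_model.build_distance_matrix(cf, pf_geom, params) * scale)
    u_rep, cell_scale = _cap_importers(u_rep, kernels, c0)
    rescale = float(cell_scale.min(initial=1.0))

    cell_frames, probe_frames, truth, noise_draws = [], [], [], []
    sigma_rec = noise_sigma if noise_sigma > 0 else SIGMA_FLOOR
    for t in range(n_frames):
        time_min = t * frame_interval_min
        cf = _cell_frame(t, time_min, cell_ids, positions[t], cell_types)
        state = np.concatenate([[0.0], u_rep[t]])       # boundary flux U = 0
        c = c0 + kernels[t] @ state
        ph_clean = field_model.predicted_ph(c)
        noise = rng.normal(0.0, noise_sigma, n_probes) if noise_sigma > 0 else np.zeros(n_probes)
        pf = _probe_frame(t, time_min, probe_ids, probes_xy, ph_clean + noise,
                          np.full(n_probes, sigma_rec))
        cell_frames.append(cf)
        probe_frames.append(pf)
        truth.append(FluxVector(0.0, tuple(cell_ids), u_rep[t].copy()))
        noise_draws.append(noise)

    return SyntheticExperiment(
        seed=seed, scenario=scenario, noise_sigma=noise_sigma, params=params,
        c0=c0, cell_frames=cell_frames, probe_frames=probe_frames,
        ground_truth=truth, noise_draws=noise_draws, importer_rescale=rescale,
        dipole_pairs=[(cell_ids[a], cell_ids[b]) for a, b in pairs],
        hub_ids=[cell_ids[h] for h in hubs],
    )


def _cap_importers(u_rep, kernels, c0, floor_fraction=0.05, max_iter=500):
    """Diffusion-limited import: cap offending importers cell by cell.

    A sustained import flux cannot deplete the local proton concentration
    below zero; where the linear superposition would push a probe below
    ``floor_fraction * c0``, the single importer contributing most to that
    deficit is scaled down (its whole time series, preserving temporal
    smoothness) until the field is physical everywhere. Returns the capped
    flux matrix and the per-cell scale factors applied.
    """
    n_frames, n_cells = u_rep.shape
    scale = np.ones(n_cells)
    floor = floor_fraction * c0
    for _ in range(max_iter):
        worst = (None, 0.0)
        for t in range(n_frames):
            c = c0 + kernels[t][:, 1:] @ (u_rep[t] * scale)
            mu = int(np.argmin(c))
            if worst[0] is None or c[mu] < worst[1]:
                worst = ((t, mu), float(c[mu]))
        (t, mu), c_min = worst
        if c_min >= floor:
            break
        contrib = kernels[t][mu, 1:] * (u_rep[t] * scale)
        i = int(np.argmin(contrib))
        if contrib[i] >= 0:   # no importer to blame; cannot happen with c0 > floor
            break
        cur = -contrib[i]
        reduce = min(floor - c_min, cur)
        scale[i] *= (cur - reduce) / cur
    return u_rep * scale[None, :], scale


def _cell_frame(idx, time_min, ids, xy, types):
    return CellFrame(idx, time_min, pd.DataFrame({
        "cell_id": ids, "x_um": xy[:, 0], "y_um": xy[:, 1], "cell_type": types,
    }))


def _probe_frame(idx, time_min, ids, xy, ph, sigma):
    return ProbeFrame(idx, time_min, pd.DataFrame({
        "probe_id": ids, "x_um": xy[:, 0], "y_um": xy[:, 1],
        "pH": ph, "sigma": sigma,
    }))


def make_bulk_series(experiment: SyntheticExperiment,
                     observation_noise: float = 0.0,
                     seed: int | None = None) -> BulkSeries:
    """Bulk efflux and bulk pH trace consistent with the ground truth.

    The per-cell bulk efflux u_b(t) is the mean ground-truth flux plus
    optional Gaussian observation noise; the bulk concentration integrates
    the total native efflux into the configured medium volume starting
    from c0.
    """
    rng = np.random.default_rng(experiment.seed + 1 if seed is None else seed)
    params = experiment.params
    times = np.array([cf.time_min for cf in experiment.cell_frames])
    means = np.array([fv.values.mean() for fv in experiment.ground_truth])
    u_b = means + (rng.normal(0, observation_noise, len(means))
                   if observation_noise > 0 else 0.0)
    totals_native = np.array([
        float(np.sum(field_model.reported_to_native(fv.values, params)))
        for fv in experiment.ground_truth
    ])
    conc = np.empty(len(times))
    conc[0] = experiment.c0
    for t in range(1, len(times)):
        dt_s = (times[t] - times[t - 1]) * 60.0
        conc[t] = conc[t - 1] + totals_native[t - 1] * dt_s / params.medium_volume_L
    return BulkSeries(times_min=times, bulk_concentration=conc, bulk_efflux=u_b)
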