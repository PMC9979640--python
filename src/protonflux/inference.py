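"""Regularized maximum-likelihood inference of per-cell fluxes.

The measured pH values enter a per-frame cost

    chi2_t(u) = sum_mu (pH_mu - pH_hat_mu(u))² / sigma_mu²  +  lambda1 sum_{i=1..N} u_i²

with pH_hat from the monopole forward model; the boundary flux u_0 = U is
excluded from the Tikhonov sum. Frames are coupled into a total cost

    chi2_tot = sum_t chi2_t + lambda2 sum_i sum_t (u_i(t+1) - u_i(t))²
                           + lambda3 sum_t (ubar(t) - u_b(t))²

where the lambda2 sum runs over tracked cells only and ubar(t) is the mean
flux of the cells present in frame t. Fluxes are treated as distributed as
P(u) ∝ exp(-chi2_tot(u)/2), the posterior of the Gaussian measurement
model; the maximum-likelihood configuration is located by
a Gauss-Newton warm start followed by simulated annealing, and credible
intervals come from a Metropolis-Hastings chain preconditioned by the
Gaussian (warm-start) approximation of the posterior.

All public fluxes are in mmol/gdw/h; the kernel is rescaled internally so
the sampled state is O(1).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular, LinAlgError
from scipy.spatial import cKDTree

from . import field_model
from .params import PhysicalParams, Hyperparams
from .tables import BulkSeries, CellFrame, FluxSolution, FluxVector, ProbeFrame

log = logging.getLogger(__name__)

LN10 = math.log(10.0)

#: The per-probe data term sums squared residuals over sigma^2, so the
#: Gaussian measurement model has density exp(-chi2/2); the posterior is
#: sampled at this temperature so that credible intervals are calibrated.
POSTERIOR_TEMPERATURE = 2.0


class InferenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# problem assembly
# ---------------------------------------------------------------------------

@dataclass
class _FrameData:
    frame_index: int
    time_min: float
    cell_ids: tuple
    kernel_rep: np.ndarray      # (M, N+1), mol/L per mmol/gdw/h
    ph_obs: np.ndarray
    sigma: np.ndarray
    c0: float

    @property
    def n_state(self) -> int:
        return self.kernel_rep.shape[1]


@dataclass
class Problem:
    """Fully assembled inference problem (kernels, penalties, tracking)."""

    frames: list
    links: list                  # per gap t: (idx_in_t, idx_in_t1) state indices
    lambda1: float
    lambda2: float
    lambda3: float
    u_b: np.ndarray | None = None
    bulk_constraint: str = "mean"

    def bulk_weights(self, t: int) -> np.ndarray:
        """Weight vector w with ubar(t) = w·u_t (boundary excluded)."""
        fd = self.frames[t]
        w = np.ones(fd.n_state)
        w[0] = 0.0
        n = fd.n_state - 1
        if self.bulk_constraint == "mean" and n > 0:
            w /= n
        return w

    def zero_states(self) -> list:
        return [np.zeros(fd.n_state) for fd in self.frames]


def estimate_frame_c0(probes: ProbeFrame) -> float:
    """Background concentration from the median probe pH of the frame."""
    return 10.0 ** (-float(np.median(probes.ph_values())))


def track_cells(cell_frames: list, max_displacement_um: float = 30.0) -> list:
    """Greedy mutual-nearest-neighbour tracking between consecutive frames.

    Returns one dict per frame gap mapping cell_id in frame t to cell_id in
    frame t+1. Cells whose mutual nearest neighbour lies beyond the
    displacement gate are left unmatched (their tracks end/start there).
    """
    matches = []
    for a, b in zip(cell_frames[:-1], cell_frames[1:]):
        xa, xb = a.positions(), b.positions()
        m: dict = {}
        if len(xa) and len(xb):
            fwd_d, fwd = cKDTree(xb).query(xa)
            _, bwd = cKDTree(xa).query(xb)
            for i, (j, dij) in enumerate(zip(fwd, fwd_d)):
                if bwd[j] == i and dij <= max_displacement_um:
                    m[a.cell_ids[i]] = b.cell_ids[j]
        matches.append(m)
    return matches


def build_problem(cell_frames: list, probe_frames: list,
                  params: PhysicalParams, lambda1: float, lambda2: float,
                  lambda3: float = 0.0, bulk: BulkSeries | None = None,
                  tracking: list | None = None,
                  bulk_constraint: str = "mean") -> Problem:
    """Assemble kernels, per-frame data and tracking links into a Problem."""
    if len(cell_frames) != len(probe_frames):
        raise InferenceError("cell and probe frame series differ in length")
    if lambda3 > 0 and bulk is None:
        raise InferenceError(
            "lambda3 > 0 requires a bulk efflux series; set lambda3 = 0 or supply bulk data"
        )
    scale = field_model.native_per_reported(params)
    frames = []
    for cf, pf in zip(cell_frames, probe_frames):
        if cf.frame_index != pf.frame_index:
            raise InferenceError(
                f"frame index mismatch: cells {cf.frame_index} vs probes {pf.frame_index}"
            )
        kernel = field_model.build_distance_matrix(cf, pf, params) * scale
        c0 = (params.background_concentration_c0
              if params.background_concentration_c0 is not None
              else estimate_frame_c0(pf))
        frames.append(_FrameData(cf.frame_index, cf.time_min, tuple(cf.cell_ids),
                                 kernel, pf.ph_values(), pf.sigmas(), c0))
    if tracking is None:
        tracking = track_cells(cell_frames)
    links = []
    for t, m in enumerate(tracking):
        ids_t = {cid: k for k, cid in enumerate(frames[t].cell_ids)}
        ids_t1 = {cid: k for k, cid in enumerate(frames[t + 1].cell_ids)}
        ii, jj = [], []
        for ca, cb in m.items():
            if ca in ids_t and cb in ids_t1:
                ii.append(ids_t[ca] + 1)   # +1: state slot 0 is the boundary
                jj.append(ids_t1[cb] + 1)
        links.append((np.asarray(ii, int), np.asarray(jj, int)))
    u_b = None
    if bulk is not None:
        if len(bulk.times_min) != len(frames):
            raise InferenceError("bulk series length does not match the frame series")
        u_b = np.asarray(bulk.bulk_efflux, float)
    return Problem(frames, links, lambda1, lambda2, lambda3, u_b, bulk_constraint)


# ---------------------------------------------------------------------------
# cost functions
# ---------------------------------------------------------------------------

def _frame_data_chi2(fd: _FrameData, u: np.ndarray) -> float:
    c = fd.c0 + fd.kernel_rep @ u
    if np.any(c <= 0):
        return np.inf
    r = (fd.ph_obs + np.log10(c)) / fd.sigma
    return float(r @ r)


def _frame_local(problem: Problem, t: int, u: np.ndarray) -> float:
    """Frame cost terms that depend only on u_t (data + λ1 + λ3)."""
    fd = problem.frames[t]
    val = _frame_data_chi2(fd, u)
    if not np.isfinite(val):
        return val
    val += problem.lambda1 * float(u[1:] @ u[1:])
    if problem.lambda3 > 0 and problem.u_b is not None:
        w = problem.bulk_weights(t)
        val += problem.lambda3 * (float(w @ u) - problem.u_b[t]) ** 2
    return val


def _link_cost(problem: Problem, t: int, u_t: np.ndarray, u_t1: np.ndarray) -> float:
    ii, jj = problem.links[t]
    if len(ii) == 0:
        return 0.0
    d = u_t1[jj] - u_t[ii]
    return problem.lambda2 * float(d @ d)


def total_chi2_states(problem: Problem, states: list) -> float:
    tot = 0.0
    for t in range(len(problem.frames)):
        tot += _frame_local(problem, t, states[t])
        if not np.isfinite(tot):
            return np.inf
    for t in range(len(problem.frames) - 1):
        tot += _link_cost(problem, t, states[t], states[t + 1])
    return tot


def frame_chi2(flux: FluxVector, cells: CellFrame, probes: ProbeFrame,
               params: PhysicalParams, lambda1: float = 0.0,
               c0: float | None = None) -> float:
    """Cost of one frame: data misfit plus the λ1 Tikhonov term.

    The boundary flux U is excluded from the penalty. An unphysical flux
    vector (non-positive predicted concentration anywhere) costs +inf.
    """
    if list(flux.cell_ids) != cells.cell_ids:
        raise InferenceError("flux vector cell ids do not match the cell frame")
    kernel = field_model.build_distance_matrix(cells, probes, params)
    fd = _FrameData(cells.frame_index, cells.time_min, tuple(cells.cell_ids),
                    kernel * field_model.native_per_reported(params),
                    probes.ph_values(), probes.sigmas(),
                    params.default_c0() if c0 is None else c0)
    u = flux.to_state()
    val = _frame_data_chi2(fd, u)
    if np.isfinite(val):
        val += lambda1 * float(u[1:] @ u[1:])
    return val


def total_chi2(fluxes: list, cell_frames: list, probe_frames: list,
               params: PhysicalParams, lambda1: float = 0.0,
               lambda2: float = 0.0, lambda3: float = 0.0,
               bulk: BulkSeries | None = None, tracking: list | None = None,
               bulk_constraint: str = "mean",
               c0: float | None = None) -> float:
    """Total regularized cost over all frames (data + λ1 + λ2 + λ3 terms)."""
    if c0 is not None:
        params_c0 = PhysicalParams(**{**params.to_dict(),
                                      "background_concentration_c0": c0})
    else:
        params_c0 = params
    problem = build_problem(cell_frames, probe_frames, params_c0, lambda1,
                            lambda2, lambda3, bulk, tracking, bulk_constraint)
    return total_chi2_states(problem, [fv.to_state() for fv in fluxes])


# ---------------------------------------------------------------------------
# Gaussian warm start (Gauss-Newton with block coordinate descent)
# ---------------------------------------------------------------------------

def _linearize(fd: _FrameData, u: np.ndarray):
    """First-order expansion of the weighted residual around u.

    Returns (A, z) with chi2_data(v) ≈ ||z - A v||² for v near u.
    """
    c = fd.c0 + fd.kernel_rep @ u
    if np.any(c <= 0):
        raise InferenceError("linearization point has non-positive concentration")
    pred = -np.log10(c)
    A = (fd.kernel_rep / (c[:, None] * LN10)) / fd.sigma[:, None]
    wres = (fd.ph_obs - pred) / fd.sigma
    # chi2_data = ||wres - A (v - u)||^2 = ||z - A v||^2 with z as below
    return A, A @ u - wres


def _frame_hessian(problem: Problem, t: int, A: np.ndarray) -> np.ndarray:
    """Gauss-Newton Hessian of frame t with neighbours held fixed."""
    fd = problem.frames[t]
    H = A.T @ A
    diag = np.arange(fd.n_state)
    H[diag[1:], diag[1:]] += problem.lambda1
    if problem.lambda2 > 0:
        counts = np.zeros(fd.n_state)
        if t > 0:
            _, jj = problem.links[t - 1]
            np.add.at(counts, jj, 1.0)
        if t < len(problem.frames) - 1:
            ii, _ = problem.links[t]
            np.add.at(counts, ii, 1.0)
        H[diag, diag] += problem.lambda2 * counts
    if problem.lambda3 > 0 and problem.u_b is not None:
        w = problem.bulk_weights(t)
        H += problem.lambda3 * np.outer(w, w)
    return H


def gaussian_warm_start(problem: Problem, x0: list | None = None,
                        max_outer: int = 60, tol: float = 1e-12,
                        return_hessians: bool = False):
    """Iterated linearization of the total cost, solved per frame.

    Each outer iteration linearizes the pH prediction around the current
    expansion point, reducing the cost to a coupled ridge regression; the
    quadratic is minimized by block coordinate descent over frames and the
    move is safeguarded by halving-step line search on the exact cost.
    Returns the fixed point (and per-frame Gauss-Newton Hessians when
    requested, used to precondition the samplers).
    """
    T = len(problem.frames)
    states = [s.copy() for s in (x0 if x0 is not None else problem.zero_states())]
    cost = total_chi2_states(problem, states)
    if not np.isfinite(cost):
        raise InferenceError("warm start must begin at a physical state")
    factors = None
    for _ in range(max_outer):
        lin = [_linearize(problem.frames[t], states[t]) for t in range(T)]
        factors, rhs0 = [], []
        for t, (A, z) in enumerate(lin):
            H = _frame_hessian(problem, t, A)
            try:
                factors.append(cho_factor(H, lower=True))
            except LinAlgError as exc:
                raise InferenceError(
                    "singular normal matrix: the problem is under-determined "
                    "(fewer probes than flux parameters); set lambda1 > 0 to "
                    "regularize"
                ) from exc
            rhs0.append(A.T @ z)
        y = [s.copy() for s in states]
        for _sweep in range(200):
            delta = 0.0
            for t in range(T):
                rhs = rhs0[t].copy()
                if problem.lambda2 > 0:
                    if t > 0:
                        ii, jj = problem.links[t - 1]
                        np.add.at(rhs, jj, problem.lambda2 * y[t - 1][ii])
                    if t < T - 1:
                        ii, jj = problem.links[t]
                        np.add.at(rhs, ii, problem.lambda2 * y[t + 1][jj])
                if problem.lambda3 > 0 and problem.u_b is not None:
                    rhs += problem.lambda3 * problem.u_b[t] * problem.bulk_weights(t)
                new = cho_solve(factors[t], rhs)
                delta = max(delta, float(np.max(np.abs(new - y[t]), initial=0.0)))
                y[t] = new
            if delta < 1e-12 * max(1.0, max(float(np.max(np.abs(s), initial=0.0)) for s in y)):
                break
        # line search toward the quadratic minimizer on the exact cost
        step, new_cost, cand = 1.0, np.inf, states
        while step >= 2.0 ** -20:
            cand = [s + step * (yt - s) for s, yt in zip(states, y)]
            new_cost = total_chi2_states(problem, cand)
            if new_cost <= cost + 1e-12 * max(1.0, cost):
                break
            step *= 0.5
        if new_cost > cost:
            break
        improvement = cost - new_cost
        states, cost = cand, new_cost
        if improvement < tol * max(1.0, cost):
            break
    if return_hessians:
        hessians = []
        for t in range(T):
            A, _ = _linearize(problem.frames[t], states[t])
            hessians.append(_frame_hessian(problem, t, A))
        return states, hessians
    return states


def select_lambda1_gcv(problem: Problem, n_grid: int = 41) -> float:
    """Generalized cross-validation for λ1 on the linearized (u=0) problem.

    The ridge is applied to every column (including the boundary) for the
    selection only; the final fits keep the boundary unpenalized.
    """
    svds, zs = [], []
    for fd in problem.frames:
        A, z = _linearize(fd, np.zeros(fd.n_state))
        U, s, _ = np.linalg.svd(A, full_matrices=False)
        svds.append(s)
        zs.append((U.T @ z, float(z @ z)))
    s_all = np.concatenate(svds)
    s_max = float(np.max(s_all))
    grid = np.logspace(math.log10(s_max**2) - 8.0, math.log10(s_max**2) + 2.0, n_grid)
    best_lam, best_gcv = grid[0], np.inf
    M_tot = sum(len(fd.ph_obs) for fd in problem.frames)
    for lam in grid:
        rss, tr = 0.0, 0.0
        for s, (utz, zz) in zip(svds, zs):
            shrink = lam / (s**2 + lam)
            rss += float(np.sum((shrink * utz) ** 2)) + max(zz - float(utz @ utz), 0.0)
            tr += float(np.sum(s**2 / (s**2 + lam)))
        denom = max(M_tot - tr, 1e-9)
        gcv = M_tot * rss / denom**2
        if gcv < best_gcv:
            best_gcv, best_lam = gcv, lam
    return float(best_lam)


# ---------------------------------------------------------------------------
# Metropolis-Hastings machinery
# ---------------------------------------------------------------------------

def _accept(delta: float, temperature: float, rng: np.random.Generator) -> bool:
    if delta <= 0:
        return True
    if not np.isfinite(delta):
        return False
    return rng.random() < math.exp(-delta / temperature)


class _BlockSampler:
    """Per-frame block Metropolis-Hastings moves on chi2_tot.

    Proposals for frame t are Gaussian steps with covariance s_t² H_t⁻¹,
    where H_t is the warm-start Gauss-Newton Hessian of the frame — the
    over-relaxation that tames the ill-conditioned directions. Step scales
    adapt toward a target acceptance during designated adaptation phases
    and are frozen otherwise (preserving detailed balance while sampling).
    """

    def __init__(self, problem: Problem, states: list, hessians: list,
                 rng: np.random.Generator, target_acceptance: float = 0.3):
        self.problem = problem
        self.states = [s.copy() for s in states]
        self.rng = rng
        self.target = target_acceptance
        self.chol = []
        for H in hessians:
            Hj = H + np.eye(H.shape[0]) * (1e-12 * max(np.trace(H), 1.0) / H.shape[0])
            self.chol.append(cholesky(Hj, lower=True))
        # target ≈ Gaussian with covariance H⁻¹/2 (chi2 convention, no 1/2)
        self.step = [2.38 / math.sqrt(2.0 * H.shape[0]) for H in hessians]
        self.local = [_frame_local(problem, t, self.states[t])
                      for t in range(len(self.states))]
        self.chi2 = total_chi2_states(problem, self.states)
        self.best = ([s.copy() for s in self.states], self.chi2)
        self.n_prop = 0
        self.n_acc = 0

    def _neighbour_cost(self, t: int, u_t: np.ndarray) -> float:
        c = 0.0
        if t > 0:
            c += _link_cost(self.problem, t - 1, self.states[t - 1], u_t)
        if t < len(self.states) - 1:
            c += _link_cost(self.problem, t, u_t, self.states[t + 1])
        return c

    def sweep(self, temperature: float = 1.0, adapt: bool = False) -> None:
        for t in range(len(self.states)):
            L = self.chol[t]
            xi = self.rng.standard_normal(L.shape[0])
            step = self.step[t] * math.sqrt(temperature)
            prop = self.states[t] + step * solve_triangular(L.T, xi, lower=False)
            old = self.local[t] + self._neighbour_cost(t, self.states[t])
            new = _frame_local(self.problem, t, prop)
            if np.isfinite(new):
                new += self._neighbour_cost(t, prop)
            delta = new - old
            self.n_prop += 1
            accepted = _accept(delta, temperature, self.rng)
            if accepted:
                self.states[t] = prop
                self.local[t] = new - self._neighbour_cost(t, prop)
                self.chi2 += delta
                self.n_acc += 1
                if self.chi2 < self.best[1]:
                    self.best = ([s.copy() for s in self.states], self.chi2)
            if adapt:
                self.step[t] *= math.exp(0.05 * ((1.0 if accepted else 0.0) - self.target))

    def flat_state(self) -> np.ndarray:
        return np.concatenate(self.states)


def anneal_to_map(problem: Problem, start: list, hessians: list,
                  hyper: Hyperparams, rng: np.random.Generator):
    """Simulated annealing on chi2_tot/T; returns the best state ever seen.

    The schedule cools geometrically from ``anneal_t_initial`` down to 1;
    the returned cost can never exceed the starting (warm-start) cost.
    """
    sampler = _BlockSampler(problem, start, hessians, rng, hyper.target_acceptance)
    T = hyper.anneal_t_initial
    while T > 1.0:
        for _ in range(hyper.anneal_sweeps_per_temp):
            sampler.sweep(temperature=T, adapt=True)
        T *= hyper.anneal_cooling
    for _ in range(hyper.anneal_sweeps_per_temp):
        sampler.sweep(temperature=1.0, adapt=True)
    best_states, best_cost = sampler.best
    # exact re-evaluation guards against incremental drift
    return [s.copy() for s in best_states], total_chi2_states(problem, best_states)


def sample_posterior(problem: Problem, start: list, hessians: list,
                     hyper: Hyperparams, rng: np.random.Generator):
    """MH chain targeting the Gaussian-model posterior exp(-chi2_tot/2).

    Step sizes adapt during burn-in only. Returns (chain, diagnostics):
    the chain holds one flattened state per post-burn-in sweep and the
    diagnostics record the acceptance rate, the minimum cost visited and
    step-size pathologies (acceptance < 1% or > 99%).
    """
    sampler = _BlockSampler(problem, start, hessians, rng, hyper.target_acceptance)
    for _ in range(hyper.burn_in):
        sampler.sweep(temperature=POSTERIOR_TEMPERATURE, adapt=True)
    sampler.n_prop = sampler.n_acc = 0
    chain = np.empty((hyper.n_samples, sum(len(s) for s in sampler.states)))
    for k in range(hyper.n_samples):
        sampler.sweep(temperature=POSTERIOR_TEMPERATURE, adapt=False)
        chain[k] = sampler.flat_state()
    acc = sampler.n_acc / max(sampler.n_prop, 1)
    warnings = []
    if acc < 0.01 or acc > 0.99:
        warnings.append(
            f"sampler acceptance rate {acc:.3f} outside [0.01, 0.99]: "
            "step-size pathology, treat credible intervals with caution"
        )
        log.warning(warnings[-1])
    diag = {
        "acceptance_rate": acc,
        "min_cost_visited": sampler.best[1],
        "step_scales": [float(s) for s in sampler.step],
        "warnings": warnings,
    }
    return chain, diag


def confidence_intervals(chain: np.ndarray, level: float = 0.68):
    """Central credible intervals and 1σ-equivalent errors from a chain.

    Returns (low, high, sigma) per state dimension. ``level = 0`` collapses
    to the chain median. Requires at least 100 samples.
    """
    chain = np.asarray(chain, float)
    if chain.ndim != 2 or chain.shape[0] < 100:
        raise InferenceError("confidence intervals need a chain of >= 100 samples")
    if not 0.0 <= level < 1.0:
        raise ValueError("level must be in [0, 1)")
    lo_q, hi_q = 0.5 - level / 2.0, 0.5 + level / 2.0
    low = np.quantile(chain, lo_q, axis=0)
    high = np.quantile(chain, hi_q, axis=0)
    sigma = chain.std(axis=0, ddof=1)
    return low, high, sigma


# ---------------------------------------------------------------------------
# generic simulated annealing (used for machinery validation)
# ---------------------------------------------------------------------------

def simulated_annealing(cost, x0: np.ndarray, proposal_scale: float,
                        t_initial: float = 100.0, cooling: float = 0.95,
                        steps_per_temp: int = 200,
                        rng: np.random.Generator | None = None):
    """Annealed random-walk minimization of an arbitrary scalar cost.

    Shares the acceptance rule of the flux annealer; returns the best
    (x, cost) ever visited, never worse than the starting point.
    """
    rng = np.random.default_rng() if rng is None else rng
    x = np.asarray(x0, float).copy()
    c = float(cost(x))
    best_x, best_c = x.copy(), c
    T = t_initial
    while T >= 1.0:
        for _ in range(steps_per_temp):
            prop = x + proposal_scale * math.sqrt(T) * rng.standard_normal(x.shape)
            cp = float(cost(prop))
            if _accept(cp - c, T, rng):
                x, c = prop, cp
                if c < best_c:
                    best_x, best_c = x.copy(), c
        T *= cooling
    return best_x, best_c


# ---------------------------------------------------------------------------
# bulk efflux
# ---------------------------------------------------------------------------

def estimate_bulk_efflux(times_min: np.ndarray, bulk_ph: np.ndarray,
                         n_cells_per_frame, params: PhysicalParams) -> BulkSeries:
    """Per-cell bulk acidic efflux from the bulk pH trend.

    Converts pH to [H+], differentiates with central finite differences
    (one-sided at the ends), scales by the medium volume and divides by the
    number of cells; the result is reported in mmol/gdw/h.
    """
    t = np.asarray(times_min, float)
    ph = np.asarray(bulk_ph, float)
    if len(t) < 3:
        raise InferenceError("bulk efflux estimation needs at least 3 time points")
    if np.any(np.diff(t) <= 0):
        raise InferenceError("bulk time vector must be strictly increasing")
    n_cells = np.broadcast_to(np.asarray(n_cells_per_frame, float), t.shape)
    c = 10.0 ** (-ph)
    dc_dt = np.gradient(c, t) / 60.0           # mol/L per second
    total_native = dc_dt * params.medium_volume_L  # mol/s summed over cells
    per_cell_native = total_native / n_cells
    return BulkSeries(times_min=t, bulk_concentration=c,
                      bulk_efflux=field_model.convert_flux_units(per_cell_native, params))


# ---------------------------------------------------------------------------
# top-level driver
# ---------------------------------------------------------------------------

def _resolve_lambdas(problem_builder, hyper: Hyperparams, bulk):
    """Resolve None hyperparameters to data-scale-aware defaults."""
    lam1 = hyper.lambda1
    if lam1 is None:
        lam1 = select_lambda1_gcv(problem_builder(0.0, 0.0, 0.0, None))
    lam2 = hyper.lambda2 if hyper.lambda2 is not None else lam1 / 10.0
    lam3 = hyper.lambda3
    if lam3 is None:
        if bulk is None:
            lam3 = 0.0
        else:
            prob = problem_builder(lam1, lam2, 0.0, None)
            ws = gaussian_warm_start(prob)
            data_misfit = sum(_frame_data_chi2(fd, s)
                              for fd, s in zip(prob.frames, ws))
            dev = 0.0
            for t, s in enumerate(ws):
                w = prob.bulk_weights(t)
                dev += (float(w @ s) - bulk.bulk_efflux[t]) ** 2
            lam3 = 0.1 * data_misfit / dev if dev > 0 else 0.0
    return lam1, lam2, lam3


def infer_fluxes(cell_frames: list, probe_frames: list,
                 bulk: BulkSeries | None = None,
                 params: PhysicalParams | None = None,
                 hyper: Hyperparams | None = None) -> FluxSolution:
    """Full inference pipeline: warm start, annealing, posterior sampling.

    Returns a :class:`FluxSolution` with MAP fluxes (mmol/gdw/h), credible
    intervals, per-probe residuals and sampler diagnostics. All randomness
    derives from ``hyper.seed``.
    """
    params = params or PhysicalParams()
    hyper = hyper or Hyperparams()
    tracking = track_cells(cell_frames, hyper.max_displacement_um)

    def builder(l1, l2, l3, b):
        return build_problem(cell_frames, probe_frames, params, l1, l2, l3,
                             b, tracking, hyper.bulk_constraint)

    lam1, lam2, lam3 = _resolve_lambdas(builder, hyper, bulk)
    log.info("hyperparameters: lambda1=%.4g lambda2=%.4g lambda3=%.4g", lam1, lam2, lam3)
    problem = builder(lam1, lam2, lam3, bulk if lam3 > 0 else None)

    rng = np.random.default_rng(hyper.seed)
    warm, hessians = gaussian_warm_start(problem, return_hessians=True)
    log.info("warm start cost %.4g", total_chi2_states(problem, warm))
    map_states, map_cost = anneal_to_map(problem, warm, hessians, hyper, rng)
    chain, diag = sample_posterior(problem, map_states, hessians, hyper, rng)

    # keep the best configuration seen anywhere
    if diag["min_cost_visited"] < map_cost:
        k = int(np.argmin([total_chi2_states(problem, _split(problem, chain[i]))
                           for i in range(len(chain))]))
        cand = _split(problem, chain[k])
        cand_cost = total_chi2_states(problem, cand)
        if cand_cost < map_cost:
            map_states, map_cost = cand, cand_cost

    low_f, high_f, sig_f = confidence_intervals(chain, hyper.ci_level)
    offsets = np.cumsum([0] + [fd.n_state for fd in problem.frames])
    flux_vectors, lows, highs, sigs, residuals = [], [], [], [], []
    for t, fd in enumerate(problem.frames):
        sl = slice(offsets[t], offsets[t + 1])
        u = map_states[t]
        lo = np.minimum(low_f[sl], u)
        hi = np.maximum(high_f[sl], u)
        flux_vectors.append(FluxVector.from_state(u, fd.cell_ids))
        lows.append(lo)
        highs.append(hi)
        sigs.append(sig_f[sl])
        c = fd.c0 + fd.kernel_rep @ u
        rec = -np.log10(c)
        residuals.append(pd.DataFrame({
            "frame_index": fd.frame_index,
            "probe_id": probe_frames[t].probes["probe_id"],
            "pH_measured": fd.ph_obs,
            "pH_reconstructed": rec,
            "residual": rec - fd.ph_obs,
            "sigma": fd.sigma,
        }))
    diag = dict(diag)
    diag.update({
        "lambda1": lam1, "lambda2": lam2, "lambda3": lam3,
        "seed": hyper.seed, "chi2_map": map_cost,
        "c0_per_frame": [fd.c0 for fd in problem.frames],
    })
    return FluxSolution(
        frame_indices=[fd.frame_index for fd in problem.frames],
        times_min=[fd.time_min for fd in problem.frames],
        map_fluxes=flux_vectors, ci_low=lows, ci_high=highs, sigma_u=sigs,
        chi2_tot=map_cost, acceptance_rate=diag["acceptance_rate"],
        residuals=residuals, diagnostics=diag,
    )


def _split(problem: Problem, flat: np.ndarray) -> list:
    out, k = [], 0
    for fd in problem.frames:
        out.append(flat[k:k + fd.n_state].copy())
        k += fd.n_state
    return out
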