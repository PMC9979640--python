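"""Stationary proton-field forward model.

Under stationarity the extracellular proton concentration solves the Laplace
equation away from the cells; each cell enters as the leading (monopole) term
of a multipole expansion, so

    c(r) = c0 + sum_i u_i / (4 pi D |r - r_i|) + U * G_B(r),

where u_i is the net single-cell flux (mol/s; positive exports protons and
lowers nearby pH), D the diffusion coefficient and U the flux entering
through the frame boundary B, discretized as n equally spaced virtual
sources along the perimeter. With positions in μm and D in μm²/s the
monopole term carries mol/μm³; an explicit 1e15 μm³/L factor converts it to
mol/L. pH is the negative decimal log of the molar concentration.
"""
from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from .params import PhysicalParams
from .tables import CellFrame, ProbeFrame, FluxVector

#: volume conversion: 1 L = 1e15 μm³
UM3_PER_LITER = 1.0e15

#: mol/s -> mmol/h
MMOL_PER_H_PER_MOL_PER_S = 3.6e6


class CoincidentPointError(ValueError):
    """A probe coincides exactly with a cell (zero distance)."""


class UnphysicalConcentrationError(ValueError):
    """A predicted concentration is non-positive; pH is undefined there."""


def boundary_points(params: PhysicalParams, n: int | None = None) -> np.ndarray:
    """Equally spaced points on the perimeter of the [0, L]² frame.

    Points sit at arc-length midpoints so that no virtual source lands
    exactly on a corner.
    """
    if n is None:
        n = params.boundary_discretization_n
    L = params.frame_size_L
    s = (np.arange(n) + 0.5) * (4.0 * L / n)
    pts = np.empty((n, 2))
    for k, sk in enumerate(s):
        edge, t = divmod(sk, L)
        if edge == 0:      # bottom, left -> right
            pts[k] = (t, 0.0)
        elif edge == 1:    # right, bottom -> top
            pts[k] = (L, t)
        elif edge == 2:    # top, right -> left
            pts[k] = (L - t, L)
        else:              # left, top -> bottom
            pts[k] = (0.0, L - t)
    return pts


def monopole_kernel(dist_um: np.ndarray, params: PhysicalParams) -> np.ndarray:
    """Monopole kernel 1/(4 pi D r) with the μm³ -> L volume factor.

    Multiplying by a flux in mol/s yields a concentration in mol/L.
    Distances are clamped from below at ``params.min_distance_um``.
    """
    d = np.maximum(np.asarray(dist_um, dtype=float), params.min_distance_um)
    return UM3_PER_LITER / (4.0 * np.pi * params.diffusion_coefficient * d)


def build_distance_matrix(cells: CellFrame, probes: ProbeFrame,
                          params: PhysicalParams) -> np.ndarray:
    """Kernel matrix Ĝ mapping the flux state [U, u_1..u_N] to mol/L.

    Shape (M, N+1). Column 0 is the boundary kernel: the mean monopole
    kernel over the perimeter discretization carrying total flux U.
    Columns 1..N are per-cell monopole kernels. Exactly coincident
    probe/cell positions raise :class:`CoincidentPointError`; distances
    below the clamp radius are clamped (finite cell size).
    """
    probe_xy = probes.positions()
    cell_xy = cells.positions()
    M = len(probe_xy)
    if len(cell_xy):
        d = cdist(probe_xy, cell_xy)
        if np.any(d == 0.0):
            mu, i = np.argwhere(d == 0.0)[0]
            raise CoincidentPointError(
                f"probe {probes.probes['probe_id'].iloc[mu]!r} coincides with "
                f"cell {cells.cells['cell_id'].iloc[i]!r} in frame {cells.frame_index}"
            )
        k_cells = monopole_kernel(d, params)
    else:
        k_cells = np.empty((M, 0))
    bpts = boundary_points(params)
    k_boundary = monopole_kernel(cdist(probe_xy, bpts), params).mean(axis=1)
    return np.column_stack([k_boundary, k_cells])


def concentration_field(flux_state: np.ndarray, kernel: np.ndarray,
                        c0: float) -> np.ndarray:
    """Predicted concentration c_mu = c0 + Ĝ·u at each probe (mol/L).

    ``flux_state`` is [U, u_1..u_N] in mol/s. The result may contain
    non-positive entries for unphysical flux vectors; the caller decides
    (the likelihood treats them as -inf log-probability).
    """
    flux_state = np.asarray(flux_state, dtype=float)
    if kernel.shape[1] != flux_state.shape[0]:
        raise ValueError(
            f"kernel has {kernel.shape[1]} columns but flux state has "
            f"{flux_state.shape[0]} entries"
        )
    return c0 + kernel @ flux_state


def predicted_ph(c: np.ndarray) -> np.ndarray:
    """pH_mu = -log10(c_mu) for molar concentrations c."""
    c = np.asarray(c, dtype=float)
    if np.any(c <= 0):
        raise UnphysicalConcentrationError(
            f"{int(np.sum(c <= 0))} non-positive concentration(s); pH undefined"
        )
    return -np.log10(c)


def concentration_at_points(cell_xy: np.ndarray, u_native: np.ndarray,
                            params: PhysicalParams, points: np.ndarray,
                            c0: float = 0.0, boundary_U: float = 0.0) -> np.ndarray:
    """Evaluate the monopole field at arbitrary 2D or 3D points.

    The kernel is three-dimensional (the planar frame is a section of the
    3D diffusion field), so evaluation points may carry a z coordinate;
    cells sit in the z = 0 plane. Used by harmonicity / Gauss-law checks.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[None, :]
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    cell_xyz = np.column_stack([np.asarray(cell_xy, float),
                                np.zeros(len(cell_xy))])
    d = cdist(pts, cell_xyz)
    c = c0 + monopole_kernel(d, params) @ np.asarray(u_native, float)
    if boundary_U != 0.0:
        bpts = np.column_stack([boundary_points(params), np.zeros(params.boundary_discretization_n)])
        c = c + boundary_U * monopole_kernel(cdist(pts, bpts), params).mean(axis=1)
    return c


def convert_flux_units(u_native, params: PhysicalParams):
    """mol/s -> mmol/gdw/h using the configured cell dry weight."""
    dry_weight_g = params.cell_dry_weight_ng * 1e-9
    return np.multiply(u_native, MMOL_PER_H_PER_MOL_PER_S / dry_weight_g)


def reported_to_native(u_reported, params: PhysicalParams):
    """mmol/gdw/h -> mol/s (inverse of :func:`convert_flux_units`)."""
    dry_weight_g = params.cell_dry_weight_ng * 1e-9
    return np.multiply(u_reported, dry_weight_g / MMOL_PER_H_PER_MOL_PER_S)


def native_per_reported(params: PhysicalParams) -> float:
    """Scale factor: one reported flux unit expressed in mol/s."""
    return params.cell_dry_weight_ng * 1e-9 / MMOL_PER_H_PER_MOL_PER_S


def predict_frame_ph(flux: FluxVector, cells: CellFrame, probes: ProbeFrame,
                     params: PhysicalParams, c0: float | None = None) -> np.ndarray:
    """Convenience: predicted pH at the probes of one frame.

    ``flux`` is in reported units (mmol/gdw/h); ``c0`` defaults to
    ``params.default_c0()``.
    """
    if list(flux.cell_ids) != cells.cell_ids:
        raise ValueError("flux vector cell ids do not match the cell frame")
    kernel = build_distance_matrix(cells, probes, params)
    state_native = flux.to_state() * native_per_reported(params)
    c = concentration_field(state_native, kernel, params.default_c0() if c0 is None else c0)
    return predicted_ph(c)
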