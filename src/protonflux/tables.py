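"""In-memory containers for per-frame observations and inference results."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CELL_COLUMNS = ("cell_id", "x_um", "y_um")
PROBE_COLUMNS = ("probe_id", "x_um", "y_um", "pH", "sigma")

PH_MIN, PH_MAX = 3.0, 11.0


class TableValidationError(ValueError):
    """A cell/probe table violates its schema or a physical invariant."""


@dataclass
class CellFrame:
    """Positions and identities of the cells observed in one frame.

    ``cells`` holds columns cell_id, x_um, y_um and optionally cell_type
    (one of tumor/fibroblast/unknown). Coordinates use the lower-left
    corner of the frame as origin, y increasing upward.
    """

    frame_index: int
    time_min: float
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise TableValidationError(f"cell frame {self.frame_index}: missing columns {missing}")
        if self.cells["cell_id"].duplicated().any():
            dup = self.cells["cell_id"][self.cells["cell_id"].duplicated()].tolist()
            raise TableValidationError(
                f"cell frame {self.frame_index}: duplicated cell_id {dup}"
            )
        self.cells = self.cells.reset_index(drop=True)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_ids(self) -> list:
        return self.cells["cell_id"].tolist()

    def positions(self) -> np.ndarray:
        return self.cells[["x_um", "y_um"]].to_numpy(float)

    def validate_bounds(self, frame_size_L: float) -> None:
        xy = self.positions()
        if xy.size and (xy.min() < 0 or xy.max() > frame_size_L):
            bad = np.where((xy < 0) | (xy > frame_size_L))[0]
            raise TableValidationError(
                f"cell frame {self.frame_index}: positions outside [0, {frame_size_L}] "
                f"at rows {sorted(set(bad.tolist()))}"
            )


@dataclass
class ProbeFrame:
    """Probe positions with measured pH and per-probe standard deviation."""

    frame_index: int
    time_min: float
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PROBE_COLUMNS if c not in self.probes.columns]
        if missing:
            raise TableValidationError(f"probe frame {self.frame_index}: missing columns {missing}")
        sig = self.probes["sigma"].to_numpy(float)
        if np.any(~np.isfinite(sig)) or np.any(sig <= 0):
            rows = np.where(~(sig > 0))[0].tolist()
            raise TableValidationError(
                f"probe frame {self.frame_index}: sigma must be > 0 (rows {rows})"
            )
        ph = self.probes["pH"].to_numpy(float)
        if np.any((ph < PH_MIN) | (ph > PH_MAX)):
            rows = np.where((ph < PH_MIN) | (ph > PH_MAX))[0].tolist()
            raise TableValidationError(
                f"probe frame {self.frame_index}: pH outside [{PH_MIN}, {PH_MAX}] (rows {rows})"
            )
        self.probes = self.probes.reset_index(drop=True)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def positions(self) -> np.ndarray:
        return self.probes[["x_um", "y_um"]].to_numpy(float)

    def ph_values(self) -> np.ndarray:
        return self.probes["pH"].to_numpy(float)

    def sigmas(self) -> np.ndarray:
        return self.probes["sigma"].to_numpy(float)


@dataclass
class FluxVector:
    """Per-cell net proton fluxes plus the frame-boundary flux U.

    Values are in mmol/gdw/h unless ``units`` says otherwise. Positive
    values export protons (acidify, lower nearby pH); negative values
    import them.
    """

    boundary_flux_U: float
    cell_ids: tuple
    values: np.ndarray
    units: str = "mmol/gdw/h"

    def __post_init__(self) -> None:
        self.cell_ids = tuple(self.cell_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids),):
            raise ValueError("values must align one-to-one with cell_ids")
        if not np.isfinite(self.values).all() or not np.isfinite(self.boundary_flux_U):
            raise ValueError("fluxes must be finite")

    def as_dict(self) -> dict:
        return dict(zip(self.cell_ids, self.values.tolist()))

    def to_state(self) -> np.ndarray:
        """Concatenated state [U, u_1, ..., u_N] used by the solvers."""
        return np.concatenate([[self.boundary_flux_U], self.values])

    @classmethod
    def from_state(cls, state: np.ndarray, cell_ids: Sequence, units: str = "mmol/gdw/h"):
        state = np.asarray(state, dtype=float)
        return cls(boundary_flux_U=float(state[0]), cell_ids=tuple(cell_ids),
                   values=state[1:].copy(), units=units)


@dataclass
class BulkSeries:
    """Bulk medium proton concentration and per-cell bulk efflux over time."""

    times_min: np.ndarray
    bulk_concentration: np.ndarray  # mol/L
    bulk_efflux: np.ndarray  # mmol/gdw/h per cell

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.bulk_concentration = np.asarray(self.bulk_concentration, dtype=float)
        self.bulk_efflux = np.asarray(self.bulk_efflux, dtype=float)
        n = len(self.times_min)
        if len(self.bulk_concentration) != n or len(self.bulk_efflux) != n:
            raise ValueError("bulk series components must share one length")

    @property
    def bulk_ph(self) -> np.ndarray:
        return -np.log10(self.bulk_concentration)


@dataclass
class FluxSolution:
    """MAP fluxes with credible intervals and fit diagnostics.

    Per-frame arrays (``ci_low``, ``ci_high``, ``sigma_u``) are aligned with
    the state ordering [U, cells...]; ``residuals`` holds one DataFrame per
    frame with reconstructed-minus-measured pH per probe.
    """

    frame_indices: list
    times_min: list
    map_fluxes: list  # list[FluxVector]
    ci_low: list
    ci_high: list
    sigma_u: list
    chi2_tot: float
    acceptance_rate: float
    residuals: list  # list[pd.DataFrame]
    diagnostics: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        """Tidy per-cell table (one row per frame x cell)."""
        rows = []
        for k, fv in enumerate(self.map_fluxes):
            for j, cid in enumerate(fv.cell_ids):
                rows.append({
                    "frame_index": self.frame_indices[k],
                    "time_min": self.times_min[k],
                    "cell_id": cid,
                    "u_map_mmol_gdw_h": fv.values[j],
                    "ci_low": self.ci_low[k][j + 1],
                    "ci_high": self.ci_high[k][j + 1],
                    "sigma_u": self.sigma_u[k][j + 1],
                })
        return pd.DataFrame(rows)

    def boundary_dataframe(self) -> pd.DataFrame:
        rows = []
        for k, fv in enumerate(self.map_fluxes):
            rows.append({
                "frame_index": self.frame_indices[k],
                "time_min": self.times_min[k],
                "U_map_mmol_gdw_h": fv.boundary_flux_U,
                "ci_low": self.ci_low[k][0],
                "ci_high": self.ci_high[k][0],
                "sigma_u": self.sigma_u[k][0],
            })
        return pd.DataFrame(rows)

    def residuals_dataframe(self) -> pd.DataFrame:
        return pd.concat(self.residuals, ignore_index=True)
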