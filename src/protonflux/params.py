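"""Physical and inference parameter containers.

All lengths are in micrometres, the diffusion coefficient in μm²/s, native
fluxes in mol/s, concentrations in mol/L, and reported fluxes in mmol per
gram dry weight per hour (mmol/gdw/h).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass(frozen=True)
class PhysicalParams:
    """Physical constants of the observed field.

    Parameters
    ----------
    diffusion_coefficient : float
        Proton diffusion coefficient D in μm²/s. The default 7e3 μm²/s is
        the literature value for protons in aqueous medium.
    frame_size_L : float
        Linear size of the square visual field, in μm.
    cell_dry_weight_ng : float
        Average single-cell dry weight in ng, used to express fluxes in
        mmol/gdw/h. Default 0.5 ng.
    background_concentration_c0 : float or None
        Background proton concentration (mol/L) far from any source. When
        None, downstream code estimates it per frame from the median probe
        pH (inference) or derives it from ``medium_ph`` (simulation).
    medium_ph : float
        Reference medium pH used to derive a default c0 when
        ``background_concentration_c0`` is None.
    boundary_discretization_n : int
        Number of virtual point sources equally spaced along the frame
        perimeter that discretize the boundary flux U.
    min_distance_um : float
        Minimum probe-source distance (μm). Distances below this are clamped
        to it: the point-source field diverges as r -> 0 and the clamp
        encodes the finite ~10 μm cell diameter.
    medium_volume_L : float
        Volume of the culture medium (L), used to convert bulk pH drift
        into a per-cell bulk efflux.
    """

    diffusion_coefficient: float = 7.0e3
    frame_size_L: float = 500.0
    cell_dry_weight_ng: float = 0.5
    background_concentration_c0: float | None = None
    medium_ph: float = 6.5
    boundary_discretization_n: int = 64
    min_distance_um: float = 5.0
    medium_volume_L: float = 1.0e-3

    def __post_init__(self) -> None:
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion_coefficient must be > 0")
        if self.frame_size_L <= 0:
            raise ValueError("frame_size_L must be > 0")
        if self.cell_dry_weight_ng <= 0:
            raise ValueError("cell_dry_weight_ng must be > 0")
        if self.background_concentration_c0 is not None and self.background_concentration_c0 <= 0:
            raise ValueError("background_concentration_c0 must be > 0")
        if self.boundary_discretization_n < 4:
            raise ValueError("boundary_discretization_n must be >= 4")
        if self.min_distance_um <= 0:
            raise ValueError("min_distance_um must be > 0")
        if self.medium_volume_L <= 0:
            raise ValueError("medium_volume_L must be > 0")

    def default_c0(self) -> float:
        """Background concentration: explicit value, or 10**(-medium_ph)."""
        if self.background_concentration_c0 is not None:
            return self.background_concentration_c0
        return 10.0 ** (-self.medium_ph)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class Hyperparams:
    """Regularization and sampler settings.

    lambda1 weighs the per-frame Gaussian (Tikhonov) prior on the cell
    fluxes, lambda2 the temporal-smoothness penalty on tracked cells, and
    lambda3 the soft constraint tying the per-frame mean flux to the bulk
    efflux. A value of None means "resolve a default at fit time": lambda1
    by generalized cross-validation on the linearized problem, lambda2 as
    lambda1/10, lambda3 so the bulk term starts at ~10% of the data misfit
    (0 when no bulk series is supplied).
    """

    lambda1: float | None = None
    lambda2: float | None = None
    lambda3: float | None = None
    bulk_constraint: str = "mean"  # "mean" or "sum" of cell fluxes per frame
    anneal_t_initial: float = 100.0
    anneal_cooling: float = 0.95
    anneal_sweeps_per_temp: int = 200
    n_samples: int = 2000
    burn_in: int = 500
    target_acceptance: float = 0.3
    ci_level: float = 0.68
    max_displacement_um: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bulk_constraint not in ("mean", "sum"):
            raise ValueError("bulk_constraint must be 'mean' or 'sum'")
        if self.anneal_t_initial < 1.0:
            raise ValueError("anneal_t_initial must be >= 1 (annealing cools down to T=1)")
        if not 0.0 < self.anneal_cooling < 1.0:
            raise ValueError("anneal_cooling must be in (0, 1)")
        if self.anneal_sweeps_per_temp < 1:
            raise ValueError("anneal_sweeps_per_temp must be >= 1")
        if self.n_samples < 1 or self.burn_in < 0:
            raise ValueError("n_samples must be >= 1 and burn_in >= 0")
        if not 0.0 < self.target_acceptance < 1.0:
            raise ValueError("target_acceptance must be in (0, 1)")
        if not 0.0 <= self.ci_level < 1.0:
            raise ValueError("ci_level must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)
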