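"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here: confined
correlated-random-walk trajectories (the movement model run generatively
with T = identity), cells with noisy membrane edge points, per-frame focus
extents, peripherally biased aggregate positions, per-cell aggregate
counts and binomial colony counts.  All generators are bit-reproducible
for a fixed seed.

The two presets emulate the study conditions of the tracked strains:

* ``wildtype`` — one focus per cell, 5 foci from 5 cells, per-axis step
  scale tuned so the mean 3D step is ~0.75 μm per 10 s, foci growing and
  slowing as they mature, ~88% of scored cells with a single aggregate.
* ``act1-122`` — 11 foci from 6 cells in a small-mobile / large-static
  mixture (overall mean step ~0.55 μm per 10 s), fewer than half of the
  scored cells with a single aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .analysis_stats import InductionCount
from .cell_geometry import FittedSphere
from .exceptions import ValidationError
from .trajectory_io import CellEdgeSet, CountTable, Trajectory

#: Mean of a 3D isotropic Gaussian step norm in units of the per-axis
#: standard deviation (chi distribution with 3 degrees of freedom).
CHI3_MEAN = 2.0 * np.sqrt(2.0 / np.pi)

#: Per-axis step scales (μm) implied by mean 3D steps of ~0.75 / ~0.55 μm.
WILDTYPE_SIGMA = 0.75 / CHI3_MEAN
ACT1_122_SIGMA = 0.55 / CHI3_MEAN


@dataclass
class SimulationParams:
    """Ground-truth parameters for one simulated focus trajectory.

    ``sigma_true`` may be a callable mapping current focus volume (μm³)
    to a per-axis step scale, emulating size-dependent mobility; by
    default it is a constant.
    """

    gamma_true: float = 0.0  # directional correlation, [0, 1)
    sigma_true: float | Callable[[float], float] = 0.25  # μm per step, per axis
    n_steps: int = 100  # steps => n_steps + 1 frames
    frame_interval: float = 10.0  # s
    cell_radius: float = 2.5  # μm
    boundary: str = "reflecting"  # 'reflecting' or 'none'
    start: str = "center"  # 'center' or 'random'
    focus_growth: float = 0.0  # μm³ per step
    focus_volume0: float = 0.25  # initial focus volume, μm³; 0 => no extents
    peripheral_bias: float = 0.0  # radial density ∝ r^(2 + bias)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma_true < 1.0):
            raise ValidationError(
                f"gamma_true must be in [0, 1); got {self.gamma_true} "
                "(the autoregressive step process is nonstationary at 1)"
            )
        if not callable(self.sigma_true) and self.sigma_true < 0:
            raise ValidationError("sigma_true must be nonnegative")
        if self.n_steps < 4:
            raise ValidationError("n_steps must be >= 4")
        if self.cell_radius <= 0:
            raise ValidationError("cell_radius must be positive")
        if self.boundary not in ("reflecting", "none"):
            raise ValidationError(f"unknown boundary {self.boundary!r}")
        if self.start not in ("center", "random"):
            raise ValidationError(f"unknown start {self.start!r}")
        if self.focus_growth < 0 or self.peripheral_bias < 0:
            raise ValidationError("focus_growth and peripheral_bias must be >= 0")


def _reflect_into_sphere(p: np.ndarray, radius: float) -> np.ndarray:
    """Specular radial fold of a point into the sphere |p| <= radius."""
    r = np.linalg.norm(p)
    while r > radius:
        p = p * (2.0 * radius - r) / r
        r = np.linalg.norm(p)
    return p


def simulate_trajectory(
    params: SimulationParams,
    focus_id: str = "focus",
    cell_id: str = "cell",
    label: str = "",
) -> Trajectory:
    """Simulate one focus trajectory from the movement model.

    Steps follow d_t = gamma_true * d_{t-1} + eps_t with eps_t isotropic
    Gaussian of per-axis scale sigma_true; a reflecting boundary folds
    positions at the sphere of ``cell_radius`` (positions are cell-centred
    coordinates).  When ``focus_volume0 > 0`` the trajectory carries
    per-frame extents of a sphere-equivalent focus growing linearly in
    volume at ``focus_growth`` μm³/step.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_steps
    radius = params.cell_radius
    positions = np.empty((n + 1, 3))
    if params.start == "center":
        positions[0] = 0.0
    else:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        positions[0] = radius * rng.random() ** (1.0 / 3.0) * u

    volumes = params.focus_volume0 + params.focus_growth * np.arange(n + 1)
    sigma_of = (
        params.sigma_true
        if callable(params.sigma_true)
        else (lambda _v, s=float(params.sigma_true): s)
    )

    d_prev = np.zeros(3)
    for t in range(n):
        eps = rng.normal(0.0, sigma_of(float(volumes[t])), size=3)
        proposal = positions[t] + params.gamma_true * d_prev + eps
        if params.boundary == "reflecting":
            proposal = _reflect_into_sphere(proposal, radius)
        positions[t + 1] = proposal
        d_prev = positions[t + 1] - positions[t]

    extents = None
    if params.focus_volume0 > 0:
        # sphere-equivalent full extents from the volume track
        lengths = 2.0 * (3.0 * volumes / (4.0 * np.pi)) ** (1.0 / 3.0)
        extents = np.repeat(lengths[:, None], 3, axis=1)

    times = np.arange(n + 1, dtype=float) * params.frame_interval
    return Trajectory(
        focus_id=focus_id,
        cell_id=cell_id,
        times=times,
        positions=positions,
        extents=extents,
        label=label,
    )


def _fibonacci_directions(n: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the sphere (Fibonacci lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def simulate_cell(
    cell_radius: float,
    edge_noise: float = 0.0,
    n_edges: int = 6,
    seed: int = 0,
    center: Sequence[float] = (0.0, 0.0, 0.0),
    cell_id: str = "cell",
) -> CellEdgeSet:
    """Membrane edge points: quasi-uniform directions, Gaussian radial noise."""
    if edge_noise < 0:
        raise ValidationError("edge_noise must be nonnegative")
    if n_edges < 4:
        raise ValidationError("n_edges must be >= 4 for sphere fitting")
    if cell_radius <= 0:
        raise ValidationError("cell_radius must be positive")
    rng = np.random.default_rng(seed)
    dirs = _fibonacci_directions(n_edges)
    radii = cell_radius + rng.normal(0.0, edge_noise, size=n_edges)
    pts = np.asarray(center, dtype=float) + radii[:, None] * dirs
    return CellEdgeSet(cell_id=cell_id, edge_points=pts)


def simulate_aggregate_positions(
    sphere: FittedSphere,
    n: int,
    peripheral_bias: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Aggregate positions with tunable peripheral bias.

    The radial coordinate is drawn with density ∝ r^(2 + bias) on [0, R]
    (bias 0 is uniform in volume; larger bias concentrates mass at the
    membrane), direction uniform on the sphere.
    """
    if peripheral_bias < 0:
        raise ValidationError("peripheral_bias must be nonnegative")
    rng = np.random.default_rng(seed)
    exponent = 3.0 + peripheral_bias
    r = sphere.radius * rng.random(n) ** (1.0 / exponent)
    dirs = rng.normal(size=(n, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return sphere.center + r[:, None] * dirs


def simulate_induction_counts(
    true_frequency: float,
    cfu_total: int = 100,
    density_factor: float = 100.0,
    seed: int = 0,
) -> InductionCount:
    """Binomial colony counts for a prion-induction plating experiment.

    ``cfu_total`` cells are plated on permissive medium and
    ``cfu_total × density_factor`` on selective medium; the selective
    colony count is Binomial with success probability ``true_frequency``,
    making the derived frequency estimate unbiased.
    """
    if not (0.0 <= true_frequency <= 1.0):
        raise ValidationError("true_frequency must be in [0, 1]")
    if cfu_total <= 0:
        raise ValidationError("cfu_total must be positive")
    rng = np.random.default_rng(seed)
    n_plated = int(round(cfu_total * density_factor))
    colonies = int(rng.binomial(n_plated, true_frequency))
    return InductionCount(
        colonies_selective=colonies,
        cfu_total=int(cfu_total),
        density_factor=float(density_factor),
    )


# -- presets ---------------------------------------------------------------

#: Aggregate-per-cell mixtures used when scoring cells per preset.
_COUNT_MIXTURES = {
    "wildtype": ([1, 2, 3], [0.88, 0.09, 0.03]),
    "act1-122": ([1, 2, 3, 4, 5], [0.45, 0.25, 0.15, 0.10, 0.05]),
}

_INDUCTION_FREQUENCY = {"wildtype": 0.006, "act1-122": 0.0035}


def _size_dependent_sigma(sigma0: float, v0: float) -> Callable[[float], float]:
    # mobility falls as the focus matures: per-axis scale ∝ v^(-2/3)
    return lambda v: sigma0 * (v0 / max(v, v0)) ** (2.0 / 3.0)


def simulate_preset(
    preset: str, seed: int = 0, n_cells_scored: int = 100
) -> dict:
    """Generate a full synthetic data set for one strain preset.

    Returns a dict with ``trajectories`` (list of Trajectory), ``edges``
    (list of CellEdgeSet), ``counts`` (CountTable of aggregates per cell)
    and ``plates`` (DataFrame of colony counts from three transformants).
    """
    if preset not in _COUNT_MIXTURES:
        raise ValidationError(
            f"unknown preset {preset!r}; choose 'wildtype' or 'act1-122'"
        )
    rng = np.random.default_rng(seed)
    trajectories: list[Trajectory] = []
    edges: list[CellEdgeSet] = []

    if preset == "wildtype":
        # five cells, one growing-and-slowing focus each
        specs = [
            ("single", WILDTYPE_SIGMA, 0.20 + 0.06 * i, 0.010) for i in range(5)
        ]
        cells = [f"wt_cell{i+1}" for i in range(5)]
        focus_cells = list(range(5))
    else:
        # six cells, 11 foci: one large static focus per cell + 5 small
        specs = [("large", 0.18, 1.00 + 0.10 * i, 0.004) for i in range(6)]
        specs += [("small", 0.50, 0.14 + 0.03 * i, 0.008) for i in range(5)]
        cells = [f"act_cell{i+1}" for i in range(6)]
        focus_cells = list(range(6)) + [0, 1, 2, 3, 4]

    for k, ((size_class, sigma0, v0, growth), ci) in enumerate(
        zip(specs, focus_cells)
    ):
        radius = float(rng.normal(2.5, 0.15))
        params = SimulationParams(
            gamma_true=0.0,
            sigma_true=_size_dependent_sigma(sigma0, v0),
            n_steps=100,
            cell_radius=radius,
            boundary="reflecting",
            start="random",
            focus_growth=growth,
            focus_volume0=v0,
            seed=int(rng.integers(2**31)),
        )
        trajectories.append(
            simulate_trajectory(
                params,
                focus_id=f"{preset}_f{k+1}",
                cell_id=cells[ci],
                label=preset if preset == "wildtype" else f"{preset}:{size_class}",
            )
        )

    for cell_id in cells:
        edges.append(
            simulate_cell(
                float(rng.normal(2.5, 0.15)),
                edge_noise=0.05,
                n_edges=6,
                seed=int(rng.integers(2**31)),
                cell_id=cell_id,
            )
        )

    values, probs = _COUNT_MIXTURES[preset]
    counts = rng.choice(values, size=n_cells_scored, p=probs)
    count_df = pd.DataFrame(
        {
            "cell_id": [f"{preset}_scored{i+1}" for i in range(n_cells_scored)],
            "group": preset,
            "count": counts,
        }
    )

    plate_rows = []
    for rep in range(3):
        ic = simulate_induction_counts(
            _INDUCTION_FREQUENCY[preset],
            cfu_total=100,
            density_factor=100.0,
            seed=int(rng.integers(2**31)),
        )
        plate_rows.append(
            {
                "group": preset,
                "replicate": rep + 1,
                "colonies_selective": ic.colonies_selective,
                "cfu_total": ic.cfu_total,
                "density_factor": ic.density_factor,
            }
        )

    return {
        "trajectories": trajectories,
        "edges": edges,
        "counts": CountTable(count_df),
        "plates": pd.DataFrame(plate_rows),
    }
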