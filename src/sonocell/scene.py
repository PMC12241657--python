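"""Synthetic scenes: vessel phantom, flow, tissue speckle, tumor fields.

Geometry convention (stated once, used everywhere): x is lateral (array
axis, origin at array center), z is axial (depth, positive away from the
array), both in metres; all extents are half-open intervals.

Scenes are collections of point scatterers of three kinds:

* ``tissue``   -- linear scatterers with Rayleigh-distributed reflectivity
  at >= 10 per resolution cell (fully developed speckle),
* ``unlabeled_cell`` -- linear scatterers whose reflectivity is drawn from
  the *same* distribution as tissue, encoding that an unlabeled
  macrophage's scattering cross-section is comparable to host cells,
* ``bubble``   -- nonlinear scatterers carrying shelled-bubble parameters
  (one microbubble per labeled cell); a labeled cell also contributes a
  tissue-like linear scatterer for its cell body.

The vessel phantom is wall-less: a fluid channel of default diameter
1.6 mm containing only cells, embedded in gel speckle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .acoustics import AcousticContext, diffraction_limits
from .bubble_dynamics import BubbleParams

__all__ = [
    "KIND_TISSUE",
    "KIND_UNLABELED_CELL",
    "KIND_BUBBLE",
    "Channel",
    "Scene",
    "expected_cell_count",
    "round_to_one_significant_figure",
    "make_vessel_phantom",
    "make_tissue_field",
    "advance_flow",
    "make_tumor_scene",
    "save_scene",
    "load_scene",
]

KIND_TISSUE = 0
KIND_UNLABELED_CELL = 1
KIND_BUBBLE = 2

#: Default full array aperture (m), used to size the resolution cell.
DEFAULT_APERTURE = 28e-3

#: Rayleigh scale of tissue/unlabeled-cell reflectivity (arbitrary
#: reflectivity units; the RF simulator's bubble coupling is calibrated
#: against this scale).
TISSUE_REFLECTIVITY_SCALE = 1.0


@dataclass(frozen=True)
class Channel:
    """Wall-less flow channel running laterally through the phantom."""

    center_depth: float = 5e-3
    diameter: float = 1.6e-3
    flow_speed: float = 0.0

    def contains(self, positions: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the channel cross-section.

        The channel axis is perpendicular to the imaging plane, so its
        cross-section is a disk centered on (0, center_depth).
        """
        positions = np.atleast_2d(positions)
        r2 = positions[:, 0] ** 2 + (positions[:, 1] - self.center_depth) ** 2
        return r2 <= (self.diameter / 2.0) ** 2


@dataclass
class Scene:
    """Point-scatterer description of one imaging plane."""

    positions: np.ndarray
    reflectivity: np.ndarray
    kind: np.ndarray
    velocities: np.ndarray
    x_limits: tuple[float, float]
    z_limits: tuple[float, float]
    channel: Channel | None = None
    bubble_params: BubbleParams | None = None
    rng_seed: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.positions.shape[0]
        if not (self.reflectivity.shape == (n,) and self.kind.shape == (n,)):
            raise ValueError("scatterer arrays must share their leading dimension")
        if np.any(self.reflectivity < 0):
            raise ValueError("reflectivity must be non-negative")
        x, z = self.positions[:, 0], self.positions[:, 1]
        if n and (
            x.min() < self.x_limits[0]
            or x.max() >= self.x_limits[1]
            or z.min() < self.z_limits[0]
            or z.max() >= self.z_limits[1]
        ):
            raise ValueError("all scatterers must lie inside the scene extent")

    @property
    def n_scatterers(self) -> int:
        return self.positions.shape[0]

    def count(self, kind: int) -> int:
        return int(np.sum(self.kind == kind))


def round_to_one_significant_figure(x: float) -> int:
    """Round a non-negative number to one significant figure."""
    if x < 0:
        raise ValueError("x must be non-negative")
    if x == 0:
        return 0
    d = math.floor(math.log10(x))
    # round half up (the convention for reporting cell counts)
    return int(math.floor(x / 10**d + 0.5) * 10**d)


def expected_cell_count(concentration: float, volume: float) -> tuple[float, int]:
    """Expected cell count in a sonication volume and its 1-sig-fig estimate.

    Parameters
    ----------
    concentration : float
        Cell concentration, cells/ml.
    volume : float
        Sonication/imaging volume, µl.

    Returns
    -------
    (expected, estimate)
        ``expected = concentration * volume`` (unit-consistent, cells) and
        the one-significant-figure integer estimate.
    """
    if concentration < 0 or volume < 0:
        raise ValueError("concentration and volume must be non-negative")
    expected = concentration * volume * 1e-3  # µl -> ml
    return expected, round_to_one_significant_figure(expected)


def _speckle_density(context: AcousticContext, depth: float, per_cell: float = 10.0) -> float:
    """Scatterers per m^2 giving ``per_cell`` per resolution cell."""
    spec = diffraction_limits(context, DEFAULT_APERTURE, depth, 2.0)
    cell_area = (spec.lateral_um * 1e-6) * (spec.axial_um * 1e-6)
    return per_cell / cell_area


def _rayleigh_reflectivity(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.rayleigh(TISSUE_REFLECTIVITY_SCALE, n)


def make_tissue_field(
    context: AcousticContext,
    seed: int,
    x_limits: tuple[float, float] = (-1.5e-3, 1.5e-3),
    z_limits: tuple[float, float] = (3.4e-3, 6.6e-3),
    unlabeled_cell_fraction: float = 0.0,
    scatterers_per_resolution_cell: float = 10.0,
) -> Scene:
    """Homogeneous speckle field, optionally with unlabeled cells mixed in.

    ``unlabeled_cell_fraction`` of the scatterers are tagged as unlabeled
    cells; their reflectivity comes from the same Rayleigh distribution as
    tissue, so the field is statistically identical to pure tissue -- the
    simulated analogue of unlabeled macrophages being invisible against
    host tissue.
    """
    rng = np.random.default_rng(seed)
    area = (x_limits[1] - x_limits[0]) * (z_limits[1] - z_limits[0])
    depth = 0.5 * (z_limits[0] + z_limits[1])
    n = rng.poisson(_speckle_density(context, depth, scatterers_per_resolution_cell) * area)
    pos = np.column_stack(
        [
            rng.uniform(x_limits[0], x_limits[1], n),
            rng.uniform(z_limits[0], z_limits[1], n),
        ]
    )
    kind = np.full(n, KIND_TISSUE, dtype=np.int8)
    n_cells = int(round(unlabeled_cell_fraction * n))
    if n_cells:
        kind[rng.choice(n, n_cells, replace=False)] = KIND_UNLABELED_CELL
    return Scene(
        positions=pos,
        reflectivity=_rayleigh_reflectivity(rng, n),
        kind=kind,
        velocities=np.zeros((n, 2)),
        x_limits=x_limits,
        z_limits=z_limits,
        rng_seed=seed,
    )


def make_vessel_phantom(
    concentration: float,
    labeled_fraction: float,
    context: AcousticContext,
    seed: int,
    channel: Channel | None = None,
    x_limits: tuple[float, float] = (-1.5e-3, 1.5e-3),
    z_limits: tuple[float, float] = (3.4e-3, 6.6e-3),
    imaging_volume_ul: float = 3.2,
    count_mode: Literal["poisson", "exact"] = "poisson",
    bubble_params: BubbleParams | None = None,
    scatterers_per_resolution_cell: float = 10.0,
    gel_reflectivity_scale: float = 0.25,
) -> Scene:
    """Wall-less gelatin vessel phantom carrying a cell suspension.

    Gel speckle surrounds a fluid channel (default 1.6 mm diameter at
    5 mm depth) that contains no tissue scatterers.  The number of cells
    in the imaged volume is Poisson with mean
    ``concentration x imaging_volume_ul`` (``count_mode="exact"`` places
    the rounded expected count instead -- used when the experimental
    protocol fixes the realized count).  ``labeled_fraction`` of the
    cells carry a microbubble.

    The gel is acoustically weak (16% gelatin is nearly transparent), so
    its speckle reflectivity is the tissue distribution scaled down by
    ``gel_reflectivity_scale``; suspended cells keep the full
    tissue-like reflectivity.

    A warning is recorded in ``scene.metadata`` if the speckle density
    falls below 10 per resolution cell.
    """
    if not 0.0 <= labeled_fraction <= 1.0:
        raise ValueError("labeled_fraction must lie in [0, 1]")
    if channel is None:
        channel = Channel()
    rng = np.random.default_rng(seed)
    metadata: dict = {}

    # gel speckle outside the channel
    area = (x_limits[1] - x_limits[0]) * (z_limits[1] - z_limits[0])
    depth = channel.center_depth
    density = _speckle_density(context, depth, scatterers_per_resolution_cell)
    n_gel = rng.poisson(density * area)
    gel_pos = np.column_stack(
        [
            rng.uniform(x_limits[0], x_limits[1], n_gel),
            rng.uniform(z_limits[0], z_limits[1], n_gel),
        ]
    )
    gel_pos = gel_pos[~channel.contains(gel_pos)]
    if scatterers_per_resolution_cell < 10.0:
        metadata["speckle_warning"] = (
            f"speckle density {scatterers_per_resolution_cell:.1f} per resolution "
            "cell is below the fully-developed threshold of 10"
        )

    # cells inside the channel
    expected, estimate = expected_cell_count(concentration, imaging_volume_ul)
    n_cells = int(rng.poisson(expected)) if count_mode == "poisson" else estimate
    cell_pos = _sample_in_channel(rng, channel, x_limits, z_limits, n_cells)
    n_labeled = int(rng.binomial(n_cells, labeled_fraction)) if n_cells else 0
    labeled_idx = rng.choice(n_cells, n_labeled, replace=False) if n_labeled else np.array([], int)

    positions = [gel_pos, cell_pos]
    reflect = [
        gel_reflectivity_scale * _rayleigh_reflectivity(rng, gel_pos.shape[0]),
        _rayleigh_reflectivity(rng, n_cells),
    ]
    kind = [
        np.full(gel_pos.shape[0], KIND_TISSUE, dtype=np.int8),
        np.full(n_cells, KIND_UNLABELED_CELL, dtype=np.int8),
    ]
    cell_vel = np.zeros((n_cells, 2))
    cell_vel[:, 0] = channel.flow_speed
    velocities = [np.zeros((gel_pos.shape[0], 2)), cell_vel]
    if n_labeled:
        # the engulfed microbubble rides at the labeled cell's position
        positions.append(cell_pos[labeled_idx])
        reflect.append(np.zeros(n_labeled))
        kind.append(np.full(n_labeled, KIND_BUBBLE, dtype=np.int8))
        velocities.append(cell_vel[labeled_idx])

    if bubble_params is None and n_labeled:
        from .config import default_phagocytosed_bubble

        bubble_params = default_phagocytosed_bubble()

    metadata.update(expected_cells=expected, cell_estimate=estimate, n_labeled=n_labeled)
    return Scene(
        positions=np.concatenate(positions, axis=0),
        reflectivity=np.concatenate(reflect),
        kind=np.concatenate(kind),
        velocities=np.concatenate(velocities, axis=0),
        x_limits=x_limits,
        z_limits=z_limits,
        channel=channel,
        bubble_params=bubble_params,
        rng_seed=seed,
        metadata=metadata,
    )


def _sample_in_channel(rng, channel, x_limits, z_limits, n):
    """Uniform samples in the channel disk clipped to the scene extent."""
    out = np.empty((0, 2))
    r = channel.diameter / 2.0
    while out.shape[0] < n:
        m = max(4 * (n - out.shape[0]), 16)
        pts = np.column_stack(
            [rng.uniform(-r, r, m), channel.center_depth + rng.uniform(-r, r, m)]
        )
        keep = channel.contains(pts)
        keep &= (pts[:, 0] >= x_limits[0]) & (pts[:, 0] < x_limits[1])
        keep &= (pts[:, 1] >= z_limits[0]) & (pts[:, 1] < z_limits[1])
        out = np.concatenate([out, pts[keep]], axis=0)
    return out[:n]


def advance_flow(scene: Scene, dt: float) -> Scene:
    """Translate moving scatterers by ``dt`` and recycle channel exits.

    Plug flow: cells move at the channel flow speed along +x.  A cell
    leaving the channel segment visible in the scene re-enters at the
    inlet (periodic wrap), which preserves the expected in-channel
    concentration exactly.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    pos = scene.positions.copy()
    moving = np.any(scene.velocities != 0.0, axis=1)
    pos[moving] += scene.velocities[moving] * dt
    if scene.channel is not None and np.any(moving):
        r = scene.channel.diameter / 2.0
        # wrap each moving scatterer within its own chord of the disk
        dz = pos[moving, 1] - scene.channel.center_depth
        chord_half = np.sqrt(np.maximum(r**2 - dz**2, 1e-30))
        x0 = np.maximum(-chord_half, scene.x_limits[0])
        x1 = np.minimum(chord_half, scene.x_limits[1])
        width = x1 - x0
        pos[moving, 0] = x0 + np.mod(pos[moving, 0] - x0, width)
    return replace(scene, positions=pos)


def make_tumor_scene(
    n_vessels: int,
    vessel_tortuosity: float = 0.3,
    periphery_bias: float = 1.0,
    seed: int = 0,
    context: AcousticContext | None = None,
    x_limits: tuple[float, float] = (-3e-3, 3e-3),
    z_limits: tuple[float, float] = (2e-3, 8e-3),
    tumor_radius: float = 2.5e-3,
    vessel_radius: float = 60e-6,
    bubbles_per_vessel: int = 1,
    flow_speed: float = 10e-3,
    n_path_points: int = 200,
    scatterers_per_resolution_cell: float = 10.0,
) -> tuple[Scene, list[np.ndarray]]:
    """Tumor-like field: speckle disk with flowing bubbles in vessels.

    Vessel center points are drawn at radius ``R * u^(1/(2(1+bias)))``:
    bias 0 gives an area-uniform distribution over the tumor disk, larger
    bias concentrates vessels toward the periphery.  Each vessel is a
    smooth curvilinear path (a chord perturbed by a sinusoidal transverse
    displacement scaled by ``vessel_tortuosity``); bubbles traverse the
    path at ``flow_speed``.

    Returns
    -------
    (scene, centerlines)
        The scene (static speckle plus bubble scatterers at their t=0
        positions) and the ground-truth centerline polylines, one
        ``(n_path_points, 2)`` array of (x, z) per vessel.  Bubble path
        assignments are stored in ``scene.metadata["bubble_paths"]`` as
        (vessel index, arc offset) pairs.
    """
    if n_vessels < 1:
        raise ValueError("n_vessels must be >= 1")
    if context is None:
        from .acoustics import IMAGING_CONTEXT

        context = IMAGING_CONTEXT
    rng = np.random.default_rng(seed)
    cx = 0.5 * (x_limits[0] + x_limits[1])
    cz = 0.5 * (z_limits[0] + z_limits[1])

    base = make_tissue_field(
        context,
        seed=seed,
        x_limits=x_limits,
        z_limits=z_limits,
        scatterers_per_resolution_cell=scatterers_per_resolution_cell,
    )

    centerlines: list[np.ndarray] = []
    vessel_centers: list[tuple[float, float]] = []
    bubble_pos = []
    bubble_vel = []
    bubble_paths = []
    for v in range(n_vessels):
        u = rng.uniform()
        r_c = tumor_radius * u ** (1.0 / (2.0 * (1.0 + periphery_bias)))
        theta = rng.uniform(0.0, 2.0 * math.pi)
        center = np.array([cx + r_c * math.cos(theta), cz + r_c * math.sin(theta)])
        vessel_centers.append((float(center[0]), float(center[1])))
        phi = rng.uniform(0.0, math.pi)
        direction = np.array([math.cos(phi), math.sin(phi)])
        normal = np.array([-direction[1], direction[0]])
        half_len = 0.6 * tumor_radius
        s = np.linspace(-half_len, half_len, n_path_points)
        wiggle = vessel_tortuosity * half_len * 0.3 * np.sin(
            2.0 * math.pi * s / (half_len) + rng.uniform(0, 2 * math.pi)
        )
        path = center[None, :] + s[:, None] * direction[None, :] + wiggle[:, None] * normal[None, :]
        # clip to the scene extent with a small margin
        eps = 1e-9
        path[:, 0] = np.clip(path[:, 0], x_limits[0] + eps, x_limits[1] - 1e-6)
        path[:, 1] = np.clip(path[:, 1], z_limits[0] + eps, z_limits[1] - 1e-6)
        centerlines.append(path)
        for b in range(bubbles_per_vessel):
            offset = rng.uniform(0.0, 1.0)
            idx = int(offset * (n_path_points - 1))
            p = path[idx]
            jitter = rng.uniform(-vessel_radius, vessel_radius, 2)
            p = p + jitter * np.array([0.3, 0.3])
            p[0] = np.clip(p[0], x_limits[0] + eps, x_limits[1] - 1e-6)
            p[1] = np.clip(p[1], z_limits[0] + eps, z_limits[1] - 1e-6)
            tangent = path[min(idx + 1, n_path_points - 1)] - path[max(idx - 1, 0)]
            tnorm = np.linalg.norm(tangent)
            tangent = tangent / tnorm if tnorm > 0 else direction
            bubble_pos.append(p)
            bubble_vel.append(tangent * flow_speed)
            bubble_paths.append((v, offset))

    from .config import default_phagocytosed_bubble

    nb = len(bubble_pos)
    scene = Scene(
        positions=np.concatenate([base.positions, np.array(bubble_pos)], axis=0),
        reflectivity=np.concatenate([base.reflectivity, np.zeros(nb)]),
        kind=np.concatenate([base.kind, np.full(nb, KIND_BUBBLE, dtype=np.int8)]),
        velocities=np.concatenate([base.velocities, np.array(bubble_vel)], axis=0),
        x_limits=x_limits,
        z_limits=z_limits,
        bubble_params=default_phagocytosed_bubble(),
        rng_seed=seed,
        metadata={
            "bubble_paths": bubble_paths,
            "vessel_centers": vessel_centers,
            "tumor_center": (cx, cz),
            "tumor_radius": tumor_radius,
            "vessel_radius": vessel_radius,
            "flow_speed": flow_speed,
        },
    )
    return scene, centerlines


def save_scene(scene: Scene, path) -> None:
    """Serialize a scene to HDF5 (`/scatterers`, `/channel`, `/meta`)."""
    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("scatterers")
        g.create_dataset("positions", data=scene.positions)
        g.create_dataset("reflectivity", data=scene.reflectivity)
        g.create_dataset("kind", data=scene.kind)
        g.create_dataset("velocities", data=scene.velocities)
        meta = f.create_group("meta")
        meta.attrs["seed"] = scene.rng_seed
        meta.attrs["x_limits"] = scene.x_limits
        meta.attrs["z_limits"] = scene.z_limits
        if scene.channel is not None:
            ch = f.create_group("channel")
            ch.attrs["center_depth"] = scene.channel.center_depth
            ch.attrs["diameter"] = scene.channel.diameter
            ch.attrs["flow_speed"] = scene.channel.flow_speed
        if scene.bubble_params is not None:
            bp = f.create_group("bubble_params")
            from dataclasses import fields as dc_fields

            for fld in dc_fields(scene.bubble_params):
                bp.attrs[fld.name] = getattr(scene.bubble_params, fld.name)


def load_scene(path) -> Scene:
    """Load a scene written by :func:`save_scene`."""
    import h5py

    with h5py.File(path, "r") as f:
        channel = None
        if "channel" in f:
            ch = f["channel"].attrs
            channel = Channel(
                center_depth=float(ch["center_depth"]),
                diameter=float(ch["diameter"]),
                flow_speed=float(ch["flow_speed"]),
            )
        bubble_params = None
        if "bubble_params" in f:
            attrs = dict(f["bubble_params"].attrs)
            attrs["compartment"] = str(attrs["compartment"])
            for key in (
                "rest_radius", "shell_elasticity", "shell_viscosity",
                "buckling_radius_ratio", "rupture_tension",
                "gas_polytropic_exponent", "buckling_smoothing",
                "liquid_viscosity", "intracellular_viscosity_multiplier",
            ):
                attrs[key] = float(attrs[key])
            bubble_params = BubbleParams(**attrs)
        meta = f["meta"].attrs
        return Scene(
            positions=f["scatterers/positions"][()],
            reflectivity=f["scatterers/reflectivity"][()],
            kind=f["scatterers/kind"][()],
            velocities=f["scatterers/velocities"][()],
            x_limits=tuple(meta["x_limits"]),
            z_limits=tuple(meta["z_limits"]),
            channel=channel,
            bubble_params=bubble_params,
            rng_seed=int(meta["seed"]),
        )
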