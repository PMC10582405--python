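"""Synthetic vascular phantoms and printed-line resolution phantoms.

Training pairs for the volumetric enhancer need ground-truth absorption maps
of vessel-like structures. Real vascular anatomy is unavailable here, so
:func:`generate_vasculature` grows stochastic branching trees of tapering
tubes (diameters 0.1-4 mm, the feature range a 2.25 MHz linear array
resolves) and rasterizes them as capsules on a metric voxel grid.
:func:`generate_line_phantom` builds the classic resolution target: a set of
parallel printed lines at a fixed depth, used to quantify lateral versus
elevation resolution through FWHM measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid

__all__ = [
    "VesselPhantom",
    "generate_vasculature",
    "generate_line_phantom",
]


@dataclass
class VesselPhantom:
    """Ground-truth 3D absorption map plus the centerlines that produced it.

    ``absorption`` is a non-negative array on ``grid`` (axial, lateral,
    elevation), max-normalized to 1 for non-empty phantoms. ``centerlines``
    is a list of segment records ``{"p0", "p1", "diameter_mm"}`` with
    endpoints in local mm coordinates.
    """

    grid: VoxelGrid
    absorption: np.ndarray
    centerlines: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorption = np.asarray(self.absorption, dtype=np.float32)
        if self.absorption.shape != self.grid.shape:
            raise ValueError(
                f"absorption shape {self.absorption.shape} != grid {self.grid.shape}"
            )
        if np.any(self.absorption < 0):
            raise ValueError("absorption must be non-negative")

    @property
    def segment_diameters_mm(self) -> np.ndarray:
        return np.array([seg["diameter_mm"] for seg in self.centerlines])

    def nonzero_fraction(self) -> float:
        return float(np.count_nonzero(self.absorption)) / self.absorption.size


def _rasterize_capsule(absorption, grid, p0, p1, diameter_mm, value):
    """Paint a capsule (cylinder with hemispherical caps) onto ``absorption``.

    A voxel belongs to the capsule when its center lies within ``radius`` of
    the segment p0-p1 (center-inside tie rule at the boundary).
    """
    r = diameter_mm / 2.0
    sp = np.asarray(grid.spacing_mm)
    lo = np.minimum(p0, p1) - r
    hi = np.maximum(p0, p1) + r
    # voxel index window covering the capsule
    i0 = np.maximum(np.floor(lo / sp - 0.5).astype(int), 0)
    i1 = np.minimum(np.ceil(hi / sp - 0.5).astype(int) + 1, np.asarray(grid.shape))
    if np.any(i0 >= i1):
        return
    coords = [
        (np.arange(i0[a], i1[a]) + 0.5) * sp[a] for a in range(3)
    ]
    Z, X, Y = np.meshgrid(*coords, indexing="ij")
    p = np.stack([Z, X, Y], axis=-1)
    d = np.asarray(p1) - np.asarray(p0)
    L2 = float(np.dot(d, d))
    if L2 == 0.0:
        dist2 = np.sum((p - p0) ** 2, axis=-1)
    else:
        t = np.clip(np.einsum("...k,k->...", p - p0, d) / L2, 0.0, 1.0)
        proj = p0 + t[..., None] * d
        dist2 = np.sum((p - proj) ** 2, axis=-1)
    mask = dist2 <= r * r
    sub = absorption[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    np.maximum(sub, np.where(mask, np.float32(value), np.float32(0.0)), out=sub)


def _check_grid_fits(grid: VoxelGrid, max_diameter_mm: float) -> None:
    for ext, name in zip(grid.extent_mm, ("axial", "lateral", "elevation")):
        if ext < max_diameter_mm / 2.0:
            raise ValueError(
                f"grid {name} extent {ext:.2f} mm is smaller than the tube "
                f"radius {max_diameter_mm / 2.0:.2f} mm; enlarge the grid or "
                "shrink diameter_range_mm"
            )


def generate_vasculature(
    seed: int,
    grid: VoxelGrid,
    n_trees: int = 4,
    diameter_range_mm: tuple[float, float] = (0.1, 4.0),
    branch_params: dict | None = None,
) -> VesselPhantom:
    """Grow a seeded branching vascular tree phantom.

    Trees follow a recursive branching random walk: each branch steps along a
    direction perturbed by Gaussian tortuosity, tapers geometrically, and
    spawns narrower children at a fixed per-step probability. Tubes are
    rasterized as capsule segments so joints stay smooth.

    Parameters
    ----------
    seed
        Seeds all stochastic choices; identical (seed, parameters) give a
        bit-identical phantom.
    n_trees
        Number of independent trees (roots placed uniformly in the interior).
    diameter_range_mm
        Closed diameter interval; every recorded segment diameter lies in it.
    branch_params
        Optional overrides: ``tortuosity`` (rad/step direction jitter),
        ``branch_prob``, ``taper`` (per-step diameter factor),
        ``child_ratio``, ``max_steps``, ``max_depth``,
        ``root_diameter_frac`` ((lo, hi) fraction of the max diameter).
    """
    d_min, d_max = float(diameter_range_mm[0]), float(diameter_range_mm[1])
    if not 0 < d_min <= d_max:
        raise ValueError("diameter_range_mm must satisfy 0 < min <= max")
    if d_max >= min(grid.extent_mm):
        raise ValueError(
            f"max diameter {d_max} mm does not fit the grid extents {grid.extent_mm}"
        )
    _check_grid_fits(grid, d_max)
    bp = {
        "tortuosity": 0.35,
        "branch_prob": 0.12,
        "taper": 0.97,
        "child_ratio": 0.7,
        "max_steps": 200,
        "max_depth": 4,
        "root_diameter_frac": (0.45, 1.0),
    }
    if branch_params:
        bp.update(branch_params)

    rng = np.random.default_rng(seed)
    extent = np.asarray(grid.extent_mm)
    absorption = np.zeros(grid.shape, dtype=np.float32)
    centerlines: list[dict] = []

    for _ in range(max(int(n_trees), 0)):
        frac = rng.uniform(*bp["root_diameter_frac"])
        d0 = float(np.clip(frac * d_max, d_min, d_max))
        root = extent * rng.uniform(0.15, 0.85, size=3)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        value = float(rng.uniform(0.6, 1.0))
        # stack of (position, direction, diameter, depth)
        stack = [(root, direction, d0, 0)]
        segs: list[tuple] = []
        while stack:
            pos, dirn, d, depth = stack.pop()
            for _ in range(int(bp["max_steps"])):
                if d < d_min:
                    break
                step = float(np.clip(0.8 * d, 2.0 * min(grid.spacing_mm), 2.0))
                dirn = dirn + bp["tortuosity"] * rng.normal(size=3)
                dirn = dirn / np.linalg.norm(dirn)
                nxt = pos + step * dirn
                if np.any(nxt < -0.5) or np.any(nxt > extent + 0.5):
                    break
                segs.append((pos.copy(), nxt.copy(), d))
                pos = nxt
                d = max(d * bp["taper"], d_min)
                if depth < bp["max_depth"] and rng.random() < bp["branch_prob"]:
                    child_dir = dirn + rng.normal(size=3)
                    child_dir /= np.linalg.norm(child_dir)
                    child_d = max(d * bp["child_ratio"], d_min)
                    stack.append((pos.copy(), child_dir, child_d, depth + 1))
        for p0, p1, d in segs:
            _rasterize_capsule(absorption, grid, p0, p1, d, value)
            centerlines.append({"p0": p0.tolist(), "p1": p1.tolist(), "diameter_mm": float(d)})

    if not np.any(absorption):
        # tiny grids can miss every random tree; guarantee one interior tube
        d = float(np.clip(3.0 * max(grid.spacing_mm), d_min, d_max))
        c = extent / 2.0
        p0 = np.array([c[0], 0.0, c[2]])
        p1 = np.array([c[0], extent[1], c[2]])
        _rasterize_capsule(absorption, grid, p0, p1, d, 1.0)
        centerlines.append({"p0": p0.tolist(), "p1": p1.tolist(), "diameter_mm": d})

    frac = np.count_nonzero(absorption) / absorption.size
    if frac >= 0.5:
        raise ValueError(
            f"phantom fills {frac:.2f} of the grid; the grid is too small for "
            "the requested vessels"
        )
    absorption /= absorption.max()
    return VesselPhantom(grid=grid, absorption=absorption, centerlines=centerlines)


def generate_line_phantom(
    diameters_mm: list[float],
    orientation: str = "lateral",
    depth_mm: float = 50.0,
    grid: VoxelGrid | None = None,
    line_spacing_mm: float = 8.0,
) -> VesselPhantom:
    """Rasterize parallel printed lines at a common depth.

    The physical analogue is a transparent sheet printed with black lines
    (0.5, 1.0, 2.0 and 3.0 mm in the reference target) placed 50 mm from the
    transducer face. Lines run the full grid length along ``orientation``
    ("lateral" or "elevation") and are separated along the other in-plane
    axis by ``line_spacing_mm`` center-to-center.
    """
    if orientation not in ("lateral", "elevation"):
        raise ValueError("orientation must be 'lateral' or 'elevation'")
    diameters = [float(d) for d in diameters_mm]
    if not diameters or any(d <= 0 for d in diameters):
        raise ValueError("diameters_mm must be positive")
    if grid is None:
        grid = VoxelGrid(shape=(64, 256, 256), spacing_mm=(0.1, 0.1, 0.1))

    z_local = depth_mm - grid.standoff_mm
    if not 0 <= z_local <= grid.extent_mm[0]:
        raise ValueError(
            f"depth {depth_mm} mm lies outside the grid (standoff "
            f"{grid.standoff_mm} mm, axial extent {grid.extent_mm[0]} mm)"
        )
    for da, db in zip(diameters[:-1], diameters[1:]):
        if line_spacing_mm < 5.0 or line_spacing_mm <= (da + db) / 2.0:
            raise ValueError(
                "lines overlap or violate the 5 mm minimum spacing: spacing "
                f"{line_spacing_mm} mm for diameters {da}, {db} mm"
            )

    along_axis = 1 if orientation == "lateral" else 2
    across_axis = 2 if orientation == "lateral" else 1
    across_extent = grid.extent_mm[across_axis]
    n = len(diameters)
    span = (n - 1) * line_spacing_mm
    if span + max(diameters) > across_extent:
        raise ValueError(
            f"{n} lines spaced {line_spacing_mm} mm do not fit the "
            f"{across_extent} mm extent"
        )
    centers = across_extent / 2.0 + (np.arange(n) - (n - 1) / 2.0) * line_spacing_mm

    absorption = np.zeros(grid.shape, dtype=np.float32)
    centerlines = []
    along_extent = grid.extent_mm[along_axis]
    for d, c in zip(diameters, centers):
        p0 = np.zeros(3)
        p1 = np.zeros(3)
        p0[0] = p1[0] = z_local
        p0[across_axis] = p1[across_axis] = c
        p0[along_axis], p1[along_axis] = 0.0, along_extent
        _rasterize_capsule(absorption, grid, p0, p1, d, 1.0)
        centerlines.append({"p0": p0.tolist(), "p1": p1.tolist(), "diameter_mm": d})

    if absorption.max() > 0:
        absorption /= absorption.max()
    return VesselPhantom(grid=grid, absorption=absorption, centerlines=centerlines)
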