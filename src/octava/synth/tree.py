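"""Parametric vascular-tree generator with analytic ground truth.

Trees are binary recursive bifurcation structures obeying Murray's radius
law r_p^k = r_1^k + r_2^k at every branching point, with sinusoidal
in-plane tortuosity whose arc length has a closed quadrature form.  All
geometry lives in physical µm coordinates with the origin at the center
of the imaged field, so the same tree can be rasterized at any pixel
resolution.  A central disk of radius ``faz_radius_um`` stays vessel-free,
emulating the foveal avascular zone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad

__all__ = [
    "TreeSpec",
    "Branch",
    "BifurcationTruth",
    "GroundTruth",
    "Tree",
    "GeometryError",
    "generate_tree",
    "generate_scene",
]


class GeometryError(ValueError):
    """Raised when a requested tree cannot fit the canvas/FAZ constraints."""


@dataclass(frozen=True)
class TreeSpec:
    """Parameters of one synthetic vascular tree.

    Radii follow Murray's law with exponent ``murray_exponent`` (3.0 is the
    energetically optimal law); ``symmetry`` is the target daughter caliber
    ratio r2/r1 in (0, 1].  ``tortuosity_amplitude`` is the peak perpendicular
    sinusoidal displacement as a fraction of branch length (0 = straight).
    """

    root_position_um: tuple[float, float] | None = None  # (x, y), origin = field center
    root_radius_um: float = 20.0
    branch_levels: int = 5
    murray_exponent: float = 3.0
    symmetry: float = 0.8
    symmetry_jitter: float = 0.15
    tortuosity_amplitude: float = 0.03
    faz_radius_um: float = 300.0
    fov_mm: float = 3.0
    root_length_um: float = 300.0
    length_decay: float = 0.75
    branch_angle_deg: float = 32.0
    angle_jitter_deg: float = 8.0
    avoid_self_crossing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.root_radius_um <= 0:
            raise ValueError("root_radius_um must be > 0")
        if self.branch_levels < 1:
            raise ValueError("branch_levels must be >= 1")
        if not (0 < self.symmetry <= 1):
            raise ValueError("symmetry must be in (0, 1]")
        if self.murray_exponent <= 0:
            raise ValueError("murray_exponent must be > 0")
        if self.tortuosity_amplitude < 0:
            raise ValueError("tortuosity_amplitude must be >= 0")
        if self.faz_radius_um < 0 or self.fov_mm <= 0:
            raise ValueError("faz_radius_um >= 0 and fov_mm > 0 required")


@dataclass
class Branch:
    """One vessel segment: a polyline in µm with a constant radius."""

    points_um: np.ndarray  # (N, 2) float
    radius_um: float
    level: int
    arc_length_um: float
    chord_length_um: float
    parent_index: int | None = None


@dataclass
class BifurcationTruth:
    parent_radius_um: float
    daughter_radii_um: tuple[float, float]
    position_um: tuple[float, float]


@dataclass
class GroundTruth:
    """Analytic per-segment / per-bifurcation truth for a generated tree."""

    segment_arc_um: list[float] = field(default_factory=list)
    segment_chord_um: list[float] = field(default_factory=list)
    segment_radius_um: list[float] = field(default_factory=list)
    bifurcations: list[BifurcationTruth] = field(default_factory=list)
    faz_area_mm2: float = 0.0
    vessel_pixel_count: int | None = None
    scale_um_per_px: float | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_bifurcations(self) -> int:
        return len(self.bifurcations)

    def mean_internal_branch_length_um(self) -> float | None:
        """Mean arc length of branches joining two bifurcations (levels
        1..L-2 of a full tree); None if the tree has no such branch."""
        internal = [
            a
            for a, lvl in zip(self.segment_arc_um, self._levels)
            if 0 < lvl < self._max_level
        ]
        return float(np.mean(internal)) if internal else None

    _levels: list[int] = field(default_factory=list)
    _max_level: int = 0


@dataclass
class Tree:
    branches: list[Branch]
    truth: GroundTruth
    spec: TreeSpec | None = None


def _murray_daughters(r_parent: float, exponent: float, symmetry: float) -> tuple[float, float]:
    """Solve r_p^k = r1^k + r2^k with r2/r1 = symmetry. Exact."""
    r1 = r_parent / (1.0 + symmetry**exponent) ** (1.0 / exponent)
    return r1, symmetry * r1


def _sinusoid_arc_length(length: float, amplitude_frac: float) -> float:
    """Arc length of y = A sin(2πt/L), t in [0, L], A = amplitude_frac·L."""
    if amplitude_frac == 0:
        return length
    a = 2.0 * math.pi * amplitude_frac
    val, _ = quad(lambda u: math.sqrt(1.0 + (a * math.cos(u)) ** 2), 0.0, 2.0 * math.pi)
    return length * val / (2.0 * math.pi)


def _branch_polyline(
    start: np.ndarray, direction: np.ndarray, length: float, amplitude_frac: float, step_um: float = 2.0
) -> np.ndarray:
    n = max(int(math.ceil(length / step_um)) + 1, 2)
    t = np.linspace(0.0, length, n)
    normal = np.array([-direction[1], direction[0]])
    offset = amplitude_frac * length * np.sin(2.0 * np.pi * t / length)
    return start[None, :] + t[:, None] * direction[None, :] + offset[:, None] * normal[None, :]


def generate_tree(spec: TreeSpec) -> Tree:
    """Grow one bifurcating tree per ``spec``; deterministic for fixed seed.

    Raises :class:`GeometryError` if any branch (inflated by its radius)
    would leave the canvas or enter the FAZ exclusion disk.
    """
    rng = np.random.default_rng(spec.seed)
    half_fov_um = spec.fov_mm * 1000.0 / 2.0

    if spec.root_position_um is None:
        # place the root just outside the FAZ, pointing radially outward
        theta = rng.uniform(0.0, 2.0 * math.pi)
        r0 = spec.faz_radius_um + spec.root_radius_um + 10.0
        root = np.array([r0 * math.cos(theta), r0 * math.sin(theta)])
        root_dir = root / np.linalg.norm(root)
    else:
        root = np.asarray(spec.root_position_um, dtype=float)
        if np.linalg.norm(root) > 0:
            root_dir = root / np.linalg.norm(root)
        else:
            root_dir = np.array([1.0, 0.0])

    branches: list[Branch] = []
    truth = GroundTruth(faz_area_mm2=math.pi * (spec.faz_radius_um / 1000.0) ** 2)
    truth._max_level = spec.branch_levels - 1

    def _collides(pts: np.ndarray, radius: float, parent_idx: int | None, start: np.ndarray) -> bool:
        """True when the candidate polyline comes closer to an existing
        non-parent branch than the sum of radii plus a 1-px-scale margin.
        Only the sibling (sharing the bifurcation point) gets a grace zone
        around the shared start."""
        arc_from_start = np.hypot(pts[:, 0] - start[0], pts[:, 1] - start[1])
        for j, other in enumerate(branches):
            if j == parent_idx:
                continue
            d = np.sqrt(
                ((pts[:, None, :] - other.points_um[None, :, :]) ** 2).sum(-1)
            ).min(axis=1)
            clearance = radius + other.radius_um + 6.0
            is_sibling = np.hypot(*(other.points_um[0] - start)) < 1e-6
            exempt = arc_from_start < 2.5 * clearance if is_sibling else np.zeros(len(pts), bool)
            if np.any((d < clearance) & ~exempt):
                return True
        return False

    # (start, unit direction, radius, length, level, parent branch index)
    stack: list[tuple[np.ndarray, np.ndarray, float, float, int, int | None]] = [
        (root, root_dir, spec.root_radius_um, spec.root_length_um, 0, None)
    ]
    # breadth-first so sibling order (and RNG use) is deterministic
    def _violation(pts: np.ndarray, radius: float, level: int) -> str | None:
        dist_center = np.hypot(pts[:, 0], pts[:, 1])
        if np.any(dist_center < spec.faz_radius_um + radius):
            return (
                f"branch at level {level} enters the FAZ exclusion disk "
                f"(min clearance {dist_center.min():.1f} µm < "
                f"{spec.faz_radius_um + radius:.1f} µm)"
            )
        if np.any(np.abs(pts) + radius > half_fov_um):
            return (
                f"branch at level {level} exceeds the {spec.fov_mm} mm canvas; "
                "reduce branch_levels or root_length_um"
            )
        return None

    while stack:
        start, direction, radius, length, level, parent_idx = stack.pop(0)
        pts = _branch_polyline(start, direction, length, spec.tortuosity_amplitude)
        problem = _violation(pts, radius, level)
        if spec.avoid_self_crossing:
            base_angle = math.atan2(direction[1], direction[0])
            for attempt in range(60):
                if problem is None and not _collides(pts, radius, parent_idx, start):
                    break
                # re-draw the branch direction (and, when crowded, shrink it)
                spread = 15.0 + 0.6 * attempt
                ang = base_angle + math.radians(rng.uniform(-spread, spread))
                direction = np.array([math.cos(ang), math.sin(ang)])
                if attempt >= 20 and attempt % 5 == 0:
                    length *= 0.85
                pts = _branch_polyline(start, direction, length, spec.tortuosity_amplitude)
                problem = _violation(pts, radius, level)
            else:
                raise GeometryError(
                    problem
                    or f"could not place a non-crossing branch at level {level}"
                )
        elif problem is not None:
            raise GeometryError(problem)
        arc = _sinusoid_arc_length(length, spec.tortuosity_amplitude)
        idx = len(branches)
        branches.append(
            Branch(
                points_um=pts,
                radius_um=radius,
                level=level,
                arc_length_um=arc,
                chord_length_um=length,
                parent_index=parent_idx,
            )
        )
        truth.segment_arc_um.append(arc)
        truth.segment_chord_um.append(length)
        truth.segment_radius_um.append(radius)
        truth._levels.append(level)

        if level < spec.branch_levels - 1:
            s = spec.symmetry
            if spec.symmetry_jitter > 0:
                s = float(
                    np.clip(
                        s + rng.uniform(-spec.symmetry_jitter, spec.symmetry_jitter),
                        0.05,
                        1.0,
                    )
                )
            r1, r2 = _murray_daughters(radius, spec.murray_exponent, s)
            end = pts[-1]
            base_angle = math.atan2(direction[1], direction[0])
            # branching angles narrow with depth so each subtree stays in
            # its own sector (space-filling without self-crossing)
            shrink = 0.75**level
            half = math.radians(spec.branch_angle_deg) * shrink
            jit1 = math.radians(rng.uniform(-spec.angle_jitter_deg, spec.angle_jitter_deg)) * shrink
            jit2 = math.radians(rng.uniform(-spec.angle_jitter_deg, spec.angle_jitter_deg)) * shrink
            child_len = length * spec.length_decay
            for r_child, ang in ((r1, base_angle - half + jit1), (r2, base_angle + half + jit2)):
                d = np.array([math.cos(ang), math.sin(ang)])
                stack.append((end, d, r_child, child_len, level + 1, idx))
            truth.bifurcations.append(
                BifurcationTruth(
                    parent_radius_um=radius,
                    daughter_radii_um=(r1, r2),
                    position_um=(float(end[0]), float(end[1])),
                )
            )

    return Tree(branches=branches, truth=truth, spec=spec)


def generate_scene(
    spec: TreeSpec,
    n_trees: int = 6,
    faz_ring_radius_um: float = 6.0,
    arcade_radii_um: tuple[float, ...] = (650.0, 1000.0),
    arcade_ring_radius_um: float = 8.0,
) -> Tree:
    """Compose several trees radiating around the FAZ plus a thin capillary
    ring bounding it, emulating a macula-centered angiogram.

    The ring centerline sits at ``faz_radius + ring_radius`` so the
    vessel-free pocket has radius exactly ``faz_radius_um``.  Tree roots are
    spread at equal angles (jittered) around the ring.  Circular "arcade"
    vessels at ``arcade_radii_um`` close the perifoveal region into small
    cells so the FAZ is the dominant avascular pocket near the center, as
    in a perfused macula.  Ground truths are concatenated; the rings are
    excluded from segment/bifurcation truth (closed loops, not branches).
    """
    rng = np.random.default_rng(spec.seed)
    branches: list[Branch] = []
    truth = GroundTruth(faz_area_mm2=math.pi * (spec.faz_radius_um / 1000.0) ** 2)
    truth._max_level = spec.branch_levels - 1
    offset = rng.uniform(0.0, 2.0 * math.pi)
    for i in range(n_trees):
        theta = offset + 2.0 * math.pi * i / n_trees + rng.uniform(-0.15, 0.15)
        r0 = spec.faz_radius_um + spec.root_radius_um + 10.0
        root = (r0 * math.cos(theta), r0 * math.sin(theta))
        sub = generate_tree(
            replace(spec, root_position_um=root, seed=int(rng.integers(2**31 - 1)))
        )
        base = len(branches)
        for b in sub.branches:
            if b.parent_index is not None:
                b.parent_index += base
        branches.extend(sub.branches)
        truth.segment_arc_um.extend(sub.truth.segment_arc_um)
        truth.segment_chord_um.extend(sub.truth.segment_chord_um)
        truth.segment_radius_um.extend(sub.truth.segment_radius_um)
        truth._levels.extend(sub.truth._levels)
        truth.bifurcations.extend(sub.truth.bifurcations)

    rings = []
    if faz_ring_radius_um > 0:
        rings.append((spec.faz_radius_um + faz_ring_radius_um, faz_ring_radius_um))
    for rc in arcade_radii_um:
        rings.append((rc, arcade_ring_radius_um))
    for rc, rr in rings:
        t = np.linspace(0.0, 2.0 * math.pi, max(int(2.0 * math.pi * rc / 2.0), 16))
        ring_pts = np.stack([rc * np.cos(t), rc * np.sin(t)], axis=1)
        branches.append(
            Branch(
                points_um=ring_pts,
                radius_um=rr,
                level=-1,
                arc_length_um=2.0 * math.pi * rc,
                chord_length_um=0.0,
                parent_index=None,
            )
        )
    return Tree(branches=branches, truth=truth, spec=spec)
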