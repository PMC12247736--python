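"""Synthetic vascular phantoms with analytic ground truth.

Tubes of known radius are rasterized around analytic centerline curves
(straight lines, circular arcs, helices, Y-junctions and random binary
trees), so the true morphology — branch lengths, chords, tortuosity,
bifurcation/endpoint counts, radius — is known exactly and every other
module can be validated without any imaging data.

A voxel is foreground iff its world-coordinate center lies within the
tube radius of the (densely sampled) centerline. Expected volume for
multi-branch phantoms is taken from the rasterized union, not a sum of
cylinder volumes, so junction overlap is never double-counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .grids import BinaryVesselMask, GridSpec, Volume3D

PHANTOM_KINDS = ("straight_tube", "arc_tube", "helix_tube", "y_tree", "random_binary_tree")


class PhantomError(ValueError):
    """Raised for infeasible phantom specifications."""


def default_grid(n: int = 128, spacing: float = 0.5) -> GridSpec:
    """The default test grid: 128^3 voxels at 0.5 mm isotropic."""
    return GridSpec(shape=(n, n, n), spacing=(spacing,) * 3)


@dataclass
class BranchTruth:
    """Analytic record of one centerline branch."""

    start_mm: np.ndarray
    end_mm: np.ndarray
    length_mm: float
    chord_mm: float

    @property
    def tortuosity(self) -> float:
        return self.length_mm / self.chord_mm if self.chord_mm > 0 else np.nan


@dataclass
class PhantomTruth:
    """Ground-truth morphology for a generated phantom."""

    kind: str
    radius_mm: float
    n_bifurcations: int
    n_endpoints: int
    n_segments: int
    branches: list[BranchTruth]
    expected_volume_mm3: float  # rasterized-union volume (junction-corrected)
    analytic_volume_mm3: float  # sum of pi r^2 L over branches (no correction)

    @property
    def total_length_mm(self) -> float:
        return float(sum(b.length_mm for b in self.branches))

    def to_dict(self) -> dict[str, Any]:
        return {
            "kind": self.kind,
            "radius_mm": self.radius_mm,
            "n_bifurcations": self.n_bifurcations,
            "n_endpoints": self.n_endpoints,
            "n_segments": self.n_segments,
            "total_length_mm": self.total_length_mm,
            "expected_volume_mm3": self.expected_volume_mm3,
            "analytic_volume_mm3": self.analytic_volume_mm3,
            "branch_tortuosities": [b.tortuosity for b in self.branches],
            "branch_lengths_mm": [b.length_mm for b in self.branches],
        }


@dataclass
class PhantomSpec:
    """Parameters of a synthetic phantom.

    ``kind`` selects the geometry; only the parameters relevant to that
    kind are used. Defaults target the 128^3, 0.5 mm isotropic test grid.
    """

    kind: str = "straight_tube"
    radius_mm: float = 2.0
    length_mm: float = 40.0
    arc_angle: float = np.pi  # radians, for arc_tube
    arc_radius_mm: float = 20.0
    helix_turns: float = 2.0
    helix_pitch_mm: float = 10.0
    n_bifurcations: int = 3  # for random_binary_tree
    branch_angle_deg: tuple[float, float] = (40.0, 55.0)
    branch_length_mm: tuple[float, float] = (10.0, 16.0)
    trunk_length_mm: tuple[float, float] = (16.0, 22.0)
    grid: GridSpec = field(default_factory=default_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise PhantomError(f"unknown phantom kind {self.kind!r}")
        if self.radius_mm <= 0:
            raise PhantomError("radius_mm must be positive")


def _curve_length(points: np.ndarray) -> float:
    return float(np.sqrt((np.diff(points, axis=0) ** 2).sum(axis=1)).sum())


def rasterize_tube(
    curve_mm: np.ndarray,
    radius_mm: float,
    grid: GridSpec,
    out: np.ndarray | None = None,
    cap_ends: tuple[bool, bool] = (False, False),
) -> BinaryVesselMask:
    """Rasterize a tube of given radius around a polyline of mm coordinates.

    ``curve_mm`` must be sampled densely (step <= min spacing / 2) — the
    rasterization marks voxels within ``radius_mm`` of a sample point, so
    the step size bounds the geometric error. By default the tube is
    clipped flat by the planes normal to the curve at its two ends (a
    straight curve yields a true finite cylinder of volume pi r^2 L);
    ``cap_ends`` keeps the hemispherical cap at either end instead, which
    multi-branch phantoms use on junction-side ends so junctions stay
    solid. Raises if the curve leaves the grid.
    """
    curve_mm = np.atleast_2d(np.asarray(curve_mm, dtype=float))
    inv = np.linalg.inv(np.asarray(grid.affine))
    vox = curve_mm @ inv[:3, :3].T + inv[:3, 3]
    shape = np.array(grid.shape)
    bad = np.any((vox < 0) | (vox > shape - 1), axis=1)
    if bad.any():
        p = curve_mm[bad][0]
        raise PhantomError(f"curve exits the grid at point {tuple(np.round(p, 2))} mm")

    spacing = np.array(grid.spacing)
    half = np.ceil(radius_mm / spacing).astype(int) + 1
    local = np.zeros(grid.shape, dtype=bool)
    # stamp a sphere of voxel centers around each curve sample
    for p_vox, p_mm in zip(vox, curve_mm):
        c = np.round(p_vox).astype(int)
        lo = np.maximum(c - half, 0)
        hi = np.minimum(c + half, shape - 1)
        sub = np.stack(
            np.meshgrid(
                *[np.arange(l, h + 1) for l, h in zip(lo, hi)], indexing="ij"
            ),
            axis=-1,
        ).reshape(-1, 3)
        centers = grid.to_world(sub)
        d2 = ((centers - p_mm) ** 2).sum(axis=1)
        inside = sub[d2 <= radius_mm**2]
        if len(inside):
            local[tuple(inside.T)] = True
    closed = len(curve_mm) > 1 and np.linalg.norm(curve_mm[0] - curve_mm[-1]) < 1e-9
    if len(curve_mm) > 1 and not closed:
        marked = np.argwhere(local)
        if len(marked):
            centers = grid.to_world(marked)
            keep = np.ones(len(marked), dtype=bool)
            if not cap_ends[0]:
                t0 = curve_mm[1] - curve_mm[0]
                keep &= (centers - curve_mm[0]) @ t0 >= 0.0
            if not cap_ends[1]:
                t1 = curve_mm[-1] - curve_mm[-2]
                keep &= (centers - curve_mm[-1]) @ t1 <= 0.0
            local[tuple(marked[~keep].T)] = False
    if out is not None:
        out |= local
        vol = out
    else:
        vol = local
    return BinaryVesselMask(grid=grid, values=vol.astype(np.uint8))


def _sample_line(a: np.ndarray, b: np.ndarray, step: float) -> np.ndarray:
    n = max(int(np.ceil(np.linalg.norm(b - a) / step)), 1)
    t = np.linspace(0.0, 1.0, n + 1)[:, None]
    return a[None, :] * (1 - t) + b[None, :] * t


def _grid_center(grid: GridSpec) -> np.ndarray:
    # the fixed sub-voxel offset (absolute mm) breaks grid-symmetric
    # alignment, so rasterization error behaves generically and shrinks
    # under grid refinement instead of being locked to a special lattice
    # phase
    return grid.to_world((np.array(grid.shape) - 1) / 2.0)[0] + np.array(
        [0.1234, 0.0567, 0.0891]
    )


def _curve_step(grid: GridSpec) -> float:
    return min(grid.spacing) / 4.0


def _finish(
    spec: PhantomSpec,
    branches: list[np.ndarray],
    n_bif: int,
    n_end: int,
    caps: list[tuple[bool, bool]] | None = None,
) -> tuple[BinaryVesselMask, PhantomTruth]:
    vol = np.zeros(spec.grid.shape, dtype=bool)
    analytic = 0.0
    truths = []
    if caps is None:
        caps = [(False, False)] * len(branches)
    for pts, cap in zip(branches, caps):
        rasterize_tube(pts, spec.radius_mm, spec.grid, out=vol, cap_ends=cap)
        L = _curve_length(pts)
        analytic += np.pi * spec.radius_mm**2 * L
        truths.append(
            BranchTruth(
                start_mm=pts[0],
                end_mm=pts[-1],
                length_mm=L,
                chord_mm=float(np.linalg.norm(pts[-1] - pts[0])),
            )
        )
    mask = BinaryVesselMask(grid=spec.grid, values=vol.astype(np.uint8))
    truth = PhantomTruth(
        kind=spec.kind,
        radius_mm=spec.radius_mm,
        n_bifurcations=n_bif,
        n_endpoints=n_end,
        n_segments=len(branches),
        branches=truths,
        expected_volume_mm3=float(vol.sum()) * spec.grid.voxel_volume_mm3,
        analytic_volume_mm3=analytic,
    )
    return mask, truth


def make_phantom(spec: PhantomSpec) -> tuple[BinaryVesselMask, PhantomTruth]:
    """Generate a phantom mask plus its analytic truth record."""
    step = _curve_step(spec.grid)
    c = _grid_center(spec.grid)
    if spec.kind == "straight_tube":
        a = c - np.array([0, 0, spec.length_mm / 2])
        b = c + np.array([0, 0, spec.length_mm / 2])
        return _finish(spec, [_sample_line(a, b, step)], 0, 2)
    if spec.kind == "arc_tube":
        R, ang = spec.arc_radius_mm, spec.arc_angle
        n = max(int(np.ceil(R * ang / step)), 8)
        t = np.linspace(0.0, ang, n + 1)
        pts = c + np.stack(
            [R * np.cos(t) - R * np.cos(ang / 2), R * np.sin(t) - R * np.sin(ang / 2), np.zeros_like(t)],
            axis=1,
        )
        # rounded ends: the capped tube's medial axis runs to the curve
        # ends, so the skeleton does not retract and tortuosity is faithful
        return _finish(spec, [pts], 0, 2, caps=[(True, True)])
    if spec.kind == "helix_tube":
        turns, pitch, R = spec.helix_turns, spec.helix_pitch_mm, spec.arc_radius_mm
        total = 2 * np.pi * turns
        n = max(int(np.ceil(np.hypot(R, pitch / (2 * np.pi)) * total / step)), 16)
        t = np.linspace(0.0, total, n + 1)
        z = pitch * t / (2 * np.pi)
        pts = c + np.stack([R * np.cos(t), R * np.sin(t), z - z[-1] / 2], axis=1)
        return _finish(spec, [pts], 0, 2, caps=[(True, True)])
    if spec.kind == "y_tree":
        return _make_y_tree(spec, step, c)
    return _make_random_tree(spec, step, c)


def _make_y_tree(spec, step, c):
    trunk_len = spec.length_mm / 2
    arm_len = spec.length_mm / 2
    root = c - np.array([0, 0, trunk_len])
    junction = c
    ang = np.deg2rad(40.0)
    arms = []
    for s in (+1, -1):
        d = np.array([s * np.sin(ang), 0.0, np.cos(ang)])
        arms.append(_sample_line(junction, junction + d * arm_len, step))
    branches = [_sample_line(root, junction, step)] + arms
    # spherical caps everywhere: a capped tube end has a clean line-shaped
    # medial axis, an obliquely clipped flat end a disc-shaped one
    caps = [(True, True)] * 3
    return _finish(spec, branches, 1, 3, caps=caps)


def _make_random_tree(spec, step, c):
    """Recursive binary branching with rejection-sampled separation.

    Branches are straight tubes; each bifurcation splits a tip into two
    children whose polar angles off the parent direction are drawn from
    ``branch_angle_deg`` and whose azimuths are ~opposed, so siblings
    diverge. Candidate branches are rejected if any sample point comes
    within 4 x radius of a non-adjacent branch (for parent/sibling pairs
    the zone within 4 x radius of the shared junction is exempt), or if
    the tube leaves the grid margin. The seed fully determines the tree.
    """
    rng = np.random.default_rng(spec.seed)
    last_err: PhantomError | None = None
    for _attempt in range(20):
        try:
            return _grow_random_tree(spec, step, c, rng)
        except PhantomError as err:  # rejection-sample a fresh tree
            last_err = err
    raise PhantomError(f"infeasible random-tree spec after 20 attempts: {last_err}")


def _grow_random_tree(spec, step, c, rng):
    r = spec.radius_mm
    sep = 4.0 * r
    spacing = np.array(spec.grid.spacing)
    margin_vox = r / spacing + 2.0
    lo_mm = spec.grid.to_world(margin_vox)[0]
    hi_mm = spec.grid.to_world(np.array(spec.grid.shape) - 1 - margin_vox)[0]
    lo_mm, hi_mm = np.minimum(lo_mm, hi_mm), np.maximum(lo_mm, hi_mm)

    def in_bounds(pts):
        return np.all((pts >= lo_mm) & (pts <= hi_mm))

    def rand_dir(parent_dir):
        theta = np.deg2rad(rng.uniform(*spec.branch_angle_deg))
        # orthonormal frame around the parent direction
        p = parent_dir / np.linalg.norm(parent_dir)
        a = np.array([1.0, 0.0, 0.0]) if abs(p[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
        u = np.cross(p, a)
        u /= np.linalg.norm(u)
        v = np.cross(p, u)
        return p, u, v, theta

    check_step = max(r / 2.0, 0.5)

    branches: list[dict] = []  # pts, samples, parent index, junction

    def separation_ok(samples, junction, parent_idx):
        for j, br in enumerate(branches):
            other = br["samples"]
            mine = samples
            if j == parent_idx or (
                parent_idx is not None and br["parent"] == parent_idx
            ):
                keep_o = np.linalg.norm(other - junction, axis=1) > sep
                keep_m = np.linalg.norm(mine - junction, axis=1) > sep
                other = other[keep_o]
                mine = mine[keep_m]
            if len(other) == 0 or len(mine) == 0:
                continue
            d2 = ((mine[:, None, :] - other[None, :, :]) ** 2).sum(axis=2)
            if d2.min() <= sep**2:
                return False
        return True

    # trunk: starts near the bottom face, roughly +z with a small tilt
    for _ in range(200):
        L0 = rng.uniform(*spec.trunk_length_mm)
        tilt = np.deg2rad(rng.uniform(0, 10))
        phi = rng.uniform(0, 2 * np.pi)
        d0 = np.array(
            [np.sin(tilt) * np.cos(phi), np.sin(tilt) * np.sin(phi), np.cos(tilt)]
        )
        root = np.array(
            [
                rng.uniform(c[0] - 5, c[0] + 5),
                rng.uniform(c[1] - 5, c[1] + 5),
                lo_mm[2] + 1.0,
            ]
        )
        end = root + d0 * L0
        if in_bounds(np.stack([root, end])):
            break
    else:
        raise PhantomError("could not place the trunk inside the grid")
    branches.append(
        {
            "pts": np.stack([root, end]),
            "samples": _sample_line(root, end, check_step),
            "parent": None,
            "dir": d0,
        }
    )

    tips = [0]  # branch indices whose distal end may still split
    n_bif = 0
    while n_bif < spec.n_bifurcations:
        if not tips:
            raise PhantomError("ran out of tips before reaching planned bifurcations")
        parent_idx = tips.pop(0)
        parent = branches[parent_idx]
        junction = parent["pts"][-1]
        placed = None
        for _ in range(300):
            p, u, v, th1 = rand_dir(parent["dir"])
            th2 = np.deg2rad(rng.uniform(*spec.branch_angle_deg))
            phi1 = rng.uniform(0, 2 * np.pi)
            # near-opposed azimuths keep the inter-sibling angle >= ~80 deg,
            # so child tubes detach within ~2 radii of the junction
            phi2 = phi1 + np.pi + rng.uniform(-np.pi / 12, np.pi / 12)
            kids = []
            ok = True
            for th, phi in ((th1, phi1), (th2, phi2)):
                d = (
                    np.cos(th) * p
                    + np.sin(th) * (np.cos(phi) * u + np.sin(phi) * v)
                )
                L = rng.uniform(*spec.branch_length_mm)
                end = junction + d * L
                pts = np.stack([junction, end])
                if not in_bounds(pts):
                    ok = False
                    break
                kids.append({"pts": pts, "dir": d})
            if not ok:
                continue
            samples = [
                _sample_line(k["pts"][0], k["pts"][1], check_step) for k in kids
            ]
            # children of the same junction: check them against each other
            # beyond the junction exemption zone, then against the rest
            s0 = samples[0][np.linalg.norm(samples[0] - junction, axis=1) > sep]
            s1 = samples[1][np.linalg.norm(samples[1] - junction, axis=1) > sep]
            if len(s0) and len(s1):
                d2 = ((s0[:, None, :] - s1[None, :, :]) ** 2).sum(axis=2)
                if d2.min() <= sep**2:
                    continue
            if all(
                separation_ok(s, junction, parent_idx)
                for s in samples
            ):
                placed = list(zip(kids, samples))
                break
        if placed is None:
            raise PhantomError(
                f"cannot separate branches at bifurcation {n_bif + 1} "
                f"(radius {r} mm, separation {sep} mm)"
            )
        for kid, s in placed:
            branches.append(
                {"pts": kid["pts"], "samples": s, "parent": parent_idx, "dir": kid["dir"]}
            )
            tips.append(len(branches) - 1)
        n_bif += 1

    pts_list = [
        _sample_line(br["pts"][0], br["pts"][1], _curve_step(spec.grid))
        for br in branches
    ]
    # spherical caps at every end: junction-side caps keep junctions solid,
    # tip-side caps give the tube end a line-shaped (not disc-shaped) medial
    # axis, so thinning stays clean on obliquely oriented branches
    caps = [(True, True)] * len(branches)
    # a binary tree grown from one root: endpoints = root + (bifurcations + 1) tips
    return _finish(spec, pts_list, spec.n_bifurcations, spec.n_bifurcations + 2, caps=caps)


def random_tree_suite(
    n_phantoms: int = 20,
    seed: int = 0,
    grid: GridSpec | None = None,
    radius_range: tuple[float, float] = (1.0, 3.0),
    n_bifurcations: int = 3,
) -> list[PhantomSpec]:
    """Specs for a seeded suite of random binary-tree phantoms.

    Branch lengths scale with the tube radius so that the > 4 x radius
    separation invariant stays feasible across the whole radius range on
    the default 128^3, 0.5 mm grid.
    """
    rng = np.random.default_rng(seed)
    specs = []
    for _ in range(n_phantoms):
        r = float(rng.uniform(*radius_range))
        lmin = max(10.0, 4.0 * r + 3.0)
        specs.append(
            PhantomSpec(
                kind="random_binary_tree",
                radius_mm=r,
                n_bifurcations=n_bifurcations,
                branch_length_mm=(lmin, lmin + 5.0),
                trunk_length_mm=(lmin + 4.0, lmin + 8.0),
                grid=grid if grid is not None else default_grid(),
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return specs


def make_paired_anatomical(
    mask: BinaryVesselMask,
    vessel_intensity: float = 200.0,
    background_intensity: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    smooth_sigma_mm: float = 0.0,
) -> Volume3D:
    """Pseudo-anatomical volume paired with a mask.

    Background intensity everywhere, vessel intensity on the mask, plus
    seeded additive Gaussian noise; optional Gaussian smoothing emulates
    partial-volume blur.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    vals = np.where(mask.values > 0, vessel_intensity, background_intensity).astype(float)
    if smooth_sigma_mm > 0:
        from scipy import ndimage

        vals = ndimage.gaussian_filter(
            vals, sigma=np.asarray(smooth_sigma_mm) / np.array(mask.grid.spacing)
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, noise_sd, size=vals.shape)
    return Volume3D(grid=mask.grid, values=vals)
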