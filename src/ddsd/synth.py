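"""Synthetic articulated voxel shapes with controlled topology changes.

Real flexible molecules bend around hinges, and at extreme conformations
previously separate surface patches can touch, creating a "shortcut"
that abruptly shortens every shortest-path metric across the contact.
The generators here emulate that behaviour with unions of capsules
(thick line segments) rasterized directly onto the lattice:

* ``bent_tube``  — a two-armed rod folding at its mid joint; at large
  bend angles the arms touch along their length.
* ``clamp``      — a U-shape whose prongs tilt inward until the tips
  touch, closing the U into a ring.
* ``tripod``     — three arms from a hub; one arm sweeps toward a fixed
  one until they merge.

Each family exposes a one-parameter conformer series (the articulation
parameter) plus two *probe* points — surface points on opposite sides of
the forming contact — so tests can watch the inner distance between them
collapse at the contact event while the diffusion distance barely moves.

Everything is deterministic: no randomness enters shape construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import label
from scipy.sparse.csgraph import dijkstra

from .innerdist import build_voxel_graph
from .voxel import VolumetricModel, extract_boundary

__all__ = [
    "ConformerSeries",
    "make_ball",
    "make_bent_tube",
    "make_clamp",
    "make_tripod",
    "make_series",
    "make_benchmark",
    "GENERATORS",
    "CONTACT_DROP",
]

#: relative inner-distance drop between consecutive conformers that labels
#: a self-contact event (a fixture-labeling convention, not a physical claim)
CONTACT_DROP = 0.25

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ConformerSeries:
    """Ordered conformers of one synthetic family.

    ``contact_index`` is the first index at which the probe-pair inner
    distance drops by more than :data:`CONTACT_DROP` relative to the
    previous conformer, or None when no self-contact occurs.
    """

    shapes: list[VolumetricModel]
    params: list[dict]
    probe_pairs: list[tuple[np.ndarray, np.ndarray]]
    tip_distances: np.ndarray
    contact_index: int | None


def _rasterize_capsules(
    segments: list[tuple[np.ndarray, np.ndarray, float]],
    dims: tuple[int, int, int],
) -> VolumetricModel:
    """Union of capsules (p0, p1, radius) onto a unit-spacing lattice.

    Coordinates are in voxel units relative to the grid centre; the
    geometry must leave a one-voxel background margin on every face.
    """
    dims = tuple(int(d) for d in dims)
    centre = (np.asarray(dims) - 1) / 2.0
    idx = np.indices(dims).reshape(3, -1).T.astype(float)
    pts = idx - centre
    occ = np.zeros(len(pts), dtype=bool)
    for p0, p1, r in segments:
        p0 = np.asarray(p0, float)
        p1 = np.asarray(p1, float)
        d = p1 - p0
        L2 = float(d @ d)
        if L2 == 0:
            dist2 = ((pts - p0) ** 2).sum(axis=1)
        else:
            t = np.clip((pts - p0) @ d / L2, 0.0, 1.0)
            nearest = p0 + t[:, None] * d
            dist2 = ((pts - nearest) ** 2).sum(axis=1)
        occ |= dist2 <= r * r
    grid = occ.reshape(dims).astype(np.uint8)
    model = VolumetricModel(grid=grid, spacing=1.0, origin=-centre)
    if model.is_empty():
        raise ValueError("capsule geometry thinner than one voxel")
    _require_connected(model)
    return model


def _require_connected(model: VolumetricModel) -> None:
    _, n = label(model.grid, structure=_STRUCT26)
    if n != 1:
        raise ValueError(f"generated shape has {n} 26-connected components")


def make_ball(radius: float, dims: int | tuple[int, int, int] = 32) -> VolumetricModel:
    """Voxelized solid ball centred in the grid (calibration fixture)."""
    if isinstance(dims, (int, np.integer)):
        dims = (int(dims),) * 3
    if radius <= 0:
        raise ValueError("radius must be positive")
    if 2 * radius > min(dims) - 3:
        raise ValueError(f"ball of radius {radius} does not fit in dims {dims}")
    return _rasterize_capsules([(np.zeros(3), np.zeros(3), radius)], dims)


def make_bent_tube(
    length: float = 36.0,
    thickness: float = 6.5,
    bend_angle: float = 0.0,
    bow: float = 5.0,
    asymmetry: float = 0.0,
    dims: int | tuple[int, int, int] = 48,
) -> tuple[VolumetricModel, tuple[np.ndarray, np.ndarray]]:
    """Tube folding at its mid joint by ``bend_angle`` degrees.

    Each arm bows slightly outward (elbow displaced by ``bow`` voxels
    perpendicular to its axis), so when the tube folds the two arm tips
    approach each other first while the mid-arms stay separated: the
    self-contact is a localized contact event rather than a gradual
    merge of the whole arms.  ``asymmetry`` shifts the joint off-centre
    (arm lengths (0.5 +/- asymmetry) * length); with unequal arms the
    long arm's tip meets the short arm's side at contact, leaving a free
    tail instead of closing a symmetric ring.  At angle 0 the tube is
    straight; contact occurs near 160 degrees for the default
    proportions.  Returns the model and the two arm-tip probe points
    (world units).
    """
    if isinstance(dims, (int, np.integer)):
        dims = (int(dims),) * 3
    r = thickness / 2.0
    arms = [(0.5 - asymmetry) * length, (0.5 + asymmetry) * length]
    phi = np.deg2rad(bend_angle) / 2.0
    axes = [
        np.array([np.cos(phi), np.sin(phi), 0.0]),
        np.array([-np.cos(phi), np.sin(phi), 0.0]),
    ]
    # outward normal of each arm: perpendicular to the axis, away from
    # the fold bisector (+y), so the concave side stays open
    perps = [
        np.array([np.sin(phi), -np.cos(phi), 0.0]),
        np.array([-np.sin(phi), -np.cos(phi), 0.0]),
    ]
    joint = np.zeros(3)
    elbows = [0.5 * arm * a + bow * p for arm, a, p in zip(arms, axes, perps)]
    tips = [arm * a for arm, a in zip(arms, axes)]
    pts = np.stack([joint, *elbows, *tips])
    lo = pts.min(axis=0) - r
    hi = pts.max(axis=0) + r
    shift = -(lo + hi) / 2.0
    segs = []
    for e, t in zip(elbows, tips):
        segs.append((joint + shift, e + shift, r))
        segs.append((e + shift, t + shift, r))
    _check_fit(lo + shift, hi + shift, dims)
    model = _rasterize_capsules(segs, dims)
    probes = tuple(t + shift + r * a for t, a in zip(tips, axes))
    return model, probes


def make_clamp(
    base_length: float = 22.0,
    prong_length: float = 14.0,
    thickness: float = 5.0,
    lobe_radius: float = 5.5,
    closing_angle: float = 0.0,
    dims: int | tuple[int, int, int] = 48,
) -> tuple[VolumetricModel, tuple[np.ndarray, np.ndarray]]:
    """Two-lobe clamp: fat lobes on prongs that tilt inward and touch.

    A base bar carries two prongs, each ending in a ball of
    ``lobe_radius`` (two heavy domains on a light hinge, so the mass
    distribution is strongly bimodal).  ``closing_angle`` tilts the
    prongs inward; at angle 0 they are parallel, and when the lobes meet
    the clamp closes into a ring — the self-contact event.  Returns the
    model and the two lobe-tip probe points.
    """
    if isinstance(dims, (int, np.integer)):
        dims = (int(dims),) * 3
    r = thickness / 2.0
    half = base_length / 2.0
    alpha = np.deg2rad(closing_angle)
    dir_l = np.array([np.sin(alpha), np.cos(alpha), 0.0])
    dir_r = np.array([-np.sin(alpha), np.cos(alpha), 0.0])
    base_l = np.array([-half, 0.0, 0.0])
    base_r = np.array([half, 0.0, 0.0])
    lobe_l = base_l + prong_length * dir_l
    lobe_r = base_r + prong_length * dir_r
    pts = np.stack([base_l, base_r, lobe_l, lobe_r])
    rad = np.array([r, r, lobe_radius, lobe_radius])
    lo = (pts - rad[:, None]).min(axis=0)
    hi = (pts + rad[:, None]).max(axis=0)
    shift = -(lo + hi) / 2.0
    segs = [
        (base_l + shift, base_r + shift, r),
        (base_l + shift, lobe_l + shift, r),
        (base_r + shift, lobe_r + shift, r),
        (lobe_l + shift, lobe_l + shift, lobe_radius),
        (lobe_r + shift, lobe_r + shift, lobe_radius),
    ]
    _check_fit(lo + shift, hi + shift, dims)
    model = _rasterize_capsules(segs, dims)
    probes = (
        lobe_l + shift + lobe_radius * dir_l,
        lobe_r + shift + lobe_radius * dir_r,
    )
    return model, probes


def make_tripod(
    arm_length: float = 16.0,
    thickness: float = 6.0,
    sweep_angle: float = 0.0,
    lobe_radius: float = 0.0,
    dims: int | tuple[int, int, int] = 48,
) -> tuple[VolumetricModel, tuple[np.ndarray, np.ndarray]]:
    """Three arms from a hub; two arms scissor while one stays fixed.

    Arms start 120 degrees apart in the xy-plane; ``sweep_angle`` rotates
    the third arm toward the first while the second co-rotates at a third
    of the rate (a scissor motion that changes the extrinsic star shape
    substantially).  With ``lobe_radius`` > 0 each arm ends in a ball,
    giving a trefoil of three heavy domains on light arms.  Near 100
    degrees of sweep the third arm reaches the first and they merge.
    Returns the two tip probes of the fixed and sweeping arms.
    """
    if isinstance(dims, (int, np.integer)):
        dims = (int(dims),) * 3
    r = thickness / 2.0
    ang1 = 0.0
    ang2 = 120.0 + sweep_angle / 3.0
    ang3 = 240.0 + sweep_angle
    dirs = [
        np.array([np.cos(np.deg2rad(a)), np.sin(np.deg2rad(a)), 0.0])
        for a in (ang1, ang2, ang3)
    ]
    tip_r = max(r, lobe_radius)
    tips = np.stack([arm_length * d for d in dirs] + [np.zeros(3)])
    rad = np.array([tip_r, tip_r, tip_r, r])
    lo = (tips - rad[:, None]).min(axis=0)
    hi = (tips + rad[:, None]).max(axis=0)
    shift = -(lo + hi) / 2.0
    hub = shift
    segs = [(hub, hub + arm_length * d, r) for d in dirs]
    if lobe_radius > 0:
        segs += [
            (hub + arm_length * d, hub + arm_length * d, lobe_radius) for d in dirs
        ]
    _check_fit(lo + shift, hi + shift, dims)
    model = _rasterize_capsules(segs, dims)
    probes = (
        hub + (arm_length + tip_r) * dirs[0],
        hub + (arm_length + tip_r) * dirs[2],
    )
    return model, probes


def _check_fit(lo: np.ndarray, hi: np.ndarray, dims: tuple[int, int, int]) -> None:
    centre = (np.asarray(dims) - 1) / 2.0
    if ((lo + centre) < 1.0).any() or ((hi + centre) > np.asarray(dims) - 2.0).any():
        raise ValueError(
            f"geometry spanning {lo} .. {hi} (voxel units about grid centre) "
            f"does not fit dims {dims} with a one-voxel margin"
        )


GENERATORS = {
    "bent_tube": (make_bent_tube, "bend_angle"),
    "clamp": (make_clamp, "closing_angle"),
    "tripod": (make_tripod, "sweep_angle"),
}


def probe_inner_distance(
    model: VolumetricModel, probes: tuple[np.ndarray, np.ndarray]
) -> float:
    """Inner distance between the boundary voxels nearest two probe points."""
    boundary = extract_boundary(model)
    graph = build_voxel_graph(model)
    node_ids = []
    for p in probes:
        b = int(np.argmin(((boundary.points - p) ** 2).sum(axis=1)))
        node_ids.append(graph.node_id_of(boundary.indices[b]))
    dist = dijkstra(graph.adjacency, directed=False, indices=node_ids[0])
    return float(dist[node_ids[1]])


def make_series(
    generator: str,
    param_grid: list[float],
    dims: int | tuple[int, int, int] = 48,
    **kwargs,
) -> ConformerSeries:
    """Conformer series over a parameter grid, with contact detection.

    ``generator`` names a family in :data:`GENERATORS`; ``param_grid``
    supplies the articulation parameter per conformer.  The probe-pair
    inner distance is monitored along the series; the first conformer at
    which it drops by more than :data:`CONTACT_DROP` relative to its
    predecessor is labelled ``contact_index``.
    """
    if generator not in GENERATORS:
        raise ValueError(f"unknown generator {generator!r}; choose from {sorted(GENERATORS)}")
    if len(param_grid) == 0:
        raise ValueError("empty parameter grid")
    fn, param_name = GENERATORS[generator]
    shapes, params, probe_pairs, tip_d = [], [], [], []
    for value in param_grid:
        model, probes = fn(**{param_name: value}, dims=dims, **kwargs)
        shapes.append(model)
        params.append({"generator": generator, param_name: value})
        probe_pairs.append(probes)
        tip_d.append(probe_inner_distance(model, probes))
    tip_d = np.asarray(tip_d)
    contact_index = None
    for i in range(1, len(tip_d)):
        if tip_d[i] < (1.0 - CONTACT_DROP) * tip_d[i - 1]:
            contact_index = i
            break
    return ConformerSeries(
        shapes=shapes,
        params=params,
        probe_pairs=probe_pairs,
        tip_distances=tip_d,
        contact_index=contact_index,
    )


#: conformer-series fixtures for topology-robustness studies: default
#: generator proportions at a 48-voxel grid, one contact event per series
SERIES_FIXTURES: dict[str, dict] = {
    "bent_tube": {"grid": [0.0, 40.0, 80.0, 120.0, 150.0, 166.0], "dims": 48},
    "clamp": {"grid": [0.0, 6.0, 12.0, 18.0, 26.0], "dims": 48},
}

#: bundled benchmark families: articulation grids span rest pose to past
#: self-contact (last conformer of each family lies beyond the contact
#: event) and the geometry is scaled to fill the default 64-voxel grid
BENCHMARK_FAMILIES: dict[str, dict] = {
    "bent_tube": {
        "grid": [0.0, 40.0, 80.0, 120.0, 150.0, 165.0],
        "kwargs": {"length": 48.0, "thickness": 8.7, "bow": 6.7, "asymmetry": 0.12},
    },
    "clamp": {
        "grid": [-30.0, -18.0, -6.0, 6.0, 14.0, 24.0],
        "kwargs": {
            "base_length": 27.0,
            "prong_length": 17.5,
            "thickness": 6.7,
            "lobe_radius": 7.0,
        },
    },
    "tripod": {
        "grid": [-80.0, -45.0, -10.0, 30.0, 65.0, 90.0],
        "kwargs": {"arm_length": 21.3, "thickness": 5.5, "lobe_radius": 6.5},
    },
}


def make_benchmark(
    dims: int | tuple[int, int, int] = 64,
) -> tuple[dict[str, VolumetricModel], list[tuple[str, str, str]]]:
    """Bundled synthetic benchmark: 3 families x 6 conformers.

    Returns shapes keyed by id plus manifest entries (id, path, group);
    paths are placeholders until the shapes are written to disk.
    """
    shapes: dict[str, VolumetricModel] = {}
    entries: list[tuple[str, str, str]] = []
    for family, spec in BENCHMARK_FAMILIES.items():
        series = make_series(family, spec["grid"], dims=dims, **spec["kwargs"])
        for i, model in enumerate(series.shapes):
            sid = f"{family}_{i}"
            shapes[sid] = model
            entries.append((sid, f"{sid}.vox", family))
    return shapes, entries
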