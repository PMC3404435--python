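"""Scene synthesis: rotating, partially occluded objects on a gray canvas.

The training scene places five occluder objects at the vertices of a
pentagon, each partially covering a central object that sits behind all of
them and is therefore never seen whole.  Every object rotates in depth
about its own vertical axis in lock-step, in equal angular steps, so that
successive views of each object overlap heavily on the retina — the
spatial-continuity condition that continuous-transformation learning
requires.

Rendering is deliberately simple and bit-deterministic: orthographic
projection, flat shading (ambient plus a single diffuse directional
light), painter's-algorithm compositing, and no anti-aliasing.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon as _fill_polygon

from .geometry import (OCCLUDED_ID, OCCLUDER_IDS, NOVEL_IDS, TRAINED_IDS,
                       ObjectModel, rotate_y)

# Fixed directional light from the upper left, in front of the scene.
_LIGHT = np.array([-0.45, 0.60, 0.70])
_LIGHT = _LIGHT / np.linalg.norm(_LIGHT)
AMBIENT = 0.3
DIFFUSE = 0.7


@dataclass(frozen=True)
class Placement:
    object_id: str
    center: tuple[float, float]   # (row, col) in pixels
    scale: float                  # pixels per unit-sphere radius
    depth_rank: int               # larger = further back


@dataclass(frozen=True)
class SceneLayout:
    placements: tuple[Placement, ...]
    canvas: tuple[int, int]
    background_level: float = 0.5

    def subset(self, object_ids) -> "SceneLayout":
        keep = tuple(p for p in self.placements if p.object_id in set(object_ids))
        missing = set(object_ids) - {p.object_id for p in keep}
        if missing:
            raise KeyError(f"objects not in layout: {sorted(missing)}")
        return SceneLayout(keep, self.canvas, self.background_level)


@dataclass(frozen=True)
class SceneFrame:
    pixels: np.ndarray            # (H, W) float in [0, 1]
    view_angle: float             # degrees in [0, 360)
    members: tuple[str, ...]


@dataclass
class ViewSequence:
    name: str
    frames: list[SceneFrame]
    step_deg: float
    label: str                    # training-pair | single-object-test | ...
    members: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        return np.stack([f.pixels for f in self.frames])


# Per-object size factors equalise the footprint of shapes whose unit-sphere
# normalization leaves very different silhouette areas (the cone and star are
# slender, the dodecahedron nearly spherical).  Together with the pentagon
# radius they are calibrated once so that (a) each occluder hides a
# substantial minority of the central silhouette at every angle and (b) the
# five mutual-overlap fragments, accumulated over a full rotation, jointly
# cover everything of the central object that is ever visible in training.
_SIZE_FACTORS = {"cone": 1.32, "cube": 1.10, "cylinder": 1.00,
                 "star": 1.30, "dodecahedron": 0.95}


def pentagon_layout(canvas_size: int = 128,
                    central_scale: float = 0.22,
                    occluder_scale: float = 0.21,
                    pentagon_radius: float = 0.19,
                    background_level: float = 0.5) -> SceneLayout:
    """Pentagon formation: five occluders equidistant from the central
    occluded object, which is behind all of them.  Scales and radius are
    fractions of the canvas size.

    Novel objects are assigned to the same six positions.
    """
    h = w = canvas_size
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    placements = [Placement(OCCLUDED_ID, (cr, cc), central_scale * canvas_size,
                            depth_rank=10)]
    novel_iter = iter(NOVEL_IDS)
    # occluder k sits at pentagon vertex k, starting at the top
    for k, oid in enumerate(OCCLUDER_IDS):
        ang = np.deg2rad(-90.0 + 72.0 * k)
        r = cr + pentagon_radius * canvas_size * np.sin(ang)
        c = cc + pentagon_radius * canvas_size * np.cos(ang)
        scale = occluder_scale * canvas_size * _SIZE_FACTORS[oid]
        placements.append(Placement(oid, (r, c), scale, depth_rank=k))
        placements.append(Placement(next(novel_iter), (r, c),
                                    occluder_scale * canvas_size, depth_rank=k))
    placements.append(Placement(next(novel_iter), (cr, cc),
                                central_scale * canvas_size, depth_rank=10))
    return SceneLayout(tuple(placements), (h, w), background_level)


def _project(model: ObjectModel, placement: Placement, angle: float):
    """Rotate about the object's vertical axis, orthographically project.

    Returns image-plane coordinates (row, col) per vertex and depth z
    (larger z = nearer the viewer), plus world-space vertices for shading.
    """
    v = rotate_y(model.vertices, angle)
    rows = placement.center[0] - placement.scale * v[:, 1]
    cols = placement.center[1] + placement.scale * v[:, 0]
    return rows, cols, v


def _paint_object(image: np.ndarray, model: ObjectModel,
                  placement: Placement, angle: float) -> None:
    rows, cols, v = _project(model, placement, angle)
    tri = model.faces
    a, b, c = v[tri[:, 0]], v[tri[:, 1]], v[tri[:, 2]]
    normals = np.cross(b - a, c - a)
    # projected winding: outward-wound faces with +z normal face the viewer
    facing = normals[:, 2] > 1e-12
    depth = (a[:, 2] + b[:, 2] + c[:, 2]) / 3.0
    norms = np.linalg.norm(normals, axis=1)
    norms[norms == 0] = 1.0
    shade = AMBIENT + DIFFUSE * np.clip(normals @ _LIGHT / norms, 0.0, None)
    shade = np.clip(model.albedo * shade, 0.0, 1.0)
    order = np.argsort(depth, kind="stable")  # far faces first
    for k in order:
        if not facing[k]:
            continue
        rr, cc = _fill_polygon(rows[tri[k]], cols[tri[k]], shape=image.shape)
        image[rr, cc] = shade[k]


def render_view(layout: SceneLayout, models: dict[str, ObjectModel],
                angle: float) -> SceneFrame:
    """Render one view angle: painter's compositing back (largest depth
    rank) to front, each object flat-shaded."""
    angle = float(angle) % 360.0
    for p in layout.placements:
        if p.object_id not in models:
            raise KeyError(f"unknown object_id in layout: {p.object_id!r}")
    image = np.full(layout.canvas, layout.background_level, dtype=np.float64)
    ordered = sorted(layout.placements, key=lambda p: -p.depth_rank)
    for p in ordered:
        _paint_object(image, models[p.object_id], p, angle)
    np.clip(image, 0.0, 1.0, out=image)
    return SceneFrame(image, angle, tuple(p.object_id for p in layout.placements))


def silhouette_mask(model: ObjectModel, placement: Placement, angle: float,
                    canvas: tuple[int, int]) -> np.ndarray:
    """Boolean silhouette of one object at one view angle."""
    rows, cols, _ = _project(model, placement, float(angle) % 360.0)
    mask = np.zeros(canvas, dtype=bool)
    for f in model.faces:
        rr, cc = _fill_polygon(rows[f], cols[f], shape=canvas)
        mask[rr, cc] = True
    return mask


def visible_mask(layout: SceneLayout, models: dict[str, ObjectModel],
                 object_id: str, angle: float) -> np.ndarray:
    """Silhouette of ``object_id`` minus everything drawn in front of it."""
    target = next(p for p in layout.placements if p.object_id == object_id)
    mask = silhouette_mask(models[object_id], target, angle, layout.canvas)
    for p in layout.placements:
        if p.depth_rank < target.depth_rank:
            mask &= ~silhouette_mask(models[p.object_id], p, angle, layout.canvas)
    return mask


def _angles(step_deg: float) -> np.ndarray:
    if not float(360.0 / step_deg).is_integer():
        raise ValueError("step_deg must divide 360")
    return np.arange(0.0, 360.0, step_deg)


def _sequence(name, layout, models, step_deg, label) -> ViewSequence:
    frames = [render_view(layout, models, a) for a in _angles(step_deg)]
    return ViewSequence(name, frames, step_deg, label,
                        members=frames[0].members)


def build_training_set(models: dict[str, ObjectModel], layout: SceneLayout,
                       step_deg: float = 1.0) -> list[ViewSequence]:
    """The 15 training sequences: the occluded object paired with each of
    the five occluders (occluded object behind), followed by all 10
    unordered occluder pairs, everything at its fixed position."""
    seqs = []
    for occ in OCCLUDER_IDS:
        seqs.append(_sequence(f"{OCCLUDED_ID}+{occ}",
                              layout.subset([OCCLUDED_ID, occ]), models,
                              step_deg, "training-pair"))
    for a, b in itertools.combinations(sorted(OCCLUDER_IDS), 2):
        seqs.append(_sequence(f"{a}+{b}", layout.subset([a, b]), models,
                              step_deg, "training-pair"))
    return seqs


def build_test_sets(models: dict[str, ObjectModel], layout: SceneLayout,
                    step_deg: float = 1.0) -> tuple[list[ViewSequence],
                                                    list[ViewSequence]]:
    """Single-object test sequences: the six trained objects alone at
    their trained positions, and six novel objects at the same positions."""
    trained = [_sequence(oid, layout.subset([oid]), models, step_deg,
                         "single-object-test") for oid in TRAINED_IDS]
    novel = [_sequence(oid, layout.subset([oid]), models, step_deg,
                       "novel-test") for oid in NOVEL_IDS]
    return trained, novel


def build_fragment_set(models: dict[str, ObjectModel], layout: SceneLayout,
                       step_deg: float = 1.0) -> list[ViewSequence]:
    """Partial-view sequences: for each occluder, the region of the
    occluded object that the occluder covers at each angle (the mutual
    overlap of their silhouettes), shown in isolation on the background."""
    bg = layout.background_level
    central = next(p for p in layout.placements if p.object_id == OCCLUDED_ID)
    seqs = []
    for occ in OCCLUDER_IDS:
        occ_p = next(p for p in layout.placements if p.object_id == occ)
        frames = []
        for a in _angles(step_deg):
            alone = render_view(layout.subset([OCCLUDED_ID]), models, a)
            m = (silhouette_mask(models[OCCLUDED_ID], central, a, layout.canvas)
                 & silhouette_mask(models[occ], occ_p, a, layout.canvas))
            if not m.any():
                warnings.warn(f"empty overlap for {occ} at angle {a}")
            frames.append(SceneFrame(np.where(m, alone.pixels, bg), a,
                                     (OCCLUDED_ID,)))
        seqs.append(ViewSequence(f"fragment-{occ}", frames, step_deg,
                                 "fragment-test", (OCCLUDED_ID,)))
    return seqs


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def save_sequence(seq: ViewSequence, out_dir) -> None:
    """Write frames as 8-bit grayscale PNGs, ``<out_dir>/<angle>.png``."""
    from pathlib import Path

    from PIL import Image

    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    for f in seq.frames:
        arr = np.round(f.pixels * 255.0).astype(np.uint8)
        Image.fromarray(arr, mode="L").save(d / f"{int(f.view_angle):03d}.png")
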