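"""Polyhedral object library for the rotating-object stimuli.

Objects are closed triangular meshes normalized to fit a unit bounding
sphere.  The trained set comprises five "occluder" shapes (cone, cube,
cylinder, five-pointed star prism, dodecahedron) plus one irregular
multifaceted convex object that plays the role of the permanently occluded
object at the centre of the scene.  A second set of novel shapes, never
shown during training, probes whether learned selectivity is for object
form rather than retinal location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull

TRAINED_IDS = ("cone", "cube", "cylinder", "star", "dodecahedron", "jaimoid")
OCCLUDER_IDS = TRAINED_IDS[:5]
OCCLUDED_ID = "jaimoid"
NOVEL_IDS = ("pyramid", "octahedron", "tetrahedron", "hexprism",
             "antiprism", "blob")

_PHI = (1.0 + np.sqrt(5.0)) / 2.0


@dataclass(frozen=True)
class ObjectModel:
    """A closed 3D polyhedral mesh with a scalar surface reflectance."""

    object_id: str
    vertices: np.ndarray  # (n_vertices, 3) float64, |v| <= 1
    faces: np.ndarray     # (n_faces, 3) int64, outward-wound triangles
    albedo: float = 1.0

    @property
    def n_faces(self) -> int:
        return len(self.faces)


def _normalize(vertices: np.ndarray) -> np.ndarray:
    """Centre on the bounding-box midpoint and scale into the unit
    bounding sphere."""
    v = np.asarray(vertices, dtype=np.float64)
    v = v - (v.min(axis=0) + v.max(axis=0)) / 2.0
    return v / np.linalg.norm(v, axis=1).max()


def _convex_mesh(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Triangulated convex hull with outward-wound faces."""
    pts = np.asarray(points, dtype=np.float64)
    hull = ConvexHull(pts)
    faces = hull.simplices.copy()
    centre = pts[np.unique(faces)].mean(axis=0)
    for k, f in enumerate(faces):
        a, b, c = pts[f]
        n = np.cross(b - a, c - a)
        if np.dot(n, (a + b + c) / 3.0 - centre) < 0:
            faces[k] = f[::-1]
    return pts, faces.astype(np.int64)


def _circle(n: int, radius: float, y: float) -> np.ndarray:
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.cos(t),
                            np.full(n, y),
                            radius * np.sin(t)])


def _cone(n: int = 24) -> np.ndarray:
    return np.vstack([_circle(n, 0.75, -0.6), [[0.0, 0.9, 0.0]]])


def _cube() -> np.ndarray:
    g = np.array([-1.0, 1.0])
    return np.array([[x, y, z] for x in g for y in g for z in g])


def _cylinder(n: int = 24) -> np.ndarray:
    return np.vstack([_circle(n, 0.62, -0.75), _circle(n, 0.62, 0.75)])


def _dodecahedron() -> np.ndarray:
    p, q = _PHI, 1.0 / _PHI
    g = np.array([-1.0, 1.0])
    cube = np.array([[x, y, z] for x in g for y in g for z in g])
    rect = []
    for s1 in g:
        for s2 in g:
            rect += [[0.0, s1 * q, s2 * p],
                     [s1 * q, s2 * p, 0.0],
                     [s1 * p, 0.0, s2 * q]]
    return np.vstack([cube, rect])


def _tetrahedron() -> np.ndarray:
    return np.array([[1.0, 1.0, 1.0], [1.0, -1.0, -1.0],
                     [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]])


def _octahedron() -> np.ndarray:
    return np.vstack([np.eye(3), -np.eye(3)])


def _pyramid() -> np.ndarray:
    base = np.array([[x, -0.55, z] for x in (-0.8, 0.8) for z in (-0.8, 0.8)])
    return np.vstack([base, [[0.0, 0.9, 0.0]]])


def _hexprism() -> np.ndarray:
    return np.vstack([_circle(6, 0.72, -0.65), _circle(6, 0.72, 0.65)])


def _antiprism(n: int = 5) -> np.ndarray:
    top = _circle(n, 0.78, 0.55)
    bot = _circle(n, 0.78, -0.55)
    rot = np.pi / n
    c, s = np.cos(rot), np.sin(rot)
    bot = bot @ np.array([[c, 0, -s], [0, 1, 0], [s, 0, c]]).T
    return np.vstack([top, bot])


def _icosahedron() -> np.ndarray:
    p = _PHI
    g = np.array([-1.0, 1.0])
    v = []
    for s1 in g:
        for s2 in g:
            v += [[0.0, s1, s2 * p], [s1, s2 * p, 0.0], [s1 * p, 0.0, s2]]
    return np.array(v)


def _jittered_icosahedron(rng: np.random.Generator,
                          jitter: float = 0.28) -> np.ndarray:
    """Irregular multifaceted convex solid: icosahedron with seeded
    radial and angular jitter of its vertices."""
    v = _icosahedron()
    v = v + jitter * rng.standard_normal(v.shape)
    return v


def _star_prism(n_points: int = 5, inner: float = 0.42,
                half_depth: float = 0.30) -> tuple[np.ndarray, np.ndarray]:
    """Five-pointed star cross-section in the image plane, extruded in
    depth.  Non-convex, so the mesh is built explicitly: two fan-
    triangulated star faces plus side quads."""
    m = 2 * n_points
    t = np.pi / 2.0 + np.arange(m) * np.pi / n_points
    r = np.where(np.arange(m) % 2 == 0, 1.0, inner)
    ring = np.column_stack([r * np.cos(t), r * np.sin(t)])
    verts = []
    for z in (half_depth, -half_depth):
        verts.append(np.column_stack([ring, np.full(m, z)]))
        verts.append([[0.0, 0.0, z]])
    v = np.vstack(verts)  # front ring 0..m-1, front centre m, back ring
    fc, bc = m, 2 * m + 1
    back = m + 1
    faces = []
    for i in range(m):
        j = (i + 1) % m
        faces.append([fc, i, j])                       # front face (+z out)
        faces.append([bc, back + j, back + i])         # back face (-z out)
        faces.append([i, back + i, back + j])          # side
        faces.append([i, back + j, j])
    return v, np.asarray(faces, dtype=np.int64)


# Fixed intrinsic pose tilt (pitch about the image-horizontal axis, in
# degrees) applied at construction.  Without it the cone and cylinder are
# surfaces of revolution about the rotation axis, so every "view" would be
# pixel-identical and view invariance would be trivial; the tilt makes
# rotation in depth genuinely change each object's image.
_TILTS = {"cone": 22.0, "cube": 15.0, "cylinder": 24.0, "star": 12.0,
          "dodecahedron": 10.0, "jaimoid": 0.0, "pyramid": 20.0,
          "octahedron": 14.0, "tetrahedron": 16.0, "hexprism": 22.0,
          "antiprism": 12.0, "blob": 0.0}


def _pitch(vertices: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    rot = np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    return vertices @ rot.T


def _build(object_id: str, rng: np.random.Generator) -> ObjectModel:
    if object_id == "star":
        v, f = _star_prism()
    else:
        cloud = {
            "cone": _cone, "cube": _cube, "cylinder": _cylinder,
            "dodecahedron": _dodecahedron, "pyramid": _pyramid,
            "octahedron": _octahedron, "tetrahedron": _tetrahedron,
            "hexprism": _hexprism, "antiprism": _antiprism,
        }
        if object_id == "jaimoid":
            pts = _jittered_icosahedron(rng)
        elif object_id == "blob":
            pts = _jittered_icosahedron(rng, jitter=0.35)
        else:
            pts = cloud[object_id]()
        v, f = _convex_mesh(pts)
    return ObjectModel(object_id, _pitch(_normalize(v), _TILTS[object_id]), f)


def make_object_library(seed: int = 0) -> dict[str, ObjectModel]:
    """Build the six trained objects plus six novel control objects.

    The irregular occluded object and the novel "blob" are generated
    deterministically from ``seed``.
    """
    rng = np.random.default_rng(seed)
    library: dict[str, ObjectModel] = {}
    for oid in TRAINED_IDS + NOVEL_IDS:
        library[oid] = _build(oid, rng)
    return library


def rotate_y(vertices: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate in depth about the object's own vertical (y) axis."""
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    rot = np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    return vertices @ rot.T
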