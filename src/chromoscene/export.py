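"""Materialize resolved scenes as meshes and static raster previews.

The interactive renderer is out of scope; instead a resolved scene can
be exported to standard 3D formats (ascii PLY with per-vertex colors,
OBJ) or rasterized to a deterministic PNG preview.

Mark tessellation: spheres become icospheres (20 * 4^subdiv faces) —
uniform triangles, unlike UV-spheres — and boxes become 12-triangle
cuboids with edge 2 * radius.  Link segments become 8-sided cylinders
of radius 0.25 * the structure's default mark radius.
"""

from __future__ import annotations

import numpy as np
import trimesh
from PIL import Image

from .core import InputError
from .encode import ResolvedScene

#: Neutral color for link cylinders (no channel is defined for links).
LINK_RGBA = (128, 128, 128, 255)

MAX_SUBDIV = 5


def scene_bounds(scene: ResolvedScene) -> np.ndarray:
    """Axis-aligned bounds of the scene as a (2, 3) [min; max] array.

    The point bounding box inflated by the largest mark radius on each
    side — the exact bounds of the union of the (ideal) spheres/boxes.
    """
    if scene.n_marks == 0:
        raise InputError("empty scene has no bounds")
    r = float(scene.radii.max())
    lo = scene.positions.min(axis=0) - r
    hi = scene.positions.max(axis=0) + r
    return np.stack([lo, hi])


def _colored(mesh: trimesh.Trimesh, rgba) -> trimesh.Trimesh:
    mesh.visual = trimesh.visual.ColorVisuals(
        mesh, vertex_colors=np.tile(np.asarray(rgba, dtype=np.uint8),
                                    (len(mesh.vertices), 1))
    )
    return mesh


def to_mesh(scene: ResolvedScene, sphere_subdiv: int = 2) -> trimesh.Trimesh:
    """Tessellate every mark (and link) of a resolved scene.

    Returns a single triangle mesh with per-vertex RGBA colors.  Face
    counts are exact: ``20 * 4^subdiv`` per sphere, 12 per box; an
    empty scene gives an empty mesh.

    ``sphere_subdiv`` above 5 is refused — each level quadruples the
    face count and 5 already means 20480 faces per sphere.
    """
    if sphere_subdiv < 0 or sphere_subdiv > MAX_SUBDIV:
        raise InputError(
            f"sphere_subdiv must be in [0, {MAX_SUBDIV}], got {sphere_subdiv}"
        )
    parts: list[trimesh.Trimesh] = []
    for pos, mark, radius, rgba in zip(
        scene.positions, scene.marks, scene.radii, scene.rgba
    ):
        if mark == "sphere":
            m = trimesh.creation.icosphere(
                subdivisions=sphere_subdiv, radius=float(radius)
            )
        elif mark == "box":
            m = trimesh.creation.box(extents=np.full(3, 2.0 * float(radius)))
        else:
            raise InputError(f"unknown mark type {mark!r}")
        m.apply_translation(np.asarray(pos, dtype=float))
        parts.append(_colored(m, rgba))

    for seg, radius in zip(scene.links, scene.link_radii):
        if np.allclose(seg[0], seg[1]):
            continue  # zero-length link has no cylinder
        cyl = trimesh.creation.cylinder(
            radius=float(radius), sections=8, segment=np.asarray(seg, float)
        )
        parts.append(_colored(cyl, LINK_RGBA))

    if not parts:
        return trimesh.Trimesh(
            vertices=np.empty((0, 3)), faces=np.empty((0, 3), dtype=int),
            process=False,
        )
    if len(parts) == 1:
        return parts[0]
    return trimesh.util.concatenate(parts)


_EMPTY_PLY = (
    "ply\nformat ascii 1.0\n"
    "element vertex 0\n"
    "property float x\nproperty float y\nproperty float z\n"
    "property uchar red\nproperty uchar green\nproperty uchar blue\n"
    "property uchar alpha\n"
    "element face 0\nproperty list uchar int vertex_indices\n"
    "end_header\n"
)


def write_ply(mesh: trimesh.Trimesh, path) -> None:
    """Write an ascii PLY with per-vertex uchar RGBA colors.

    A zero-mark scene yields a valid 0-element PLY.
    """
    if len(mesh.vertices) == 0:
        data = _EMPTY_PLY.encode()
    else:
        data = trimesh.exchange.ply.export_ply(mesh, encoding="ascii")
    with open(path, "wb") as fh:
        fh.write(data)


def write_obj(mesh: trimesh.Trimesh, path) -> None:
    """Write a Wavefront OBJ.

    OBJ carries no per-vertex colors; geometry/topology only.  Use PLY
    when colors matter.
    """
    data = trimesh.exchange.obj.export_obj(mesh, include_color=False)
    with open(path, "w", newline="\n") as fh:
        fh.write(data)


def read_ply(path) -> trimesh.Trimesh:
    """Load a PLY without vertex merging (topology preserved as written)."""
    return trimesh.load_mesh(path, file_type="ply", process=False)


# ---------------------------------------------------------------------
# Raster preview


def _view_basis(direction) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    d = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(d)
    if norm == 0 or not np.isfinite(d).all():
        raise InputError("view direction must be a finite non-zero 3-vector")
    d = d / norm
    up = np.array([0.0, 0.0, 1.0])
    if abs(d @ up) > 0.999:
        up = np.array([0.0, 1.0, 0.0])
    u = np.cross(up, d)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v, d


def render_preview(
    scene: ResolvedScene,
    path,
    direction=(1.0, 1.0, 1.0),
    size: int = 400,
) -> None:
    """Rasterize an orthographic preview of the scene to a PNG.

    Marks are drawn as filled discs of their mark color, back to front
    by projected depth (painter's algorithm; the bin nearest the camera
    wins overlapping pixels).  Links are drawn as thin grey segments
    behind the marks.  The output is byte-deterministic for fixed
    inputs: rasterization is pure integer/float arithmetic on a numpy
    framebuffer and the PNG writer embeds no timestamps.
    """
    if scene.n_marks == 0:
        raise InputError("cannot render an empty scene")
    u, v, d = _view_basis(direction)
    P = scene.positions
    px, py, depth = P @ u, P @ v, P @ d
    r = scene.radii

    margin = 0.05 * (size - 1)
    lo = np.array([(px - r).min(), (py - r).min()])
    hi = np.array([(px + r).max(), (py + r).max()])
    extent = float(max(hi[0] - lo[0], hi[1] - lo[1]))
    if extent == 0:
        extent = 1.0
    s = (size - 1 - 2 * margin) / extent

    def to_pix(ax, ay):
        cx = margin + (ax - lo[0]) * s
        cy = (size - 1) - (margin + (ay - lo[1]) * s)
        return cx, cy

    img = np.zeros((size, size, 4), dtype=np.uint8)
    img[:, :, :3] = 255  # white background, opaque
    img[:, :, 3] = 255

    yy, xx = np.mgrid[0:size, 0:size]

    def stamp(cx, cy, pr, rgba):
        x0 = max(int(np.floor(cx - pr)) - 1, 0)
        x1 = min(int(np.ceil(cx + pr)) + 2, size)
        y0 = max(int(np.floor(cy - pr)) - 1, 0)
        y1 = min(int(np.ceil(cy + pr)) + 2, size)
        if x0 >= x1 or y0 >= y1:
            return
        win_y, win_x = yy[y0:y1, x0:x1], xx[y0:y1, x0:x1]
        disc = (win_x - cx) ** 2 + (win_y - cy) ** 2 <= pr**2
        img[y0:y1, x0:x1][disc] = rgba

    # links first: thin segments sampled as small discs
    for seg, lr in zip(scene.links, scene.link_radii):
        a2 = np.array(to_pix(seg[0] @ u, seg[0] @ v))
        b2 = np.array(to_pix(seg[1] @ u, seg[1] @ v))
        length = np.linalg.norm(b2 - a2)
        n_steps = max(int(np.ceil(length)), 1)
        pr = max(lr * s, 0.5)
        for t in np.linspace(0.0, 1.0, n_steps + 1):
            c = a2 * (1 - t) + b2 * t
            stamp(c[0], c[1], pr, LINK_RGBA)

    # far-to-near: larger depth along the view direction = farther
    order = np.argsort(-depth, kind="stable")
    for i in order:
        cx, cy = to_pix(px[i], py[i])
        stamp(cx, cy, r[i] * s, scene.rgba[i])

    Image.fromarray(img, mode="RGBA").save(path, format="PNG")
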