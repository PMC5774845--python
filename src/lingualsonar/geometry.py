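"""Head meshes, mouth-aperture arrays and tongue positions.

Coordinate convention (used throughout the package): the head frame has
``x`` pointing rostrally (head aim), ``z`` dorsally (head normal) and
``y = z × x`` to the animal's left.  Azimuth is positive to the left,
elevation positive dorsal.  Meshes are in millimetres; the acoustics layer
converts to metres internally.

The canonical geometry is a *simplified artificial head*: a smooth closed
surface built from an ellipsoidal cranium, a protruding rounded rostrum and
optional ear bumps, sampled on a latitude/longitude grid and triangulated.
The mouth opening is represented by an ordered line of mesh vertices along a
lip seam low on the rostrum, tagged left/right of the sagittal plane; array
elements for the transmission-array model are placed on those vertices.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

__all__ = [
    "HeadMesh",
    "ArraySpec",
    "TonguePosition",
    "ElementRanges",
    "build_simplified_head",
    "place_elements",
    "element_ranges",
    "default_tongue",
    "read_mesh",
    "write_mesh",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeadMesh:
    """Closed triangulated head surface in millimetres.

    Attributes
    ----------
    vertices : (N, 3) float array
        Vertex coordinates, mm, head frame.
    triangles : (M, 3) int array
        Vertex index triples, consistently outward-wound.
    mouth_line : (K,) int array
        Ordered vertex indices along the mouth opening, running from the
        animal's right lip corner through the rostral midline to the left
        corner.
    mouth_side : (K,) array of "L"/"R"
        Side tag of each mouth-line vertex relative to the sagittal plane.
    provenance : str
        ``"simplified"`` for the canonical artificial head, ``"variant"``
        for modified shapes (e.g. ears removed).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    mouth_line: np.ndarray
    mouth_side: np.ndarray
    provenance: str = "simplified"

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        t = np.asarray(self.triangles, dtype=np.int64)
        ml = np.asarray(self.mouth_line, dtype=np.int64)
        side = np.asarray(self.mouth_side)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "triangles", t)
        object.__setattr__(self, "mouth_line", ml)
        object.__setattr__(self, "mouth_side", side)
        if t.ndim != 2 or t.shape[1] != 3:
            raise ValueError("triangles must be an (M, 3) index array")
        if ml.size and (ml.min() < 0 or ml.max() >= len(v)):
            raise ValueError("mouth_line contains invalid vertex indices")
        if len(side) != len(ml):
            raise ValueError("mouth_side must tag every mouth_line vertex")
        # left tag <=> positive y under the left-positive convention
        y = v[ml, 1]
        ok = np.all((side == "L") == (y > 0.0))
        if not ok:
            raise ValueError("left/right tags do not partition mouth_line "
                             "by the sagittal plane")

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.triangles.copy(),
                               process=False)

    @property
    def mouth_points(self) -> np.ndarray:
        """Coordinates of the mouth-line vertices, ordered R → L."""
        return self.vertices[self.mouth_line]

    def check_watertight(self) -> None:
        tm = self.as_trimesh()
        if not tm.is_watertight:
            raise ValueError("head mesh is not watertight")
        if tm.volume <= 0:
            raise ValueError("head mesh is inside-out (negative volume)")

    def edge_length(self) -> float:
        """Mean edge length, mm."""
        tm = self.as_trimesh()
        e = tm.edges_unique
        d = np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]],
                           axis=1)
        return float(d.mean())


@dataclass(frozen=True)
class ArraySpec:
    """Mouth-aperture element set for the transmission-array model.

    ``normals`` (optional) are outward surface normals at the elements,
    used by the fast-mode baffled element model to emulate head shadowing.
    """

    positions: np.ndarray        # (N, 3) mm, on the mouth line
    side: str                    # "left" | "right" | "both"
    mode: str                    # "discrete" | "continuous"
    normals: np.ndarray | None = None

    def __post_init__(self) -> None:
        p = np.atleast_2d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", p)
        if self.normals is not None:
            nrm = np.atleast_2d(np.asarray(self.normals, dtype=float))
            nrm = nrm / np.linalg.norm(nrm, axis=1, keepdims=True)
            object.__setattr__(self, "normals", nrm)
            if nrm.shape != p.shape:
                raise ValueError("normals must match positions")
        if self.side not in ("left", "right", "both"):
            raise ValueError(f"invalid side {self.side!r}")
        if self.mode not in ("discrete", "continuous"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if len(p) < 1:
            raise ValueError("array needs at least one element")
        y = p[:, 1]
        if self.side == "left" and not np.all(y > 0):
            raise ValueError("side='left' requires all elements left of "
                             "the midline (y > 0)")
        if self.side == "right" and not np.all(y < 0):
            raise ValueError("side='right' requires all elements right of "
                             "the midline (y < 0)")

    @property
    def n_elements(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class TonguePosition:
    """Location of the clicking tongue inside the mouth cavity, mm."""

    location: np.ndarray
    side: str = "center"

    def __post_init__(self) -> None:
        loc = np.asarray(self.location, dtype=float).reshape(3)
        object.__setattr__(self, "location", loc)


@dataclass(frozen=True)
class ElementRanges:
    """Tongue-to-element distances r_n (mm), one per array element."""

    r_n: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r_n, dtype=float).ravel()
        object.__setattr__(self, "r_n", r)
        if np.any(r <= 0):
            raise ValueError("all element ranges must be positive")


# ---------------------------------------------------------------------------
# simplified artificial head
# ---------------------------------------------------------------------------

# angular placement of the lip seam and facial features on the unit shape
_MOUTH_POLAR_DEG = 110.0      # polar angle of the lip seam (below equator)
_MOUTH_HALF_SPAN_DEG = 65.0   # frontal azimuthal half-extent of the mouth
_ROSTRUM_POLAR_DEG = 100.0    # rostrum bump axis, slightly below equator
# ears sit low enough on the cranium that the bounding box is set by the
# cranium alone: removing them is then a purely local edit
_EAR_POLAR_DEG = 55.0
_EAR_AZIMUTH_DEG = 130.0


def _shape_radius(theta: np.ndarray, phi: np.ndarray, *, rostrum: float,
                  rostrum_width: float, ears: bool,
                  ear_height: float) -> np.ndarray:
    """Radius of the unit head shape for polar angle theta, azimuth phi."""
    ux = np.sin(theta) * np.cos(phi)
    uy = np.sin(theta) * np.sin(phi)
    uz = np.cos(theta)
    # ellipsoidal cranium, slightly longer than wide
    ax, ay, az = 1.2, 1.0, 1.0
    rho = 1.0 / np.sqrt((ux / ax) ** 2 + (uy / ay) ** 2 + (uz / az) ** 2)
    # protruding rounded rostrum on the +x axis, slightly below the equator
    th0 = np.radians(_ROSTRUM_POLAR_DEG)
    snout_axis = np.array([np.sin(th0), 0.0, np.cos(th0)])
    cosang = ux * snout_axis[0] + uy * snout_axis[1] + uz * snout_axis[2]
    ang = np.arccos(np.clip(cosang, -1.0, 1.0))
    rho = rho + rostrum * np.exp(-(ang / rostrum_width) ** 2)
    if ears:
        # compactly supported C^2 bumps: removing the ears leaves every
        # vertex outside their support bit-identical
        cutoff = 0.55
        for sgn in (+1.0, -1.0):
            te = np.radians(_EAR_POLAR_DEG)
            pe = sgn * np.radians(_EAR_AZIMUTH_DEG)
            exa = np.array([np.sin(te) * np.cos(pe),
                            np.sin(te) * np.sin(pe), np.cos(te)])
            cose = ux * exa[0] + uy * exa[1] + uz * exa[2]
            ange = np.arccos(np.clip(cose, -1.0, 1.0))
            t = np.clip(1.0 - (ange / cutoff) ** 2, 0.0, None)
            rho = rho + ear_height * t ** 3
    return rho


def build_simplified_head(length: float = 40.0, width: float = 25.0,
                          height: float = 25.0, *, edge_length: float = 0.5,
                          rostrum: float = 0.55, rostrum_width: float = 0.75,
                          ears: bool = True,
                          ear_height: float = 0.35) -> HeadMesh:
    """Build the simplified artificial bat head.

    The surface is a smooth radial shape (ellipsoidal cranium + rostral bump
    + optional ear bumps) sampled on a latitude/longitude grid, triangulated,
    and finally rescaled per axis so the bounding box equals exactly
    ``length × width × height`` mm.  The mouth line is the frontal arc of the
    latitude row at the lip seam.

    Parameters
    ----------
    length, width, height : float
        Target bounding-box dimensions, mm (rostrocaudal, lateral, dorsoventral).
    edge_length : float
        Target triangle edge length, mm.  0.5 mm matches the remeshing
        resolution used for detailed head models; coarser values are adequate
        for low-frequency boundary-element runs.
    rostrum, rostrum_width : float
        Amplitude (unit-shape radii) and angular width (rad) of the rostral
        protrusion.
    ears : bool
        Include ear bumps (``False`` gives the "ears removed" variant).
    ear_height : float
        Ear bump amplitude in unit-shape radii.

    Construction is deterministic: identical parameters give a byte-identical
    mesh.
    """
    if min(length, width, height) <= 0:
        raise ValueError("head dimensions must be positive")
    if edge_length <= 0:
        raise ValueError("edge_length must be positive")

    # grid resolution from the target edge length at the final scale
    mean_radius = (length + width + height) / 6.0
    n_theta = max(24, int(np.ceil(np.pi * mean_radius / edge_length)))
    n_phi = max(48, int(np.ceil(2 * np.pi * mean_radius / edge_length)))
    if n_phi % 2:
        n_phi += 1

    theta_rows = np.linspace(0.0, np.pi, n_theta + 1)[1:-1]
    # snap the nearest row onto the lip seam so mouth vertices lie exactly on it
    th_mouth = np.radians(_MOUTH_POLAR_DEG)
    i_mouth = int(np.argmin(np.abs(theta_rows - th_mouth)))
    theta_rows[i_mouth] = th_mouth
    # half-step azimuth sampling: no vertex exactly on the sagittal plane,
    # and the sample set is mirror-symmetric in y
    phi = -np.pi + 2 * np.pi * (np.arange(n_phi) + 0.5) / n_phi

    tt, pp = np.meshgrid(theta_rows, phi, indexing="ij")
    rho = _shape_radius(tt, pp, rostrum=rostrum, rostrum_width=rostrum_width,
                        ears=ears, ear_height=ear_height)
    ring_v = np.stack([rho * np.sin(tt) * np.cos(pp),
                       rho * np.sin(tt) * np.sin(pp),
                       rho * np.cos(tt)], axis=-1)

    r_top = _shape_radius(np.array(0.0), np.array(0.0), rostrum=rostrum,
                          rostrum_width=rostrum_width, ears=ears,
                          ear_height=ear_height)
    r_bot = _shape_radius(np.array(np.pi), np.array(0.0), rostrum=rostrum,
                          rostrum_width=rostrum_width, ears=ears,
                          ear_height=ear_height)
    n_rows = len(theta_rows)
    verts = np.concatenate([
        np.array([[0.0, 0.0, float(r_top)]]),
        ring_v.reshape(-1, 3),
        np.array([[0.0, 0.0, -float(r_bot)]]),
    ])

    def rv(i: int, j: int) -> int:
        return 1 + i * n_phi + (j % n_phi)

    faces = []
    for j in range(n_phi):               # top fan (outward winding)
        faces.append([0, rv(0, j), rv(0, j + 1)])
    for i in range(n_rows - 1):
        for j in range(n_phi):
            a, b = rv(i, j), rv(i, j + 1)
            c, d = rv(i + 1, j), rv(i + 1, j + 1)
            faces.append([a, c, b])
            faces.append([b, c, d])
    bot = len(verts) - 1
    for j in range(n_phi):               # bottom fan
        faces.append([bot, rv(n_rows - 1, j + 1), rv(n_rows - 1, j)])
    faces = np.asarray(faces, dtype=np.int64)

    # exact per-axis rescale to the requested bounding box
    span = verts.max(axis=0) - verts.min(axis=0)
    center = 0.5 * (verts.max(axis=0) + verts.min(axis=0))
    verts = (verts - center) * (np.array([length, width, height]) / span)

    # mouth line: frontal arc of the lip-seam row, ordered right -> left
    half = np.radians(_MOUTH_HALF_SPAN_DEG)
    jj = np.where(np.abs(phi) <= half)[0]
    jj = jj[np.argsort(phi[jj])]                  # increasing phi = R -> L
    mouth_idx = np.array([rv(i_mouth, int(j)) for j in jj], dtype=np.int64)
    mouth_side = np.where(verts[mouth_idx, 1] > 0, "L", "R")

    mesh = HeadMesh(verts, faces, mouth_idx, mouth_side,
                    provenance="simplified" if ears else "variant")
    tm = mesh.as_trimesh()
    if not tm.is_watertight or tm.volume <= 0:
        raise RuntimeError(
            "simplified head construction produced a non-manifold mesh "
            f"(watertight={tm.is_watertight}, volume={tm.volume:.3g})")
    return mesh


def mouth_cavity_bounds(mesh: HeadMesh, depth: float | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned bounding box of the mouth cavity, (lo, hi) in mm.

    The cavity is taken to extend caudally from the lip seam by ``depth``
    (default: 40% of head length), spanning the lateral/vertical extent of
    the mouth line with a small vertical allowance for the tongue body.
    """
    mp = mesh.mouth_points
    length = float(np.ptp(mesh.vertices[:, 0]))
    if depth is None:
        depth = 0.4 * length
    lo = np.array([mp[:, 0].max() - depth, mp[:, 1].min(),
                   mp[:, 2].min() - 1.0])
    hi = np.array([mp[:, 0].max(), mp[:, 1].max(), mp[:, 2].max() + 4.0])
    return lo, hi


def default_tongue(mesh: HeadMesh, lateral: float = 0.0,
                   depth_frac: float = 0.5) -> TonguePosition:
    """Tongue position inside the mouth cavity.

    ``lateral`` displaces the tongue along y (positive = bat's left);
    ``depth_frac`` places it between the lip seam (0) and the caudal end of
    the cavity (1).
    """
    lo, hi = mouth_cavity_bounds(mesh)
    x = hi[0] + depth_frac * (lo[0] - hi[0])
    z = 0.5 * (lo[2] + hi[2])
    tp = TonguePosition(np.array([x, lateral, z]),
                        side="left" if lateral > 0 else
                        ("right" if lateral < 0 else "center"))
    validate_tongue(tp, mesh)
    return tp


def validate_tongue(tongue: TonguePosition, mesh: HeadMesh) -> None:
    lo, hi = mouth_cavity_bounds(mesh)
    loc = tongue.location
    if np.any(loc < lo - 1e-9) or np.any(loc > hi + 1e-9):
        raise ValueError(
            f"tongue position {loc} lies outside the mouth cavity box "
            f"[{lo}, {hi}]")


# ---------------------------------------------------------------------------
# element placement and ranges
# ---------------------------------------------------------------------------


def _side_arc(mesh: HeadMesh, side_tag: str) -> tuple[np.ndarray, np.ndarray]:
    """Mouth-line points and outward normals of one side, rostral → caudal."""
    sel = mesh.mouth_line[mesh.mouth_side == side_tag]
    if len(sel) == 0:
        raise ValueError(f"mouth line has no vertices on side {side_tag!r}")
    pts = mesh.vertices[sel]
    order = np.argsort(-pts[:, 0])         # decreasing x = rostral first
    normals = np.asarray(mesh.as_trimesh().vertex_normals)[sel]
    return pts[order], normals[order]


def _arc_lengths(pts: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def place_elements(mesh: HeadMesh, side: str = "left",
                   mode: str = "discrete", n: int | None = None,
                   spacing: float | None = None,
                   rostral_shift: float = 0.0) -> ArraySpec:
    """Place transmission-array elements on the mouth line.

    Discrete mode picks ``n`` mouth-line vertices evenly spaced in arc
    length (the gaps between clenched teeth); continuous mode takes every
    vertex closest to a regular arc-length grid of step ``spacing`` (the
    narrow slit between parted lips).  ``side='both'`` mirrors the left
    element set about the sagittal plane.  ``rostral_shift`` moves the whole
    occupied arc toward the rostrum by a fraction of the free arc length
    (0 = default placement, 1 = fully rostral), used for placement
    sensitivity studies.
    """
    if side == "both":
        left = place_elements(mesh, "left", mode, n=n, spacing=spacing,
                              rostral_shift=rostral_shift)
        flip = np.array([1.0, -1.0, 1.0])
        pos = np.vstack([left.positions, left.positions * flip])
        nrm = None
        if left.normals is not None:
            nrm = np.vstack([left.normals, left.normals * flip])
        return ArraySpec(pos, "both", mode, nrm)

    tag = "L" if side == "left" else "R"
    pts, nrms = _side_arc(mesh, tag)
    s = _arc_lengths(pts)
    total = s[-1]

    # both modes occupy the same central-60% window of the arc, so that a
    # continuous array is a densified version of the discrete one;
    # rostral_shift slides the window toward the rostrum
    frac = 0.6
    lo = (1.0 - frac) * total * 0.5 * (1.0 - rostral_shift)
    if mode == "discrete":
        if n is None:
            raise ValueError("discrete mode requires element count n")
        if n > len(pts):
            raise ValueError(
                f"requested {n} elements but the {side} mouth line has only "
                f"{len(pts)} vertices")
        targets = lo + np.linspace(0.0, frac * total, n)
    else:
        if spacing is None or spacing <= 0:
            raise ValueError("continuous mode requires a positive spacing")
        targets = lo + np.arange(0.0, frac * total + 1e-9, spacing)
    idx = np.unique([int(np.argmin(np.abs(s - t))) for t in targets])
    # rostral -> caudal ordering is inherited from the arc
    return ArraySpec(pts[idx], side, mode, nrms[idx])


def element_ranges(tongue: TonguePosition, array: ArraySpec) -> ElementRanges:
    """Tongue-to-element Euclidean distances r_n, mm."""
    d = np.linalg.norm(array.positions - tongue.location[None, :], axis=1)
    if np.any(d < 1e-9):
        raise ValueError("tongue position coincides with an array element")
    return ElementRanges(d)


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".annot.json")


def write_mesh(mesh: HeadMesh, path: str | Path) -> None:
    """Write the mesh as STL or OBJ with a JSON annotation sidecar.

    The sidecar stores mouth-line vertex *coordinates* (not indices), so the
    annotation survives format round trips that merge or reorder vertices.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in (".stl", ".obj"):
        raise ValueError(f"unsupported mesh format {ext!r} (use .stl or .obj)")
    tm = mesh.as_trimesh()
    if ext == ".stl":
        path.write_bytes(trimesh.exchange.stl.export_stl_ascii(tm)
                         .encode("ascii"))
    else:
        path.write_text(trimesh.exchange.obj.export_obj(tm,
                                                        include_normals=False))
    annot = {
        "provenance": mesh.provenance,
        "mouth_points": mesh.mouth_points.tolist(),
        "mouth_side": [str(s) for s in mesh.mouth_side],
    }
    _sidecar_path(path).write_text(json.dumps(annot, indent=1))


def read_mesh(path: str | Path) -> HeadMesh:
    """Read an STL/OBJ mesh and its annotation sidecar.

    Inside-out meshes (negative volume with consistent winding) are
    reoriented; inconsistent winding raises.  Non-triangulated input raises.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in (".stl", ".obj"):
        raise ValueError(f"unsupported mesh format {ext!r} (use .stl or .obj)")
    loaded = trimesh.load(str(path), process=(ext == ".stl"),
                          force="mesh", maintain_order=(ext == ".obj"))
    if not isinstance(loaded, trimesh.Trimesh) or loaded.faces.shape[1] != 3:
        raise ValueError(f"{path} is not a triangulated surface mesh")
    if ext == ".stl":
        loaded.merge_vertices()
    if not loaded.is_winding_consistent:
        raise ValueError(f"{path}: inconsistent triangle winding")
    if loaded.volume < 0:
        warnings.warn(f"{path}: flipped normals detected; reorienting",
                      stacklevel=2)
        loaded.invert()

    side = _sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"annotation sidecar {side} not found")
    annot = json.loads(side.read_text())
    mouth_pts = np.asarray(annot["mouth_points"], dtype=float)
    tree = cKDTree(loaded.vertices)
    dist, idx = tree.query(mouth_pts)
    if np.any(dist > 1e-4):
        raise ValueError(
            f"{path}: mouth-line annotation does not match mesh vertices "
            f"(max deviation {dist.max():.3g} mm)")
    return HeadMesh(np.asarray(loaded.vertices), np.asarray(loaded.faces),
                    np.asarray(idx, dtype=np.int64),
                    np.asarray(annot["mouth_side"]),
                    provenance=annot.get("provenance", "variant"))
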