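"""Arch-form extraction from a dental-cast mesh.

Dental side: segment tooth crowns from the cast by curvature-bounded region
growing, pick one landmark per crown (buccal cusp / cusp tip / incisal edge
apex), and fit a 6th-degree polynomial through the landmarks in the occlusal
frame.

Dentoalveolar side: slice the remaining soft tissue into horizontal layers
between the gingival margin and the alveolar mucosa, project each layer onto
the occlusal plane, and keep the smoothest projection -- the LiLo curve --
scored by the standard deviation of the first differences of the
arc-length-resampled polyline.  Choosing the smoothest layer avoids the
gingival margin, whose festooned outline leaves many corner points after
projection.  The LiLo contour is then fitted with the same 6th-degree
polynomial.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import Polynomial
from scipy import sparse

from .geometry import (
    ArchMeasurements,
    DentalMesh,
    GeometryError,
    OcclusalFrame,
    build_occlusal_frame,
    fit_occlusal_plane,
    measure_depth_width,
)

__all__ = [
    "ExtractionError",
    "SegmentationError",
    "ArchLandmarks",
    "LayeredContours",
    "ArchCurve",
    "SegmentationResult",
    "ExtractionResult",
    "segment_teeth",
    "occlusal_up_axis",
    "identify_landmarks",
    "layer_soft_tissue",
    "smoothness_score",
    "select_lilo",
    "fit_arch_polynomial",
    "cross_section",
    "resample_polyline",
    "extract_arch_forms",
]


class ExtractionError(ValueError):
    pass


class SegmentationError(ExtractionError):
    pass


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchLandmarks:
    """Ordered arch landmarks, distal-left to distal-right.

    One point per tooth: buccal cusps of molars/premolars, cusp tips of
    canines, incisal edges of incisors.
    """

    points: np.ndarray
    roles: tuple = ()
    tooth_labels: tuple = ()

    def __post_init__(self):
        p = np.atleast_2d(np.asarray(self.points, float))
        if p.shape[0] < 7:
            raise ExtractionError("need at least 7 landmarks for a degree-6 fit")
        object.__setattr__(self, "points", p)
        object.__setattr__(self, "roles", tuple(self.roles))
        object.__setattr__(self, "tooth_labels", tuple(self.tooth_labels))

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class LayeredContours:
    """Horizontal soft-tissue contours projected onto the occlusal plane.

    ``raw_layers`` hold the untouched section polylines (used for curve
    fitting); ``layers`` are the same contours resampled to uniform
    arc-length spacing (used for smoothness scoring).  Invalid layers (empty
    cross-sections) carry ``None`` entries and infinite smoothness.
    """

    heights: np.ndarray
    raw_layers: list
    layers: list
    smoothness: np.ndarray
    valid: np.ndarray

    @property
    def n_layers(self) -> int:
        return len(self.heights)


@dataclass(frozen=True)
class ArchCurve:
    """Degree-6 polynomial arch form y(x) in occlusal-frame mm."""

    coefficients: np.ndarray  # ascending powers, length 7
    domain: tuple
    source: str = "dental"
    rms_residual: float = 0.0

    def __post_init__(self):
        c = np.asarray(self.coefficients, float)
        if c.shape != (7,) or not np.all(np.isfinite(c)):
            raise ExtractionError("coefficients must be 7 finite reals")
        if not self.domain[1] > self.domain[0]:
            raise ExtractionError("degenerate curve domain")
        object.__setattr__(self, "coefficients", c)
        object.__setattr__(self, "domain", (float(self.domain[0]), float(self.domain[1])))

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return Polynomial(self.coefficients)(np.asarray(x, float))

    def sample(self, n: int = 500) -> np.ndarray:
        x = np.linspace(self.domain[0], self.domain[1], n)
        return np.column_stack([x, self.evaluate(x)])

    def measure(self) -> ArchMeasurements:
        return measure_depth_width(self.sample(501))


@dataclass
class SegmentationResult:
    teeth: list
    remainder: DentalMesh
    vertex_labels: np.ndarray  # -1 soft tissue / boundary, 0..T-1 tooth index
    boundary_z: float          # most apical z of the tooth/tissue boundary contour


@dataclass
class ExtractionResult:
    frame: OcclusalFrame
    landmarks: ArchLandmarks          # framed, ordered by x
    dental_curve: ArchCurve
    contours: LayeredContours
    lilo_index: int
    dentoalveolar_curve: ArchCurve
    margin_z: float
    segmentation: SegmentationResult


# ---------------------------------------------------------------------------
# mesh helpers
# ---------------------------------------------------------------------------


def _vertex_adjacency(faces: np.ndarray, n: int) -> sparse.csr_matrix:
    e = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    data = np.ones(len(e))
    adj = sparse.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
    adj = adj + adj.T
    adj.data[:] = 1.0
    return adj.tocsr()


def _boundary_vertices(faces: np.ndarray, n: int) -> np.ndarray:
    edges = np.vstack([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    mask = np.zeros(n, dtype=bool)
    mask[uniq[counts == 1].ravel()] = True
    return mask


def _vertex_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # area-weighted
    vn = np.zeros_like(vertices)
    for k in range(3):
        np.add.at(vn, faces[:, k], fn)
    norms = np.linalg.norm(vn, axis=1)
    norms[norms == 0] = 1.0
    vn = vn / norms[:, None]
    # orient outward: the cast is roughly star-shaped around its centroid
    centroid = vertices.mean(axis=0)
    if np.mean(np.einsum("ij,ij->i", vertices - centroid, vn)) < 0:
        vn = -vn
    return vn


def vertex_concavity(mesh: DentalMesh) -> np.ndarray:
    """Signed concavity per vertex (1/mm); positive in valleys and creases.

    Umbrella Laplacian projected on the outward vertex normal and scaled by
    the squared mean incident edge length, a discrete proxy for mean
    curvature that is invariant to rigid motion.
    """
    v, f = mesh.vertices, mesh.faces
    adj = _vertex_adjacency(f, len(v))
    deg = np.asarray(adj.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    lap = (adj @ v) / deg[:, None] - v
    # mean incident edge length per vertex
    edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    elen = np.linalg.norm(v[edges[:, 0]] - v[edges[:, 1]], axis=1)
    acc = np.zeros(len(v))
    cnt = np.zeros(len(v))
    np.add.at(acc, edges[:, 0], elen)
    np.add.at(acc, edges[:, 1], elen)
    np.add.at(cnt, edges[:, 0], 1.0)
    np.add.at(cnt, edges[:, 1], 1.0)
    cnt[cnt == 0] = 1.0
    mean_edge = acc / cnt
    mean_edge[mean_edge == 0] = 1.0
    normals = _vertex_normals(v, f)
    return np.einsum("ij,ij->i", lap, normals) / mean_edge**2


def concave_edge_vertices(mesh: DentalMesh, angle_deg: float) -> np.ndarray:
    """Vertices incident to a strongly concave crease edge.

    An interior edge is concave when its two faces meet at a dihedral angle
    bent toward the outward normals (a valley/groove line) by more than
    ``angle_deg``.  Angle-based, hence invariant to rigid motion and mesh
    scale, and robust where vertex normals degenerate (narrow grooves).
    """
    v, f = mesh.vertices, mesh.faces
    tri = v[f]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(fn, axis=1)
    norms[norms == 0] = 1.0
    fn = fn / norms[:, None]
    # orient consistently outward (generator meshes have consistent winding;
    # flip globally if the winding points inward on average)
    centroid = v.mean(axis=0)
    fc = tri.mean(axis=1)
    if np.mean(np.einsum("ij,ij->i", fc - centroid, fn)) < 0:
        fn = -fn
    # per-face edges with their opposite vertex
    e0 = f[:, [0, 1]]
    e1 = f[:, [1, 2]]
    e2 = f[:, [2, 0]]
    edges = np.vstack([e0, e1, e2])
    opp = np.concatenate([f[:, 2], f[:, 0], f[:, 1]])
    face_id = np.tile(np.arange(len(f)), 3)
    key = np.sort(edges, axis=1)
    order = np.lexsort((key[:, 1], key[:, 0]))
    key, edges, opp, face_id = key[order], edges[order], opp[order], face_id[order]
    same = np.all(key[:-1] == key[1:], axis=1)
    i, j = np.flatnonzero(same), np.flatnonzero(same) + 1
    n1, n2 = fn[face_id[i]], fn[face_id[j]]
    cos_ang = np.einsum("ij,ij->i", n1, n2)
    bent = cos_ang < np.cos(np.deg2rad(angle_deg))
    # concave when the opposite vertex of the second face lies on the
    # outward side of the first face's plane
    d = v[opp[j]] - v[key[i][:, 0]]
    concave = np.einsum("ij,ij->i", n1, d) > 0
    mask = np.zeros(len(v), dtype=bool)
    hit = key[i][bent & concave]
    mask[hit.ravel()] = True
    return mask


def _submesh(mesh: DentalMesh, vertex_mask: np.ndarray) -> DentalMesh:
    idx = np.flatnonzero(vertex_mask)
    remap = -np.ones(mesh.n_vertices, dtype=np.int64)
    remap[idx] = np.arange(len(idx))
    fmask = vertex_mask[mesh.faces].all(axis=1)
    faces = remap[mesh.faces[fmask]]
    return DentalMesh(vertices=mesh.vertices[idx], faces=faces, jaw=mesh.jaw)


# ---------------------------------------------------------------------------
# tooth segmentation
# ---------------------------------------------------------------------------


def segment_teeth(
    mesh: DentalMesh,
    barrier_angle: float = 40.0,
    barrier_concavity: float = 0.8,
    cap_convexity: float = 0.25,
    min_region: int = 20,
    max_tooth_radius: float = 18.0,
    min_relief: float = 0.1,
) -> SegmentationResult:
    """Partition a cast into tooth crowns and a soft-tissue remainder.

    Crowns are separated from the gingiva (and from each other) by
    negative-curvature contour lines: vertices on concave crease edges
    (dihedral bent beyond ``barrier_angle`` degrees), vertices whose
    discrete concavity exceeds ``barrier_concavity`` and mesh-boundary
    vertices form barriers, and the connected components of the remaining
    vertex graph are candidate regions.  A component is a tooth crown when it has at least
    ``min_region`` vertices, is compact (no vertex farther than
    ``max_tooth_radius`` mm from the component centroid -- crowns are small
    bumps, soft-tissue patches span the arch) and carries crown relief
    (out-of-plane spread above ``min_relief`` mm; flat tissue shelves are
    planar).  Everything else, including the barrier contours themselves,
    is the soft-tissue remainder.  The rule uses no height axis, so
    segmentation is invariant to rigid motion.

    Raises :class:`SegmentationError` when convex crown caps are present but
    no separating concave contour delimits them.
    """
    v, f = mesh.vertices, mesh.faces
    n = len(v)
    conc = vertex_concavity(mesh)
    barrier = concave_edge_vertices(mesh, barrier_angle)
    barrier |= conc > barrier_concavity
    open_mask = ~barrier
    adj = _vertex_adjacency(f, n)
    sub = adj[open_mask][:, open_mask]
    n_comp, comp = sparse.csgraph.connected_components(sub, directed=False)
    full_comp = -np.ones(n, dtype=np.int64)
    full_comp[open_mask] = comp
    vertex_labels = -np.ones(n, dtype=np.int64)
    teeth: list[DentalMesh] = []
    tooth_comps = []
    for c in range(n_comp):
        mask = full_comp == c
        if mask.sum() < min_region:
            continue
        pts = v[mask]
        centered = pts - pts.mean(axis=0)
        radius = np.linalg.norm(centered, axis=1).max()
        relief = np.sqrt(max(np.linalg.eigvalsh(np.cov(centered.T))[0], 0.0))
        if radius <= max_tooth_radius and relief > min_relief:
            tooth_comps.append(c)
    # deterministic ordering: by component centroid x, then y
    cents = [v[full_comp == c].mean(axis=0) for c in tooth_comps]
    order = sorted(range(len(tooth_comps)), key=lambda i: (cents[i][0], cents[i][1]))
    for t, i in enumerate(order):
        mask = full_comp == tooth_comps[i]
        vertex_labels[mask] = t
        teeth.append(_submesh(mesh, mask))
    if not teeth:
        strong_caps = int(np.sum(conc < -cap_convexity))
        if strong_caps >= min_region and barrier.sum() == 0:
            raise SegmentationError(
                "crown-like convex caps detected but no negative-curvature "
                "separating contour was found; check mesh resolution or "
                "barrier_concavity"
            )
    # faces not fully inside one crown form the remainder, so the partition
    # is exhaustive and disjoint over faces
    flab = vertex_labels[mesh.faces]
    in_tooth = (flab[:, 0] >= 0) & (flab[:, 0] == flab[:, 1]) & (flab[:, 1] == flab[:, 2])
    rem_faces = mesh.faces[~in_tooth]
    if len(rem_faces):
        used = np.zeros(n, dtype=bool)
        used[rem_faces.ravel()] = True
        remap = -np.ones(n, dtype=np.int64)
        remap[used] = np.arange(used.sum())
        remainder = DentalMesh(
            vertices=v[used], faces=remap[rem_faces], jaw=mesh.jaw
        )
    else:
        remainder = DentalMesh(vertices=v, faces=np.empty((0, 3), dtype=np.int64), jaw=mesh.jaw)
    # boundary contour: soft-tissue vertices adjacent to a tooth vertex
    tooth_mask = vertex_labels >= 0
    if tooth_mask.any():
        near_tooth = np.asarray(adj[:, tooth_mask].sum(axis=1)).ravel() > 0
        bverts = (~tooth_mask) & near_tooth
        boundary_z = float(v[bverts, 2].min()) if bverts.any() else float(v[:, 2].max())
    else:
        boundary_z = float(v[:, 2].max())
    return SegmentationResult(
        teeth=teeth, remainder=remainder, vertex_labels=vertex_labels, boundary_z=boundary_z
    )


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------


def _local_height_maxima(mesh: DentalMesh, up: np.ndarray) -> np.ndarray:
    adj = _vertex_adjacency(mesh.faces, mesh.n_vertices).tolil()
    z = mesh.vertices @ up
    out = []
    for i in range(mesh.n_vertices):
        nbr = adj.rows[i]
        if nbr and all(z[i] >= z[j] for j in nbr) and any(z[i] > z[j] for j in nbr):
            out.append(i)
    return np.array(out, dtype=np.int64)


def occlusal_up_axis(teeth: list, below: np.ndarray | None = None) -> np.ndarray:
    """Cast-intrinsic crown-side axis: normal of the total-least-squares
    plane through the tooth-component centroids, oriented away from
    ``below`` (e.g. the soft-tissue centroid) or toward +z."""
    cents = np.array([t.vertices.mean(axis=0) for t in teeth])
    if len(cents) < 3:
        return np.array([0.0, 0.0, 1.0])
    _, _, vt = np.linalg.svd(cents - cents.mean(axis=0))
    up = vt[2]
    if below is not None:
        if up @ (cents.mean(axis=0) - np.asarray(below, float)) < 0:
            up = -up
    elif up[2] < 0:
        up = -up
    return up


def identify_landmarks(
    tooth_meshes: list, roles: tuple | None = None, up: np.ndarray | None = None
) -> ArchLandmarks:
    """One landmark per crown: the (buccal) apex vertex.

    Height is measured along ``up`` (default: the cast-intrinsic crown-side
    axis from :func:`occlusal_up_axis`, so the result is invariant to rigid
    motion).  Per tooth, candidate apices are the locally height-maximal
    vertices within 0.3 mm of the crown top; among candidates the buccal
    one -- farthest from the arch-interior axis through the centroid of all
    crown centroids -- is kept.  Landmarks are ordered along the arch by a
    greedy nearest-neighbour walk between the two mutually farthest crowns.
    """
    if not tooth_meshes:
        raise ExtractionError("no tooth meshes supplied")
    if up is None:
        up = occlusal_up_axis(tooth_meshes)
    up = np.asarray(up, float)
    up = up / np.linalg.norm(up)
    inner = np.mean([t.vertices.mean(axis=0) for t in tooth_meshes], axis=0)
    apices = []
    for tooth in tooth_meshes:
        z = tooth.vertices @ up
        zmax = z.max()
        cand = _local_height_maxima(tooth, up)
        cand = cand[z[cand] >= zmax - 0.3] if len(cand) else cand
        if len(cand) == 0:
            # plateau apex: every top vertex ties; fall back to top vertices
            cand = np.flatnonzero(z >= zmax - 1e-9)
            if len(cand) == 0:
                raise ExtractionError("tooth with no local height maximum")
        pts = tooth.vertices[cand]
        rel = pts - inner
        rel_t = rel - np.outer(rel @ up, up)  # in-plane offset from arch interior
        apices.append(pts[int(np.argmax(np.linalg.norm(rel_t, axis=1)))])
    apices = np.asarray(apices)
    order = _arch_order(apices, up)
    roles = tuple(roles[i] for i in order) if roles else _default_roles(len(apices))
    labels = tuple(f"T{i + 1}" for i in range(len(apices)))
    return ArchLandmarks(points=apices[order], roles=roles, tooth_labels=labels)


def _arch_order(points: np.ndarray, up: np.ndarray) -> list:
    """Order points along the arch by angle about their centroid.

    Points are projected onto the plane perpendicular to ``up``; the arch
    is a horseshoe, so sorting by angle and cutting the sequence at the
    largest angular gap (the open lingual side) walks the arch end to end.
    Rotation-invariant; the walk direction is resolved later by the frame.
    """
    n = len(points)
    if n <= 2:
        return list(range(n))
    rel = points - points.mean(axis=0)
    rel = rel - np.outer(rel @ up, up)
    b1 = np.cross(up, [1.0, 0.0, 0.0])
    if np.linalg.norm(b1) < 1e-6:
        b1 = np.cross(up, [0.0, 1.0, 0.0])
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(up, b1)
    ang = np.arctan2(rel @ b2, rel @ b1)
    order = np.argsort(ang)
    gaps = np.diff(np.concatenate([ang[order], [ang[order[0]] + 2 * np.pi]]))
    cut = int(np.argmax(gaps)) + 1
    return list(np.roll(order, -cut))


def _default_roles(n: int) -> tuple:
    # distal -> mesial -> distal: molars/premolars, canines, incisors
    n_incisor = max(2, n - 2 * (n // 3) - 2)
    n_side = (n - n_incisor) // 2
    half = ["buccal_cusp"] * (n_side - 1) + ["cusp_tip"]
    roles = half + ["incisal_edge"] * (n - 2 * n_side) + half[::-1]
    return tuple(roles[:n])


# ---------------------------------------------------------------------------
# soft-tissue layering
# ---------------------------------------------------------------------------


def cross_section(mesh: DentalMesh, z: float) -> np.ndarray | None:
    """Ordered occlusal-plane projection of the mesh section at height z.

    Intersects every triangle with the plane z = const and chains the
    resulting segments into polylines; the longest polyline (the buccal arc)
    is returned as (k, 2) XY points ordered by increasing x.  The plane is
    nudged by 1e-9 mm when it would pass exactly through vertices, keeping
    the section deterministic.  Returns ``None`` for an empty section.
    """
    v, f = mesh.vertices, mesh.faces
    zc = float(z)
    scale = max(1.0, np.abs(v[:, 2]).max())
    while np.any(np.abs(v[:, 2] - zc) < 1e-12 * scale):
        zc += 1e-9 * scale
    below = v[:, 2] < zc
    fb = below[f]
    mixed = fb.any(axis=1) & ~fb.all(axis=1)
    if not mixed.any():
        return None
    segments = []  # (edge_key_a, edge_key_b, pt_a, pt_b)
    for face in f[mixed]:
        pts, keys = [], []
        for a, b in ((face[0], face[1]), (face[1], face[2]), (face[2], face[0])):
            za, zb = v[a, 2], v[b, 2]
            if (za < zc) != (zb < zc):
                t = (zc - za) / (zb - za)
                p = v[a] + t * (v[b] - v[a])
                pts.append(p[:2])
                keys.append((min(a, b), max(a, b)))
        if len(pts) == 2:
            segments.append((keys[0], keys[1], pts[0], pts[1]))
    if not segments:
        return None
    # chain segments that share an edge key
    by_key = defaultdict(list)
    for i, (ka, kb, _, _) in enumerate(segments):
        by_key[ka].append(i)
        by_key[kb].append(i)
    used = np.zeros(len(segments), dtype=bool)
    chains = []
    for i0 in range(len(segments)):
        if used[i0]:
            continue
        chain = [segments[i0][0], segments[i0][1]]
        used[i0] = True
        for end in (0, 1):
            key = chain[-1] if end == 0 else chain[0]
            while True:
                nxt = [j for j in by_key[key] if not used[j]]
                if not nxt:
                    break
                j = nxt[0]
                ka, kb, _, _ = segments[j]
                key = kb if ka == key else ka
                used[j] = True
                if end == 0:
                    chain.append(key)
                else:
                    chain.insert(0, key)
        chains.append(chain)
    key_pts = {}
    for ka, kb, pa, pb in segments:
        key_pts[ka] = pa
        key_pts[kb] = pb
    best = max(chains, key=len)
    pts = np.asarray([key_pts[k] for k in best])
    if len(pts) >= 2 and pts[0, 0] > pts[-1, 0]:
        pts = pts[::-1]
    return pts


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample an ordered polyline to n points uniform in arc length."""
    pts = np.asarray(points, float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    if s[-1] <= 0:
        return np.repeat(pts[:1], n, axis=0)
    t = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(t, s, pts[:, k]) for k in range(pts.shape[1])])


def smoothness_score(polyline: np.ndarray) -> float:
    """Standard deviation of the first differences of a polyline.

    Differences are taken on consecutive 2D points and reduced to their
    magnitudes; on a uniformly arc-length-resampled polyline the score is 0
    for straight segments and circles and grows with corner points.
    """
    pts = np.atleast_2d(np.asarray(polyline, float))
    if len(pts) < 3:
        raise ExtractionError("smoothness score needs at least 3 points")
    mags = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return float(np.std(mags))


def layer_soft_tissue(
    soft_tissue: DentalMesh,
    n_layers: int = 10,
    top: float | None = None,
    bottom: float | None = None,
    resample_n: int = 200,
) -> LayeredContours:
    """Slice the soft tissue into n horizontal layers and project them.

    Layer heights are evenly spaced strictly between the gingival-margin
    height (``top``, default: highest soft-tissue z) and the mucosal base
    (``bottom``, default: lowest z): z_i = top - i*(top-bottom)/(n+1),
    i = 1..n, ordered from the margin downward.  Empty cross-sections are
    marked invalid and excluded from LiLo selection.
    """
    if n_layers < 2:
        raise ExtractionError("need at least 2 layers")
    z = soft_tissue.vertices[:, 2]
    top = float(z.max()) if top is None else float(top)
    bottom = float(z.min()) if bottom is None else float(bottom)
    if not top > bottom:
        raise ExtractionError("soft tissue must span a positive z-range")
    step = (top - bottom) / (n_layers + 1)
    heights = top - step * np.arange(1, n_layers + 1)
    raw_layers, layers, smooth, valid = [], [], [], []
    for h in heights:
        raw = cross_section(soft_tissue, h)
        if raw is None or len(raw) < 3:
            raw_layers.append(None)
            layers.append(None)
            smooth.append(np.inf)
            valid.append(False)
            continue
        res = resample_polyline(raw, resample_n)
        raw_layers.append(raw)
        layers.append(res)
        smooth.append(smoothness_score(res))
        valid.append(True)
    return LayeredContours(
        heights=heights,
        raw_layers=raw_layers,
        layers=layers,
        smoothness=np.asarray(smooth),
        valid=np.asarray(valid),
    )


def select_lilo(contours: LayeredContours) -> int:
    """Index of the smoothest valid layer (the LiLo curve).

    Ties are broken toward the more apical (lower) layer, i.e. the larger
    index since layers are ordered from the gingival margin downward.
    """
    if not contours.valid.any():
        raise ExtractionError("no valid soft-tissue layers")
    best, best_score = None, np.inf
    for i in range(contours.n_layers):
        if contours.valid[i] and contours.smoothness[i] <= best_score:
            best, best_score = i, contours.smoothness[i]
    return int(best)


# ---------------------------------------------------------------------------
# polynomial fitting
# ---------------------------------------------------------------------------


def fit_arch_polynomial(points: np.ndarray, source: str = "dental") -> ArchCurve:
    """Least-squares degree-6 fit of y on x for an ordered 2D arch curve.

    x is centred and scaled internally to control conditioning; coefficients
    are reported in the original occlusal frame.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    x, y = pts[:, 0], pts[:, 1]
    if len(np.unique(x)) < 7:
        raise ExtractionError("degree-6 fit needs at least 7 distinct x values")
    fit = Polynomial.fit(x, y, 6)
    xm = (x - fit.domain.mean()) / (np.ptp(fit.domain) / 2)
    cond = np.linalg.cond(np.vander(xm, 7))
    if cond > 1e12:
        raise ExtractionError(
            f"near-singular design (cond={cond:.2e}); recenter or spread the x values"
        )
    coef = fit.convert().coef
    coef = np.pad(coef, (0, 7 - len(coef)))
    rms = float(np.sqrt(np.mean((fit(x) - y) ** 2)))
    return ArchCurve(
        coefficients=coef,
        domain=(float(x.min()), float(x.max())),
        source=source,
        rms_residual=rms,
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def extract_arch_forms(
    mesh: DentalMesh,
    n_layers: int = 10,
    incisor_contact: np.ndarray | None = None,
    resample_n: int = 200,
    barrier_angle: float = 40.0,
) -> ExtractionResult:
    """Run the full geometric pipeline on one cast.

    Steps: tooth segmentation; landmark identification; occlusal plane fit
    through the three most distal cusp landmarks on each side; frame
    construction (incisor contact defaults to the midpoint of the two most
    anterior landmarks); dental degree-6 fit through the framed landmarks;
    soft-tissue layering between the segmentation-boundary height and the
    mucosal base; LiLo selection; dentoalveolar degree-6 fit on the raw LiLo
    section points.
    """
    seg = segment_teeth(mesh, barrier_angle=barrier_angle)
    if len(seg.teeth) < 7:
        raise ExtractionError(
            f"only {len(seg.teeth)} crowns segmented; need at least 7 for the arch fit"
        )
    up = occlusal_up_axis(seg.teeth, below=seg.remainder.vertices.mean(axis=0))
    lm = identify_landmarks(seg.teeth, up=up)
    pts = lm.points
    n = len(pts)
    posterior = np.vstack([pts[:3], pts[-3:]])
    plane = fit_occlusal_plane(posterior, below=seg.remainder.vertices.mean(axis=0))
    if incisor_contact is None:
        mid = n // 2
        incisor_contact = (pts[mid - 1] + pts[mid]) / 2.0
    frame = build_occlusal_frame(plane, incisor_contact, pts[0], pts[-1])
    fpts = frame.transform(pts)
    order = np.argsort(fpts[:, 0])
    lm_framed = ArchLandmarks(
        points=fpts[order],
        roles=tuple(lm.roles[i] for i in order),
        tooth_labels=tuple(lm.tooth_labels[i] for i in order),
    )
    dental_curve = fit_arch_polynomial(lm_framed.points[:, :2], source="dental")
    soft = DentalMesh(
        vertices=frame.transform(seg.remainder.vertices),
        faces=seg.remainder.faces,
        jaw=mesh.jaw,
    )
    # gingival margin: framed z of the segmentation boundary contour (its most
    # apical point, below any festooning); boundary_z is world z, so recompute
    tooth_mask = seg.vertex_labels >= 0
    adj = _vertex_adjacency(mesh.faces, mesh.n_vertices)
    near_tooth = np.asarray(adj[:, tooth_mask].sum(axis=1)).ravel() > 0
    bverts = (~tooth_mask) & near_tooth
    framed_all = frame.transform(mesh.vertices)
    margin_z = float(framed_all[bverts, 2].min()) if bverts.any() else float(soft.vertices[:, 2].max())
    contours = layer_soft_tissue(soft, n_layers=n_layers, top=margin_z, resample_n=resample_n)
    lilo = select_lilo(contours)
    dentoalveolar_curve = fit_arch_polynomial(contours.raw_layers[lilo], source="dentoalveolar")
    return ExtractionResult(
        frame=frame,
        landmarks=lm_framed,
        dental_curve=dental_curve,
        contours=contours,
        lilo_index=lilo,
        dentoalveolar_curve=dentoalveolar_curve,
        margin_z=margin_z,
        segmentation=seg,
    )
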