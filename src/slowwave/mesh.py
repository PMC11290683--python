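"""Cortical sheet geometry: icosphere meshes, geodesics, parcels, hierarchy.

The cortical sheet is modeled as a triangulated sphere (one hemisphere of
cortex, inflated to a sphere, has spherical topology; the medial wall is a
masked cap of that sphere rather than a hole).  One cortical column sits at
every vertex.  Recursive icosahedral subdivision at level ``L`` yields
``10 * 4**L + 2`` vertices: 12 at level 0, 642 at level 3, 10,242 at level 5.

Geodesic distances are exact great-circle arcs for the built-in spherical
meshes; user-supplied non-spherical meshes fall back to heat-method geodesics
computed with sparse linear solves.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import trimesh

__all__ = [
    "HemisphereMesh",
    "build_icosphere",
    "geodesic_distances",
    "assign_parcels",
    "assign_hierarchy",
    "vertex_adjacency",
    "neighbor_rings",
    "save_mesh",
    "load_mesh",
    "save_column_table",
    "load_column_table",
]

#: Fraction of vertices masked as medial wall by default.  Chosen so that an
#: ico5 sphere (10,242 vertices) masks exactly 870 vertices, leaving 9,372
#: active columns.
DEFAULT_MEDIAL_WALL_FRACTION = 870.0 / 10242.0

#: Hemisphere extent: maximum geodesic distance between columns, in mm.
DEFAULT_MAX_GEODESIC_MM = 226.1


@dataclasses.dataclass
class HemisphereMesh:
    """A triangulated cortical sheet with per-column annotations.

    Attributes
    ----------
    vertices : (N, 3) float array, mm
        Column positions.
    faces : (F, 3) int array
        Triangles indexing into ``vertices``.
    subdivision_level : int or None
        Icosphere subdivision level, if built by :func:`build_icosphere`.
    medial_wall : (N,) bool array
        True for masked (non-cortical) columns.
    parcel_label : (N,) int array
        Parcel id in ``[0, n_parcels)`` for active columns, −1 elsewhere.
    hierarchy_index : (n_parcels,) float array or None
        Per-parcel hierarchy index in [0, 1]; higher = lower myelination.
    sphere_radius : float or None
        If the mesh is a sphere centred at the origin, its radius (enables
        exact geodesics).
    """

    vertices: np.ndarray
    faces: np.ndarray
    subdivision_level: int | None = None
    medial_wall: np.ndarray | None = None
    parcel_label: np.ndarray | None = None
    hierarchy_index: np.ndarray | None = None
    sphere_radius: float | None = None
    #: True for planar sheets (geodesic = Euclidean in-plane distance)
    is_flat: bool = False

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        n = len(self.vertices)
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= n):
            raise ValueError("faces reference invalid vertex indices")
        if self.medial_wall is None:
            self.medial_wall = np.zeros(n, dtype=bool)
        else:
            self.medial_wall = np.asarray(self.medial_wall, dtype=bool)
        if self.parcel_label is None:
            self.parcel_label = np.full(n, -1, dtype=np.int64)
        else:
            self.parcel_label = np.asarray(self.parcel_label, dtype=np.int64)

    @property
    def n_columns(self) -> int:
        return len(self.vertices)

    @property
    def active(self) -> np.ndarray:
        """Boolean mask of non-medial-wall columns."""
        return ~self.medial_wall

    @property
    def n_parcels(self) -> int:
        lab = self.parcel_label[self.active]
        return int(lab.max()) + 1 if lab.size and lab.max() >= 0 else 0

    def parcel_members(self, parcel: int) -> np.ndarray:
        return np.flatnonzero(self.parcel_label == parcel)


def build_icosphere(
    level: int,
    target_max_geodesic_mm: float = DEFAULT_MAX_GEODESIC_MM,
    medial_wall_fraction: float = DEFAULT_MEDIAL_WALL_FRACTION,
    medial_wall_axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> HemisphereMesh:
    """Build a spherical cortical sheet by icosahedral subdivision.

    The sphere is scaled so that the maximum geodesic (great-circle) distance
    between columns equals ``target_max_geodesic_mm``.  A cap of
    ``medial_wall_fraction`` of the vertices around ``medial_wall_axis`` is
    masked as medial wall; masked columns carry no parcels and are excluded
    from all analyses, but remain part of the surface for distance purposes.
    """
    if level < 0:
        raise ValueError(f"subdivision level must be >= 0, got {level}")
    if target_max_geodesic_mm <= 0:
        raise ValueError("target_max_geodesic_mm must be positive")
    radius = target_max_geodesic_mm / np.pi
    ico = trimesh.creation.icosphere(subdivisions=level, radius=1.0)
    verts = np.asarray(ico.vertices, dtype=np.float64)
    # re-project exactly to the unit sphere, then scale
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    n = len(verts)
    expected = 10 * 4**level + 2
    if n != expected:  # pragma: no cover - guards against trimesh changes
        raise RuntimeError(f"icosphere level {level}: got {n} vertices, expected {expected}")

    axis = np.asarray(medial_wall_axis, dtype=np.float64)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("medial_wall_axis must be non-zero")
    axis = axis / nrm
    n_wall = int(round(medial_wall_fraction * n))
    wall = np.zeros(n, dtype=bool)
    if n_wall > 0:
        # the n_wall vertices closest (in angle) to the axis form the cap
        order = np.argsort(-(verts @ axis), kind="stable")
        wall[order[:n_wall]] = True

    return HemisphereMesh(
        vertices=verts * radius,
        faces=np.asarray(ico.faces, dtype=np.int64),
        subdivision_level=level,
        medial_wall=wall,
        sphere_radius=radius,
    )


# ---------------------------------------------------------------------------
# geodesic distances
# ---------------------------------------------------------------------------

def vertex_adjacency(mesh: HemisphereMesh) -> sp.csr_matrix:
    """Sparse symmetric vertex adjacency (1 where an edge connects vertices)."""
    f = mesh.faces
    e = np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    i = np.concatenate([e[:, 0], e[:, 1]])
    j = np.concatenate([e[:, 1], e[:, 0]])
    a = sp.csr_matrix((np.ones(len(i)), (i, j)), shape=(mesh.n_columns,) * 2)
    a.data[:] = 1.0
    return a


def _check_connected(mesh: HemisphereMesh) -> None:
    n_comp, labels = sp.csgraph.connected_components(vertex_adjacency(mesh), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        orphan = int(np.argmin(sizes))
        members = np.flatnonzero(labels == orphan)[:5]
        raise ValueError(
            f"mesh is disconnected ({n_comp} components); smallest component "
            f"contains vertices {members.tolist()}..."
        )


def geodesic_distances(
    mesh: HemisphereMesh, sources: np.ndarray | None = None
) -> np.ndarray:
    """Geodesic distances from ``sources`` (default: all vertices) to all vertices.

    Exact great-circle arcs for spherical meshes; heat-method geodesics for
    general meshes.  Returned array has shape ``(len(sources), n_columns)``.
    When computed densely the matrix is symmetrized.
    """
    if sources is None:
        src = np.arange(mesh.n_columns)
    else:
        src = np.atleast_1d(np.asarray(sources, dtype=np.int64))
        if src.size == 0:
            raise ValueError("sources must be non-empty")
    _check_connected(mesh)
    if mesh.is_flat:
        diff = mesh.vertices[src][:, None, :] - mesh.vertices[None, :, :]
        d = np.linalg.norm(diff, axis=-1)
    elif mesh.sphere_radius is not None:
        r = mesh.sphere_radius
        unit = mesh.vertices / r
        cosang = np.clip(unit[src] @ unit.T, -1.0, 1.0)
        d = r * np.arccos(cosang)
    else:
        solver = _HeatGeodesics(mesh)
        d = np.vstack([solver.distance_from(s) for s in src])
    if sources is None:
        d = 0.5 * (d + d.T)
        np.fill_diagonal(d, 0.0)
    else:
        d[np.arange(len(src)), src] = 0.0
    return d


class _HeatGeodesics:
    """Heat-method geodesic distances on a triangle mesh.

    Diffuses heat for a short time from the source, normalizes the gradient
    field to unit vectors, and recovers distance from a Poisson solve.
    Accuracy on well-shaped meshes is well under the few-percent level needed
    for connectivity kernels.
    """

    def __init__(self, mesh: HemisphereMesh):
        v, f = mesh.vertices, mesh.faces
        n = len(v)
        self.v, self.f = v, f
        e01 = v[f[:, 1]] - v[f[:, 0]]
        e02 = v[f[:, 2]] - v[f[:, 0]]
        fn = np.cross(e01, e02)
        dbl_area = np.linalg.norm(fn, axis=1)
        self.face_normal = fn / dbl_area[:, None]
        self.face_area = 0.5 * dbl_area

        # cotangent Laplacian
        ii, jj, vv = [], [], []
        for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            u = v[f[:, b]] - v[f[:, a]]
            w = v[f[:, c]] - v[f[:, a]]
            cot = np.einsum("ij,ij->i", u, w) / np.linalg.norm(np.cross(u, w), axis=1)
            ii.extend([f[:, b], f[:, c]])
            jj.extend([f[:, c], f[:, b]])
            vv.extend([0.5 * cot, 0.5 * cot])
        W = sp.csr_matrix((np.concatenate(vv), (np.concatenate(ii), np.concatenate(jj))), shape=(n, n))
        L = sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W
        mass = np.zeros(n)
        np.add.at(mass, f.ravel(), np.repeat(self.face_area / 3.0, 3))
        self.mass = mass

        h = np.mean(np.linalg.norm(e01, axis=1)) ** 2
        eps = 1e-10 * sp.eye(n)
        self._heat = spla.factorized((sp.diags(mass) + h * L + eps).tocsc())
        self._poisson = spla.factorized((L + eps).tocsc())
        self._L = L

    def distance_from(self, source: int) -> np.ndarray:
        n = len(self.v)
        u0 = np.zeros(n)
        u0[source] = 1.0
        u = self._heat(self.mass * u0)
        f, v = self.f, self.v
        # per-face gradient of u
        grad = np.zeros((len(f), 3))
        for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            edge = v[f[:, c]] - v[f[:, b]]
            grad += u[f[:, a], None] * np.cross(self.face_normal, edge)
        grad /= 2.0 * self.face_area[:, None]
        nrm = np.linalg.norm(grad, axis=1)
        nrm[nrm == 0] = 1.0
        X = -grad / nrm[:, None]
        # integrated divergence
        div = np.zeros(n)
        for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            e1 = v[f[:, b]] - v[f[:, a]]
            e2 = v[f[:, c]] - v[f[:, a]]
            eo = v[f[:, c]] - v[f[:, b]]
            cot1 = np.einsum("ij,ij->i", e2, eo) / np.linalg.norm(np.cross(e2, eo), axis=1)
            cot2 = -np.einsum("ij,ij->i", e1, eo) / np.linalg.norm(np.cross(e1, eo), axis=1)
            np.add.at(
                div,
                f[:, a],
                0.5 * (cot1 * np.einsum("ij,ij->i", e1, X) + cot2 * np.einsum("ij,ij->i", e2, X)),
            )
        phi = self._poisson(div)
        phi -= phi[source]
        return np.abs(phi)


def neighbor_rings(mesh: HemisphereMesh, max_order: int = 2) -> list[np.ndarray]:
    """Per-vertex neighbor indices up to ``max_order`` mesh-adjacency hops.

    Returns a list of arrays; entry ``i`` holds the vertices whose hop
    distance from ``i`` is in ``[1, max_order]`` (vertex ``i`` excluded).
    """
    adj = vertex_adjacency(mesh)
    reach = sp.eye(mesh.n_columns, format="csr")
    acc = sp.csr_matrix(reach.shape)
    for _ in range(max_order):
        reach = (reach @ adj).sign()
        acc = (acc + reach).sign()
    acc = acc.tolil()
    acc.setdiag(0)
    acc = acc.tocsr()
    return [acc.indices[acc.indptr[i]:acc.indptr[i + 1]] for i in range(mesh.n_columns)]


# ---------------------------------------------------------------------------
# parcels and hierarchy
# ---------------------------------------------------------------------------

def assign_parcels(
    mesh: HemisphereMesh,
    n_parcels: int = 180,
    seed: int = 0,
    n_lloyd: int = 8,
) -> HemisphereMesh:
    """Partition active columns into spatially contiguous, equal-area parcels.

    Furthest-point seeding followed by geodesic Lloyd iterations (k-means on
    the surface, with parcel centroids snapped back to member vertices).  The
    result is deterministic for a given seed.
    """
    if n_parcels <= 0:
        raise ValueError("n_parcels must be positive")
    active = np.flatnonzero(mesh.active)
    if n_parcels > active.size:
        raise ValueError(f"n_parcels={n_parcels} exceeds {active.size} active columns")

    labels = np.full(mesh.n_columns, -1, dtype=np.int64)
    if n_parcels == active.size:
        labels[active] = np.arange(n_parcels)
        return dataclasses.replace(mesh, parcel_label=labels)

    rng = np.random.default_rng(seed)
    # furthest-point seeding over active vertices
    first = active[rng.integers(active.size)]
    centroids = [first]
    d_to_set = geodesic_distances(mesh, np.array([first]))[0][active]
    for _ in range(1, n_parcels):
        nxt = active[int(np.argmax(d_to_set))]
        centroids.append(nxt)
        d_new = geodesic_distances(mesh, np.array([nxt]))[0][active]
        d_to_set = np.minimum(d_to_set, d_new)
    centroids = np.array(centroids)

    for _ in range(n_lloyd):
        dmat = geodesic_distances(mesh, centroids)[:, active]  # (K, n_active)
        assign = np.argmin(dmat, axis=0)
        new_centroids = centroids.copy()
        for k in range(n_parcels):
            members = active[assign == k]
            if members.size == 0:
                # reseed empty parcel at the vertex worst-served by others
                worst = active[int(np.argmax(np.min(dmat, axis=0)))]
                new_centroids[k] = worst
                continue
            mean_pos = mesh.vertices[members].mean(axis=0)
            new_centroids[k] = members[
                int(np.argmin(np.linalg.norm(mesh.vertices[members] - mean_pos, axis=1)))
            ]
        if np.array_equal(new_centroids, centroids):
            break
        centroids = new_centroids

    dmat = geodesic_distances(mesh, centroids)[:, active]
    labels[active] = np.argmin(dmat, axis=0)
    labels = _fix_contiguity(mesh, labels)
    return dataclasses.replace(mesh, parcel_label=labels)


def _fix_contiguity(mesh: HemisphereMesh, labels: np.ndarray) -> np.ndarray:
    """Reassign stray parcel fragments to the dominant neighboring parcel."""
    adj = vertex_adjacency(mesh)
    labels = labels.copy()
    for _ in range(10):
        changed = False
        for k in range(labels.max() + 1):
            members = np.flatnonzero(labels == k)
            if members.size == 0:
                continue
            sub = adj[members][:, members]
            n_comp, comp = sp.csgraph.connected_components(sub, directed=False)
            if n_comp == 1:
                continue
            sizes = np.bincount(comp)
            keep = int(np.argmax(sizes))
            for c in range(n_comp):
                if c == keep:
                    continue
                frag = members[comp == c]
                for v in frag:
                    nbrs = adj.indices[adj.indptr[v]:adj.indptr[v + 1]]
                    nbr_labels = labels[nbrs]
                    nbr_labels = nbr_labels[(nbr_labels >= 0) & (nbr_labels != k)]
                    if nbr_labels.size:
                        labels[v] = np.bincount(nbr_labels).argmax()
                        changed = True
        if not changed:
            break
    return labels


def parcel_centroids(mesh: HemisphereMesh) -> np.ndarray:
    """(n_parcels, 3) Euclidean mean position of each parcel's columns."""
    k = mesh.n_parcels
    out = np.zeros((k, 3))
    for p in range(k):
        out[p] = mesh.vertices[mesh.parcel_members(p)].mean(axis=0)
    return out


def assign_hierarchy(
    mesh: HemisphereMesh,
    gradient_axis: tuple[float, float, float] = (0.0, 1.0, 0.0),
    table: np.ndarray | None = None,
) -> HemisphereMesh:
    """Assign a per-parcel hierarchy index in [0, 1].

    By default a smooth myelination-like surrogate: the normalized projection
    of each parcel centroid onto ``gradient_axis`` (higher projection = higher
    hierarchy = lower myelination).  A user-supplied per-parcel ``table`` is
    stored verbatim instead.
    """
    k = mesh.n_parcels
    if k == 0:
        raise ValueError("parcels must be assigned before hierarchy")
    if table is not None:
        table = np.asarray(table, dtype=np.float64)
        if table.shape != (k,):
            raise ValueError(f"hierarchy table must have shape ({k},)")
        if not np.all(np.isfinite(table)):
            raise ValueError("hierarchy table must be finite")
        return dataclasses.replace(mesh, hierarchy_index=table)
    axis = np.asarray(gradient_axis, dtype=np.float64)
    nrm = np.linalg.norm(axis)
    if nrm == 0:
        raise ValueError("gradient_axis must be non-zero")
    proj = parcel_centroids(mesh) @ (axis / nrm)
    lo, hi = proj.min(), proj.max()
    h = np.zeros(k) if hi == lo else (proj - lo) / (hi - lo)
    return dataclasses.replace(mesh, hierarchy_index=h)


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def save_mesh(mesh: HemisphereMesh, path: str | Path) -> None:
    """Write the surface as plain-text OFF; annotations go to sibling TSVs."""
    path = Path(path)
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
    data = tm.export(file_type="off")
    path.write_bytes(data.encode() if isinstance(data, str) else data)
    save_column_table(mesh, path.with_suffix(".columns.tsv"))


def load_mesh(path: str | Path, sphere_radius: float | None = None) -> HemisphereMesh:
    path = Path(path)
    tm = trimesh.load(str(path), file_type=path.suffix.lstrip("."), process=False)
    mesh = HemisphereMesh(
        vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces), sphere_radius=sphere_radius
    )
    tsv = path.with_suffix(".columns.tsv")
    if tsv.exists():
        mesh = load_column_table(mesh, tsv)
    return mesh


def save_column_table(mesh: HemisphereMesh, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "column_id": np.arange(mesh.n_columns),
            "medial_wall": mesh.medial_wall.astype(int),
            "parcel_label": mesh.parcel_label,
        }
    )
    if mesh.hierarchy_index is not None:
        hi = np.full(mesh.n_columns, np.nan)
        ok = mesh.parcel_label >= 0
        hi[ok] = mesh.hierarchy_index[mesh.parcel_label[ok]]
        df["hierarchy_index"] = hi
    df.to_csv(path, sep="\t", index=False)


def load_column_table(mesh: HemisphereMesh, path: str | Path) -> HemisphereMesh:
    df = pd.read_csv(path, sep="\t").set_index("column_id").sort_index()
    wall = df["medial_wall"].to_numpy().astype(bool)
    labels = df["parcel_label"].to_numpy().astype(np.int64)
    hierarchy = None
    if "hierarchy_index" in df:
        k = labels.max() + 1
        hierarchy = np.zeros(k)
        for p in range(k):
            vals = df["hierarchy_index"].to_numpy()[labels == p]
            hierarchy[p] = vals[0] if vals.size else np.nan
    return dataclasses.replace(
        mesh, medial_wall=wall, parcel_label=labels, hierarchy_index=hierarchy
    )
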