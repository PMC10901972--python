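"""Point-cloud construction from surface meshes.

A mesh is converted to the network input in two stages: area-uniform
oversampling of the surface, then farthest-point sampling (FPS) down to a
fixed cloud size (8,192 points by default).  FPS greedily picks the point
farthest from the already-selected set, which spreads the sample evenly over
the surface.  Local neighborhoods for the set-abstraction layers are built
with a ball query (all points within a radius of a centroid, capped at
``max_k``).  Clouds round-trip through plain-text ``xyz`` files, one
whitespace-separated point per line.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

#: default cloud size fed to the classifier
DEFAULT_N_POINTS = 8192
#: raw surface samples drawn per requested FPS point
DEFAULT_OVERSAMPLE = 4


@dataclass
class PointCloud:
    """N x 3 coordinates in mm, or in unit-sphere units once normalized.

    ``norm_record`` keeps the (centroid, scale) pair applied by
    :func:`normalize` so risk reports can refer back to mm coordinates.
    """

    coords: np.ndarray
    normalized: bool = False
    provenance: str = ""
    norm_record: tuple | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if len(self.coords) < 1:
            raise ValueError("point cloud must contain at least one point")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class GroupIndex:
    """Ball-query result: per-centroid neighbor index lists.

    ``neighbor_lists`` is (K, max_k); lists shorter than ``max_k`` are padded
    by repeating their first entry, ``counts`` records the true sizes.
    """

    centroid_indices: np.ndarray
    neighbor_lists: np.ndarray
    counts: np.ndarray
    radius: float


def sample_surface(mesh: trimesh.Trimesh, n_raw: int, seed: int = 0) -> PointCloud:
    """Draw ``n_raw`` area-uniform points on the mesh surface.

    Deterministic for a given ``seed``.
    """
    if n_raw < 1:
        raise ValueError("n_raw must be >= 1")
    if len(mesh.faces) == 0:
        raise ValueError("cannot sample an empty mesh")
    pts, _ = trimesh.sample.sample_surface(mesh, n_raw, seed=int(seed))
    return PointCloud(np.asarray(pts, dtype=np.float64),
                      provenance=str(mesh.metadata.get("id", "")))


def fps(cloud: PointCloud | np.ndarray, k: int, start_index: int = 0) -> np.ndarray:
    """Greedy farthest-point sampling: indices of ``k`` max-min points.

    Each successive index maximizes the distance to the already-selected
    set; ties break toward the lowest index, so the selection is fully
    deterministic given ``start_index``.
    """
    coords = cloud.coords if isinstance(cloud, PointCloud) else np.asarray(coords_arg(cloud))
    n = len(coords)
    if not 1 <= k <= n:
        raise ValueError(f"k={k} must be in [1, {n}]")
    if not 0 <= start_index < n:
        raise ValueError("start_index out of range")
    selected = np.empty(k, dtype=np.intp)
    selected[0] = start_index
    # running min-distance to the selected set; argmax picks the first
    # (lowest-index) maximizer, which is the tie-break contract; selected
    # indices are marked ineligible so duplicate points are never re-picked
    dist = np.linalg.norm(coords - coords[start_index], axis=1)
    dist[start_index] = -1.0
    for i in range(1, k):
        nxt = int(np.argmax(dist))
        selected[i] = nxt
        np.minimum(dist, np.linalg.norm(coords - coords[nxt], axis=1), out=dist)
        dist[nxt] = -1.0
    return selected


def coords_arg(x) -> np.ndarray:
    a = np.asarray(x, dtype=np.float64)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("expected an (N, 3) array")
    return a


def mesh_to_cloud(mesh: trimesh.Trimesh,
                  n_points: int = DEFAULT_N_POINTS,
                  oversample: float = DEFAULT_OVERSAMPLE,
                  seed: int = 0,
                  start_index: int = 0) -> PointCloud:
    """Area-uniform oversampling followed by FPS to exactly ``n_points``."""
    n_raw = max(int(round(oversample * n_points)), n_points)
    raw = sample_surface(mesh, n_raw, seed=seed)
    idx = fps(raw, n_points, start_index=start_index)
    return PointCloud(raw.coords[idx], provenance=raw.provenance)


def normalize(cloud: PointCloud) -> PointCloud:
    """Center at the origin and scale so the farthest point has norm 1."""
    c = cloud.coords
    if len(c) < 2 or np.allclose(c, c[0]):
        raise ValueError("cannot normalize a degenerate (single-location) cloud")
    centroid = c.mean(axis=0)
    shifted = c - centroid
    scale = float(np.linalg.norm(shifted, axis=1).max())
    return PointCloud(shifted / scale, normalized=True,
                      provenance=cloud.provenance,
                      norm_record=(centroid.copy(), scale))


def denormalize(cloud: PointCloud) -> PointCloud:
    if not cloud.normalized or cloud.norm_record is None:
        raise ValueError("cloud carries no normalization record")
    centroid, scale = cloud.norm_record
    return PointCloud(cloud.coords * scale + centroid,
                      provenance=cloud.provenance)


def ball_query(cloud: PointCloud | np.ndarray,
               centroids: np.ndarray,
               radius: float,
               max_k: int,
               order: str = "index") -> GroupIndex:
    """All points within ``radius`` of each centroid, up to ``max_k``.

    ``order="index"`` returns ascending point indices (the serialization
    contract); ``order="distance"`` returns nearest-first (ties broken by
    lowest index), which makes the truncated neighborhood a function of the
    point set alone — the network layers use this so that shuffling the
    input points cannot change the grouped geometry.  Short lists are padded
    by repeating the first entry (the centroid itself always qualifies at
    distance zero, so lists are never empty).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if max_k < 1:
        raise ValueError("max_k must be >= 1")
    if order not in ("index", "distance"):
        raise ValueError("order must be 'index' or 'distance'")
    coords = cloud.coords if isinstance(cloud, PointCloud) else coords_arg(cloud)
    centroids = np.asarray(centroids, dtype=np.intp)
    if centroids.size and (centroids.min() < 0 or centroids.max() >= len(coords)):
        raise ValueError("centroid index out of range")
    tree = cKDTree(coords)
    hits = tree.query_ball_point(coords[centroids], r=radius)
    k = len(centroids)
    lists = np.empty((k, max_k), dtype=np.intp)
    counts = np.empty(k, dtype=np.intp)
    for row, (ci, h) in enumerate(zip(centroids, hits)):
        if not h:                       # numerically defensive; self always hits
            h = [int(ci)]
        if order == "distance":
            h = np.asarray(sorted(h))
            d = np.linalg.norm(coords[h] - coords[ci], axis=1)
            h = h[np.argsort(d, kind="stable")].tolist()
        else:
            h = sorted(h)
        h = h[:max_k]
        counts[row] = len(h)
        lists[row, :len(h)] = h
        lists[row, len(h):] = h[0]
    return GroupIndex(centroids, lists, counts, float(radius))


def write_txt(cloud: PointCloud, path) -> None:
    """One point per line: ``x y z`` with 8 significant digits."""
    np.savetxt(path, cloud.coords, fmt="%.8g", delimiter=" ")


def read_txt(path) -> PointCloud:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 coordinates, got {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no points found")
    return PointCloud(np.asarray(rows, dtype=np.float64), provenance=str(path))


def covering_radius(coords: np.ndarray, selected: np.ndarray) -> float:
    """Max distance from any point to its nearest selected point."""
    tree = cKDTree(np.asarray(coords)[np.asarray(selected, dtype=np.intp)])
    d, _ = tree.query(coords)
    return float(d.max())
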