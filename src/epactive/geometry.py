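"""Cardiac geometry: node clouds, k-NN graphs, graph Laplacians, lead fields.

The geometry is a discrete myocardium: a point cloud with a symmetric
k-nearest-neighbor adjacency whose weighted graph Laplacian stands in for
the diffusion operator of the reaction-diffusion model.  A synthetic
"fixture" generator produces an LV-like half-ellipsoidal shell with AHA
17-segment labels and an apex pacing site, so that every experiment can run
without patient data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree


@dataclass
class CardiacGeometry:
    """Discrete myocardium: nodes, symmetric k-NN graph, weighted Laplacian.

    Attributes
    ----------
    node_coords : (N, 3) float array, mm
    adjacency : sparse (N, N) symmetric 0/1 k-NN adjacency
    laplacian : sparse (N, N) weighted graph Laplacian (rows sum to zero)
    pacing_nodes : int array of stimulated node indices
    segment_labels : (N,) int array, AHA segment 1..17, or 0 for non-LV
    """

    node_coords: np.ndarray
    adjacency: sp.spmatrix
    laplacian: sp.spmatrix
    pacing_nodes: np.ndarray
    segment_labels: np.ndarray

    def __post_init__(self) -> None:
        self.node_coords = np.asarray(self.node_coords, dtype=float)
        self.pacing_nodes = np.asarray(self.pacing_nodes, dtype=np.int64)
        self.segment_labels = np.asarray(self.segment_labels, dtype=np.int64)
        n = self.n_nodes
        if self.adjacency.shape != (n, n) or self.laplacian.shape != (n, n):
            raise ValueError("adjacency/laplacian shape inconsistent with node count")
        if (self.adjacency != self.adjacency.T).nnz != 0:
            raise ValueError("neighbor graph must be symmetric")
        row_sums = np.asarray(self.laplacian.sum(axis=1)).ravel()
        if not np.allclose(row_sums, 0.0, atol=1e-9):
            raise ValueError("laplacian rows must sum to zero")
        if len(self.segment_labels) != n:
            raise ValueError("segment_labels length mismatch")

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency, directed=False)
        return n_comp == 1

    def laplacian_max_eig(self) -> float:
        """Largest Laplacian eigenvalue (for the explicit-Euler stability bound)."""
        lam = sp.linalg.eigsh(
            self.laplacian.astype(float), k=1, which="LA", return_eigenvectors=False
        )
        return float(lam[0])


@dataclass
class LeadField:
    """Linear transfer matrix from per-node potential to body-surface leads."""

    H: np.ndarray
    n_leads: int = 120

    def __post_init__(self) -> None:
        self.H = np.asarray(self.H, dtype=float)
        if not np.all(np.isfinite(self.H)):
            raise ValueError("lead-field matrix must be finite")
        if self.H.shape[0] != self.n_leads:
            raise ValueError("n_leads inconsistent with H")


def build_knn_graph(coords: np.ndarray, k: int = 6) -> tuple[sp.csr_matrix, sp.csr_matrix]:
    """Symmetric k-NN adjacency and inverse-square-distance weighted Laplacian.

    Edge weights are 1/d^2 rescaled so the mean weighted degree is 1, which
    keeps the Laplacian spectrum at an O(1) scale independent of the node
    spacing (diffusion strength is then set solely by ``d_iso``).
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    tree = cKDTree(coords)
    dist, idx = tree.query(coords, k=k + 1)
    rows = np.repeat(np.arange(n), k)
    cols = idx[:, 1:].ravel()
    adj = sp.coo_matrix((np.ones(n * k), (rows, cols)), shape=(n, n)).tocsr()
    adj = ((adj + adj.T) > 0).astype(np.int8).tocsr()

    ii, jj = adj.nonzero()
    d2 = np.sum((coords[ii] - coords[jj]) ** 2, axis=1)
    w = 1.0 / np.maximum(d2, 1e-12)
    W = sp.coo_matrix((w, (ii, jj)), shape=(n, n)).tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    W = W / deg.mean()
    deg = np.asarray(W.sum(axis=1)).ravel()
    lap = sp.diags(deg) - W
    return adj, lap.tocsr()


def _aha_segment_labels(coords: np.ndarray) -> np.ndarray:
    """Approximate AHA 17-segment labels for an LV-like shell.

    Long axis is z (apex at min z, base at max z).  Basal and mid thirds are
    split into circumferential sextants (segments 1-6, 7-12), the apical
    third into quadrants (13-16), and the apical cap (bottom 5% of the long
    axis) is segment 17.
    """
    z = coords[:, 2]
    zmin, zmax = z.min(), z.max()
    t = (z - zmin) / max(zmax - zmin, 1e-12)  # 0 apex .. 1 base
    phi = np.arctan2(coords[:, 1], coords[:, 0])  # (-pi, pi]

    labels = np.zeros(len(coords), dtype=np.int64)
    cap = t < 0.05
    apical = (~cap) & (t < 1.0 / 3.0)
    mid = (t >= 1.0 / 3.0) & (t < 2.0 / 3.0)
    basal = t >= 2.0 / 3.0

    sextant = np.floor((phi + np.pi) / (2 * np.pi) * 6).astype(int) % 6
    quadrant = np.floor((phi + np.pi) / (2 * np.pi) * 4).astype(int) % 4
    labels[basal] = 1 + sextant[basal]
    labels[mid] = 7 + sextant[mid]
    labels[apical] = 13 + quadrant[apical]
    labels[cap] = 17
    return labels


def make_fixture_geometry(
    n_nodes: int = 300,
    knn: int = 6,
    seed: int = 0,
    outer_radii: tuple[float, float, float] = (30.0, 30.0, 60.0),
    wall_thickness: float = 8.0,
) -> CardiacGeometry:
    """Generate a synthetic LV-like half-ellipsoidal shell geometry.

    Nodes are drawn uniformly in the shell between an outer (epicardial)
    and inner (endocardial) half-ellipsoid, apex pointing down (z < 0),
    truncated at the base plane z = 0.  The node nearest the apex is the
    pacing site.  Deterministic given ``seed``.
    """
    if n_nodes < 50:
        raise ValueError("fixture geometry requires at least 50 nodes")
    a, b, c = outer_radii
    ai, bi, ci = a - wall_thickness, b - wall_thickness, c - wall_thickness
    if min(ai, bi, ci) <= 0:
        raise ValueError("wall thickness incompatible with radii")
    rng = np.random.default_rng(seed)
    pts = []
    while len(pts) < n_nodes:
        cand = rng.uniform([-a, -b, -c], [a, b, 0.0], size=(4 * n_nodes, 3))
        r_out = (cand[:, 0] / a) ** 2 + (cand[:, 1] / b) ** 2 + (cand[:, 2] / c) ** 2
        r_in = (cand[:, 0] / ai) ** 2 + (cand[:, 1] / bi) ** 2 + (cand[:, 2] / ci) ** 2
        keep = (r_out <= 1.0) & (r_in >= 1.0)
        pts.extend(cand[keep])
    coords = np.array(pts[:n_nodes])
    adj, lap = build_knn_graph(coords, k=knn)
    labels = _aha_segment_labels(coords)
    # pacing region: apex node plus its graph neighbors (point stimuli are
    # drained by diffusion before they can trigger an upstroke)
    apex = int(np.argmin(coords[:, 2]))
    pacing = np.unique(np.concatenate([[apex], adj[apex].nonzero()[1]]))
    geom = CardiacGeometry(coords, adj, lap, pacing, labels)
    if not geom.is_connected():
        # densify the graph until connected; keeps the fixture usable at low N
        for k_try in range(knn + 2, knn + 20, 2):
            adj, lap = build_knn_graph(coords, k=k_try)
            pacing = np.unique(np.concatenate([[apex], adj[apex].nonzero()[1]]))
            geom = CardiacGeometry(coords, adj, lap, pacing, labels)
            if geom.is_connected():
                break
        else:
            raise RuntimeError("could not build a connected fixture graph")
    return geom


def build_synthetic_lead_field(
    geom: CardiacGeometry, n_leads: int = 120, seed: int = 0,
    radius_factor: float = 1.2, reference: bool = True,
) -> LeadField:
    """Synthetic torso transfer matrix from electrodes on an enclosing cylinder.

    Electrodes are placed on a cylinder enclosing the node cloud (jittered
    rings); each row of H is the inverse squared electrode-to-node
    distance, normalized to sum to one, and then referenced against the
    average lead (Wilson-central-terminal style).  Referencing removes the
    rank-one common mode that otherwise dominates far-field rows and
    leaves the spatial contrasts that make the ECG informative about
    *where* tissue is abnormal.  Scale-invariant by construction: scaling
    all distances by a common factor leaves H unchanged.
    """
    if n_leads < 1:
        raise ValueError("need at least one lead")
    rng = np.random.default_rng(seed)
    coords = geom.node_coords
    center = coords.mean(axis=0)
    extent = np.linalg.norm(coords - center, axis=1).max()
    radius = radius_factor * extent
    zlo = coords[:, 2].min() - 0.2 * extent
    zhi = coords[:, 2].max() + 0.2 * extent

    n_rings = max(1, int(np.ceil(n_leads / 12)))
    electrodes = []
    i = 0
    for ring in range(n_rings):
        zr = zlo + (zhi - zlo) * (ring + 0.5) / n_rings
        per_ring = min(12, n_leads - len(electrodes))
        for j_el in range(per_ring):
            phi = 2 * np.pi * j_el / per_ring + rng.uniform(0, 0.1)
            electrodes.append(
                [
                    center[0] + radius * np.cos(phi),
                    center[1] + radius * np.sin(phi),
                    zr + rng.uniform(-0.02, 0.02) * extent,  # scale-free jitter
                ]
            )
            i += 1
        if len(electrodes) >= n_leads:
            break
    electrodes = np.array(electrodes[:n_leads])

    d2 = np.sum((electrodes[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    while np.any(d2 < 1e-9 * extent**2):
        electrodes += rng.normal(scale=0.01 * extent, size=electrodes.shape)
        d2 = np.sum((electrodes[:, None, :] - coords[None, :, :]) ** 2, axis=2)
    H = 1.0 / d2
    H /= H.sum(axis=1, keepdims=True)
    if reference:
        H = H - H.mean(axis=0, keepdims=True)
    return LeadField(H=H, n_leads=n_leads)


def save_geometry(path: str, geom: CardiacGeometry) -> None:
    ii, jj = geom.adjacency.nonzero()
    with h5py.File(path, "w") as f:
        f.create_dataset("nodes", data=geom.node_coords)
        f.create_dataset("adjacency", data=np.column_stack([ii, jj]))
        f.create_dataset("segments", data=geom.segment_labels)
        f.create_dataset("pacing", data=geom.pacing_nodes)


def load_geometry(path: str) -> CardiacGeometry:
    with h5py.File(path, "r") as f:
        coords = f["nodes"][:]
        edges = f["adjacency"][:]
        segments = f["segments"][:]
        pacing = f["pacing"][:]
    n = coords.shape[0]
    adj = sp.coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n, n)
    ).tocsr()
    adj = ((adj + adj.T) > 0).astype(np.int8)
    ii, jj = adj.nonzero()
    d2 = np.sum((coords[ii] - coords[jj]) ** 2, axis=1)
    w = 1.0 / np.maximum(d2, 1e-12)
    W = sp.coo_matrix((w, (ii, jj)), shape=(n, n)).tocsr()
    W = W / np.asarray(W.sum(axis=1)).ravel().mean()
    lap = sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W
    return CardiacGeometry(coords, adj, lap.tocsr(), pacing, segments)


def load_node_cloud_csv(path: str, knn: int = 6) -> CardiacGeometry:
    """Import a plain x,y,z CSV as a geometry (no segments, no pacing)."""
    coords = np.loadtxt(path, delimiter=",", ndmin=2)
    if coords.shape[1] != 3:
        raise ValueError("node cloud CSV must have three columns (x,y,z)")
    adj, lap = build_knn_graph(coords, k=knn)
    labels = np.zeros(coords.shape[0], dtype=np.int64)
    return CardiacGeometry(coords, adj, lap, np.array([], dtype=np.int64), labels)
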