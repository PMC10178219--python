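"""Core computational geometry for pocket measurement.

The orthosteric pocket volume is defined over the Cα atoms of the ten
surrogate residues: the points are tessellated by Delaunay triangulation
and the simplex volumes are summed, which for a 3-D point set equals the
volume of the convex hull.  Also provided: pairwise Cα–Cα distances,
tetrahedron volume from its six edge lengths via the Cayley–Menger
determinant, and least-squares rigid superposition RMSD (Kabsch, proper
rotations only).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError
from scipy.spatial.distance import pdist

from .errors import DegenerateGeometryError, FormatError, NonRealizableError
from .numbering import GenericResidueID

__all__ = [
    "LabeledPointSet",
    "PairDistance",
    "pairwise_distances",
    "count_interhelix_pairs",
    "pocket_volume",
    "tetra_volume_from_edges",
    "superpose_rmsd",
]

#: rank-test tolerance (Å) below which a configuration counts as coplanar
COPLANAR_TOL = 1e-8


@dataclass(frozen=True)
class LabeledPointSet:
    """An ordered set of labeled 3-D points (labels unique, coords finite)."""

    labels: tuple
    coords: np.ndarray  # (n, 3) float array, Å

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise FormatError("coordinates must be an (n, 3) array")
        if coords.shape[0] != len(self.labels):
            raise FormatError("labels and coordinates differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise FormatError("point labels must be unique")
        if not np.all(np.isfinite(coords)):
            raise FormatError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @classmethod
    def from_resolved(cls, resolved: Sequence[tuple]) -> "LabeledPointSet":
        """Build from ``resolve()`` output: (id, pose_number, ca_xyz)."""
        labels = tuple(item[0] for item in resolved)
        coords = np.array([item[2] for item in resolved], dtype=float)
        return cls(labels, coords)

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class PairDistance:
    id_a: object
    id_b: object
    distance: float


def _canonical_pair(a, b):
    return (a, b) if _label_key(a) <= _label_key(b) else (b, a)


def _label_key(label):
    if isinstance(label, GenericResidueID):
        return (0, label.helix, label.bw, label.gpcrdb)
    return (1, str(label))


def pairwise_distances(pts: LabeledPointSet) -> list[PairDistance]:
    """All n(n−1)/2 unique Euclidean Cα–Cα distances, in Å.

    Each unordered pair is stored once with its labels in canonical
    order (generic-ID order for generic labels, lexicographic for text).
    """
    n = len(pts)
    if n < 2:
        raise FormatError("need at least 2 points for pairwise distances")
    dists = pdist(pts.coords)
    out: list[PairDistance] = []
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            a, b = _canonical_pair(pts.labels[i], pts.labels[j])
            out.append(PairDistance(a, b, float(dists[k])))
            k += 1
    return out


def count_interhelix_pairs(pairs: Sequence[PairDistance]) -> int:
    """Number of pairs whose two residues sit on different TM helices."""
    count = 0
    for p in pairs:
        if not (isinstance(p.id_a, GenericResidueID)
                and isinstance(p.id_b, GenericResidueID)):
            raise FormatError("inter-helix counting needs generic residue labels")
        if p.id_a.helix != p.id_b.helix:
            count += 1
    return count


def _check_rank(coords: np.ndarray) -> None:
    centered = coords - coords.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv.size < 3 or sv[2] <= COPLANAR_TOL:
        raise DegenerateGeometryError(
            "point configuration is (near-)coplanar; volume undefined"
        )


def pocket_volume(pts: LabeledPointSet) -> float:
    """Pocket volume in Å³: Delaunay tessellation, simplex volumes summed.

    Equals the convex-hull volume of the points.  Raises
    :class:`DegenerateGeometryError` for fewer than 4 points or a
    coplanar/collinear configuration rather than returning 0, so that
    degenerate inputs cannot leak into downstream volume filters.
    """
    coords = pts.coords
    if len(coords) < 4:
        raise DegenerateGeometryError("volume needs at least 4 points")
    _check_rank(coords)
    try:
        tess = Delaunay(coords)
    except QhullError as exc:  # pragma: no cover - rank test catches most
        raise DegenerateGeometryError(str(exc)) from exc
    simplices = coords[tess.simplices]  # (m, 4, 3)
    edges = simplices[:, 1:, :] - simplices[:, :1, :]  # (m, 3, 3)
    vols = np.abs(np.linalg.det(edges)) / 6.0
    return float(vols.sum())


def tetra_volume_from_edges(edges: Sequence[float]) -> float:
    """Tetrahedron volume from its 6 edge lengths (Cayley–Menger).

    Edge order is ``(d12, d13, d14, d23, d24, d34)`` for vertices
    1..4.  A zero or negative Cayley–Menger determinant means the edge
    set does not embed in 3-space and raises
    :class:`NonRealizableError`.
    """
    if len(edges) != 6:
        raise FormatError("exactly 6 edge lengths required")
    d12, d13, d14, d23, d24, d34 = (float(e) for e in edges)
    if min(d12, d13, d14, d23, d24, d34) <= 0:
        raise FormatError("edge lengths must be positive")
    sq = [x * x for x in (d12, d13, d14, d23, d24, d34)]
    q12, q13, q14, q23, q24, q34 = sq
    cm = np.array([
        [0, 1, 1, 1, 1],
        [1, 0, q12, q13, q14],
        [1, q12, 0, q23, q24],
        [1, q13, q23, 0, q34],
        [1, q14, q24, q34, 0],
    ], dtype=float)
    det = np.linalg.det(cm)
    # 288 V² = CM determinant for a 3-simplex; the threshold scales with
    # the determinant's natural magnitude so exactly-flat edge sets are
    # flagged despite floating-point noise
    tol = 1e-12 * max(1.0, float(np.mean(sq)) ** 3)
    if det <= tol:
        raise NonRealizableError(
            "edge lengths do not embed as a tetrahedron (CM determinant "
            f"= {det:.3g})"
        )
    return float(np.sqrt(det / 288.0))


def superpose_rmsd(a: LabeledPointSet, b: LabeledPointSet) -> float:
    """Least-squares rigid-superposition RMSD (Å) between two labeled sets.

    Points are matched by label (order-independent).  The optimal
    rotation is the Kabsch solution restricted to proper rotations
    (det = +1); reflections are never applied.
    """
    if set(a.labels) != set(b.labels):
        raise FormatError("point sets must carry identical labels")
    if len(a) < 3:
        raise DegenerateGeometryError("superposition needs at least 3 points")
    order = {lab: i for i, lab in enumerate(b.labels)}
    pa = a.coords
    pb = b.coords[[order[lab] for lab in a.labels]]
    ca = pa - pa.mean(axis=0)
    cb = pb - pb.mean(axis=0)
    sv = np.linalg.svd(ca, compute_uv=False)
    if sv[1] <= COPLANAR_TOL:
        raise DegenerateGeometryError("collinear configuration; rotation ill-defined")
    h = cb.T @ ca
    u, s, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.diag([1.0, 1.0, sign])
    rot = u @ d @ vt
    diff = ca - cb @ rot
    return float(np.sqrt((diff ** 2).sum() / len(ca)))
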