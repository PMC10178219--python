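"""Tetrahedral distance restraints for pocket-size control.

A restraint set consists of two tetrahedra spanning the orthosteric
pocket, each defined by four generic residue positions and the six
Cα–Cα distances between them.  Every edge becomes a Rosetta AtomPair
restraint with potential

    f(d) = A * ( ((d - C) / B)^2 + D )

where ``C`` is the reference distance (the knowledge-base median or a
template-structure measurement, inflated by a scale factor ``s``),
``A`` the weight, ``B`` the harmonic steepness and ``D`` a constant
negative offset.  The minimum value ``A*D`` is reached at ``d == C``.
Parameters are drawn uniformly from ranges tuned so the restrained
models reproduce reference pocket sizes while still sampling the
±200 Å³ natural volume variation: A ∈ {2,3,4}, B ∈ [0.4, 0.8] on a
0.1 grid, s ∈ [1.03, 1.07] (3–7 % inflation, counteracting the pocket
shrinkage of unrestrained relaxation), D ∈ {−10, …, −1}.  The six
edges of one tetrahedron share one parameter draw; the two tetrahedra
of a set may differ.

The constraint-file dialect emitted/parsed here is the Rosetta
``AtomPair … SCALARWEIGHTEDFUNC … SUMFUNC 2 HARMONIC x0 sd
CONSTANTFUNC D`` line format, with pose numbering starting at 1.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import FormatError, ResolutionError
from .knowledge_base import DistanceStatsTable
from .numbering import (
    GenericResidueID,
    PocketDefinition,
    ResidueMap,
    parse_generic_id,
    resolve,
)
from .structure_io import StructureModel

__all__ = [
    "RestraintParams",
    "EdgeRestraint",
    "TetrahedronRestraint",
    "RestraintSet",
    "sample_params",
    "build_restraint_set",
    "restraint_score",
    "score_restraint_set",
    "write_constraint_file",
    "format_restraint_line",
    "parse_constraint_file",
    "reference_median_table",
    "REFERENCE_EDGE_MEDIANS",
]

# Knowledge-base reference distances (Å): median Cα–Cα distance of each
# tetrahedron edge over the inactive class A structure census, bundled
# as the default reference for knowledge-base mode.
REFERENCE_EDGE_MEDIANS: dict[tuple[str, str], float] = {
    ("2.60x59", "3.40x40"): 22.50,
    ("2.60x59", "5.38x39"): 24.25,
    ("2.60x59", "7.32x31"): 18.78,
    ("3.40x40", "5.38x39"): 17.94,
    ("3.40x40", "7.32x31"): 25.35,
    ("5.38x39", "7.32x31"): 20.30,
    ("2.65x64", "4.57x57"): 23.08,
    ("2.65x64", "5.46x461"): 25.35,
    ("2.65x64", "6.48x48"): 19.92,
    ("4.57x57", "5.46x461"): 10.76,
    ("4.57x57", "6.48x48"): 17.34,
    ("5.46x461", "6.48x48"): 11.23,
}


def reference_median_table() -> DistanceStatsTable:
    """The bundled reference medians as a :class:`DistanceStatsTable`.

    Only the median field is meaningful (n is set to 1, mean to the
    median, sd to 0): the underlying census is not redistributable.
    """
    table = DistanceStatsTable()
    for (a_txt, b_txt), med in REFERENCE_EDGE_MEDIANS.items():
        a, b = parse_generic_id(a_txt), parse_generic_id(b_txt)
        key = (a, b) if a <= b else (b, a)
        table.entries[key] = (1, med, med, 0.0)
    return table


@dataclass(frozen=True)
class RestraintParams:
    """One parameter draw shared by the six edges of a tetrahedron."""

    weight: int          # A
    steepness: float     # B, Å
    scale: float         # s, multiplies the reference distance
    offset: int          # D, score units

    def __post_init__(self) -> None:
        if self.weight not in (2, 3, 4):
            raise FormatError(f"weight A must be in {{2,3,4}}, got {self.weight}")
        if not 0.4 - 1e-9 <= self.steepness <= 0.8 + 1e-9:
            raise FormatError(f"steepness B outside [0.4, 0.8]: {self.steepness}")
        if not 1.03 - 1e-9 <= self.scale <= 1.07 + 1e-9:
            raise FormatError(f"scale s outside [1.03, 1.07]: {self.scale}")
        if not -10 <= self.offset <= -1:
            raise FormatError(f"offset D outside [-10, -1]: {self.offset}")


@dataclass(frozen=True)
class EdgeRestraint:
    pose_i: int
    pose_j: int
    reference: float  # C, Å

    def __post_init__(self) -> None:
        if self.pose_i == self.pose_j:
            raise FormatError("an edge restraint needs two distinct residues")
        if self.reference <= 0:
            raise FormatError("reference distance C must be positive")


# edge enumeration order within a tetrahedron, by vertex index
_EDGE_ORDER = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


@dataclass(frozen=True)
class TetrahedronRestraint:
    vertex_ids: tuple[GenericResidueID, GenericResidueID,
                      GenericResidueID, GenericResidueID]
    edges: tuple[EdgeRestraint, ...]
    params: RestraintParams

    def __post_init__(self) -> None:
        if len(self.edges) != 6:
            raise FormatError("a tetrahedron restraint has exactly 6 edges")


@dataclass(frozen=True)
class RestraintSet:
    tetra1: TetrahedronRestraint
    tetra2: TetrahedronRestraint
    seed: int

    @property
    def all_edges(self) -> list[tuple[EdgeRestraint, RestraintParams]]:
        return [(e, self.tetra1.params) for e in self.tetra1.edges] + [
            (e, self.tetra2.params) for e in self.tetra2.edges
        ]


def sample_params(rng: np.random.Generator, gridded: bool = True) -> RestraintParams:
    """Draw one parameter set uniformly from the tuned ranges.

    ``gridded`` (default) keeps B on a 0.1 grid and A, D integral, the
    granularity seen in worked restraint files; disable for fully
    continuous B sampling.
    """
    weight = int(rng.integers(2, 5))
    b = float(rng.uniform(0.4, 0.8))
    if gridded:
        b = round(b, 1)
    scale = float(rng.uniform(1.03, 1.07))
    offset = int(rng.integers(-10, 0))
    return RestraintParams(weight=weight, steepness=b, scale=scale, offset=offset)


def _reference_distance(
    id_a: GenericResidueID,
    id_b: GenericResidueID,
    stats: DistanceStatsTable | None,
    measured: dict[GenericResidueID, np.ndarray] | None,
) -> float:
    if stats is not None:
        entry = stats.get(id_a, id_b)
        if entry is None:
            raise FormatError(f"no reference distance for edge ({id_a}, {id_b})")
        return entry[1]
    assert measured is not None
    return float(np.linalg.norm(measured[id_a] - measured[id_b]))


def build_restraint_set(
    rmap: ResidueMap,
    model: StructureModel,
    pocket: PocketDefinition,
    rng: np.random.Generator,
    stats: DistanceStatsTable | None = None,
    params_override: tuple[RestraintParams, RestraintParams] | None = None,
    scale_override: float | None = None,
    seed: int = 0,
) -> RestraintSet:
    """Build the two-tetrahedron restraint set for one receptor model.

    Reference distances come from ``stats`` medians (knowledge-base
    mode) when given, otherwise from Cα distances measured in ``model``
    (template mode).  Each edge's restraint center is ``C = s * d_ref``.
    Parameters are drawn once per tetrahedron; ``params_override`` and
    ``scale_override`` pin them for testing/reproduction.
    """
    tetras = []
    for idx, vertex_ids in enumerate((pocket.tetra1_ids, pocket.tetra2_ids)):
        resolved = resolve(rmap, model, vertex_ids)  # raises naming the id
        poses = {gid: pose for gid, pose, _ in resolved}
        coords = {gid: np.asarray(xyz, dtype=float) for gid, _, xyz in resolved}
        params = (params_override[idx] if params_override is not None
                  else sample_params(rng))
        scale = scale_override if scale_override is not None else params.scale
        edges = []
        for i, j in _EDGE_ORDER:
            a, b = vertex_ids[i], vertex_ids[j]
            d_ref = _reference_distance(a, b, stats, coords)
            edges.append(
                EdgeRestraint(
                    pose_i=poses[a], pose_j=poses[b], reference=scale * d_ref
                )
            )
        tetras.append(
            TetrahedronRestraint(
                vertex_ids=tuple(vertex_ids), edges=tuple(edges), params=params
            )
        )
    return RestraintSet(tetra1=tetras[0], tetra2=tetras[1], seed=seed)


def restraint_score(d: float, params: RestraintParams, reference: float) -> float:
    """Evaluate the restraint potential A*(((d−C)/B)² + D) at distance d."""
    if params.steepness == 0:
        raise FormatError("steepness B must be non-zero")
    if d < 0 or reference <= 0:
        raise FormatError("distance must be >= 0 and reference C > 0")
    z = (d - reference) / params.steepness
    return params.weight * (z * z + params.offset)


def score_restraint_set(
    model: StructureModel, rset: RestraintSet
) -> tuple[float, list[tuple[int, int, float, float]]]:
    """Score a model against a restraint set.

    Returns the total (sum over the 12 edges) and a per-edge breakdown
    of ``(pose_i, pose_j, measured distance, score)``.
    """
    breakdown = []
    total = 0.0
    for edge, params in rset.all_edges:
        try:
            ri = model.residue_by_pose(edge.pose_i)
            rj = model.residue_by_pose(edge.pose_j)
        except KeyError as exc:
            raise ResolutionError(str(exc)) from exc
        d = float(np.linalg.norm(ri.ca_xyz - rj.ca_xyz))
        s = restraint_score(d, params, edge.reference)
        breakdown.append((edge.pose_i, edge.pose_j, d, s))
        total += s
    return total, breakdown


def format_restraint_line(edge: EdgeRestraint, params: RestraintParams) -> str:
    """Render one AtomPair line in the canonical single-space dialect."""
    return (
        f"AtomPair CA {edge.pose_i} CA {edge.pose_j} "
        f"SCALARWEIGHTEDFUNC {params.weight} SUMFUNC 2 "
        f"HARMONIC {edge.reference:.4f} {params.steepness:.1f} "
        f"CONSTANTFUNC {params.offset}"
    )


def write_constraint_file(rset: RestraintSet) -> str:
    """Emit the 12 AtomPair lines (tetrahedron 1 first), trailing newline."""
    lines = [format_restraint_line(e, p) for e, p in rset.all_edges]
    return "\n".join(lines) + "\n"


# Tolerant of typesetting-damaged spacing ("CA66", "SUMFUNC2HARMONIC",
# "CONSTANTFUNC-8"); canonical single-space output is never affected.
_LINE_RE = re.compile(
    r"^AtomPair\s*CA\s*(\d+)\s*CA\s*(\d+)\s*"
    r"SCALARWEIGHTEDFUNC\s*(-?\d+(?:\.\d+)?)\s*"
    r"SUMFUNC\s*2\s*"
    r"HARMONIC\s*(\d+(?:\.\d+)?)\s+(\d+(?:\.\d+)?)\s*"
    r"CONSTANTFUNC\s*(-?\d+(?:\.\d+)?)\s*$"
)


@dataclass(frozen=True)
class ParsedRestraintLine:
    pose_i: int
    pose_j: int
    weight: float      # A
    reference: float   # C
    steepness: float   # B
    offset: float      # D


def parse_constraint_file(text: str) -> list[ParsedRestraintLine]:
    """Parse constraint-file lines back into edge records.

    Unknown function names (anything outside the AtomPair /
    SCALARWEIGHTEDFUNC / SUMFUNC / HARMONIC / CONSTANTFUNC dialect)
    are rejected with the offending line number.
    """
    out = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        m = _LINE_RE.match(line)
        if m is None:
            raise FormatError(f"line {lineno}: not a valid AtomPair restraint line")
        i, j = int(m.group(1)), int(m.group(2))
        out.append(
            ParsedRestraintLine(
                pose_i=i,
                pose_j=j,
                weight=float(m.group(3)),
                reference=float(m.group(4)),
                steepness=float(m.group(5)),
                offset=float(m.group(6)),
            )
        )
    return out


def restraint_manifest(rset: RestraintSet) -> str:
    """JSON manifest of a restraint set (seed, params, vertices, poses)."""
    def tetra_dict(t: TetrahedronRestraint) -> dict:
        return {
            "vertices": [v.render() for v in t.vertex_ids],
            "params": {
                "weight": t.params.weight,
                "steepness": t.params.steepness,
                "scale": t.params.scale,
                "offset": t.params.offset,
            },
            "edges": [
                {"pose_i": e.pose_i, "pose_j": e.pose_j,
                 "reference": round(e.reference, 4)}
                for e in t.edges
            ],
        }

    return json.dumps(
        {"seed": rset.seed,
         "tetra1": tetra_dict(rset.tetra1),
         "tetra2": tetra_dict(rset.tetra2)},
        indent=2,
    ) + "\n"
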