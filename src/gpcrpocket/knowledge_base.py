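"""Statistical knowledge base over a set of experimental structures.

Given many receptor structures with per-receptor generic-number maps,
this module aggregates Cα–Cα distance statistics per residue pair
(count, median, mean, population SD), detects pocket-lining residues by
ligand proximity (closed 3.5 Å ball around any ligand heavy atom), and
ranks residues by how often they contact ligands across structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import FormatError
from .geometry import LabeledPointSet, pairwise_distances
from .numbering import GenericResidueID, ResidueMap, resolve
from .structure_io import HeteroGroup, StructureModel

__all__ = [
    "DistanceStatsTable",
    "ContactReport",
    "aggregate_distance_stats",
    "detect_pocket_residues",
    "rank_residue_frequency",
    "CONTACT_CUTOFF",
]

#: default ligand-contact cutoff, Å (closed ball: boundary included)
CONTACT_CUTOFF = 3.5


@dataclass
class DistanceStatsTable:
    """Per-pair distance statistics over a structure census."""

    entries: dict[tuple[GenericResidueID, GenericResidueID],
                  tuple[int, float, float, float]] = field(default_factory=dict)

    def get(self, id_a: GenericResidueID, id_b: GenericResidueID):
        key = (id_a, id_b) if id_a <= id_b else (id_b, id_a)
        return self.entries.get(key)

    def median(self, id_a: GenericResidueID, id_b: GenericResidueID) -> float:
        entry = self.get(id_a, id_b)
        if entry is None:
            raise KeyError(f"no statistics for pair ({id_a}, {id_b})")
        return entry[1]

    def to_tsv(self) -> str:
        lines = ["id_a\tid_b\tn\tmedian\tmean\tsd"]
        for (a, b), (n, med, mean, sd) in sorted(self.entries.items()):
            lines.append(
                f"{a.render()}\t{b.render()}\t{n}\t{med:.4f}\t{mean:.4f}\t{sd:.4f}"
            )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "DistanceStatsTable":
        from .numbering import parse_generic_id

        table = cls()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = lines[0].split("\t")
        if header[:2] != ["id_a", "id_b"]:
            raise FormatError("distance-stats TSV must start with id_a/id_b columns")
        for ln in lines[1:]:
            fields = ln.split("\t")
            a, b = parse_generic_id(fields[0]), parse_generic_id(fields[1])
            n, med, mean, sd = int(fields[2]), *map(float, fields[3:6])
            table.entries[(a, b) if a <= b else (b, a)] = (n, med, mean, sd)
        return table


@dataclass
class ContactReport:
    """Residues of one structure within the contact cutoff of a ligand."""

    label: str
    cutoff: float
    # (author_chain, author_seq, icode, resname, min_distance, generic_id|None)
    contacts: list[tuple[str, int, str, str, float, GenericResidueID | None]] = (
        field(default_factory=list)
    )

    def to_tsv(self) -> str:
        lines = ["chain\tresseq\ticode\tresname\tmin_distance\tgeneric_id"]
        for chain, seq, icode, name, dist, gid in self.contacts:
            gid_txt = gid.render() if gid is not None else ""
            lines.append(f"{chain}\t{seq}\t{icode}\t{name}\t{dist:.4f}\t{gid_txt}")
        return "\n".join(lines) + "\n"


def aggregate_distance_stats(
    samples: Sequence[tuple[StructureModel, ResidueMap]],
    ids: Sequence[GenericResidueID],
) -> DistanceStatsTable:
    """Aggregate pairwise Cα distance statistics over many structures.

    For each structure only the IDs it can resolve contribute, so a
    structure missing one mapped residue still informs every pair it can
    measure; per-pair counts record the effective census size.  The
    median of an even count is the mean of the two middle values and the
    SD is the population (n-denominator) form.
    """
    if not samples:
        raise FormatError("empty sample set")
    per_pair: dict[tuple[GenericResidueID, GenericResidueID], list[float]] = {}
    for model, rmap in samples:
        resolved = []
        for gid in ids:
            try:
                resolved.extend(resolve(rmap, model, [gid]))
            except Exception:
                warnings.warn(
                    f"structure {model.label!r} cannot resolve {gid}; "
                    "pair statistics involving it skip this structure",
                    stacklevel=2,
                )
        if len(resolved) < 2:
            continue
        pts = LabeledPointSet.from_resolved(resolved)
        for pair in pairwise_distances(pts):
            per_pair.setdefault((pair.id_a, pair.id_b), []).append(pair.distance)
    table = DistanceStatsTable()
    for key, values in per_pair.items():
        arr = np.asarray(values, dtype=float)
        table.entries[key] = (
            len(arr),
            float(np.median(arr)),
            float(arr.mean()),
            float(arr.std(ddof=0)),
        )
    return table


def _heavy_coords(residue) -> np.ndarray:
    if residue.heavy_atoms:
        return np.array([xyz for _, xyz in residue.heavy_atoms], dtype=float)
    return np.asarray(residue.ca_xyz, dtype=float).reshape(1, 3)


def detect_pocket_residues(
    model: StructureModel,
    ligand: HeteroGroup,
    cutoff: float = CONTACT_CUTOFF,
    rmap: ResidueMap | None = None,
) -> ContactReport:
    """Residues with any heavy atom within ``cutoff`` Å of a ligand heavy atom.

    The cutoff is a closed ball: a residue exactly at the boundary is
    included.  Hydrogens (and deuteriums) are ignored on both sides.
    If ``rmap`` is given, matched contacts are annotated with their
    generic residue number.
    """
    lig_coords = np.array(
        [xyz for _, element, xyz in ligand.atoms if element not in ("H", "D")],
        dtype=float,
    )
    if lig_coords.size == 0:
        raise FormatError("ligand has no heavy atoms")
    if any(not r.heavy_atoms for r in model.residues):
        warnings.warn(
            "some residues carry no heavy-atom list; falling back to Cα-only "
            "contact distances for those residues",
            stacklevel=2,
        )
    tree = cKDTree(lig_coords)
    reverse: dict[tuple[str, int, str], GenericResidueID] = {}
    if rmap is not None:
        reverse = {target: gid for gid, target in rmap.entries.items()}
    report = ContactReport(label=model.label, cutoff=cutoff)
    for res in model.residues:
        dmin = float(tree.query(_heavy_coords(res))[0].min())
        if dmin <= cutoff:
            gid = reverse.get((res.author_chain, res.author_seq, res.icode))
            report.contacts.append(
                (res.author_chain, res.author_seq, res.icode, res.name, dmin, gid)
            )
    return report


def rank_residue_frequency(
    reports: Iterable[ContactReport],
) -> list[tuple[GenericResidueID, int]]:
    """Rank generic positions by how often they contact a ligand.

    Contacts without a generic annotation are ignored (with a warning);
    output is sorted by descending count, ties broken by canonical
    generic-ID order.
    """
    counts: dict[GenericResidueID, int] = {}
    unmapped = 0
    for report in reports:
        for *_rest, gid in report.contacts:
            if gid is None:
                unmapped += 1
                continue
            counts[gid] = counts.get(gid, 0) + 1
    if unmapped:
        warnings.warn(
            f"{unmapped} contact(s) had no generic-number annotation and were "
            "ignored in the frequency ranking",
            stacklevel=2,
        )
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
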