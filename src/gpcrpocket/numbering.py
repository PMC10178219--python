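"""Generic residue numbering for class A GPCRs.

The Ballesteros–Weinstein (BW) scheme labels a transmembrane residue as
``helix.position`` (e.g. ``2.57``), where the position is counted relative
to the most conserved residue of the helix (position 50).  The GPCRdb
extension appends a structure-based position after an ``x`` separator
(``2.57x56``) that corrects for helix bulges and alignment gaps, so the
same label identifies the spatially equivalent residue across receptors.

This module provides the :class:`GenericResidueID` value type, parsing of
both the plain machine form (``2.57x56``) and the typographic form seen in
print (``2.57 × 56``), per-receptor mapping tables from generic IDs to
author numbering (:class:`ResidueMap`), and the canonical pocket
definition used throughout the toolkit: the 10 surrogate residues whose
Cα atoms span the orthosteric pocket, and the two tetrahedron vertex sets
used for distance restraints.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from io import StringIO
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, ResolutionError

__all__ = [
    "GenericResidueID",
    "ResidueMap",
    "PocketDefinition",
    "parse_generic_id",
    "load_residue_map",
    "load_pocket_definition",
    "resolve",
    "default_pocket_definition",
    "SURROGATE_IDS",
    "TETRA1_IDS",
    "TETRA2_IDS",
]

_ID_RE = re.compile(
    r"^\s*(\d+)\s*\.\s*(\d+)\s*(?:[x×]\s*(\d+)\s*)?$"
)


@dataclass(frozen=True, order=True)
class GenericResidueID:
    """A BW × GPCRdb generic residue number, e.g. ``2.57x56``.

    Ordering is lexicographic on (helix, bw, gpcrdb), which is the
    canonical tie-break order used everywhere in the package.
    """

    helix: int
    bw: int
    gpcrdb: int

    def __post_init__(self) -> None:
        if not 1 <= self.helix <= 8:
            raise FormatError(f"helix index {self.helix} outside 1..8")
        if self.bw < 1 or self.gpcrdb < 1:
            raise FormatError("BW and GPCRdb positions must be >= 1")

    def render(self) -> str:
        return f"{self.helix}.{self.bw}x{self.gpcrdb}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


def parse_generic_id(token: str) -> GenericResidueID:
    """Parse ``h.bb`` or ``h.bbxgg`` (also tolerating ``h.bb × gg``).

    When the x-part is absent the GPCRdb position defaults to the BW
    position, which is correct for helices without bulges or gaps.
    """
    m = _ID_RE.match(token)
    if m is None:
        raise FormatError(f"cannot parse generic residue id {token!r}")
    helix, bw = int(m.group(1)), int(m.group(2))
    gpcrdb = int(m.group(3)) if m.group(3) is not None else bw
    return GenericResidueID(helix, bw, gpcrdb)


# The 10 surrogate residues spanning the orthosteric pocket: the highest
# and lowest frequently ligand-contacting position on each of TM2, TM3,
# TM5, TM6 and TM7 (TM1 and TM4 do not line the pocket with more than two
# residues and are omitted).
SURROGATE_IDS: tuple[GenericResidueID, ...] = tuple(
    parse_generic_id(t)
    for t in (
        "2.57x56", "2.65x64", "3.28x28", "3.37x37", "5.38x39",
        "5.47x47", "6.51x51", "6.58x58", "7.32x31", "7.43x42",
    )
)

# Vertex sets of the two pocket-spanning restraint tetrahedra.
TETRA1_IDS: tuple[GenericResidueID, ...] = tuple(
    parse_generic_id(t) for t in ("2.60x59", "3.40x40", "5.38x39", "7.32x31")
)
TETRA2_IDS: tuple[GenericResidueID, ...] = tuple(
    parse_generic_id(t) for t in ("2.65x64", "4.57x57", "5.46x461", "6.48x48")
)

# Partial extended pocket list: the union of every generic ID named in the
# pocket analysis (surrogates plus tetrahedron vertices).  The full
# 34-residue census is a user-supplied configuration; this bundled default
# covers the subset needed by the restraint machinery.
_EXTENDED_DEFAULT: tuple[GenericResidueID, ...] = tuple(
    sorted(set(SURROGATE_IDS) | set(TETRA1_IDS) | set(TETRA2_IDS))
)


@dataclass(frozen=True)
class PocketDefinition:
    """The residue sets that define the orthosteric pocket.

    ``surrogate_ids`` are the 10 positions whose Cα convex hull measures
    the pocket volume; ``tetra1_ids``/``tetra2_ids`` are the two
    tetrahedron vertex quadruples used for restraints; ``extended_ids``
    is the (nominally 34-residue) pocket-lining census.
    """

    surrogate_ids: tuple[GenericResidueID, ...] = SURROGATE_IDS
    tetra1_ids: tuple[GenericResidueID, ...] = TETRA1_IDS
    tetra2_ids: tuple[GenericResidueID, ...] = TETRA2_IDS
    extended_ids: tuple[GenericResidueID, ...] = _EXTENDED_DEFAULT

    def __post_init__(self) -> None:
        helices = {i.helix for i in self.surrogate_ids}
        if not helices <= {2, 3, 5, 6, 7}:
            raise FormatError(
                "surrogate residues must lie on TM2/3/5/6/7; "
                f"got helices {sorted(helices)}"
            )
        for ids, tag in ((self.tetra1_ids, "tetra1"), (self.tetra2_ids, "tetra2")):
            if len(ids) != 4 or len(set(ids)) != 4:
                raise FormatError(f"{tag} must contain 4 distinct generic ids")


def default_pocket_definition() -> PocketDefinition:
    """The bundled pocket definition (surrogates + restraint tetrahedra)."""
    return PocketDefinition()


@dataclass
class ResidueMap:
    """Per-receptor resolution of generic IDs to author numbering."""

    receptor: str
    entries: dict[GenericResidueID, tuple[str, int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        targets = list(self.entries.values())
        if len(set(targets)) != len(targets):
            raise FormatError(
                f"mapping for {self.receptor!r} is not injective: "
                "two generic ids point at the same author residue"
            )

    def __contains__(self, gid: GenericResidueID) -> bool:
        return gid in self.entries

    def __len__(self) -> int:
        return len(self.entries)


def load_residue_map(tsv_text: str, receptor: str = "") -> ResidueMap:
    """Load a generic-number mapping table.

    Expected columns: ``generic_id``, ``chain``, ``resseq`` and an
    optional ``icode``.  Lines starting with ``#`` are comments.
    """
    df = pd.read_csv(
        StringIO(tsv_text), sep="\t", comment="#", dtype=str, skip_blank_lines=True
    )
    required = {"generic_id", "chain", "resseq"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"mapping table lacks column(s): {sorted(missing)}")
    entries: dict[GenericResidueID, tuple[str, int, str]] = {}
    for _, row in df.iterrows():
        gid = parse_generic_id(str(row["generic_id"]))
        if gid in entries:
            raise FormatError(f"duplicate mapping for generic id {gid}")
        icode = ""
        if "icode" in df.columns and isinstance(row["icode"], str):
            icode = row["icode"].strip()
        entries[gid] = (str(row["chain"]).strip(), int(row["resseq"]), icode)
    return ResidueMap(receptor=receptor, entries=entries)


def dump_residue_map(rmap: ResidueMap) -> str:
    """Serialize a :class:`ResidueMap` back to its TSV dialect."""
    lines = ["generic_id\tchain\tresseq\ticode"]
    for gid in sorted(rmap.entries):
        chain, resseq, icode = rmap.entries[gid]
        lines.append(f"{gid.render()}\t{chain}\t{resseq}\t{icode}")
    return "\n".join(lines) + "\n"


def dump_pocket_definition(pdef: PocketDefinition) -> str:
    """Serialize a pocket definition to the sectioned one-ID-per-line format."""
    parts = []
    for section, ids in (
        ("surrogates", pdef.surrogate_ids),
        ("tetra1", pdef.tetra1_ids),
        ("tetra2", pdef.tetra2_ids),
        ("extended", pdef.extended_ids),
    ):
        parts.append(f"[{section}]")
        parts.extend(gid.render() for gid in ids)
        parts.append("")
    return "\n".join(parts).rstrip("\n") + "\n"


_SECTIONS = {"surrogates", "tetra1", "tetra2", "extended"}


def load_pocket_definition(text: str) -> PocketDefinition:
    """Parse a pocket-definition file: one generic ID per line with
    optional ``[surrogates]`` / ``[tetra1]`` / ``[tetra2]`` / ``[extended]``
    section headers.  Sections left out fall back to the bundled defaults.
    """
    sections: dict[str, list[GenericResidueID]] = {s: [] for s in _SECTIONS}
    current = "extended"
    seen: set[str] = set()
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            name = line[1:-1].strip().lower()
            if name not in _SECTIONS:
                raise FormatError(f"line {lineno}: unknown section [{name}]")
            current = name
            seen.add(name)
            continue
        sections[current].append(parse_generic_id(line))
    default = PocketDefinition()
    return PocketDefinition(
        surrogate_ids=tuple(sections["surrogates"]) or default.surrogate_ids,
        tetra1_ids=tuple(sections["tetra1"]) or default.tetra1_ids,
        tetra2_ids=tuple(sections["tetra2"]) or default.tetra2_ids,
        extended_ids=tuple(sections["extended"]) or default.extended_ids,
    )


def resolve(rmap: ResidueMap, model, ids: Iterable[GenericResidueID]):
    """Resolve generic IDs to ``(id, pose_number, ca_xyz)`` triples.

    Output order equals input order.  Raises :class:`ResolutionError`
    naming the offending ID if it is unmapped or the mapped author
    residue is absent from the model.
    """
    index = {
        (r.author_chain, r.author_seq, r.icode): r for r in model.residues
    }
    out = []
    for gid in ids:
        if gid not in rmap.entries:
            raise ResolutionError(
                f"generic id {gid} not in mapping for {rmap.receptor!r}"
            )
        key = rmap.entries[gid]
        res = index.get(key)
        if res is None:
            raise ResolutionError(
                f"generic id {gid} maps to {key} which is absent from "
                f"structure {model.label!r}"
            )
        out.append((gid, res.pose_number, res.ca_xyz))
    return out
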