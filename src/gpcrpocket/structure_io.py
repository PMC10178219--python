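"""Coordinate and score-table I/O.

Reads PDB-format text into a light in-memory :class:`StructureModel`
holding the polymer residues (with Cα and heavy-atom coordinates) under
Rosetta-style pose numbering (sequential, 1-based over the retained
residues) plus any hetero groups (ligands etc.) that survive the
exclusion filter.  PDB parsing and writing are delegated to :mod:`gemmi`;
this module only decides *which* records become part of the model
(chain selection, altloc policy, hetero exclusions).

Also parses the whitespace-delimited ``SCORE:`` table dialect produced by
Rosetta scorefiles (``score.sc``), whose ``description`` column carries
the model label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .errors import EmptyStructureError, FormatError

__all__ = [
    "PolymerResidue",
    "HeteroGroup",
    "StructureModel",
    "DEFAULT_HET_EXCLUSIONS",
    "read_structure",
    "write_structure",
    "read_score_table",
]

# Waters and common crystallization additives/ions.  Membrane lipids and
# detergents are deliberately NOT excluded by default: in several GPCR
# entries they occupy the orthosteric pocket and count as bound ligands.
DEFAULT_HET_EXCLUSIONS: frozenset[str] = frozenset(
    {"HOH", "DOD", "NA", "CL", "K", "MG", "ZN", "CA", "SO4", "PO4",
     "GOL", "EDO", "PEG"}
)

_HYDROGEN = {"H", "D"}


@dataclass
class PolymerResidue:
    author_chain: str
    author_seq: int
    icode: str
    name: str
    ca_xyz: np.ndarray
    heavy_atoms: list[tuple[str, np.ndarray]] = field(default_factory=list)
    pose_number: int = 0


@dataclass
class HeteroGroup:
    name: str
    author_chain: str
    author_seq: int
    atoms: list[tuple[str, str, np.ndarray]] = field(default_factory=list)


@dataclass
class StructureModel:
    label: str
    residues: list[PolymerResidue] = field(default_factory=list)
    hetero_groups: list[HeteroGroup] = field(default_factory=list)

    def residue_by_pose(self, pose_number: int) -> PolymerResidue:
        if not 1 <= pose_number <= len(self.residues):
            raise KeyError(f"pose number {pose_number} outside 1..{len(self.residues)}")
        return self.residues[pose_number - 1]

    def ca_coordinates(self) -> np.ndarray:
        return np.array([r.ca_xyz for r in self.residues], dtype=float)


def _pick_altloc(atoms: list[gemmi.Atom], policy: str) -> gemmi.Atom:
    if len(atoms) == 1 or policy == "keep-first":
        return atoms[0]
    if policy == "keep-highest-occupancy":
        # stable max: ties resolve to the first-seen conformer
        return max(atoms, key=lambda a: a.occ)
    raise ValueError(f"unknown altloc policy {policy!r}")


def _residue_atoms(res: gemmi.Residue, altloc_policy: str):
    """One representative atom per atom name, altloc policy applied."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for atom in res:
        by_name.setdefault(atom.name, []).append(atom)
    for name, group in by_name.items():
        yield name, _pick_altloc(group, altloc_policy)


def _select_chains(model: gemmi.Model, chain_policy: str) -> list[gemmi.Chain]:
    chains = list(model)
    if not chains:
        return []
    if chain_policy == "all":
        return chains
    if chain_policy == "first":
        return [chains[0]]
    if chain_policy == "auto":
        # first chain that looks like a receptor: >= 100 polymer residues;
        # fall back to the chain with the most polymer residues.
        def n_polymer(ch: gemmi.Chain) -> int:
            return sum(1 for r in ch if r.het_flag == "A")

        for ch in chains:
            if n_polymer(ch) >= 100:
                return [ch]
        return [max(chains, key=n_polymer)]
    named = [ch for ch in chains if ch.name == chain_policy]
    if not named:
        raise FormatError(f"chain {chain_policy!r} not present in structure")
    return named


def read_structure(
    pdb_text: str,
    label: str = "",
    chain_policy: str = "auto",
    altloc_policy: str = "keep-first",
    het_exclusions: frozenset[str] | None = None,
    strict: bool = False,
) -> StructureModel:
    """Parse PDB text into a :class:`StructureModel`.

    Parameters
    ----------
    chain_policy:
        ``"auto"`` (default) keeps the first chain with at least 100
        polymer residues — GPCR entries often carry fusion partners on
        other chains; ``"all"``, ``"first"`` or an explicit chain name
        select differently.
    altloc_policy:
        ``"keep-first"`` (default, deterministic) or
        ``"keep-highest-occupancy"``.
    het_exclusions:
        Hetero residue names to drop; defaults to waters and common
        ions/additives.  Pass an empty set to disable exclusion.
    strict:
        If true, a polymer residue lacking a Cα raises instead of being
        dropped with a warning.

    Only the first MODEL block of multi-model files is read.
    """
    if het_exclusions is None:
        het_exclusions = DEFAULT_HET_EXCLUSIONS
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise EmptyStructureError("no coordinate records found")
    gmodel = st[0]  # first MODEL only

    model = StructureModel(label=label)
    selected = {ch.name for ch in _select_chains(gmodel, chain_policy)}
    # hetero groups are collected from every chain: ligands frequently sit
    # on a different author chain than the receptor polymer
    for chain in gmodel:
        for res in chain:
            atoms = list(_residue_atoms(res, altloc_policy))
            if res.het_flag == "H":
                if res.name.strip() in het_exclusions:
                    continue
                group = HeteroGroup(
                    name=res.name,
                    author_chain=chain.name,
                    author_seq=res.seqid.num,
                    atoms=[
                        (name, atom.element.name, np.array(
                            [atom.pos.x, atom.pos.y, atom.pos.z]))
                        for name, atom in atoms
                    ],
                )
                if group.atoms:
                    model.hetero_groups.append(group)
                continue
            if chain.name not in selected:
                continue
            # polymer (ATOM) residue — anything with a Cα is retained,
            # including modified amino acids encoded as ATOM records
            ca = next((a for n, a in atoms if n == "CA"), None)
            if ca is None:
                msg = (f"residue {res.name} {chain.name}{res.seqid.num} "
                       "has no CA atom")
                if strict:
                    raise FormatError(msg)
                warnings.warn(msg + "; dropped", stacklevel=2)
                continue
            heavy = [
                (name, np.array([a.pos.x, a.pos.y, a.pos.z]))
                for name, a in atoms
                if a.element.name not in _HYDROGEN
            ]
            model.residues.append(
                PolymerResidue(
                    author_chain=chain.name,
                    author_seq=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    name=res.name,
                    ca_xyz=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                    heavy_atoms=heavy,
                )
            )
    if not model.residues:
        raise EmptyStructureError("no polymer residues with Cα found")
    for i, res in enumerate(model.residues, start=1):
        res.pose_number = i
    return model


def _guess_element(atom_name: str) -> gemmi.Element:
    stripped = atom_name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br", "Fe", "Zn", "Mg", "Na", "Se"):
        return gemmi.Element(stripped[:2].capitalize())
    return gemmi.Element(stripped[:1]) if stripped else gemmi.Element("X")


def write_structure(model: StructureModel) -> str:
    """Serialize a model back to PDB text (via gemmi's writer).

    Re-reading the output reproduces residue order exactly and all
    coordinates at PDB precision (3 decimals).
    """
    if not model.residues:
        raise EmptyStructureError("refusing to write a model with no residues")
    st = gemmi.Structure()
    st.name = model.label or "model"
    gmodel = gemmi.Model("1")
    chains: dict[str, gemmi.Chain] = {}

    def chain_for(name: str) -> gemmi.Chain:
        if name not in chains:
            chains[name] = gemmi.Chain(name)
        return chains[name]

    for res in model.residues:
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.author_seq, res.icode or " ")
        gres.het_flag = "A"
        names_written = set()
        atom_list = res.heavy_atoms or [("CA", res.ca_xyz)]
        for name, xyz in atom_list:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = _guess_element(name)
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            gres.add_atom(atom)
            names_written.add(name)
        if "CA" not in names_written:
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*map(float, res.ca_xyz))
            atom.occ = 1.0
            gres.add_atom(atom)
        chain_for(res.author_chain).add_residue(gres)
    for het in model.hetero_groups:
        gres = gemmi.Residue()
        gres.name = het.name
        gres.seqid = gemmi.SeqId(het.author_seq, " ")
        gres.het_flag = "H"
        for name, element, xyz in het.atoms:
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(element)
            atom.pos = gemmi.Position(*map(float, xyz))
            atom.occ = 1.0
            gres.add_atom(atom)
        chain_for(het.author_chain).add_residue(gres)
    for chain in chains.values():
        gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    return st.make_pdb_string()


def read_score_table(text: str) -> dict[str, dict[str, float | str]]:
    """Parse Rosetta ``score.sc``-style tables.

    Lines starting with ``SCORE:`` are data; the first such line is the
    header and must contain a ``description`` column holding the model
    label.  Numeric cells are parsed as floats, everything else is kept
    as text.  Duplicate labels keep the last row (with a warning).
    """
    header: list[str] | None = None
    out: dict[str, dict[str, float | str]] = {}
    for raw in text.splitlines():
        if not raw.startswith("SCORE:"):
            continue
        fields = raw.split()[1:]
        if header is None:
            if "description" not in fields:
                raise FormatError("score-table header lacks a description column")
            header = fields
            continue
        if len(fields) != len(header):
            raise FormatError(
                f"score row has {len(fields)} fields, header has {len(header)}"
            )
        row: dict[str, float | str] = {}
        for key, cell in zip(header, fields):
            try:
                row[key] = float(cell)
            except ValueError:
                row[key] = cell
        label = str(row["description"])
        if label in out:
            warnings.warn(f"duplicate score-table label {label!r}; last row wins",
                          stacklevel=2)
        out[label] = row
    if header is None:
        raise FormatError("no SCORE: header line found")
    return out
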