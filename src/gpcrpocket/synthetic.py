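"""Synthetic 7TM bundles, ligands and ensembles for download-free testing.

Real class A GPCR coordinates cannot be bundled with the package, so
this module builds idealized seven-helix Cα bundles with a central
cavity whose size is controlled by the helix-axis circle radius.  The
helices use textbook α-helix geometry (rise 1.5 Å per residue, twist
100° per residue, Cα helix radius 2.3 Å) and alternate direction as in
a membrane bundle.  Pocket generic numbers are planted at fixed
per-helix indices and emitted as a regular :class:`ResidueMap`, so every
I/O, numbering, geometry and restraint code path can be exercised
against planted ground truth.

The default bundle radius is chosen so the surrogate-residue pocket
volume lands near 2600 Å³, the typical inactive-state class A pocket
size; the synthetic ensemble generator defaults to a 2600 ± 200 Å³
volume distribution for the same reason.  Everything is deterministic
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .ensemble import ModelRecord
from .errors import FormatError
from .geometry import LabeledPointSet, pocket_volume
from .numbering import (
    GenericResidueID,
    PocketDefinition,
    ResidueMap,
    default_pocket_definition,
    resolve,
)
from .structure_io import HeteroGroup, PolymerResidue, StructureModel

__all__ = [
    "BundleSpec",
    "make_bundle",
    "scale_pocket",
    "plant_ligand",
    "make_ensemble",
    "make_shrink_trajectory",
]

# ideal alpha-helix Calpha geometry
HELIX_RISE = 1.5       # Å per residue along the axis
HELIX_TWIST = 100.0    # degrees per residue
HELIX_CA_RADIUS = 2.3  # Å, Calpha distance from the helix axis

# residue index (1-based within a helix) planted for BW position b is
# b - _BW_INDEX_OFFSET; with 40 residues per helix this hosts BW 28..65.
_BW_INDEX_OFFSET = 26


@dataclass(frozen=True)
class BundleSpec:
    """Parameters of an idealized 7TM Cα bundle.

    ``pocket_radius`` is the radius (Å) of the circle on which the seven
    helix axes sit; it is the single dial controlling cavity size.  The
    default yields a surrogate pocket volume close to the 2600 Å³
    typical of inactive class A receptors.  ``jitter`` adds seeded
    Gaussian coordinate noise (Å) to emulate structural heterogeneity
    across a census.
    """

    pocket_radius: float = 8.35
    residues_per_helix: int = 40
    rise: float = HELIX_RISE
    twist: float = HELIX_TWIST
    ca_radius: float = HELIX_CA_RADIUS
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pocket_radius <= 0:
            raise FormatError("pocket_radius must be positive")
        if self.residues_per_helix < 40:
            raise FormatError(
                "residues_per_helix must be >= 40 to host all planted "
                "pocket positions"
            )


def _planted_ids(pocket: PocketDefinition) -> list[GenericResidueID]:
    return sorted(set(pocket.surrogate_ids) | set(pocket.tetra1_ids)
                  | set(pocket.tetra2_ids) | set(pocket.extended_ids))


def make_bundle(
    spec: BundleSpec = BundleSpec(), label: str = "bundle"
) -> tuple[StructureModel, ResidueMap, PocketDefinition]:
    """Build a 7-helix Cα bundle with a planted pocket definition.

    Returns the structure, a mapping that resolves every bundled pocket
    generic number, and the bundled :class:`PocketDefinition`.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.residues_per_helix
    model = StructureModel(label=label)
    seq = 0
    for helix in range(1, 8):
        theta = 2.0 * np.pi * (helix - 1) / 7.0
        axis_xy = spec.pocket_radius * np.array([np.cos(theta), np.sin(theta)])
        direction = 1.0 if helix % 2 == 1 else -1.0
        for t in range(n):
            seq += 1
            phase = np.deg2rad(spec.twist * t) + theta + np.pi
            local = spec.ca_radius * np.array([np.cos(phase), np.sin(phase)])
            z = direction * (t - (n - 1) / 2.0) * spec.rise
            xyz = np.array([axis_xy[0] + local[0], axis_xy[1] + local[1], z])
            if spec.jitter > 0:
                xyz = xyz + rng.normal(0.0, spec.jitter, size=3)
            model.residues.append(
                PolymerResidue(
                    author_chain="A",
                    author_seq=seq,
                    icode="",
                    name="ALA",
                    ca_xyz=xyz,
                    heavy_atoms=[("CA", xyz)],
                    pose_number=seq,
                )
            )
    pocket = default_pocket_definition()
    entries: dict[GenericResidueID, tuple[str, int, str]] = {}
    for gid in _planted_ids(pocket):
        idx_in_helix = gid.bw - _BW_INDEX_OFFSET  # 1-based
        if not 1 <= idx_in_helix <= n:
            raise FormatError(f"cannot plant {gid} on a {n}-residue helix")
        entries[gid] = ("A", (gid.helix - 1) * n + idx_in_helix, "")
    rmap = ResidueMap(receptor=label, entries=entries)
    return model, rmap, pocket


def scale_pocket(
    model: StructureModel, factor: float, center: np.ndarray | None = None
) -> StructureModel:
    """Scale all coordinates radially about ``center`` (default: the Cα
    centroid).  Any enclosed volume scales by exactly ``factor ** 3``."""
    if factor <= 0:
        raise FormatError("scale factor must be positive")
    if center is None:
        center = model.ca_coordinates().mean(axis=0)
    center = np.asarray(center, dtype=float)

    def move(xyz: np.ndarray) -> np.ndarray:
        return center + factor * (np.asarray(xyz, dtype=float) - center)

    out = StructureModel(label=model.label)
    for res in model.residues:
        out.residues.append(
            PolymerResidue(
                author_chain=res.author_chain,
                author_seq=res.author_seq,
                icode=res.icode,
                name=res.name,
                ca_xyz=move(res.ca_xyz),
                heavy_atoms=[(nm, move(xyz)) for nm, xyz in res.heavy_atoms],
                pose_number=res.pose_number,
            )
        )
    for het in model.hetero_groups:
        out.hetero_groups.append(
            HeteroGroup(
                name=het.name,
                author_chain=het.author_chain,
                author_seq=het.author_seq,
                atoms=[(nm, el, move(xyz)) for nm, el, xyz in het.atoms],
            )
        )
    return out


def _fibonacci_sphere(m: int) -> np.ndarray:
    """m near-uniform unit vectors (deterministic Fibonacci lattice)."""
    k = np.arange(m, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / m
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def plant_ligand(
    model: StructureModel,
    target_ids: Sequence[GenericResidueID],
    rmap: ResidueMap,
    contact_distance: float = 3.0,
    clearance: float = 3.5,
) -> HeteroGroup:
    """Place a hetero group contacting exactly the target residues.

    One ligand atom is placed ``contact_distance`` Å from each target's
    Cα, along the direction (searched over a deterministic unit-sphere
    grid) that keeps every other residue as far away as possible.
    Raises if no direction keeps all non-target residues farther than
    ``clearance`` Å from the ligand atom.
    """
    if not target_ids:
        raise FormatError("need at least one target residue")
    if contact_distance >= clearance:
        raise FormatError("contact_distance must be below the clearance cutoff")
    resolved = resolve(rmap, model, list(target_ids))
    target_keys = {rmap.entries[gid] for gid in target_ids}
    other_coords = np.array([
        xyz
        for res in model.residues
        if (res.author_chain, res.author_seq, res.icode) not in target_keys
        for _, xyz in (res.heavy_atoms or [("CA", res.ca_xyz)])
    ])
    directions = _fibonacci_sphere(200)
    atoms = []
    for k, (gid, _pose, ca) in enumerate(resolved, start=1):
        candidates = ca[None, :] + contact_distance * directions  # (m, 3)
        # for each candidate position, its clearance from all other residues
        dmin = np.sqrt(
            ((candidates[:, None, :] - other_coords[None, :, :]) ** 2).sum(-1)
        ).min(axis=1)
        best = int(np.argmax(dmin))
        if dmin[best] <= clearance:
            raise FormatError(
                f"infeasible placement: no direction around target {gid} "
                f"clears {clearance} Å (best {dmin[best]:.2f} Å)"
            )
        atoms.append((f"C{k}", "C", candidates[best]))
    ligand = HeteroGroup(name="LIG", author_chain="X", author_seq=900, atoms=atoms)

    lig_coords = np.array([xyz for _, _, xyz in atoms])
    targets = {rmap.entries[gid] for gid in target_ids}
    for res in model.residues:
        coords = np.array([xyz for _, xyz in res.heavy_atoms]) \
            if res.heavy_atoms else res.ca_xyz.reshape(1, 3)
        dmin = np.sqrt(
            ((coords[:, None, :] - lig_coords[None, :, :]) ** 2).sum(-1)
        ).min()
        key = (res.author_chain, res.author_seq, res.icode)
        if key in targets:
            if dmin > contact_distance + 1e-6:
                raise FormatError(f"planted ligand misses target residue {key}")
        elif dmin <= clearance:
            raise FormatError(
                "infeasible placement: ligand atom within the clearance "
                f"distance of non-target residue {key} ({dmin:.2f} Å)"
            )
    return ligand


def make_ensemble(
    n: int,
    median_target: float = 2600.0,
    sd: float = 200.0,
    seed: int = 0,
    score_center: float = -300.0,
    score_sd: float = 10.0,
) -> tuple[list[ModelRecord], str]:
    """Model records with a controlled pocket-volume distribution.

    Volumes are drawn from N(``median_target``, ``sd``²) — the default
    2600 ± 200 Å³ mirrors the observed inactive class A census, in which
    68 % of receptors fall inside that band.  Total and interface scores
    are drawn independently.  Also returns a ``SCORE:`` table that
    round-trips through :func:`gpcrpocket.structure_io.read_score_table`.
    """
    if n < 1:
        raise FormatError("ensemble size must be >= 1")
    rng = np.random.default_rng(seed)
    volumes = rng.normal(median_target, sd, size=n)
    totals = rng.normal(score_center, score_sd, size=n)
    interfaces = rng.normal(-5.0, 2.0, size=n)
    records = []
    lines = ["SCORE: total_score interface_delta_X description"]
    width = max(4, len(str(n)))
    for i in range(n):
        label = f"model_{i + 1:0{width}d}"
        records.append(
            ModelRecord(
                label=label,
                volume=float(volumes[i]),
                total_score=float(totals[i]),
                interface_score=float(interfaces[i]),
            )
        )
        lines.append(
            f"SCORE: {totals[i]:.3f} {interfaces[i]:.3f} {label}"
        )
    return records, "\n".join(lines) + "\n"


def make_shrink_trajectory(
    spec: BundleSpec, factors: Sequence[float], label: str = "relax"
) -> list[tuple[str, StructureModel]]:
    """A relax-like structure series: one bundle per radial scale factor.

    Emulates the volume collapse seen when a receptor is repeatedly
    energy-minimized: pass factors like (1.0, 0.95, 0.9, 0.9, 0.9).
    """
    base, rmap, pocket = make_bundle(spec, label=label)
    resolved = resolve(rmap, base, pocket.surrogate_ids)
    center = np.array([xyz for _, _, xyz in resolved]).mean(axis=0)
    return [
        (f"{label}_{k}", scale_pocket(base, f, center=center))
        for k, f in enumerate(factors)
    ]
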