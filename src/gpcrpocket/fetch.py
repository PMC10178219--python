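"""Convenience downloads of experimental inputs (network required).

Fetches PDB entries from RCSB and per-receptor generic residue
numbering from the GPCRdb web service, turning the latter into a
:class:`~gpcrpocket.numbering.ResidueMap`.  Nothing in the package's
offline workflows depends on these helpers; they exist so that real
experimental structures can be analyzed with one call where network
access is available.
"""

from __future__ import annotations

import json
import urllib.request

from .errors import FormatError
from .numbering import GenericResidueID, ResidueMap, parse_generic_id

__all__ = ["fetch_pdb", "fetch_gpcrdb_residue_map"]

RCSB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"
GPCRDB_RESIDUES_URL = "https://gpcrdb.org/services/residues/{entry_name}/"


def _get(url: str, timeout: float) -> bytes:
    req = urllib.request.Request(url, headers={"User-Agent": "gpcrpocket"})
    with urllib.request.urlopen(req, timeout=timeout) as resp:
        return resp.read()


def fetch_pdb(pdb_id: str, timeout: float = 15.0) -> str:
    """Download a PDB entry as PDB-format text."""
    pdb_id = pdb_id.strip().upper()
    if len(pdb_id) != 4:
        raise FormatError(f"not a PDB id: {pdb_id!r}")
    return _get(RCSB_URL.format(pdb_id=pdb_id), timeout).decode()


def fetch_gpcrdb_residue_map(
    entry_name: str, chain: str = "A", timeout: float = 15.0
) -> ResidueMap:
    """Build a ResidueMap from GPCRdb's residue-numbering service.

    ``entry_name`` is the GPCRdb protein slug (e.g. ``opsd_bovin``).
    GPCRdb reports generic numbers against UniProt sequence positions,
    which for most crystallographic GPCR entries coincide with the
    author numbering of the receptor chain; supply ``chain`` to match
    the structure being analyzed.
    """
    raw = _get(GPCRDB_RESIDUES_URL.format(entry_name=entry_name.lower()), timeout)
    rows = json.loads(raw)
    entries: dict[GenericResidueID, tuple[str, int, str]] = {}
    for row in rows:
        token = row.get("display_generic_number")
        if not token:
            continue
        try:
            gid = parse_generic_id(str(token))
        except FormatError:
            continue  # non class-A style tokens
        entries[gid] = (chain, int(row["sequence_number"]), "")
    if not entries:
        raise FormatError(f"no generic numbers returned for {entry_name!r}")
    return ResidueMap(receptor=entry_name, entries=entries)
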