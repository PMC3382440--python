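"""Protein structure ingestion and the atom-name sequence view.

A protein chain is held as an ordered list of atom records exactly as they
appear in the PDB file (first model, one chain, altlocs resolved).  The
atom-name sequence — the string of tokens ``N CA C O CB ...`` over the whole
chain — is the operand of the atom-level local alignment stage: in PDB files
every residue lists its atoms in the conventional order N, CA, C, O followed
by the side chain in order of increasing remoteness, so the chain's atom
names form a well-defined sequence over the atom-name alphabet.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ProteinStructure",
    "AtomSequence",
    "PDBReadError",
    "NoAtomRecordsError",
    "ChainNotFoundError",
    "EmptyStructureError",
    "read_pdb",
    "extract_atom_sequence",
]


class PDBReadError(ValueError):
    """Base class for structure-ingestion failures."""


class NoAtomRecordsError(PDBReadError):
    """The file contains no usable ATOM records."""


class ChainNotFoundError(PDBReadError):
    """The requested chain id is absent from the file."""


class EmptyStructureError(ValueError):
    """An operation received a structure with no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a protein chain.

    ``name`` is the full PDB atom-name token (``"CG1"`` is distinct from
    ``"CG2"``); ``residue_number`` is the author numbering, preserved exactly.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    coord: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not all(np.isfinite(self.coord)):
            raise ValueError(f"non-finite coordinate for atom {self.name}")

    @property
    def residue_key(self) -> tuple[int, str]:
        return (self.residue_number, self.insertion_code)


@dataclass
class ProteinStructure:
    """An ordered single-chain atom model.

    Atoms appear in file order; after altloc resolution no
    (residue_number, insertion_code, name) triple occurs twice.
    """

    id: str
    atoms: list[AtomRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise EmptyStructureError(f"structure {self.id!r} has no atoms")
        seen: set[tuple[int, str, str]] = set()
        for a in self.atoms:
            key = (a.residue_number, a.insertion_code, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom {key} in {self.id!r}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """All atom coordinates as an (n, 3) float array, Angstrom."""
        return np.array([a.coord for a in self.atoms], dtype=float)

    def residue_numbers(self) -> list[int]:
        return [a.residue_number for a in self.atoms]


@dataclass
class AtomSequence:
    """The atom-name token sequence of a structure.

    ``atom_index[k]`` maps token position k back to the atom's index in the
    source structure; it is strictly increasing.
    """

    tokens: list[str]
    atom_index: list[int]

    def __post_init__(self) -> None:
        if len(self.tokens) != len(self.atom_index):
            raise ValueError("tokens and atom_index length mismatch")

    def __len__(self) -> int:
        return len(self.tokens)


def _element_from_name(name: str) -> str:
    # PDB atom names start with the element; two-letter elements are rare in
    # polymers, so fall back to the first alphabetic character.
    stripped = name.strip("0123456789'\"")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Fe", "Zn", "Mg", "Se", "Cl", "Br"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def read_pdb(
    path: str | os.PathLike,
    chain: str | None = None,
    *,
    keep_hydrogens: bool = False,
    keep_hetatm: bool = False,
) -> ProteinStructure:
    """Read one chain of a PDB file into a :class:`ProteinStructure`.

    Only the first model is used.  Alternate locations are resolved to the
    highest-occupancy conformer (ties: first encountered).  Hydrogens and
    HETATM records are excluded unless the corresponding flag is set.

    Parameters
    ----------
    path:
        PDB file (ATOM/HETATM records, wwPDB v3.3 columns).
    chain:
        Chain id to select; ``None`` selects the first chain that has
        ATOM records.

    Raises
    ------
    FileNotFoundError
        If *path* does not exist.
    NoAtomRecordsError
        If the file holds no usable ATOM records.
    ChainNotFoundError
        If *chain* is given but absent.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    st = gemmi.read_pdb(path)
    if len(st) == 0:
        raise NoAtomRecordsError(f"no models in {path}")
    model = st[0]

    chain_ids = [ch.name for ch in model]
    if chain is not None and chain not in chain_ids:
        raise ChainNotFoundError(f"chain {chain!r} not in {path} (has {chain_ids})")

    atoms: list[AtomRecord] = []
    selected_chain: str | None = chain
    serial = 0
    for ch in model:
        if selected_chain is not None and ch.name != selected_chain:
            continue
        for res in ch:
            is_het = res.het_flag == "H"
            if is_het and not keep_hetatm:
                continue
            # resolve altlocs: group by atom name, keep highest occupancy
            best: dict[str, gemmi.Atom] = {}
            order: list[str] = []
            for at in res:
                if not keep_hydrogens and at.element.is_hydrogen:
                    continue
                if at.name not in best:
                    best[at.name] = at
                    order.append(at.name)
                elif at.occ > best[at.name].occ:
                    best[at.name] = at
            for name in order:
                at = best[name]
                serial += 1
                element = at.element.name if at.element.name not in ("", "X") else _element_from_name(at.name)
                atoms.append(
                    AtomRecord(
                        serial=serial,
                        name=at.name,
                        element=element,
                        residue_name=res.name,
                        residue_number=res.seqid.num,
                        insertion_code=(res.seqid.icode or "").strip(),
                        chain_id=ch.name,
                        coord=(at.pos.x, at.pos.y, at.pos.z),
                    )
                )
        if atoms and selected_chain is None:
            selected_chain = ch.name
        if selected_chain is not None and atoms:
            break

    if not atoms:
        raise NoAtomRecordsError(f"no ATOM records for chain {chain!r} in {path}")

    pdb_id = os.path.splitext(os.path.basename(path))[0].upper()
    struct_id = f"{pdb_id}{selected_chain}" if selected_chain else pdb_id
    return ProteinStructure(
        id=struct_id,
        atoms=atoms,
        provenance={
            "path": path,
            "chain": selected_chain,
            "keep_hydrogens": keep_hydrogens,
            "keep_hetatm": keep_hetatm,
        },
    )


def extract_atom_sequence(structure: ProteinStructure) -> AtomSequence:
    """Translate a structure into its sequence of atom-name tokens."""
    if not structure.atoms:
        raise EmptyStructureError(f"structure {structure.id!r} is empty")
    return AtomSequence(
        tokens=[a.name for a in structure.atoms],
        atom_index=list(range(len(structure.atoms))),
    )
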