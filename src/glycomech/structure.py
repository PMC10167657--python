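"""Reading protein/carbohydrate structures and addressing atoms.

PDB and mmCIF files are parsed with gemmi; the result is flattened into a
simple ordered list of :class:`AtomRecord` so downstream geometry code never
has to walk a model/chain/residue hierarchy.  Ligand HETATM residues (e.g.
the glucosyl units of cellobiose or laminaribiose) are first-class residues
addressable by chain and residue number, exactly like amino acids.

By default only model 1 is loaded: the crystal structures this package
targets are single-model.  Alternate locations default to the
highest-occupancy copy, with ties broken toward alt-loc 'A'.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import gemmi

__all__ = [
    "AtomRecord",
    "Structure",
    "SelectionSpec",
    "AltLocPolicy",
    "StructureError",
    "AtomNotFoundError",
    "read_structure",
    "select_atoms",
    "write_pdb",
]


class StructureError(ValueError):
    """Unreadable file, empty structure, or invalid selection."""


class AtomNotFoundError(StructureError, KeyError):
    """A requested atom does not exist in the structure."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return ValueError.__str__(self)


class AltLocPolicy(str, enum.Enum):
    FIRST = "first"
    HIGHEST_OCCUPANCY = "highest-occupancy"


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    alt_loc: str          # '' if no alternate location
    res_name: str
    res_seq: int
    chain: str
    position: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    model: int = 1
    icode: str = ""       # insertion code, '' if none
    het: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"invalid position for atom {self.name}")
        object.__setattr__(self, "position", pos)


@dataclass
class Structure:
    """Ordered atom collection with deterministic (chain, res_seq, name) lookup."""

    atoms: list[AtomRecord]
    identifier: str = ""
    source_format: str = ""
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.atoms:
            raise StructureError("structure contains no atoms")
        self._index = {}
        for a in self.atoms:
            self._index.setdefault((a.chain, a.res_seq, a.name), []).append(a)

    def __len__(self) -> int:
        return len(self.atoms)

    def find(
        self,
        chain: str,
        res_seq: int,
        name: str,
        alt_loc_policy: AltLocPolicy = AltLocPolicy.HIGHEST_OCCUPANCY,
    ) -> AtomRecord:
        """Return the unique atom at (chain, res_seq, name), resolving alt-locs."""
        cands = self._index.get((chain, res_seq, name))
        if not cands:
            raise AtomNotFoundError(
                f"atom {name!r} not found in chain {chain!r} residue {res_seq}"
            )
        if len(cands) == 1:
            return cands[0]
        if alt_loc_policy is AltLocPolicy.FIRST:
            return cands[0]
        # highest occupancy; ties go to the lexicographically first alt-loc ('A')
        return max(cands, key=lambda a: (a.occupancy, _altloc_rank(a.alt_loc)))

    def residue_atoms(self, chain: str, res_seq: int) -> list[AtomRecord]:
        out = [a for a in self.atoms if a.chain == chain and a.res_seq == res_seq]
        if not out:
            raise AtomNotFoundError(f"residue {res_seq} not found in chain {chain!r}")
        return out

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain)
        return list(seen)


def _altloc_rank(alt: str) -> float:
    # larger is preferred; '' beats everything, then 'A' > 'B' > ...
    if alt == "":
        return 1000.0
    return -ord(alt)


@dataclass(frozen=True)
class SelectionSpec:
    """Which atoms to pull from a structure, and in what order."""

    atom_names: tuple[str, ...]
    chain: str | None = None
    res_seq: int | None = None
    res_name: str | None = None
    alt_loc_policy: AltLocPolicy = AltLocPolicy.HIGHEST_OCCUPANCY

    def __post_init__(self):
        if not self.atom_names and self.chain is None and self.res_seq is None \
                and self.res_name is None:
            raise StructureError("SelectionSpec must set at least one criterion")


_FORMAT_MAP = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path: str | Path, format: str = "auto", model: int = 1) -> Structure:
    """Parse a PDB or mmCIF file into a flat :class:`Structure`.

    Parameters
    ----------
    path : file path
    format : "pdb", "mmcif" or "auto" (detect from contents/extension)
    model : which model to load (1-based); crystal structures have one.
    """
    path = Path(path)
    if format not in _FORMAT_MAP:
        raise StructureError(f"unknown format {format!r}")
    try:
        st = gemmi.read_structure(str(path), format=_FORMAT_MAP[format])
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureError(f"cannot read {path}: {exc}") from exc
    st.setup_entities()
    atoms: list[AtomRecord] = []
    for imodel, mod in enumerate(st, start=1):
        if imodel != model:
            continue
        for chain in mod:
            for res in chain:
                for atom in res:
                    atoms.append(
                        AtomRecord(
                            serial=atom.serial,
                            name=atom.name,
                            element=atom.element.name,
                            alt_loc=atom.altloc if atom.altloc != "\x00" else "",
                            res_name=res.name,
                            res_seq=res.seqid.num,
                            chain=chain.name,
                            position=np.array(
                                [atom.pos.x, atom.pos.y, atom.pos.z]
                            ),
                            occupancy=atom.occ,
                            model=imodel,
                            icode=res.seqid.icode.strip(),
                            het=res.het_flag == "H",
                        )
                    )
    if not atoms:
        raise StructureError(f"no atoms in model {model} of {path}")
    return Structure(atoms=atoms, identifier=st.name or path.stem,
                     source_format=format)


def select_atoms(s: Structure, spec: SelectionSpec) -> list[AtomRecord]:
    """Return atoms matching ``spec``, ordered as ``spec.atom_names``.

    A missing atom raises :class:`AtomNotFoundError` naming it.
    """
    pool = s.atoms
    if spec.chain is not None:
        pool = [a for a in pool if a.chain == spec.chain]
    if spec.res_seq is not None:
        pool = [a for a in pool if a.res_seq == spec.res_seq]
    if spec.res_name is not None:
        pool = [a for a in pool if a.res_name == spec.res_name]
    out: list[AtomRecord] = []
    for name in spec.atom_names:
        cands = [a for a in pool if a.name == name]
        if not cands:
            raise AtomNotFoundError(
                f"atom {name!r} not found "
                f"(chain={spec.chain!r}, res_seq={spec.res_seq}, "
                f"res_name={spec.res_name!r})"
            )
        if len(cands) > 1:
            alts = {a.alt_loc for a in cands}
            if alts == {""}:
                raise StructureError(
                    f"ambiguous selection for atom {name!r}: "
                    f"{len(cands)} matches without alt-loc to disambiguate"
                )
            if spec.alt_loc_policy is AltLocPolicy.FIRST:
                out.append(cands[0])
            else:
                out.append(max(cands,
                               key=lambda a: (a.occupancy, _altloc_rank(a.alt_loc))))
        else:
            out.append(cands[0])
    return out


def write_pdb(atoms: Iterable[AtomRecord] | Structure, path: str | Path,
              identifier: str = "SYNTH") -> Path:
    """Write atoms as a minimal single-model PDB file (fixture output).

    Residues with ``het=True`` become HETATM records.  Coordinates are
    written at the format's 3-decimal precision.
    """
    if isinstance(atoms, Structure):
        records: Sequence[AtomRecord] = atoms.atoms
    else:
        records = list(atoms)
    st = gemmi.Structure()
    st.name = identifier
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    residues: dict[tuple, gemmi.Residue] = {}
    for rec in records:
        ch = chains.get(rec.chain)
        if ch is None:
            ch = gemmi.Chain(rec.chain)
            chains[rec.chain] = ch
            model.add_chain(ch)
            ch = model[rec.chain]
            chains[rec.chain] = ch
        key = (rec.chain, rec.res_seq, rec.res_name)
        res = residues.get(key)
        if res is None:
            res = gemmi.Residue()
            res.name = rec.res_name
            res.seqid = gemmi.SeqId(rec.res_seq, rec.icode or " ")
            res.het_flag = "H" if rec.het else "A"
            ch.add_residue(res)
            res = ch[-1]
            residues[key] = res
        atom = gemmi.Atom()
        atom.name = rec.name
        atom.element = gemmi.Element(rec.element)
        atom.pos = gemmi.Position(*rec.position)
        atom.occ = rec.occupancy
        atom.altloc = rec.alt_loc or "\x00"
        atom.serial = rec.serial
        res.add_atom(atom)
    st.add_model(model)
    path = Path(path)
    st.write_pdb(str(path))
    return path
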