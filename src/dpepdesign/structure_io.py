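"""Reading, writing and slicing molecular structures.

File I/O is delegated to gemmi (PDB and mmCIF); the rest of the package
works on the lightweight record types defined here. Coordinates are numpy
arrays in Angstrom. Residue numbering follows the author seq ids in the
file, 1-based with inclusive ranges, matching the conventional H1..I31
labelling of peptide positions.

Alternate locations are resolved to a single atom per (residue, name):
highest occupancy wins, ties broken alphabetically by altloc id. HETATM
residues are excluded by default. Insertion codes are rejected — the
intended inputs are simple peptide chains.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

from .errors import InsertionCodeError, SegmentGapError, StructureParseError

__all__ = [
    "AtomRecord",
    "ResidueRecord",
    "StructureModel",
    "Segment",
    "read_structure",
    "extract_segment",
    "write_structure",
    "D_RESIDUE_CODES",
]

#: PDB chemical-component codes for the D-enantiomers of the standard amino
#: acids, used when writing with ``d_naming="prefixed"``. Glycine is achiral.
D_RESIDUE_CODES = {
    "ALA": "DAL", "ARG": "DAR", "ASN": "DSG", "ASP": "DAS", "CYS": "DCY",
    "GLN": "DGN", "GLU": "DGL", "HIS": "DHI", "ILE": "DIL", "LEU": "DLE",
    "LYS": "DLY", "MET": "MED", "PHE": "DPN", "PRO": "DPR", "SER": "DSN",
    "THR": "DTH", "TRP": "DTR", "TYR": "DTY", "VAL": "DVA",
}


@dataclass
class AtomRecord:
    name: str
    element: str
    coords: np.ndarray  # (3,) Angstrom
    occupancy: float = 1.0
    serial: int = 0

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")

    def copy(self) -> "AtomRecord":
        return replace(self, coords=np.array(self.coords, dtype=float))


@dataclass
class ResidueRecord:
    res_name: str
    seq_id: int
    chain_id: str
    atoms: list[AtomRecord] = field(default_factory=list)
    handedness_flag: str = "unknown"  # one of L, D, achiral, unknown

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, names) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)

    def copy(self) -> "ResidueRecord":
        return ResidueRecord(
            res_name=self.res_name,
            seq_id=self.seq_id,
            chain_id=self.chain_id,
            atoms=[a.copy() for a in self.atoms],
            handedness_flag=self.handedness_flag,
        )


@dataclass
class StructureModel:
    entry_id: str
    chains: dict[str, list[ResidueRecord]] = field(default_factory=dict)
    source_path: str = ""

    def chain(self, chain_id: str) -> list[ResidueRecord]:
        if chain_id not in self.chains:
            raise KeyError(f"no chain {chain_id!r} in {self.entry_id!r} (have {sorted(self.chains)})")
        return self.chains[chain_id]

    def iter_residues(self):
        for chain_id in self.chains:
            yield from self.chains[chain_id]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.iter_residues())

    def copy(self) -> "StructureModel":
        return StructureModel(
            entry_id=self.entry_id,
            chains={c: [r.copy() for r in rs] for c, rs in self.chains.items()},
            source_path=self.source_path,
        )


@dataclass
class Segment:
    """A contiguous residue range of one chain (inclusive, author numbering)."""

    parent: StructureModel
    chain_id: str
    start_seq_id: int
    end_seq_id: int
    residues: list[ResidueRecord]

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, seq_id: int) -> ResidueRecord:
        return self.residues[seq_id - self.start_seq_id]


def _resolve_altlocs(raw_atoms) -> list[AtomRecord]:
    """Collapse altloc variants: per atom name keep highest occupancy, ties
    broken alphabetically by altloc id; blank altloc sorts first."""
    by_name: dict[str, list] = {}
    order: list[str] = []
    for atom, altloc in raw_atoms:
        if atom.name not in by_name:
            by_name[atom.name] = []
            order.append(atom.name)
        by_name[atom.name].append((atom, altloc))
    out = []
    for name in order:
        variants = by_name[name]
        best = min(variants, key=lambda av: (-av[0].occ, av[1]))
        atom = best[0]
        out.append(
            AtomRecord(
                name=atom.name,
                element=atom.element.name,
                coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float),
                occupancy=float(atom.occ),
                serial=int(atom.serial),
            )
        )
    return out


def read_structure(path: str | os.PathLike, model_index: int = 0, include_hetatm: bool = False) -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    Keeps one atom per (residue, name) after altloc resolution; hydrogens are
    retained (flagged via :attr:`AtomRecord.is_hydrogen`); HETATM residues are
    excluded unless ``include_hetatm``.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise StructureParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"failed to parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureParseError(f"{path}: file contains no models")
    if not (0 <= model_index < len(st)):
        raise StructureParseError(
            f"{path}: model_index {model_index} out of range (file has {len(st)} model(s))"
        )

    model = st[model_index]
    entry_id = st.name or os.path.splitext(os.path.basename(path))[0]
    out = StructureModel(entry_id=entry_id, source_path=path)
    for chain in model:
        residues: list[ResidueRecord] = []
        last_seq = None
        for res in chain:
            if res.het_flag == "H" and not include_hetatm:
                continue
            icode = res.seqid.icode
            if icode not in (" ", "", "\x00"):
                raise InsertionCodeError(
                    f"{path}: residue {chain.name}/{res.name}{res.seqid.num}{icode.strip()} "
                    "has an insertion code; insertion codes are not supported"
                )
            seq_id = int(res.seqid.num)
            if last_seq is not None and seq_id <= last_seq:
                raise StructureParseError(
                    f"{path}: chain {chain.name!r} residue numbering not strictly "
                    f"increasing at {res.name}{seq_id}"
                )
            last_seq = seq_id
            raw = [(a, a.altloc if a.altloc not in ("\x00",) else "") for a in res]
            atoms = _resolve_altlocs(raw)
            if not all(np.all(np.isfinite(a.coords)) for a in atoms):
                raise StructureParseError(f"{path}: non-finite coordinates in {res.name}{seq_id}")
            residues.append(
                ResidueRecord(res_name=res.name, seq_id=seq_id, chain_id=chain.name, atoms=atoms)
            )
        if residues:
            out.chains[chain.name] = residues
    if not out.chains:
        raise StructureParseError(f"{path}: no polymer residues found")
    return out


def extract_segment(s: StructureModel, chain_id: str, start_seq_id: int, end_seq_id: int) -> Segment:
    """Slice the inclusive residue range [start, end] out of one chain.

    The range must be contiguous in author numbering; missing seq ids raise
    :class:`SegmentGapError` listing them.
    """
    if start_seq_id > end_seq_id:
        raise ValueError(f"start_seq_id {start_seq_id} > end_seq_id {end_seq_id}")
    chain = s.chain(chain_id)
    by_seq = {r.seq_id: r for r in chain}
    wanted = range(start_seq_id, end_seq_id + 1)
    missing = [i for i in wanted if i not in by_seq]
    if missing:
        raise SegmentGapError(chain_id, missing)
    return Segment(
        parent=s,
        chain_id=chain_id,
        start_seq_id=start_seq_id,
        end_seq_id=end_seq_id,
        residues=[by_seq[i] for i in wanted],
    )


def _to_gemmi(s: StructureModel, d_naming: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = s.entry_id
    model = gemmi.Model("1")
    serial = 0
    for chain_id, residues in s.chains.items():
        chain = gemmi.Chain(chain_id)
        for r in residues:
            name = r.res_name
            if d_naming == "prefixed" and r.handedness_flag == "D":
                name = D_RESIDUE_CODES.get(name, name)
            res = gemmi.Residue()
            res.name = name
            res.seqid = gemmi.SeqId(r.seq_id, " ")
            res.het_flag = "A"
            for a in r.atoms:
                if not np.all(np.isfinite(a.coords)):
                    raise ValueError(f"non-finite coordinates on {r.res_name}{r.seq_id}/{a.name}")
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*[float(x) for x in a.coords])
                atom.occ = float(a.occupancy)
                serial += 1
                atom.serial = serial
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_structure(s: StructureModel, path: str | os.PathLike, d_naming: str = "plain") -> None:
    """Write a PDB file.

    ``d_naming``: "plain" keeps the parent 3-letter codes (handedness lives in
    the metadata flag); "prefixed" writes PDB D-component codes (DAL, DPN, ...)
    for residues flagged D, for downstream tools that need explicit chirality.
    """
    if d_naming not in ("plain", "prefixed"):
        raise ValueError(f"d_naming must be 'plain' or 'prefixed', got {d_naming!r}")
    if not s.chains or s.n_atoms() == 0:
        raise ValueError("refusing to write an empty structure")
    st = _to_gemmi(s, d_naming)
    try:
        st.write_pdb(os.fspath(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"could not write {path}: {exc}") from exc
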