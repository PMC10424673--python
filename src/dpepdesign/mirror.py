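"""Mirror-image (d-PDB) transform and chirality bookkeeping.

Reflecting a structure through a plane is an isometry with determinant -1:
all internal distances, angles and covalent geometry are preserved exactly
while every chiral centre inverts, turning L-amino acids into D-amino acids.
Applying the same reflection twice is the identity. Which plane is used is
irrelevant up to a proper rotation; xy (negate z) is the fixed default for
reproducibility.

Handedness is called from the signed volume det[N-CA, C-CA, CB-CA] of each
residue: positive for L, negative for D in the convention used throughout
this package, with glycine achiral and residues missing any of the four
atoms reported as indeterminate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import ResidueRecord, StructureModel

__all__ = [
    "MIRROR_PLANES",
    "ChiralityReport",
    "mirror_structure",
    "mirror_coords",
    "chirality_sign",
    "handedness_call",
    "chirality_report",
    "fraction_flipped",
]

#: plane name -> index of the coordinate that is negated
MIRROR_PLANES = {"xy": 2, "xz": 1, "yz": 0}


def mirror_coords(coords: np.ndarray, plane: str = "xy") -> np.ndarray:
    """Reflect an (n, 3) coordinate array through the given plane."""
    if plane not in MIRROR_PLANES:
        raise ValueError(f"plane must be one of {sorted(MIRROR_PLANES)}, got {plane!r}")
    out = np.array(coords, dtype=float)
    out[..., MIRROR_PLANES[plane]] *= -1.0
    return out


def chirality_sign(r: ResidueRecord) -> float | None:
    """Signed volume (A^3) of the N/CA/C/CB tetrahedron, or None if achiral
    or indeterminate (glycine, missing atoms)."""
    if r.res_name == "GLY":
        return None
    needed = ("N", "CA", "C", "CB")
    atoms = {a.name: a.coords for a in r.atoms}
    if any(n not in atoms for n in needed):
        return None
    ca = atoms["CA"]
    m = np.stack([atoms["N"] - ca, atoms["C"] - ca, atoms["CB"] - ca])
    return float(np.linalg.det(m))


def handedness_call(r: ResidueRecord) -> str:
    """One of "L", "D", "achiral" (glycine) or "unknown" (incomplete residue)."""
    if r.res_name == "GLY":
        return "achiral"
    sign = chirality_sign(r)
    if sign is None:
        return "unknown"
    return "L" if sign > 0 else "D"


@dataclass
class ChiralityReport:
    entry_id: str
    signed_volumes: dict[tuple[str, int], float | None]  # (chain_id, seq_id) -> volume
    calls: dict[tuple[str, int], str]

    def chiral_keys(self) -> list[tuple[str, int]]:
        return [k for k, v in self.signed_volumes.items() if v is not None]


def chirality_report(s: StructureModel) -> ChiralityReport:
    volumes: dict[tuple[str, int], float | None] = {}
    calls: dict[tuple[str, int], str] = {}
    for r in s.iter_residues():
        key = (r.chain_id, r.seq_id)
        volumes[key] = chirality_sign(r)
        calls[key] = handedness_call(r)
    return ChiralityReport(entry_id=s.entry_id, signed_volumes=volumes, calls=calls)


def fraction_flipped(before: ChiralityReport, after: ChiralityReport) -> float:
    """Fraction of chiral residues whose signed volume changed sign between
    two reports of the same structure (glycine and indeterminate excluded)."""
    keys = [k for k in before.chiral_keys() if k in after.signed_volumes and after.signed_volumes[k] is not None]
    if not keys:
        return 0.0
    flipped = sum(
        1 for k in keys if before.signed_volumes[k] * after.signed_volumes[k] < 0
    )
    return flipped / len(keys)


def mirror_structure(s: StructureModel, plane: str = "xy") -> StructureModel:
    """Return the mirror image of a structure.

    Every atom's coordinate component normal to ``plane`` is negated;
    handedness flags are swapped L <-> D (glycine keeps "achiral").
    """
    if not s.chains:
        raise ValueError("cannot mirror an empty structure")
    out = s.copy()
    idx = MIRROR_PLANES.get(plane)
    if idx is None:
        raise ValueError(f"plane must be one of {sorted(MIRROR_PLANES)}, got {plane!r}")
    flip = {"L": "D", "D": "L"}
    for r in out.iter_residues():
        for a in r.atoms:
            a.coords[idx] *= -1.0
        if r.res_name == "GLY":
            r.handedness_flag = "achiral"
        elif r.handedness_flag in flip:
            r.handedness_flag = flip[r.handedness_flag]
        else:
            r.handedness_flag = handedness_call(r)
    return out
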