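"""Hotspot definition and combinatorial query generation.

A query is a small labelled constellation of atoms taken from the hotspot
residues of one scaffold segment. Each hotspot contributes one of several
"atom levels" — nested subsets running from the CA alone, through CA+CB,
up to CA+CB plus residue-specific side-chain tip atoms — and one query is
emitted per element of the Cartesian product of the per-hotspot levels.
Varying the level trades positional specificity (more atoms pin the side
chain) against retrievability (fewer atoms match more database fragments).

The default scheme gives 4 levels to histidine (whose imidazole supports a
full five-atom ring anchor) and 3 to the other hotspot-capable residue
types, so a segment with hotspots {His, X, Y} yields 4*3*3 = 36 queries and
one with three non-His hotspots yields 27.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import HotspotValidationError, SchemeError
from .structure_io import Segment

__all__ = [
    "HotspotSpec",
    "HotspotSet",
    "AtomLevelScheme",
    "QueryStructure",
    "default_scheme",
    "define_hotspots",
    "enumerate_queries",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
]

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: residue-specific side-chain "tip" atoms used by level 3 of the default
#: scheme: two atoms that fix the orientation of the functional end group.
DEFAULT_TIP_ATOMS = {
    "PHE": ("CG", "CZ"),
    "TRP": ("CG", "CH2"),
    "ASP": ("CG", "OD1"),
    "GLU": ("CD", "OE1"),
    "LEU": ("CG", "CD1"),
    "HIS": ("CG", "NE2"),
}


@dataclass(frozen=True)
class HotspotSpec:
    """A hotspot residue named by scaffold position and expected identity."""

    seq_id: int
    res_name: str
    rationale: str = ""


@dataclass
class HotspotSet:
    segment: Segment
    hotspots: list[HotspotSpec]  # ordered by seq_id

    def __len__(self) -> int:
        return len(self.hotspots)


@dataclass
class AtomLevelScheme:
    """Per-residue-type atom levels; ``levels_for`` resolves a hotspot to its
    ordered list of atom-name tuples."""

    overrides: dict[str, list[tuple[str, ...]]] = field(default_factory=dict)

    def levels_for(self, res_name: str) -> list[tuple[str, ...]]:
        if res_name in self.overrides:
            return [tuple(l) for l in self.overrides[res_name]]
        levels: list[tuple[str, ...]] = [("CA",)]
        if res_name != "GLY":
            levels.append(("CA", "CB"))
        tip = DEFAULT_TIP_ATOMS.get(res_name)
        if tip is not None:
            levels.append(("CA", "CB") + tip)
        if res_name == "HIS":
            levels.append(("CA", "CB", "CG", "ND1", "NE2"))
        return levels


def default_scheme() -> AtomLevelScheme:
    return AtomLevelScheme()


@dataclass
class QueryStructure:
    """One atom-level combination: an ordered list of hotspot atoms with
    scaffold coordinates."""

    helix_id: str
    combo_id: tuple[int, ...]  # chosen level index per hotspot, in seq order
    atoms: list[tuple[int, str]]  # (hotspot seq_id, atom name), ordered
    coords: np.ndarray  # (n_atoms, 3)
    span_start: int
    span_end: int
    hotspot_res_names: dict[int, str] = field(default_factory=dict)  # seq_id -> 3-letter code

    @property
    def span_length(self) -> int:
        return self.span_end - self.span_start + 1

    def hotspot_seq_ids(self) -> list[int]:
        seen: list[int] = []
        for seq_id, _ in self.atoms:
            if seq_id not in seen:
                seen.append(seq_id)
        return seen

    def atoms_by_hotspot(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for seq_id, name in self.atoms:
            out.setdefault(seq_id, []).append(name)
        return out


def define_hotspots(segment: Segment, specs: list[HotspotSpec]) -> HotspotSet:
    """Validate hotspot specs against the scaffold segment.

    Each spec must name a residue inside the segment whose identity matches;
    a mismatch (e.g. expecting Phe at 6, finding Ala) is a hard error since
    it means the scaffold and the design intent disagree.
    """
    if not specs:
        raise HotspotValidationError("a segment must have at least one hotspot")
    for spec in specs:
        if not (segment.start_seq_id <= spec.seq_id <= segment.end_seq_id):
            raise HotspotValidationError(
                f"hotspot {spec.res_name}{spec.seq_id} outside segment "
                f"{segment.start_seq_id}..{segment.end_seq_id}"
            )
        found = segment.residue_at(spec.seq_id)
        if found.res_name != spec.res_name:
            raise HotspotValidationError(
                f"position {spec.seq_id}: expected {spec.res_name}, scaffold has {found.res_name}"
            )
    seq_ids = [s.seq_id for s in specs]
    if len(set(seq_ids)) != len(seq_ids):
        raise HotspotValidationError(f"duplicate hotspot positions: {seq_ids}")
    return HotspotSet(segment=segment, hotspots=sorted(specs, key=lambda s: s.seq_id))


def enumerate_queries(
    hotspots: HotspotSet,
    scheme: AtomLevelScheme | None = None,
    helix_id: str = "helix",
    min_atoms: int = 3,
) -> list[QueryStructure]:
    """Emit one query per element of the Cartesian product of per-hotspot
    atom levels, in lexicographic order of the level indices.

    Every named atom must exist on the scaffold residue; any combination
    with fewer than ``min_atoms`` atoms is rejected outright (superposition
    needs >= 3 points), never silently dropped.
    """
    scheme = scheme or default_scheme()
    seg = hotspots.segment

    per_hotspot_levels: list[list[tuple[str, ...]]] = []
    for spec in hotspots.hotspots:
        levels = scheme.levels_for(spec.res_name)
        if not levels:
            raise SchemeError(f"scheme defines no levels for {spec.res_name}")
        residue = seg.residue_at(spec.seq_id)
        for level in levels:
            missing = [n for n in level if residue.atom(n) is None]
            if missing:
                raise SchemeError(
                    f"hotspot {spec.res_name}{spec.seq_id}: scaffold residue lacks atom(s) "
                    f"{missing} required by level {level}"
                )
        per_hotspot_levels.append(levels)

    queries: list[QueryStructure] = []
    for combo in itertools.product(*(range(len(ls)) for ls in per_hotspot_levels)):
        atoms: list[tuple[int, str]] = []
        coords: list[np.ndarray] = []
        for spec, levels, level_idx in zip(hotspots.hotspots, per_hotspot_levels, combo):
            residue = seg.residue_at(spec.seq_id)
            for name in levels[level_idx]:
                atoms.append((spec.seq_id, name))
                coords.append(residue.atom(name).coords)
        if len(atoms) < min_atoms:
            raise SchemeError(
                f"combination {combo} for {helix_id} yields only {len(atoms)} atom(s); "
                f"queries need >= {min_atoms}"
            )
        queries.append(
            QueryStructure(
                helix_id=helix_id,
                combo_id=tuple(combo),
                atoms=atoms,
                coords=np.array(coords, dtype=float),
                span_start=seg.start_seq_id,
                span_end=seg.end_seq_id,
                hotspot_res_names={s.seq_id: s.res_name for s in hotspots.hotspots},
            )
        )
    return queries
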