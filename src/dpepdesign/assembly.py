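"""Splicing per-helix fragment matches into one retro-inverso D-peptide.

Each selected match is placed into the scaffold frame by the rigid
transform stored with its superposition, so its hotspot-aligned atoms
overlay the scaffold hotspots. The splice plan assigns every scaffold
position to exactly one fragment, with crossover points at the midpoints
of the segment overlaps. Because matches are read in the reverse
direction, the assembled peptide's own N-to-C order runs from the
scaffold's C-terminal end back to position 1: the D-analogue's N-terminus
corresponds to the scaffold's C-terminal region.

Junction chemistry is not rebuilt: consecutive C-N distances are measured
and flagged when outside peptide-bond range, and a steric clash count is
reported, but no minimization is performed (structure refinement belongs
to downstream MD, out of scope here).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import CoverageError
from .fragment_search import FragmentLibrary, FragmentMatch, gather_window_atoms
from .geometry import superpose
from .mirror import handedness_call, mirror_coords
from .structure_io import ResidueRecord, Segment, StructureModel

__all__ = [
    "SplicePlan",
    "ResidueProvenance",
    "AssembledPeptide",
    "default_plan",
    "place_match",
    "assemble",
    "geometry_check",
]

PEPTIDE_BOND_RANGE = (1.2, 1.5)  # Angstrom, acceptable C-N distance
CLASH_CUTOFF = 2.0  # Angstrom, non-bonded heavy-atom pair


@dataclass(frozen=True)
class SplicePlan:
    """Ordered (helix_id, scaffold_start, scaffold_end) contributions that
    partition the scaffold range without gaps."""

    contributions: tuple[tuple[str, int, int], ...]

    def __post_init__(self):
        if not self.contributions:
            raise ValueError("empty splice plan")
        prev_end = None
        for helix_id, start, end in self.contributions:
            if start > end:
                raise ValueError(f"{helix_id}: start {start} > end {end}")
            if prev_end is not None and start != prev_end + 1:
                raise ValueError(
                    f"{helix_id}: contribution starts at {start}, expected {prev_end + 1} "
                    "(contributions must tile the scaffold without gaps or overlap)"
                )
            prev_end = end

    @property
    def scaffold_range(self) -> tuple[int, int]:
        return self.contributions[0][1], self.contributions[-1][2]


def default_plan(segment_ranges: dict[str, tuple[int, int]]) -> SplicePlan:
    """Midpoint-crossover plan: each overlap [lo, hi] is cut after
    lo + ceil(n/2) - 1, ties toward the N-terminal fragment.

    For the canonical three-helix segmentation 1-14 / 7-19 / 15-31 this
    yields contributions 1-10 / 11-17 / 18-31.
    """
    items = sorted(segment_ranges.items(), key=lambda kv: (kv[1][0], kv[1][1]))
    contributions: list[tuple[str, int, int]] = []
    boundary = items[0][1][0] - 1  # last scaffold position already assigned
    for i, (helix_id, (start, end)) in enumerate(items):
        if i + 1 < len(items):
            nxt_start, nxt_end = items[i + 1][1]
            lo, hi = nxt_start, min(end, nxt_end)
            if lo > hi:
                raise ValueError(
                    f"segments {helix_id} and {items[i + 1][0]} do not overlap; "
                    "cannot place a crossover"
                )
            n = hi - lo + 1
            cut = lo + math.ceil(n / 2) - 1  # last position kept by this fragment
        else:
            cut = end
        if boundary + 1 > cut:
            raise ValueError(f"{helix_id}: empty contribution under midpoint rule")
        contributions.append((helix_id, boundary + 1, cut))
        boundary = cut
    return SplicePlan(tuple(contributions))


@dataclass(frozen=True)
class ResidueProvenance:
    helix_id: str
    entry_id: str
    chain_id: str
    source_seq_id: int  # residue numbering inside the library chain
    scaffold_seq_id: int


@dataclass
class AssembledPeptide:
    residues: list[ResidueRecord]  # the D-peptide in its own N-to-C order
    provenance: list[ResidueProvenance]  # parallel to residues
    scaffold_map: dict[int, int]  # assembled position (1-based) -> scaffold seq_id
    geometry: dict = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)  # e.g. sequence-level modifications

    def __len__(self) -> int:
        return len(self.residues)

    def to_structure(self, entry_id: str = "assembled_d_peptide", chain_id: str = "A") -> StructureModel:
        chain = []
        for i, r in enumerate(self.residues, start=1):
            c = r.copy()
            c.seq_id = i
            c.chain_id = chain_id
            chain.append(c)
        return StructureModel(entry_id=entry_id, chains={chain_id: chain})


def place_match(match: FragmentMatch, lib: FragmentLibrary, frame: str = "mirror") -> list[ResidueRecord]:
    """Return copies of the match's window residues rigidly placed against
    the scaffold, in the window's native (library) residue order.

    Two frames are offered, fitting the same hotspot correspondence:

    - ``frame="scaffold"`` applies the fit stored with the match, so the
      hotspot-aligned atoms overlay the scaffold hotspot atoms directly
      (residual = the stored match RMSD). This is the presentation frame —
      the D-analogue drawn over the parent peptide — but an exact hotspot
      fit does not extend along the rest of a helical fragment here: the
      global map that would do so is improper, which the proper-rotation
      search rightly forbids. Good for overlay figures, unsafe for splicing.
    - ``frame="mirror"`` (default) re-fits the window atoms onto the
      *mirrored* query coordinates, building the fragment in the
      mirrored-scaffold frame. There the map extending an exact hotspot fit
      along a helix is a proper dyad rotation, so fragments sharing helical
      geometry splice seamlessly and the assembled model's mirror image is
      what superposes on the scaffold. For coplanar query constellations
      (e.g. the three-CA level) the mirror-frame residual equals the stored
      match RMSD exactly; for larger atom sets it may differ (it is the
      reverse-reading fit without chirality inversion).
    """
    if frame not in ("mirror", "scaffold"):
        raise ValueError(f"frame must be 'mirror' or 'scaffold', got {frame!r}")
    try:
        residues = lib.chain(match.window.entry_id, match.window.chain_id)
    except KeyError as exc:
        raise CoverageError(f"match references a window absent from the library: {exc}") from exc
    w = match.window
    if w.start + w.length > len(residues):
        raise CoverageError(
            f"window {w} exceeds chain length {len(residues)}; library changed since search?"
        )
    if frame == "mirror":
        if match.query is None:
            raise CoverageError("match carries no query; cannot re-fit in the mirror frame")
        gathered = gather_window_atoms(match.query, w, lib)
        if isinstance(gathered, str):
            raise CoverageError(f"window no longer scoreable ({gathered}); library changed?")
        moving, _ = gathered
        sup = superpose(moving, mirror_coords(match.query.coords, lib.mirror_plane))
    else:
        sup = match.superposition
    R, t = sup.rotation, sup.translation
    placed = []
    for res in residues[w.start : w.start + w.length]:
        c = res.copy()
        for a in c.atoms:
            a.coords = R @ a.coords + t
        placed.append(c)
    return placed


def assemble(
    matches: dict[str, FragmentMatch],
    plan: SplicePlan,
    lib: FragmentLibrary,
    segments: dict[str, Segment],
    frame: str = "mirror",
) -> AssembledPeptide:
    """Splice one placed match per helix into a single D-peptide chain.

    ``segments`` gives the scaffold segment each helix's queries were built
    from (needed to map scaffold positions to window offsets). All matches
    must share one reading direction; with reverse-direction matches the
    output order is scaffold-descending.
    """
    directions = {m.window.direction for m in matches.values()}
    if len(directions) != 1:
        raise ValueError(f"matches mix directions {sorted(directions)}; refuse to splice")
    direction = directions.pop()

    for helix_id, start, end in plan.contributions:
        if helix_id not in matches:
            raise CoverageError(f"no match supplied for {helix_id}")
        if helix_id not in segments:
            raise CoverageError(f"no scaffold segment supplied for {helix_id}")
        seg = segments[helix_id]
        if start < seg.start_seq_id or end > seg.end_seq_id:
            raise CoverageError(
                f"{helix_id}: contribution {start}-{end} outside its segment "
                f"{seg.start_seq_id}-{seg.end_seq_id}"
            )

    placed = {h: place_match(matches[h], lib, frame=frame) for h in matches}

    # scaffold positions each fragment serves, in scaffold order
    per_position: list[tuple[int, str]] = []
    for helix_id, start, end in plan.contributions:
        per_position.extend((p, helix_id) for p in range(start, end + 1))
    if direction == "reverse":
        per_position = per_position[::-1]

    residues: list[ResidueRecord] = []
    provenance: list[ResidueProvenance] = []
    scaffold_map: dict[int, int] = {}
    for out_idx, (p, helix_id) in enumerate(per_position, start=1):
        seg = segments[helix_id]
        w = matches[helix_id].window
        offset = p - seg.start_seq_id
        widx = offset if direction == "forward" else w.length - 1 - offset
        res = placed[helix_id][widx]
        out = res.copy()
        out.seq_id = out_idx
        residues.append(out)
        provenance.append(
            ResidueProvenance(
                helix_id=helix_id,
                entry_id=w.entry_id,
                chain_id=w.chain_id,
                source_seq_id=res.seq_id,
                scaffold_seq_id=p,
            )
        )
        scaffold_map[out_idx] = p

    peptide = AssembledPeptide(
        residues=residues, provenance=provenance, scaffold_map=scaffold_map
    )
    peptide.annotations["frame"] = frame
    peptide.geometry = geometry_check(peptide)
    peptide.geometry["scaffold_ca_rmsd"] = _scaffold_ca_rmsd(
        peptide, segments, lib.mirror_plane, frame
    )
    return peptide


def _scaffold_ca_rmsd(
    p: AssembledPeptide,
    segments: dict[str, Segment],
    mirror_plane: str,
    frame: str,
) -> float | None:
    """CA RMSD between the assembled model and the scaffold after optimal
    superposition, pairing residues through the scaffold map.

    In the mirror frame the assembled CAs are reflected back first, so the
    number reported is always "how well does the D-analogue (viewed in the
    scaffold's world) retrace the parent backbone"."""
    by_seq = {}
    for seg in segments.values():
        for r in seg.residues:
            by_seq[r.seq_id] = r
    asm_ca, sc_ca = [], []
    for i, r in enumerate(p.residues, start=1):
        a = r.atom("CA")
        sc = by_seq.get(p.scaffold_map[i])
        b = sc.atom("CA") if sc is not None else None
        if a is not None and b is not None:
            asm_ca.append(a.coords)
            sc_ca.append(b.coords)
    if len(asm_ca) < 3:
        return None
    asm_arr = np.array(asm_ca)
    if frame == "mirror":
        asm_arr = mirror_coords(asm_arr, mirror_plane)
    return superpose(asm_arr, np.array(sc_ca)).rmsd


def geometry_check(p: AssembledPeptide) -> dict:
    """Per-junction C-N distances, steric clash count, handedness audit.

    Report only; nothing raises. "Junctions" between residues sourced from
    different fragments are listed separately from within-fragment bonds.
    """
    lo, hi = PEPTIDE_BOND_RANGE
    bonds = []
    for i in range(len(p.residues) - 1):
        c = p.residues[i].atom("C")
        n = p.residues[i + 1].atom("N")
        dist = float(np.linalg.norm(c.coords - n.coords)) if (c and n) else None
        is_junction = p.provenance[i].helix_id != p.provenance[i + 1].helix_id
        bonds.append(
            {
                "position": i + 1,
                "between": [p.provenance[i].helix_id, p.provenance[i + 1].helix_id],
                "c_n_distance": dist,
                "is_junction": is_junction,
                "ok": dist is not None and lo <= dist <= hi,
            }
        )

    # clash scan over heavy atoms, excluding intra-residue pairs and the
    # backbone C(i)-N(i+1) bonded pair
    coords, owner, names = [], [], []
    for i, r in enumerate(p.residues):
        for a in r.atoms:
            if a.is_hydrogen:
                continue
            coords.append(a.coords)
            owner.append(i)
            names.append(a.name)
    clashes = 0
    if coords:
        arr = np.array(coords)
        tree = cKDTree(arr)
        for ia, ib in tree.query_pairs(CLASH_CUTOFF):
            ra, rb = owner[ia], owner[ib]
            if ra == rb:
                continue
            if abs(ra - rb) == 1:
                lo_i, hi_i = (ia, ib) if ra < rb else (ib, ia)
                if names[lo_i] == "C" and names[hi_i] == "N":
                    continue
            clashes += 1

    calls = [handedness_call(r) for r in p.residues]
    chiral_calls = [c for c in calls if c in ("L", "D")]
    return {
        "n_residues": len(p.residues),
        "bonds": bonds,
        "junction_violations": [b for b in bonds if b["is_junction"] and not b["ok"]],
        "clash_count": clashes,
        "handedness": {
            "calls": calls,
            "uniform": len(set(chiral_calls)) <= 1,
            "dominant": chiral_calls[0] if chiral_calls else None,
        },
    }
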