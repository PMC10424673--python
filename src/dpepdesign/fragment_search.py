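"""Mirror-library fragment search: window enumeration, superposition
scoring and RMSD-ranked profiles.

The library holds mirror images of the input chains (the d-PDB idea: an
L-query matched into a mirrored database retrieves fragments that, read
back in the real world, are D-peptides mimicking the query). Scanning is a
linear pass over all contiguous residue windows of query-span length, in
the forward and/or reverse reading direction. Reverse reading is what makes
the retrieved D-fragment a *retro*-inverso mimic: the hotspot at span
offset i is compared against the window residue at offset length-1-i, so
the fragment's own N-to-C direction runs antiparallel to the scaffold's.

Correspondence is by atom role (CA<->CA, CB<->CB, tip<->tip, same names);
a window lacking a required atom is skipped and counted, as is a window
failing the optional residue-identity filter. Scores are minimal RMSDs
over proper rotations only — allowing reflections would silently undo the
mirror and defeat the search.

Across the 27-36 atom-level variants of one helix the per-window score is
the minimum over all queries (min-RMSD pooling), so a window is ranked by
the best way any variant can be placed onto it.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import DegenerateGeometryError, NoMatchesError
from .geometry import Superposition, superpose
from .mirror import handedness_call, mirror_structure
from .query_builder import QueryStructure
from .structure_io import ResidueRecord, StructureModel

__all__ = [
    "FragmentLibrary",
    "FragmentWindow",
    "FragmentMatch",
    "RMSDProfile",
    "SkipLog",
    "build_library",
    "enumerate_windows",
    "score_window",
    "gather_window_atoms",
    "search",
    "helix_filter",
]

logger = logging.getLogger(__name__)

DIRECTIONS = ("forward", "reverse")


@dataclass
class FragmentLibrary:
    """Mirrored chains indexed by (entry_id, chain_id)."""

    entries: list[tuple[str, str, list[ResidueRecord]]] = field(default_factory=list)
    mirror_plane: str = "xy"
    dropped_chains: int = 0

    def chain(self, entry_id: str, chain_id: str) -> list[ResidueRecord]:
        for eid, cid, residues in self.entries:
            if eid == entry_id and cid == chain_id:
                return residues
        raise KeyError(f"no chain ({entry_id!r}, {chain_id!r}) in library")

    def chain_lengths(self) -> dict[tuple[str, str], int]:
        return {(eid, cid): len(res) for eid, cid, res in self.entries}


@dataclass(frozen=True)
class FragmentWindow:
    entry_id: str
    chain_id: str
    start: int  # 0-based offset within the chain
    length: int
    direction: str  # "forward" | "reverse"

    def sort_key(self):
        return (self.entry_id, self.chain_id, self.start, self.direction)


@dataclass
class FragmentMatch:
    combo_id: tuple[int, ...]
    window: FragmentWindow
    superposition: Superposition
    matched_residues: tuple[str, ...]  # residue names at hotspot-aligned positions
    query: QueryStructure | None = None  # the variant that produced this score

    @property
    def rmsd(self) -> float:
        return self.superposition.rmsd


@dataclass
class RMSDProfile:
    """Ranked best matches for one helix, ascending RMSD, capped at top_k."""

    helix_id: str
    matches: list[FragmentMatch]
    top_k: int
    n_windows_scored: int = 0
    skip_histogram: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.matches)

    def best(self) -> FragmentMatch:
        return self.matches[0]


@dataclass
class SkipLog:
    counts: Counter = field(default_factory=Counter)

    def skip(self, reason: str) -> None:
        self.counts[reason] += 1


def build_library(
    structures: Iterable[StructureModel],
    min_chain_length: int,
    mirror_plane: str = "xy",
) -> FragmentLibrary:
    """Mirror every chain and index those long enough to hold a window.

    Chains shorter than ``min_chain_length`` are dropped (counted and
    logged); duplicate (entry_id, chain_id) pairs keep the first occurrence.
    """
    lib = FragmentLibrary(mirror_plane=mirror_plane)
    seen: set[tuple[str, str]] = set()
    for s in structures:
        mirrored = mirror_structure(s, plane=mirror_plane)
        for chain_id, residues in mirrored.chains.items():
            key = (mirrored.entry_id, chain_id)
            if key in seen:
                continue
            seen.add(key)
            if len(residues) < min_chain_length:
                lib.dropped_chains += 1
                logger.info("dropping short chain %s/%s (%d < %d residues)",
                            mirrored.entry_id, chain_id, len(residues), min_chain_length)
                continue
            lib.entries.append((mirrored.entry_id, chain_id, residues))
    if not lib.entries:
        raise ValueError(
            f"no usable chains: all {lib.dropped_chains} chain(s) shorter than {min_chain_length}"
        )
    logger.info("library: %d chain(s) kept, %d dropped", len(lib.entries), lib.dropped_chains)
    return lib


def enumerate_windows(
    lib: FragmentLibrary,
    length: int,
    directions: Sequence[str] = DIRECTIONS,
) -> Iterator[FragmentWindow]:
    """All contiguous windows of ``length`` residues from every chain, in
    deterministic order; a chain shorter than the window yields nothing."""
    if length < 1:
        raise ValueError(f"window length must be >= 1, got {length}")
    for d in directions:
        if d not in DIRECTIONS:
            raise ValueError(f"direction must be in {DIRECTIONS}, got {d!r}")
    for entry_id, chain_id, residues in lib.entries:
        n = len(residues)
        for start in range(0, n - length + 1):
            for direction in directions:
                yield FragmentWindow(entry_id, chain_id, start, length, direction)


def gather_window_atoms(
    query: QueryStructure,
    window: FragmentWindow,
    lib: FragmentLibrary,
    identity_filter: bool = False,
) -> tuple[np.ndarray, tuple[str, ...]] | str:
    """Collect the window atoms corresponding to the query's hotspot atoms.

    The hotspot at span offset i reads window offset i (forward) or
    length-1-i (reverse); atoms correspond by name within the aligned
    residue. Returns (coords, residue names) or a skip-reason string.
    """
    if window.length != query.span_length:
        raise ValueError(
            f"window length {window.length} != query span {query.span_length}"
        )
    residues = lib.chain(window.entry_id, window.chain_id)
    atoms_by_hotspot = query.atoms_by_hotspot()

    moving: list[np.ndarray] = []
    matched_names: list[str] = []
    for seq_id in query.hotspot_seq_ids():
        offset = seq_id - query.span_start
        widx = offset if window.direction == "forward" else window.length - 1 - offset
        res = residues[window.start + widx]
        if identity_filter:
            expected = query.hotspot_res_names.get(seq_id)
            if expected is not None and res.res_name != expected:
                return "identity"
        for name in atoms_by_hotspot[seq_id]:
            a = res.atom(name)
            if a is None:
                return "missing_atom"
            moving.append(a.coords)
        matched_names.append(res.res_name)
    return np.array(moving), tuple(matched_names)


def score_window(
    query: QueryStructure,
    window: FragmentWindow,
    lib: FragmentLibrary,
    identity_filter: bool = False,
    skip_log: SkipLog | None = None,
) -> FragmentMatch | None:
    """Superpose the window's hotspot-aligned atoms onto the query.

    Returns None (recording a reason) when the window cannot supply the
    required atoms, fails the identity filter, or is geometrically
    degenerate.
    """
    gathered = gather_window_atoms(query, window, lib, identity_filter=identity_filter)
    if isinstance(gathered, str):
        if skip_log:
            skip_log.skip(gathered)
        return None
    moving, matched_names = gathered
    try:
        sup = superpose(moving, query.coords)
    except DegenerateGeometryError:
        if skip_log:
            skip_log.skip("degenerate")
        return None
    return FragmentMatch(
        combo_id=query.combo_id,
        window=window,
        superposition=sup,
        matched_residues=matched_names,
        query=query,
    )


def helix_filter(residues: list[ResidueRecord], window: FragmentWindow,
                 lo: float = 5.9, hi: float = 6.7) -> bool:
    """Optional secondary-structure pre-filter: every CA(i)-CA(i+4) distance
    inside the window must fall in [lo, hi] Angstrom (alpha-helical pitch)."""
    cas = []
    for i in range(window.length):
        a = residues[window.start + i].atom("CA")
        if a is None:
            return False
        cas.append(a.coords)
    cas = np.array(cas)
    if len(cas) < 5:
        return True
    d = np.linalg.norm(cas[4:] - cas[:-4], axis=1)
    return bool(np.all((d >= lo) & (d <= hi)))


def search(
    queries: Sequence[QueryStructure],
    lib: FragmentLibrary,
    top_k: int = 1000,
    directions: Sequence[str] = DIRECTIONS,
    identity_filter: bool = False,
    require_helix: bool = False,
) -> RMSDProfile:
    """Scan all windows with every query variant and rank windows by their
    pooled (minimum over queries) RMSD.

    Deterministic: ties are broken by (rmsd, entry_id, chain_id, start,
    direction). Raises :class:`NoMatchesError` with the skip histogram if
    nothing scores.
    """
    if not queries:
        raise ValueError("empty query set")
    if top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    helix_id = queries[0].helix_id
    span = queries[0].span_length
    if any(q.span_length != span for q in queries):
        raise ValueError("all queries of one helix must share the segment span")

    skip_log = SkipLog()
    best_per_window: list[FragmentMatch] = []
    n_scored = 0
    for window in enumerate_windows(lib, span, directions):
        if require_helix and not helix_filter(lib.chain(window.entry_id, window.chain_id), window):
            skip_log.skip("not_helical")
            continue
        best: FragmentMatch | None = None
        for q in queries:
            m = score_window(q, window, lib, identity_filter=identity_filter, skip_log=skip_log)
            if m is not None and (best is None or m.rmsd < best.rmsd):
                best = m
        if best is not None:
            n_scored += 1
            best_per_window.append(best)
    if not best_per_window:
        raise NoMatchesError(dict(skip_log.counts))

    best_per_window.sort(key=lambda m: (m.rmsd,) + m.window.sort_key())
    profile = RMSDProfile(
        helix_id=helix_id,
        matches=best_per_window[:top_k],
        top_k=top_k,
        n_windows_scored=n_scored,
        skip_histogram=dict(skip_log.counts),
    )
    logger.info(
        "search %s: %d windows scored, %d kept (top_k=%d), skips=%s",
        helix_id, n_scored, len(profile.matches), top_k, profile.skip_histogram,
    )
    return profile
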