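"""Fragment placement, splicing, and geometry auditing."""
from __future__ import annotations

import numpy as np
import pytest

import dpepdesign as dp
from dpepdesign import assembly as asm
from dpepdesign.errors import CoverageError
from dpepdesign.fixtures import random_rigid_transform
from dpepdesign.mirror import mirror_coords

from .conftest import SEGMENT_RANGES, segment_copy_model


@pytest.fixture(scope="module")
def self_matches(segments, queries, self_library):
    """Best reverse-direction match of each helix against the scaffold's
    own mirrored segments."""
    return {
        h: dp.search(queries[h], self_library, top_k=5, directions=("reverse",)).best()
        for h in segments
    }


@pytest.fixture(scope="module")
def reconstruction(self_matches, segments, self_library):
    plan = asm.default_plan(SEGMENT_RANGES)
    return asm.assemble(self_matches, plan, self_library, segments)


def test_default_plan_cuts_overlaps_at_midpoints():
    """Overlaps 7-14 and 15-19 split after 10 and 17 (ties toward the
    N-terminal fragment), giving contributions 1-10 / 11-17 / 18-31."""
    plan = asm.default_plan(SEGMENT_RANGES)
    assert plan.contributions == (
        ("helix1", 1, 10),
        ("helix2", 11, 17),
        ("helix3", 18, 31),
    )


def test_plan_rejects_gaps():
    with pytest.raises(ValueError, match="tile"):
        asm.SplicePlan((("helix1", 1, 9), ("helix2", 11, 17)))


def test_plan_requires_overlapping_segments():
    with pytest.raises(ValueError, match="overlap"):
        asm.default_plan({"a": (1, 5), "b": (9, 14)})


def test_placed_hotspot_residual_equals_match_rmsd(self_matches, self_library):
    """Scaffold-frame placement reproduces the stored fit: the residual at
    the hotspot-aligned atoms is the match RMSD itself."""
    for m in self_matches.values():
        placed = asm.place_match(m, self_library, frame="scaffold")
        q = m.query
        coords = []
        for seq_id in q.hotspot_seq_ids():
            offset = seq_id - q.span_start
            widx = m.window.length - 1 - offset  # reverse reading
            res = placed[widx]
            coords.extend(res.atom(name).coords for name in q.atoms_by_hotspot()[seq_id])
        residual = np.sqrt(np.mean(np.sum((np.array(coords) - q.coords) ** 2, axis=1)))
        assert residual == pytest.approx(m.rmsd, abs=1e-9)


def test_mirror_frame_residual_matches_for_planar_queries(self_matches, self_library):
    """For the coplanar three-CA queries the mirror-frame refit achieves
    the same residual as the stored match (against the mirrored hotspots)."""
    for m in self_matches.values():
        assert len(m.query.atoms) == 3  # pooling selects the exact CA-only level here
        placed = asm.place_match(m, self_library, frame="mirror")
        q = m.query
        target = mirror_coords(q.coords)
        coords = []
        for i, seq_id in enumerate(q.hotspot_seq_ids()):
            offset = seq_id - q.span_start
            widx = m.window.length - 1 - offset
            coords.append(placed[widx].atom("CA").coords)
        residual = np.sqrt(np.mean(np.sum((np.array(coords) - target) ** 2, axis=1)))
        assert residual == pytest.approx(m.rmsd, abs=1e-6)


def test_placement_invariant_under_rigid_predisplacement(segments, queries):
    """Rigidly pre-moving the library copy changes the stored transform but
    not the placed coordinates."""
    seg = segments["helix1"]
    base = segment_copy_model(seg, "copy")
    moved = base.copy()
    R, t = random_rigid_transform(np.random.default_rng(5))
    for r in moved.iter_residues():
        for a in r.atoms:
            a.coords = R @ a.coords + t
    q = next(x for x in queries["helix1"] if x.combo_id == (1, 1, 1))
    placements = []
    for model in (base, moved):
        lib = dp.build_library([model], min_chain_length=14)
        m = dp.score_window(q, dp.FragmentWindow(model.entry_id, "A", 0, 14, "reverse"), lib)
        placed = asm.place_match(m, lib, frame="mirror")
        placements.append(np.array([a.coords for r in placed for a in r.atoms]))
    np.testing.assert_allclose(placements[0], placements[1], atol=1e-8)


def test_stale_window_reference_errors(self_matches):
    empty = dp.FragmentLibrary(entries=[])
    with pytest.raises(CoverageError):
        asm.place_match(self_matches["helix1"], empty)


def test_self_reconstruction_recovers_scaffold_mirror(reconstruction, scaffold):
    """Assembled from the scaffold's own mirrored segments, the model's
    mirror image superposes on the scaffold at CA RMSD ~ 0."""
    pep = reconstruction
    assert len(pep) == 31
    assert pep.geometry["scaffold_ca_rmsd"] <= 1e-6
    # direct check against the scaffold, independent of the stored report
    ca = np.array(
        [pep.residues[i - 1].atom("CA").coords for i in sorted(pep.scaffold_map)]
    )
    sc = np.array(
        [scaffold.chains["A"][pep.scaffold_map[i] - 1].atom("CA").coords
         for i in sorted(pep.scaffold_map)]
    )
    assert dp.superpose(mirror_coords(ca), sc).rmsd <= 1e-6


def test_self_reconstruction_geometry_is_clean(reconstruction):
    geo = reconstruction.geometry
    assert geo["clash_count"] == 0
    assert geo["junction_violations"] == []
    assert all(b["ok"] for b in geo["bonds"])
    assert geo["handedness"]["uniform"] and geo["handedness"]["dominant"] == "D"


def test_reverse_provenance_orientation(reconstruction):
    """The D-analogue's N-terminus maps to the scaffold's C-terminal end."""
    assert reconstruction.scaffold_map[1] == 31
    assert reconstruction.scaffold_map[len(reconstruction)] == 1


def test_provenance_is_complete_and_unique(reconstruction):
    pep = reconstruction
    assert len(pep.provenance) == len(pep)
    scaffold_positions = [p.scaffold_seq_id for p in pep.provenance]
    assert sorted(scaffold_positions) == list(range(1, 32))
    assert set(pep.scaffold_map.values()) == set(scaffold_positions)
    for idx, prov in zip(sorted(pep.scaffold_map), pep.provenance):
        assert pep.scaffold_map[idx] == prov.scaffold_seq_id


def test_hotspot_positions_carry_matched_residues(reconstruction, self_matches):
    """Each hotspot inside its fragment's contribution range shows, in the
    assembled peptide, the residue type the search matched there."""
    plan = asm.default_plan(SEGMENT_RANGES)
    ranges = {h: (a, b) for h, a, b in plan.contributions}
    by_scaffold = {p.scaffold_seq_id: p for p in reconstruction.provenance}
    residues_by_scaffold = {
        prov.scaffold_seq_id: res
        for res, prov in zip(reconstruction.residues, reconstruction.provenance)
    }
    for helix, m in self_matches.items():
        lo, hi = ranges[helix]
        for i, seq_id in enumerate(m.query.hotspot_seq_ids()):
            if not (lo <= seq_id <= hi):
                continue  # hotspot lies in another fragment's contribution
            assert by_scaffold[seq_id].helix_id == helix
            assert residues_by_scaffold[seq_id].res_name == m.matched_residues[i]


def test_mixed_directions_refused(self_matches, segments, self_library, queries):
    fwd = dp.search(queries["helix1"], self_library, top_k=1, directions=("forward",)).best()
    mixed = dict(self_matches)
    mixed["helix1"] = fwd
    with pytest.raises(ValueError, match="direction"):
        asm.assemble(mixed, asm.default_plan(SEGMENT_RANGES), self_library, segments)


def test_contribution_outside_segment_errors(self_matches, segments, self_library):
    bad = asm.SplicePlan((("helix1", 1, 16), ("helix2", 17, 17), ("helix3", 18, 31)))
    with pytest.raises(CoverageError, match="helix1"):
        asm.assemble(self_matches, bad, self_library, segments)


def test_translated_fragment_flags_junction(self_matches, segments, self_library):
    pep = asm.assemble(
        self_matches, asm.default_plan(SEGMENT_RANGES), self_library, segments
    )
    # displace every residue sourced from helix3 and re-audit
    for res, prov in zip(pep.residues, pep.provenance):
        if prov.helix_id == "helix3":
            for a in res.atoms:
                a.coords = a.coords + np.array([8.0, 0.0, 0.0])
    report = asm.geometry_check(pep)
    assert len(report["junction_violations"]) >= 1
    assert any(b["is_junction"] and not b["ok"] for b in report["bonds"])


def test_clash_count_matches_brute_force(reconstruction):
    """KD-tree clash counting equals an O(n^2) all-pairs loop, on both the
    clean model and a deliberately collapsed copy."""

    def brute_force(pep):
        atoms = []
        for i, r in enumerate(pep.residues):
            for a in r.atoms:
                if not a.is_hydrogen:
                    atoms.append((i, a.name, a.coords))
        count = 0
        for x in range(len(atoms)):
            for y in range(x + 1, len(atoms)):
                ri, ni, ci = atoms[x]
                rj, nj, cj = atoms[y]
                if ri == rj:
                    continue
                if abs(ri - rj) == 1:
                    lo, hi = (x, y) if ri < rj else (y, x)
                    if atoms[lo][1] == "C" and atoms[hi][1] == "N":
                        continue
                if float(np.linalg.norm(ci - cj)) < asm.CLASH_CUTOFF:
                    count += 1
        return count

    assert reconstruction.geometry["clash_count"] == brute_force(reconstruction)

    squeezed = dp.AssembledPeptide(
        residues=[r.copy() for r in reconstruction.residues[:8]],
        provenance=list(reconstruction.provenance[:8]),
        scaffold_map={k: v for k, v in reconstruction.scaffold_map.items() if k <= 8},
    )
    for i, r in enumerate(squeezed.residues):
        for a in r.atoms:
            a.coords = a.coords * 0.55  # compress toward the origin
    report = asm.geometry_check(squeezed)
    assert report["clash_count"] == brute_force(squeezed)
    assert report["clash_count"] > 0


def test_written_assembly_is_deterministic(reconstruction, tmp_path):
    p1, p2 = tmp_path / "a.pdb", tmp_path / "b.pdb"
    dp.write_structure(reconstruction.to_structure(), p1)
    dp.write_structure(reconstruction.to_structure(), p2)
    assert p1.read_bytes() == p2.read_bytes()
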