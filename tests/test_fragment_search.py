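"""Window enumeration, scoring, ranking, and search-level invariants."""
from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import dpepdesign as dp
from dpepdesign.errors import NoMatchesError
from dpepdesign.fixtures import plant_match, random_helix
from dpepdesign.fragment_search import enumerate_windows, gather_window_atoms
from dpepdesign.mirror import mirror_coords
from dpepdesign.query_builder import QueryStructure

from .conftest import HOTSPOTS, segment_copy_model


def _query(queries, helix, combo):
    return next(q for q in queries[helix] if q.combo_id == combo)


# ---------------------------------------------------------------- library


def test_build_library_mirrors_and_drops_short_chains(segments):
    long_model = segment_copy_model(segments["helix3"], "long")  # 17 residues
    short_model = segment_copy_model(segments["helix2"], "short")  # 13 residues
    lib = dp.build_library([long_model, short_model], min_chain_length=14)
    assert [(e, c) for e, c, _ in lib.entries] == [("long", "A")]
    assert lib.dropped_chains == 1


def test_library_chains_are_d_flagged(self_library):
    """After mirroring, every chiral residue audits as D (negative volume)."""
    for _, _, residues in self_library.entries:
        for r in residues:
            if r.res_name == "GLY":
                continue
            assert r.handedness_flag == "D"
            assert dp.chirality_sign(r) < 0


def test_duplicate_entries_deduplicated(segments):
    m = segment_copy_model(segments["helix1"], "dup")
    lib = dp.build_library([m, m.copy()], min_chain_length=10)
    assert len(lib.entries) == 1


def test_empty_library_errors(segments):
    with pytest.raises(ValueError):
        dp.build_library([segment_copy_model(segments["helix2"], "s")], min_chain_length=14)


# ---------------------------------------------------------------- windows


@pytest.mark.parametrize(
    "directions, expected",
    [(("forward",), 27), (("forward", "reverse"), 54)],
)
def test_window_counts(rng, directions, expected):
    lib = dp.build_library([random_helix(rng, 40, "r40")], min_chain_length=14)
    assert sum(1 for _ in enumerate_windows(lib, 14, directions)) == expected


def test_window_longer_than_chain_yields_nothing(rng):
    lib = dp.build_library([random_helix(rng, 20, "r20")], min_chain_length=14)
    assert list(enumerate_windows(lib, 25)) == []


# ---------------------------------------------------------------- scoring


def test_self_match_through_the_mirror_is_exact(segments, queries):
    """The CA-only query matches the mirrored copy of its own source
    segment in the reverse reading at rmsd ~ 0: on an ideal helix the
    reversed hotspot offsets have identical pairwise CA separations."""
    lib = dp.build_library([segment_copy_model(segments["helix1"], "self")], min_chain_length=14)
    q = _query(queries, "helix1", (0, 0, 0))
    m = dp.score_window(q, dp.FragmentWindow("self", "A", 0, 14, "reverse"), lib)
    assert m is not None and m.rmsd <= 1e-6


def test_identity_filter_skips_mismatched_windows(segments, queries):
    lib = dp.build_library([segment_copy_model(segments["helix1"], "self")], min_chain_length=14)
    q = _query(queries, "helix1", (0, 0, 0))
    w = dp.FragmentWindow("self", "A", 0, 14, "reverse")
    from dpepdesign.fragment_search import SkipLog

    log = SkipLog()
    # reverse alignment pairs H1 with the window's C-terminal residue (Leu)
    assert dp.score_window(q, w, lib, identity_filter=True, skip_log=log) is None
    assert log.counts["identity"] == 1
    # forward alignment pairs each hotspot with its own residue type
    assert dp.score_window(q, dp.FragmentWindow("self", "A", 0, 14, "forward"), lib,
                           identity_filter=True) is not None


def test_missing_atom_windows_are_skipped_with_reason(rng, segments, queries):
    polyA = dp.build_ideal_helix(dp.HelixSpec(sequence="A" * 20), entry_id="polyA")
    lib = dp.build_library([polyA], min_chain_length=14)
    q = _query(queries, "helix1", (3, 2, 2))  # needs His/Phe/Glu side-chain tips
    from dpepdesign.fragment_search import SkipLog

    log = SkipLog()
    assert dp.score_window(q, dp.FragmentWindow("polyA", "A", 0, 14, "forward"), lib,
                           skip_log=log) is None
    assert log.counts["missing_atom"] == 1


def test_planted_noise_rmsd_within_three_sigma(segments, queries):
    """Over 100 seeds, the planted window scores within [0, 3*sigma]."""
    sigma = 0.3
    q = _query(queries, "helix1", (1, 1, 1))
    rmsds = []
    for seed in range(100):
        planted = plant_match(segments["helix1"], noise_sigma=sigma, seed=seed, decoys=0)
        m = dp.score_window(q, planted.planted, planted.library)
        assert m is not None
        rmsds.append(m.rmsd)
    assert all(0.0 <= r <= 3 * sigma for r in rmsds)
    assert np.mean(rmsds) > 0.1  # the noise is real, not degenerate


def test_superset_query_never_reduces_summed_squared_residual(segments, queries):
    """Adding atoms to a query cannot reduce the minimal summed squared
    residual n*rmsd^2 against a fixed window (each extra atom adds a
    non-negative term to the objective)."""
    lib = dp.build_library([segment_copy_model(segments["helix1"], "self")], min_chain_length=14)
    # forward reading pairs each hotspot with its own residue type, so every
    # nested level (including side-chain tips) can be gathered
    w = dp.FragmentWindow("self", "A", 0, 14, "forward")
    nested = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1), (2, 1, 1), (3, 2, 2)]
    ss = []
    for combo in nested:
        q = _query(queries, "helix1", combo)
        m = dp.score_window(q, w, lib)
        ss.append(len(q.atoms) * m.rmsd**2)
    assert all(b >= a - 1e-9 for a, b in zip(ss, ss[1:]))


# ---------------------------------------------------------------- search


def test_profile_capped_at_top_k_and_sorted(rng, queries):
    structures = [random_helix(rng, 50, f"d{i:02d}") for i in range(16)]
    lib = dp.build_library(structures, min_chain_length=14)
    n_windows = sum(l - 14 + 1 for l in lib.chain_lengths().values()) * 2
    assert n_windows >= 1000
    profile = dp.search(queries["helix1"], lib, top_k=1000)
    assert len(profile) == 1000
    rmsds = [m.rmsd for m in profile.matches]
    assert rmsds == sorted(rmsds)


def test_search_equals_exhaustive_brute_force(rng, queries):
    """On a small library the ranked profile must equal an independent
    re-scoring of every window (scipy superposition, python min/sort)."""
    structures = [random_helix(rng, 30, f"b{i}") for i in range(3)]
    lib = dp.build_library(structures, min_chain_length=14)
    qs = queries["helix1"]
    windows = list(enumerate_windows(lib, 14))
    assert len(windows) <= 210

    def oracle_rmsd(q, w):
        gathered = gather_window_atoms(q, w, lib)
        if isinstance(gathered, str):
            return None
        moving, _ = gathered
        rot, rssd = Rotation.align_vectors(
            q.coords - q.coords.mean(axis=0), moving - moving.mean(axis=0)
        )
        return rssd / np.sqrt(len(moving))

    expected = []
    for w in windows:
        scores = [r for r in (oracle_rmsd(q, w) for q in qs) if r is not None]
        if scores:
            expected.append((min(scores), w))
    expected.sort(key=lambda t: (t[0],) + t[1].sort_key())

    profile = dp.search(qs, lib, top_k=len(expected))
    assert len(profile) == len(expected)
    for (exp_rmsd, exp_w), match in zip(expected, profile.matches):
        assert match.window == exp_w
        assert match.rmsd == pytest.approx(exp_rmsd, abs=1e-8)


def test_enlarging_library_never_worsens_rank_one(rng, queries):
    base = [random_helix(rng, 30, f"m{i}") for i in range(2)]
    extra = [random_helix(rng, 30, f"x{i}") for i in range(3)]
    best_small = dp.search(queries["helix2"], dp.build_library(base, 13), top_k=5).best().rmsd
    best_large = dp.search(
        queries["helix2"], dp.build_library(base + extra, 13), top_k=5
    ).best().rmsd
    assert best_large <= best_small + 1e-12


def test_mirror_conjugation_symmetry_of_search(rng, queries):
    """Mirroring both the query and the library leaves every score — and
    hence the rank-1 RMSD — unchanged (reflections conjugate proper
    rotations to proper rotations)."""
    structures = [random_helix(rng, 25, f"s{i}") for i in range(2)]
    lib = dp.build_library(structures, min_chain_length=14)
    lib_mirrored = dp.build_library(
        [dp.mirror_structure(s) for s in structures], min_chain_length=14
    )
    q = _query(queries, "helix1", (1, 1, 1))
    q_mirrored = QueryStructure(
        helix_id=q.helix_id,
        combo_id=q.combo_id,
        atoms=q.atoms,
        coords=mirror_coords(q.coords),
        span_start=q.span_start,
        span_end=q.span_end,
        hotspot_res_names=q.hotspot_res_names,
    )
    for direction in ("forward", "reverse"):
        p1 = dp.search([q], lib, top_k=3, directions=(direction,))
        p2 = dp.search([q_mirrored], lib_mirrored, top_k=3, directions=(direction,))
        assert p1.best().rmsd == pytest.approx(p2.best().rmsd, abs=1e-9)
        assert p1.best().window == p2.best().window


def test_planted_window_recovered_at_rank_one(segments, queries):
    """sigma = 0.3 A, 50 decoys, CA+CB query: the planted D-mimic must win
    rank 1 in at least 19 of 20 seeded repeats."""
    q = _query(queries, "helix1", (1, 1, 1))
    wins = 0
    for seed in range(20):
        planted = plant_match(segments["helix1"], noise_sigma=0.3, seed=seed, decoys=50)
        profile = dp.search([q], planted.library, top_k=3)
        wins += profile.best().window == planted.planted
    assert wins >= 19


def test_tie_break_is_deterministic(segments, queries):
    """Two identical chains under different entry ids score identically;
    order falls back to entry_id."""
    a = segment_copy_model(segments["helix1"], "aaa")
    b = segment_copy_model(segments["helix1"], "bbb")
    lib = dp.build_library([a, b], min_chain_length=14)
    profile = dp.search([_query(queries, "helix1", (0, 0, 0))], lib, top_k=4,
                        directions=("reverse",))
    assert [m.window.entry_id for m in profile.matches[:2]] == ["aaa", "bbb"]
    assert profile.matches[0].rmsd == pytest.approx(profile.matches[1].rmsd, abs=1e-9)


def test_all_windows_skipped_raises_with_histogram(segments, queries):
    polyA = dp.build_ideal_helix(dp.HelixSpec(sequence="A" * 20), entry_id="polyA")
    lib = dp.build_library([polyA], min_chain_length=14)
    q = _query(queries, "helix1", (3, 2, 2))
    with pytest.raises(NoMatchesError) as err:
        dp.search([q], lib, top_k=10)
    assert err.value.skip_histogram.get("missing_atom", 0) > 0
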