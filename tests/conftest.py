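"""Shared fixtures: the GLP-2 ideal-helix scaffold, its three-segment
split with the canonical hotspots, and a self-library built from the
scaffold's own segments."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dpepdesign as dp

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

SEGMENT_RANGES = {"helix1": (1, 14), "helix2": (7, 19), "helix3": (15, 31)}
HOTSPOTS = {
    "helix1": [dp.HotspotSpec(1, "HIS"), dp.HotspotSpec(6, "PHE"), dp.HotspotSpec(9, "GLU")],
    "helix2": [dp.HotspotSpec(8, "ASP"), dp.HotspotSpec(14, "LEU"), dp.HotspotSpec(17, "LEU")],
    "helix3": [dp.HotspotSpec(21, "ASP"), dp.HotspotSpec(22, "PHE"), dp.HotspotSpec(25, "TRP")],
}


@pytest.fixture(scope="session")
def scaffold() -> dp.StructureModel:
    return dp.build_ideal_helix(dp.HelixSpec(sequence=dp.GLP2_SEQUENCE), entry_id="glp2")


@pytest.fixture(scope="session")
def segments(scaffold) -> dict[str, dp.Segment]:
    return {
        h: dp.extract_segment(scaffold, "A", a, b) for h, (a, b) in SEGMENT_RANGES.items()
    }


@pytest.fixture(scope="session")
def queries(segments) -> dict[str, list[dp.QueryStructure]]:
    return {
        h: dp.enumerate_queries(dp.define_hotspots(segments[h], HOTSPOTS[h]), helix_id=h)
        for h in segments
    }


def segment_copy_model(segment: dp.Segment, entry_id: str) -> dp.StructureModel:
    """A standalone structure holding a renumbered copy of a segment."""
    residues = [r.copy() for r in segment.residues]
    for i, r in enumerate(residues, start=1):
        r.seq_id = i
        r.chain_id = "A"
    return dp.StructureModel(entry_id=entry_id, chains={"A": residues})


@pytest.fixture(scope="session")
def self_library(segments) -> dp.FragmentLibrary:
    """Mirrored copies of the scaffold's own three segments."""
    structures = [segment_copy_model(seg, f"self_{h}") for h, seg in segments.items()]
    return dp.build_library(structures, min_chain_length=min(len(s) for s in segments.values()))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)


def random_point_set(rng: np.random.Generator, n: int, spread: float = 10.0) -> np.ndarray:
    """Random non-degenerate point cloud for superposition tests."""
    while True:
        pts = rng.uniform(-spread / 2, spread / 2, size=(n, 3))
        sv = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
        if sv[1] > 0.5:
            return pts
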