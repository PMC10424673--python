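"""Synthetic structure generation: ideal helices, decoy libraries and
planted-match benchmarks.

Everything here is built from standard internal coordinates (NeRF chain
extension with textbook bond lengths and angles), so no structure
downloads are ever needed to exercise the pipeline. Side chains are
deliberately minimal: CB for every non-glycine residue plus the small set
of "tip" atoms the default query scheme can ask for, placed with
idealized geometry. D-handedness builds are the exact mirror image of the
corresponding L build.

All generation is seed-deterministic: the same spec and seed reproduce
byte-identical structures.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fragment_search import FragmentLibrary, FragmentWindow, build_library
from .geometry import nerf
from .mirror import mirror_structure
from .query_builder import ONE_TO_THREE
from .structure_io import AtomRecord, ResidueRecord, Segment, StructureModel

__all__ = [
    "HelixSpec",
    "PlantedLibrary",
    "build_ideal_helix",
    "random_helix",
    "plant_match",
    "random_rigid_transform",
]

# backbone geometry (Angstrom / degrees)
BOND_N_CA, BOND_CA_C, BOND_C_N, BOND_C_O = 1.458, 1.525, 1.329, 1.231
ANG_N_CA_C, ANG_CA_C_N, ANG_C_N_CA, ANG_CA_C_O = 111.2, 116.2, 121.7, 120.5

# side-chain tip recipes: atom -> NeRF refs + internal coordinates, or a
# collinear extension of the CB->CG axis (ring para positions)
_NERF = "nerf"
_EXTEND = "extend"
SIDE_CHAIN_RECIPES: dict[str, list[tuple]] = {
    "ASP": [(_NERF, "CG", ("N", "CA", "CB"), 1.52, 112.6, -60.0),
            (_NERF, "OD1", ("CA", "CB", "CG"), 1.25, 118.4, 0.0)],
    "GLU": [(_NERF, "CG", ("N", "CA", "CB"), 1.52, 114.1, -60.0),
            (_NERF, "CD", ("CA", "CB", "CG"), 1.52, 112.6, 180.0),
            (_NERF, "OE1", ("CB", "CG", "CD"), 1.25, 118.4, 0.0)],
    "LEU": [(_NERF, "CG", ("N", "CA", "CB"), 1.53, 116.3, -60.0),
            (_NERF, "CD1", ("CA", "CB", "CG"), 1.52, 110.7, 180.0)],
    "PHE": [(_NERF, "CG", ("N", "CA", "CB"), 1.50, 113.8, -60.0),
            (_EXTEND, "CZ", ("CB", "CG"), 2.80)],
    "TRP": [(_NERF, "CG", ("N", "CA", "CB"), 1.50, 113.6, -60.0),
            (_EXTEND, "CH2", ("CB", "CG"), 4.20)],
    "HIS": [(_NERF, "CG", ("N", "CA", "CB"), 1.50, 113.7, -60.0),
            (_NERF, "ND1", ("CA", "CB", "CG"), 1.38, 122.9, -90.0),
            (_NERF, "NE2", ("CB", "CG", "ND1"), 2.16, 72.7, 180.0)],
}


@dataclass(frozen=True)
class HelixSpec:
    """Ideal-helix recipe: sequence plus uniform backbone torsions."""

    sequence: str
    phi: float = -57.0
    psi: float = -47.0
    omega: float = 180.0
    handedness: str = "L"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = [c for c in self.sequence if c not in ONE_TO_THREE]
        if bad:
            raise ValueError(f"invalid residue letter(s) {bad}; use the standard one-letter alphabet")
        if self.handedness not in ("L", "D"):
            raise ValueError(f"handedness must be 'L' or 'D', got {self.handedness!r}")


def _element_of(name: str) -> str:
    return name[0]


def _place_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # standard tetrahedral CB reconstruction for an L-residue
    b = ca - n
    cv = c - ca
    a = np.cross(b, cv)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cv + ca


def _build_chain(
    sequence: str,
    phis: np.ndarray,
    psis: np.ndarray,
    omegas: np.ndarray,
    chain_id: str = "A",
) -> list[ResidueRecord]:
    n_res = len(sequence)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))

    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    theta = np.deg2rad(180.0 - ANG_N_CA_C)
    C[0] = CA[0] + BOND_CA_C * np.array([np.cos(theta), np.sin(theta), 0.0])

    for i in range(n_res - 1):
        N[i + 1] = nerf(N[i], CA[i], C[i], BOND_C_N, ANG_CA_C_N, psis[i])
        CA[i + 1] = nerf(CA[i], C[i], N[i + 1], BOND_N_CA, ANG_C_N_CA, omegas[i])
        C[i + 1] = nerf(C[i], N[i + 1], CA[i + 1], BOND_CA_C, ANG_N_CA_C, phis[i + 1])

    residues = []
    for i, letter in enumerate(sequence):
        res_name = ONE_TO_THREE[letter]
        coords: dict[str, np.ndarray] = {"N": N[i], "CA": CA[i], "C": C[i]}
        coords["O"] = nerf(N[i], CA[i], C[i], BOND_C_O, ANG_CA_C_O, psis[i] + 180.0)
        if res_name != "GLY":
            coords["CB"] = _place_cb(N[i], CA[i], C[i])
        for recipe in SIDE_CHAIN_RECIPES.get(res_name, []):
            if recipe[0] == _NERF:
                _, name, refs, bond, angle, torsion = recipe
                coords[name] = nerf(*(coords[r] for r in refs), bond, angle, torsion)
            else:
                _, name, (ref_a, ref_b), dist = recipe
                axis = coords[ref_b] - coords[ref_a]
                coords[name] = coords[ref_b] + dist * axis / np.linalg.norm(axis)
        atoms = [
            AtomRecord(name=nm, element=_element_of(nm), coords=np.asarray(xyz, float), serial=0)
            for nm, xyz in coords.items()
        ]
        residues.append(
            ResidueRecord(
                res_name=res_name,
                seq_id=i + 1,
                chain_id=chain_id,
                atoms=atoms,
                handedness_flag="achiral" if res_name == "GLY" else "L",
            )
        )
    return residues


def build_ideal_helix(spec: HelixSpec, entry_id: str = "ideal_helix", chain_id: str = "A") -> StructureModel:
    """Build an ideal helix from uniform phi/psi/omega.

    The L build uses the given torsions directly; the D build is its exact
    mirror image (equivalently, the helix with all torsions negated), so
    chirality signs come out residue-wise opposite to the L build.
    """
    n = len(spec.sequence)
    phis = np.full(n, spec.phi)
    psis = np.full(n, spec.psi)
    omegas = np.full(n, spec.omega)
    model = StructureModel(
        entry_id=entry_id,
        chains={chain_id: _build_chain(spec.sequence, phis, psis, omegas, chain_id)},
    )
    if spec.handedness == "D":
        model = mirror_structure(model, plane="xy")
        model.entry_id = entry_id
    return model


def random_helix(
    rng: np.random.Generator,
    length: int,
    entry_id: str,
    jitter_deg: float = 25.0,
    chain_id: str = "A",
) -> StructureModel:
    """Decoy generator: helix-like chain with random (non-glycine) sequence
    and per-residue phi/psi jitter uniform in +-jitter_deg around -57/-47.

    The jitter keeps local geometry helix-like while decorrelating the
    longer-range hotspot constellations that the search scores, so decoys
    are plausible but not degenerate with an ideal-helix scaffold.
    """
    alphabet = [c for c in ONE_TO_THREE if c != "G"]
    sequence = "".join(rng.choice(alphabet) for _ in range(length))
    phis = -57.0 + rng.uniform(-jitter_deg, jitter_deg, size=length)
    psis = -47.0 + rng.uniform(-jitter_deg, jitter_deg, size=length)
    omegas = np.full(length, 180.0)
    return StructureModel(
        entry_id=entry_id,
        chains={chain_id: _build_chain(sequence, phis, psis, omegas, chain_id)},
    )


def random_rigid_transform(rng: np.random.Generator, box: float = 20.0):
    """Uniform random rotation (Shoemake quaternion method) plus a uniform
    translation inside a cube of side ``box`` Angstrom."""
    u1, u2, u3 = rng.uniform(size=3)
    q = np.array(
        [
            np.sqrt(1 - u1) * np.sin(2 * np.pi * u2),
            np.sqrt(1 - u1) * np.cos(2 * np.pi * u2),
            np.sqrt(u1) * np.sin(2 * np.pi * u3),
            np.sqrt(u1) * np.cos(2 * np.pi * u3),
        ]
    )
    x, y, z, w = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.uniform(-box / 2, box / 2, size=3)
    return R, t


@dataclass
class PlantedLibrary:
    """A search benchmark: a mirrored library hiding one noisy copy of a
    scaffold segment among decoys, with the ground-truth window recorded."""

    library: FragmentLibrary
    planted: FragmentWindow  # the reverse-direction window that should win
    inputs: list[StructureModel] = field(default_factory=list)  # pre-mirror structures


def plant_match(
    segment: Segment,
    noise_sigma: float,
    seed: int,
    decoys: int = 50,
    decoy_extra_length: int = 10,
    jitter_deg: float = 25.0,
) -> PlantedLibrary:
    """Hide a noise-perturbed, rigidly displaced copy of ``segment`` in a
    decoy library.

    The planted input is the segment's ideal D-mimic — its mirror image —
    perturbed by Gaussian coordinate noise of ``noise_sigma`` Angstrom and
    then moved by a random rigid transform. A D-fragment is precisely what
    a real library hit would be: the d-PDB transform maps it back to
    query-matching L-geometry, so inside the built (mirrored) library the
    planted chain is a noisy rigid copy of the segment, recoverable in the
    forward reading at an RMSD set by the noise alone. (An L-copy planted
    instead would face the intrinsic chirality floor: no proper fit can
    take a mirrored non-coplanar constellation onto the original.) Ground
    truth is the forward full-chain window of entry "planted".
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    length = len(segment)

    planted_residues = [r.copy() for r in segment.residues]
    for res in planted_residues:
        res.chain_id = "A"
        if noise_sigma > 0:
            for a in res.atoms:
                a.coords = a.coords + rng.normal(0.0, noise_sigma, size=3)
    for i, res in enumerate(planted_residues, start=1):
        res.seq_id = i
    planted_model = mirror_structure(
        StructureModel(entry_id="planted", chains={"A": planted_residues})
    )
    planted_model.entry_id = "planted"
    R, t = random_rigid_transform(rng)
    for res in planted_model.iter_residues():
        for a in res.atoms:
            a.coords = R @ a.coords + t

    inputs = [planted_model]
    for d in range(decoys):
        inputs.append(random_helix(rng, length + decoy_extra_length, entry_id=f"decoy{d:03d}",
                                   jitter_deg=jitter_deg))

    library = build_library(inputs, min_chain_length=length)
    truth = FragmentWindow(entry_id="planted", chain_id="A", start=0, length=length,
                           direction="forward")
    return PlantedLibrary(library=library, planted=truth, inputs=inputs)
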