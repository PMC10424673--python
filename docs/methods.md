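# Methods

## The design problem

Given a helical L-peptide agonist in its receptor-bound conformation and a
set of hotspot residues (positions whose side chains drive binding and
activation, typically established by alanine scanning), find D-peptide
fragments whose side-chain geometry mimics the hotspot constellation, and
splice the best per-segment fragments into one retro-inverso analogue. The
worked scaffold throughout is GLP-2 (HADGSFSDEMNTILDNLAARDFINWLIQTKITD,
positions 1–33), segmented into helix1 (1–14), helix2 (7–19) and helix3
(15–31) with hotspots H1/F6/E9, D8/L14/L17 and D21/F22/W25.

## The mirror-image (d-PDB) search

A reflection M (default: through the xy plane, i.e. z → −z; any plane is
equivalent up to a proper rotation and the choice is fixed only for
reproducibility) is an isometry with det M = −1: it preserves every
internal distance and angle exactly while inverting every chiral centre.
Applying M to a library of L-protein chains yields a library of D-chains.
An L-query matched into that library therefore retrieves fragments that
exist in the real world as D-peptides mimicking the query.

Handedness is audited with the signed volume

    V = det[ N−CA, C−CA, CB−CA ]   (Å³),

positive for L-residues, negative for D in this package's convention
(≈ ±2.5 Å³ for idealized geometry); glycine is achiral and residues missing
any of the four atoms are reported indeterminate rather than raising.

## Queries and atom levels

Each hotspot contributes an ordered list of nested atom subsets:

| level | atoms | meaning |
|---|---|---|
| 1 | CA | backbone position only |
| 2 | CA, CB | + side-chain direction |
| 3 | CA, CB, tip | + functional-group placement |
| 4 (His only) | CA, CB, CG, ND1, NE2 | full imidazole anchor |

with residue-specific tips Phe CG+CZ, Trp CG+CH2, Asp CG+OD1, Glu CD+OE1,
Leu CG+CD1, His CG+NE2. One query is emitted per element of the Cartesian
product of per-hotspot levels, in lexicographic order of level indices, so
the three GLP-2 segments yield 4·3·3 = 36 and 3·3·3 = 27 and 27 queries.
The level definitions are this package's own reconstruction, calibrated so
that the combinatorics produce exactly these counts; they are fully
overridable per residue type through the YAML config. Combinations with
fewer than 3 atoms are rejected at enumeration (superposition would be
ill-posed), never silently dropped.

## Scoring

Windows of query-span length are enumerated from every library chain in
forward and reverse reading directions; the hotspot at span offset *i*
reads window offset *i* (forward) or *length−1−i* (reverse), and atoms
correspond by name. A window lacking a named atom, or failing the optional
residue-identity filter, is skipped with a counted reason. Match quality is
the least-squares superposition RMSD restricted to proper rotations
(Kabsch via SVD with the determinant sign correction). Restricting to
det R = +1 is essential: a reflection in the fit would cancel the library
mirror and reduce the search to ordinary L-vs-L matching. Collinear or
sub-3-point sets raise a well-posedness error (second singular value of
the centred coordinates below 1e−8).

Per window, the score is pooled as the minimum RMSD over all query
variants of that helix; profiles are sorted ascending with deterministic
tie-breaking (rmsd, entry id, chain id, start, direction) and truncated to
the 1000 best by default.

Two consequences of chirality are worth stating because they shape the
tests and the expectations for real libraries:

- **Coplanar constellations are chirality-blind.** Any 3-point (CA-only)
  query is planar, and a planar set is properly congruent to its own
  mirror image; such queries can score exactly 0 against geometrically
  trivial partners and are therefore promiscuous. They are useful as
  retrievability floors, not as discriminators.
- **Non-coplanar constellations have an intrinsic floor.** No proper
  rotation maps the mirror of a chiral point set onto the original, so
  even the *ideal* D-mimic of a helical segment (its exact mirror, read in
  reverse) scores ≈ 0.8–1.2 Å against a CA+CB-level query. Sub-angstrom
  exact matching of rich queries through the mirror is geometrically
  impossible — which is why realistic best matches for 7–13-atom hotspot
  constellations land in the 1–1.5 Å range rather than near zero.

## Placement and assembly frames

A match stores the proper-rotation fit of the window atoms onto the query.
Applying that fit directly ("scaffold frame") overlays the hotspot atoms
on the scaffold hotspots — the natural frame for presentation figures —
but it extends poorly beyond the fitted atoms: the global map that would
carry the *whole* reversed mirrored helix onto the scaffold is improper,
so remote residues of an exactly-fitted fragment can land far away.

Assembly therefore places fragments in the **mirrored-scaffold frame**
(default): the window atoms are re-fitted onto M·(query coordinates). In
that frame the map extending an exact hotspot fit along a regular helix is
a proper rotation (the helix dyad — the two-fold axis perpendicular to the
helix axis — conjugated by M), so fragments sharing helical geometry
splice seamlessly, and the assembled model's *mirror image* is what
superposes on the scaffold. For coplanar (CA-only) queries the
mirror-frame residual equals the stored match RMSD exactly; for larger
atom sets it is the reverse-reading fit without chirality inversion and
may differ. The geometry report always states `scaffold_ca_rmsd`: the CA
RMSD between the model (reflected back into the scaffold's world) and the
parent backbone after optimal superposition.

The splice plan assigns scaffold ranges to fragments with crossovers at
the midpoints of segment overlaps, ties toward the N-terminal fragment:
overlaps 7–14 and 15–19 cut after positions 10 and 17, giving
contributions 1–10 / 11–17 / 18–31. All matches must share one reading
direction; with reverse matches the assembled chain's own N→C order runs
from the scaffold's C-terminal end back to position 1 (the defining retro
property). Junction chemistry is *not* rebuilt: consecutive C–N distances
are measured and flagged outside 1.2–1.5 Å, heavy-atom pairs closer than
2.0 Å (excluding intra-residue pairs and the bonded C(i)–N(i+1) pair) are
counted as clashes, and handedness uniformity is checked. Refinement of a
spliced model is a molecular-dynamics task outside this package's scope.

## Synthetic structures

The fixtures module builds helices by NeRF chain extension with textbook
geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; N–CA–C 111.2°,
CA–C–N 116.2°, C–N–CA 121.7°; φ = −57°, ψ = −47°, ω = 180° by default),
CB from the standard tetrahedral reconstruction, and side chains built
only to the tip atoms the default scheme can request, with idealized
internal coordinates (ring para atoms placed along the CB→CG axis). A
D-handedness build is the exact mirror of the L build. Consecutive CA–CA
distances come out at 3.804 Å and CA(i)–CA(i+4) distances inside the
5.9–6.7 Å α-helical band.

The planted-match benchmark hides the *ideal D-mimic* of a scaffold
segment — its mirror image, perturbed by isotropic Gaussian coordinate
noise (default σ = 0.3 Å) and moved by a random rigid transform (uniform
quaternion rotation, translation in a 20 Å box) — among decoy helices
(default 50) with random non-glycine sequences and per-residue φ/ψ jitter
uniform in ±25° about the helical values. Planting the D-mimic (rather
than an L-copy) is what makes recovery well-posed: the d-PDB transform
maps it back to query-matching geometry, so at σ = 0 every atom level
recovers it exactly, and at σ = 0.3 Å a 6-atom CA+CB query finds it at
rank 1 (noise floor ≈ 0.4 Å) against a decoy floor near 0.75 Å. The jitter
matters: unjittered decoys would share the scaffold's exact CA geometry
and make the benchmark unwinnable by construction. All generation is
seed-deterministic.

What the synthetic conditions do *not* emulate: real side-chain rotamer
diversity, non-helical secondary structure, crystallographic noise and
missing atoms, and the sheer scale and redundancy of a full structure
database. Passing tests therefore demonstrate the correctness of the
geometry, ranking and splicing machinery, not retrieval statistics on the
real PDB.

## Numerical choices and determinism

- Superposition: SVD-based Kabsch, determinant-corrected; degenerate
  inputs raise rather than returning arbitrary rotations.
- Altloc resolution: highest occupancy, ties alphabetical; insertion codes
  rejected; HETATM excluded by default; hydrogens kept but flagged.
- PDB output carries 3 coordinate decimals, so file round-trips are exact
  to 1e−3 Å and a file-mediated self-reconstruction bottoms out near
  5e−4 Å rather than machine precision (the in-memory pipeline reaches
  ~1e−14).
- The design pipeline is fully deterministic — identical inputs give
  byte-identical outputs (manifest checksums make this checkable);
  randomness is confined to the fixtures generators, all seeded.

## Known limitations

- Correspondence is offset-respecting (forward/reverse along the chain),
  not fully order-free: retro-inverso matching of collinear helix queries
  is exactly the reverse-direction case, but matches that would require
  arbitrary residue permutations are out of reach by design.
- Hotspots are user input; no automatic hotspot prediction.
- No nucleic acids, ligands, waters, multi-model averaging, or insertion
  codes; non-standard residues are excluded from libraries.
- No energetic scoring, MD refinement, or free-energy estimation of the
  assembled model; terminal modifications are recorded as sequence-level
  annotations only.
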