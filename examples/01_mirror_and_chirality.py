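"""Mirror a peptide (the d-PDB transform) and audit chirality.

Builds an ideal L-helix carrying the GLP-2 sequence, reflects it through
the xy plane, and shows the per-residue signed volumes flipping sign while
every interatomic distance is preserved exactly.
"""
import numpy as np

import dpepdesign as dp

scaffold = dp.build_ideal_helix(dp.HelixSpec(sequence=dp.GLP2_SEQUENCE), entry_id="glp2")
mirrored = dp.mirror_structure(scaffold)

before = dp.chirality_report(scaffold)
after = dp.chirality_report(mirrored)
frac = dp.fraction_flipped(before, after)

coords = np.array([a.coords for r in scaffold.iter_residues() for a in r.atoms])
m_coords = np.array([a.coords for r in mirrored.iter_residues() for a in r.atoms])
d_before = np.linalg.norm(coords[0] - coords[-1])
d_after = np.linalg.norm(m_coords[0] - m_coords[-1])

first = scaffold.chains["A"][0]
print(f"residues: {len(scaffold.chains['A'])} (glycine at position 4 is achiral)")
print(f"signed volume of {first.res_name}1: "
      f"{dp.chirality_sign(first):+.3f} A^3 (L) -> "
      f"{dp.chirality_sign(mirrored.chains['A'][0]):+.3f} A^3 (D)")
print(f"fraction of chiral residues flipped: {frac:.0%}")
print(f"end-to-end distance before/after: {d_before:.6f} / {d_after:.6f} A")
print("A positive volume marks an L-residue, negative marks D; the mirror is an")
print("exact isometry, so all internal geometry survives while handedness inverts.")
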