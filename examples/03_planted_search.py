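"""Hide a noisy D-mimic of a scaffold segment in a decoy library and find it.

plant_match perturbs the mirror image of helix1 with 0.3 A Gaussian noise,
moves it rigidly, and buries it among 50 jittered decoy helices. The
mirrored-library search should rank the planted window first, at an RMSD
set by the noise level.
"""
import dpepdesign as dp

scaffold = dp.build_ideal_helix(dp.HelixSpec(sequence=dp.GLP2_SEQUENCE), entry_id="glp2")
segment = dp.extract_segment(scaffold, "A", 1, 14)
hotspots = dp.define_hotspots(
    segment, [dp.HotspotSpec(1, "HIS"), dp.HotspotSpec(6, "PHE"), dp.HotspotSpec(9, "GLU")]
)
queries = dp.enumerate_queries(hotspots, helix_id="helix1")
query = next(q for q in queries if q.combo_id == (1, 1, 1))  # CA+CB at every hotspot

planted = dp.plant_match(segment, noise_sigma=0.3, seed=7, decoys=50)
profile = dp.search([query], planted.library, top_k=5)

print(f"library: {len(planted.library.entries)} chains, "
      f"{profile.n_windows_scored} windows scored")
for rank, m in enumerate(profile.matches[:3], start=1):
    tag = "  <- planted" if m.window == planted.planted else ""
    print(f"rank {rank}: {m.window.entry_id} start {m.window.start} "
          f"({m.window.direction}) rmsd {m.rmsd:.3f} A{tag}")
print("The planted copy wins at an RMSD near the 0.3 A noise floor; the best")
print("decoy sits well above it, so recovery is a geometric, not a trivial, result.")
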