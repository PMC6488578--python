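"""Build a synthetic cargo protein and produce its NES lookup table.

One class-1a motif is planted in a disordered tail; two decoys that also
match the consensus are planted inside an ordered, domain-covered core
(one additionally with β-strand structure over its middle). The pipeline
scans the sequence, attaches the disorder/domain/β context and highlights
only the segments whose context is compatible with CRM1 binding — the
planted motif should be the single highlighted row.
"""

from nescan.pipeline import RunConfig, run_protein
from nescan.structure import SamplingConfig
from nescan.synthetic import PlantSpec, gen_protein, gen_tracks

plants = [
    PlantSpec("1a", 150, "disordered_tail"),
    PlantSpec("1a", 60, "ordered_core", decoy=True, category="ordered"),
    PlantSpec("2", 230, "ordered_core", decoy=True, category="beta"),
]
record, truth = gen_protein(plants, 300, seed=5)
diso, spotd, iup, ss, domains = gen_tracks(record.sequence, truth, seed=6)

config = RunConfig(structure_stage=True, sampling=SamplingConfig.minimal(),
                   seed=0)
table = run_protein(record, diso, spotd, iup, ss, domains, [], config)

cols = ["class", "priority", "seg_start", "seg_end", "loc_DISO", "loc_CDD",
        "beta", "flags", "highlighted", "e_bind_rsa"]
print(table[cols].to_string(index=False))

planted = truth.planted[0]
print(f"\nplanted class-1a motif: Φ registry {planted.phi_positions}, "
      f"window {planted.window} (disordered tail)")
print("Highlighted rows are outside ordered regions with ≤50% β in the "
      "middle; only those get an E_bind^RSA score (lower = better binder).")
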