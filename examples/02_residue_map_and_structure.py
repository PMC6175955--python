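"""Consolidate peptide calls to residues and color a structure.

Continues from the differential run: collapses peptide classifications
onto residues (majority rule for conflicts), writes the binary color
scheme into the B-factor column of a PDB (+1 red / −1 blue / 0 white /
99 gray), and prints the Woods-plot table head.
"""

import tempfile
from pathlib import Path

import hdxdiff as hd

SEED = 1

scenario = hd.default_transporter_scenario(300, "toward_IF", seed=SEED)
digest = hd.digest_in_silico(scenario.sequence, target_coverage=0.8,
                             seed=SEED, min_peptides=60)
conditions = hd.LabelingConditions.detergent()
noise = hd.NoiseModel(replicate_sd=0.05, seed=SEED)
control = hd.simulate_dataset(scenario, digest.peptides, conditions,
                              "control", noise)
variant = hd.simulate_dataset(scenario, digest.peptides, conditions,
                              "variant", noise)
result = hd.run_differential(control, variant)

rmap = hd.consolidate_to_residues(result.records, 300)
print("residue label counts:", rmap.summary())

woods = hd.woods_plot_data(result.records, result.thresholds)
print("\nWoods table head:")
print(woods.head().to_string(index=False))

# a synthetic straight-chain model standing in for a crystal structure
workdir = Path(tempfile.mkdtemp())
model = workdir / "model.pdb"
lines = [
    f"ATOM  {r:5d}  CA  ALA A{r:4d}    "
    f"{1.0:8.3f}{0.0:8.3f}{float(r):8.3f}{1.0:6.2f}{0.0:6.2f}           C"
    for r in range(1, 301)
]
model.write_text("\n".join(lines) + "\nEND\n")

df = hd.write_structure_annotation(
    rmap, model, workdir / "annotated.pdb", tsv_out=workdir / "residues.tsv"
)
print(f"\nannotated {len(df)} residues -> {workdir / 'annotated.pdb'}")
print("B-factor codes: +1.00 red, -1.00 blue, 0.00 white, 99.00 gray")
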