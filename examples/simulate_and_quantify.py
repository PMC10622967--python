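"""Simulate a POS-challenge experiment and recover per-POS marker content.

Cells are challenged at 20 POS per cell; the synthetic runs carry known
amounts of each marker VLC-PUFA.  The pipeline extracts 5-ppm EICs,
integrates RT-matched peaks, normalizes to the 21:5 internal standard and
converts responses to moles.  Dividing by the number of POS particles
returns the per-POS content, which should match the generator's truth.
"""

import warnings

from vlcpufa import ScenarioConfig, load_reference_panel, quantify_runs, simulate_experiment
from vlcpufa.quant import amount_per_pos
from vlcpufa.simulate import IS_AMOUNT_MOL, PER_POS_AMOUNTS

warnings.filterwarnings("ignore", message="isomers .* unresolvable")

panel = load_reference_panel()
config = ScenarioConfig(scenario="pos_only", pos_per_cell=20, n_cells=1e5, noise_cv=0.0)
runs, design, truths = simulate_experiment(config, n_replicates=1, seed=42)
table = quantify_runs(runs, panel, is_amount=IS_AMOUNT_MOL)

n_pos = config.pos_per_cell * config.n_cells
print(f"challenge: {config.pos_per_cell:g} POS/cell x {config.n_cells:g} cells = {n_pos:g} POS")
print(f"{'marker':8s} {'recovered mol/POS':>18s} {'true mol/POS':>14s} {'error':>8s}")
for marker, per_pos_true in sorted(PER_POS_AMOUNTS.items()):
    est_total = table.loc[table.species_label == marker, "est_amount_mol"].iloc[0]
    est_per_pos = amount_per_pos(est_total, n_pos)
    err = (est_per_pos - per_pos_true) / per_pos_true
    print(f"{marker:8s} {est_per_pos:18.3e} {per_pos_true:14.3e} {err:+8.2%}")
print("\nEach recovered value is moles of that fatty acid carried by a single")
print("POS particle; sub-percent errors show the EIC/peak/IS chain is unbiased.")
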