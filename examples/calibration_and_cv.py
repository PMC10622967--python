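"""Calibration linearity and replicate reproducibility of the assay.

A five-level dilution series of 32:6 (50-1000 nmol/L) is simulated and fit
by ordinary least squares; the limit of quantification is the lowest level
whose back-calculated concentration stays within 20% of nominal.  A second
experiment repeats one challenge condition ten times with 8% prep-to-prep
variability and reports the coefficient of variation per marker.
"""

import warnings

from vlcpufa import (
    ScenarioConfig,
    fit_calibration,
    load_reference_panel,
    quantify_runs,
    simulate_experiment,
)
from vlcpufa.quant import replicate_cv

warnings.filterwarnings("ignore", message="isomers .* unresolvable")
panel = load_reference_panel()

# calibration series
cal = ScenarioConfig(scenario="calibration_series", noise_cv=0.02)
runs, design, _ = simulate_experiment(cal, seed=11)
table = quantify_runs(runs, panel)
points = []
for _, row in design.table.iterrows():
    resp = table.loc[
        (table.sample_id == row["sample_id"]) & (table.species_label == "32:6"),
        "normalized_response",
    ].iloc[0]
    points.append((float(row["calibration_nmol_l"]), resp))
curve = fit_calibration(points, "32:6")
print("calibration of 32:6 over 50-1000 nmol/L:")
print(f"  slope {curve.slope:.3e} response per nmol/L, r = {curve.r:.4f}, LOQ = {curve.loq:g} nmol/L")

# replicate reproducibility
rep = ScenarioConfig(scenario="replicate_cv", pos_per_cell=20, noise_cv=0.08)
runs, _, _ = simulate_experiment(rep, n_replicates=10, seed=13)
table = quantify_runs(runs, panel)
print("\nreplicate CV over 10 simulated preparations (8% injected variability):")
for marker in ("34:4", "34:6", "36:6"):
    vals = table.loc[table.species_label == marker, "normalized_response"].dropna()
    print(f"  {marker:6s} CV = {replicate_cv(list(vals)):5.2f}%")
print("CVs near the injected variability confirm the read-out adds little noise.")
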