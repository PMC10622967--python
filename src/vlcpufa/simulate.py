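"""Synthetic LC-MS runs and experiments with known ground truth.

Every pipeline stage is testable without instrument data: each fatty-acid
species contributes a Gaussian chromatographic peak at its library
retention time, with centroids placed at its theoretical [M-H]- m/z plus a
small per-run ppm offset (inside the 5-ppm extraction window),
multiplicative per-scan noise, and uniform background centroids at random
m/z outside all target windows.  Scenario presets emulate the assay's
study designs: untreated RPE (LC-PUFAs only, no very-long-chain species),
POS challenge at a dose in POS/cell, receptor knockdown with reduced
uptake, replicate reproducibility, and a calibration dilution series.

Amounts map to areas through a fixed instrument response constant; the
internal standard is always present at the amount corresponding to a 1 ug
spike of fatty acid 21:5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import load_reference_panel, ppm_window
from .ms_io import Spectrum, SpectrumRun
from .quant import ExperimentDesign, is_amount_from_micrograms

__all__ = [
    "GroundTruth",
    "ScenarioConfig",
    "SCENARIOS",
    "PER_POS_AMOUNTS",
    "RESPONSE_PER_MOL",
    "simulate_run",
    "simulate_experiment",
]

#: Moles of each marker species carried by a single POS particle
#: (32:6 / 34:6 / 36:6 measured; 34:4 / 34:5 plausible defaults of the
#: same order, since only three per-POS values have been published).
PER_POS_AMOUNTS: dict[str, float] = {
    "32:6": 1.20e-15,
    "34:6": 2.01e-15,
    "36:6": 9.86e-16,
    "34:4": 8.0e-16,
    "34:5": 1.5e-15,
}

#: LC-PUFA content of cultured RPE cells per sample (mol) — abundant
#: long-chain species, no very-long-chain species (>= 30 carbons).
UNTREATED_RPE_AMOUNTS: dict[str, float] = {
    "20:4": 2.0e-9,
    "20:5": 4.0e-10,
    "22:4": 3.0e-10,
    "22:5 (1)": 1.5e-10,
    "22:5 (2)": 2.5e-10,
    "22:6": 3.0e-9,
}

#: Instrument response: chromatographic area (counts * min) per mole.
RESPONSE_PER_MOL = 1.0e20

#: Internal standard amount: 1 ug of 21:5 per sample.
IS_AMOUNT_MOL = is_amount_from_micrograms(1.0)

SCENARIOS = (
    "untreated_rpe",
    "pos_only",
    "pos_challenge",
    "knockdown",
    "replicate_cv",
    "calibration_series",
)

CALIBRATION_LEVELS_NMOL_L = (50.0, 100.0, 250.0, 500.0, 1000.0)
#: Nominal extract volume mapping nmol/L to moles on column.
CALIBRATION_VOLUME_L = 1e-3


@dataclass
class GroundTruth:
    """Known per-run truth: realized amounts, areas and peak parameters."""

    run_id: str
    seed: int
    scenario: str
    amounts_mol: dict[str, float]
    nominal_amounts_mol: dict[str, float]
    true_areas: dict[str, float]
    apex_rt_min: dict[str, float]
    sigma_min: float
    ppm_offsets: dict[str, float]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)


@dataclass
class ScenarioConfig:
    """Study-condition knobs for one simulated experiment arm."""

    scenario: str = "pos_challenge"
    pos_per_cell: float = 20.0
    incubation_h: float = 2.0
    n_cells: float = 1.0e5
    uptake_fraction: float = 1.0
    knockdown_effect: float = 0.0
    noise_cv: float = 0.05
    per_pos_amounts: Mapping[str, float] = field(default_factory=lambda: dict(PER_POS_AMOUNTS))
    condition: Optional[str] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if not 0 <= self.uptake_fraction <= 1:
            raise ValueError("uptake_fraction must be in [0, 1]")
        if not 0 <= self.knockdown_effect <= 1:
            raise ValueError("knockdown_effect must be in [0, 1]")
        if self.pos_per_cell < 0 or self.n_cells <= 0 or self.noise_cv < 0:
            raise ValueError("doses and counts must be non-negative, n_cells positive")

    @property
    def label(self) -> str:
        return self.condition or self.scenario


def _true_amounts(config: ScenarioConfig) -> dict[str, float]:
    """Nominal per-sample species amounts (mol) implied by a scenario."""
    amounts: dict[str, float] = {}
    eff_uptake = config.uptake_fraction * (1.0 - config.knockdown_effect)
    if config.scenario == "untreated_rpe":
        amounts.update(UNTREATED_RPE_AMOUNTS)
    elif config.scenario == "pos_only":
        n_pos = config.pos_per_cell * config.n_cells
        for label, per_pos in config.per_pos_amounts.items():
            amounts[label] = per_pos * n_pos
    elif config.scenario in ("pos_challenge", "knockdown", "replicate_cv"):
        amounts.update(UNTREATED_RPE_AMOUNTS)
        n_pos = config.pos_per_cell * config.n_cells
        for label, per_pos in config.per_pos_amounts.items():
            amounts[label] = amounts.get(label, 0.0) + per_pos * n_pos * eff_uptake
    elif config.scenario == "calibration_series":
        # handled level-by-level in simulate_experiment
        pass
    return amounts


def simulate_run(
    amounts_mol: Mapping[str, float],
    *,
    seed: int,
    run_id: str = "synthetic",
    scenario: str = "pos_challenge",
    panel: Optional[pd.DataFrame] = None,
    sigma_min: float = 0.04,
    scan_period_min: float = 0.01,
    rt_range_min: tuple[float, float] = (0.0, 8.0),
    scan_range: tuple[float, float] = (250.0, 800.0),
    noise_cv: float = 0.0,
    ppm_jitter_max: float = 2.0,
    background_per_scan: int = 4,
    include_is: bool = True,
    response_per_mol: float = RESPONSE_PER_MOL,
) -> tuple[SpectrumRun, GroundTruth]:
    """Simulate one centroided negative-mode run from known species amounts.

    Each species with a positive amount and a library RT contributes a
    Gaussian elution profile (area = amount * response constant) sampled at
    the scan times, with one centroid per scan at its ppm-shifted
    theoretical m/z.  Same seed, same inputs -> identical run.
    """
    panel = panel if panel is not None else load_reference_panel()
    rng = np.random.default_rng(seed)
    if scan_period_min <= 0:
        raise ValueError("scan period must be positive")

    amounts = dict(amounts_mol)
    if include_is:
        is_label = panel.loc[panel["role"] == "internal_standard", "species_label"].iloc[0]
        amounts.setdefault(is_label, IS_AMOUNT_MOL)

    by_label = panel.set_index("species_label")
    active: list[tuple[str, float, float, float]] = []  # label, amount, rt, mz
    for label, amount in amounts.items():
        if amount <= 0:
            continue
        if label not in by_label.index:
            raise KeyError(f"species {label!r} not in panel")
        row = by_label.loc[label]
        rt = row["expected_rt_min"]
        if not np.isfinite(rt):
            continue  # no library RT (e.g. species never observed): cannot place a peak
        active.append((label, float(amount), float(rt), float(row["mz_theoretical"])))

    # warn about same-m/z isomer peaks too close to resolve chromatographically
    # (species at different m/z get separate EICs and never interfere)
    by_mz: dict[float, list[tuple[float, str]]] = {}
    for label, _, rt, mz in active:
        by_mz.setdefault(round(mz, 4), []).append((rt, label))
    for group in by_mz.values():
        group.sort()
        for (rt1, l1), (rt2, l2) in zip(group, group[1:]):
            if rt2 - rt1 < 3 * sigma_min:
                warnings.warn(
                    f"isomers {l1} and {l2} share m/z and elute {rt2 - rt1:.3f} min "
                    f"apart (< 3 sigma = {3 * sigma_min:.3f}): unresolvable by design",
                    stacklevel=2,
                )

    scan_times = np.arange(rt_range_min[0], rt_range_min[1], scan_period_min)
    n_scans = scan_times.size

    ppm_offsets = {
        label: float(rng.uniform(-ppm_jitter_max, ppm_jitter_max))
        for label, _, _, _ in active
    }
    true_areas = {label: amount * response_per_mol for label, amount, _, _ in active}

    # per-species intensity profile across all scans
    profiles: list[tuple[float, np.ndarray]] = []
    norm = sigma_min * np.sqrt(2 * np.pi)
    for label, amount, rt, mz in active:
        area = true_areas[label]
        profile = area / norm * np.exp(-0.5 * ((scan_times - rt) / sigma_min) ** 2)
        if noise_cv > 0:
            profile = profile * np.clip(1.0 + noise_cv * rng.standard_normal(n_scans), 0.0, None)
        shifted_mz = mz * (1.0 + ppm_offsets[label] * 1e-6)
        profiles.append((shifted_mz, profile))

    # background: uniform random centroids outside every target's 10-ppm window
    target_windows = [ppm_window(mz, 10.0) for mz in panel["mz_theoretical"].unique()]
    heights = [a / norm for a in true_areas.values()]
    typical_height = float(np.median(heights)) if heights else 1.0
    bg_height = 0.1 * typical_height

    spectra: list[Spectrum] = []
    floor = 1e-9 * typical_height  # drop numerically invisible tails
    for i, t in enumerate(scan_times):
        mzs: list[float] = []
        ints: list[float] = []
        for shifted_mz, profile in profiles:
            if profile[i] > floor:
                mzs.append(shifted_mz)
                ints.append(float(profile[i]))
        for _ in range(background_per_scan):
            for _attempt in range(20):
                m = float(rng.uniform(*scan_range))
                if not any(lo <= m <= hi for lo, hi in target_windows):
                    mzs.append(m)
                    ints.append(float(bg_height * rng.uniform(0.2, 1.0)))
                    break
        order = np.argsort(mzs)
        spectra.append(
            Spectrum(
                rt_min=float(t),
                mz=np.asarray(mzs, dtype=float)[order],
                intensity=np.asarray(ints, dtype=float)[order],
            )
        )

    run = SpectrumRun(
        spectra=spectra,
        polarity="negative",
        scan_range=scan_range,
        run_id=run_id,
        metadata={"scenario": scenario, "seed": int(seed)},
    )
    truth = GroundTruth(
        run_id=run_id,
        seed=int(seed),
        scenario=scenario,
        amounts_mol={l: a for l, a, _, _ in active},
        nominal_amounts_mol=dict(amounts),
        true_areas=true_areas,
        apex_rt_min={l: rt for l, _, rt, _ in active},
        sigma_min=sigma_min,
        ppm_offsets=ppm_offsets,
    )
    return run, truth


def simulate_experiment(
    configs: ScenarioConfig | Sequence[ScenarioConfig],
    n_replicates: int = 3,
    seed: int = 0,
    **run_kwargs,
) -> tuple[list[SpectrumRun], ExperimentDesign, list[GroundTruth]]:
    """Simulate a whole experiment: arms x replicates, with a design table.

    Per-replicate variability: every nominal species amount is multiplied
    by a lognormal factor with coefficient of variation ``noise_cv`` (the
    realized amounts are what GroundTruth records); the same noise_cv also
    drives per-scan multiplicative noise inside each run.  All randomness
    flows from ``seed``.
    """
    if isinstance(configs, ScenarioConfig):
        configs = [configs]
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    root = np.random.default_rng(seed)

    runs: list[SpectrumRun] = []
    truths: list[GroundTruth] = []
    design_rows: list[dict] = []
    for config in configs:
        if config.scenario == "calibration_series":
            arm_jobs = [
                (f"{config.label}_L{int(level)}", {"32:6": level * 1e-9 * CALIBRATION_VOLUME_L}, level)
                for level in CALIBRATION_LEVELS_NMOL_L
            ]
        else:
            arm_jobs = [(config.label, _true_amounts(config), None)] * n_replicates

        for rep, (cond_label, nominal, level) in enumerate(arm_jobs, start=1):
            run_seed = int(root.integers(0, 2**31 - 1))
            rep_rng = np.random.default_rng(run_seed)
            realized = dict(nominal)
            if config.noise_cv > 0:
                s = np.sqrt(np.log1p(config.noise_cv**2))
                for label in realized:
                    realized[label] *= float(rep_rng.lognormal(-0.5 * s * s, s))
            run_id = f"{cond_label}_r{rep}"
            run, truth = simulate_run(
                realized,
                seed=run_seed,
                run_id=run_id,
                scenario=config.scenario,
                noise_cv=config.noise_cv,
                **run_kwargs,
            )
            runs.append(run)
            truths.append(truth)
            design_rows.append(
                {
                    "sample_id": run_id,
                    "condition": cond_label,
                    "pos_per_cell": config.pos_per_cell if level is None else 0.0,
                    "incubation_h": config.incubation_h,
                    "n_cells": config.n_cells,
                    "replicate": rep,
                    "calibration_nmol_l": level if level is not None else "",
                }
            )
    design = ExperimentDesign(pd.DataFrame(design_rows))
    return runs, design, truths
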