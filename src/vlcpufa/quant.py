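"""Internal-standard quantification and phagocytosis assay metrics.

Peak areas become comparable across runs by dividing each marker area by
the area of the co-extracted internal standard (fatty acid 21:5, spiked at
a known amount before extraction), which cancels injection and ionization
variation.  Normalized responses convert to moles through the known IS
amount and an optional per-species response factor (default 1, an
approximation documented in the methods note).  On top of the per-species
amounts the module computes the assay read-outs: composition profiles,
per-POS and per-cell amounts, percent change between conditions,
mean +/- SD across markers, and replicate coefficients of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .chem import FattyAcidSpecies, grams_to_mol, mz_deprotonated, parse_species
from .eic import detect_peaks, extract_eic, match_peak_to_rt
from .ms_io import SpectrumRun

__all__ = [
    "QuantRecord",
    "ExperimentDesign",
    "CalibrationCurve",
    "DEFAULT_MARKERS",
    "normalize_to_is",
    "amount_mol",
    "fit_calibration",
    "composition_profile",
    "uptake_per_cell",
    "amount_per_pos",
    "percent_change",
    "summarize_marker_changes",
    "replicate_cv",
    "quantify_run",
    "quantify_runs",
    "records_to_frame",
    "assay_report",
    "is_amount_from_micrograms",
]

#: Marker species quantified as tracers of internalized POS.
DEFAULT_MARKERS = ("32:6", "34:4", "34:5", "34:6", "36:6")

#: Internal standard: 1 ug of fatty acid 21:5 spiked per sample.
DEFAULT_IS_LABEL = "21:5"


def is_amount_from_micrograms(micrograms: float = 1.0, label: str = DEFAULT_IS_LABEL) -> float:
    """Moles of internal standard in a weighed spike (default 1 ug of 21:5)."""
    return grams_to_mol(micrograms * 1e-6, parse_species(label))


@dataclass
class QuantRecord:
    """Quantification result for one species in one sample."""

    sample_id: str
    species: FattyAcidSpecies
    species_label: str
    raw_area: float = 0.0
    normalized_response: Optional[float] = None
    est_amount_mol: Optional[float] = None
    matched_rt: Optional[float] = None
    flags: set[str] = field(default_factory=set)

    @property
    def detected(self) -> bool:
        return "not_detected" not in self.flags and "no_is" not in self.flags


@dataclass
class ExperimentDesign:
    """Sample -> condition mapping with dose, time and cell-count covariates."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "condition", "pos_per_cell", "incubation_h", "n_cells", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"design table missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design table")

    @classmethod
    def read_tsv(cls, path) -> "ExperimentDesign":
        return cls(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def samples_for(self, condition: str) -> list[str]:
        t = self.table
        return list(t.loc[t["condition"] == condition, "sample_id"])


@dataclass
class CalibrationCurve:
    """Ordinary least-squares response-vs-concentration line for one species."""

    species_label: str
    concentrations: np.ndarray
    responses: np.ndarray
    slope: float
    intercept: float
    r: float
    loq: Optional[float] = None

    def back_calculate(self, response: float) -> float:
        return (response - self.intercept) / self.slope


def normalize_to_is(
    areas: Mapping[str, float], is_area: float
) -> dict[str, Optional[float]]:
    """Divide each species area by the internal-standard area.

    Returns None for every species when the IS area is non-positive
    (callers flag such samples ``no_is``).
    """
    if is_area is None or is_area <= 0 or not math.isfinite(is_area):
        return {label: None for label in areas}
    return {label: area / is_area for label, area in areas.items()}


def amount_mol(
    response: float, is_amount_mol: float, response_factor: float = 1.0
) -> float:
    """Convert an IS-normalized response to moles.

    amount = response * is_amount / response_factor, where the response
    factor expresses per-species ionization efficiency relative to the IS.
    """
    if is_amount_mol <= 0:
        raise ValueError("is_amount_mol must be positive")
    if response_factor <= 0:
        raise ValueError("response_factor must be positive")
    if response < 0:
        raise ValueError("response must be non-negative")
    return response * is_amount_mol / response_factor


def fit_calibration(
    points: Sequence[tuple[float, float]],
    species_label: str = "",
    loq_accuracy_pct: float = 20.0,
) -> CalibrationCurve:
    """Fit an OLS line to (concentration, response) calibration points.

    LOQ is the lowest level whose back-calculated concentration is within
    ``loq_accuracy_pct`` of nominal; absent when no level qualifies.
    Requires >= 3 points spanning more than a 2x concentration range.
    """
    if len(points) < 3:
        raise ValueError("calibration needs at least 3 points")
    conc = np.array([p[0] for p in points], dtype=float)
    resp = np.array([p[1] for p in points], dtype=float)
    if conc.min() <= 0 or conc.max() / conc.min() <= 2:
        raise ValueError("calibration must span more than a 2x concentration range")
    fit = stats.linregress(conc, resp)
    curve = CalibrationCurve(
        species_label=species_label,
        concentrations=conc,
        responses=resp,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
    )
    qualifying = []
    for c, y in zip(conc, resp):
        back = curve.back_calculate(y)
        if abs(back - c) <= loq_accuracy_pct / 100.0 * c:
            qualifying.append(c)
    curve.loq = float(min(qualifying)) if qualifying else None
    return curve


def composition_profile(records: Sequence[QuantRecord]) -> dict[str, float]:
    """Relative abundance of each species within one sample (IS excluded).

    Fractions are normalized responses over their sum; species flagged
    not-detected contribute zero.  Raises on an all-zero sample.
    """
    responses = {}
    for r in records:
        if r.species.is_internal_standard:
            continue
        resp = r.normalized_response if r.detected and r.normalized_response else 0.0
        responses[r.species_label] = resp
    total = sum(responses.values())
    if total <= 0:
        raise ValueError("no detected species: composition undefined")
    return {label: resp / total for label, resp in responses.items()}


def uptake_per_cell(
    challenged_mol: float, unchallenged_mol: float, n_cells: float
) -> float:
    """Moles of marker gained per cell relative to an unchallenged reference.

    Negative values (challenged < reference) are returned as-is; callers
    flag them rather than clipping.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    return (challenged_mol - unchallenged_mol) / n_cells


def amount_per_pos(total_mol: float, n_pos: float) -> float:
    """Moles of one species per POS particle."""
    if n_pos <= 0:
        raise ValueError("n_pos must be positive")
    return total_mol / n_pos


def percent_change(reference: float, treated: float) -> float:
    """Signed percent change, 100 * (treated - reference) / reference.

    Negative means a decrease; report |value| with a direction label when
    quoting "a decrease of X%".
    """
    if reference == 0:
        raise ValueError("reference must be nonzero")
    return 100.0 * (treated - reference) / reference


def summarize_marker_changes(per_marker_percent: Sequence[float]) -> tuple[float, float]:
    """Arithmetic mean and sample (n-1) SD of per-marker percent changes."""
    if len(per_marker_percent) < 2:
        raise ValueError("need at least 2 marker values")
    arr = np.asarray(per_marker_percent, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))


def replicate_cv(values: Sequence[float]) -> float:
    """Coefficient of variation, 100 * sample SD / mean, in percent."""
    if len(values) < 2:
        raise ValueError("need at least 2 replicate values")
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("replicate mean must be positive")
    return float(100.0 * arr.std(ddof=1) / mean)


def quantify_run(
    run: SpectrumRun,
    panel: pd.DataFrame,
    *,
    tolerance_ppm: float = 5.0,
    rt_tolerance_min: float = 0.15,
    min_snr: float = 3.0,
    smoothing_window: int = 3,
    is_amount: Optional[float] = None,
    response_factors: Optional[Mapping[str, float]] = None,
    sample_id: Optional[str] = None,
) -> list[QuantRecord]:
    """Run the full EIC -> peak -> IS-normalization pipeline on one run.

    ``panel`` needs columns species_label, species, mz_theoretical,
    expected_rt_min and role (see :func:`vlcpufa.chem.load_reference_panel`).
    Isomer entries sharing an m/z are resolved by RT from one shared EIC.
    When ``is_amount`` (moles of spiked IS) is given, detected species also
    get ``est_amount_mol``.
    """
    sample_id = sample_id if sample_id is not None else run.run_id
    response_factors = response_factors or {}

    # one EIC per distinct target m/z; isomers share it
    eics: dict[float, object] = {}
    for mz in sorted(set(panel["mz_theoretical"])):
        eics[mz] = extract_eic(run, mz, tolerance_ppm)

    areas: dict[str, float] = {}
    matched_rt: dict[str, Optional[float]] = {}
    for _, row in panel.iterrows():
        label = row["species_label"]
        chrom = eics[row["mz_theoretical"]]
        expected_rt = row["expected_rt_min"]
        if not np.isfinite(expected_rt):
            areas[label] = 0.0
            matched_rt[label] = None
            continue
        try:
            peaks = detect_peaks(chrom, min_snr=min_snr, smoothing_window=smoothing_window)
        except ValueError:
            peaks = []
        peak = match_peak_to_rt(peaks, expected_rt, rt_tolerance_min)
        if peak is None:
            areas[label] = 0.0
            matched_rt[label] = None
        else:
            areas[label] = peak.area
            matched_rt[label] = peak.apex_rt

    is_rows = panel[panel["role"] == "internal_standard"]
    is_label = is_rows["species_label"].iloc[0] if len(is_rows) else None
    is_area = areas.get(is_label, 0.0) if is_label else 0.0
    non_is_areas = {l: a for l, a in areas.items() if l != is_label}
    responses = normalize_to_is(non_is_areas, is_area)
    no_is = is_area <= 0

    records: list[QuantRecord] = []
    for _, row in panel.iterrows():
        label = row["species_label"]
        species = row["species"]
        rec = QuantRecord(
            sample_id=sample_id,
            species=species,
            species_label=label,
            raw_area=areas[label],
            matched_rt=matched_rt[label],
        )
        if label == is_label:
            rec.normalized_response = None if no_is else 1.0
            if no_is:
                rec.flags.add("no_is")
        else:
            if no_is:
                rec.flags.add("no_is")
            else:
                rec.normalized_response = responses[label]
            if matched_rt[label] is None:
                rec.flags.add("not_detected")
            if rec.normalized_response is not None and is_amount is not None:
                rf = response_factors.get(label, 1.0)
                rec.est_amount_mol = amount_mol(rec.normalized_response, is_amount, rf)
        records.append(rec)
    return records


def quantify_runs(runs: Sequence[SpectrumRun], panel: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Quantify several runs and stack the results into one tidy table."""
    frames = [records_to_frame(quantify_run(run, panel, **kwargs)) for run in runs]
    return pd.concat(frames, ignore_index=True)


def assay_report(
    quant_table: pd.DataFrame,
    design: ExperimentDesign,
    *,
    markers: Sequence[str] = DEFAULT_MARKERS,
    reference_condition: Optional[str] = None,
) -> dict:
    """Condition-level assay summary from a tidy quantification table.

    For every condition and marker: mean and sample SD of the IS-normalized
    response across replicates and the replicate CV.  When a reference
    condition is named, per-marker percent changes versus the reference and
    their mean +/- SD across markers (the phagocytosis-impairment summary)
    are added.
    """
    merged = quant_table.merge(
        design.table[["sample_id", "condition"]], on="sample_id", how="left"
    )
    if merged["condition"].isna().any():
        missing = merged.loc[merged["condition"].isna(), "sample_id"].unique()
        raise ValueError(f"samples missing from design table: {list(missing)}")
    report: dict = {"markers": list(markers), "conditions": {}}
    for condition, group in merged.groupby("condition"):
        per_marker = {}
        for marker in markers:
            vals = group.loc[
                group["species_label"] == marker, "normalized_response"
            ].dropna()
            entry = {
                "n": int(len(vals)),
                "mean_response": float(vals.mean()) if len(vals) else None,
                "sd_response": float(vals.std(ddof=1)) if len(vals) > 1 else None,
            }
            if len(vals) > 1 and vals.mean() > 0:
                entry["cv_percent"] = replicate_cv(list(vals))
            per_marker[marker] = entry
        report["conditions"][condition] = per_marker
    if reference_condition is not None:
        if reference_condition not in report["conditions"]:
            raise ValueError(f"reference condition {reference_condition!r} not found")
        ref = report["conditions"][reference_condition]
        for condition, per_marker in report["conditions"].items():
            if condition == reference_condition:
                continue
            changes = {}
            for marker in markers:
                r = ref[marker]["mean_response"]
                t = per_marker[marker]["mean_response"]
                if r and t is not None:
                    changes[marker] = percent_change(r, t)
            if len(changes) >= 2:
                mean, sd = summarize_marker_changes(list(changes.values()))
            else:
                mean = sd = None
            report.setdefault("percent_change_vs_reference", {})[condition] = {
                "reference": reference_condition,
                "per_marker_percent": changes,
                "mean_percent": mean,
                "sd_percent": sd,
            }
    return report


def records_to_frame(records: Sequence[QuantRecord]) -> pd.DataFrame:
    """Flatten QuantRecords into a tidy per-sample, per-species table."""
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "species_label": [r.species_label for r in records],
            "raw_area": [r.raw_area for r in records],
            "normalized_response": [r.normalized_response for r in records],
            "est_amount_mol": [r.est_amount_mol for r in records],
            "matched_rt": [r.matched_rt for r in records],
            "flags": [";".join(sorted(r.flags)) for r in records],
        }
    )
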