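"""Extracted-ion chromatograms and chromatographic peak quantification.

An EIC is built by summing, per spectrum, the centroid intensities whose
m/z falls in a symmetric ppm window around a target; peaks are detected as
local maxima above a robust baseline (median) plus a multiple of a robust
noise scale (1.4826 x median absolute deviation) and integrated by the
trapezoid rule over a local linear baseline.  Identification is by
retention time against a library of expected RTs; isomer pairs sharing one
m/z are resolved purely by RT from one shared EIC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .chem import ppm_window
from .ms_io import SpectrumRun

__all__ = [
    "Chromatogram",
    "ChromPeak",
    "extract_eic",
    "detect_peaks",
    "integrate_peak",
    "match_peak_to_rt",
    "plot_eic",
]


@dataclass
class Chromatogram:
    """Intensity vs retention time for one ppm-windowed m/z target."""

    target_mz: float
    tolerance_ppm: float
    rt: np.ndarray
    intensity: np.ndarray
    run_id: str = ""
    out_of_scan_range: bool = False

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if self.rt.size > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("rt must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity in chromatogram")

    def __len__(self) -> int:
        return self.rt.size


@dataclass
class ChromPeak:
    """One detected chromatographic peak."""

    apex_rt: float
    left_rt: float
    right_rt: float
    height: float
    area: float
    snr: float

    def __post_init__(self) -> None:
        if not (self.left_rt <= self.apex_rt <= self.right_rt):
            raise ValueError("peak apex must lie within its boundaries")


def extract_eic(
    run: SpectrumRun, target_mz: float, tolerance_ppm: float = 5.0
) -> Chromatogram:
    """Extract an ion chromatogram at ppm tolerance.

    Each spectrum contributes the sum of its centroid intensities inside
    ``ppm_window(target_mz, tolerance_ppm)``; spectra with no matching
    centroid contribute zero.  A target outside the declared scan range
    yields an all-zero chromatogram flagged ``out_of_scan_range``.
    """
    if tolerance_ppm <= 0:
        raise ValueError("tolerance_ppm must be positive")
    lo, hi = ppm_window(target_mz, tolerance_ppm)
    out_of_range = False
    if run.scan_range is not None:
        s_lo, s_hi = run.scan_range
        if target_mz < s_lo or target_mz > s_hi:
            out_of_range = True
    rt = run.rt
    intensity = np.zeros(len(run))
    if not out_of_range:
        for i, s in enumerate(run.spectra):
            a = np.searchsorted(s.mz, lo, side="left")
            b = np.searchsorted(s.mz, hi, side="right")
            if b > a:
                intensity[i] = s.intensity[a:b].sum()
    return Chromatogram(
        target_mz=target_mz,
        tolerance_ppm=tolerance_ppm,
        rt=rt,
        intensity=intensity,
        run_id=run.run_id,
        out_of_scan_range=out_of_range,
    )


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    kernel = np.ones(window) / window
    # reflect-pad so the moving average does not shrink edge maxima to zero
    pad = window // 2
    padded = np.concatenate([y[pad:0:-1], y, y[-2 : -2 - pad : -1]])
    out = np.convolve(padded, kernel, mode="valid")
    return out[: y.size]


def detect_peaks(
    chrom: Chromatogram,
    min_snr: float = 3.0,
    smoothing_window: int = 3,
) -> list[ChromPeak]:
    """Detect peaks as smoothed local maxima above baseline + min_snr * noise.

    Baseline is the trace median; noise is the scaled median absolute
    deviation (1.4826 * MAD), both robust to the peaks themselves.  Peak
    boundaries extend from the apex to the nearest local minimum or
    baseline crossing.  Returns peaks sorted by apex RT; a flat trace
    yields an empty list.
    """
    if len(chrom) < 5:
        raise ValueError("need at least 5 chromatogram points")
    y = chrom.intensity
    if np.all(y == y[0]):
        return []
    ys = _smooth(y, smoothing_window)
    baseline = float(np.median(ys))
    mad = float(np.median(np.abs(ys - baseline)))
    noise = 1.4826 * mad
    # floor so a noiseless trace (MAD = 0) still has a positive threshold
    noise_floor = max(noise, 1e-12 * float(ys.max()), 1e-300)
    threshold = baseline + min_snr * noise_floor

    apexes = (
        np.flatnonzero(
            (ys[1:-1] > threshold) & (ys[1:-1] >= ys[:-2]) & (ys[1:-1] > ys[2:])
        )
        + 1
    )

    def boundary(apex: int, direction: int) -> int:
        # walk outward to the baseline crossing, or to the valley floor when
        # the trace rises again into a neighbouring peak; tracking the running
        # minimum makes the walk robust to noise-induced local upticks
        i = best = apex
        n = ys.size
        while True:
            j = i + direction
            if j < 0 or j >= n:
                return best
            i = j
            if ys[i] < ys[best]:
                best = i
            if ys[i] <= baseline:
                return i
            if ys[best] < 0.5 * ys[apex] and ys[i] > 2.0 * max(ys[best], threshold):
                return best

    peaks: list[ChromPeak] = []
    for apex in apexes:
        left = boundary(apex, -1)
        right = boundary(apex, +1)
        if right - left < 2:
            continue
        peak = ChromPeak(
            apex_rt=float(chrom.rt[apex]),
            left_rt=float(chrom.rt[left]),
            right_rt=float(chrom.rt[right]),
            height=float(y[apex]),
            area=0.0,
            snr=float((ys[apex] - baseline) / noise_floor) if noise > 0 else float("inf"),
        )
        peak.area = integrate_peak(chrom, peak)
        if peak.area > 0:
            peaks.append(peak)
    # noise apexes inside one peak walk to (near-)identical boundaries:
    # collapse substantially overlapping detections, keeping the tallest
    peaks.sort(key=lambda p: p.apex_rt)
    merged: list[ChromPeak] = []
    for p in peaks:
        if merged:
            prev = merged[-1]
            overlap = min(prev.right_rt, p.right_rt) - max(prev.left_rt, p.left_rt)
            width = min(prev.right_rt - prev.left_rt, p.right_rt - p.left_rt)
            if width > 0 and overlap > 0.5 * width:
                if p.height > prev.height:
                    merged[-1] = p
                continue
        merged.append(p)
    return merged


def integrate_peak(chrom: Chromatogram, peak: ChromPeak) -> float:
    """Trapezoidal area above a local linear baseline, floored at zero.

    The baseline is the straight line joining the trace values at the peak
    boundaries, with each anchor clipped to the chromatogram's robust
    background level (the trace median) so that a boundary sitting in the
    valley between two overlapping peaks drops to the background instead
    of slicing off the peak flanks.  Units are counts * min.
    """
    if peak.left_rt > peak.right_rt:
        raise ValueError("inverted peak boundaries")
    sel = (chrom.rt >= peak.left_rt - 1e-12) & (chrom.rt <= peak.right_rt + 1e-12)
    rt = chrom.rt[sel]
    y = chrom.intensity[sel]
    if rt.size < 2:
        return 0.0
    background = float(np.median(chrom.intensity))
    anchors = [min(float(y[0]), background), min(float(y[-1]), background)]
    baseline = np.interp(rt, [rt[0], rt[-1]], anchors)
    return float(max(np.trapezoid(y - baseline, rt), 0.0))


def match_peak_to_rt(
    peaks: Sequence[ChromPeak],
    expected_rt: float,
    rt_tolerance: float = 0.15,
) -> Optional[ChromPeak]:
    """Pick the peak nearest an expected RT within tolerance.

    Ties in |RT error| go to the larger area; returns None when no peak
    qualifies (absence is a valid result, not an error).
    """
    if rt_tolerance <= 0:
        raise ValueError("rt_tolerance must be positive")
    candidates = [p for p in peaks if abs(p.apex_rt - expected_rt) <= rt_tolerance]
    if not candidates:
        return None
    return min(candidates, key=lambda p: (abs(p.apex_rt - expected_rt), -p.area))


def plot_eic(
    chrom: Chromatogram,
    peaks: Sequence[ChromPeak] = (),
    path: Optional[str] = None,
    title: Optional[str] = None,
):
    """QC plot of one EIC with detected peak bounds; saves PNG/SVG if ``path``."""
    import matplotlib

    if path:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(chrom.rt, chrom.intensity, lw=0.8, color="k")
    for p in peaks:
        ax.axvspan(p.left_rt, p.right_rt, alpha=0.15, color="tab:blue")
        ax.plot([p.apex_rt], [p.height], "v", color="tab:red", ms=5)
    ax.set_xlabel("retention time (min)")
    ax.set_ylabel("intensity")
    ax.set_title(title or f"EIC m/z {chrom.target_mz:.4f} ± {chrom.tolerance_ppm:g} ppm")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
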