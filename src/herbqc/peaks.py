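"""Chromatographic peak detection, QC metrics and fingerprint construction.

Peaks are detected on a (near-)flat-baseline UV trace, integrated by the
trapezoid rule on the native time grid, and matched across sample batches by
relative retention time (RRT) against an internal-standard reference peak.
The matched batches x common-peaks area matrix is the substrate for the
chemometric and single-marker quantification stages, and each batch's
common-peak profile is scored against the mean profile with the congruence
(cosine) coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, peak_widths

__all__ = [
    "Chromatogram",
    "Peak",
    "PeakTable",
    "RRTTemplate",
    "detect_peaks",
    "asymmetry_factor",
    "resolution",
    "compute_rrt",
    "match_peaks",
    "similarity",
    "qc_report",
]


class ChromatogramError(ValueError):
    """Raised for malformed traces or unresolvable QC measurements."""


class MatchingError(ValueError):
    """Raised when peak-to-template assignment fails or is ambiguous."""


@dataclass
class Chromatogram:
    """A single-wavelength detector trace on a strictly increasing time grid."""

    times: np.ndarray  # minutes
    intensities: np.ndarray
    batch_id: str = ""
    wavelength_nm: float = 325.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.intensities.shape:
            raise ChromatogramError("times and intensities must be equal-length vectors")
        if self.times.size < 2 or not np.all(np.diff(self.times) > 0):
            raise ChromatogramError("time grid must be strictly increasing")


@dataclass
class Peak:
    """One integrated chromatographic peak."""

    apex_time: float  # minutes
    area: float  # intensity * min
    height: float
    left: float
    right: float
    sigma: float  # Gaussian-equivalent width from the half-height width
    asymmetry: float | None = None
    assigned_id: str | None = None
    unresolved: bool = False

    def __post_init__(self) -> None:
        if not (self.left < self.apex_time < self.right):
            raise ChromatogramError("peak bounds must bracket the apex")
        if self.area <= 0:
            raise ChromatogramError("peak area must be positive")


@dataclass
class PeakTable:
    """Batches x common-peaks area matrix with region labels."""

    batch_ids: list[str]
    regions: list[str]
    peak_ids: list[str]
    areas: np.ndarray
    reference_peak: str | None = None

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.batch_ids), len(self.peak_ids)):
            raise ChromatogramError("area matrix shape must be (batches, peaks)")
        if len(self.regions) != len(self.batch_ids):
            raise ChromatogramError("one region label per batch required")

    def validate(self, strict: bool = True) -> None:
        """Reject missing cells (strict) or negative areas (always)."""
        if strict and np.isnan(self.areas).any():
            rows, cols = np.nonzero(np.isnan(self.areas))
            raise ChromatogramError(
                f"missing common-peak cells, first at batch "
                f"{self.batch_ids[rows[0]]!r} / peak {self.peak_ids[cols[0]]!r}"
            )
        with np.errstate(invalid="ignore"):
            if (self.areas < 0).any():
                rows, cols = np.nonzero(self.areas < 0)
                raise ChromatogramError(
                    f"negative area at batch {self.batch_ids[rows[0]]!r} / "
                    f"peak {self.peak_ids[cols[0]]!r}"
                )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.areas, columns=self.peak_ids)
        frame.insert(0, "region", self.regions)
        frame.insert(0, "batch_id", self.batch_ids)
        return frame

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, reference_peak: str | None = None) -> "PeakTable":
        peak_cols = [c for c in frame.columns if c not in ("batch_id", "region")]
        return cls(
            batch_ids=[str(b) for b in frame["batch_id"]],
            regions=[str(r).strip() for r in frame["region"]],
            peak_ids=peak_cols,
            areas=frame[peak_cols].to_numpy(dtype=float),
            reference_peak=reference_peak,
        )

    def region_mask(self, region: str) -> np.ndarray:
        return np.array([r == region for r in self.regions])


@dataclass
class RRTTemplate:
    """Expected relative retention times of the common peaks.

    ``reference_time_min`` is the expected absolute retention of the internal
    standard, used only to locate that peak before everything switches to the
    shift-invariant RRT scale.
    """

    entries: dict[str, float]
    tolerance: float = 0.02  # relative RRT deviation accepted for a match
    reference_peak: str = "reference"
    reference_time_min: float = 12.0

    def __post_init__(self) -> None:
        if self.reference_peak not in self.entries:
            self.entries = {**self.entries, self.reference_peak: 1.0}
        if abs(self.entries[self.reference_peak] - 1.0) > 1e-12:
            raise MatchingError("reference peak must have RRT exactly 1.0")
        if any(v <= 0 for v in self.entries.values()):
            raise MatchingError("all template RRT values must be positive")


# ---------------------------------------------------------------------------
# Detection and QC
# ---------------------------------------------------------------------------


def detect_peaks(
    chrom: Chromatogram,
    min_height: float = 1.0,
    min_prominence: float = 0.5,
) -> list[Peak]:
    """Detect and integrate peaks on a flat-baseline trace.

    One peak per local maximum exceeding the height and prominence
    thresholds (both measured above the baseline, estimated as the median of
    the trace).  Bounds are placed at flanking valleys or where the signal
    returns to baseline; areas are baseline-subtracted trapezoid integrals
    between the bounds.  A peak is flagged ``unresolved`` when the valley
    separating it from a neighbour stays above 50% of the lower apex.
    """
    if min_height <= 0:
        raise ChromatogramError("min_height must be positive")
    t, y = chrom.times, chrom.intensities
    baseline = float(np.median(y))
    signal = y - baseline

    idx, _ = find_peaks(signal, height=min_height, prominence=min_prominence)
    if idx.size == 0:
        return []

    widths, _, _, _ = peak_widths(signal, idx, rel_height=0.5)
    dt = float(np.median(np.diff(t)))

    peaks: list[Peak] = []
    for j, apex in enumerate(idx):
        height = signal[apex]
        floor = max(1e-3 * height, 1e-12)

        left = apex
        lo_limit = idx[j - 1] if j > 0 else 0
        while left > lo_limit and signal[left - 1] <= signal[left] and signal[left] > floor:
            left -= 1
        right = apex
        hi_limit = idx[j + 1] if j + 1 < idx.size else y.size - 1
        while right < hi_limit and signal[right + 1] <= signal[right] and signal[right] > floor:
            right += 1
        if left == apex or right == apex:
            continue

        unresolved = False
        if j > 0:
            valley = signal[idx[j - 1]: apex + 1].min()
            unresolved |= valley > 0.5 * min(signal[idx[j - 1]], height)
        if j + 1 < idx.size:
            valley = signal[apex: idx[j + 1] + 1].min()
            unresolved |= valley > 0.5 * min(signal[idx[j + 1]], height)

        area = float(np.trapezoid(np.clip(signal[left:right + 1], 0, None),
                                  t[left:right + 1]))
        if area <= 0:
            continue
        peaks.append(
            Peak(
                apex_time=float(t[apex]),
                area=area,
                height=float(height),
                left=float(t[left]),
                right=float(t[right]),
                sigma=float(widths[j] * dt / 2.3548),
                unresolved=unresolved,
            )
        )

    for peak in peaks:
        try:
            peak.asymmetry = asymmetry_factor(chrom, peak)
        except ChromatogramError:
            peak.asymmetry = None
    return peaks


def asymmetry_factor(chrom: Chromatogram, peak: Peak) -> float:
    """Peak asymmetry As = b/a at 10% of peak height.

    ``a`` and ``b`` are the front and back half-widths where the
    baseline-corrected signal crosses 10% of the apex height inside the peak
    bounds (pharmacopoeial convention).
    """
    t, y = chrom.times, chrom.intensities
    baseline = float(np.median(y))
    mask = (t >= peak.left) & (t <= peak.right)
    tt, yy = t[mask], y[mask] - baseline
    apex_i = int(np.argmax(yy))
    level = 0.10 * yy[apex_i]

    front = _crossing_time(tt[: apex_i + 1], yy[: apex_i + 1], level, rising=True)
    back = _crossing_time(tt[apex_i:], yy[apex_i:], level, rising=False)
    if front is None or back is None:
        raise ChromatogramError("10% height level not crossed inside peak bounds")
    a = tt[apex_i] - front
    b = back - tt[apex_i]
    if a <= 0 or b <= 0:
        raise ChromatogramError("degenerate half-widths at 10% height")
    return b / a


def _crossing_time(t: np.ndarray, y: np.ndarray, level: float, rising: bool) -> float | None:
    """Linear-interpolated time where y crosses ``level`` nearest the apex."""
    if rising:
        below = np.nonzero(y < level)[0]
        if below.size == 0:
            return None
        i = below[-1]
        if i + 1 >= y.size:
            return None
        j = i + 1
    else:
        below = np.nonzero(y < level)[0]
        if below.size == 0:
            return None
        j = below[0]
        if j == 0:
            return None
        i = j - 1
    if y[j] == y[i]:
        return float(t[i])
    frac = (level - y[i]) / (y[j] - y[i])
    return float(t[i] + frac * (t[j] - t[i]))


def resolution(p1: Peak, p2: Peak) -> float:
    """Chromatographic resolution Rs = 2(t2 - t1)/(w1 + w2).

    Baseline widths are taken as 4 sigma with sigma estimated from the
    half-height width (Gaussian relation w_half = 2.3548 sigma).
    """
    if p1.apex_time > p2.apex_time:
        raise ChromatogramError("resolution requires p1 eluting before p2")
    w1, w2 = 4.0 * p1.sigma, 4.0 * p2.sigma
    if w1 <= 0 or w2 <= 0:
        raise ChromatogramError("peak widths could not be estimated")
    return 2.0 * (p2.apex_time - p1.apex_time) / (w1 + w2)


# ---------------------------------------------------------------------------
# RRT matching
# ---------------------------------------------------------------------------


def compute_rrt(peaks: list[Peak], reference_id: str) -> dict[str, float]:
    """RRT_i = t_i / t_s for every assigned peak; the reference maps to 1.0."""
    ref = [p for p in peaks if p.assigned_id == reference_id]
    if not ref:
        raise MatchingError(f"reference peak {reference_id!r} not assigned")
    t_s = ref[0].apex_time
    return {
        p.assigned_id: p.apex_time / t_s for p in peaks if p.assigned_id is not None
    }


def _find_reference(peaks: list[Peak], template: RRTTemplate) -> Peak:
    """Identify the internal-standard peak near its expected retention.

    Among peaks within +/-5% of the expected reference retention, small ones
    (below half the largest candidate's area) are discarded and the remaining
    candidate closest to the expected time wins: the internal standard is
    abundant in every batch, but a comparably large neighbour must not steal
    the assignment just because its area fluctuated higher.
    """
    lo = 0.95 * template.reference_time_min
    hi = 1.05 * template.reference_time_min
    candidates = [p for p in peaks if lo <= p.apex_time <= hi]
    if not candidates:
        raise MatchingError(
            f"no reference peak within 5% of {template.reference_time_min} min"
        )
    biggest = max(p.area for p in candidates)
    candidates = [p for p in candidates if p.area >= 0.5 * biggest]
    return min(candidates, key=lambda p: abs(p.apex_time - template.reference_time_min))


def match_batch(peaks: list[Peak], template: RRTTemplate) -> tuple[dict[str, Peak], list[str]]:
    """Assign one observed peak to each template entry by nearest RRT.

    Returns (assignments, missing peak ids).  Raises when two template
    entries claim the same observed peak.
    """
    ref = _find_reference(peaks, template)
    t_s = ref.apex_time

    assigned: dict[str, Peak] = {}
    claimed: dict[int, str] = {}
    missing: list[str] = []
    for pid, rrt_exp in template.entries.items():
        best = None
        best_dev = None
        for k, p in enumerate(peaks):
            dev = abs(p.apex_time / t_s - rrt_exp) / rrt_exp
            if dev > template.tolerance:
                continue
            if best is None or dev < best_dev - 1e-12 or (
                abs(dev - best_dev) <= 1e-12 and p.area > best.area
            ):
                best, best_dev, best_k = p, dev, k
        if best is None:
            missing.append(pid)
            continue
        if best_k in claimed:
            raise MatchingError(
                f"observed peak at {best.apex_time:.3f} min claimed by both "
                f"{claimed[best_k]!r} and {pid!r}"
            )
        claimed[best_k] = pid
        best.assigned_id = pid
        assigned[pid] = best
    return assigned, missing


def match_peaks(
    peaks_per_batch: dict[str, list[Peak]],
    template: RRTTemplate,
    regions: dict[str, str] | None = None,
) -> tuple[PeakTable, dict[str, list[str]]]:
    """Build the common-peak area matrix across batches.

    Returns the PeakTable (missing entries as NaN) and a per-batch report of
    unassigned common peaks.  RRT matching cancels uniform retention shifts.
    """
    peak_ids = list(template.entries)
    batch_ids = list(peaks_per_batch)
    areas = np.full((len(batch_ids), len(peak_ids)), np.nan)
    report: dict[str, list[str]] = {}
    for i, batch in enumerate(batch_ids):
        assigned, missing = match_batch(peaks_per_batch[batch], template)
        if missing:
            report[batch] = missing
        for j, pid in enumerate(peak_ids):
            if pid in assigned:
                areas[i, j] = assigned[pid].area
    table = PeakTable(
        batch_ids=batch_ids,
        regions=[regions.get(b, "") if regions else "" for b in batch_ids],
        peak_ids=peak_ids,
        areas=areas,
        reference_peak=template.reference_peak,
    )
    return table, report


# ---------------------------------------------------------------------------
# Fingerprint similarity
# ---------------------------------------------------------------------------


def similarity(profile: np.ndarray, reference: np.ndarray, method: str = "cosine") -> float:
    """Congruence between a batch profile and the reference profile.

    ``cosine`` is the congruence coefficient of the two common-peak area
    vectors (scale-invariant); ``correlation`` is Pearson's r on the same
    vectors, offered as a configuration alternative.
    """
    x = np.asarray(profile, dtype=float)
    y = np.asarray(reference, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ChromatogramError("profiles must be equal-length vectors of length >= 2")
    if (x < 0).any() or (y < 0).any():
        raise ChromatogramError("profiles must be non-negative")
    if not x.any() or not y.any():
        raise ChromatogramError("similarity undefined for a zero profile")
    if method == "cosine":
        return float(x @ y / (np.linalg.norm(x) * np.linalg.norm(y)))
    if method == "correlation":
        return float(np.corrcoef(x, y)[0, 1])
    raise ChromatogramError(f"unknown similarity method {method!r}")


def qc_report(
    table: PeakTable,
    peaks_per_batch: dict[str, list[Peak]] | None = None,
    method: str = "cosine",
) -> pd.DataFrame:
    """Per-batch similarity to the mean profile, plus peak-level QC if given."""
    table.validate(strict=True)
    mean_profile = table.areas.mean(axis=0)
    rows = []
    for i, batch in enumerate(table.batch_ids):
        row: dict[str, object] = {
            "batch_id": batch,
            "similarity": similarity(table.areas[i], mean_profile, method=method),
        }
        if peaks_per_batch is not None:
            assigned = sorted(
                (p for p in peaks_per_batch[batch] if p.assigned_id),
                key=lambda p: p.apex_time,
            )
            if assigned:
                res = [
                    resolution(a, b) for a, b in zip(assigned[:-1], assigned[1:])
                ]
                row["min_resolution"] = min(res) if res else np.nan
                asym = [p.asymmetry for p in assigned if p.asymmetry is not None]
                row["asymmetry_min"] = min(asym) if asym else np.nan
                row["asymmetry_max"] = max(asym) if asym else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
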