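"""Single-marker multicomponent quantification (QAMS) and ESM calibration.

QAMS quantifies several analytes from one internal standard through
pre-established relative correction factors

    f = f_s / f_i = (A_s / C_s) / (A_i / C_i),

so that an analyte concentration follows from C_i = f * C_s * A_i / A_s
without its own standard curve.  Analytes are located by relative retention
time RRT = t_i / t_s.  The external standard method (ESM) fits one ordinary
least-squares calibration line per analyte and inverts it.  Contents are
converted to mg per g of dry material using the extraction stoichiometry
(sample mass and extract volume), and method agreement is measured by the
relative deviation RD% = |C_ESM - C_QAMS| / (C_ESM + C_QAMS) * 100.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import Peak, RRTTemplate, MatchingError

__all__ = [
    "QuantObservation",
    "CorrectionFactorSet",
    "CalibrationData",
    "CalibrationCurve",
    "QuantResult",
    "ExtractionSpec",
    "correction_factor",
    "aggregate_conditions",
    "fit_calibration",
    "quantify_esm",
    "quantify_qams",
    "identify_by_rrt",
    "relative_deviation",
    "summarize_by_region",
    "spike_recovery",
    "load_table1",
    "load_table2",
    "load_table3",
]


class QuantError(ValueError):
    """Raised for invalid quantification inputs."""


@dataclass
class ExtractionSpec:
    """Extraction stoichiometry: mg/g = C (mg/mL) * volume / mass."""

    sample_mass_g: float = 0.2
    extract_volume_ml: float = 25.0

    def __post_init__(self) -> None:
        if self.sample_mass_g <= 0 or self.extract_volume_ml <= 0:
            raise QuantError("sample mass and extract volume must be positive")

    def to_mg_per_g(self, conc_mg_per_ml: float) -> float:
        return conc_mg_per_ml * self.extract_volume_ml / self.sample_mass_g


@dataclass
class QuantObservation:
    """Paired analyte/internal-standard measurement under one condition."""

    analyte: str
    internal_standard: str
    A_i: float
    A_s: float
    C_i: float
    C_s: float
    t_i: float | None = None
    t_s: float | None = None
    condition: str = ""


@dataclass
class CorrectionFactorSet:
    """Per-condition f and RRT values for one analyte, with aggregates."""

    analyte: str
    per_condition_f: dict[str, float]
    per_condition_rrt: dict[str, float] = field(default_factory=dict)

    @property
    def mean_f(self) -> float:
        return aggregate_conditions(self.per_condition_f)[0]

    @property
    def rsd_f(self) -> float:
        return aggregate_conditions(self.per_condition_f)[1]

    @property
    def mean_rrt(self) -> float:
        return aggregate_conditions(self.per_condition_rrt)[0]

    @property
    def rsd_rrt(self) -> float:
        return aggregate_conditions(self.per_condition_rrt)[1]


@dataclass
class CalibrationData:
    """(concentration mg/mL, area) pairs for one analyte."""

    analyte: str
    levels: list[tuple[float, float]]


@dataclass
class CalibrationCurve:
    """Fitted OLS line area = slope * conc + intercept."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    conc_range: tuple[float, float]

    def concentration(self, area: float, clip_negative: bool = True) -> float:
        """Inverse prediction; negative estimates clip to 0 (with warning)."""
        if self.slope == 0:
            raise QuantError("cannot invert a zero-slope calibration")
        c = (area - self.intercept) / self.slope
        if c < 0 and clip_negative:
            import warnings

            warnings.warn(
                f"negative inverse prediction for {self.analyte!r} clipped to 0",
                stacklevel=2,
            )
            return 0.0
        return c


@dataclass
class QuantResult:
    """ESM and QAMS contents (mg/g) for one batch and analyte."""

    batch: str
    region: str
    analyte: str
    c_esm: float
    c_qams: float

    @property
    def rd(self) -> float:
        return relative_deviation(self.c_esm, self.c_qams)


# ---------------------------------------------------------------------------
# Core formulas
# ---------------------------------------------------------------------------


def correction_factor(obs: QuantObservation) -> float:
    """Relative correction factor f = (A_s/C_s) / (A_i/C_i)."""
    for name, v in (("A_s", obs.A_s), ("C_s", obs.C_s), ("A_i", obs.A_i), ("C_i", obs.C_i)):
        if v <= 0:
            raise QuantError(f"{name} must be positive, got {v}")
    return (obs.A_s / obs.C_s) / (obs.A_i / obs.C_i)


def aggregate_conditions(values: dict[str, float] | list[float]) -> tuple[float, float]:
    """Arithmetic mean and RSD% (100 * sd(n-1) / mean) across conditions."""
    vals = np.asarray(list(values.values()) if isinstance(values, dict) else values,
                      dtype=float)
    if vals.size < 2:
        raise QuantError("aggregation requires at least two condition values")
    mean = float(vals.mean())
    if mean == 0:
        raise QuantError("RSD undefined for zero mean")
    return mean, float(100.0 * vals.std(ddof=1) / mean)


def fit_calibration(data: CalibrationData) -> CalibrationCurve:
    """Ordinary least-squares calibration line with free intercept."""
    if len(data.levels) < 2:
        raise QuantError("calibration needs at least two levels")
    conc = np.array([c for c, _ in data.levels], dtype=float)
    area = np.array([a for _, a in data.levels], dtype=float)
    if np.unique(conc).size < 2:
        raise QuantError("calibration concentrations must not all coincide")
    fit = stats.linregress(conc, area)
    return CalibrationCurve(
        analyte=data.analyte,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        conc_range=(float(conc.min()), float(conc.max())),
    )


def quantify_esm(
    A_i: float, curve: CalibrationCurve, ext: ExtractionSpec | None = None
) -> float:
    """External-standard content in mg/g from one peak area."""
    ext = ext or ExtractionSpec()
    lo = curve.slope * curve.conc_range[0] + curve.intercept
    hi = curve.slope * curve.conc_range[1] + curve.intercept
    if not (min(lo, hi) <= A_i <= max(lo, hi)):
        import warnings

        warnings.warn(
            f"area {A_i:.4g} outside the calibrated response range of "
            f"{curve.analyte!r}", stacklevel=2,
        )
    return ext.to_mg_per_g(curve.concentration(A_i))


def quantify_qams(
    A_i: float,
    A_s: float,
    C_s: float,
    f: float,
    ext: ExtractionSpec | None = None,
) -> float:
    """Single-marker content in mg/g: C_i = f * C_s * A_i / A_s, then mg/g."""
    if A_s <= 0:
        raise QuantError("internal-standard area must be positive")
    if f <= 0:
        raise QuantError("correction factor must be positive")
    ext = ext or ExtractionSpec()
    return ext.to_mg_per_g(f * C_s * A_i / A_s)


def identify_by_rrt(
    peaks: list[Peak], template: RRTTemplate, reference_time: float | None = None
) -> dict[str, Peak]:
    """Assign analytes to detected peaks by nearest template RRT.

    The reference peak must already be assigned (or ``reference_time``
    given).  Each analyte goes to the peak minimising |RRT_obs - RRT_exp|
    within the template tolerance; double assignment raises.
    """
    if reference_time is None:
        ref = [p for p in peaks if p.assigned_id == template.reference_peak]
        if not ref:
            raise MatchingError("reference peak not assigned; supply reference_time")
        reference_time = ref[0].apex_time

    out: dict[str, Peak] = {}
    claimed: dict[int, str] = {}
    for analyte, rrt_exp in template.entries.items():
        best, best_dev, best_k = None, None, None
        for k, p in enumerate(peaks):
            dev = abs(p.apex_time / reference_time - rrt_exp) / rrt_exp
            if dev > template.tolerance:
                continue
            if best is None or dev < best_dev:
                best, best_dev, best_k = p, dev, k
        if best is None:
            continue
        if best_k in claimed:
            raise MatchingError(
                f"peak at {best.apex_time:.3f} min claimed by both "
                f"{claimed[best_k]!r} and {analyte!r}"
            )
        claimed[best_k] = analyte
        out[analyte] = best
    return out


def relative_deviation(c_esm: float, c_qams: float, conventional: bool = False) -> float:
    """Method-agreement RD% between ESM and QAMS contents.

    Default is |ESM - QAMS| / (ESM + QAMS) * 100; ``conventional=True``
    switches to |ESM - QAMS| / ESM * 100.
    """
    if conventional:
        if c_esm == 0:
            raise QuantError("conventional RD undefined for zero ESM content")
        return abs(c_esm - c_qams) / c_esm * 100.0
    total = c_esm + c_qams
    if total <= 0:
        raise QuantError("RD undefined when both contents are zero")
    return abs(c_esm - c_qams) / total * 100.0


def summarize_by_region(
    results: list[QuantResult] | pd.DataFrame, value: str = "c_esm"
) -> pd.DataFrame:
    """Arithmetic mean content per (region, analyte), plus per-batch totals.

    Totals sum the non-internal-standard analytes of each batch; the column
    ``total`` in the output is the region mean of those batch totals.
    """
    if isinstance(results, pd.DataFrame):
        frame = results.copy()
    else:
        frame = pd.DataFrame(
            [
                {
                    "batch": r.batch,
                    "region": r.region,
                    "analyte": r.analyte,
                    "c_esm": r.c_esm,
                    "c_qams": r.c_qams,
                }
                for r in results
            ]
        )
    if frame.empty:
        raise QuantError("no quantification results to summarise")
    means = frame.pivot_table(index="region", columns="analyte", values=value,
                              aggfunc="mean")
    totals = (
        frame.groupby(["region", "batch"])[value].sum().groupby("region").mean()
    )
    means["total"] = totals
    return means


def spike_recovery(measured_spiked: float, measured_base: float, added: float) -> float:
    """Spike-and-recovery percentage: 100 * (spiked - base) / added."""
    if added <= 0:
        raise QuantError("spiked amount must be positive")
    return 100.0 * (measured_spiked - measured_base) / added


# ---------------------------------------------------------------------------
# Packaged reference tables
# ---------------------------------------------------------------------------


def _read_packaged(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("herbqc.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def load_table1() -> pd.DataFrame:
    """Per-condition relative correction factors (19 robustness conditions)."""
    return _read_packaged("table1_correction_factors.csv")


def load_table2() -> pd.DataFrame:
    """Per-condition relative retention times (19 robustness conditions)."""
    return _read_packaged("table2_relative_retention.csv")


def load_table3() -> pd.DataFrame:
    """Published ESM/QAMS batch contents (tidy: batch, region, analyte, ...)."""
    return _read_packaged("table3_batch_contents.csv")
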