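"""Synthetic inputs for the whole pipeline: batch sets, traces, spectra, curves.

The generator emulates an 18-batch study of a dried-leaf herbal material from
two producing regions ("HN" and "HB", nine batches each) whose UV fingerprints
share 18 common peaks.  Region-dependent abundances for the eight compounds
with published batch contents are taken from the packaged reference table;
seven peaks are planted as genuine regional markers, the rest have equal
region means.  Peak areas follow

    area = C_extract (mg/mL) * response_factor * lognormal noise,

with C_extract = content (mg/g) * sample_mass / extract_volume, so a full
noise-free round trip through detection, matching and external-standard
calibration recovers the planted contents to within numerical integration
error.  MS2 spectra are emitted from the fragmentation-rule library at its
reference relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from . import msannot
from .msannot import Spectrum
from .peaks import Chromatogram, PeakTable, RRTTemplate
from .qams import CalibrationData, ExtractionSpec, load_table1, load_table3

__all__ = [
    "RegionEffectSpec",
    "ChromTemplate",
    "GroundTruth",
    "PEAK_COMPOUNDS",
    "MARKER_PEAKS",
    "REGIONS",
    "default_region_specs",
    "default_response_factors",
    "default_template",
    "default_rrt_template",
    "simulate_batch_set",
    "simulate_chromatogram",
    "simulate_ms2",
    "simulate_calibration",
]


class ConfigurationError(ValueError):
    """Raised for inconsistent generator configuration."""


class ResolutionError(ValueError):
    """Raised when the sampling grid cannot resolve the peak shape."""


REGIONS = ("HN", "HB")

#: Common-peak roster (fingerprint numbering) -> compound identity.
PEAK_COMPOUNDS: dict[str, str] = {
    "P1": "neochlorogenic acid",
    "P2": "chlorogenic acid",
    "P3": "cryptochlorogenic acid",
    "P4": "caffeic acid",
    "P5": "schaftoside",
    "P6": "neoschaftoside",
    "P7": "rutin",
    "P8": "isochlorogenic acid B",
    "P9": "1,5-O-dicaffeoylquinic acid",
    "P10": "isochlorogenic acid A",
    "P11": "isochlorogenic acid C",
    "P12": "3,4,5-tricaffeoylquinic acid",
    "P13": "apigenin",
    "P14": "diosmetin",
    "P15": "jaceosidin",
    "P16": "centaureidin",
    "P17": "eupatilin",
    "P18": "pectolinarigenin",
}

COMPOUND_PEAKS = {v: k for k, v in PEAK_COMPOUNDS.items()}

#: The seven planted regional markers (the internal standard P11 among them).
MARKER_PEAKS = ("P2", "P8", "P9", "P10", "P11", "P12", "P17")

REFERENCE_PEAK = "P11"  # isochlorogenic acid C, the internal standard

#: Template relative retention times; measured averages where published,
#: interpolated placements elsewhere.  Reference peak at RRT 1.0 (12.0 min).
TEMPLATE_RRT: dict[str, float] = {
    "P1": 0.219,
    "P2": 0.348,
    "P3": 0.397,
    "P4": 0.454,
    "P5": 0.55,
    "P6": 0.62,
    "P7": 0.72,
    "P8": 0.891,
    "P9": 0.93,
    "P10": 0.96,
    "P11": 1.0,
    "P12": 1.10,
    "P13": 1.20,
    "P14": 1.28,
    "P15": 1.390,
    "P16": 1.47,
    "P17": 1.554,
    "P18": 1.63,
}

REFERENCE_TIME_MIN = 12.0

#: Default batch-to-batch relative variability of peak areas.
DEFAULT_NOISE_CV = 0.10


@dataclass
class RegionEffectSpec:
    """Planted abundance of one compound: region means and batch variability."""

    compound_id: str
    region_means: dict[str, float]  # mg/g per region
    cv: float = DEFAULT_NOISE_CV
    distribution: str = "lognormal"

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.region_means.values()):
            raise ConfigurationError("region means must be strictly positive")
        if self.cv < 0:
            raise ConfigurationError("cv must be non-negative")
        if self.distribution != "lognormal":
            raise ConfigurationError("only the lognormal noise model is implemented")


@dataclass
class ChromTemplate:
    """Retention-time layout and peak shape for simulated traces."""

    peak_ids: list[str]
    retention_times: dict[str, float]  # minutes
    reference_peak: str = REFERENCE_PEAK
    peak_width_sigma: float = 0.05  # minutes
    baseline_level: float = 0.0
    tailing: float = 0.0  # 0 = symmetric; b/a at 10% height = 1 + tailing
    sampling_step: float = 0.005  # minutes

    def __post_init__(self) -> None:
        times = [self.retention_times[p] for p in self.peak_ids]
        if any(b <= a for a, b in zip(times[:-1], times[1:])):
            raise ConfigurationError("retention times must be strictly increasing")
        if self.reference_peak not in self.peak_ids:
            raise ConfigurationError("reference peak must be in the roster")
        if self.peak_width_sigma <= 0:
            raise ConfigurationError("peak width must be positive")


@dataclass
class GroundTruth:
    """Planted contents for one simulated batch."""

    batch_id: str
    region: str
    true_concentrations: dict[str, float]  # compound -> mg/g
    seed: int


def default_template() -> ChromTemplate:
    peak_ids = list(PEAK_COMPOUNDS)
    times = {p: TEMPLATE_RRT[p] * REFERENCE_TIME_MIN for p in peak_ids}
    return ChromTemplate(peak_ids=peak_ids, retention_times=times)


def default_rrt_template(tolerance: float = 0.02) -> RRTTemplate:
    return RRTTemplate(
        entries=dict(TEMPLATE_RRT),
        tolerance=tolerance,
        reference_peak=REFERENCE_PEAK,
        reference_time_min=REFERENCE_TIME_MIN,
    )


# Planted contents without a published batch table: the HN-rich / HB-rich
# direction follows the fingerprint loading analysis, magnitudes sit at the
# scale of the published contents.
_UNPUBLISHED_MEANS: dict[str, tuple[float, float]] = {  # (HN, HB) mg/g
    "schaftoside": (0.60, 0.60),
    "neoschaftoside": (0.35, 0.35),
    "rutin": (0.80, 0.80),
    "1,5-O-dicaffeoylquinic acid": (1.30, 0.75),
    "isochlorogenic acid A": (2.60, 1.40),
    "3,4,5-tricaffeoylquinic acid": (0.45, 0.95),
    "apigenin": (0.30, 0.30),
    "diosmetin": (0.25, 0.25),
    "centaureidin": (0.28, 0.28),
    "pectolinarigenin": (0.40, 0.40),
}

# Published region means for isochlorogenic acid B are indistinguishable
# (1.825 vs 1.768 mg/g) although the compound is a confirmed marker, so the
# generator plants a contrast at the scale of the other marker contrasts.
_ISO_B_MEANS = (2.20, 1.40)


@lru_cache(maxsize=1)
def _table3_region_means() -> dict[str, dict[str, float]]:
    frame = load_table3()
    frame = frame[frame["analyte"] != "total"]
    piv = frame.pivot_table(index="analyte", columns="region", values="esm",
                            aggfunc="mean")
    return {a: {"HN": float(piv.loc[a, "HN"]), "HB": float(piv.loc[a, "HB"])}
            for a in piv.index}


def default_region_specs(cv: float = DEFAULT_NOISE_CV) -> list[RegionEffectSpec]:
    """Planted contents for the 18 common peaks.

    Marker peaks get differential region means (published means where the
    published contrast is real); every other peak gets equal means (the
    pooled published mean where one exists).
    """
    table3 = _table3_region_means()
    specs = []
    for pid, compound in PEAK_COMPOUNDS.items():
        if compound == "isochlorogenic acid B":
            means = {"HN": _ISO_B_MEANS[0], "HB": _ISO_B_MEANS[1]}
        elif compound in table3:
            m = table3[compound]
            if pid in MARKER_PEAKS:
                means = dict(m)
            else:
                pooled = (m["HN"] + m["HB"]) / 2.0
                means = {"HN": pooled, "HB": pooled}
        else:
            hn, hb = _UNPUBLISHED_MEANS[compound]
            means = {"HN": hn, "HB": hb}
        specs.append(RegionEffectSpec(compound_id=compound, region_means=means, cv=cv))
    return specs


@lru_cache(maxsize=1)
def default_response_factors() -> dict[str, float]:
    """Fixed detector response factors (area units per mg/mL).

    The internal standard is pinned at 500; the seven single-marker analytes
    derive from it through the published mean correction factors, so the
    correction factors recomputed downstream land at the published
    magnitudes.  The remaining roster compounds use fixed nearby values.
    """
    rf = {"isochlorogenic acid C": 500.0}
    table1 = load_table1()
    for analyte in table1.columns[2:]:
        rf[analyte] = 500.0 / float(table1[analyte].mean())
    rf.update(
        {
            "schaftoside": 420.0,
            "neoschaftoside": 430.0,
            "rutin": 460.0,
            "1,5-O-dicaffeoylquinic acid": 520.0,
            "isochlorogenic acid A": 510.0,
            "3,4,5-tricaffeoylquinic acid": 480.0,
            "apigenin": 550.0,
            "diosmetin": 540.0,
            "centaureidin": 450.0,
            "pectolinarigenin": 470.0,
        }
    )
    return rf


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with mean exactly 1."""
    if cv == 0:
        return np.ones(size if size is not None else ())
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_batch_set(
    specs: list[RegionEffectSpec] | None = None,
    n_per_region: int = 9,
    noise_cv: float | None = None,
    seed: int = 0,
    ext: ExtractionSpec | None = None,
    response_factors: dict[str, float] | None = None,
) -> tuple[PeakTable, list[GroundTruth]]:
    """Generate the batches x common-peaks area matrix with planted effects.

    Per-compound noise_cv (when given) overrides each spec's own cv.  The
    planted content of a batch is its region mean; noise is multiplicative
    lognormal on the areas.
    """
    if specs is None:
        specs = default_region_specs()
    if n_per_region < 2:
        raise ConfigurationError("need at least two batches per region")
    ext = ext or ExtractionSpec()
    rf = response_factors or default_response_factors()

    for spec in specs:
        if spec.compound_id not in COMPOUND_PEAKS:
            raise ConfigurationError(f"unknown compound {spec.compound_id!r}")
        for region in spec.region_means:
            if region not in REGIONS:
                raise ConfigurationError(f"unknown region label {spec.region_means} "
                                         f"({region!r})")

    peak_ids = [COMPOUND_PEAKS[s.compound_id] for s in specs]
    order = np.argsort([int(p[1:]) for p in peak_ids])
    specs = [specs[i] for i in order]
    peak_ids = [peak_ids[i] for i in order]

    rng = np.random.default_rng(seed)
    batch_ids, regions, truths = [], [], []
    areas = np.zeros((n_per_region * len(REGIONS), len(specs)))
    row = 0
    for region in REGIONS:
        for k in range(n_per_region):
            batch = f"{region}{k + 1}"
            contents = {s.compound_id: s.region_means[region] for s in specs}
            for j, s in enumerate(specs):
                cv = noise_cv if noise_cv is not None else s.cv
                conc_extract = contents[s.compound_id] * ext.sample_mass_g / ext.extract_volume_ml
                noise = float(_lognormal_factors(rng, cv, None))
                areas[row, j] = conc_extract * rf[s.compound_id] * noise
            batch_ids.append(batch)
            regions.append(region)
            truths.append(
                GroundTruth(batch_id=batch, region=region,
                            true_concentrations=contents, seed=seed)
            )
            row += 1

    table = PeakTable(
        batch_ids=batch_ids,
        regions=regions,
        peak_ids=peak_ids,
        areas=areas,
        reference_peak=REFERENCE_PEAK,
    )
    return table, truths


def simulate_chromatogram(
    truth: GroundTruth,
    template: ChromTemplate | None = None,
    noise_sd: float = 0.0,
    ext: ExtractionSpec | None = None,
    response_factors: dict[str, float] | None = None,
    seed: int = 0,
) -> Chromatogram:
    """Render one batch as a UV trace: Gaussian peaks on a flat baseline.

    Peak areas equal C_extract * response_factor; an optional tailing
    parameter skews the back half-width.  The numeric integral of an isolated
    peak reproduces its specified area to well under 1%.
    """
    template = template or default_template()
    ext = ext or ExtractionSpec()
    rf = response_factors or default_response_factors()
    sig = template.peak_width_sigma
    if template.sampling_step >= sig / 5:
        raise ResolutionError(
            f"sampling step {template.sampling_step} min too coarse for "
            f"sigma {sig} min (need < sigma/5)"
        )

    t_max = max(template.retention_times.values()) + 10 * sig + 1.0
    t = np.arange(0.0, t_max, template.sampling_step)
    y = np.full_like(t, float(template.baseline_level))

    sig_l = sig
    sig_r = sig * (1.0 + template.tailing)
    norm = np.sqrt(2 * np.pi) * 0.5 * (sig_l + sig_r)
    for pid in template.peak_ids:
        compound = PEAK_COMPOUNDS[pid]
        content = truth.true_concentrations.get(compound, 0.0)
        if content <= 0:
            continue
        area = content * ext.sample_mass_g / ext.extract_volume_ml * rf[compound]
        mu = template.retention_times[pid]
        height = area / norm
        left = t < mu
        y += np.where(
            left,
            height * np.exp(-0.5 * ((t - mu) / sig_l) ** 2),
            height * np.exp(-0.5 * ((t - mu) / sig_r) ** 2),
        )

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.size)

    return Chromatogram(times=t, intensities=y, batch_id=truth.batch_id)


def simulate_ms2(
    compound_id: str,
    polarity: str = "negative",
    abundance_noise_cv: float = 0.0,
    seed: int = 0,
) -> Spectrum:
    """Emit the rule library's reference MS2 spectrum for one compound.

    Diagnostic ions appear at their theoretical m/z and reference relative
    abundances, perturbed by multiplicative lognormal noise and rescaled so
    the base peak is 100%.
    """
    rule = msannot.get_rule(compound_id)
    ions = rule.reference_spectrum(polarity)
    rng = np.random.default_rng(seed)
    noise = _lognormal_factors(rng, abundance_noise_cv, len(ions))
    raw = np.array([ion.abundance for ion in ions]) * noise
    rescaled = 100.0 * (raw / raw.max())  # base peak lands at exactly 100
    peaks = [(ion.mz, float(ab)) for ion, ab in zip(ions, rescaled)]
    return Spectrum(
        precursor_mz=rule.precursor_mz(polarity),
        polarity=polarity,
        peaks=peaks,
        spectrum_id=f"{compound_id} [{polarity}]",
    )


def simulate_robustness(
    analytes: list[str] | None = None,
    internal_standard: str = "isochlorogenic acid C",
    n_conditions: int = 19,
    seed: int = 0,
    conc_mg_per_ml: float = 0.05,
    response_common: float = 0.05,
    response_differential: float = 0.02,
    retention_common: float = 0.02,
    retention_differential: float = 0.005,
) -> pd.DataFrame:
    """Correction factors and RRTs under simulated condition changes.

    Each condition perturbs detector response by a common factor (uniform
    +/-5%, shared by analyte and internal standard, cancelling in f) plus a
    small differential factor (+/-2% per compound), and retention by a common
    +/-2% shift plus a +/-0.5% differential.  The common parts model
    instrument/column/flow effects that the ratio formulation removes - the
    robustness the single-marker method relies on - while the differential
    parts set the residual RSD scale.
    """
    if analytes is None:
        analytes = [
            c for c in (
                "neochlorogenic acid", "chlorogenic acid", "cryptochlorogenic acid",
                "caffeic acid", "isochlorogenic acid B", "jaceosidin", "eupatilin",
            )
        ]
    rf = default_response_factors()
    rng = np.random.default_rng(seed)
    t_ref = REFERENCE_TIME_MIN
    rows = []
    for k in range(n_conditions):
        common_resp = 1.0 + rng.uniform(-response_common, response_common)
        common_ret = 1.0 + rng.uniform(-retention_common, retention_common)
        resp_s = rf[internal_standard] * common_resp * (
            1.0 + rng.uniform(-response_differential, response_differential)
        )
        t_s = t_ref * common_ret * (
            1.0 + rng.uniform(-retention_differential, retention_differential)
        )
        a_s = resp_s * conc_mg_per_ml
        for analyte in analytes:
            resp_i = rf[analyte] * common_resp * (
                1.0 + rng.uniform(-response_differential, response_differential)
            )
            t_i = (
                TEMPLATE_RRT[COMPOUND_PEAKS[analyte]]
                * t_ref
                * common_ret
                * (1.0 + rng.uniform(-retention_differential, retention_differential))
            )
            a_i = resp_i * conc_mg_per_ml
            f = (a_s / conc_mg_per_ml) / (a_i / conc_mg_per_ml)
            rows.append(
                {
                    "condition": f"condition-{k + 1}",
                    "analyte": analyte,
                    "f": f,
                    "rrt": t_i / t_s,
                }
            )
    return pd.DataFrame(rows)


def simulate_calibration(
    compound_id: str,
    levels: list[float] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
    response_factors: dict[str, float] | None = None,
) -> CalibrationData:
    """Dilution-series calibration data: area = RF * concentration * noise."""
    rf = response_factors or default_response_factors()
    if compound_id not in rf:
        raise ConfigurationError(f"unknown compound {compound_id!r}")
    if levels is None:
        # 7-level geometric series spanning the extract concentrations that
        # 0.025-6 mg/g contents produce under the default extraction
        levels = list(np.geomspace(0.0002, 0.05, 7))  # mg/mL
    if len(levels) < 2:
        raise ConfigurationError("calibration needs at least two levels")
    if any(c <= 0 for c in levels):
        raise ConfigurationError("calibration levels must be positive")
    rng = np.random.default_rng(seed)
    noise = _lognormal_factors(rng, noise_cv, len(levels))
    pairs = [(float(c), float(rf[compound_id] * c * nz)) for c, nz in zip(levels, noise)]
    return CalibrationData(analyte=compound_id, levels=pairs)
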