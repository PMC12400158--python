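"""File formats, configuration, logging and the end-to-end pipeline runner.

Tables travel as RFC-4180 CSV, chromatograms as two-column CSV
(time_min, intensity), MS2 spectra as MGF, and configuration as YAML with a
strict schema (unknown keys are rejected before any stage runs).  Readers
validate rather than coerce; writers round to 6 significant digits except the
batch-content report, which uses 3 decimals.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pyteomics import mgf as _mgf

from . import chemo, qams, synth
from .msannot import Spectrum, annotate
from .peaks import (
    Chromatogram,
    PeakTable,
    detect_peaks,
    match_peaks,
    qc_report,
)
from .qams import (
    CalibrationData,
    ExtractionSpec,
    QuantResult,
    correction_factor,
    QuantObservation,
    fit_calibration,
    quantify_esm,
    quantify_qams,
    relative_deviation,
    summarize_by_region,
)

__all__ = [
    "PipelineConfig",
    "RunLog",
    "read_peak_table",
    "write_peak_table",
    "read_chromatogram",
    "write_chromatogram",
    "read_mgf",
    "write_mgf",
    "read_calibration",
    "write_calibration",
    "write_ground_truths",
    "run_pipeline",
]

logger = logging.getLogger("herbqc")


class IOValidationError(ValueError):
    """Raised when an input file fails validation."""


def configure_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@dataclass
class RunLog:
    """Timestamped stage events and warnings; warnings carry identifiers."""

    events: list[tuple[float, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)

    def stage(self, name: str, message: str = "") -> None:
        self.events.append((time.time(), name, message))
        logger.info("stage %s %s", name, message)

    def warn(self, identifier: str, message: str) -> None:
        self.warnings.append((identifier, message))
        logger.warning("%s: %s", identifier, message)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for ts, name, msg in self.events:
                fh.write(f"{time.strftime('%Y-%m-%dT%H:%M:%S', time.gmtime(ts))}\t"
                         f"STAGE\t{name}\t{msg}\n")
            for ident, msg in self.warnings:
                fh.write(f"-\tWARNING\t{ident}\t{msg}\n")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def write_peak_table(table: PeakTable, path: str | Path, decimals: int | None = None) -> None:
    frame = table.to_frame()
    if decimals is not None:
        frame = frame.round(decimals)
        frame.to_csv(path, index=False, float_format=f"%.{decimals}f")
    else:
        frame.to_csv(path, index=False, float_format="%.6g")


def read_peak_table(path: str | Path, reference_peak: str | None = None) -> PeakTable:
    """Read and validate a batches x peaks CSV (header: batch_id, region, peaks)."""
    frame = pd.read_csv(path)
    for col in ("batch_id", "region"):
        if col not in frame.columns:
            raise IOValidationError(f"peak table missing required column {col!r}")
    peak_cols = [c for c in frame.columns if c not in ("batch_id", "region")]
    if not peak_cols:
        raise IOValidationError("peak table has no peak columns")
    for col in peak_cols:
        series = pd.to_numeric(frame[col], errors="coerce")
        if series.isna().any():
            row = frame.loc[series.isna(), "batch_id"].iloc[0]
            raise IOValidationError(
                f"missing or non-numeric area at batch {row!r}, peak {col!r}"
            )
        if (series < 0).any():
            row = frame.loc[series < 0, "batch_id"].iloc[0]
            raise IOValidationError(f"negative area at batch {row!r}, peak {col!r}")
        frame[col] = series
    return PeakTable.from_frame(frame, reference_peak=reference_peak)


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    pd.DataFrame({"time_min": chrom.times, "intensity": chrom.intensities}).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_chromatogram(path: str | Path, batch_id: str = "") -> Chromatogram:
    frame = pd.read_csv(path)
    for col in ("time_min", "intensity"):
        if col not in frame.columns:
            raise IOValidationError(f"chromatogram missing column {col!r}")
    return Chromatogram(
        times=frame["time_min"].to_numpy(float),
        intensities=frame["intensity"].to_numpy(float),
        batch_id=batch_id or Path(path).stem,
    )


def write_mgf(spectra: list[Spectrum], path: str | Path) -> None:
    records = []
    for i, spec in enumerate(spectra):
        mz = np.array([m for m, _ in spec.peaks])
        ab = np.array([a for _, a in spec.peaks])
        records.append(
            {
                "m/z array": mz,
                "intensity array": ab,
                "params": {
                    "title": spec.spectrum_id or f"spectrum_{i}",
                    "pepmass": spec.precursor_mz,
                    "charge": "1-" if spec.polarity == "negative" else "1+",
                },
            }
        )
    _mgf.write(records, str(path), file_mode="w")


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read MGF blocks; abundances are rescaled to percent of base peak."""
    spectra = []
    with _mgf.read(str(path)) as reader:
        for block in reader:
            params = block["params"]
            if "pepmass" not in params:
                raise IOValidationError(f"MGF block without PEPMASS in {path}")
            charge = str(params.get("charge", ["1-"])[0])
            polarity = "negative" if "-" in charge else "positive"
            ab = np.asarray(block["intensity array"], dtype=float)
            if ab.size == 0:
                continue
            ab = 100.0 * ab / ab.max()
            peaks = [(float(m), float(a)) for m, a in zip(block["m/z array"], ab)]
            spectra.append(
                Spectrum(
                    precursor_mz=float(params["pepmass"][0]),
                    polarity=polarity,
                    peaks=peaks,
                    spectrum_id=str(params.get("title", "")),
                )
            )
    return spectra


def write_calibration(data: list[CalibrationData], path: str | Path) -> None:
    rows = [
        {"analyte": d.analyte, "concentration": c, "area": a}
        for d in data
        for c, a in d.levels
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


def read_calibration(path: str | Path) -> list[CalibrationData]:
    frame = pd.read_csv(path)
    for col in ("analyte", "concentration", "area"):
        if col not in frame.columns:
            raise IOValidationError(f"calibration file missing column {col!r}")
    out = []
    for analyte, grp in frame.groupby("analyte", sort=False):
        levels = list(zip(grp["concentration"].astype(float), grp["area"].astype(float)))
        out.append(CalibrationData(analyte=str(analyte), levels=levels))
    return out


def write_ground_truths(truths: list[synth.GroundTruth], path: str | Path) -> None:
    rows = [
        {"batch_id": t.batch_id, "region": t.region, "compound": c,
         "mg_per_g": v, "seed": t.seed}
        for t in truths
        for c, v in t.true_concentrations.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Schema-validated pipeline options; unknown keys are rejected."""

    seed: int = 0
    n_per_region: int = 9
    noise_cv: float = synth.DEFAULT_NOISE_CV
    internal_standard: str = "isochlorogenic acid C"
    rrt_tolerance: float = 0.02
    ppm_tolerance: float = 10.0
    scaling: str = "autoscale"
    n_orthogonal: int = 1
    n_permutations: int = 200
    cv_folds: int = 7
    similarity_method: str = "cosine"
    sample_mass_g: float = 0.2
    extract_volume_ml: float = 25.0

    def __post_init__(self) -> None:
        if self.internal_standard not in synth.COMPOUND_PEAKS:
            raise IOValidationError(
                f"internal standard {self.internal_standard!r} is not a roster compound"
            )
        if self.scaling not in ("center", "autoscale", "pareto"):
            raise IOValidationError(f"unknown scaling {self.scaling!r}")
        if self.similarity_method not in ("cosine", "correlation"):
            raise IOValidationError(f"unknown similarity method {self.similarity_method!r}")
        if self.n_per_region < 2 or self.n_permutations < 20 or self.cv_folds < 2:
            raise IOValidationError("n_per_region >= 2, n_permutations >= 20, cv_folds >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise IOValidationError("config must be a YAML mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise IOValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def extraction(self) -> ExtractionSpec:
        return ExtractionSpec(self.sample_mass_g, self.extract_volume_ml)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

QAMS_ANALYTES = (
    "neochlorogenic acid",
    "chlorogenic acid",
    "cryptochlorogenic acid",
    "caffeic acid",
    "isochlorogenic acid B",
    "jaceosidin",
    "eupatilin",
)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Simulate -> fingerprint -> chemometrics -> single-marker quantification.

    Writes every intermediate as CSV plus a run log and returns the artifact
    paths.  A stage failure propagates (non-zero exit in the CLI).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = RunLog()
    artifacts: dict[str, Path] = {}
    ext = config.extraction()

    # --- simulate -----------------------------------------------------------
    log.stage("simulate", f"seed={config.seed} n_per_region={config.n_per_region}")
    table, truths = synth.simulate_batch_set(
        n_per_region=config.n_per_region,
        noise_cv=config.noise_cv,
        seed=config.seed,
        ext=ext,
    )
    artifacts["peak_table"] = out / "peak_table.csv"
    write_peak_table(table, artifacts["peak_table"])
    artifacts["ground_truth"] = out / "ground_truth.csv"
    write_ground_truths(truths, artifacts["ground_truth"])

    template = synth.default_template()
    rrt_template = synth.default_rrt_template(tolerance=config.rrt_tolerance)
    chrom_dir = out / "chromatograms"
    chrom_dir.mkdir(exist_ok=True)
    peaks_per_batch = {}
    rng = np.random.default_rng(config.seed)
    for truth, row in zip(truths, table.areas):
        # render the trace from the noisy areas so fingerprints inherit noise
        noisy = synth.GroundTruth(
            batch_id=truth.batch_id,
            region=truth.region,
            true_concentrations={
                synth.PEAK_COMPOUNDS[p]: float(
                    row[j]
                    / synth.default_response_factors()[synth.PEAK_COMPOUNDS[p]]
                    / ext.sample_mass_g
                    * ext.extract_volume_ml
                )
                for j, p in enumerate(table.peak_ids)
            },
            seed=config.seed,
        )
        chrom = synth.simulate_chromatogram(
            noisy, template, ext=ext, seed=int(rng.integers(2**31))
        )
        write_chromatogram(chrom, chrom_dir / f"{truth.batch_id}.csv")
        peaks_per_batch[truth.batch_id] = detect_peaks(chrom)

    # --- fingerprint --------------------------------------------------------
    log.stage("fingerprint", f"{len(peaks_per_batch)} traces")
    matched, missing = match_peaks(
        peaks_per_batch,
        rrt_template,
        regions={t.batch_id: t.region for t in truths},
    )
    for batch, pids in missing.items():
        log.warn(batch, f"unmatched common peaks: {pids}")
    matched.validate(strict=True)
    artifacts["matched"] = out / "matched.csv"
    write_peak_table(matched, artifacts["matched"])
    artifacts["qc"] = out / "qc_report.csv"
    qc_report(matched, peaks_per_batch, method=config.similarity_method).to_csv(
        artifacts["qc"], index=False, float_format="%.6g"
    )

    # --- chemometrics -------------------------------------------------------
    log.stage("chemo", f"scaling={config.scaling}")
    X, _ = chemo.preprocess(matched, scaling=config.scaling)
    y, coding = chemo.encode_labels(matched.regions)
    pca_model = chemo.pca(X, n_components=min(4, len(matched.batch_ids) - 1))
    model = chemo.oplsda(X, y, n_orthogonal=config.n_orthogonal, n_folds=config.cv_folds)
    r2_icpt, q2_icpt, perm = chemo.permutation_test(
        X, y, n_perm=config.n_permutations, seed=config.seed,
        n_orthogonal=config.n_orthogonal, n_folds=config.cv_folds,
    )
    model.perm_intercepts = (r2_icpt, q2_icpt)
    markers = chemo.select_markers(matched, model)

    artifacts["scores"] = out / "scores.csv"
    pd.DataFrame(
        {
            "batch_id": matched.batch_ids,
            "region": matched.regions,
            "t_pred": model.scores[:, 0],
            **{f"t_orth{a + 1}": model.orthogonal_scores[:, a]
               for a in range(model.n_orthogonal)},
            "pca_t1": pca_model.scores[:, 0],
            "pca_t2": pca_model.scores[:, 1],
        }
    ).to_csv(artifacts["scores"], index=False, float_format="%.6g")
    artifacts["markers"] = out / "markers.csv"
    pd.DataFrame(
        [
            {
                "peak_id": m.peak_id,
                "compound": synth.PEAK_COMPOUNDS.get(m.peak_id, ""),
                "vip": m.vip,
                "p_value": m.p_value,
                "selected": m.selected,
                **{f"mean_{k}": v for k, v in m.group_means.items()},
            }
            for m in markers
        ]
    ).to_csv(artifacts["markers"], index=False, float_format="%.6g")
    artifacts["splot"] = out / "s_plot.csv"
    pd.DataFrame(model.splot, columns=["covariance", "correlation"]).assign(
        peak_id=matched.peak_ids
    ).to_csv(artifacts["splot"], index=False, float_format="%.6g")
    artifacts["permutation"] = out / "permutation.csv"
    perm.to_csv(artifacts["permutation"], index=False, float_format="%.6g")
    artifacts["model_summary"] = out / "model_summary.csv"
    pd.DataFrame(
        [
            {
                "R2X_cum": model.R2X_cum,
                "R2Y": model.R2Y,
                "Q2": model.Q2,
                "R2_intercept": r2_icpt,
                "Q2_intercept": q2_icpt,
                "pca_R2X_cum": pca_model.R2X_cum,
                "y_coding": str(coding),
            }
        ]
    ).to_csv(artifacts["model_summary"], index=False, float_format="%.6g")

    # --- QAMS ---------------------------------------------------------------
    log.stage("qams", f"internal standard {config.internal_standard}")
    analytes = [a for a in QAMS_ANALYTES if a != config.internal_standard]
    calib = [
        synth.simulate_calibration(a, seed=config.seed)
        for a in (config.internal_standard, *analytes)
    ]
    artifacts["calibration"] = out / "calibration.csv"
    write_calibration(calib, artifacts["calibration"])
    curves = {c.analyte: fit_calibration(c) for c in calib}
    curve_s = curves[config.internal_standard]

    calib_by_analyte = {c.analyte: c for c in calib}
    factors = {}
    for analyte in analytes:
        per_level = {}
        for (c_i, a_i), (c_s, a_s) in zip(
            calib_by_analyte[analyte].levels,
            calib_by_analyte[config.internal_standard].levels,
        ):
            per_level[f"level-{c_i:g}"] = correction_factor(
                QuantObservation(
                    analyte=analyte, internal_standard=config.internal_standard,
                    A_i=a_i, A_s=a_s, C_i=c_i, C_s=c_s,
                )
            )
        factors[analyte] = float(np.mean(list(per_level.values())))

    is_col = synth.COMPOUND_PEAKS[config.internal_standard]
    results: list[QuantResult] = []
    for i, batch in enumerate(matched.batch_ids):
        a_s = matched.areas[i][matched.peak_ids.index(is_col)]
        c_s = curve_s.concentration(a_s)
        for analyte in analytes:
            a_i = matched.areas[i][matched.peak_ids.index(synth.COMPOUND_PEAKS[analyte])]
            results.append(
                QuantResult(
                    batch=batch,
                    region=matched.regions[i],
                    analyte=analyte,
                    c_esm=quantify_esm(a_i, curves[analyte], ext),
                    c_qams=quantify_qams(a_i, a_s, c_s, factors[analyte], ext),
                )
            )

    artifacts["quant"] = out / "quantification.csv"
    pd.DataFrame(
        [
            {
                "batch": r.batch,
                "region": r.region,
                "analyte": r.analyte,
                "esm_mg_per_g": round(r.c_esm, 3),
                "qams_mg_per_g": round(r.c_qams, 3),
                "rd_percent": round(relative_deviation(r.c_esm, r.c_qams), 3),
            }
            for r in results
        ]
    ).to_csv(artifacts["quant"], index=False, float_format="%.3f")
    artifacts["region_summary"] = out / "region_summary.csv"
    summarize_by_region(results).round(3).to_csv(
        artifacts["region_summary"], float_format="%.3f"
    )

    artifacts["runlog"] = out / "run_log.txt"
    log.write(artifacts["runlog"])
    return artifacts


def save_score_plot(model, regions: list[str], path: str | Path) -> None:
    """Predictive-vs-first-orthogonal score scatter, coloured by region."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = model.scores[:, 0]
    t2 = (
        model.orthogonal_scores[:, 0]
        if model.orthogonal_scores is not None and model.orthogonal_scores.size
        else np.zeros_like(t)
    )
    fig, ax = plt.subplots(figsize=(5, 4))
    for region in sorted(set(regions)):
        mask = np.array([r == region for r in regions])
        ax.scatter(t[mask], t2[mask], label=region)
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    ax.set_xlabel("t (predictive)")
    ax.set_ylabel("t_orth 1")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def save_permutation_plot(frame: pd.DataFrame, path: str | Path) -> None:
    """R2Y/Q2 against |corr(y, y_perm)| with regression lines through 1.0."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for col, marker in (("R2Y", "o"), ("Q2", "s")):
        ax.scatter(frame["correlation"], frame[col], s=12, marker=marker, label=col)
        slope, icept = np.polyfit(frame["correlation"], frame[col], 1)
        xs = np.array([0.0, 1.0])
        ax.plot(xs, slope * xs + icept, lw=0.8)
    ax.set_xlabel("|corr(y, y_perm)|")
    ax.set_ylabel("statistic")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def annotate_mgf(path: str | Path, tol_ppm: float = 10.0) -> pd.DataFrame:
    """Annotate every spectrum in an MGF file; one row per spectrum."""
    rows = []
    for spec in read_mgf(path):
        hyps = annotate(spec, tol_ppm=tol_ppm)
        top = hyps[0]
        rows.append(
            {
                "spectrum_id": spec.spectrum_id,
                "precursor_mz": spec.precursor_mz,
                "polarity": spec.polarity,
                "class": top.compound_class,
                "compound": top.isomer or "",
                "score": top.score,
                "n_matched_ions": len(top.matched),
                "mean_abs_ppm": (
                    float(np.mean([abs(m[3]) for m in top.matched]))
                    if top.matched
                    else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
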