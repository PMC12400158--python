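"""Chemometrics on the common-peak matrix: PCA, OPLS-DA and marker screening.

The supervised model is orthogonal projections to latent structures
discriminant analysis (OPLS-DA): a single NIPALS PLS1 predictive component
after the removal of ``n_orthogonal`` components of X-variation orthogonal
to the class response.  Model quality is summarised by R2X (explained
X-variance), R2Y (explained class variance) and Q2 (cross-validated
predictive fraction, 1 - PRESS/TSS, stratified 7-fold).  Variable influence
is quantified by VIP (mean VIP^2 = 1 by construction), the S-plot
(covariance vs. correlation of each variable with the predictive score) and
a response-permutation test against chance classification.  Candidate
markers are peaks with VIP > 1 and Welch-t p < 0.05 between regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .peaks import PeakTable

__all__ = [
    "LatentModel",
    "MarkerReport",
    "preprocess",
    "pca",
    "oplsda",
    "vip",
    "s_plot",
    "permutation_test",
    "select_markers",
    "encode_labels",
]


class ChemometricsError(ValueError):
    """Raised for design or preprocessing problems."""


@dataclass
class Preprocessor:
    """Column-wise centering/scaling with stored parameters for re-application."""

    scaling: str
    mean_: np.ndarray
    scale_: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean_) / self.scale_

    def invert(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) * self.scale_ + self.mean_


def preprocess(
    table: PeakTable | np.ndarray, scaling: str = "autoscale"
) -> tuple[np.ndarray, Preprocessor]:
    """Center/scale the area matrix column-wise.

    ``center`` subtracts column means, ``autoscale`` additionally divides by
    the column standard deviation (unit variance), ``pareto`` by its square
    root.  Standard deviations use the n-1 denominator.
    """
    if scaling not in ("center", "autoscale", "pareto"):
        raise ChemometricsError(f"unknown scaling {scaling!r}")
    if isinstance(table, PeakTable):
        table.validate(strict=True)
        X = table.areas
        names = table.peak_ids
    else:
        X = np.asarray(table, dtype=float)
        names = [str(j) for j in range(X.shape[1])]
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scaling == "center":
        scale = np.ones_like(sd)
    else:
        bad = np.nonzero(sd == 0)[0]
        if bad.size:
            raise ChemometricsError(
                f"zero-variance column {names[bad[0]]!r} cannot be "
                f"{scaling}d; drop it or use 'center'"
            )
        scale = sd if scaling == "autoscale" else np.sqrt(sd)
    prep = Preprocessor(scaling=scaling, mean_=mean, scale_=scale)
    return prep.apply(X), prep


@dataclass
class LatentModel:
    """Fitted PCA or OPLS-DA model."""

    kind: str  # "pca" | "oplsda"
    scores: np.ndarray  # samples x components (predictive first for OPLS-DA)
    loadings: np.ndarray  # variables x components
    explained: np.ndarray  # per-component R2X
    R2X_cum: float
    R2Y: float | None = None
    Q2: float | None = None
    weights: np.ndarray | None = None  # predictive w (OPLS-DA)
    c: float | None = None  # inner y-loading (OPLS-DA)
    orthogonal_scores: np.ndarray | None = None
    orthogonal_loadings: np.ndarray | None = None
    vip: np.ndarray | None = None
    splot: np.ndarray | None = None  # variables x (cov, corr)
    perm_intercepts: tuple[float, float] | None = None
    hotelling: dict | None = None
    n_orthogonal: int = 0
    extras: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict the (centered) class response for preprocessed rows."""
        if self.kind != "oplsda":
            raise ChemometricsError("prediction is defined for OPLS-DA models")
        E = np.asarray(X, dtype=float).copy()
        if self.n_orthogonal and self.orthogonal_loadings is not None:
            W_o = self.extras["orthogonal_weights"]
            P_o = self.orthogonal_loadings
            for a in range(self.n_orthogonal):
                t_o = E @ W_o[:, a]
                E = E - np.outer(t_o, P_o[:, a])
        return (E @ self.weights) * self.c


def encode_labels(labels: list[str] | np.ndarray) -> tuple[np.ndarray, dict[str, float]]:
    """Code a two-class label vector as +1/-1 (alphabetically first -> +1)."""
    uniq = sorted(set(map(str, labels)))
    if len(uniq) != 2:
        raise ChemometricsError(f"exactly two classes required, got {uniq}")
    coding = {uniq[0]: 1.0, uniq[1]: -1.0}
    return np.array([coding[str(v)] for v in labels]), coding


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca(X: np.ndarray, n_components: int = 2) -> LatentModel:
    """Principal component analysis by singular value decomposition.

    ``X`` is the preprocessed (at least centered) matrix.  Scores are U*S,
    loadings the right singular vectors; explained_a = sigma_a^2 / sum of
    all sigma^2.  Hotelling T-squared 95% ellipse parameters for the first
    two components are attached for score plots.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    rank = int(np.linalg.matrix_rank(X))
    if n_components > min(n - 1, p) or n_components > rank:
        raise ChemometricsError(
            f"n_components={n_components} exceeds usable rank {min(rank, n - 1, p)}"
        )
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total = float((s**2).sum())
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    explained = (s[:n_components] ** 2) / total

    hotelling = None
    if n_components >= 2 and n > 2:
        lam = (s[:2] ** 2) / (n - 1)
        f_crit = stats.f.ppf(0.95, 2, n - 2)
        t2_crit = 2 * (n - 1) * (n + 1) / (n * (n - 2)) * f_crit
        hotelling = {
            "t2_crit": float(t2_crit),
            "semi_axes": tuple(float(np.sqrt(l * t2_crit)) for l in lam),
        }

    return LatentModel(
        kind="pca",
        scores=scores,
        loadings=loadings,
        explained=explained,
        R2X_cum=float(explained.sum()),
        hotelling=hotelling,
    )


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------


def _opls_fit(X: np.ndarray, y: np.ndarray, n_orthogonal: int) -> dict:
    """Core OPLS decomposition: orthogonal deflation then one PLS1 component."""
    E = X.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_orthogonal):
        w = E.T @ y
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ChemometricsError("degenerate model: X carries no y covariance")
        w /= norm
        t = E @ w
        p = E.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break  # no orthogonal variation left
        w_o /= n_o
        t_o = E @ w_o
        p_o = E.T @ t_o / (t_o @ t_o)
        E = E - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)

    w = E.T @ y
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ChemometricsError("degenerate model: X carries no y covariance")
    w /= norm
    t = E @ w
    tt = float(t @ t)
    if tt == 0:
        raise ChemometricsError("degenerate predictive component")
    p = E.T @ t / tt
    c = float(y @ t / tt)
    return {
        "w": w,
        "t": t,
        "p": p,
        "c": c,
        "W_o": np.column_stack(W_o) if W_o else np.empty((X.shape[1], 0)),
        "P_o": np.column_stack(P_o) if P_o else np.empty((X.shape[1], 0)),
        "T_o": np.column_stack(T_o) if T_o else np.empty((X.shape[0], 0)),
    }


def _opls_predict(fit: dict, X: np.ndarray) -> np.ndarray:
    E = np.asarray(X, dtype=float).copy()
    for a in range(fit["W_o"].shape[1]):
        t_o = E @ fit["W_o"][:, a]
        E = E - np.outer(t_o, fit["P_o"][:, a])
    return (E @ fit["w"]) * fit["c"]


def _q2(
    X: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int,
    n_folds: int = 7,
    shuffle_seed: int | None = None,
) -> float:
    """Q2 = 1 - PRESS/TSS by stratified k-fold cross-validation."""
    classes = y > 0
    min_class = min(int(classes.sum()), int((~classes).sum()))
    if min_class < 2:
        raise ChemometricsError("each class needs >= 2 samples for cross-validation")
    folds = max(2, min(n_folds, min_class))
    if shuffle_seed is None:
        skf = StratifiedKFold(n_splits=folds, shuffle=False)
    else:
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=shuffle_seed)
    press = 0.0
    for train, test in skf.split(X, classes):
        fit = _opls_fit(X[train], y[train], n_orthogonal)
        pred = _opls_predict(fit, X[test])
        press += float(((y[test] - pred) ** 2).sum())
    tss = float((y**2).sum())
    return 1.0 - press / tss


def oplsda(
    X: np.ndarray,
    y: np.ndarray,
    n_orthogonal: int = 1,
    n_folds: int = 7,
) -> LatentModel:
    """Fit an OPLS-DA model with one predictive component.

    ``X`` is the preprocessed matrix, ``y`` the +1/-1 class coding (it is
    centered internally).  With ``n_orthogonal=0`` the model reduces exactly
    to single-component PLS1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ChemometricsError("X must be 2-D with one y value per row")
    if len(np.unique(y)) != 2:
        raise ChemometricsError("y must contain exactly two classes")
    classes = y > np.mean(np.unique(y))
    if min(int(classes.sum()), int((~classes).sum())) < 3:
        raise ChemometricsError("each class needs >= 3 samples")
    yc = y - y.mean()

    fit = _opls_fit(X, yc, n_orthogonal)
    t, p, c, w = fit["t"], fit["p"], fit["c"], fit["w"]
    T_o, P_o = fit["T_o"], fit["P_o"]

    ssx = float((X**2).sum())
    r2x_pred = float((t @ t) * (p @ p)) / ssx
    r2x_orth = [
        float((T_o[:, a] @ T_o[:, a]) * (P_o[:, a] @ P_o[:, a])) / ssx
        for a in range(T_o.shape[1])
    ]
    explained = np.array([r2x_pred] + r2x_orth)
    r2y = float((c**2) * (t @ t) / (yc @ yc))
    q2 = _q2(X, yc, n_orthogonal, n_folds=n_folds)

    scores = np.column_stack([t] + [T_o[:, a] for a in range(T_o.shape[1])])
    loadings = np.column_stack([p] + [P_o[:, a] for a in range(P_o.shape[1])])

    model = LatentModel(
        kind="oplsda",
        scores=scores,
        loadings=loadings,
        explained=explained,
        R2X_cum=float(explained.sum()),
        R2Y=r2y,
        Q2=q2,
        weights=w,
        c=c,
        orthogonal_scores=T_o,
        orthogonal_loadings=P_o,
        n_orthogonal=T_o.shape[1],
        extras={"orthogonal_weights": fit["W_o"], "y_mean": float(y.mean())},
    )
    model.vip = vip(model)
    model.splot = s_plot(model, X)
    return model


def vip(model: LatentModel) -> np.ndarray:
    """Variable importance in projection over the predictive component(s).

    VIP_j = sqrt(p * sum_a w_ja^2 SSY_a / sum_a SSY_a); with one predictive
    component this is sqrt(p) * |w_j|, so mean(VIP^2) = 1 exactly.
    """
    if model.kind != "oplsda" or model.weights is None:
        raise ChemometricsError("VIP is defined for fitted OPLS-DA models")
    w = model.weights
    ssw = float(w @ w)
    if ssw == 0:
        raise ChemometricsError("degenerate zero-weight model")
    p = w.size
    return np.sqrt(p * (w**2) / ssw)


def s_plot(model: LatentModel, X: np.ndarray) -> np.ndarray:
    """S-plot coordinates: (cov(t, x_j), corr(t, x_j)) per variable.

    Zero-variance variables get NaN correlation (reported missing).
    """
    if model.kind != "oplsda":
        raise ChemometricsError("the S-plot is defined for OPLS-DA models")
    X = np.asarray(X, dtype=float)
    t = model.scores[:, 0]
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    tc = t - t.mean()
    cov = tc @ xc / (n - 1)
    sd_t = tc.std(ddof=1)
    sd_x = xc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.where(sd_x > 0, cov / (sd_t * sd_x), np.nan)
    return np.column_stack([cov, corr])


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
    n_orthogonal: int = 1,
    n_folds: int = 7,
) -> tuple[float, float, pd.DataFrame]:
    """Response-permutation validation of an OPLS-DA model.

    Refits the model for ``n_perm`` random permutations of y and records
    (|corr(y, y_perm)|, R2Y, Q2).  The unpermuted model enters at abscissa
    1.0; intercepts of the least-squares lines through all points give the
    chance-level R2 and Q2 estimates.
    """
    if n_perm < 20:
        raise ChemometricsError("use at least 20 permutations")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(seed)

    rows = []
    base = oplsda(X, y, n_orthogonal=n_orthogonal, n_folds=n_folds)
    rows.append({"correlation": 1.0, "R2Y": base.R2Y, "Q2": base.Q2, "permuted": False})
    yc = y - y.mean()
    for _ in range(n_perm):
        y_perm = rng.permutation(y)
        ypc = y_perm - y_perm.mean()
        denom = np.linalg.norm(yc) * np.linalg.norm(ypc)
        r = abs(float(yc @ ypc) / denom) if denom > 0 else 0.0
        fit = oplsda(X, y_perm, n_orthogonal=n_orthogonal, n_folds=n_folds)
        rows.append({"correlation": r, "R2Y": fit.R2Y, "Q2": fit.Q2, "permuted": True})
    frame = pd.DataFrame(rows)

    def intercept(col: str) -> float:
        slope, icept = np.polyfit(frame["correlation"], frame[col], 1)
        return float(icept)

    return intercept("R2Y"), intercept("Q2"), frame


@dataclass
class MarkerReport:
    """Per-peak marker screening outcome."""

    peak_id: str
    vip: float
    p_value: float
    group_means: dict[str, float]
    selected: bool


def select_markers(
    table: PeakTable,
    model: LatentModel,
    alpha: float = 0.05,
    vip_threshold: float = 1.0,
    fdr: bool = False,
) -> list[MarkerReport]:
    """Screen common peaks: selected iff VIP > 1 AND Welch-t p < alpha.

    p-values come from a two-sided Welch t-test on the raw (unscaled) areas
    between the two regions; with ``fdr=True`` they are Benjamini-Hochberg
    adjusted first.  The report is sorted by VIP, descending.
    """
    table.validate(strict=True)
    regions = sorted(set(table.regions))
    if len(regions) != 2:
        raise ChemometricsError("marker screening requires exactly two regions")
    if model.vip is None or len(model.vip) != len(table.peak_ids):
        raise ChemometricsError("model VIP vector does not match the peak table")
    g1 = table.areas[table.region_mask(regions[0])]
    g2 = table.areas[table.region_mask(regions[1])]
    if g1.shape[0] < 2 or g2.shape[0] < 2:
        raise ChemometricsError("each region needs >= 2 batches for the t-test")

    pvals = np.array(
        [
            stats.ttest_ind(g1[:, j], g2[:, j], equal_var=False).pvalue
            for j in range(len(table.peak_ids))
        ]
    )
    if fdr:
        pvals = stats.false_discovery_control(pvals, method="bh")

    reports = [
        MarkerReport(
            peak_id=pid,
            vip=float(model.vip[j]),
            p_value=float(pvals[j]),
            group_means={
                regions[0]: float(g1[:, j].mean()),
                regions[1]: float(g2[:, j].mean()),
            },
            selected=bool(model.vip[j] > vip_threshold and pvals[j] < alpha),
        )
        for j, pid in enumerate(table.peak_ids)
    ]
    return sorted(reports, key=lambda r: r.vip, reverse=True)
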