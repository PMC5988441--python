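"""Behavioural factor analyses for an aphasia assessment battery.

Implements the behavioural half of the pipeline: preparation of a
patients × measures score matrix on a common percent scale, cross-validated
selection of the number of principal components, varimax/promax-rotated PCA
of the correlation matrix with regression-method factor scores, sampling
adequacy diagnostics (KMO, Bartlett's sphericity test), an
eigenvalue-greater-than-one PCA of naming-error rates, and starred Pearson
correlation tables.

All PCA operations work on the correlation matrix (measures are on mixed
scales), and rotations use Kaiser row normalisation.  Rotated factors are
reported in decreasing order of explained variance with the dominant loading
of each factor made positive, so factor order and sign are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "BatteryMatrix",
    "CVResult",
    "FactorModel",
    "FactorDiagnostics",
    "CorrelationResult",
    "prepare_matrix",
    "cv_select_components",
    "fit_pca_rotated",
    "diagnostics",
    "error_type_pca",
    "correlate",
    "correlation_table",
    "withhold_and_validate",
    "tucker_congruence",
    "congruence_matrix",
]


@dataclass
class BatteryMatrix:
    """Prepared battery: percent-scale scores and their z-scored version."""

    percent: pd.DataFrame
    z: pd.DataFrame
    scaling: dict[str, str]

    @property
    def measures(self) -> list[str]:
        return list(self.percent.columns)

    @property
    def n_patients(self) -> int:
        return len(self.percent)


def prepare_matrix(
    raw: pd.DataFrame, max_scores: Mapping[str, float] | None = None
) -> BatteryMatrix:
    """Convert raw test scores to percent and z-score each measure.

    A measure with a declared maximum is scaled to percent of that maximum;
    otherwise the in-sample maximum is used.  Downstream PCA consumes the
    z-scored matrix.
    """
    if raw.shape[0] < 2 or raw.shape[1] < 2:
        raise ValueError("need at least 2 patients and 2 measures")
    if raw.isna().any().any():
        raise ValueError("missing cells in battery matrix; impute or drop upstream")
    max_scores = dict(max_scores or {})
    percent = pd.DataFrame(index=raw.index)
    scaling: dict[str, str] = {}
    for col in raw.columns:
        if col in max_scores:
            denom = float(max_scores[col])
            scaling[col] = "declared-max"
        else:
            denom = float(raw[col].max())
            scaling[col] = "sample-max"
        if denom == 0:
            raise ValueError(f"measure {col!r} has zero maximum")
        percent[col] = raw[col] / denom * 100.0
    sd = percent.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant measures (zero variance): {constant}")
    z = (percent - percent.mean()) / sd
    return BatteryMatrix(percent=percent, z=z, scaling=scaling)


# ---------------------------------------------------------------------------
# component-count selection by 5-fold cross-validation


@dataclass
class CVResult:
    k_candidates: list[int]
    mean_rmse: list[float]
    chosen_k: int
    n_folds: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"k": self.k_candidates, "mean_rmse": self.mean_rmse})


def _principal_axes(Z: np.ndarray, k: int) -> np.ndarray:
    """Top-k eigenvectors of the correlation matrix of pre-standardised Z."""
    R = np.corrcoef(Z, rowvar=False)
    vals, vecs = linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    return vecs[:, order[:k]]


def cv_select_components(
    X: BatteryMatrix | pd.DataFrame,
    k_max: int = 8,
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Choose the component count minimising cross-validated prediction RMSE.

    For each fold, a PCA is fitted on the training rows.  Each cell of each
    holdout row is then predicted from the row's *other* variables: the row
    (with the target variable deleted) is least-squares projected onto the
    loading matrix with the target variable's loading row deleted, and the
    target is reconstructed from the projected component scores.  The mean
    RMSE over all (fold, variable) omissions is minimised over k; ties break
    toward the smaller k.
    """
    frame = X.z if isinstance(X, BatteryMatrix) else X
    data = np.asarray(frame, dtype=float)
    n, v = data.shape
    if n_folds > n:
        raise ValueError("more folds than patients")
    if k_max >= v:
        raise ValueError("k_max must be smaller than the number of measures")
    rng = np.random.default_rng(seed)
    fold_of = np.repeat(np.arange(n_folds), int(np.ceil(n / n_folds)))[:n]
    rng.shuffle(fold_of)

    ks = list(range(1, k_max + 1))
    sse = np.zeros(len(ks))
    count = 0
    for fold in range(n_folds):
        train = data[fold_of != fold]
        test = data[fold_of == fold]
        if np.linalg.matrix_rank(train) <= k_max:
            raise ValueError(f"k_max={k_max} not below the rank of the training partition")
        mu = train.mean(axis=0)
        sd = train.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("constant training column in a CV fold")
        Zt = (train - mu) / sd
        Ztest = (test - mu) / sd
        V = _principal_axes(Zt, k_max)
        for ki, k in enumerate(ks):
            Vk = V[:, :k]
            for j in range(v):
                keep = np.arange(v) != j
                proj = np.linalg.pinv(Vk[keep]) @ Ztest[:, keep].T  # (k, n_test)
                pred = Vk[j] @ proj
                sse[ki] += np.sum((Ztest[:, j] - pred) ** 2)
        count += test.shape[0] * v
    rmse = np.sqrt(sse / count)
    chosen = ks[int(np.argmin(rmse))]  # argmin returns the first (smallest) k on ties
    return CVResult(
        k_candidates=ks, mean_rmse=rmse.tolist(), chosen_k=chosen,
        n_folds=n_folds, seed=seed,
    )


# ---------------------------------------------------------------------------
# rotated PCA


@dataclass
class FactorModel:
    loadings: pd.DataFrame  # measures × factors
    rotation: str
    variance_explained: np.ndarray  # % of total variance per factor
    scores: pd.DataFrame  # patients × factors
    communalities: pd.Series
    eigenvalues: np.ndarray
    factor_correlations: pd.DataFrame | None = None  # promax only

    @property
    def k(self) -> int:
        return self.loadings.shape[1]


def _varimax(L: np.ndarray, kaiser: bool = True, tol: float = 1e-12,
             max_iter: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation; returns rotated loadings and the rotation matrix."""
    L = np.array(L, dtype=float)
    p, k = L.shape
    if k == 1:
        return L, np.eye(1)
    h = np.sqrt((L**2).sum(axis=1)) if kaiser else np.ones(p)
    h[h == 0] = 1.0
    Ln = L / h[:, None]
    T = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        Lr = Ln @ T
        B = Ln.T @ (Lr**3 - Lr @ np.diag((Lr**2).sum(axis=0)) / p)
        U, svals, Vt = np.linalg.svd(B)
        T = U @ Vt
        d_new = svals.sum()
        if d_new <= d * (1 + tol):
            break
        d = d_new
    return (Ln @ T) * h[:, None], T


def _promax(L_varimax: np.ndarray, power: int = 4) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Promax oblique rotation built on a varimax solution.

    Returns (pattern matrix, oblique transform U, factor correlation Phi).
    """
    X = np.asarray(L_varimax, dtype=float)
    Q = X * np.abs(X) ** (power - 1)
    U, *_ = np.linalg.lstsq(X, Q, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U * np.sqrt(d)
    pattern = X @ U
    Uinv = np.linalg.inv(U)
    Phi = Uinv @ Uinv.T
    return pattern, U, Phi


def _order_and_sign(L: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic factor order (variance desc) and sign (dominant loading > 0)."""
    ss = (L**2).sum(axis=0)
    order = np.argsort(ss)[::-1]
    signs = np.ones(len(order))
    for f, col in enumerate(order):
        if L[np.argmax(np.abs(L[:, col])), col] < 0:
            signs[f] = -1.0
    return order, signs, ss[order]


def fit_pca_rotated(
    X: BatteryMatrix | pd.DataFrame,
    k: int,
    rotation: str = "varimax",
    promax_power: int = 4,
) -> FactorModel:
    """PCA of the correlation matrix with k rotated components.

    Loadings are eigenvectors scaled by the square root of their eigenvalues
    (component–measure correlations).  Factor scores use the regression
    method; under varimax the scores of different factors are exactly
    uncorrelated.  Promax is built on the varimax solution.
    """
    if rotation not in {"varimax", "promax", "none"}:
        raise ValueError(f"unknown rotation {rotation!r}")
    frame = X.z if isinstance(X, BatteryMatrix) else X
    Z = np.asarray(frame, dtype=float)
    measures = list(frame.columns)
    patients = list(frame.index)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)
    R = np.corrcoef(Z, rowvar=False)
    vals, vecs = linalg.eigh(R)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if k > np.sum(vals > 1e-10):
        raise ValueError(f"k={k} exceeds the number of positive eigenvalues")
    L = vecs[:, :k] * np.sqrt(vals[:k])

    phi = None
    if rotation == "none":
        Lr, T = L, np.eye(k)
    else:
        Lr, T = _varimax(L)
        if rotation == "promax":
            Lr, U, phi = _promax(Lr, power=promax_power)
            T = T @ U

    colord, signs, ss = _order_and_sign(Lr)
    Lr = Lr[:, colord] * signs
    T = T[:, colord] * signs
    if phi is not None:
        phi = (phi[np.ix_(colord, colord)] * signs[:, None]) * signs[None, :]

    v = len(measures)
    var_explained = ss / v * 100.0

    Rinv = np.linalg.pinv(R)
    if rotation == "promax":
        structure = Lr @ phi
        W = Rinv @ structure
    else:
        W = Rinv @ Lr
    scores = Z @ W

    if rotation == "promax":
        communal = pd.Series(((Lr @ linalg.cholesky(phi, lower=True)) ** 2).sum(axis=1),
                             index=measures, name="h2")
    else:
        communal = pd.Series((Lr**2).sum(axis=1), index=measures, name="h2")

    names = [f"F{i+1}" for i in range(k)]
    return FactorModel(
        loadings=pd.DataFrame(Lr, index=measures, columns=names),
        rotation=rotation,
        variance_explained=var_explained,
        scores=pd.DataFrame(scores, index=patients, columns=names),
        communalities=communal,
        eigenvalues=vals,
        factor_correlations=pd.DataFrame(phi, index=names, columns=names)
        if phi is not None
        else None,
    )


# ---------------------------------------------------------------------------
# sampling-adequacy diagnostics


@dataclass
class FactorDiagnostics:
    kmo: float
    bartlett_chi2: float
    bartlett_df: int
    bartlett_p: float

    def as_dict(self) -> dict:
        return {
            "kmo": self.kmo,
            "bartlett_chi2": self.bartlett_chi2,
            "bartlett_df": self.bartlett_df,
            "bartlett_p": self.bartlett_p,
        }


def diagnostics(X: BatteryMatrix | pd.DataFrame) -> FactorDiagnostics:
    """KMO sampling adequacy and Bartlett's test of sphericity.

    Bartlett: chi2 = -(n - 1 - (2v + 5) / 6) * ln|R| on v(v-1)/2 degrees of
    freedom.  KMO: ratio of summed squared off-diagonal correlations to the
    same sum plus summed squared partial correlations (anti-image).
    """
    frame = X.z if isinstance(X, BatteryMatrix) else X
    Z = np.asarray(frame, dtype=float)
    n, v = Z.shape
    R = np.corrcoef(Z, rowvar=False)
    df = v * (v - 1) // 2

    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0 or not np.isfinite(logdet):
        chi2 = np.inf
        p = 0.0
    else:
        chi2 = -(n - 1 - (2 * v + 5) / 6) * logdet
        p = float(stats.chi2.sf(chi2, df))

    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular correlation matrix: KMO undefined") from exc
    d = np.sqrt(np.diag(Rinv))
    partial = -Rinv / np.outer(d, d)
    off = ~np.eye(v, dtype=bool)
    r2 = (R[off] ** 2).sum()
    pr2 = (partial[off] ** 2).sum()
    kmo = float(r2 / (r2 + pr2))
    return FactorDiagnostics(kmo=kmo, bartlett_chi2=float(chi2), bartlett_df=df, bartlett_p=p)


def error_type_pca(error_props: pd.DataFrame, rotation: str = "varimax") -> FactorModel:
    """Varimax PCA of error-rate columns retaining eigenvalues strictly > 1."""
    if error_props.shape[1] < 2:
        raise ValueError("need at least 2 eligible error categories")
    Z = (error_props - error_props.mean()) / error_props.std(ddof=1)
    R = np.corrcoef(np.asarray(Z, dtype=float), rowvar=False)
    vals = np.sort(linalg.eigvalsh(R))[::-1]
    k = int((vals > 1.0).sum())  # strictly greater than 1
    k = max(k, 1)
    return fit_pca_rotated(Z, k=k, rotation=rotation)


# ---------------------------------------------------------------------------
# correlations


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    stars: str
    n: int


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlate(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson correlation with a two-sided p value and significance stars."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of at least 3 values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input: correlation undefined")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue),
                             stars=_stars(res.pvalue), n=len(x))


def correlation_table(
    left: pd.DataFrame,
    right: pd.DataFrame,
    holm: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """All pairwise correlations of right columns (rows) vs left columns.

    Returns (r, p, starred) frames; ``starred`` holds strings such as
    ``"-0.491***"``.  With ``holm=True`` the star tiers use Holm-adjusted
    p values across the whole table.
    """
    rows = list(right.columns)
    cols = list(left.columns)
    r = pd.DataFrame(index=rows, columns=cols, dtype=float)
    p = pd.DataFrame(index=rows, columns=cols, dtype=float)
    for a in rows:
        for b in cols:
            res = correlate(right[a], left[b])
            r.loc[a, b] = res.r
            p.loc[a, b] = res.p_value
    p_for_stars = p.copy()
    if holm:
        flat = p.to_numpy().ravel()
        order = np.argsort(flat)
        adj = np.empty_like(flat)
        m = len(flat)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * flat[idx])
            adj[idx] = min(running, 1.0)
        p_for_stars = pd.DataFrame(adj.reshape(p.shape), index=rows, columns=cols)
    starred = pd.DataFrame(
        [
            [f"{r.loc[a, b]:.3f}{_stars(p_for_stars.loc[a, b])}" for b in cols]
            for a in rows
        ],
        index=rows,
        columns=cols,
    )
    return r, p, starred


def withhold_and_validate(
    X: BatteryMatrix | pd.DataFrame,
    withheld: Sequence[str],
    k: int,
    rotation: str = "varimax",
) -> tuple[FactorModel, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Refit the PCA without the withheld measures; correlate them post hoc.

    Returns the refitted model plus (r, p, starred) tables of each withheld
    measure against the refitted factor scores.
    """
    frame = X.z if isinstance(X, BatteryMatrix) else X
    withheld = list(withheld)
    if not withheld:
        raise ValueError("withheld set is empty")
    missing = [w for w in withheld if w not in frame.columns]
    if missing:
        raise ValueError(f"withheld measures not in matrix: {missing}")
    kept = frame.drop(columns=withheld)
    if kept.shape[1] < 2:
        raise ValueError("withholding leaves fewer than 2 measures")
    model = fit_pca_rotated(kept, k=k, rotation=rotation)
    r, p, starred = correlation_table(model.scores, frame[withheld])
    return model, r, p, starred


# ---------------------------------------------------------------------------
# recovery metrics


def tucker_congruence(a: Sequence[float], b: Sequence[float]) -> float:
    """Tucker's congruence coefficient (cosine of two loading vectors)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def congruence_matrix(A: pd.DataFrame | np.ndarray, B: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise |congruence| between columns of two loading matrices."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    out = np.zeros((A.shape[1], B.shape[1]))
    for i in range(A.shape[1]):
        for j in range(B.shape[1]):
            out[i, j] = abs(tucker_congruence(A[:, i], B[:, j]))
    return out
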