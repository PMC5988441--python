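"""Voxel-based correlational methodology (VBCM) on co-registered volumes.

VBCM regresses continuous voxel intensity (tissue signal) on continuous
behavioural scores across a patient cohort, voxel by voxel, with age,
education and (optionally) lesion volume as nuisance covariates.  Unlike
binary voxel-lesion symptom mapping no lesion segmentation enters the
regression; the binary lesion maps produced here serve only descriptive
overlap maps and the lesion-volume covariate.

Cluster-level familywise-error control uses a permutation null of the
maximum supra-threshold cluster size under the Freedman–Lane scheme: the
behavioural regressor of interest is tested by permuting the data residuals
of the nuisance-only model while the nuisance design stays fixed.

All volumes in one analysis must share grid shape and voxel size; no spatial
normalisation is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "Volume",
    "LesionResult",
    "OverlapResult",
    "StatMap",
    "ClusterTable",
    "gaussian_smooth",
    "control_sd_mask",
    "identify_lesion",
    "overlap_map",
    "fit_vbcm",
    "cluster_fwe",
    "load_volume",
    "save_volume",
]

_FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548...
_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Volume:
    """A 3-D scalar grid with voxel geometry."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    space: str = "common"
    subject_id: str = ""
    group: str = "patient"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3-D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size))

    def like(self, data: np.ndarray, **kw) -> "Volume":
        return Volume(data=data, voxel_size=self.voxel_size, space=self.space, **kw)


def _check_common_grid(volumes: Sequence[Volume]) -> None:
    ref = volumes[0]
    for v in volumes[1:]:
        if v.data.shape != ref.data.shape or v.voxel_size != ref.voxel_size or v.space != ref.space:
            raise ValueError(
                f"volume {v.subject_id!r} not on the common grid "
                f"({v.data.shape}, {v.voxel_size}, {v.space})"
            )


def load_volume(path, **kw) -> Volume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    return Volume(data=np.asarray(img.get_fdata()), voxel_size=tuple(zooms), **kw)


def save_volume(vol: Volume, path) -> None:
    affine = np.diag(list(vol.voxel_size) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine), str(path))


def gaussian_smooth(vol: Volume, fwhm_mm: float) -> Volume:
    """Separable Gaussian smoothing with per-axis SD = FWHM / (2*sqrt(2 ln 2)).

    FWHM is given in mm and converted per axis to voxel units, so anisotropic
    voxels are handled correctly.  The boundary is constant-(zero-)padded.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma_vox = [fwhm_mm / _FWHM_TO_SD / vs for vs in vol.voxel_size]
    sm = ndimage.gaussian_filter(np.asarray(vol.data, dtype=float), sigma=sigma_vox,
                                 mode="constant", cval=0.0)
    return vol.like(sm, subject_id=vol.subject_id, group=vol.group)


# ---------------------------------------------------------------------------
# lesion identification


@dataclass
class LesionResult:
    lesion: Volume  # binary 0/1
    abnormality: Volume  # fuzzy membership in [0, 1]
    volume_mm3: float
    n_voxels: int
    n_excluded_voxels: int  # zero control variance


def control_sd_mask(controls: Sequence[Volume], sd_floor_rel: float = 0.05) -> np.ndarray:
    """Voxels whose control SD is meaningfully positive.

    Smoothing tapers signal and noise jointly toward zero at the volume
    boundary, leaving voxels with SD of ~1e-8 that are numerically positive
    but carry no information; z-scores and GLM t values there are pure
    artefact.  A voxel is kept when its control SD exceeds ``sd_floor_rel``
    times the median positive control SD.
    """
    sd = np.std(np.stack([c.data for c in controls]).astype(float), axis=0, ddof=1)
    positive = sd[sd > 0]
    if positive.size == 0:
        return np.zeros(sd.shape, dtype=bool)
    return sd > sd_floor_rel * np.median(positive)


def identify_lesion(
    patient: Volume,
    controls: Sequence[Volume],
    u_threshold: float = 0.5,
    z_midpoint: float = 3.0,
    z_slope: float = 1.0,
    sd_floor_rel: float = 0.05,
) -> LesionResult:
    """Outlier-based lesion delineation against a control sample.

    Per voxel the patient's deviation |z| from the control mean (in control
    SD units) is squashed to a [0, 1] abnormality membership by a logistic
    with midpoint ``z_midpoint`` and slope ``z_slope``; membership at or
    above the U-threshold marks the voxel lesioned.  With the defaults
    (midpoint 3, U = 0.5) a voxel is lesioned iff it deviates by at least 3
    control SDs.  Voxels with (near-)zero control variance are excluded
    (see :func:`control_sd_mask`).
    """
    if len(controls) < 2:
        raise ValueError("need at least 2 control volumes")
    _check_common_grid([patient, *controls])
    ctrl = np.stack([c.data for c in controls]).astype(float)
    mu = ctrl.mean(axis=0)
    sd = ctrl.std(axis=0, ddof=1)
    valid = control_sd_mask(controls, sd_floor_rel=sd_floor_rel)
    z = np.zeros_like(mu)
    z[valid] = np.abs(patient.data[valid] - mu[valid]) / sd[valid]
    membership = np.zeros_like(mu)
    membership[valid] = 1.0 / (1.0 + np.exp(-z_slope * (z[valid] - z_midpoint)))
    lesion = (membership >= u_threshold) & valid
    n_vox = int(lesion.sum())
    return LesionResult(
        lesion=patient.like(lesion.astype(np.uint8), subject_id=patient.subject_id),
        abnormality=patient.like(membership, subject_id=patient.subject_id),
        volume_mm3=n_vox * patient.voxel_volume_mm3,
        n_voxels=n_vox,
        n_excluded_voxels=int((~valid).sum()),
    )


@dataclass
class OverlapResult:
    counts: Volume
    max_count: int
    max_coordinate: tuple[int, int, int]


def overlap_map(lesion_maps: Sequence[Volume]) -> OverlapResult:
    """Voxelwise sum of binary lesion maps, with the peak-overlap location."""
    if not lesion_maps:
        raise ValueError("no lesion maps supplied")
    _check_common_grid(lesion_maps)
    for m in lesion_maps:
        vals = np.unique(m.data)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"lesion map {m.subject_id!r} is not binary")
    counts = np.sum([m.data for m in lesion_maps], axis=0).astype(np.int32)
    peak = np.unravel_index(int(np.argmax(counts)), counts.shape)
    return OverlapResult(
        counts=lesion_maps[0].like(counts),
        max_count=int(counts.max()),
        max_coordinate=tuple(int(i) for i in peak),
    )


# ---------------------------------------------------------------------------
# mass-univariate GLM


@dataclass
class StatMap:
    """Voxelwise t map for one regressor of interest, plus fit context.

    The fit context (design matrix, masked data, column index) stays attached
    so that permutation inference can re-fit without re-assembling inputs.
    """

    t: Volume
    df: int
    regressor: str
    direction: str = "positive"
    voxel_p: float = 0.005
    mask: np.ndarray | None = None
    _X: np.ndarray | None = field(default=None, repr=False)
    _Y: np.ndarray | None = field(default=None, repr=False)
    _col: int | None = field(default=None, repr=False)

    def t_threshold(self, voxel_p: float | None = None) -> float:
        p = self.voxel_p if voxel_p is None else voxel_p
        if self.direction == "two-sided":
            return float(stats.t.isf(p / 2.0, self.df))
        return float(stats.t.isf(p, self.df))

    def suprathreshold(self, voxel_p: float | None = None) -> np.ndarray:
        cut = self.t_threshold(voxel_p)
        tvals = np.nan_to_num(self.t.data, nan=-np.inf)
        if self.direction == "two-sided":
            return np.abs(tvals) >= cut
        return tvals >= cut


def _design_matrix(
    covars: pd.DataFrame,
    interest: Sequence[str],
    nuisance: Sequence[str],
) -> tuple[np.ndarray, list[str]]:
    cols = ["intercept"] + list(interest) + list(nuisance)
    X = np.column_stack(
        [np.ones(len(covars))] + [np.asarray(covars[c], dtype=float) for c in cols[1:]]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns via near-zero R diagonal of a QR factorisation
        _, R = np.linalg.qr(X)
        bad = [cols[i] for i in range(X.shape[1]) if abs(R[i, i]) < 1e-8 * abs(R[0, 0])]
        raise ValueError(f"rank-deficient design; collinear columns: {bad or cols}")
    return X, cols


def fit_vbcm(
    volumes: Sequence[Volume],
    covars: pd.DataFrame,
    regressors: Sequence[str],
    mode: str = "simultaneous",
    mask: np.ndarray | None = None,
    include_lesion_volume: bool = True,
    direction: str = "positive",
    voxel_p: float = 0.005,
) -> dict[str, StatMap]:
    """Voxelwise OLS of intensity on behavioural regressors plus nuisance.

    ``mode='simultaneous'`` enters all regressors of interest in one model;
    ``mode='separate'`` fits one model per regressor.  Age and education are
    always nuisance covariates; lesion volume optionally (column
    ``lesion_volume``).  By default the positive association (higher score ↔
    more intact signal) is tested.  Voxels where the model fits exactly
    (zero residual) receive a +inf t sentinel.
    """
    if mode not in {"separate", "simultaneous"}:
        raise ValueError(f"unknown mode {mode!r}")
    _check_common_grid(volumes)
    if len(volumes) != len(covars):
        raise ValueError("covariate rows must align one-to-one with volumes")
    if covars[list(regressors)].isna().any().any():
        raise ValueError("missing values in covariates")
    nuisance = ["age", "education"]
    if include_lesion_volume:
        nuisance.append("lesion_volume")
    n_required = (len(regressors) if mode == "simultaneous" else 1) + 3
    if len(volumes) < n_required + len(nuisance):
        raise ValueError("too few patients for the requested design")

    shape = volumes[0].data.shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty analysis mask")
    Y = np.stack([v.data[mask] for v in volumes]).astype(float)  # n × V

    groups = [list(regressors)] if mode == "simultaneous" else [[r] for r in regressors]
    out: dict[str, StatMap] = {}
    for interest in groups:
        X, cols = _design_matrix(covars, interest, nuisance)
        n, k = X.shape
        df = n - k
        pinv = np.linalg.pinv(X)
        beta = pinv @ Y
        resid = Y - X @ beta
        rss = (resid**2).sum(axis=0)
        xtx_inv = np.linalg.inv(X.T @ X)
        for name in interest:
            c = cols.index(name)
            with np.errstate(divide="ignore", invalid="ignore"):
                se = np.sqrt(rss / df * xtx_inv[c, c])
                t = beta[c] / se
            t[(rss <= 1e-12) & (np.abs(beta[c]) > 0)] = np.inf
            tvol = np.full(shape, np.nan)
            tvol[mask] = t
            out[name] = StatMap(
                t=volumes[0].like(tvol),
                df=df,
                regressor=name,
                direction=direction,
                voxel_p=voxel_p,
                mask=mask,
                _X=X,
                _Y=Y,
                _col=c,
            )
    return out


# ---------------------------------------------------------------------------
# permutation cluster-level FWE


@dataclass
class ClusterTable:
    table: pd.DataFrame  # cluster_id, n_voxels, peak ijk/mm, peak_t, p_fwe
    labels: Volume  # integer cluster labels (0 = background)
    t_threshold: float
    n_perm: int
    null_max_sizes: np.ndarray

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_fwe"] <= alpha]

    def significant_mask(self, alpha: float = 0.05) -> np.ndarray:
        ids = self.significant(alpha)["cluster_id"].to_numpy()
        return np.isin(self.labels.data, ids)


def _cluster_sizes(supra: np.ndarray) -> tuple[np.ndarray, int, np.ndarray]:
    labels, n = ndimage.label(supra, structure=_CONNECTIVITY_26)
    if n == 0:
        return labels, 0, np.array([], dtype=int)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels, n, sizes.astype(int)


def cluster_fwe(
    stat: StatMap,
    voxel_p: float = 0.005,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> ClusterTable:
    """Cluster-size FWE correction by Freedman–Lane sign-free permutation.

    Supra-threshold voxels at the one-sided t cutoff for ``voxel_p`` are
    grouped into 26-connected clusters.  The null distribution of the maximum
    cluster size is built by permuting the rows of the data residualised
    against the nuisance design (all columns except the regressor of
    interest) and re-computing the t map.  Corrected
    p = (1 + #{null max >= observed size}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    if stat._X is None or stat._Y is None or stat._col is None:
        raise ValueError("StatMap lacks fit context; produce it with fit_vbcm")
    X, Y, c = stat._X, stat._Y, stat._col
    n, k = X.shape
    df = n - k
    tcut = float(stats.t.isf(voxel_p, df)) if stat.direction != "two-sided" else float(
        stats.t.isf(voxel_p / 2.0, df)
    )
    shape = stat.t.data.shape
    mask = stat.mask

    # partial out the nuisance columns once
    Z = np.delete(X, c, axis=1)
    Qz, _ = np.linalg.qr(Z)
    x = X[:, c]
    x_t = x - Qz @ (Qz.T @ x)  # residualised regressor
    xss = float(x_t @ x_t)
    Y_t = Y - Qz @ (Qz.T @ Y)  # residualised data
    yss = (Y_t**2).sum(axis=0)  # invariant under row permutation

    # Permuting the rows of the residualised data and re-residualising is
    # algebraically identical to contracting the *inverse-permuted* small
    # design vectors against the fixed data:  x'PY = (P'x)'Y  and
    # ||Rz P Y||^2 = ||Y||^2 - ||(P'Qz)'Y||^2.  This keeps the per-
    # permutation cost at two thin matrix products instead of copying and
    # refitting the full data matrix.
    def t_of_perm(inv: np.ndarray) -> np.ndarray:
        b = (x_t[inv] @ Y_t) / xss
        qy = Qz[inv].T @ Y_t
        rss = yss - (qy**2).sum(axis=0) - b**2 * xss
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b * np.sqrt(xss) / np.sqrt(rss / df)
        bad = rss <= 1e-12
        t[bad] = np.inf * np.sign(b[bad])
        return t

    def max_cluster(tvals: np.ndarray) -> int:
        supra = np.zeros(shape, dtype=bool)
        if stat.direction == "two-sided":
            supra[mask] = np.abs(tvals) >= tcut
        else:
            supra[mask] = tvals >= tcut
        _, nclus, sizes = _cluster_sizes(supra)
        return int(sizes.max()) if nclus else 0

    # observed clusters from the actual fit
    supra_obs = stat.suprathreshold(voxel_p)
    labels, n_obs, sizes = _cluster_sizes(supra_obs)

    rng = np.random.default_rng(seed)
    null_max = np.empty(n_perm, dtype=int)
    for b_i in range(n_perm):
        perm = rng.permutation(n)
        null_max[b_i] = max_cluster(t_of_perm(perm))

    rows = []
    tdata = stat.t.data
    for cid in range(1, n_obs + 1):
        in_cluster = labels == cid
        tvals = np.where(in_cluster, np.nan_to_num(tdata, nan=-np.inf), -np.inf)
        peak = np.unravel_index(int(np.argmax(np.abs(tvals) if stat.direction == "two-sided" else tvals)), shape)
        size = int(sizes[cid - 1])
        p_fwe = (1 + int((null_max >= size).sum())) / (n_perm + 1)
        rows.append(
            {
                "cluster_id": cid,
                "n_voxels": size,
                "peak_i": peak[0],
                "peak_j": peak[1],
                "peak_k": peak[2],
                "peak_mm_x": peak[0] * stat.t.voxel_size[0],
                "peak_mm_y": peak[1] * stat.t.voxel_size[1],
                "peak_mm_z": peak[2] * stat.t.voxel_size[2],
                "peak_t": float(tdata[peak]),
                "p_fwe": p_fwe,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "n_voxels", "peak_i", "peak_j", "peak_k",
            "peak_mm_x", "peak_mm_y", "peak_mm_z", "peak_t", "p_fwe",
        ],
    ).sort_values("n_voxels", ascending=False, ignore_index=True) if rows else pd.DataFrame(
        columns=[
            "cluster_id", "n_voxels", "peak_i", "peak_j", "peak_k",
            "peak_mm_x", "peak_mm_y", "peak_mm_z", "peak_t", "p_fwe",
        ]
    )
    return ClusterTable(
        table=table,
        labels=stat.t.like(labels.astype(np.int32)),
        t_threshold=tcut,
        n_perm=n_perm,
        null_max_sizes=null_max,
    )
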