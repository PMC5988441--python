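"""End-to-end orchestration: coding → model fitting → factors → lesion maps.

``run_all`` executes the full analysis on a cohort (synthetic or loaded from
disk) in the canonical order: patient/category screening, collapse to the
six model categories, (s, p) grid-search fitting, parameter–error
correlation tables, error-type PCA with its correlation table, the omnibus
rotated PCA of battery + √s + √p with diagnostics and withheld-test
validation, and voxel-based correlational mapping with permutation cluster
correction, including the omission-rate map and its overlap with the s and
p maps.  Every stage's outputs are written as CSV/JSON/NIfTI and a manifest
records all seeds and settings.

Module seeds are derived deterministically from one master seed as
``SeedSequence((master_seed, crc32(module_name)))``.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import errcode, factors, spmodel, vbcm
from .synthcohort import CohortConfig, CohortData, generate_cohort

__all__ = ["RunConfig", "RunBundle", "run_all", "overlap_report", "derive_seed"]


def derive_seed(master_seed: int, module: str) -> int:
    """Deterministic per-module seed from the master seed."""
    ss = np.random.SeedSequence((master_seed, zlib.crc32(module.encode())))
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class RunConfig:
    master_seed: int = 0
    # fitting
    grid_points: int = 50
    grid_min: float = 1e-3
    n_sims: int = 10_000
    # factors
    n_folds: int = 5
    k_max: int = 8
    rotation: str = "varimax"
    promax_power: int = 4
    withheld_measures: tuple[str, ...] = ()
    # vbcm
    run_vbcm: bool = True
    fwhm_mm: float = 8.0
    u_threshold: float = 0.5
    voxel_p: float = 0.005
    alpha: float = 0.05
    n_perm: int = 500
    include_lesion_volume: bool = True

    def seed_for(self, module: str) -> int:
        return derive_seed(self.master_seed, module)


@dataclass
class RunBundle:
    """In-memory results of a full run (also persisted to the output dir)."""

    fits: pd.DataFrame
    error_rates: pd.DataFrame
    param_error_corr: pd.DataFrame
    error_pca: factors.FactorModel
    error_factor_corr: pd.DataFrame
    cv: factors.CVResult
    omnibus: factors.FactorModel
    diag: factors.FactorDiagnostics
    withheld: pd.DataFrame | None
    cluster_tables: dict[str, vbcm.ClusterTable]
    stat_maps: dict[str, vbcm.StatMap]
    overlap: dict
    manifest: dict


def overlap_report(map_a: np.ndarray, map_b: np.ndarray) -> dict:
    """Dice coefficient and joint voxel count of two binary maps."""
    a = np.asarray(map_a, dtype=bool)
    b = np.asarray(map_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("maps must share a grid")
    inter = int((a & b).sum())
    denom = int(a.sum()) + int(b.sum())
    dice = 2.0 * inter / denom if denom else 0.0
    return {"dice": dice, "intersection_voxels": inter, "a_voxels": int(a.sum()),
            "b_voxels": int(b.sum())}


def _error_rate_table(profiles: list[errcode.ErrorProfile], categories: list[str]) -> pd.DataFrame:
    """Per-patient ratio of each category to the number of items attempted."""
    rows = {}
    for p in profiles:
        denom = max(p.n_attempted, 1)
        rows[p.patient_id] = {c: p.counts[c] / denom for c in ["correct", *categories]}
    return pd.DataFrame.from_dict(rows, orient="index")


def run_all(
    config: RunConfig,
    cohort: CohortData | None = None,
    cohort_config: CohortConfig | None = None,
    outdir: str | Path | None = None,
) -> RunBundle:
    """Run the complete analysis; returns the bundle and writes artefacts.

    If no cohort is supplied one is generated from ``cohort_config`` (or the
    defaults) using the master seed.
    """
    t_start = time.time()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []

    def stage(name):
        log.append({"stage": name, "t": round(time.time() - t_start, 2)})

    if cohort is None:
        cc = cohort_config or CohortConfig(seed=config.seed_for("synthcohort"))
        cohort = generate_cohort(cc, with_volumes=config.run_vbcm)
    stage("cohort")

    # 1. screening ---------------------------------------------------------
    included, eligible = errcode.screen_patients_and_categories(cohort.profiles)
    kept_ids = [p.patient_id for p in included]
    stage("screening")

    # 2. Dell recoding -----------------------------------------------------
    dell = [errcode.recode_to_dell(p) for p in included]
    stage("recode")

    # 3. (s, p) fitting ----------------------------------------------------
    grid = spmodel.default_grid(config.grid_points, grid_min=config.grid_min)
    cache = spmodel.GridCache.build(
        s_grid=grid, p_grid=grid, n_sims=config.n_sims, seed=config.seed_for("spmodel"),
    )
    fits = spmodel.fit_cohort(dell, cache)
    stage("fit")

    # 4. parameter–error correlations ------------------------------------
    rates = _error_rate_table(included, eligible).loc[kept_ids]
    sq = fits.loc[kept_ids, ["sqrt_s", "sqrt_p"]]
    # drop zero-variance categories (never produced by this cohort)
    varying = rates.columns[rates.std(ddof=1) > 0]
    r2, p2, table2 = factors.correlation_table(sq, rates[varying])
    stage("param_error_corr")

    # 5. error-type PCA + correlations ------------------------------------
    err_model = factors.error_type_pca(rates[[c for c in varying if c != "correct"]])
    r3, p3, table3 = factors.correlation_table(sq, err_model.scores)
    stage("error_factor_corr")

    # 6. omnibus PCA (battery + sqrt weights) ------------------------------
    battery = factors.prepare_matrix(cohort.battery.loc[kept_ids], cohort.max_scores)
    omni_in = battery.z.copy()
    omni_in["sqrt_s"] = (sq["sqrt_s"] - sq["sqrt_s"].mean()) / sq["sqrt_s"].std(ddof=1)
    omni_in["sqrt_p"] = (sq["sqrt_p"] - sq["sqrt_p"].mean()) / sq["sqrt_p"].std(ddof=1)
    cv = factors.cv_select_components(
        omni_in, k_max=config.k_max, n_folds=config.n_folds, seed=config.seed_for("factors"),
    )
    omnibus = factors.fit_pca_rotated(
        omni_in, k=cv.chosen_k, rotation=config.rotation, promax_power=config.promax_power,
    )
    diag = factors.diagnostics(omni_in)
    stage("omnibus")

    # 7. withheld-test validation ------------------------------------------
    withheld_tbl = None
    if config.withheld_measures:
        _, _, _, withheld_tbl = factors.withhold_and_validate(
            omni_in, list(config.withheld_measures), k=cv.chosen_k, rotation=config.rotation,
        )
    stage("withheld")

    # 8. VBCM ---------------------------------------------------------------
    cluster_tables: dict[str, vbcm.ClusterTable] = {}
    stat_maps: dict[str, vbcm.StatMap] = {}
    overlap: dict = {}
    if config.run_vbcm and cohort.volumes is not None:
        vols = cohort.volumes
        id_to_vol = {v.subject_id: v for v in vols.patients}
        pat_vols = [vbcm.gaussian_smooth(id_to_vol[i], config.fwhm_mm) for i in kept_ids]
        ctl_vols = [vbcm.gaussian_smooth(v, config.fwhm_mm) for v in vols.controls]

        lesions = [vbcm.identify_lesion(v, ctl_vols, u_threshold=config.u_threshold)
                   for v in pat_vols]
        ov = vbcm.overlap_map([l.lesion for l in lesions])

        covars = vols.covariates.loc[kept_ids].copy()
        covars["lesion_volume"] = [l.volume_mm3 for l in lesions]
        covars["sqrt_s"] = sq["sqrt_s"]
        covars["sqrt_p"] = sq["sqrt_p"]
        covars["omission_rate"] = [
            1.0 - p.n_attempted / p.n_items for p in included
        ]

        lesioned_any = np.any([l.lesion.data > 0 for l in lesions], axis=0)
        mask = vbcm.control_sd_mask(ctl_vols) | lesioned_any

        perm_seed = config.seed_for("vbcm")
        for mode in ("separate", "simultaneous"):
            maps = vbcm.fit_vbcm(
                pat_vols, covars, ["sqrt_s", "sqrt_p"], mode=mode, mask=mask,
                include_lesion_volume=config.include_lesion_volume,
                voxel_p=config.voxel_p,
            )
            for name, sm in maps.items():
                key = f"{name}_{mode}"
                stat_maps[key] = sm
                cluster_tables[key] = vbcm.cluster_fwe(
                    sm, voxel_p=config.voxel_p, alpha=config.alpha,
                    n_perm=config.n_perm, seed=perm_seed,
                )
        om_maps = vbcm.fit_vbcm(
            pat_vols, covars, ["omission_rate"], mode="separate", mask=mask,
            include_lesion_volume=config.include_lesion_volume,
            voxel_p=config.voxel_p, direction="two-sided",
        )
        sm = om_maps["omission_rate"]
        stat_maps["omission_rate"] = sm
        cluster_tables["omission_rate"] = vbcm.cluster_fwe(
            sm, voxel_p=config.voxel_p, alpha=config.alpha,
            n_perm=config.n_perm, seed=perm_seed,
        )

        om_sig = cluster_tables["omission_rate"].significant_mask(config.alpha)
        s_sig = cluster_tables["sqrt_s_simultaneous"].significant_mask(config.alpha)
        p_sig = cluster_tables["sqrt_p_simultaneous"].significant_mask(config.alpha)
        overlap = {
            "omission_vs_s": overlap_report(om_sig, s_sig),
            "omission_vs_p": overlap_report(om_sig, p_sig),
            "s_vs_p": overlap_report(s_sig, p_sig),
            "lesion_overlap_max": ov.max_count,
            "lesion_overlap_peak": list(ov.max_coordinate),
        }
        if out is not None:
            vbcm.save_volume(ov.counts, out / "lesion_overlap.nii.gz")
            for key, sm in stat_maps.items():
                vbcm.save_volume(sm.t, out / f"tmap_{key}.nii.gz")
    stage("vbcm")

    manifest = {
        "master_seed": config.master_seed,
        "module_seeds": {m: config.seed_for(m) for m in ("synthcohort", "spmodel", "factors", "vbcm")},
        "settings": {k: v for k, v in asdict(config).items()},
        "n_patients_included": len(kept_ids),
        "eligible_categories": eligible,
        "chosen_k": cv.chosen_k,
        "stages": log,
    }

    if out is not None:
        errcode.profiles_to_frame(included).to_csv(out / "profiles.csv")
        errcode.dell_profiles_to_frame(dell).to_csv(out / "dell_input.csv")
        fits.to_csv(out / "fits.csv")
        rates.to_csv(out / "error_rates.csv")
        table2.to_csv(out / "param_error_correlations.csv")
        table3.to_csv(out / "error_factor_correlations.csv")
        err_model.loadings.to_csv(out / "error_pca_loadings.csv")
        cv.as_frame().to_csv(out / "cv_rmse.csv", index=False)
        loadings_out = omnibus.loadings.copy()
        loadings_out.columns = [
            f"{c} ({v:.2f}%)" for c, v in zip(loadings_out.columns, omnibus.variance_explained)
        ]
        loadings_out.to_csv(out / "omnibus_loadings.csv")
        omnibus.scores.to_csv(out / "factor_scores.csv")
        with open(out / "diagnostics.json", "w") as fh:
            json.dump(diag.as_dict(), fh, indent=2)
        if withheld_tbl is not None:
            withheld_tbl.to_csv(out / "withheld_validation.csv")
        for key, ct in cluster_tables.items():
            ct.table.to_csv(out / f"clusters_{key}.csv", index=False)
        if overlap:
            with open(out / "overlap_report.json", "w") as fh:
                json.dump(overlap, fh, indent=2)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)

    return RunBundle(
        fits=fits, error_rates=rates, param_error_corr=table2, error_pca=err_model,
        error_factor_corr=table3, cv=cv, omnibus=omnibus, diag=diag, withheld=withheld_tbl,
        cluster_tables=cluster_tables, stat_maps=stat_maps, overlap=overlap,
        manifest=manifest,
    )
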