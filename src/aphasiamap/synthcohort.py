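"""Synthetic aphasia-cohort generator.

Produces complete cohorts with known ground truth so every stage of the
pipeline is testable without patient data: naming-response tables simulated
from the two-step production model at known (s, p) with an independent
omission process layered on top; a neuropsychological battery with a planted
four-factor loading structure (phonology, semantics, auditory working
memory, executive) whose phonology and semantic latents are tied to the true
p and s weights; and patient/control volumes with planted hypointense
lesion regions whose severity covaries with specific latent abilities, plus
age/education effects on global intensity.

Every generator is a pure function of (config, seed): repeated calls are
bit-identical.  The ground truth is returned alongside each cohort for
recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import spmodel
from .errcode import DELL_CATEGORIES, ErrorProfile, NamingRecord
from .spmodel import LexicalNetwork, SPParameters, build_network
from .vbcm import Volume

__all__ = [
    "LesionRegion",
    "CohortConfig",
    "SyntheticTruth",
    "sample_truth",
    "generate_naming",
    "naming_to_profiles",
    "generate_battery",
    "generate_grouped_error_rates",
    "generate_volumes",
    "generate_cohort",
    "CohortData",
]

#: battery measure names, grouped by the factor they are planted to load on.
DEFAULT_MEASURE_GROUPS: dict[str, list[str]] = {
    "phonology": [
        "word_rep_imm", "word_rep_del", "nonword_rep_imm", "nonword_rep_del",
        "naming_a", "naming_b",
    ],
    "semantic": [
        "spoken_wpm", "written_wpm", "synonym_judgement", "word_min_pairs",
        "assoc_pictures",
    ],
    "working_memory": [
        "digit_span_fwd", "digit_span_bwd", "sentence_comprehension",
        "type_token_ratio", "serial_recall",
    ],
    "executive": [
        "matrices", "spatial_anticipation", "token_test", "picture_sequencing",
        "rule_shift",
    ],
}


@dataclass
class LesionRegion:
    """A spherical planted lesion whose severity tracks one latent variable."""

    name: str
    center: tuple[int, int, int]
    radius_voxels: float
    driver: str  # "s", "p", or a latent factor name
    max_drop: float = 35.0  # intensity units removed at full severity


@dataclass
class CohortConfig:
    """All generator settings.  Defaults mirror the reference cohort:
    53 patients, 19 controls, 124 naming items."""

    n_patients: int = 53
    n_controls: int = 19
    n_items: int = 124
    seed: int = 0

    # true-weight sampler: uniform over the interior of the fitting grid
    grid_points: int = 50
    grid_min: float = 1e-3
    cap: float = 0.1
    interior_fraction: float = 0.8

    # omission process: P(omit) = logistic(b0 + bs*log10 s + bp*log10 p)
    omission_intercept: float = -4.2
    omission_s_slope: float = -1.3
    omission_p_slope: float = 0.0

    # battery plan
    measure_groups: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_MEASURE_GROUPS.items()}
    )
    loading_primary: float = 0.8
    battery_noise_sd: float = 0.4
    # latent ↔ weight links (correlation of the latent with z-scored sqrt weight)
    link_phonology_p: float = 0.9
    link_semantic_s: float = 0.75
    link_wm_s: float = 0.45

    # volumes
    volume_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 4.0
    template_intensity: float = 100.0
    control_noise_sd: float = 2.0
    patient_noise_sd: float = 2.0
    age_mean: float = 62.0
    age_sd: float = 9.0
    age_slope: float = -0.15  # intensity units per year, inside the brain
    education_mean: float = 13.0
    education_sd: float = 2.5
    education_slope: float = 0.2
    lesion_regions: list[LesionRegion] = field(
        default_factory=lambda: [
            LesionRegion("s_region", (11, 24, 20), 4.5, "s"),
            LesionRegion("p_region", (28, 24, 20), 4.5, "p"),
            LesionRegion("wm_region", (20, 36, 20), 4.0, "working_memory"),
        ]
    )

    @property
    def measures(self) -> list[str]:
        return [m for grp in self.measure_groups.values() for m in grp]

    def weight_grid(self) -> np.ndarray:
        return spmodel.default_grid(self.grid_points, grid_min=self.grid_min, cap=self.cap)

    def base_params(self) -> SPParameters:
        return SPParameters(cap=self.cap)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["volume_shape"] = list(self.volume_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "lesion_regions" in d:
            d["lesion_regions"] = [
                LesionRegion(**{**r, "center": tuple(r["center"])})
                if isinstance(r, dict) else r
                for r in d["lesion_regions"]
            ]
        if "volume_shape" in d:
            d["volume_shape"] = tuple(d["volume_shape"])
        return cls(**d)


def _rng(config: CohortConfig, stream: str) -> np.random.Generator:
    """Independent, reproducible stream per generator component."""
    key = int.from_bytes(stream.encode(), "little") % (2**31)
    return np.random.default_rng(np.random.SeedSequence((config.seed, key)))


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside every generated cohort."""

    s: np.ndarray
    p: np.ndarray
    s_index: np.ndarray
    p_index: np.ndarray
    latents: pd.DataFrame  # patients × 4 factors, unit variance
    omission_rate: np.ndarray
    patient_ids: list[str]

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "s_true": self.s,
                "p_true": self.p,
                "s_index": self.s_index,
                "p_index": self.p_index,
                "omission_rate": self.omission_rate,
            },
            index=self.patient_ids,
        )
        return pd.concat([df, self.latents.add_prefix("latent_")], axis=1)


def sample_truth(config: CohortConfig) -> SyntheticTruth:
    """Draw per-patient true weights, latent abilities and omission rates.

    Weights are uniform over the interior of the fitting grid (avoiding the
    outer 10% on each side so boundary pile-up cannot confound recovery).
    Latents are unit-variance Gaussians tied to the weights: phonology tracks
    z(√p), semantics tracks z(√s), working memory tracks z(√s) more weakly,
    executive is independent.
    """
    rng = _rng(config, "truth")
    grid = config.weight_grid()
    n = config.n_patients
    margin = int(round(config.grid_points * (1 - config.interior_fraction) / 2))
    interior = np.arange(margin, config.grid_points - margin)
    s_idx = rng.choice(interior, size=n)
    p_idx = rng.choice(interior, size=n)
    s, p = grid[s_idx], grid[p_idx]

    def z(v: np.ndarray) -> np.ndarray:
        return (v - v.mean()) / v.std()

    zs, zp = z(np.sqrt(s)), z(np.sqrt(p))

    def latent(link: float, driver: np.ndarray) -> np.ndarray:
        eps = rng.standard_normal(n)
        return link * driver + np.sqrt(max(1.0 - link**2, 0.0)) * eps

    latents = pd.DataFrame(
        {
            "phonology": latent(config.link_phonology_p, zp),
            "semantic": latent(config.link_semantic_s, zs),
            "working_memory": latent(config.link_wm_s, zs),
            "executive": rng.standard_normal(n),
        },
        index=[f"P{i+1:03d}" for i in range(n)],
    )
    logit = (
        config.omission_intercept
        + config.omission_s_slope * np.log10(s)
        + config.omission_p_slope * np.log10(p)
    )
    om = 1.0 / (1.0 + np.exp(-logit))
    if not ((om > 0) & (om < 1)).all():
        raise ValueError("omission probability outside (0,1); check slope config")
    return SyntheticTruth(
        s=s, p=p, s_index=s_idx, p_index=p_idx, latents=latents,
        omission_rate=om, patient_ids=list(latents.index),
    )


# ---------------------------------------------------------------------------
# naming responses


def _response_plan(network: LexicalNetwork) -> dict[str, dict]:
    """Concrete response realisation for each simulated category."""
    words = {role: i for i, role in enumerate(network.word_roles)}
    lab = network.word_labels

    def word(role):
        i = words[role]
        ph = [network.slot_phonemes[k][network.word_phoneme_codes[i, k]]
              for k in range(len(network.slots))]
        return {"label": lab[i], "phonemes": tuple(ph)}

    tgt = word("target")
    # a non-word sharing >=30% of target phonemes in any position → phonemic
    nonword_ph = (network.slot_phonemes[0][1], *tgt["phonemes"][1:-1],
                  network.slot_phonemes[-1][1])
    return {
        "correct": {**word("target"), "is_word": True, "sem": False},
        "semantic": {**word("semantic"), "is_word": True, "sem": True},
        "formal": {**word("formal"), "is_word": True, "sem": False},
        "mixed": {**word("mixed"), "is_word": True, "sem": True},
        "unrelated": {**word("unrelated"), "is_word": True, "sem": False},
        "nonword": {"label": "", "phonemes": nonword_ph, "is_word": False, "sem": False},
        "_target": tgt,
    }


def generate_naming(
    config: CohortConfig,
    truth: SyntheticTruth,
    network: LexicalNetwork | None = None,
) -> dict[str, list[NamingRecord]]:
    """Simulate per-trial naming responses for every patient.

    Each trial draws a six-way category from the production model at the
    patient's true (s, p) and realises it as a concrete response against the
    fixture lexicon; an omission then replaces the response independently
    with the patient's omission probability (so the independence account
    holds by construction).
    """
    network = network or build_network()
    plan = _response_plan(network)
    tgt = plan["_target"]
    rng = _rng(config, "naming")
    base = config.base_params()
    out: dict[str, list[NamingRecord]] = {}
    for i, pid in enumerate(truth.patient_ids):
        params = base.with_weights(float(truth.s[i]), float(truth.p[i]))
        cats = spmodel._simulate_batch(network, params, config.n_items, rng)
        omit = rng.random(config.n_items) < truth.omission_rate[i]
        records = []
        for trial, (cat_idx, om) in enumerate(zip(cats, omit)):
            if om:
                rec = NamingRecord(
                    item_id=f"item{trial+1:03d}",
                    target_label=tgt["label"],
                    target_phonemes=tgt["phonemes"],
                    response_phonemes=None,
                )
            else:
                r = plan[DELL_CATEGORIES[cat_idx]]
                rec = NamingRecord(
                    item_id=f"item{trial+1:03d}",
                    target_label=tgt["label"],
                    target_phonemes=tgt["phonemes"],
                    response_phonemes=r["phonemes"],
                    response_is_real_word=r["is_word"],
                    semantically_related=r["sem"],
                )
            records.append(rec)
        out[pid] = records
    return out


def naming_to_profiles(naming: Mapping[str, Sequence[NamingRecord]]) -> list[ErrorProfile]:
    return [ErrorProfile.from_records(recs, patient_id=pid) for pid, recs in naming.items()]


def naming_to_csv(naming: Mapping[str, Sequence[NamingRecord]], path) -> None:
    rows = []
    for pid, recs in naming.items():
        for r in recs:
            rows.append(
                {
                    "patient_id": pid,
                    "item_id": r.item_id,
                    "target": r.target_label,
                    "target_phonemes": " ".join(r.target_phonemes),
                    "response_phonemes": " ".join(r.response_phonemes or ()),
                    "is_word": "" if r.response_is_real_word is None else int(r.response_is_real_word),
                    "sem_related": "" if r.semantically_related is None else int(r.semantically_related),
                    "in_time": int(r.within_time_limit),
                    "coder_category": r.coder_category or "",
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# battery


def generate_battery(
    config: CohortConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Battery scores with the planted 4-factor loading structure.

    score = Λ f + ε in z units (primary loading ``loading_primary``, zero
    cross-loadings, noise SD ``battery_noise_sd``), then mapped affinely to a
    0–100 percent scale.  Returns (raw scores, declared max-score table).
    """
    rng = _rng(config, "battery")
    factors = list(config.measure_groups)
    F = truth.latents[factors].to_numpy()
    rows = []
    names = []
    lam = config.loading_primary
    for fi, fac in enumerate(factors):
        for m in config.measure_groups[fac]:
            noise = rng.standard_normal(config.n_patients) * config.battery_noise_sd
            if lam**2 + config.battery_noise_sd**2 > 1.0 + 1e-9:
                raise ValueError("loading plan implies variance > 1")
            rows.append(lam * F[:, fi] + noise)
            names.append(m)
    Z = np.column_stack(rows)
    percent = np.clip(60.0 + 14.0 * Z, 0.0, 100.0)
    scores = pd.DataFrame(percent, index=truth.patient_ids, columns=names)
    max_scores = {m: 100.0 for m in names}
    return scores, max_scores


def generate_grouped_error_rates(
    n_patients: int,
    group_sizes: Sequence[int],
    loading: float = 0.8,
    noise_sd: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Generic rate matrix with planted latent groups (one factor per group).

    Used to emulate error-rate tables whose categories cluster into latent
    families; column ``g<i>_v<j>`` belongs to group i.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    for gi, size in enumerate(group_sizes):
        f = rng.standard_normal(n_patients)
        for vi in range(size):
            cols[f"g{gi+1}_v{vi+1}"] = loading * f + noise_sd * rng.standard_normal(n_patients)
    return pd.DataFrame(cols, index=[f"P{i+1:03d}" for i in range(n_patients)])


# ---------------------------------------------------------------------------
# volumes


def _brain_mask(shape: tuple[int, int, int]) -> np.ndarray:
    """Ellipsoidal stand-in brain occupying the middle of the grid."""
    zz = [np.linspace(-1.2, 1.2, s) for s in shape]
    X, Y, Z = np.meshgrid(*zz, indexing="ij")
    return (X**2 + (Y / 1.1) ** 2 + Z**2) <= 1.0


def _severity(values: np.ndarray) -> np.ndarray:
    """Map a cohort vector to [0, 1] severity: worst value → 1, best → 0."""
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros_like(values)
    return (hi - values) / (hi - lo)


@dataclass
class VolumeSet:
    patients: list[Volume]
    controls: list[Volume]
    covariates: pd.DataFrame
    brain_mask: np.ndarray
    region_masks: dict[str, np.ndarray]
    true_severity: pd.DataFrame


def generate_volumes(config: CohortConfig, truth: SyntheticTruth) -> VolumeSet:
    """Patient and control volumes with planted lesion–behaviour coupling.

    Controls are the template plus Gaussian noise.  Patients additionally
    lose, inside each planted spherical region, an intensity proportional to
    the severity of the region's driver variable (1 = worst in cohort), and
    carry genuine age/education effects on global intensity.
    """
    regions = config.lesion_regions
    drivers = {r.driver for r in regions}
    if len(regions) < 2 or len({r.driver for r in regions}) < 2:
        raise ValueError("need >=2 planted regions mapped to distinct latent variables")
    rng = _rng(config, "volumes")
    shape = tuple(config.volume_shape)
    vs = (config.voxel_size_mm,) * 3
    brain = _brain_mask(shape)
    template = np.where(brain, config.template_intensity, 0.0)

    region_masks: dict[str, np.ndarray] = {}
    grids = np.indices(shape)
    for r in regions:
        d2 = sum((grids[a] - r.center[a]) ** 2 for a in range(3))
        m = (d2 <= r.radius_voxels**2) & brain
        if not m.any():
            raise ValueError(f"region {r.name!r} lies outside the brain mask/grid")
        region_masks[r.name] = m

    def driver_values(driver: str) -> np.ndarray:
        if driver == "s":
            return np.sqrt(truth.s)
        if driver == "p":
            return np.sqrt(truth.p)
        if driver in truth.latents.columns:
            return truth.latents[driver].to_numpy()
        raise ValueError(f"unknown lesion driver {driver!r}")

    severity = pd.DataFrame(
        {r.name: _severity(driver_values(r.driver)) for r in regions},
        index=truth.patient_ids,
    )

    age = config.age_mean + config.age_sd * rng.standard_normal(config.n_patients)
    edu = config.education_mean + config.education_sd * rng.standard_normal(config.n_patients)

    patients = []
    for i, pid in enumerate(truth.patient_ids):
        vol = template + rng.standard_normal(shape) * config.patient_noise_sd
        for r in regions:
            vol[region_masks[r.name]] -= r.max_drop * severity.loc[pid, r.name]
        vol[brain] += config.age_slope * (age[i] - config.age_mean)
        vol[brain] += config.education_slope * (edu[i] - config.education_mean)
        vol[~brain] = 0.0
        patients.append(Volume(vol, vs, subject_id=pid, group="patient"))

    controls = []
    ctrl_age = config.age_mean + config.age_sd * rng.standard_normal(config.n_controls)
    ctrl_edu = config.education_mean + config.education_sd * rng.standard_normal(config.n_controls)
    for i in range(config.n_controls):
        vol = template + rng.standard_normal(shape) * config.control_noise_sd
        vol[brain] += config.age_slope * (ctrl_age[i] - config.age_mean)
        vol[brain] += config.education_slope * (ctrl_edu[i] - config.education_mean)
        vol[~brain] = 0.0
        controls.append(Volume(vol, vs, subject_id=f"C{i+1:03d}", group="control"))

    covars = pd.DataFrame({"age": age, "education": edu}, index=truth.patient_ids)
    return VolumeSet(
        patients=patients, controls=controls, covariates=covars,
        brain_mask=brain, region_masks=region_masks, true_severity=severity,
    )


# ---------------------------------------------------------------------------
# whole cohort


@dataclass
class CohortData:
    config: CohortConfig
    truth: SyntheticTruth
    naming: dict[str, list[NamingRecord]]
    profiles: list[ErrorProfile]
    battery: pd.DataFrame
    max_scores: dict[str, float]
    volumes: VolumeSet


def generate_cohort(config: CohortConfig | None = None, with_volumes: bool = True) -> CohortData:
    """Generate a full cohort (naming + battery + optionally volumes)."""
    config = config or CohortConfig()
    truth = sample_truth(config)
    naming = generate_naming(config, truth)
    profiles = naming_to_profiles(naming)
    battery, max_scores = generate_battery(config, truth)
    volumes = generate_volumes(config, truth) if with_volumes else None
    return CohortData(
        config=config, truth=truth, naming=naming, profiles=profiles,
        battery=battery, max_scores=max_scores, volumes=volumes,
    )
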