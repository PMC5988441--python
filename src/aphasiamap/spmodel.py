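"""Interactive two-step (semantic–phonological) model of word production.

The model is a three-layer spreading-activation network: semantic feature
nodes, lexical (word) nodes and slot-structured phoneme nodes, with
bidirectional connections feature↔word of weight ``s`` and word↔phoneme of
weight ``p``.  Naming is simulated in two retrieval steps.  Step 1: a jolt of
activation is injected into the target's semantic features and spread for a
fixed number of noisy update cycles, after which the most activated word is
selected.  Step 2: the selected word receives a large boost, activation
spreads again, and the most activated phoneme in each slot is selected.  The
assembled phoneme string is classified against the model lexicon: matching a
word yields that word's neighbourhood role (correct / semantic / formal /
mixed / unrelated); anything else is a non-word.

Lexical impairment is modelled purely by lowering ``s`` and/or ``p`` below
their normal value (the cap).  Fitting recovers ``(s, p)`` for an observed
six-way response profile by exhaustive grid search minimising a chi-square
statistic between observed counts and Monte-Carlo predicted probabilities,
with common random numbers shared across grid points so that neighbouring
points differ by parameters and not by noise realisation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from math import sqrt
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errcode import DELL_CATEGORIES, DellProfile

__all__ = [
    "SPParameters",
    "LexicalNetwork",
    "ResponseDistribution",
    "SPFit",
    "GridCache",
    "canonical_lexicon",
    "build_network",
    "run_trial",
    "predict_distribution",
    "default_grid",
    "fit_parameters",
    "fit_cohort",
]

#: word-role → index into the canonical six-category order.
_ROLE_TO_CATEGORY = {
    "target": "correct",
    "semantic": "semantic",
    "formal": "formal",
    "mixed": "mixed",
    "unrelated": "unrelated",
}


@dataclass(frozen=True)
class SPParameters:
    """Network constants.  Only ``s`` and ``p`` vary between patients.

    Defaults follow the published semantic–phonological model family: decay
    q = 0.6 per step, 8 update steps per retrieval stage, a semantic jolt of
    100 activation units split across the target's features (10 per feature
    for a 10-feature word), a lexical boost of 100 to the selected word,
    intrinsic noise SD 0.01, activation-proportional noise SD 0.16, and a
    "normal" weight cap of 0.1.  At the cap the network names ~97% of
    trials correctly, matching the model family's unimpaired profile.
    """

    s: float = 0.1
    p: float = 0.1
    q: float = 0.6
    sigma_intrinsic: float = 0.01
    sigma_activation: float = 0.16
    steps_per_stage: int = 8
    jolt_semantic: float = 100.0
    jolt_lexical: float = 100.0
    cap: float = 0.1

    def __post_init__(self) -> None:
        if not (0.0 <= self.s <= self.cap and 0.0 <= self.p <= self.cap):
            raise ValueError(f"s and p must lie in [0, cap={self.cap}]")
        if not 0.0 < self.q < 1.0:
            raise ValueError("decay q must lie in (0, 1)")
        if self.steps_per_stage < 1:
            raise ValueError("steps_per_stage must be >= 1")

    def with_weights(self, s: float, p: float) -> "SPParameters":
        return SPParameters(
            s=s,
            p=p,
            q=self.q,
            sigma_intrinsic=self.sigma_intrinsic,
            sigma_activation=self.sigma_activation,
            steps_per_stage=self.steps_per_stage,
            jolt_semantic=self.jolt_semantic,
            jolt_lexical=self.jolt_lexical,
            cap=self.cap,
        )


def canonical_lexicon() -> dict:
    """The standard five-word naming neighbourhood.

    Target *cat* with one neighbour of each role: *dog* (semantic — shares
    the "animal" feature, no phoneme-in-slot), *rat* (mixed — shares the
    feature and the vowel/coda), *mat* (formal — shares vowel/coda only) and
    *log* (unrelated — shares nothing).  Three phoneme slots: onset, vowel,
    coda.  Each word carries 10 semantic features; related neighbours share
    one, a sharing level calibrated so the unimpaired (capped) network
    reproduces the model family's ~97% correct normal naming profile.
    """
    return {
        "slots": ["onset", "vowel", "coda"],
        "words": [
            {
                "label": "cat",
                "role": "target",
                "phonemes": ["k", "ae", "t"],
                "features": [f"cat{i}" for i in range(1, 10)] + ["animal"],
            },
            {
                "label": "dog",
                "role": "semantic",
                "phonemes": ["d", "aa", "g"],
                "features": [f"dog{i}" for i in range(1, 10)] + ["animal"],
            },
            {
                "label": "rat",
                "role": "mixed",
                "phonemes": ["r", "ae", "t"],
                "features": [f"rat{i}" for i in range(1, 10)] + ["animal"],
            },
            {
                "label": "mat",
                "role": "formal",
                "phonemes": ["m", "ae", "t"],
                "features": [f"mat{i}" for i in range(1, 11)],
            },
            {
                "label": "log",
                "role": "unrelated",
                "phonemes": ["l", "aa", "g"],
                "features": [f"log{i}" for i in range(1, 11)],
            },
        ],
    }


class LexicalNetwork:
    """Three-layer network compiled from a lexicon specification.

    Connectivity is stored as 0/1 incidence matrices; the s/p weights are
    bound at simulation time, so one network serves every grid point.
    """

    def __init__(self, spec: Mapping) -> None:
        self.slots = list(spec["slots"])
        words = spec["words"]
        self.word_labels = [w["label"] for w in words]
        self.word_roles = [w["role"] for w in words]
        roles = set(self.word_roles)
        for required in ("target", "semantic", "formal", "mixed", "unrelated"):
            if required not in roles:
                raise ValueError(f"lexicon must declare a {required!r} word")
        self.target_index = self.word_roles.index("target")

        # feature nodes
        feat_names: list[str] = []
        for w in words:
            for f in w["features"]:
                if f not in feat_names:
                    feat_names.append(f)
        self.feature_names = feat_names
        self.n_features = len(feat_names)
        self.n_words = len(words)

        # phoneme nodes, grouped by slot
        self.slot_phonemes: list[list[str]] = []
        for k, slot in enumerate(self.slots):
            symbols = []
            for w in words:
                ph = w["phonemes"][k]
                if ph not in symbols:
                    symbols.append(ph)
            self.slot_phonemes.append(symbols)
        self.n_phonemes = sum(len(s) for s in self.slot_phonemes)
        self._slot_offsets = np.cumsum([0] + [len(s) for s in self.slot_phonemes])

        # incidence matrices (bidirectional edges: one matrix serves both ways)
        self.F = np.zeros((self.n_words, self.n_features), dtype=np.float32)
        self.P = np.zeros((self.n_words, self.n_phonemes), dtype=np.float32)
        self.word_phoneme_codes = np.zeros((self.n_words, len(self.slots)), dtype=np.int64)
        for i, w in enumerate(words):
            if len(w["phonemes"]) != len(self.slots):
                raise ValueError(f"word {w['label']!r} does not fill every phoneme slot")
            for f in w["features"]:
                self.F[i, feat_names.index(f)] = 1.0
            for k, ph in enumerate(w["phonemes"]):
                j = self._slot_offsets[k] + self.slot_phonemes[k].index(ph)
                self.P[i, j] = 1.0
                self.word_phoneme_codes[i, k] = self.slot_phonemes[k].index(ph)
        self._validate_roles(words)

        # integer code of each word's phoneme string for fast classification
        radix = np.array([len(s) for s in self.slot_phonemes], dtype=np.int64)
        self._radix = radix
        self._word_codes = self._encode(self.word_phoneme_codes)

    def _encode(self, slot_indices: np.ndarray) -> np.ndarray:
        code = np.zeros(slot_indices.shape[:-1], dtype=np.int64)
        for k in range(len(self.slots)):
            code = code * self._radix[k] + slot_indices[..., k]
        return code

    def _validate_roles(self, words) -> None:
        tgt = words[self.target_index]
        tgt_feats = set(tgt["features"])
        for w in words:
            if w["role"] == "target":
                continue
            shares_feat = bool(tgt_feats & set(w["features"]))
            shares_phon = any(
                a == b for a, b in zip(tgt["phonemes"], w["phonemes"])
            )
            role = w["role"]
            ok = {
                "semantic": shares_feat and not shares_phon,
                "formal": shares_phon and not shares_feat,
                "mixed": shares_feat and shares_phon,
                "unrelated": not shares_feat and not shares_phon,
            }.get(role)
            if ok is None:
                raise ValueError(f"unknown role {role!r} for word {w['label']!r}")
            if not ok:
                raise ValueError(
                    f"word {w['label']!r} violates its {role!r} role constraints "
                    "(feature/phoneme sharing with the target is wrong)"
                )

    @property
    def n_nodes(self) -> int:
        return self.n_features + self.n_words + self.n_phonemes

    def category_of_code(self) -> dict[int, int]:
        """Map phoneme-string code → index in the six-category order."""
        return {
            int(code): DELL_CATEGORIES.index(_ROLE_TO_CATEGORY[role])
            for code, role in zip(self._word_codes, self.word_roles)
        }

    @classmethod
    def from_json(cls, path) -> "LexicalNetwork":
        with open(path) as fh:
            return cls(json.load(fh))


def build_network(lexicon_spec: Mapping | None = None) -> LexicalNetwork:
    """Compile a lexicon specification (default: the canonical neighbourhood)."""
    return LexicalNetwork(lexicon_spec if lexicon_spec is not None else canonical_lexicon())


# ---------------------------------------------------------------------------
# simulation


def _simulate_batch(
    network: LexicalNetwork,
    params: SPParameters,
    n_sims: int,
    rng: np.random.Generator,
    eps: np.ndarray | None = None,
    tie_u: np.ndarray | None = None,
) -> np.ndarray:
    """Simulate ``n_sims`` independent naming trials; return category indices.

    ``eps`` may carry pre-generated standard normals of shape
    (2 * steps_per_stage, n_sims, n_nodes) to implement common random numbers
    across parameter settings; otherwise noise is drawn from ``rng``.
    """
    nf, nw, npho = network.n_features, network.n_words, network.n_phonemes
    steps = params.steps_per_stage
    s32 = np.float32(params.s)
    p32 = np.float32(params.p)
    retain = np.float32(1.0 - params.q)
    var_i = np.float32(params.sigma_intrinsic**2)
    sd_a = np.float32(params.sigma_activation)
    noisy = params.sigma_intrinsic > 0 or params.sigma_activation > 0

    a_f = np.zeros((n_sims, nf), dtype=np.float32)
    a_w = np.zeros((n_sims, nw), dtype=np.float32)
    a_p = np.zeros((n_sims, npho), dtype=np.float32)

    tgt_feats = network.F[network.target_index] > 0
    a_f[:, tgt_feats] = np.float32(params.jolt_semantic / tgt_feats.sum())

    F, P = network.F, network.P

    def step(t: int) -> None:
        in_w = s32 * (a_f @ F.T) + p32 * (a_p @ P.T)
        in_f = s32 * (a_w @ F)
        in_p = p32 * (a_w @ P)
        for a, inp, lo in ((a_f, in_f, 0), (a_w, in_w, nf), (a_p, in_p, nf + nw)):
            # a <- a(1-q) + input + noise, noise SD = sqrt(var_i + (sd_a * a)^2)
            if noisy:
                sd = np.sqrt(var_i + np.square(sd_a * a))
                if eps is not None:
                    noise = eps[t, :, lo : lo + a.shape[1]] * sd
                else:
                    noise = rng.standard_normal(a.shape, dtype=np.float32) * sd
            else:
                noise = 0.0
            a *= retain
            a += inp
            a += noise

    for t in range(steps):
        step(t)

    selected = _argmax_tiebreak(a_w, rng, tie_u)
    a_w[np.arange(n_sims), selected] += np.float32(params.jolt_lexical)

    for t in range(steps, 2 * steps):
        step(t)

    if not np.isfinite(a_p).all():
        bad = np.argwhere(~np.isfinite(a_p))[0]
        raise FloatingPointError(f"non-finite phoneme activation (sim {bad[0]}, node {bad[1]})")

    # per-slot phoneme selection
    slot_idx = np.empty((n_sims, len(network.slots)), dtype=np.int64)
    for k in range(len(network.slots)):
        lo, hi = network._slot_offsets[k], network._slot_offsets[k + 1]
        slot_idx[:, k] = _argmax_tiebreak(a_p[:, lo:hi], rng, tie_u)
    codes = network._encode(slot_idx)

    cats = np.full(n_sims, DELL_CATEGORIES.index("nonword"), dtype=np.int64)
    for code, cat in network.category_of_code().items():
        cats[codes == code] = cat
    return cats


def _argmax_tiebreak(
    a: np.ndarray, rng: np.random.Generator, tie_u: np.ndarray | None
) -> np.ndarray:
    """Row-wise argmax with uniform random choice among exact ties."""
    idx = np.argmax(a, axis=1)
    amax = a[np.arange(a.shape[0]), idx]
    tied = (a == amax[:, None]).sum(axis=1) > 1
    if tied.any():
        for i in np.flatnonzero(tied):
            choices = np.flatnonzero(a[i] == amax[i])
            if tie_u is not None:
                pick = choices[int(tie_u[i] * len(choices)) % len(choices)]
            else:
                pick = rng.choice(choices)
            idx[i] = pick
    return idx


def run_trial(network: LexicalNetwork, params: SPParameters, rng_seed: int) -> str:
    """Simulate one naming trial; returns one of the six category labels."""
    rng = np.random.default_rng(rng_seed)
    cat = _simulate_batch(network, params, 1, rng)[0]
    return DELL_CATEGORIES[cat]


@dataclass
class ResponseDistribution:
    """Empirical six-way response distribution from Monte-Carlo simulation."""

    probabilities: dict[str, float]
    n_sims: int
    seed: int

    def __post_init__(self) -> None:
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}")

    def as_vector(self) -> np.ndarray:
        return np.array([self.probabilities[c] for c in DELL_CATEGORIES])


_MAX_CHUNK = 20_000


def predict_distribution(
    params: SPParameters,
    n_sims: int,
    seed: int,
    network: LexicalNetwork | None = None,
) -> ResponseDistribution:
    """Estimate the six-way response distribution at (s, p) by simulation."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    network = network if network is not None else build_network()
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(DELL_CATEGORIES), dtype=np.int64)
    remaining = n_sims
    while remaining:
        chunk = min(remaining, _MAX_CHUNK)
        cats = _simulate_batch(network, params, chunk, rng)
        counts += np.bincount(cats, minlength=len(DELL_CATEGORIES))
        remaining -= chunk
    probs = counts / n_sims
    return ResponseDistribution(
        probabilities=dict(zip(DELL_CATEGORIES, probs.tolist())), n_sims=n_sims, seed=seed
    )


# ---------------------------------------------------------------------------
# grid-search fitting


def default_grid(n: int = 50, grid_min: float = 1e-3, cap: float = 0.1) -> np.ndarray:
    """Logarithmically spaced weight grid on (grid_min, cap].

    The floor excludes the regime where a weight's contribution falls below
    the network's intrinsic noise floor and the response profile saturates,
    i.e. where the parameter is no longer identifiable from behaviour.
    """
    return np.geomspace(grid_min, cap, n)


@dataclass
class GridCache:
    """Predicted six-way distributions tabulated over an (s, p) grid.

    The table is patient-independent, so one cache serves a whole cohort.
    Built with common random numbers: every grid point reuses the same noise
    realisations, which makes the chi-square surface smooth in (s, p).
    """

    s_grid: np.ndarray
    p_grid: np.ndarray
    probs: np.ndarray  # (len(s_grid), len(p_grid), 6)
    n_sims: int
    seed: int

    @classmethod
    def build(
        cls,
        s_grid: np.ndarray | None = None,
        p_grid: np.ndarray | None = None,
        n_sims: int = 10_000,
        seed: int = 0,
        network: LexicalNetwork | None = None,
        base_params: SPParameters | None = None,
    ) -> "GridCache":
        network = network if network is not None else build_network()
        base = base_params if base_params is not None else SPParameters()
        s_grid = np.asarray(s_grid if s_grid is not None else default_grid(cap=base.cap))
        p_grid = np.asarray(p_grid if p_grid is not None else default_grid(cap=base.cap))
        if s_grid.size == 0 or p_grid.size == 0:
            raise ValueError("empty parameter grid")
        if s_grid.max() > base.cap or p_grid.max() > base.cap:
            raise ValueError("grid exceeds the weight cap")

        steps = base.steps_per_stage
        n_nodes = network.n_nodes
        chunk = min(n_sims, _MAX_CHUNK)
        rng = np.random.default_rng(seed)
        probs = np.zeros((len(s_grid), len(p_grid), len(DELL_CATEGORIES)))

        remaining = n_sims
        while remaining:
            this = min(remaining, chunk)
            eps = rng.standard_normal((2 * steps, this, n_nodes), dtype=np.float32)
            tie_u = rng.random(this)
            for i, s in enumerate(s_grid):
                for j, p in enumerate(p_grid):
                    cats = _simulate_batch(
                        network, base.with_weights(float(s), float(p)), this,
                        rng, eps=eps, tie_u=tie_u,
                    )
                    probs[i, j] += np.bincount(cats, minlength=len(DELL_CATEGORIES))
            remaining -= this
        probs /= n_sims
        return cls(s_grid=s_grid, p_grid=p_grid, probs=probs, n_sims=n_sims, seed=seed)

    def save(self, path) -> None:
        np.savez_compressed(
            path, s_grid=self.s_grid, p_grid=self.p_grid, probs=self.probs,
            n_sims=self.n_sims, seed=self.seed,
        )

    @classmethod
    def load(cls, path) -> "GridCache":
        with np.load(path) as z:
            return cls(
                s_grid=z["s_grid"], p_grid=z["p_grid"], probs=z["probs"],
                n_sims=int(z["n_sims"]), seed=int(z["seed"]),
            )


@dataclass
class SPFit:
    """Fitted weights for one patient."""

    s_hat: float
    p_hat: float
    sqrt_s: float
    sqrt_p: float
    chi2: float
    s_index: int
    p_index: int
    at_boundary_s: bool
    at_boundary_p: bool
    patient_id: str = "patient"


def fit_parameters(
    observed: DellProfile,
    cache: GridCache,
    expected_floor: float = 0.5,
) -> SPFit:
    """Grid-search chi-square fit of (s, p) to an observed six-way profile.

    chi2(s, p) = sum_c (O_c - n pi_c)^2 / max(n pi_c, floor), with O the
    observed category counts (proportions × n_effective) and pi the cached
    Monte-Carlo predictions.  The floor guards cells whose predicted count is
    near zero.  Exact chi-square ties resolve to the least-impaired grid
    point (largest s + p indices), consistent with the constraint that
    weights sit below — but as close as the data allow to — the normal cap.
    """
    obs = np.asarray(observed.as_vector(), dtype=float)
    if abs(obs.sum() - 1.0) > 1e-9:
        raise ValueError("observed proportions must sum to 1")
    n = observed.n_effective
    if n <= 0:
        raise ValueError("n_effective must be positive")
    O = obs * n
    expected = cache.probs * n
    chi2 = ((O - expected) ** 2 / np.maximum(expected, expected_floor)).sum(axis=2)
    ties = np.argwhere(chi2 == chi2.min())
    i, j = max(map(tuple, ties), key=lambda ij: (ij[0] + ij[1], ij[0], ij[1]))
    return SPFit(
        s_hat=float(cache.s_grid[i]),
        p_hat=float(cache.p_grid[j]),
        sqrt_s=sqrt(float(cache.s_grid[i])),
        sqrt_p=sqrt(float(cache.p_grid[j])),
        chi2=float(chi2[i, j]),
        s_index=int(i),
        p_index=int(j),
        at_boundary_s=i in (0, len(cache.s_grid) - 1),
        at_boundary_p=j in (0, len(cache.p_grid) - 1),
        patient_id=observed.patient_id,
    )


def fit_cohort(
    profiles: Sequence[DellProfile],
    cache: GridCache,
    expected_floor: float = 0.5,
) -> pd.DataFrame:
    """Fit every patient against one shared grid cache; tabular result."""
    rows = []
    for prof in profiles:
        f = fit_parameters(prof, cache, expected_floor=expected_floor)
        rows.append(
            {
                "patient_id": f.patient_id,
                "s_hat": f.s_hat,
                "p_hat": f.p_hat,
                "sqrt_s": f.sqrt_s,
                "sqrt_p": f.sqrt_p,
                "chi2": f.chi2,
                "at_boundary_s": f.at_boundary_s,
                "at_boundary_p": f.at_boundary_p,
            }
        )
    return pd.DataFrame(rows).set_index("patient_id")
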