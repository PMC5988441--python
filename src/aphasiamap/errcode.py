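"""Naming-response coding for aphasic picture naming.

Responses are first coded into the fine-grained clinical scheme (14 error
categories plus ``correct`` and ``not-a-incorrect``), then collapsed onto the
six categories the interactive two-step model predicts (correct, semantic,
formal, mixed, unrelated, non-word).  Omission-type categories are pooled and
removed under the independence account before model fitting: the remaining
six proportions are renormalised so they describe only trials on which a
scoreable naming attempt was made.

Phonological relatedness is a purely symbolic predicate over phoneme
sequences: a response is related to its target if it preserves the first or
last phoneme, keeps at least two other phonemes in position, or contains at
least 30% of the target's phonemes in any position.  Semantic relatedness is
an externally supplied judgement (human coding), never computed here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "FINE_CATEGORIES",
    "DELL_CATEGORIES",
    "NamingRecord",
    "ErrorProfile",
    "DellProfile",
    "UnclassifiableError",
    "phonologically_related",
    "classify_response",
    "recode_to_dell",
    "apply_independence_account",
    "screen_patients_and_categories",
    "read_naming_csv",
    "profiles_to_frame",
    "dell_profiles_to_frame",
]

#: Closed response vocabulary: 14 error categories + correct + not-a-incorrect.
FINE_CATEGORIES: tuple[str, ...] = (
    "correct",
    "semantic",
    "phonemic",
    "neologism",
    "formal",
    "mixed",
    "unrelated",
    "initial",
    "dysfluency",
    "perseveration",
    "circumlocution",
    "not-a-correct",
    "visual",
    "omission",
    "other",
    "morphological",
    "not-a-incorrect",
)

#: The six categories the SP model fits, in the canonical fitting order.
DELL_CATEGORIES: tuple[str, ...] = (
    "correct",
    "semantic",
    "formal",
    "mixed",
    "unrelated",
    "nonword",
)

# fine-grained -> Dell collapse.  Perseverations are handled per trial (coded in
# relation to the current target); not-a-incorrect is not re-coded at all.
_TO_CORRECT = frozenset({"correct", "dysfluency", "not-a-correct"})
_TO_NONWORD = frozenset({"phonemic", "neologism"})
_TO_OMISSION = frozenset(
    {"omission", "circumlocution", "initial", "visual", "other", "morphological"}
)
#: Categories that feed the model fit and are never dropped by the rarity screen.
DELL_REQUIRED = frozenset(
    {"semantic", "formal", "mixed", "unrelated", "phonemic", "neologism"}
)


class UnclassifiableError(ValueError):
    """Raised when a response cannot be categorised from the available flags."""


@dataclass
class NamingRecord:
    """One naming trial: target, transcribed response and coding flags."""

    item_id: str
    target_label: str
    target_phonemes: tuple[str, ...]
    response_phonemes: tuple[str, ...] | None = None
    response_is_real_word: bool | None = None
    semantically_related: bool | None = None
    within_time_limit: bool = True
    coder_category: str | None = None

    def __post_init__(self) -> None:
        self.target_phonemes = tuple(self.target_phonemes)
        if self.response_phonemes is not None:
            self.response_phonemes = tuple(self.response_phonemes)
        if self.coder_category is not None and self.coder_category not in FINE_CATEGORIES:
            raise ValueError(
                f"coder_category {self.coder_category!r} not in the category vocabulary"
            )


def phonologically_related(
    target: Sequence[str], response: Sequence[str]
) -> bool:
    """Phonemic-definition relatedness between two phoneme sequences.

    True when the response preserves the first or last target phoneme in
    position, keeps at least two other phonemes in their correct position,
    or contains at least 30% of the target's phonemes in any position.
    """
    target = tuple(target)
    response = tuple(response)
    if not target:
        raise ValueError("empty target phoneme sequence")
    if not response:
        return False
    if response[0] == target[0] or response[-1] == target[-1]:
        return True
    # positional matches excluding the first and last target slots
    interior = range(1, min(len(target), len(response)) - 1)
    if sum(target[i] == response[i] for i in interior) >= 2:
        return True
    shared = sum((Counter(target) & Counter(response)).values())
    return shared / len(target) >= 0.30


def classify_response(record: NamingRecord, phoneme_inventory: Iterable[str] | None = None) -> str:
    """Assign one fine-grained category to a naming trial.

    An explicit ``coder_category`` always wins (human coding overrides the
    automatic rule).  Otherwise: no response, or a response outside the time
    limit, is an omission; an exact phoneme match is correct; real words split
    into semantic / formal / mixed / unrelated by the two relatedness flags;
    non-words split into phonemic / neologism by phonological relatedness.
    """
    if not record.target_phonemes:
        raise ValueError(f"record {record.item_id}: empty target phonemes")
    if phoneme_inventory is not None:
        inventory = set(phoneme_inventory)
        unknown = set(record.target_phonemes) - inventory
        if unknown:
            raise ValueError(f"record {record.item_id}: phonemes {unknown} not in inventory")
    if record.coder_category is not None:
        return record.coder_category
    if record.response_phonemes is None or not record.within_time_limit:
        return "omission"
    if record.response_phonemes == record.target_phonemes:
        return "correct"
    phon = phonologically_related(record.target_phonemes, record.response_phonemes)
    if record.response_is_real_word is None:
        raise UnclassifiableError(
            f"record {record.item_id}: real-word status unknown and no coder category"
        )
    if not record.response_is_real_word:
        return "phonemic" if phon else "neologism"
    if record.semantically_related is None:
        raise UnclassifiableError(
            f"record {record.item_id}: semantic relatedness unknown and no coder category"
        )
    if record.semantically_related and phon:
        return "mixed"
    if record.semantically_related:
        return "semantic"
    if phon:
        return "formal"
    return "unrelated"


@dataclass
class ErrorProfile:
    """Per-patient counts over the fine-grained categories."""

    counts: dict[str, int]
    n_items: int
    n_attempted: int
    patient_id: str = "patient"

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(FINE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown categories {unknown}")
        self.counts = {c: int(self.counts.get(c, 0)) for c in FINE_CATEGORIES}
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative category count")
        if sum(self.counts.values()) != self.n_items:
            raise ValueError(
                f"counts sum to {sum(self.counts.values())}, expected n_items={self.n_items}"
            )
        if self.n_attempted > self.n_items:
            raise ValueError("n_attempted exceeds n_items")

    @classmethod
    def from_records(
        cls, records: Sequence[NamingRecord], patient_id: str = "patient"
    ) -> "ErrorProfile":
        cats = [classify_response(r) for r in records]
        counts = Counter(cats)
        n_attempted = sum(c != "omission" for c in cats)
        return cls(dict(counts), n_items=len(records), n_attempted=n_attempted, patient_id=patient_id)

    @property
    def attempt_rate(self) -> float:
        return self.n_attempted / self.n_items


@dataclass
class DellProfile:
    """Six-way response proportions after the independence account.

    ``omission_mass`` is the fraction of all trials routed to the omission
    pool; it is recorded separately and is *not* part of the six-way sum.
    """

    proportions: dict[str, float]
    omission_mass: float
    n_effective: int
    patient_id: str = "patient"

    def __post_init__(self) -> None:
        if set(self.proportions) != set(DELL_CATEGORIES):
            raise ValueError("proportions must cover exactly the six model categories")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"six-way proportions sum to {total}, not 1")
        if not 0.0 <= self.omission_mass < 1.0:
            raise ValueError("omission_mass must lie in [0, 1)")

    def as_vector(self) -> list[float]:
        return [self.proportions[c] for c in DELL_CATEGORIES]


def apply_independence_account(
    dell_counts: Mapping[str, float], omission_count: float
) -> dict[str, float]:
    """Drop the omission pool and renormalise the six model categories.

    Under the independence account omissions arise from a process unrelated to
    the lexical-access competition the model simulates, so the model is fitted
    to proportions conditional on an attempt having been made.
    """
    counts = {c: float(dell_counts.get(c, 0.0)) for c in DELL_CATEGORIES}
    if any(v < 0 for v in counts.values()) or omission_count < 0:
        raise ValueError("negative counts")
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no scoreable responses: all trials omitted")
    return {c: v / total for c, v in counts.items()}


def recode_to_dell(
    profile: ErrorProfile,
    perseveration_targets: Sequence[str] | None = None,
) -> DellProfile:
    """Collapse a fine-grained profile onto the six model categories.

    Perseverations carry no category of their own: each is re-coded by the
    relation of the repeated response to the *current* target, supplied as a
    sequence of Dell labels (one per perseveration trial).  Omission-type
    categories (omission, circumlocution, initial, visual, other,
    morphological) are pooled; not-a-incorrect responses are excluded
    entirely (neither correct pool nor model input).
    """
    c = profile.counts
    n_pers = c["perseveration"]
    pers = Counter()
    if n_pers:
        if perseveration_targets is None:
            raise ValueError(
                f"{profile.patient_id}: {n_pers} perseverations present but no "
                "target-relatedness information supplied"
            )
        if len(perseveration_targets) != n_pers:
            raise ValueError(
                f"{profile.patient_id}: got {len(perseveration_targets)} perseveration "
                f"codes for {n_pers} perseveration trials"
            )
        allowed = set(DELL_CATEGORIES) | {"omission"}
        bad = [t for t in perseveration_targets if t not in allowed]
        if bad:
            raise ValueError(f"unresolvable perseveration codes: {bad}")
        pers = Counter(perseveration_targets)

    dell = {
        "correct": sum(c[m] for m in _TO_CORRECT) + pers["correct"],
        "semantic": c["semantic"] + pers["semantic"],
        "formal": c["formal"] + pers["formal"],
        "mixed": c["mixed"] + pers["mixed"],
        "unrelated": c["unrelated"] + pers["unrelated"],
        "nonword": sum(c[m] for m in _TO_NONWORD) + pers["nonword"],
    }
    omission_pool = sum(c[m] for m in _TO_OMISSION) + pers["omission"]
    # conservation: dell + omission pool + not-a-incorrect = n_items
    assert sum(dell.values()) + omission_pool + c["not-a-incorrect"] == profile.n_items
    proportions = apply_independence_account(dell, omission_pool)
    return DellProfile(
        proportions=proportions,
        omission_mass=omission_pool / profile.n_items,
        n_effective=int(sum(dell.values())),
        patient_id=profile.patient_id,
    )


def screen_patients_and_categories(
    profiles: Sequence[ErrorProfile],
    min_attempt_rate: float = 0.5,
    rarity_threshold: float = 0.02,
) -> tuple[list[ErrorProfile], list[str]]:
    """Apply the cohort inclusion screen and the rare-category screen.

    Patients attempting fewer than ``min_attempt_rate`` of their items are
    excluded.  An error category is dropped from downstream PCA input iff its
    pooled share of all errors (across included patients) is below
    ``rarity_threshold`` *and* it is not one of the six categories the model
    fit requires.
    """
    if not profiles:
        raise ValueError("no profiles supplied")
    included = [p for p in profiles if p.attempt_rate >= min_attempt_rate]
    pooled = Counter()
    for p in included:
        pooled.update(p.counts)
    error_cats = [m for m in FINE_CATEGORIES if m != "correct"]
    total_errors = sum(pooled[m] for m in error_cats)
    eligible = []
    for m in error_cats:
        share = pooled[m] / total_errors if total_errors else 0.0
        if share >= rarity_threshold or m in DELL_REQUIRED:
            eligible.append(m)
    return included, eligible


# ---------------------------------------------------------------------------
# CSV interfaces


def read_naming_csv(path) -> dict[str, list[NamingRecord]]:
    """Read a per-trial naming CSV into records grouped by patient.

    Expected columns: patient_id, item_id, target, target_phonemes,
    response_phonemes (blank for omission), is_word, sem_related, in_time,
    coder_category.  Phoneme sequences are space-separated symbols.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out: dict[str, list[NamingRecord]] = {}

    def _flag(v: str) -> bool | None:
        return None if v == "" else v.lower() in {"1", "true", "yes"}

    for row in df.itertuples(index=False):
        rec = NamingRecord(
            item_id=row.item_id,
            target_label=row.target,
            target_phonemes=tuple(row.target_phonemes.split()),
            response_phonemes=tuple(row.response_phonemes.split()) or None
            if row.response_phonemes
            else None,
            response_is_real_word=_flag(row.is_word),
            semantically_related=_flag(row.sem_related),
            within_time_limit=_flag(row.in_time) if row.in_time != "" else True,
            coder_category=row.coder_category or None,
        )
        out.setdefault(row.patient_id, []).append(rec)
    return out


def profiles_to_frame(profiles: Sequence[ErrorProfile]) -> pd.DataFrame:
    """Per-patient category counts and attempt rates as a DataFrame."""
    rows = []
    for p in profiles:
        row = {"patient_id": p.patient_id, "n_items": p.n_items, "n_attempted": p.n_attempted}
        row.update(p.counts)
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


def dell_profiles_to_frame(profiles: Sequence[DellProfile]) -> pd.DataFrame:
    """Six-way fitting proportions (canonical order) plus omission mass."""
    rows = []
    for p in profiles:
        row = {"patient_id": p.patient_id}
        row.update({c: p.proportions[c] for c in DELL_CATEGORIES})
        row["omission_mass"] = p.omission_mass
        row["n_effective"] = p.n_effective
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")
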