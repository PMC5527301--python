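"""Couple-pairing permutation null.

An "incorrect pairing" is a derangement of the couple indices: every
female is matched to a male who is not her true partner.  Observed
statistics (PERMANOVA pseudo-F on couple labels, or supervised
classifier error) are compared against their values under relabelings
induced by the incorrect pairings."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from skinmatch.beta import DistanceMatrix
from skinmatch.permanova import pseudo_f
from skinmatch.tables import OtuTable, SampleFrame

log = logging.getLogger(__name__)

__all__ = [
    "CouplePairing",
    "NullDistribution",
    "derangement_count",
    "enumerate_derangements",
    "enumerate_incorrect_pairings",
    "sample_unique_pairings",
    "true_pairing",
    "relabel_couples",
    "pairing_null_permanova",
    "couple_classifier_error",
    "pairing_null_classifier",
    "classify_metadata_label",
]

_ENUMERATION_LIMIT = 9  # 9! = 362,880 permutations is still cheap to scan


@dataclass(frozen=True)
class CouplePairing:
    """A bijection from female to male participants.

    ``males[i]`` is paired with ``females[i]``.  An incorrect pairing
    maps no female to her true partner.
    """

    females: tuple[str, ...]
    males: tuple[str, ...]
    is_true_pairing: bool = False

    def __post_init__(self) -> None:
        if len(self.females) != len(self.males):
            raise ValueError("females and males must have equal length")
        if len(set(self.females)) != len(self.females) or len(set(self.males)) != len(self.males):
            raise ValueError("pairing is not a bijection (duplicate participant)")

    @property
    def n_couples(self) -> int:
        return len(self.females)

    def as_mapping(self) -> dict[str, str]:
        return dict(zip(self.females, self.males))


def derangement_count(n: int) -> int:
    """!n via the recurrence !n = (n-1)(!(n-1) + !(n-2))."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return 1
    if n == 1:
        return 0
    a, b = 1, 0  # !0, !1
    for k in range(2, n + 1):
        a, b = b, (k - 1) * (a + b)
    return b


def enumerate_derangements(n: int) -> list[tuple[int, ...]]:
    """All permutations of 0..n-1 with no fixed point, in lexicographic order."""
    if n < 2:
        raise ValueError("need n >= 2 couples")
    if n > _ENUMERATION_LIMIT:
        raise ValueError(
            f"refusing to enumerate {n}! permutations; use sample_unique_pairings"
        )
    return [p for p in itertools.permutations(range(n)) if all(p[i] != i for i in range(n))]


def _sample_derangements(n: int, k: int, rng: np.random.Generator) -> list[tuple[int, ...]]:
    total = derangement_count(n)
    if k > total:
        raise ValueError(f"requested {k} distinct incorrect pairings but only {total} exist")
    if n <= _ENUMERATION_LIMIT and total <= 50_000:
        all_d = enumerate_derangements(n)
        idx = rng.choice(total, size=k, replace=False)
        return [all_d[i] for i in idx]
    # rejection sampling; a uniform random permutation is a derangement w.p. ~1/e
    out: set[tuple[int, ...]] = set()
    while len(out) < k:
        p = tuple(int(x) for x in rng.permutation(n))
        if all(p[i] != i for i in range(n)):
            out.add(p)
    return sorted(out)


def true_pairing(meta: SampleFrame) -> CouplePairing:
    """The observed female-male pairing, ordered by couple id."""
    members = meta.couple_members()
    couples = sorted(members)
    return CouplePairing(
        tuple(members[c][0] for c in couples),
        tuple(members[c][1] for c in couples),
        is_true_pairing=True,
    )


def _pairing_from_derangement(truth: CouplePairing, sigma: Sequence[int]) -> CouplePairing:
    return CouplePairing(truth.females, tuple(truth.males[j] for j in sigma), False)


def enumerate_incorrect_pairings(meta: SampleFrame) -> list[CouplePairing]:
    """Every derangement of the couples, as participant-level pairings."""
    truth = true_pairing(meta)
    return [_pairing_from_derangement(truth, s) for s in enumerate_derangements(truth.n_couples)]


def sample_unique_pairings(
    meta: SampleFrame, n_samples: int, seed: int | np.random.Generator = 0
) -> list[CouplePairing]:
    """``n_samples`` distinct incorrect pairings, uniform without replacement."""
    truth = true_pairing(meta)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigmas = _sample_derangements(truth.n_couples, n_samples, rng)
    return [_pairing_from_derangement(truth, s) for s in sigmas]


def relabel_couples(meta: SampleFrame, pairing: CouplePairing) -> SampleFrame:
    """Metadata with couple labels of each pseudo-couple {female_i, male_sigma(i)}.

    Every field other than the couple column is untouched; each
    pseudo-couple keeps the female's couple id and therefore still
    contains exactly one female and one male.
    """
    df = meta.df
    missing = [p for p in pairing.females + pairing.males if p not in set(df["participant"])]
    if missing:
        raise KeyError(f"pairing participants missing from metadata: {missing}")
    new_couple = df["couple"].copy()
    for f, m in zip(pairing.females, pairing.males):
        fc = df.loc[df["participant"] == f, "couple"].iloc[0]
        new_couple[df["participant"] == m] = fc
    out = df.copy()
    out["couple"] = new_couple
    return SampleFrame(out)


def _null_couple_labels(
    participants: np.ndarray, couple_of: dict[str, str], pairing: CouplePairing
) -> np.ndarray:
    """Per-sample pseudo-couple labels for one pairing (fast path).

    Produces exactly the couple column of ``relabel_couples`` without
    building a new SampleFrame.
    """
    mapping = {f: couple_of[f] for f in pairing.females}
    for f, m in zip(pairing.females, pairing.males):
        mapping[m] = couple_of[f]
    return np.array([mapping.get(p, couple_of[p]) for p in participants])


@dataclass(frozen=True)
class NullDistribution:
    """Observed statistic vs its values under incorrect pairings."""

    statistic: str  # permanova_F | classifier_error
    observed: float
    null_values: np.ndarray
    p: float
    n_null: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "p": self.p,
            "n_null": self.n_null,
            "null_mean": float(np.mean(self.null_values)),
            "null_sd": float(np.std(self.null_values, ddof=1)) if self.n_null > 1 else 0.0,
        }


def pairing_null_permanova(
    dm: DistanceMatrix,
    meta: SampleFrame,
    pairings: Sequence[CouplePairing],
    body_location: str | None = None,
) -> NullDistribution:
    """Pseudo-F on true couple labels vs under each incorrect pairing.

    p = (1 + #{F_null >= F_obs}) / (1 + n_null).  ``body_location``
    restricts the analysis to one site's samples.
    """
    if not pairings:
        raise ValueError("need at least one incorrect pairing")
    ids = list(dm.sample_ids)
    if body_location is not None:
        locs = meta.df.loc[ids, "body_location"]
        ids = [s for s in ids if locs[s] == body_location]
        if not ids:
            raise ValueError(f"no samples at body location {body_location!r}")
        dm = dm.subset(ids)
    f_obs, _, _ = pseudo_f(dm, meta.df.loc[ids, "couple"].to_numpy())
    participants = meta.df.loc[ids, "participant"].to_numpy()
    couple_of = dict(
        meta.df.drop_duplicates("participant")[["participant", "couple"]].itertuples(index=False)
    )
    nulls = np.empty(len(pairings))
    for k, pairing in enumerate(pairings):
        nulls[k], _, _ = pseudo_f(dm, _null_couple_labels(participants, couple_of, pairing))
    p = (1 + int(np.sum(nulls >= f_obs - 1e-12))) / (1 + len(pairings))
    return NullDistribution("permanova_F", float(f_obs), nulls, float(p), len(pairings))


# ---------------------------------------------------------------------------
# supervised classification
# ---------------------------------------------------------------------------

def couple_classifier_error(
    table: OtuTable,
    labels: Sequence,
    n_trees: int = 1000,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[float, float]:
    """Stratified k-fold cross-validated misclassification rate of a
    random-forest classifier on rarefied OTU counts.

    Returns (mean error over folds, per-fold standard deviation).  If a
    class has fewer members than ``n_folds`` the fold count degrades
    gracefully with a warning.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold

    y = np.asarray([str(x) for x in labels])
    if len(y) != table.n_samples:
        raise ValueError("label length does not match sample count")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError(f"class {classes[int(counts.argmin())]!r} has a single sample")
    folds = int(min(n_folds, counts.min()))
    if folds < n_folds:
        log.warning("reducing folds from %d to %d (smallest class size)", n_folds, folds)
    x = table.counts
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errs = []
    for k, (train, test) in enumerate(skf.split(x, y)):
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + k, n_jobs=1)
        clf.fit(x[train], y[train])
        errs.append(float(np.mean(clf.predict(x[test]) != y[test])))
    errs_arr = np.array(errs)
    sd = float(errs_arr.std(ddof=1)) if folds > 1 else 0.0
    return float(errs_arr.mean()), sd


def pairing_null_classifier(
    table: OtuTable,
    meta: SampleFrame,
    pairings: Sequence[CouplePairing],
    n_trees: int = 1000,
    n_folds: int = 10,
    seed: int = 0,
) -> NullDistribution:
    """Classifier error on true couple labels vs under incorrect pairings.

    Lower error is more extreme: p = (1 + #{err_null <= err_obs}) /
    (1 + n_null).  Full-scale defaults (1,000 trees, 10 folds, 1,000
    pairings) are expensive; scale down for testing.
    """
    if not pairings:
        raise ValueError("need at least one incorrect pairing")
    ids = list(table.sample_ids)
    obs, _ = couple_classifier_error(
        table, meta.df.loc[ids, "couple"].to_numpy(), n_trees, n_folds, seed
    )
    participants = meta.df.loc[ids, "participant"].to_numpy()
    couple_of = dict(
        meta.df.drop_duplicates("participant")[["participant", "couple"]].itertuples(index=False)
    )
    nulls = np.empty(len(pairings))
    for k, pairing in enumerate(pairings):
        nulls[k], _ = couple_classifier_error(
            table, _null_couple_labels(participants, couple_of, pairing), n_trees, n_folds, seed
        )
    p = (1 + int(np.sum(nulls <= obs + 1e-12))) / (1 + len(pairings))
    return NullDistribution("classifier_error", float(obs), nulls, float(p), len(pairings))


def classify_metadata_label(
    table: OtuTable,
    meta: SampleFrame,
    label: str,
    n_trees: int = 1000,
    n_folds: int = 10,
    seed: int = 0,
    per_location: bool = False,
) -> dict:
    """Cross-validated accuracy of the classifier for any categorical label,
    overall and optionally per body location."""
    if label not in meta.df.columns:
        raise KeyError(f"label {label!r} not in metadata")
    ids = list(table.sample_ids)
    err, sd = couple_classifier_error(
        table, meta.df.loc[ids, label].to_numpy(), n_trees, n_folds, seed
    )
    out = {"label": label, "accuracy": 1.0 - err, "error": err, "fold_sd": sd}
    if per_location:
        locs = meta.df.loc[ids, "body_location"]
        by_loc = {}
        for loc in sorted(locs.unique()):
            sub_ids = [s for s in ids if locs[s] == loc]
            y = meta.df.loc[sub_ids, label].to_numpy()
            if len(np.unique(y)) < 2 or min(np.unique(y, return_counts=True)[1]) < 2:
                log.warning("skipping location %r for label %r", loc, label)
                continue
            e, s = couple_classifier_error(table.select_samples(sub_ids), y, n_trees, n_folds, seed)
            by_loc[loc] = {"accuracy": 1.0 - e, "error": e, "fold_sd": s}
        out["per_location"] = by_loc
    return out
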