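"""Nearest-neighbor sample matching: classify each sample's closest
other sample as self / partner / other under three candidate scopes,
with analytic chance baselines."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from skinmatch.beta import DistanceMatrix
from skinmatch.tables import SampleFrame

log = logging.getLogger(__name__)

__all__ = [
    "MatchRecord",
    "SCOPES",
    "nearest_neighbors",
    "match_proportions",
    "chance_baseline",
    "same_sex_nonpartner_rate",
]

SCOPES = ("all", "nonself", "nonself_opposite_sex")
RELATIONS = ("self", "partner", "other")


@dataclass(frozen=True)
class MatchRecord:
    """One query sample and its minimum-distance candidate."""

    query: str
    match: str
    distance: float
    relation: str  # self | partner | other
    scope: str
    body_location: str


def _relation(meta: SampleFrame, query: str, match: str) -> str:
    pq = meta.df.at[query, "participant"]
    pm = meta.df.at[match, "participant"]
    if pq == pm:
        return "self"
    if meta.df.at[query, "couple"] == meta.df.at[match, "couple"]:
        return "partner"
    return "other"


def nearest_neighbors(
    dm: DistanceMatrix,
    meta: SampleFrame,
    scope: str = "nonself",
    within_location: bool = True,
) -> list[MatchRecord]:
    """Find each sample's minimum-distance candidate under ``scope``.

    Scopes: ``all`` excludes only the query itself; ``nonself`` also
    excludes every sample of the query's participant;
    ``nonself_opposite_sex`` further excludes all same-sex participants.
    ``within_location`` restricts candidates to the query's body
    location.  Distance ties are broken by lexicographic sample id and
    counted in the log; queries with an empty candidate pool are skipped
    with a warning.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}; expected one of {SCOPES}")
    ids = dm.sample_ids
    missing = [s for s in ids if s not in meta.df.index]
    if missing:
        raise KeyError(f"distance-matrix samples missing from metadata: {missing[:5]}")
    participant = meta.df.loc[list(ids), "participant"].to_numpy()
    sex = meta.df.loc[list(ids), "sex"].to_numpy()
    location = meta.df.loc[list(ids), "body_location"].to_numpy()
    id_arr = np.array(ids)
    records: list[MatchRecord] = []
    n_ties = 0
    for i, query in enumerate(ids):
        mask = np.ones(len(ids), dtype=bool)
        mask[i] = False
        if scope in ("nonself", "nonself_opposite_sex"):
            mask &= participant != participant[i]
        if scope == "nonself_opposite_sex":
            mask &= sex != sex[i]
        if within_location:
            mask &= location == location[i]
        if not mask.any():
            log.warning("no candidates for %r under scope %r; skipped", query, scope)
            continue
        cand = np.flatnonzero(mask)
        dists = dm.data[i, cand]
        dmin = dists.min()
        best = cand[dists == dmin]
        if best.size > 1:
            n_ties += 1
            best = best[np.argsort(id_arr[best])]
        j = int(best[0])
        records.append(
            MatchRecord(
                query=query,
                match=ids[j],
                distance=float(dm.data[i, j]),
                relation=_relation(meta, query, ids[j]),
                scope=scope,
                body_location=str(location[i]),
            )
        )
    if n_ties:
        log.warning("%d distance ties broken lexicographically", n_ties)
    return records


def chance_baseline(n_participants: int, scope: str) -> float:
    """Participant-level uniform-choice baseline for the partner relation.

    ``nonself`` (and ``all``, once self matches are excluded): the
    partner is 1 of the ``n - 1`` other participants;
    ``nonself_opposite_sex``: 1 of the ``n/2`` opposite-sex participants.
    """
    if scope not in SCOPES:
        raise ValueError(f"unknown scope {scope!r}")
    if n_participants < 4 or n_participants % 2:
        raise ValueError(f"n_participants must be even and >= 4, got {n_participants}")
    if scope == "nonself_opposite_sex":
        return 1.0 / (n_participants / 2)
    return 1.0 / (n_participants - 1)


def match_proportions(
    records: Sequence[MatchRecord],
    meta: SampleFrame,
) -> pd.DataFrame:
    """Per-location (and pooled) self/partner/other proportions.

    Returns one row per ``(scope, body_location)`` plus a pooled
    ``(all locations)`` row per scope, with the analytic partner chance
    baseline and the partner fold-over-chance.
    """
    if not records:
        raise ValueError("no match records")
    n_participants = len(meta.participants)
    df = pd.DataFrame([r.__dict__ for r in records])
    rows = []
    for scope, sub_scope in df.groupby("scope"):
        strata = [("(all locations)", sub_scope)] + [
            (loc, g) for loc, g in sub_scope.groupby("body_location")
        ]
        for loc, g in strata:
            n = len(g)
            props = {rel: float((g["relation"] == rel).mean()) for rel in RELATIONS}
            baseline = chance_baseline(n_participants, str(scope))
            rows.append(
                {
                    "scope": scope,
                    "body_location": loc,
                    "n": n,
                    "prop_self": props["self"],
                    "prop_partner": props["partner"],
                    "prop_other": props["other"],
                    "chance_partner": baseline,
                    "fold_partner": props["partner"] / baseline,
                }
            )
    return pd.DataFrame(rows)


def same_sex_nonpartner_rate(
    records: Sequence[MatchRecord],
    meta: SampleFrame,
) -> tuple[float, float]:
    """Among nonself matches to non-partners, the same-sex fraction.

    Tested two-sided against the balanced-design null probability
    ``(n/2 - 1) / (n - 2)`` (same-sex non-partner participants over all
    non-partner participants); for 10 couples this is 9/18 = 0.5.
    """
    others = [r for r in records if r.relation == "other"]
    if not others:
        raise ValueError("no non-partner ('other') match records")
    if any(r.scope != "nonself" for r in others):
        raise ValueError("same-sex rate is defined on scope='nonself' records")
    n = len(meta.participants)
    same = sum(
        1
        for r in others
        if meta.df.at[r.query, "sex"] == meta.df.at[r.match, "sex"]
    )
    p0 = (n / 2 - 1) / (n - 2)
    res = binomtest(same, len(others), p0, alternative="two-sided")
    return same / len(others), float(res.pvalue)
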