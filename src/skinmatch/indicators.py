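"""Indicator-value analysis, core-OTU detection, and the sex-enrichment table.

IndVal for OTU i in group g is specificity x fidelity: A = the group's
share of the OTU's summed group means, B = the fraction of the group's
samples containing the OTU.  Significance is assessed by permuting group
labels with the per-OTU max-over-groups IndVal as the statistic."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from skinmatch.tables import OtuTable, SampleFrame

log = logging.getLogger(__name__)

__all__ = [
    "IndValRecord",
    "indval",
    "filter_indicators",
    "core_otus",
    "sex_enrichment_table",
]


@dataclass(frozen=True)
class IndValRecord:
    otu_id: str
    group: str
    a: float  # specificity: group mean / sum of group means
    b: float  # fidelity: fraction of group samples where present
    indval: float  # a * b
    p: float  # permutation p of the OTU's max-over-groups indval
    mean_abundance: float  # mean count within the group


def _indval_matrix(counts: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[np.ndarray, ...]:
    """(A, B, IV, group means), each shaped (n_groups, n_otus)."""
    n_otus = counts.shape[1]
    means = np.empty((n_groups, n_otus))
    prev = np.empty((n_groups, n_otus))
    for g in range(n_groups):
        m = codes == g
        means[g] = counts[m].mean(axis=0)
        prev[g] = (counts[m] > 0).mean(axis=0)
    tot = means.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(tot > 0, means / np.where(tot > 0, tot, 1.0), 0.0)
    iv = a * prev
    return a, prev, iv, means


def indval(
    table: OtuTable,
    groups: Sequence,
    n_perms: int = 999,
    seed: int = 0,
    percent_scale: bool = False,
) -> list[IndValRecord]:
    """Per-OTU, per-group indicator values with permutation p-values.

    Values are on the 0-1 scale unless ``percent_scale`` (0-100).  OTUs
    absent everywhere get indval 0 and p 1.  Deterministic per seed.
    """
    labels = np.asarray([str(g) for g in groups])
    if len(labels) != table.n_samples:
        raise ValueError("group labels do not match sample count")
    names, codes = np.unique(labels, return_inverse=True)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    counts = table.counts.astype(float)
    a, b, iv, means = _indval_matrix(counts, codes, len(names))
    obs_max = iv.max(axis=0)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(table.n_otus)
    for _ in range(n_perms):
        perm = rng.permutation(codes)
        _, _, iv_p, _ = _indval_matrix(counts, perm, len(names))
        exceed += iv_p.max(axis=0) >= obs_max - 1e-12
    p = (1 + exceed) / (1 + n_perms)
    scale = 100.0 if percent_scale else 1.0
    records = []
    for j, otu in enumerate(table.otu_ids):
        for g, name in enumerate(names):
            records.append(
                IndValRecord(
                    otu_id=otu,
                    group=str(name),
                    a=float(a[g, j]),
                    b=float(b[g, j]),
                    indval=float(iv[g, j] * scale),
                    p=float(p[j]),
                    mean_abundance=float(means[g, j]),
                )
            )
    return records


def filter_indicators(
    records: Sequence[IndValRecord],
    indval_min: float = 0.7,
    mean_min: float = 10.0,
    alpha: float = 0.05,
) -> list[IndValRecord]:
    """Keep records with indval >= threshold, group mean abundance >=
    minimum, and permutation p < alpha."""
    return [
        r
        for r in records
        if r.indval >= indval_min and r.mean_abundance >= mean_min and r.p < alpha
    ]


def indicators_to_frame(records: Sequence[IndValRecord], table: OtuTable | None = None) -> pd.DataFrame:
    """Tabulate indicator records, attaching taxonomy when available."""
    df = pd.DataFrame([r.__dict__ for r in records])
    if table is not None and table.taxonomy is not None and not df.empty:
        tax = dict(zip(table.otu_ids, table.taxonomy))
        df["taxonomy"] = df["otu_id"].map(tax)
    return df


def core_otus(table: OtuTable, meta: SampleFrame, category: str, level: str) -> set[str]:
    """OTUs with at least one read in EVERY sample of the category level."""
    if category not in meta.df.columns:
        raise KeyError(f"category {category!r} not in metadata")
    ids = [s for s in table.sample_ids if meta.df.at[s, category] == level]
    if not ids:
        raise ValueError(f"no samples with {category}={level!r}")
    sub = table.select_samples(ids)
    present = (sub.counts >= 1).all(axis=0)
    return {table.otu_ids[j] for j in np.flatnonzero(present)}


def sex_enrichment_table(
    table: OtuTable,
    meta: SampleFrame,
    prevalence_min: float = 0.30,
    top_n: int = 10,
) -> pd.DataFrame:
    """Top OTUs disproportionately abundant on each sex.

    Percent increase = (mean_high / mean_low - 1) * 100 for OTUs present
    in at least ``prevalence_min`` of the enriched sex's samples.  OTUs
    absent from the depleted sex (infinite ratio) are flagged and
    excluded from the ranking.
    """
    sexes = meta.df.loc[list(table.sample_ids), "sex"].to_numpy()
    present = sorted(set(sexes))
    if present != ["female", "male"]:
        raise ValueError(f"need both sexes in the table, got {present}")
    fm = sexes == "female"
    counts = table.counts.astype(float)
    mean_f = counts[fm].mean(axis=0)
    mean_m = counts[~fm].mean(axis=0)
    prev_f = (counts[fm] > 0).mean(axis=0)
    prev_m = (counts[~fm] > 0).mean(axis=0)
    rows = []
    for j, otu in enumerate(table.otu_ids):
        hi_is_f = mean_f[j] >= mean_m[j]
        hi, lo = (mean_f[j], mean_m[j]) if hi_is_f else (mean_m[j], mean_f[j])
        prev = prev_f[j] if hi_is_f else prev_m[j]
        if hi == 0 or prev < prevalence_min:
            continue
        infinite = lo == 0
        rows.append(
            {
                "otu_id": otu,
                "taxonomy": table.taxonomy[j] if table.taxonomy else "",
                "direction": "female" if hi_is_f else "male",
                "mean_female": mean_f[j],
                "mean_male": mean_m[j],
                "prevalence_enriched": prev,
                "percent_increase": np.inf if infinite else (hi / lo - 1.0) * 100.0,
                "infinite_ratio": infinite,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    ranked = df[~df["infinite_ratio"]]
    out = (
        ranked.sort_values("percent_increase", ascending=False)
        .groupby("direction", group_keys=False)
        .head(top_n)
        .sort_values(["direction", "percent_increase"], ascending=[True, False])
        .reset_index(drop=True)
    )
    return out
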