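"""One-factor distance-based permutational multivariate ANOVA.

Pseudo-F from the among/within sums-of-squared-distances decomposition,
permutation p-values with the +1 smoothed estimator, and a per-category
(optionally per-body-location) significance sweep."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from skinmatch.beta import DistanceMatrix
from skinmatch.tables import SampleFrame

log = logging.getLogger(__name__)

__all__ = ["PermanovaResult", "pseudo_f", "permanova_test", "category_sweep"]


@dataclass(frozen=True)
class PermanovaResult:
    factor: str
    f: float
    r2: float
    df_between: int
    df_within: int
    p: float
    n_perms: int


def _codes(labels: Sequence) -> tuple[np.ndarray, int]:
    arr = np.asarray([str(x) for x in labels])
    _, codes = np.unique(arr, return_inverse=True)
    return codes, int(codes.max()) + 1


def _decompose(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(n_groups):
        m = codes == g
        ng = int(m.sum())
        ss_within += d2[np.ix_(m, m)].sum() / (2.0 * ng)
    return float(ss_total), float(ss_within)


def pseudo_f(dm: DistanceMatrix, labels: Sequence) -> tuple[float, float, tuple[int, int]]:
    """Pseudo-F, R-squared, and (df_between, df_within) for one factor.

    SS_total = (1/N) sum_{i<j} d_ij^2; SS_within sums within-group
    squared distances each scaled by 1/n_g; F = (SS_among/(a-1)) /
    (SS_within/(N-a)).
    """
    codes, a = _codes(labels)
    n = dm.n_samples
    if len(codes) != n:
        raise ValueError(f"{len(codes)} labels for {n} samples")
    if a < 2:
        raise ValueError("need at least 2 groups")
    if n <= a:
        raise ValueError(f"need more samples ({n}) than groups ({a})")
    d2 = dm.data**2
    ss_total, ss_within = _decompose(d2, codes, a)
    ss_among = ss_total - ss_within
    dfb, dfw = a - 1, n - a
    f = (ss_among / dfb) / (ss_within / dfw) if ss_within > 0 else np.inf
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2), (dfb, dfw)


def _perm_f(d2: np.ndarray, codes: np.ndarray, n_groups: int, perm_codes: np.ndarray) -> np.ndarray:
    """Vectorized pseudo-F over rows of permuted group codes."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    counts = np.bincount(codes, minlength=n_groups)
    ss_within = np.zeros(perm_codes.shape[0])
    for g in range(n_groups):
        m = (perm_codes == g).astype(float)
        ss_within += np.einsum("pi,ij,pj->p", m, d2, m) / (2.0 * counts[g])
    dfb, dfw = n_groups - 1, n - n_groups
    ss_among = ss_total - ss_within
    with np.errstate(divide="ignore"):
        return (ss_among / dfb) / (ss_within / dfw)


def permanova_test(
    dm: DistanceMatrix,
    labels: Sequence,
    n_perms: int = 999,
    seed: int | np.random.Generator = 0,
    factor: str = "factor",
) -> PermanovaResult:
    """PERMANOVA with unrestricted label permutations.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_perms); deterministic per seed.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    f_obs, r2, (dfb, dfw) = pseudo_f(dm, labels)
    codes, a = _codes(labels)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = dm.n_samples
    order = np.argsort(rng.random((n_perms, n)), axis=1)
    perm_codes = codes[order]
    f_perm = _perm_f(dm.data**2, codes, a, perm_codes)
    exceed = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (1 + exceed) / (1 + n_perms)
    return PermanovaResult(factor, f_obs, r2, dfb, dfw, float(p), n_perms)


def category_sweep(
    dm: DistanceMatrix,
    meta: SampleFrame,
    categories: Sequence[str],
    per_location: bool = False,
    n_perms: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run a one-factor PERMANOVA for every category (x body location).

    Categories constant within a subset are skipped with a warning.
    Returns a long table with F, R2, p and a significance flag
    (non-significant cells are rendered blank downstream).
    """
    rng = np.random.default_rng(seed)
    ids = list(dm.sample_ids)
    strata: list[tuple[str, list[str]]]
    if per_location:
        locs = meta.df.loc[ids, "body_location"]
        strata = [(loc, [s for s in ids if locs[s] == loc]) for loc in sorted(locs.unique())]
    else:
        strata = [("(all locations)", ids)]
    rows = []
    for cat in sorted(categories):
        if cat not in meta.df.columns:
            raise KeyError(f"category {cat!r} not in metadata")
        for loc, sub_ids in strata:
            labels = meta.df.loc[sub_ids, cat]
            counts = labels.value_counts()
            if len(counts) < 2 or len(sub_ids) <= len(counts):
                log.warning("skipping %r at %s: category constant or too few samples", cat, loc)
                continue
            res = permanova_test(dm.subset(sub_ids), labels.to_numpy(), n_perms, rng, cat)
            rows.append(
                {
                    "category": cat,
                    "body_location": loc,
                    "f": res.f,
                    "r2": res.r2,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "p": res.p,
                    "significant": res.p < alpha,
                }
            )
    return pd.DataFrame(rows)


def sweep_matrix(sweep: pd.DataFrame) -> pd.DataFrame:
    """Pivot a per-location sweep into the categories x locations F matrix,
    blanking non-significant cells."""
    df = sweep.copy()
    df.loc[~df["significant"], "f"] = np.nan
    return df.pivot(index="category", columns="body_location", values="f")
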