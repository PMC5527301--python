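"""Alpha diversity: Shannon index, observed OTUs, multiple-rarefaction
sweeps, and nonparametric (permutation) two-sample t tests with
Bonferroni correction across metadata categories."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from skinmatch.tables import OtuTable, SampleFrame, rarefy

log = logging.getLogger(__name__)

__all__ = [
    "AlphaResult",
    "CategoryTestResult",
    "shannon",
    "observed_otus",
    "multiple_rarefactions_alpha",
    "nonparametric_t_test",
    "alpha_category_sweep",
]

_METRICS = ("shannon", "observed_otus")


def shannon(counts: np.ndarray, base: float = 2.0) -> float:
    """Shannon diversity H = -sum p_i log_base p_i (zero terms drop out)."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon index undefined for an all-zero vector")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def observed_otus(counts: np.ndarray) -> int:
    """Number of OTUs with a strictly positive count."""
    return int(np.count_nonzero(np.asarray(counts) > 0))


@dataclass(frozen=True)
class AlphaResult:
    """Per-sample alpha values over a rarefaction depth grid.

    ``values`` has shape ``(n_samples, n_depths, n_reps)``.
    """

    metric: str
    sample_ids: tuple[str, ...]
    depths: np.ndarray
    values: np.ndarray

    @property
    def n_rarefactions(self) -> int:
        return int(self.depths.size * self.values.shape[2])

    def at_max_depth(self) -> pd.Series:
        """Per-sample metric averaged over replicates at the deepest grid point."""
        vals = self.values[:, -1, :].mean(axis=1)
        return pd.Series(vals, index=list(self.sample_ids))


def _metric_fn(metric: str, base: float):
    if metric == "shannon":
        return lambda row: shannon(row, base=base)
    if metric == "observed_otus":
        return lambda row: float(observed_otus(row))
    raise ValueError(f"unknown metric {metric!r}; expected one of {_METRICS}")


def multiple_rarefactions_alpha(
    table: OtuTable,
    min_depth: int,
    max_depth: int,
    step: int,
    reps: int,
    metric: str = "shannon",
    seed: int = 0,
    base: float = 2.0,
) -> AlphaResult:
    """Compute an alpha metric on ``reps`` independent rarefactions at
    every depth in ``range(min_depth, max_depth + 1, step)``.

    The defaults of the full-scale analysis (100..5290 step 100, 10
    reps) yield 53 x 10 = 530 rarefactions.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    depths = np.arange(min_depth, max_depth + 1, step)
    if depths.size == 0:
        raise ValueError(f"empty depth grid: min={min_depth} max={max_depth} step={step}")
    if depths[-1] != max_depth:
        # the stated maximum is always evaluated, even when off-grid
        # (100..5290 step 100 thus yields 53 levels)
        depths = np.append(depths, max_depth)
    min_sum = int(table.sample_sums().min())
    if depths[-1] > min_sum:
        raise ValueError(f"max depth {depths[-1]} exceeds the smallest sample depth {min_sum}")
    fn = _metric_fn(metric, base)
    rng = np.random.default_rng(seed)
    values = np.empty((table.n_samples, depths.size, reps))
    for d_i, depth in enumerate(depths):
        for r in range(reps):
            sub = rarefy(table, int(depth), rng)
            values[:, d_i, r] = [fn(sub.counts[i]) for i in range(sub.n_samples)]
    return AlphaResult(metric, table.sample_ids, depths, values)


def _welch_t(a: np.ndarray, b: np.ndarray) -> float:
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    denom = np.sqrt(va / a.size + vb / b.size)
    if denom == 0:
        return 0.0 if ma == mb else float(np.sign(ma - mb) * np.inf)
    return float((ma - mb) / denom)


def nonparametric_t_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_perms: int = 999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Permutation two-sample t test (unequal-variance t statistic).

    p = (1 + #{|t_perm| >= |t_obs|}) / (1 + n_perms) over random
    relabelings, so p is never 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    t_obs = _welch_t(a, b)
    if t_obs == 0.0 and a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        return 0.0, 1.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = np.concatenate([a, b])
    n = pool.size
    na = a.size
    # vectorized relabeling: each row of P is a random permutation of 0..n-1
    P = np.argsort(rng.random((n_perms, n)), axis=1)
    perm = pool[P]
    pa, pb = perm[:, :na], perm[:, na:]
    ma, mb = pa.mean(axis=1), pb.mean(axis=1)
    va, vb = pa.var(axis=1, ddof=1), pb.var(axis=1, ddof=1)
    denom = np.sqrt(va / na + vb / (n - na))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = np.where(denom == 0, np.where(ma == mb, 0.0, np.inf), (ma - mb) / denom)
    exceed = int(np.sum(np.abs(t_perm) >= abs(t_obs) - 1e-12))
    p = (1 + exceed) / (1 + n_perms)
    return t_obs, float(p)


@dataclass(frozen=True)
class CategoryTestResult:
    """One binary contrast of a metadata category on a per-sample alpha vector."""

    category: str
    level_a: str
    level_b: str
    n_a: int
    n_b: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    t: float
    p_raw: float
    p_adjusted: float


def alpha_category_sweep(
    alpha: AlphaResult,
    meta: SampleFrame,
    categories: Sequence[str],
    n_perms: int = 999,
    seed: int = 0,
) -> list[CategoryTestResult]:
    """Test every pairwise level contrast of each category.

    Per-sample alpha is the replicate mean at the maximum depth.
    Multi-level categories expand to all pairwise contrasts; the
    Bonferroni factor is the number of tests actually executed, which is
    logged.  Levels with < 2 samples are skipped with a warning.
    """
    per_sample = alpha.at_max_depth()
    rng = np.random.default_rng(seed)
    contrasts: list[tuple[str, str, str, np.ndarray, np.ndarray]] = []
    for cat in categories:
        if cat not in meta.df.columns:
            raise KeyError(f"category {cat!r} not in metadata")
        col = meta.df.loc[list(per_sample.index), cat]
        levels = sorted(col.unique())
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                va = per_sample[col == levels[i]].to_numpy()
                vb = per_sample[col == levels[j]].to_numpy()
                if va.size < 2 or vb.size < 2:
                    log.warning(
                        "skipping contrast %s: %s vs %s (level with < 2 samples)",
                        cat, levels[i], levels[j],
                    )
                    continue
                contrasts.append((cat, levels[i], levels[j], va, vb))
    m = len(contrasts)
    log.info("alpha sweep: %d contrasts executed (Bonferroni factor %d)", m, m)
    results = []
    for cat, la, lb, va, vb in contrasts:
        t, p = nonparametric_t_test(va, vb, n_perms=n_perms, seed=rng)
        results.append(
            CategoryTestResult(
                category=cat,
                level_a=la,
                level_b=lb,
                n_a=va.size,
                n_b=vb.size,
                mean_a=float(va.mean()),
                sd_a=float(va.std(ddof=1)),
                mean_b=float(vb.mean()),
                sd_b=float(vb.std(ddof=1)),
                t=t,
                p_raw=p,
                p_adjusted=min(1.0, p * m),
            )
        )
    return results


def sweep_to_frame(results: Sequence[CategoryTestResult]) -> pd.DataFrame:
    """Tabulate sweep results (means, sds, t, raw and adjusted p)."""
    return pd.DataFrame([r.__dict__ for r in results])
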