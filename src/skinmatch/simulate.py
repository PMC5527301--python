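"""Household-structured synthetic community generator.

Generates OTU tables plus matching metadata with hierarchical
log-additive effects (body site >> individual > couple > sex), softmax
composition, optional Dirichlet overdispersion, and multinomial
sampling at a log-normal read depth with a floor.  The default
configuration reproduces the target study shape: 10 couples x 2
participants x 17 swabs (7 bilateral + 3 single body locations) = 340
samples before depth filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from skinmatch.tables import (
    BODY_LOCATIONS,
    OtuTable,
    SampleFrame,
    TableError,
    subsample_counts,
)

import pandas as pd

__all__ = [
    "SiteSpec",
    "SimConfig",
    "SimTruth",
    "default_sites",
    "simulate_community",
    "seed_low_depth_samples",
]


@dataclass(frozen=True)
class SiteSpec:
    """One body location in a simulated design."""

    name: str
    bilateral: bool
    moisture: str


def default_sites() -> tuple[SiteSpec, ...]:
    """The 10-location study design (7 bilateral + 3 single)."""
    return tuple(SiteSpec(n, b, m) for n, (b, m) in BODY_LOCATIONS.items())


_PHYLA = ("Actinobacteria", "Firmicutes", "Proteobacteria", "Bacteroidetes", "Minorphyla")
_PHYLUM_PROBS = (0.40, 0.30, 0.22, 0.05, 0.03)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the hierarchical community simulation.

    Effect scales are standard deviations of per-OTU Gaussian
    log-abundance effects; site effects should dominate, individual
    effects exceed couple effects, and the sex effect applies only on
    ``sex_effect_sites``.
    """

    n_couples: int = 10
    body_locations: tuple[SiteSpec, ...] = field(default_factory=default_sites)
    n_otus: int = 300
    depth_meanlog: float = 8.1
    depth_sdlog: float = 0.35
    depth_floor: int = 6000
    sigma_site: float = 1.2
    sigma_individual: float = 0.8
    sigma_couple: float = 0.3
    sigma_sex: float = 0.8
    sigma_noise: float = 0.35
    sex_effect_sites: tuple[str, ...] = ("inner thigh", "armpit")
    dispersion: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_couples < 2:
            raise ValueError("n_couples must be >= 2")
        if self.n_otus < 10:
            raise ValueError("n_otus must be >= 10")
        if self.depth_floor < 1:
            raise ValueError("depth_floor must be >= 1")
        for name in ("sigma_site", "sigma_individual", "sigma_couple", "sigma_sex", "sigma_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive when given")
        unknown = set(self.sex_effect_sites) - {s.name for s in self.body_locations}
        if unknown:
            raise ValueError(f"sex_effect_sites not in design: {sorted(unknown)}")

    @property
    def n_participants(self) -> int:
        return 2 * self.n_couples

    @property
    def swabs_per_participant(self) -> int:
        return sum(2 if s.bilateral else 1 for s in self.body_locations)

    @property
    def n_samples(self) -> int:
        return self.n_participants * self.swabs_per_participant


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth effect vectors and realized compositions."""

    baseline: np.ndarray  # (n_otus,)
    site_effects: dict[str, np.ndarray]  # site -> (n_otus,)
    participant_effects: dict[str, np.ndarray]
    couple_effects: dict[str, np.ndarray]
    sex_effect: np.ndarray  # (n_otus,), +v/2 female, -v/2 male on designated sites
    compositions: np.ndarray  # (n_samples, n_otus) expected proportions
    sample_ids: tuple[str, ...]


def _slug(name: str) -> str:
    return name.replace(" ", "-")


def _make_taxonomy(n_otus: int, rng: np.random.Generator) -> tuple[str, ...]:
    phyla = rng.choice(len(_PHYLA), size=n_otus, p=_PHYLUM_PROBS)
    tax = []
    for j in range(n_otus):
        p = _PHYLA[phyla[j]]
        fam = f"Family{j % 25:02d}"
        tax.append(
            f"k__Bacteria; p__{p}; c__Class{phyla[j]}; o__Order{phyla[j]}; "
            f"f__{p}_{fam}; g__Genus{j % 60:02d}; s__otu{j:04d}"
        )
    return tuple(tax)


def simulate_community(config: SimConfig) -> tuple[OtuTable, SampleFrame, SimTruth]:
    """Simulate an OTU table and metadata under ``config``.

    For each sample, per-OTU log-weights are the sum of a global
    baseline, a site effect, a participant effect, a couple effect, a
    signed sex effect on the designated sites, and replicate noise.
    Weights are softmax-normalized, optionally Dirichlet-perturbed, then
    multinomially sampled at a depth ``floor + round(lognormal)``.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    if (
        config.sigma_site == 0
        and config.sigma_individual == 0
        and config.sigma_couple == 0
        and config.sigma_sex == 0
        and config.sigma_noise == 0
    ):
        import warnings

        warnings.warn("all effect scales are zero: samples differ only by sampling noise")

    n_otus = config.n_otus
    baseline = rng.normal(0.0, 1.5, size=n_otus)
    site_eff = {
        s.name: rng.normal(0.0, config.sigma_site, size=n_otus) for s in config.body_locations
    }
    couples = [f"H{c + 1:02d}" for c in range(config.n_couples)]
    participants = {c: (f"{c}A", f"{c}B") for c in couples}  # A = female, B = male
    part_eff = {
        p: rng.normal(0.0, config.sigma_individual, size=n_otus)
        for c in couples
        for p in participants[c]
    }
    couple_eff = {c: rng.normal(0.0, config.sigma_couple, size=n_otus) for c in couples}
    sex_eff = rng.normal(0.0, config.sigma_sex, size=n_otus)

    rows = []
    meta_rows = []
    sample_ids: list[str] = []
    comps = []
    for c in couples:
        for p, sex in zip(participants[c], ("female", "male")):
            for site in config.body_locations:
                sides = ("left", "right") if site.bilateral else ("none",)
                for side in sides:
                    logw = (
                        baseline
                        + site_eff[site.name]
                        + part_eff[p]
                        + couple_eff[c]
                    )
                    if site.name in config.sex_effect_sites:
                        logw = logw + (0.5 if sex == "female" else -0.5) * sex_eff
                    logw = logw + rng.normal(0.0, config.sigma_noise, size=n_otus)
                    w = np.exp(logw - logw.max())
                    w /= w.sum()
                    if config.dispersion is not None:
                        alpha = np.maximum(w * config.dispersion, 1e-9)
                        w = rng.dirichlet(alpha)
                    depth = config.depth_floor + int(
                        round(rng.lognormal(config.depth_meanlog, config.depth_sdlog))
                    )
                    rows.append(rng.multinomial(depth, w))
                    comps.append(w)
                    suffix = {"left": "L", "right": "R", "none": "C"}[side]
                    sid = f"{p}.{_slug(site.name)}.{suffix}"
                    sample_ids.append(sid)
                    meta_rows.append(
                        {
                            "sample_id": sid,
                            "participant": p,
                            "couple": c,
                            "sex": sex,
                            "body_location": site.name,
                            "side": side,
                            "moisture": site.moisture,
                        }
                    )

    counts = np.array(rows, dtype=np.int64)
    taxonomy = _make_taxonomy(n_otus, rng)
    otu_ids = tuple(f"OTU{j:04d}" for j in range(n_otus))
    table = OtuTable(counts, tuple(sample_ids), otu_ids, taxonomy)
    meta_df = pd.DataFrame(meta_rows).set_index("sample_id")
    meta = SampleFrame(meta_df)
    truth = SimTruth(
        baseline=baseline,
        site_effects=site_eff,
        participant_effects=part_eff,
        couple_effects=couple_eff,
        sex_effect=sex_eff,
        compositions=np.array(comps),
        sample_ids=tuple(sample_ids),
    )
    return table, meta, truth


def seed_low_depth_samples(
    table: OtuTable, n: int, below: int, seed: int = 0
) -> OtuTable:
    """Downsample exactly ``n`` randomly chosen samples to depths < ``below``.

    Fixture helper so the low-depth filter has a known amount of work to
    do; the retained/removed partition is deterministic per seed.
    """
    if n >= table.n_samples:
        raise TableError(f"n={n} must be smaller than the sample count {table.n_samples}")
    if n == 0:
        return table
    rng = np.random.default_rng(seed)
    idx = rng.choice(table.n_samples, size=n, replace=False)
    counts = table.counts.copy()
    for i in idx:
        target = int(rng.integers(max(1, below // 2), below))
        target = min(target, int(counts[i].sum()))
        counts[i] = subsample_counts(counts[i], target, rng)
    return replace(table, counts=counts)
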