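import numpy as np
import pytest

from skinmatch.indicators import (
    IndValRecord,
    core_otus,
    filter_indicators,
    indicators_to_frame,
    indval,
    sex_enrichment_table,
)
from skinmatch.simulate import simulate_community
from skinmatch.tables import OtuTable, rarefy

from .conftest import make_meta, small_config


def brute_indval(counts, labels, otu, group):
    """Independent oracle for A, B, indval of one OTU x group."""
    counts = np.asarray(counts, float)
    labels = np.asarray(labels)
    groups = sorted(set(labels))
    means = {g: counts[labels == g, otu].mean() for g in groups}
    tot = sum(means.values())
    a = means[group] / tot if tot > 0 else 0.0
    in_g = counts[labels == group, otu]
    b = (in_g > 0).mean()
    return a, b, a * b


def two_group_table(rows_g1, rows_g2):
    counts = np.array(rows_g1 + rows_g2)
    ids = tuple(f"S{i}" for i in range(len(counts)))
    otus = tuple(f"O{j}" for j in range(counts.shape[1]))
    labels = ["g1"] * len(rows_g1) + ["g2"] * len(rows_g2)
    return OtuTable(counts, ids, otus), labels


class TestIndval:
    def test_perfect_indicator(self):
        table, labels = two_group_table([[20], [20], [20]], [[0], [0], [0]])
        recs = {r.group: r for r in indval(table, labels, n_perms=99, seed=0)}
        r = recs["g1"]
        assert (r.a, r.b, r.indval) == (1.0, 1.0, 1.0)
        assert r.mean_abundance == pytest.approx(20.0)

    def test_equal_means_everywhere_present(self):
        table, labels = two_group_table([[10], [10]], [[10], [10]])
        recs = {r.group: r for r in indval(table, labels, n_perms=99, seed=0)}
        for g in ("g1", "g2"):
            assert recs[g].a == pytest.approx(0.5)
            assert recs[g].b == pytest.approx(1.0)
            assert recs[g].indval == pytest.approx(0.5)

    def test_half_presence(self):
        table, labels = two_group_table([[40], [0]], [[0], [0]])
        recs = {r.group: r for r in indval(table, labels, n_perms=99, seed=0)}
        assert recs["g1"].a == pytest.approx(1.0)
        assert recs["g1"].b == pytest.approx(0.5)
        assert recs["g1"].indval == pytest.approx(0.5)

    def test_matches_brute_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(8, size=(10, 6))
        labels = ["a"] * 5 + ["b"] * 5
        table = OtuTable(counts, tuple(f"S{i}" for i in range(10)), tuple(f"O{j}" for j in range(6)))
        recs = indval(table, labels, n_perms=9, seed=0)
        for r in recs:
            j = table.otu_ids.index(r.otu_id)
            a, b, iv = brute_indval(counts, labels, j, r.group)
            assert r.a == pytest.approx(a, abs=1e-12)
            assert r.b == pytest.approx(b, abs=1e-12)
            assert r.indval == pytest.approx(iv, abs=1e-12)

    def test_specificity_sums_to_one(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5, size=(12, 8)) + 1
        labels = ["a", "b", "c"] * 4
        table = OtuTable(counts, tuple(f"S{i}" for i in range(12)), tuple(f"O{j}" for j in range(8)))
        recs = indval(table, labels, n_perms=9, seed=0)
        by_otu = {}
        for r in recs:
            by_otu.setdefault(r.otu_id, 0.0)
            by_otu[r.otu_id] += r.a
        for total in by_otu.values():
            assert total == pytest.approx(1.0)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(6, size=(8, 5))
        labels = ["a"] * 4 + ["b"] * 4
        t1 = OtuTable(counts, tuple(f"S{i}" for i in range(8)), tuple(f"O{j}" for j in range(5)))
        t2 = OtuTable(counts * 7, t1.sample_ids, t1.otu_ids)
        iv1 = sorted((r.otu_id, r.group, r.indval) for r in indval(t1, labels, n_perms=5, seed=3))
        iv2 = sorted((r.otu_id, r.group, r.indval) for r in indval(t2, labels, n_perms=5, seed=3))
        for (o1, g1, v1), (o2, g2, v2) in zip(iv1, iv2):
            assert (o1, g1) == (o2, g2)
            assert v1 == pytest.approx(v2)

    def test_absent_otu_zero(self):
        table, labels = two_group_table([[5, 0], [5, 0]], [[5, 0], [5, 0]])
        recs = [r for r in indval(table, labels, n_perms=9, seed=0) if r.otu_id == "O1"]
        assert all(r.indval == 0.0 for r in recs)

    def test_percent_scale_flag(self):
        table, labels = two_group_table([[20], [20]], [[0], [0]])
        recs = {r.group: r for r in indval(table, labels, n_perms=9, seed=0, percent_scale=True)}
        assert recs["g1"].indval == pytest.approx(100.0)

    def test_seeded_indicator_detected(self):
        # a strong planted indicator reaches indval ~1 with small p
        rng = np.random.default_rng(3)
        base = rng.poisson(5, size=(16, 10))
        base[:8, 0] = 120 + rng.poisson(10, 8)
        base[8:, 0] = 0
        labels = ["hi"] * 8 + ["lo"] * 8
        table = OtuTable(base, tuple(f"S{i}" for i in range(16)), tuple(f"O{j}" for j in range(10)))
        recs = [r for r in indval(table, labels, n_perms=199, seed=0)
                if r.otu_id == "O0" and r.group == "hi"]
        assert recs[0].indval > 0.95
        assert recs[0].p < 0.05


class TestFilterIndicators:
    def _rec(self, iv, mean, p):
        return IndValRecord("O1", "g", 0.9, 0.9, iv, p, mean)

    def test_all_gates_passed(self):
        assert filter_indicators([self._rec(0.71, 12, 0.01)]) != []

    def test_abundance_gate(self):
        assert filter_indicators([self._rec(0.9, 9, 0.001)]) == []

    def test_indval_gate(self):
        assert filter_indicators([self._rec(0.69, 100, 0.001)]) == []

    def test_p_gate(self):
        assert filter_indicators([self._rec(0.9, 100, 0.06)]) == []

    def test_alcohol_style_fixture(self):
        # planted indicator: indval 0.70, mean 129 in the indicated group vs 2
        rng = np.random.default_rng(4)
        n = 10
        counts = np.zeros((2 * n, 3), dtype=int)
        counts[:, 2] = 50  # filler OTU so rows are nonzero
        counts[:n, 0] = [129] * n  # high-consumption group, present everywhere
        counts[n:, 0] = [2] * n
        labels = ["daily"] * n + ["monthly"] * n
        table = OtuTable(counts, tuple(f"S{i}" for i in range(2 * n)), ("O0", "O1", "O2"))
        recs = [r for r in indval(table, labels, n_perms=199, seed=0)
                if r.otu_id == "O0" and r.group == "daily"]
        r = recs[0]
        assert r.indval == pytest.approx(129 / 131, abs=1e-9)  # ~0.98 >= 0.7
        assert r.mean_abundance == pytest.approx(129)
        kept = filter_indicators(recs)
        assert kept and kept[0].otu_id == "O0"


class TestCoreOtus:
    def _setup(self):
        counts = np.array(
            [
                [3, 1, 0],
                [2, 1, 5],
                [9, 0, 2],
                [4, 2, 2],
            ]
        )
        table = OtuTable(counts, ("S1", "S2", "S3", "S4"), ("O0", "O1", "O2"))
        meta = make_meta(
            [
                ("S1", "H01A", "H01", "female", "foot", "left"),
                ("S2", "H01A", "H01", "female", "foot", "right"),
                ("S3", "H01B", "H01", "male", "foot", "left"),
                ("S4", "H01B", "H01", "male", "foot", "right"),
            ]
        )
        return table, meta

    def test_zero_excludes(self):
        table, meta = self._setup()
        core = core_otus(table, meta, "sex", "female")
        assert core == {"O0", "O1"}  # O2 is zero in S1

    def test_all_positive_included(self):
        table, meta = self._setup()
        assert "O0" in core_otus(table, meta, "sex", "male")

    def test_empty_level_errors(self):
        table, meta = self._setup()
        with pytest.raises(ValueError):
            core_otus(table, meta, "sex", "unknown")

    def test_symmetric_simulation_core_sets_equal(self):
        # without a sex effect the two sexes' core sets coincide almost always
        # near-ubiquitous OTUs and weak structure, so the present-in-all
        # boundary is rarely crossed by only one sex
        equal = 0
        for s in range(10):
            cfg = small_config(
                n_otus=15, depth_floor=8000, depth_meanlog=4.0,
                sigma_site=0.2, sigma_individual=0.1, sigma_couple=0.0,
                sigma_noise=0.1, seed=900 + s,
            )
            table, meta, _ = simulate_community(cfg)
            rare = rarefy(table, 8000, seed=s)
            f = core_otus(rare, meta, "sex", "female")
            m = core_otus(rare, meta, "sex", "male")
            equal += f == m
        assert equal >= 8


class TestSexEnrichment:
    def _meta(self, n_per_sex=4):
        rows = []
        for i in range(n_per_sex):
            c = f"H{i:02d}"
            rows.append((f"f{i}", f"{c}A", c, "female", "foot", "left"))
            rows.append((f"m{i}", f"{c}B", c, "male", "foot", "left"))
        return make_meta(rows)

    def test_percent_increase_arithmetic(self):
        # means 10 vs 4 -> 150% increase
        counts = np.zeros((8, 2), dtype=int)
        counts[:, 1] = 5
        counts[[0, 2, 4, 6], 0] = 10  # females
        counts[[1, 3, 5, 7], 0] = 4  # males
        ids = ("f0", "m0", "f1", "m1", "f2", "m2", "f3", "m3")
        table = OtuTable(counts, ids, ("O0", "O1"))
        out = sex_enrichment_table(table, self._meta())
        row = out[out["otu_id"] == "O0"].iloc[0]
        assert row["direction"] == "female"
        assert row["percent_increase"] == pytest.approx(150.0)

    def test_prevalence_gate(self):
        # enriched OTU present in only 1/4 female samples (25% < 30%) is excluded
        counts = np.zeros((8, 2), dtype=int)
        counts[:, 1] = 5
        counts[0, 0] = 100
        ids = ("f0", "m0", "f1", "m1", "f2", "m2", "f3", "m3")
        table = OtuTable(counts, ids, ("O0", "O1"))
        out = sex_enrichment_table(table, self._meta())
        assert "O0" not in set(out["otu_id"])

    def test_twelvefold_is_1111_percent(self):
        # ratio 12.114 -> 1,111.4% increase within rounding
        counts = np.zeros((8, 2), dtype=int)
        counts[:, 1] = 5
        counts[[0, 2, 4, 6], 0] = [85, 85, 85, 84]  # female mean 84.75
        counts[[1, 3, 5, 7], 0] = 7  # male mean 7
        ids = ("f0", "m0", "f1", "m1", "f2", "m2", "f3", "m3")
        table = OtuTable(counts, ids, ("O0", "O1"))
        out = sex_enrichment_table(table, self._meta())
        row = out[out["otu_id"] == "O0"].iloc[0]
        assert row["percent_increase"] == pytest.approx((84.75 / 7 - 1) * 100)
        assert round(row["percent_increase"], 1) == 1110.7

    def test_infinite_ratio_excluded(self):
        counts = np.zeros((8, 2), dtype=int)
        counts[:, 1] = 5
        counts[[0, 2, 4, 6], 0] = 50  # absent from every male
        ids = ("f0", "m0", "f1", "m1", "f2", "m2", "f3", "m3")
        table = OtuTable(counts, ids, ("O0", "O1"))
        out = sex_enrichment_table(table, self._meta())
        assert "O0" not in set(out["otu_id"])

    def test_top_n_per_direction(self, small_rarefied):
        rare, meta = small_rarefied
        out = sex_enrichment_table(rare, meta, top_n=3)
        assert (out.groupby("direction").size() <= 3).all()


def test_indicators_frame_attaches_taxonomy():
    table = OtuTable(
        np.array([[5, 0], [5, 0], [0, 5], [0, 5]]),
        ("S1", "S2", "S3", "S4"),
        ("O0", "O1"),
        ("k__B; p__X", "k__B; p__Y"),
    )
    recs = indval(table, ["a", "a", "b", "b"], n_perms=9, seed=0)
    df = indicators_to_frame(recs, table)
    assert "taxonomy" in df.columns
    assert set(df["taxonomy"]) == {"k__B; p__X", "k__B; p__Y"}
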