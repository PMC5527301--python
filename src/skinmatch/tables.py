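"""Data model and I/O for OTU count tables and sample metadata.

The canonical on-disk dialect is the classic tab-separated OTU table
(``#OTU ID`` sentinel in the first header cell, one row per OTU, optional
trailing ``taxonomy`` column) and the classic mapping file
(``#SampleID`` first column).  Depth filtering and rarefaction
(subsampling without replacement) live here because they operate purely
on the count matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleFrame",
    "TableError",
    "BODY_LOCATIONS",
    "BILATERAL_LOCATIONS",
    "SINGLE_LOCATIONS",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "filter_low_depth",
    "rarefy",
    "relative_abundance",
    "collapse_taxonomy",
]


class TableError(ValueError):
    """Raised for malformed tables or metadata."""


#: body location -> (bilateral?, default moisture class)
BODY_LOCATIONS: dict[str, tuple[bool, str]] = {
    "eyelid": (True, "oily"),
    "outer nose": (True, "oily"),
    "inner nostril": (True, "moist"),
    "armpit": (True, "moist"),
    "torso": (False, "oily"),
    "back": (False, "oily"),
    "navel": (False, "moist"),
    "inner thigh": (True, "dry"),
    "foot": (True, "moist"),
    "palm": (True, "dry"),
}

BILATERAL_LOCATIONS = tuple(k for k, (b, _) in BODY_LOCATIONS.items() if b)
SINGLE_LOCATIONS = tuple(k for k, (b, _) in BODY_LOCATIONS.items() if not b)

SEXES = ("female", "male")
MOISTURES = ("dry", "moist", "oily")
SIDES = ("left", "right", "none")

_META_COLUMNS = {
    "Participant": "participant",
    "Couple": "couple",
    "Sex": "sex",
    "BodyLocation": "body_location",
    "Side": "side",
    "Moisture": "moisture",
}


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise TableError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class OtuTable:
    """A samples x OTUs non-negative integer count matrix.

    Parameters
    ----------
    counts
        Integer matrix, shape ``(n_samples, n_otus)``.
    sample_ids, otu_ids
        Unique ordered identifiers for rows and columns.
    taxonomy
        Optional semicolon-ranked lineage string per OTU.
    """

    counts: np.ndarray
    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    taxonomy: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.size == 0:
            raise TableError("counts must be a non-empty 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if np.issubdtype(counts.dtype, np.floating) and np.all(counts == np.floor(counts)):
                counts = counts.astype(np.int64)
            else:
                bad = np.argwhere(counts != np.floor(counts))
                loc = tuple(bad[0]) if len(bad) else (0, 0)
                raise TableError(f"non-integer count at row {loc[0]}, column {loc[1]}")
        if np.any(counts < 0):
            r, c = np.argwhere(counts < 0)[0]
            raise TableError(f"negative count at row {r} ({self.sample_ids[r]!r}), column {c}")
        object.__setattr__(self, "counts", counts.astype(np.int64))
        sample_ids = tuple(str(s) for s in self.sample_ids)
        otu_ids = tuple(str(o) for o in self.otu_ids)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "otu_ids", otu_ids)
        if counts.shape != (len(sample_ids), len(otu_ids)):
            raise TableError(
                f"counts shape {counts.shape} does not match "
                f"{len(sample_ids)} samples x {len(otu_ids)} OTUs"
            )
        _check_unique(sample_ids, "sample")
        _check_unique(otu_ids, "OTU")
        if self.taxonomy is not None:
            tax = tuple(str(t) for t in self.taxonomy)
            if len(tax) != len(otu_ids):
                raise TableError("taxonomy length does not match number of OTUs")
            object.__setattr__(self, "taxonomy", tax)

    # -- basic views ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_sums(self) -> np.ndarray:
        """Per-sample read depth (row sums)."""
        return self.counts.sum(axis=1)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_index(sample_id)]

    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        """Subset (and reorder) to the given sample ids."""
        ids = list(sample_ids)
        idx = [self.sample_index(s) for s in ids]
        return replace(self, counts=self.counts[idx], sample_ids=tuple(ids))

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=0) > 0
        tax = tuple(np.array(self.taxonomy)[keep]) if self.taxonomy is not None else None
        return OtuTable(
            self.counts[:, keep],
            self.sample_ids,
            tuple(np.array(self.otu_ids)[keep]),
            tax,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.sample_ids), columns=list(self.otu_ids))


class SampleFrame:
    """Per-sample metadata: participant, couple, sex, body site, lifestyle.

    Wraps a :class:`pandas.DataFrame` indexed by sample id with columns
    ``participant, couple, sex, body_location, side, moisture`` plus free
    lifestyle columns (kept verbatim as strings).
    """

    CORE = ("participant", "couple", "sex", "body_location", "side", "moisture")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.CORE if c not in df.columns]
        if missing:
            raise TableError(f"metadata missing required columns: {missing}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise TableError(f"duplicate sample id: {dup!r}")
        df = df.copy()
        df.index = df.index.astype(str)
        for c in df.columns:
            df[c] = df[c].astype(str)
        self._validate(df)
        self.df = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        bad_sex = set(df["sex"]) - set(SEXES)
        if bad_sex:
            raise TableError(f"unknown sex value(s): {sorted(bad_sex)}")
        bad_loc = set(df["body_location"]) - set(BODY_LOCATIONS)
        if bad_loc:
            raise TableError(f"unknown body_location value(s): {sorted(bad_loc)}")
        for loc, sub in df.groupby("body_location"):
            bilateral, _ = BODY_LOCATIONS[str(loc)]
            allowed = {"left", "right"} if bilateral else {"none"}
            bad = set(sub["side"]) - allowed
            if bad:
                raise TableError(f"invalid side {sorted(bad)} for location {loc!r}")
        # one couple per participant
        pc = df.groupby("participant")["couple"].nunique()
        if (pc > 1).any():
            p = pc.index[pc > 1][0]
            raise TableError(f"participant {p!r} assigned to multiple couples")
        # each couple: exactly 2 participants, one of each sex
        by_couple = df.drop_duplicates("participant").groupby("couple")
        for couple, sub in by_couple:
            if len(sub) != 2:
                raise TableError(f"couple {couple!r} has {len(sub)} participants, expected 2")
            if sorted(sub["sex"]) != ["female", "male"]:
                raise TableError(f"couple {couple!r} must have one female and one male")

    # -- views ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.df.index)

    @property
    def participants(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.df["participant"]))

    @property
    def couples(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.df["couple"]))

    @property
    def lifestyle_categories(self) -> tuple[str, ...]:
        return tuple(c for c in self.df.columns if c not in self.CORE)

    def column(self, name: str, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        sub = self.df if sample_ids is None else self.df.loc[list(sample_ids)]
        return sub[name].to_numpy()

    def subset(self, sample_ids: Iterable[str]) -> "SampleFrame":
        ids = [s for s in sample_ids]
        missing = [s for s in ids if s not in self.df.index]
        if missing:
            raise TableError(f"sample ids not in metadata: {missing[:5]}")
        # couple invariant may break on arbitrary subsets; bypass re-validation
        out = SampleFrame.__new__(SampleFrame)
        out.df = self.df.loc[ids].copy()
        return out

    def sex_of(self, participant: str) -> str:
        sub = self.df[self.df["participant"] == participant]
        if sub.empty:
            raise KeyError(f"unknown participant {participant!r}")
        return str(sub["sex"].iloc[0])

    def couple_of(self, participant: str) -> str:
        sub = self.df[self.df["participant"] == participant]
        if sub.empty:
            raise KeyError(f"unknown participant {participant!r}")
        return str(sub["couple"].iloc[0])

    def partner_of(self, participant: str) -> str:
        couple = self.couple_of(participant)
        members = self.df[self.df["couple"] == couple]["participant"].unique()
        others = [m for m in members if m != participant]
        if len(others) != 1:
            raise TableError(f"couple {couple!r} does not have exactly one partner")
        return str(others[0])

    def couple_members(self) -> dict[str, tuple[str, str]]:
        """couple id -> (female participant, male participant)."""
        out: dict[str, tuple[str, str]] = {}
        for couple, sub in self.df.drop_duplicates("participant").groupby("couple"):
            f = sub[sub["sex"] == "female"]["participant"].iloc[0]
            m = sub[sub["sex"] == "male"]["participant"].iloc[0]
            out[str(couple)] = (str(f), str(m))
        return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path: str | Path, orientation: str = "auto") -> OtuTable:
    """Read a tab-separated OTU table.

    ``orientation`` is one of ``otus_as_rows`` (classic dialect, header
    sentinel ``#OTU ID``), ``samples_as_rows``, or ``auto`` (detect from
    the sentinel).  A trailing ``taxonomy`` column is captured when
    present in the OTU-as-rows dialect.
    """
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise TableError(f"empty table file: {path}")
    header = lines[0].split("\t")
    if orientation == "auto":
        orientation = "otus_as_rows" if header[0] == "#OTU ID" else "samples_as_rows"
    if orientation not in ("otus_as_rows", "samples_as_rows"):
        raise TableError(f"unknown orientation {orientation!r}")
    if len(lines) < 2:
        raise TableError(f"table has no data rows: {path}")

    col_ids = header[1:]
    has_tax = orientation == "otus_as_rows" and col_ids and col_ids[-1].lower() == "taxonomy"
    if has_tax:
        col_ids = col_ids[:-1]
    row_ids: list[str] = []
    rows: list[list[int]] = []
    taxonomy: list[str] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        row_ids.append(cells[0])
        vals = cells[1 : 1 + len(col_ids)]
        if len(vals) != len(col_ids):
            raise TableError(f"{path}:{lineno}: expected {len(col_ids)} counts, got {len(vals)}")
        row: list[int] = []
        for j, v in enumerate(vals):
            try:
                x = float(v)
            except ValueError:
                raise TableError(f"{path}:{lineno}: non-numeric count {v!r} in column {col_ids[j]!r}") from None
            if x != int(x):
                raise TableError(f"{path}:{lineno}: non-integer count {v!r} in column {col_ids[j]!r}")
            row.append(int(x))
        rows.append(row)
        if has_tax:
            taxonomy.append(cells[1 + len(col_ids)] if len(cells) > 1 + len(col_ids) else "")

    mat = np.array(rows, dtype=np.int64)
    if orientation == "otus_as_rows":
        return OtuTable(mat.T, tuple(col_ids), tuple(row_ids), tuple(taxonomy) if has_tax else None)
    return OtuTable(mat, tuple(row_ids), tuple(col_ids), None)


def write_otu_table(table: OtuTable, path: str | Path) -> None:
    """Write the canonical OTU-as-rows dialect (``#OTU ID`` sentinel)."""
    with open(path, "w") as fh:
        cols = "\t".join(table.sample_ids)
        fh.write(f"#OTU ID\t{cols}")
        if table.taxonomy is not None:
            fh.write("\ttaxonomy")
        fh.write("\n")
        for j, otu in enumerate(table.otu_ids):
            vals = "\t".join(str(int(v)) for v in table.counts[:, j])
            fh.write(f"{otu}\t{vals}")
            if table.taxonomy is not None:
                fh.write(f"\t{table.taxonomy[j]}")
            fh.write("\n")


def read_metadata(path: str | Path) -> SampleFrame:
    """Read a classic mapping file (``#SampleID`` first column).

    Required columns: Participant, Couple, Sex, BodyLocation, Side,
    Moisture.  Any extra column becomes a lifestyle category, preserved
    verbatim as strings.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    first = df.columns[0]
    if first not in ("#SampleID", "SampleID", "sample_id"):
        raise TableError(f"first metadata column must be '#SampleID', got {first!r}")
    df = df.set_index(first)
    df.index.name = "sample_id"
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise TableError(f"metadata file missing columns: {missing}")
    df = df.rename(columns=_META_COLUMNS)
    order = list(SampleFrame.CORE) + [c for c in df.columns if c not in SampleFrame.CORE]
    return SampleFrame(df[order])


def write_metadata(meta: SampleFrame, path: str | Path) -> None:
    inv = {v: k for k, v in _META_COLUMNS.items()}
    df = meta.df.rename(columns=inv)
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# depth filtering / rarefaction / normalization
# ---------------------------------------------------------------------------

def filter_low_depth(table: OtuTable, min_depth: int) -> tuple[OtuTable, list[str]]:
    """Drop samples with fewer than ``min_depth`` reads.

    Returns the filtered table and the removed sample ids in input order.
    """
    if min_depth < 1:
        raise TableError("min_depth must be >= 1")
    sums = table.sample_sums()
    keep = sums >= min_depth
    removed = [s for s, k in zip(table.sample_ids, keep) if not k]
    if not keep.any():
        raise TableError(f"all {table.n_samples} samples fall below depth {min_depth}")
    kept = [s for s, k in zip(table.sample_ids, keep) if k]
    return table.select_samples(kept), removed


def subsample_counts(row: np.ndarray, depth: int, rng: np.random.Generator) -> np.ndarray:
    """Subsample one count vector WITHOUT replacement to ``depth`` reads."""
    total = int(row.sum())
    if depth > total:
        raise TableError(f"depth {depth} exceeds row total {total}")
    if depth == total:
        return row.copy()
    return rng.multivariate_hypergeometric(row, depth).astype(np.int64)


def rarefy(
    table: OtuTable,
    depth: int,
    seed: int | np.random.Generator = 0,
    drop_empty_otus: bool = False,
) -> OtuTable:
    """Rarefy every sample to exactly ``depth`` reads.

    Subsampling is uniform without replacement (multivariate
    hypergeometric), deterministic for a fixed seed.  All-zero OTU
    columns are retained unless ``drop_empty_otus`` is set, so OTU
    indices stay aligned across replicate rarefactions.
    """
    if depth < 1:
        raise TableError("rarefaction depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sums = table.sample_sums()
    low = np.flatnonzero(sums < depth)
    if low.size:
        s = table.sample_ids[low[0]]
        raise TableError(
            f"sample {s!r} has only {sums[low[0]]} reads, below rarefaction depth {depth}; "
            "filter low-depth samples first"
        )
    new = np.empty_like(table.counts)
    for i in range(table.n_samples):
        new[i] = subsample_counts(table.counts[i], depth, rng)
    out = replace(table, counts=new)
    return out.drop_empty_otus() if drop_empty_otus else out


def relative_abundance(table: OtuTable) -> np.ndarray:
    """Row-normalized proportion matrix (rows sum to 1)."""
    sums = table.sample_sums()
    if np.any(sums == 0):
        s = table.sample_ids[int(np.flatnonzero(sums == 0)[0])]
        raise TableError(f"sample {s!r} has zero total count")
    return table.counts / sums[:, None]


def collapse_taxonomy(table: OtuTable, rank: int) -> OtuTable:
    """Sum counts over OTUs sharing the first ``rank`` lineage levels.

    ``rank`` runs 1 (kingdom/domain) .. 7 (species).  OTUs without
    taxonomy fall into an ``unclassified`` bucket.  Total counts are
    conserved per sample.
    """
    if not 1 <= rank <= 7:
        raise TableError(f"rank must be in 1..7, got {rank}")
    if table.taxonomy is None:
        lineages = ["unclassified"] * table.n_otus
    else:
        lineages = []
        for t in table.taxonomy:
            levels = [lv.strip() for lv in t.split(";") if lv.strip()]
            lineages.append("; ".join(levels[:rank]) if levels else "unclassified")
    groups: dict[str, list[int]] = {}
    for j, g in enumerate(lineages):
        groups.setdefault(g, []).append(j)
    ids = tuple(groups)
    counts = np.stack([table.counts[:, idx].sum(axis=1) for idx in groups.values()], axis=1)
    return OtuTable(counts, table.sample_ids, ids, taxonomy=ids)


def abundant_groups(table: OtuTable, threshold: float = 0.01) -> pd.DataFrame:
    """Mean relative abundance per column, pooling sub-threshold columns as 'other'.

    Intended for taxonomy-collapsed tables (e.g. family-level summaries
    keeping only groups above 1%).
    """
    props = relative_abundance(table)
    mean = props.mean(axis=0)
    keep = mean >= threshold
    data = {table.otu_ids[j]: mean[j] for j in np.flatnonzero(keep)}
    other = float(mean[~keep].sum())
    if other > 0:
        data["other"] = other
    out = pd.DataFrame({"group": list(data), "mean_relative_abundance": list(data.values())})
    return out.sort_values("mean_relative_abundance", ascending=False, ignore_index=True)
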