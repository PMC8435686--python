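"""Binary compound-occurrence tables and occurrence-based diversity.

The central object is the :class:`FeatureTable`: a binary samples x
compounds presence matrix with nested sample metadata (species > plant >
organ).  From it this module computes Sørensen (binary Bray-Curtis)
dissimilarity, the organ-occurrence partition (compounds shared by all
organs vs unique to fruit or leaf), and alpha/gamma richness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

ORGANS: tuple[str, ...] = ("leaf", "seed", "unripe_pulp", "ripe_pulp")
#: fruit = any of the three reproductive sample types
FRUIT_ORGANS: tuple[str, ...] = ("seed", "unripe_pulp", "ripe_pulp")

METADATA_COLUMNS = ("species", "plant", "organ")

__all__ = [
    "ORGANS", "FRUIT_ORGANS", "FeatureTable", "DistanceMatrix",
    "OrganPartition", "read_feature_table", "write_feature_table",
    "sorensen_matrix", "organ_partition", "alpha_richness", "gamma_richness",
    "write_distance_matrix", "read_distance_matrix",
]


@dataclass
class FeatureTable:
    """Binary samples x compounds occurrence matrix with sample metadata.

    ``presence``: DataFrame of 0/1 indexed by sample id, columns = compound
    ids.  ``metadata``: DataFrame indexed identically with columns
    ``species``, ``plant``, ``organ``.  Each plant id maps to exactly one
    species; organ labels come from the fixed vocabulary.
    """

    presence: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.presence.index.equals(self.metadata.index):
            raise ValueError("presence and metadata sample ids differ")
        if self.presence.index.has_duplicates:
            dup = self.presence.index[self.presence.index.duplicated()][0]
            raise ValueError(f"duplicated sample id {dup!r}")
        if self.presence.columns.has_duplicates:
            dup = self.presence.columns[self.presence.columns.duplicated()][0]
            raise ValueError(f"duplicated compound id {dup!r}")
        missing = set(METADATA_COLUMNS) - set(self.metadata.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        bad_organ = set(self.metadata["organ"]) - set(ORGANS)
        if bad_organ:
            raise ValueError(
                f"unknown organ label(s) {sorted(bad_organ)}; expected one of {ORGANS}")
        values = self.presence.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-binary cell at sample {self.presence.index[i]!r}, "
                f"compound {self.presence.columns[j]!r}: {values[i, j]!r}")
        self.presence = self.presence.astype(np.int8)
        span = self.metadata.groupby("plant")["species"].nunique()
        if (span > 1).any():
            plant = span[span > 1].index[0]
            raise ValueError(f"plant {plant!r} spans more than one species")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.presence.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.presence.columns)

    @property
    def n_samples(self) -> int:
        return len(self.presence)

    @property
    def n_compounds(self) -> int:
        return self.presence.shape[1]

    def subset(self, mask: pd.Series | np.ndarray) -> "FeatureTable":
        return FeatureTable(presence=self.presence.loc[mask],
                            metadata=self.metadata.loc[mask])

    def restrict_compounds(self, compound_ids: list[str]) -> "FeatureTable":
        keep = [c for c in self.compound_ids if c in set(compound_ids)]
        return FeatureTable(presence=self.presence[keep], metadata=self.metadata)

    def detected_compounds(self) -> list[str]:
        """Compounds present in at least one sample."""
        present = self.presence.sum(axis=0) > 0
        return list(self.presence.columns[present])


@dataclass
class DistanceMatrix:
    """Symmetric sample x sample dissimilarity in [0, 1], zero diagonal."""

    sample_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match sample_ids")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal must be 0")
        if self.d.min() < -1e-12 or self.d.max() > 1 + 1e-9:
            raise ValueError("distances must lie in [0, 1]")
        np.clip(self.d, 0.0, 1.0, out=self.d)

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in ids]
        return DistanceMatrix(sample_ids=list(ids), d=self.d[np.ix_(idx, idx)])


#: organ-occurrence categories, a disjoint cover of detected compounds
PARTITION_CATEGORIES = ("all_organs", "fruit_only", "leaf_only", "other_mixtures")


@dataclass
class OrganPartition:
    """Counts and memberships of detected compounds by organ occurrence."""

    counts: dict[str, int]
    membership: dict[str, set[str]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "counts": self.counts,
            "membership": {k: sorted(v) for k, v in self.membership.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read the TSV dialect: sample_id index column, then metadata columns
    species/plant/organ, then one 0/1 column per compound."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"feature table missing metadata columns: {sorted(missing)}")
    meta = df[list(METADATA_COLUMNS)].astype(str)
    presence = df.drop(columns=list(METADATA_COLUMNS))
    return FeatureTable(presence=presence, metadata=meta)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    out = pd.concat([table.metadata[list(METADATA_COLUMNS)], table.presence], axis=1)
    out.to_csv(path, sep="\t", index_label="sample_id")


def sorensen_matrix(table: FeatureTable) -> DistanceMatrix:
    """Sørensen dissimilarity 1 - 2|A∩B| / (|A| + |B|) between all sample
    pairs (the binary form of Bray-Curtis).  Every sample must contain at
    least one compound."""
    x = table.presence.to_numpy(dtype=float)
    empty = x.sum(axis=1) == 0
    if empty.any():
        sid = table.sample_ids[int(np.flatnonzero(empty)[0])]
        raise ValueError(f"sample {sid!r} has no present compounds")
    # Bray-Curtis on a binary matrix is exactly Sørensen
    d = squareform(pdist(x, metric="braycurtis"))
    return DistanceMatrix(sample_ids=table.sample_ids, d=d)


def organ_partition(table: FeatureTable) -> OrganPartition:
    """Partition detected compounds by organ occurrence.

    ``fruit_only``: present in >= 1 fruit-organ sample (seed, unripe or ripe
    pulp) and in no leaf sample; ``leaf_only`` symmetric; ``all_organs``:
    present in >= 1 sample of every organ type; remainder
    ``other_mixtures``.  Compounds absent everywhere are excluded.
    """
    organs_present = set(table.metadata["organ"])
    missing = set(ORGANS) - organs_present
    if missing:
        raise ValueError(f"no samples for organ(s): {sorted(missing)}")
    pres = table.presence.to_numpy(bool)
    organ_of = table.metadata["organ"].to_numpy()
    in_organ = {o: pres[organ_of == o].any(axis=0) for o in ORGANS}
    detected = pres.any(axis=0)
    in_fruit = np.logical_or.reduce([in_organ[o] for o in FRUIT_ORGANS])
    in_leaf = in_organ["leaf"]
    in_all = np.logical_and.reduce([in_organ[o] for o in ORGANS])

    cats = np.full(table.n_compounds, "other_mixtures", dtype=object)
    cats[in_fruit & ~in_leaf] = "fruit_only"
    cats[in_leaf & ~in_fruit] = "leaf_only"
    cats[in_all] = "all_organs"
    cats[~detected] = ""

    cols = np.asarray(table.compound_ids, dtype=object)
    membership = {c: set(cols[(cats == c) & detected]) for c in PARTITION_CATEGORIES}
    counts = {c: len(membership[c]) for c in PARTITION_CATEGORIES}
    return OrganPartition(counts=counts, membership=membership)


def alpha_richness(table: FeatureTable) -> pd.Series:
    """Per-sample compound count (row sums of presence)."""
    return table.presence.sum(axis=1).rename("alpha_richness")


def gamma_richness(table: FeatureTable, group_by: str) -> pd.Series:
    """Per-group count of compounds present in >= 1 sample of the group."""
    if group_by not in table.metadata.columns:
        raise ValueError(f"unknown metadata key {group_by!r}")
    groups = table.metadata[group_by]
    out = {}
    for g, idx in table.presence.groupby(groups).groups.items():
        out[g] = int((table.presence.loc[idx].sum(axis=0) > 0).sum())
    return pd.Series(out, name="gamma_richness").sort_index()


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Square TSV with header row and leading sample id column."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(dm.sample_ids) + "\n")
        for i, sid in enumerate(dm.sample_ids):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in dm.d[i]) + "\n")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError("distance matrix rows and columns differ")
    return DistanceMatrix(sample_ids=[str(s) for s in df.columns],
                          d=df.to_numpy(float))
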