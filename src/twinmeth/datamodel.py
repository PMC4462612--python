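"""Core domain types: beta matrices, twin designs, probe annotations, gene sets.

The types are thin validating wrappers around :class:`pandas.DataFrame`
objects, so downstream numerics can operate on plain arrays while
construction enforces the documented invariants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataValidationError

#: Diagnostic groups, in the fixed column order used everywhere.
GROUPS: tuple[str, ...] = ("concordant", "discordant", "healthy")

#: Closed vocabulary of gene-region feature categories.
FEATURE_CATEGORIES: tuple[str, ...] = (
    "TSS1500",
    "TSS200",
    "5'UTR",
    "1st exon",
    "Body",
    "3'UTR",
    "intergenic",
)

# Normalization map for feature-category spellings seen in annotation files
# (case differences, unicode primes, "1stExon" style tokens).
_FEATURE_ALIASES: dict[str, str] = {
    "tss1500": "TSS1500",
    "tss200": "TSS200",
    "5'utr": "5'UTR",
    "5utr": "5'UTR",
    "1st exon": "1st exon",
    "1stexon": "1st exon",
    "first exon": "1st exon",
    "firstexon": "1st exon",
    "body": "Body",
    "3'utr": "3'UTR",
    "3utr": "3'UTR",
    "intergenic": "intergenic",
}


def normalize_feature(token: str) -> str:
    """Map a raw feature-category token onto the closed vocabulary.

    Raises
    ------
    DataValidationError
        If the token is not a recognized category spelling.
    """
    key = token.strip().replace("′", "'").lower()
    try:
        return _FEATURE_ALIASES[key]
    except KeyError:
        raise DataValidationError(
            f"unknown gene-region feature category: {token!r}"
        ) from None


class BetaMatrix:
    """Probe x sample matrix of methylation fractions in [0, 1].

    Missing values are represented as NaN. Probe and sample identifiers
    must be unique; every non-missing value must lie in [0, 1].
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate probe_id(s): {dups[:5]}")
        if data.columns.duplicated().any():
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise DataValidationError(f"duplicate sample_id(s): {dups[:5]}")
        values = data.to_numpy(dtype=float, copy=False)
        bad = (values < 0.0) | (values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DataValidationError(
                f"beta value out of [0,1] at probe {data.index[i]!r}, "
                f"sample {data.columns[j]!r}: {values[i, j]}"
            )
        self._data = data.astype(float)
        self._data.index.name = "probe_id"

    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def probe_ids(self) -> list[str]:
        return self._data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._data.columns.tolist()

    @property
    def n_probes(self) -> int:
        return self._data.shape[0]

    @property
    def n_samples(self) -> int:
        return self._data.shape[1]

    def values_for(self, samples: Sequence[str]) -> np.ndarray:
        """Array view of the matrix restricted to ``samples`` (in order)."""
        missing = [s for s in samples if s not in self._data.columns]
        if missing:
            raise DataValidationError(f"unknown sample_id(s): {missing}")
        return self._data[list(samples)].to_numpy()

    def subset(
        self,
        probes: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "BetaMatrix":
        data = self._data
        if probes is not None:
            missing = [p for p in probes if p not in data.index]
            if missing:
                raise DataValidationError(f"unknown probe_id(s): {missing}")
            data = data.loc[list(probes)]
        if samples is not None:
            missing = [s for s in samples if s not in data.columns]
            if missing:
                raise DataValidationError(f"unknown sample_id(s): {missing}")
            data = data[list(samples)]
        return BetaMatrix(data.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BetaMatrix):
            return NotImplemented
        return self._data.equals(other._data)

    def __repr__(self) -> str:
        return f"BetaMatrix({self.n_probes} probes x {self.n_samples} samples)"


class TwinDesign:
    """Assignment of samples to twin pairs, diagnostic groups and roles.

    Invariants enforced at construction:

    * every pair_id occurs exactly twice;
    * both members of a pair share the same group;
    * discordant pairs have exactly one affected member, concordant pairs
      two, healthy pairs none.
    """

    REQUIRED_COLUMNS = ("sample_id", "pair_id", "group", "affected")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise DataValidationError(f"sample sheet missing column(s): {missing}")
        table = table[list(self.REQUIRED_COLUMNS)].copy()
        table["affected"] = table["affected"].astype(bool)
        if table["sample_id"].duplicated().any():
            dup = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
            raise DataValidationError(f"duplicate sample_id(s): {dup}")
        unknown = set(table["group"]) - set(GROUPS)
        if unknown:
            raise DataValidationError(
                f"unknown group label(s): {sorted(unknown)}; expected one of {GROUPS}"
            )
        for pair_id, sub in table.groupby("pair_id", sort=False):
            if len(sub) != 2:
                raise DataValidationError(
                    f"pair {pair_id!r} has {len(sub)} member(s); expected 2"
                )
            groups = set(sub["group"])
            if len(groups) != 1:
                raise DataValidationError(
                    f"pair {pair_id!r} members have different groups: {sorted(groups)}"
                )
            group = groups.pop()
            n_affected = int(sub["affected"].sum())
            expected = {"concordant": 2, "discordant": 1, "healthy": 0}[group]
            if n_affected != expected:
                raise DataValidationError(
                    f"{group} pair {pair_id!r} has {n_affected} affected member(s); "
                    f"expected {expected}"
                )
        self._table = table.reset_index(drop=True)

    @property
    def table(self) -> pd.DataFrame:
        return self._table.copy()

    @property
    def sample_ids(self) -> list[str]:
        return self._table["sample_id"].tolist()

    @property
    def pair_ids(self) -> list[str]:
        return self._table["pair_id"].drop_duplicates().tolist()

    def pairs(self) -> pd.DataFrame:
        """One row per pair with columns pair_id, group, first, second.

        For discordant pairs ``first`` is the affected co-twin; for
        concordant and healthy pairs the orientation is the (arbitrary but
        fixed) sheet order. Analyses must only rely on orientation for
        discordant pairs.
        """
        rows = []
        for pair_id, sub in self._table.groupby("pair_id", sort=False):
            group = sub["group"].iloc[0]
            if group == "discordant":
                first = sub.loc[sub["affected"], "sample_id"].iloc[0]
                second = sub.loc[~sub["affected"], "sample_id"].iloc[0]
            else:
                first, second = sub["sample_id"].tolist()
            rows.append((pair_id, group, first, second))
        return pd.DataFrame(rows, columns=["pair_id", "group", "first", "second"])

    def pairs_in_group(self, group: str) -> pd.DataFrame:
        if group not in GROUPS:
            raise DataValidationError(f"unknown group {group!r}")
        pairs = self.pairs()
        return pairs[pairs["group"] == group].reset_index(drop=True)

    def group_pair_counts(self) -> dict[str, int]:
        pairs = self.pairs()
        return {g: int((pairs["group"] == g).sum()) for g in GROUPS}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TwinDesign):
            return NotImplemented
        return self._table.equals(other._table)

    def __repr__(self) -> str:
        counts = self.group_pair_counts()
        return f"TwinDesign({counts})"


@dataclass(frozen=True, eq=False)
class ProbeAnnotation:
    """Per-probe genomic annotation: location, genes and feature categories."""

    table: pd.DataFrame  # columns: probe_id, chromosome, position, genes, features

    def __post_init__(self):
        required = {"probe_id", "chromosome", "position", "genes", "features"}
        missing = required - set(self.table.columns)
        if missing:
            raise DataValidationError(f"annotation missing column(s): {sorted(missing)}")
        if self.table["probe_id"].duplicated().any():
            dup = self.table.loc[
                self.table["probe_id"].duplicated(), "probe_id"
            ].tolist()
            raise DataValidationError(f"duplicate annotated probe_id(s): {dup[:5]}")
        has_chrom = self.table["chromosome"].notna() & (
            self.table["chromosome"] != ""
        )
        pos = self.table.loc[has_chrom, "position"]
        if (pos.fillna(0) < 1).any():
            raise DataValidationError("annotation position must be >= 1 (1-based)")
        for feats in self.table["features"]:
            for f in feats:
                if f not in FEATURE_CATEGORIES:
                    raise DataValidationError(
                        f"feature category {f!r} outside closed vocabulary"
                    )
        object.__setattr__(
            self, "_by_probe", self.table.set_index("probe_id", drop=False)
        )

    def genes_for(self, probe_id: str) -> tuple[str, ...]:
        try:
            return tuple(self._by_probe.at[probe_id, "genes"])
        except KeyError:
            return ()

    def features_for(self, probe_id: str) -> tuple[str, ...]:
        try:
            return tuple(self._by_probe.at[probe_id, "features"])
        except KeyError:
            return ()

    def has_probe(self, probe_id: str) -> bool:
        return probe_id in self._by_probe.index

    def all_genes(self) -> list[str]:
        """Sorted union of gene names over all annotated probes."""
        genes: set[str] = set()
        for g in self.table["genes"]:
            genes.update(g)
        return sorted(genes)


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit background universe."""

    sets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    universe: tuple[str, ...] | None = None

    def __post_init__(self):
        for name, members in self.sets.items():
            if len(members) == 0:
                raise DataValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)
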