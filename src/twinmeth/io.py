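"""Readers and writers for the plain-text interchange formats.

Formats
-------
* beta matrix: TSV, header ``probe_id\\t<sample>...``, configurable missing
  token (default ``NA``);
* sample sheet: CSV with columns sample_id, pair_id, group, affected;
* probe annotation: CSV with columns probe_id, chr, pos, gene, feature
  (semicolon-separated multi-values);
* gene sets: standard GMT (name, description, members, tab-separated).

Writers emit full ``repr`` float precision so write-then-read round-trips
are value-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    BetaMatrix,
    GeneSetCollection,
    ProbeAnnotation,
    TwinDesign,
    normalize_feature,
)
from .errors import DataValidationError, ParseError

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKEN = "NA"

_TRUE_TOKENS = {"true", "1", "yes", "t", "y"}
_FALSE_TOKENS = {"false", "0", "no", "f", "n"}


def read_beta_matrix(
    path: str | Path, missing_token: str = DEFAULT_MISSING_TOKEN
) -> BetaMatrix:
    """Read a probe x sample beta-value TSV.

    Cells equal to ``missing_token`` become NaN. Non-numeric cells raise a
    :class:`ParseError` naming the probe and sample; out-of-range values and
    duplicate probe ids raise :class:`DataValidationError`.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=[missing_token],
            keep_default_na=False,
            dtype=None,
        )
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty beta matrix file") from None
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    for col in raw.columns:
        if raw[col].dtype == object:
            converted = pd.to_numeric(raw[col], errors="coerce")
            bad = converted.isna() & raw[col].notna()
            if bad.any():
                probe = raw.index[bad.to_numpy().nonzero()[0][0]]
                cell = raw.loc[probe, col]
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at probe {probe!r}, "
                    f"sample {col!r}"
                )
            raw[col] = converted
    return BetaMatrix(raw)


def write_beta_matrix(
    bm: BetaMatrix, path: str | Path, missing_token: str = DEFAULT_MISSING_TOKEN
) -> None:
    bm.data.to_csv(Path(path), sep="\t", na_rep=missing_token)


def read_twin_design(path: str | Path) -> TwinDesign:
    """Read a sample sheet CSV into a validated :class:`TwinDesign`."""
    path = Path(path)
    try:
        table = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty sample sheet") from None
    missing = [c for c in TwinDesign.REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: sample sheet missing column(s) {missing}")

    def parse_bool(token: str, row: int) -> bool:
        key = token.strip().lower()
        if key in _TRUE_TOKENS:
            return True
        if key in _FALSE_TOKENS:
            return False
        raise ParseError(
            f"{path}: row {row}: cannot parse affected flag {token!r}"
        )

    table["affected"] = [
        parse_bool(tok, i + 2) for i, tok in enumerate(table["affected"])
    ]
    table["group"] = table["group"].str.strip().str.lower()
    return TwinDesign(table)


def write_twin_design(design: TwinDesign, path: str | Path) -> None:
    table = design.table
    table["affected"] = table["affected"].map({True: "true", False: "false"})
    table.to_csv(Path(path), index=False)


def _split_multi(cell: str) -> list[str]:
    if cell is None or cell == "" or (isinstance(cell, float) and np.isnan(cell)):
        return []
    return [tok.strip() for tok in str(cell).split(";") if tok.strip()]


def read_probe_annotation(path: str | Path) -> ProbeAnnotation:
    """Read probe annotation CSV (probe_id, chr, pos, gene, feature).

    Multi-valued gene/feature cells are semicolon-separated; duplicates are
    collapsed and feature spellings normalized onto the closed vocabulary.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty annotation file") from None
    required = ["probe_id", "chr", "pos", "gene", "feature"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: annotation missing column(s) {missing}")
    rows = []
    for i, rec in raw.iterrows():
        chrom = rec["chr"].strip()
        pos_token = rec["pos"].strip()
        if pos_token:
            try:
                position = int(pos_token)
            except ValueError:
                raise ParseError(
                    f"{path}: row {i + 2}: non-integer position {pos_token!r}"
                ) from None
        else:
            position = np.nan
        genes = tuple(dict.fromkeys(_split_multi(rec["gene"])))
        features = tuple(
            dict.fromkeys(normalize_feature(tok) for tok in _split_multi(rec["feature"]))
        )
        rows.append((rec["probe_id"].strip(), chrom, position, genes, features))
    table = pd.DataFrame(
        rows, columns=["probe_id", "chromosome", "position", "genes", "features"]
    )
    return ProbeAnnotation(table)


def write_probe_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "probe_id": ann.table["probe_id"],
            "chr": ann.table["chromosome"].fillna(""),
            "pos": [
                "" if pd.isna(p) else str(int(p)) for p in ann.table["position"]
            ],
            "gene": [";".join(g) for g in ann.table["genes"]],
            "feature": [";".join(f) for f in ann.table["features"]],
        }
    )
    out.to_csv(Path(path), index=False)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file. Duplicate members within a set are collapsed."""
    path = Path(path)
    sets: dict[str, tuple[str, ...]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT line has {len(fields)} field(s); "
                    "expected name, description and at least one member"
                )
            name = fields[0]
            if name in sets:
                raise DataValidationError(
                    f"{path}: duplicate gene set name {name!r}"
                )
            members = tuple(dict.fromkeys(g for g in fields[2:] if g.strip()))
            sets[name] = members
    if not sets:
        logger.warning("%s: GMT file contains no gene sets", path)
    return GeneSetCollection(sets=sets)


def write_gene_sets(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(Path(path), "w") as fh:
        for name, members in gsc.sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-gene-per-line text file (blank lines skipped)."""
    with open(Path(path)) as fh:
        return [line.strip() for line in fh if line.strip()]
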