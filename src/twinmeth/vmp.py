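"""Variably methylated probe detection via group medians of |delta|.

Pipeline: per-pair absolute within-pair differences -> per-group medians
(an m x 3 matrix over concordant/discordant/healthy) -> inclusive threshold
on the median (default 0.1) -> exclusivity partition over the three groups.
The median is used as the per-group centrality measure because it is robust
to a single outlying pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .datamodel import GROUPS, BetaMatrix, ProbeAnnotation, TwinDesign
from .errors import AnalysisError, DataValidationError
from .preprocess import filter_complete_probes

logger = logging.getLogger(__name__)

#: Exclusivity labels, in reporting order.
EXCLUSIVITY_LABELS = (
    "concordant-only",
    "discordant-only",
    "healthy-only",
    "shared",
    "none",
)

#: Venn-region keys reported by classify_vmps, in reporting order.
VENN_REGIONS = (
    "concordant-only",
    "discordant-only",
    "healthy-only",
    "concordant&discordant",
    "concordant&healthy",
    "discordant&healthy",
    "concordant&discordant&healthy",
    "none",
)


@dataclass(frozen=True)
class VmpConfig:
    """Threshold on the group median |delta| above which a probe is variable.

    The comparison is inclusive (median >= threshold counts as variable).
    """

    threshold: float = 0.1

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise AnalysisError(
                f"threshold must be in (0,1), got {self.threshold}"
            )


class Exceedance(NamedTuple):
    fraction: float
    numerator: int
    denominator: int


def abs_diff_matrix(b: BetaMatrix, d: TwinDesign) -> pd.DataFrame:
    """Probe x pair matrix of absolute within-pair beta differences.

    Probes with a missing value in any design sample are dropped (logged).
    Twin orientation within a pair is irrelevant under the absolute value.
    """
    pairs = d.pairs()
    for _, rec in pairs.iterrows():
        for member in (rec["first"], rec["second"]):
            if member not in b.data.columns:
                raise DataValidationError(
                    f"pair {rec['pair_id']!r}: sample {member!r} absent from beta matrix"
                )
    complete = filter_complete_probes(b, d.sample_ids)
    if complete.n_probes == 0:
        raise AnalysisError("no probes with complete data across all pairs")
    first = complete.values_for(pairs["first"].tolist())
    second = complete.values_for(pairs["second"].tolist())
    values = np.abs(first - second)
    return pd.DataFrame(
        values, index=pd.Index(complete.probe_ids, name="probe_id"),
        columns=pairs["pair_id"].tolist(),
    )


def group_medians(a: pd.DataFrame, d: TwinDesign) -> pd.DataFrame:
    """Per-probe, per-group median of absolute within-pair differences.

    Returns the m x 3 matrix with columns in the fixed group order
    (concordant, discordant, healthy). Even group sizes take the mean of
    the two central order statistics.
    """
    pairs = d.pairs()
    out = {}
    for group in GROUPS:
        cols = pairs.loc[pairs["group"] == group, "pair_id"].tolist()
        if not cols:
            raise AnalysisError(f"group {group!r} has no pairs")
        missing = [c for c in cols if c not in a.columns]
        if missing:
            raise DataValidationError(
                f"pair column(s) absent from difference matrix: {missing}"
            )
        out[group] = np.median(a[cols].to_numpy(), axis=1)
    return pd.DataFrame(out, index=a.index.copy())


def classify_vmps(
    g: pd.DataFrame, cfg: VmpConfig = VmpConfig()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Threshold the median matrix and partition probes by group exclusivity.

    Returns ``(classification, venn_counts)`` where classification has
    columns probe_id, variable_in (semicolon-joined group names), and
    exclusivity (one of ``EXCLUSIVITY_LABELS``); venn_counts maps each of
    the seven Venn regions plus ``"none"`` to its probe count.
    """
    missing = [c for c in GROUPS if c not in g.columns]
    if missing:
        raise DataValidationError(f"median matrix missing group column(s): {missing}")
    ind = g[list(GROUPS)].to_numpy() >= cfg.threshold  # inclusive threshold
    n_var = ind.sum(axis=1)

    variable_in = [
        ";".join(gr for gr, flag in zip(GROUPS, row) if flag) for row in ind
    ]
    exclusivity = np.where(
        n_var == 0,
        "none",
        np.where(
            n_var >= 2,
            "shared",
            np.array([f"{gr}-only" for gr in GROUPS], dtype=object)[
                np.argmax(ind, axis=1)
            ],
        ),
    )
    classification = pd.DataFrame(
        {
            "probe_id": g.index.tolist(),
            "variable_in": variable_in,
            "exclusivity": exclusivity,
        }
    )

    region_of_row = {
        (True, False, False): "concordant-only",
        (False, True, False): "discordant-only",
        (False, False, True): "healthy-only",
        (True, True, False): "concordant&discordant",
        (True, False, True): "concordant&healthy",
        (False, True, True): "discordant&healthy",
        (True, True, True): "concordant&discordant&healthy",
        (False, False, False): "none",
    }
    venn_counts = {region: 0 for region in VENN_REGIONS}
    keys, counts = np.unique(ind, axis=0, return_counts=True)
    for key, count in zip(keys, counts):
        venn_counts[region_of_row[tuple(bool(k) for k in key)]] += int(count)
    return classification, venn_counts


def exceedance_fraction(a: pd.DataFrame, cfg: VmpConfig = VmpConfig()) -> Exceedance:
    """Fraction of |delta| cells at or above the threshold (inclusive)."""
    values = a.to_numpy()
    if values.size == 0:
        raise AnalysisError("empty difference matrix")
    numerator = int((values >= cfg.threshold).sum())
    return Exceedance(numerator / values.size, numerator, int(values.size))


def feature_category_summary(
    classification: pd.DataFrame, ann: ProbeAnnotation | None
) -> dict[str, dict[str, float]]:
    """Feature-category percentages for each exclusive VMP set.

    A probe contributes one count per *distinct* category; probes without
    annotation count as ``unannotated`` (logged). Percentages sum to 100
    within each group (up to rounding).
    """
    summary: dict[str, dict[str, float]] = {}
    for label in ("concordant-only", "discordant-only", "healthy-only"):
        probes = classification.loc[
            classification["exclusivity"] == label, "probe_id"
        ].tolist()
        counts: dict[str, int] = {}
        n_unannotated = 0
        for probe in probes:
            cats = ann.features_for(probe) if ann is not None else ()
            if not cats:
                cats = ("unannotated",)
                n_unannotated += 1
            for cat in dict.fromkeys(cats):
                counts[cat] = counts.get(cat, 0) + 1
        if n_unannotated:
            logger.info(
                "feature_category_summary[%s]: %d probe(s) without annotation",
                label,
                n_unannotated,
            )
        total = sum(counts.values())
        summary[label] = (
            {cat: 100.0 * n / total for cat, n in sorted(counts.items())}
            if total
            else {}
        )
    return summary
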