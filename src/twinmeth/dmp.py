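"""Differential-methylation ranking on disease-discordant twin pairs.

Each probe receives two linear rank scores — one from the paired-test
P-value (lower is better) and one from the absolute mean within-pair
difference (larger is better). The scores are added and probes are ranked
by the sum, so probes combining a small P with a large difference rise to
the top. No multiple-testing correction is applied: the output is a
ranking, not a set of significance calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import BetaMatrix, ProbeAnnotation, TwinDesign
from .errors import AnalysisError
from .preprocess import filter_complete_probes

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DmpConfig:
    """Knobs for the ranking: size of the extracted head and tie policy."""

    top_k: int = 10
    tie_method: str = "average"

    def __post_init__(self):
        if self.top_k < 1:
            raise AnalysisError(f"top_k must be >= 1, got {self.top_k}")
        if self.tie_method not in ("average", "min", "max"):
            raise AnalysisError(f"unsupported tie_method {self.tie_method!r}")


class PairedTResult(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool


def paired_t_test(
    affected: Sequence[float], unaffected: Sequence[float]
) -> PairedTResult:
    """Classical paired t-test on within-pair differences (two-sided).

    Degenerate inputs (zero variance of the differences) do not admit a t
    statistic; the P-value is reported as the limiting value (1 for all-zero
    differences, 0 for a constant nonzero difference) with the
    ``degenerate`` flag set.
    """
    aff = np.asarray(affected, dtype=float)
    unaff = np.asarray(unaffected, dtype=float)
    if aff.shape != unaff.shape:
        raise AnalysisError("affected and unaffected must have equal length")
    n = aff.size
    if n < 2:
        raise AnalysisError(f"paired t-test needs >= 2 pairs, got {n}")
    d = aff - unaff
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(float("nan"), 1.0, True)
        return PairedTResult(float("inf") if mean > 0 else float("-inf"), 0.0, True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return PairedTResult(float(t), float(p), False)


def rank_scores(
    values: Sequence[float], better: str, tie_method: str = "average"
) -> np.ndarray:
    """Linear rank scores: best value scores m, worst scores 1, ties averaged.

    ``better`` is ``"lower"`` (e.g. P-values) or ``"higher"`` (e.g. |delta|).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise AnalysisError("rank_scores: empty input")
    if not np.all(np.isfinite(v)):
        raise AnalysisError("rank_scores: non-finite value encountered")
    if better == "lower":
        return stats.rankdata(-v, method=tie_method)
    if better == "higher":
        return stats.rankdata(v, method=tie_method)
    raise AnalysisError(f"better must be 'lower' or 'higher', got {better!r}")


def rank_dmps(
    b: BetaMatrix, d: TwinDesign, cfg: DmpConfig = DmpConfig()
) -> pd.DataFrame:
    """Rank all probes by combined P-value and |mean delta| scores.

    Only discordant pairs enter the computation. Probes with missing values
    in any discordant-pair sample are dropped (logged). Returns a DataFrame
    sorted best-first with columns probe_id, p_value, t_statistic,
    mean_delta, degenerate, p_score, delta_score, combined_score, rank.

    Ties on combined_score break on smaller P, then probe_id, so output is
    deterministic.
    """
    pairs = d.pairs_in_group("discordant")
    if len(pairs) < 2:
        raise AnalysisError(
            f"need >= 2 discordant pairs, design has {len(pairs)}"
        )
    affected_samples = pairs["first"].tolist()
    unaffected_samples = pairs["second"].tolist()
    complete = filter_complete_probes(b, affected_samples + unaffected_samples)
    if complete.n_probes == 0:
        raise AnalysisError("no probes with complete data in discordant pairs")

    aff = complete.values_for(affected_samples)
    unaff = complete.values_for(unaffected_samples)
    diffs = aff - unaff  # (m, n_pairs), affected minus unaffected
    n = diffs.shape[1]
    mean_delta = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)

    degenerate = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean_delta / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    p[degenerate & (mean_delta == 0.0)] = 1.0
    p[degenerate & (mean_delta != 0.0)] = 0.0
    if degenerate.any():
        logger.info("rank_dmps: %d probe(s) with degenerate variance", degenerate.sum())

    p_score = rank_scores(p, better="lower", tie_method=cfg.tie_method)
    delta_score = rank_scores(
        np.abs(mean_delta), better="higher", tie_method=cfg.tie_method
    )
    combined = p_score + delta_score

    records = pd.DataFrame(
        {
            "probe_id": complete.probe_ids,
            "p_value": p,
            "t_statistic": t,
            "mean_delta": mean_delta,
            "degenerate": degenerate,
            "p_score": p_score,
            "delta_score": delta_score,
            "combined_score": combined,
        }
    )
    records = records.sort_values(
        by=["combined_score", "p_value", "probe_id"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    records["rank"] = np.arange(1, len(records) + 1)
    return records


def top_dmps(records: pd.DataFrame, cfg: DmpConfig = DmpConfig()) -> pd.DataFrame:
    """Extract the top-k head of a ranked DMP table."""
    return records.head(cfg.top_k).reset_index(drop=True)


def annotate_dmps(
    records: pd.DataFrame, ann: ProbeAnnotation | None
) -> pd.DataFrame:
    """Join gene names and feature categories onto a ranked DMP table."""
    out = records.copy()
    if ann is None:
        out["gene"] = ""
        out["feature"] = ""
        return out
    out["gene"] = [";".join(ann.genes_for(p)) for p in out["probe_id"]]
    out["feature"] = [";".join(ann.features_for(p)) for p in out["probe_id"]]
    return out
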