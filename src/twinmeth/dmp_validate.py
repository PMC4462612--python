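"""Cross-group validation of top-ranked probes.

A probe that shows large within-pair differences in every diagnostic group
is merely environmentally labile; a disease-linked probe should differ more
within discordant pairs than within concordant or healthy pairs. Each probe
is therefore tested twice with a one-sided Wilcoxon-Mann-Whitney test:
discordant |delta| greater than concordant, and greater than healthy.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .datamodel import BetaMatrix, TwinDesign
from .errors import AnalysisError
from .vmp import abs_diff_matrix

# Largest combined sample size for which the exact null distribution is used
# (no ties only; beyond this, or with ties, the normal approximation with
# continuity and tie correction applies).
EXACT_LIMIT = 25

DEFAULT_ALPHA_LEVEL = 0.05


class WmwResult(NamedTuple):
    u_statistic: float
    p_value: float
    exact: bool


def wmw_one_sided(x: Sequence[float], y: Sequence[float]) -> WmwResult:
    """One-sided Wilcoxon-Mann-Whitney test: x stochastically greater than y.

    Exact permutation P when the pooled sample is tie-free and of size at
    most ``EXACT_LIMIT``; otherwise the normal approximation with continuity
    correction and tie-corrected variance.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise AnalysisError("wmw_one_sided: empty sample")
    pooled = np.concatenate([xa, ya])
    no_ties = np.unique(pooled).size == pooled.size
    use_exact = no_ties and pooled.size <= EXACT_LIMIT
    method = "exact" if use_exact else "asymptotic"
    res = mannwhitneyu(xa, ya, alternative="greater", method=method)
    return WmwResult(float(res.statistic), float(min(res.pvalue, 1.0)), use_exact)


def validate_dmps(
    b: BetaMatrix,
    d: TwinDesign,
    probes: Sequence[str],
    alpha_level: float = DEFAULT_ALPHA_LEVEL,
) -> pd.DataFrame:
    """Per-probe cross-group validation over all pairs of the design.

    For each requested probe, the absolute within-pair differences are
    computed in every pair (twin orientation is irrelevant under the
    absolute value) and two one-sided WMW tests compare the discordant
    group against concordant and healthy. A probe is *validated* against a
    group when its P-value falls below ``alpha_level``.

    Returns a DataFrame with columns probe_id, median_abs_delta_concordant /
    _discordant / _healthy, u_vs_concordant, p_vs_concordant,
    validated_vs_concordant, u_vs_healthy, p_vs_healthy, validated_vs_healthy.
    """
    if not 0 < alpha_level < 1:
        raise AnalysisError(f"alpha_level must be in (0,1), got {alpha_level}")
    probes = list(probes)
    missing = [p for p in probes if p not in b.data.index]
    if missing:
        raise AnalysisError(f"probe(s) absent from beta matrix: {missing}")
    for group in ("concordant", "discordant", "healthy"):
        if len(d.pairs_in_group(group)) == 0:
            raise AnalysisError(f"design has no {group} pairs")

    absdiff = abs_diff_matrix(b.subset(probes=probes), d)
    pairs = d.pairs()
    cols = {
        g: pairs.loc[pairs["group"] == g, "pair_id"].tolist()
        for g in ("concordant", "discordant", "healthy")
    }

    rows = []
    for probe in probes:
        by_group = {g: absdiff.loc[probe, cols[g]].to_numpy() for g in cols}
        res_c = wmw_one_sided(by_group["discordant"], by_group["concordant"])
        res_h = wmw_one_sided(by_group["discordant"], by_group["healthy"])
        rows.append(
            {
                "probe_id": probe,
                "median_abs_delta_concordant": float(np.median(by_group["concordant"])),
                "median_abs_delta_discordant": float(np.median(by_group["discordant"])),
                "median_abs_delta_healthy": float(np.median(by_group["healthy"])),
                "u_vs_concordant": res_c.u_statistic,
                "p_vs_concordant": res_c.p_value,
                "validated_vs_concordant": res_c.p_value < alpha_level,
                "u_vs_healthy": res_h.u_statistic,
                "p_vs_healthy": res_h.p_value,
                "validated_vs_healthy": res_h.p_value < alpha_level,
            }
        )
    return pd.DataFrame(rows)
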