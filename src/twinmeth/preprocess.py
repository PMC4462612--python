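"""Beta computation from raw intensities and per-analysis probe filtering."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import BetaMatrix
from .errors import AnalysisError, DataValidationError, ParseError

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 100.0


@dataclass(frozen=True)
class IntensityPair:
    """Methylated/unmethylated fluorescence intensities plus offset.

    ``alpha`` is a stabilizing offset added to the denominator; with
    alpha > 0 the resulting fraction is always strictly below 1.
    """

    M: float
    U: float
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self):
        if self.M < 0 or self.U < 0 or self.alpha < 0:
            raise DataValidationError(
                f"intensities and alpha must be non-negative: "
                f"M={self.M}, U={self.U}, alpha={self.alpha}"
            )
        if self.M + self.U + self.alpha == 0:
            raise DataValidationError("M + U + alpha must be positive")


def compute_beta(x: IntensityPair) -> float:
    """Methylation fraction M / (M + U + alpha)."""
    denom = x.M + x.U + x.alpha
    if denom == 0:
        raise AnalysisError("undefined beta: M + U + alpha is zero")
    return x.M / denom


def read_intensities(path: str | Path) -> pd.DataFrame:
    """Read a long-format intensity TSV with columns probe_id, sample_id, M, U."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    required = ["probe_id", "sample_id", "M", "U"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: intensity table missing column(s) {missing}")
    return table


def betas_from_intensities(
    intensities: pd.DataFrame, alpha: float = DEFAULT_ALPHA
) -> BetaMatrix:
    """Pivot a long intensity table into a BetaMatrix via M/(M+U+alpha)."""
    if alpha < 0:
        raise DataValidationError(f"alpha must be >= 0, got {alpha}")
    t = intensities.copy()
    if (t["M"] < 0).any() or (t["U"] < 0).any():
        raise DataValidationError("negative intensity encountered")
    denom = t["M"] + t["U"] + alpha
    if (denom == 0).any():
        bad = t.loc[denom == 0].iloc[0]
        raise AnalysisError(
            f"undefined beta (M+U+alpha == 0) for probe {bad['probe_id']!r}, "
            f"sample {bad['sample_id']!r}"
        )
    t["beta"] = t["M"] / denom
    wide = t.pivot(index="probe_id", columns="sample_id", values="beta")
    wide.columns.name = None
    return BetaMatrix(wide)


def filter_complete_probes(b: BetaMatrix, samples: Sequence[str]) -> BetaMatrix:
    """Restrict to ``samples`` and drop probes with any missing value there.

    The number of dropped probes is logged so data loss is visible.
    """
    unknown = [s for s in samples if s not in b.sample_ids]
    if unknown:
        raise DataValidationError(f"unknown sample_id(s): {unknown}")
    sub = b.data[list(samples)]
    complete = sub.notna().all(axis=1)
    n_removed = int((~complete).sum())
    if n_removed:
        logger.info(
            "filter_complete_probes: dropped %d/%d probes with missing values",
            n_removed,
            len(complete),
        )
    return BetaMatrix(sub.loc[complete].copy())


def beta_to_mvalue(beta: np.ndarray | float) -> np.ndarray | float:
    """Logit transform log2(beta / (1 - beta)).

    Opt-in utility; all shipped analyses operate on the beta scale.
    """
    arr = np.asarray(beta, dtype=float)
    if ((arr <= 0) | (arr >= 1)).any():
        raise AnalysisError("M-value transform requires beta strictly in (0, 1)")
    out = np.log2(arr / (1.0 - arr))
    return out if out.shape else float(out)
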