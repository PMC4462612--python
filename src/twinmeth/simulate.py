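"""Seeded generator of synthetic monozygotic-twin methylation data.

The generator emits a beta matrix with the structure the analyses assume:
a bimodal per-probe baseline, small additive per-twin noise, optional
planted mean shifts in the affected co-twins of discordant pairs
(differential signal) and optional planted group-exclusive large
within-pair differences (variability signal). Truth tables record what was
planted so recovery can be scored.

Noise is additive Gaussian on the beta scale with clipping to [0, 1]; this
keeps the within-pair difference distribution analytically tractable
(difference of two independent N(0, sigma^2) deviations is N(0, 2 sigma^2))
as long as baselines stay away from the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .datamodel import (
    FEATURE_CATEGORIES,
    GROUPS,
    BetaMatrix,
    GeneSetCollection,
    ProbeAnnotation,
    TwinDesign,
)
from .errors import AnalysisError

_GROUP_PREFIX = {"concordant": "C", "discordant": "D", "healthy": "H"}


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; identical config + seed => identical output."""

    n_pairs: dict[str, int] = field(
        default_factory=lambda: {"concordant": 4, "discordant": 6, "healthy": 7}
    )
    n_probes: int = 10_000
    # two-component baseline mixture on the beta scale
    baseline_low_mean: float = 0.15
    baseline_high_mean: float = 0.85
    baseline_sd: float = 0.05
    baseline_high_weight: float = 0.5
    baseline_bounds: tuple[float, float] = (0.01, 0.99)
    pair_noise_sd: float = 0.02
    # planted differential signal (discordant pairs, affected minus unaffected)
    n_dmp: int = 0
    dmp_effect: float = -0.08
    # planted group-exclusive variability signal
    n_vmp: dict[str, int] = field(
        default_factory=lambda: {"concordant": 0, "discordant": 0, "healthy": 0}
    )
    vmp_magnitude: float = 0.3
    probes_per_gene: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_probes < 1:
            raise AnalysisError("n_probes must be >= 1")
        if set(self.n_pairs) != set(GROUPS):
            raise AnalysisError(f"n_pairs must have keys {GROUPS}")
        if set(self.n_vmp) != set(GROUPS):
            raise AnalysisError(f"n_vmp must have keys {GROUPS}")
        lo, hi = self.baseline_bounds
        if not 0.0 <= lo < hi <= 1.0:
            raise AnalysisError(f"invalid baseline_bounds {self.baseline_bounds}")
        total_planted = self.n_dmp + sum(self.n_vmp.values())
        if total_planted > self.n_probes:
            raise AnalysisError(
                f"{total_planted} planted probes requested but only "
                f"{self.n_probes} probes available"
            )


class SimResult(NamedTuple):
    beta: BetaMatrix
    design: TwinDesign
    annotation: ProbeAnnotation
    truth_dmp: pd.DataFrame  # probe_id, effect
    truth_vmp: pd.DataFrame  # probe_id, group, magnitude


def _make_design(n_pairs: dict[str, int]) -> TwinDesign:
    rows = []
    for group in GROUPS:
        prefix = _GROUP_PREFIX[group]
        for i in range(1, n_pairs[group] + 1):
            pair_id = f"{prefix}{i}"
            for twin, suffix in enumerate(("a", "b")):
                affected = {
                    "concordant": True,
                    "discordant": twin == 0,
                    "healthy": False,
                }[group]
                rows.append((f"{pair_id}_{suffix}", pair_id, group, affected))
    return TwinDesign(
        pd.DataFrame(rows, columns=["sample_id", "pair_id", "group", "affected"])
    )


def _make_annotation(
    probe_ids: list[str], cfg: SimConfig, rng: np.random.Generator
) -> ProbeAnnotation:
    m = len(probe_ids)
    chroms = rng.integers(1, 23, size=m)
    positions = rng.integers(1, 200_000_000, size=m)
    genic_features = [f for f in FEATURE_CATEGORIES if f != "intergenic"]
    intergenic = rng.random(m) < 0.1
    rows = []
    for i, probe in enumerate(probe_ids):
        if intergenic[i]:
            genes: tuple[str, ...] = ()
            features: tuple[str, ...] = ("intergenic",)
        else:
            genes = (f"GENE{i // cfg.probes_per_gene:05d}",)
            k = int(rng.integers(1, 3))
            features = tuple(
                sorted(rng.choice(genic_features, size=k, replace=False))
            )
        rows.append((probe, f"chr{chroms[i]}", int(positions[i]), genes, features))
    return ProbeAnnotation(
        pd.DataFrame(
            rows, columns=["probe_id", "chromosome", "position", "genes", "features"]
        )
    )


def simulate(cfg: SimConfig) -> SimResult:
    """Generate a complete synthetic data set plus planted-truth tables."""
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_probes
    design = _make_design(cfg.n_pairs)
    sample_ids = design.sample_ids
    n_samples = len(sample_ids)
    probe_ids = [f"cg{i:08d}" for i in range(m)]

    high = rng.random(m) < cfg.baseline_high_weight
    baseline = rng.normal(
        np.where(high, cfg.baseline_high_mean, cfg.baseline_low_mean),
        cfg.baseline_sd,
    )
    baseline = np.clip(baseline, *cfg.baseline_bounds)

    if cfg.pair_noise_sd > 0:
        beta = baseline[:, None] + rng.normal(0.0, cfg.pair_noise_sd, (m, n_samples))
    else:
        beta = np.repeat(baseline[:, None], n_samples, axis=1)

    # disjoint planted probe sets
    n_planted = cfg.n_dmp + sum(cfg.n_vmp.values())
    planted = (
        rng.choice(m, size=n_planted, replace=False) if n_planted else np.array([], int)
    )
    cursor = 0
    dmp_idx = planted[cursor : cursor + cfg.n_dmp]
    cursor += cfg.n_dmp
    vmp_idx: dict[str, np.ndarray] = {}
    for group in GROUPS:
        vmp_idx[group] = planted[cursor : cursor + cfg.n_vmp[group]]
        cursor += cfg.n_vmp[group]

    col_of = {s: j for j, s in enumerate(sample_ids)}
    pairs = design.pairs()

    if cfg.n_dmp:
        affected_cols = [
            col_of[s] for s in pairs.loc[pairs["group"] == "discordant", "first"]
        ]
        beta[np.ix_(dmp_idx, affected_cols)] += cfg.dmp_effect

    for group in GROUPS:
        idx = vmp_idx[group]
        if idx.size == 0:
            continue
        group_pairs = pairs[pairs["group"] == group]
        # shift direction points toward the interior so clipping cannot
        # shrink the planted difference
        sign = np.where(baseline[idx] <= 0.5, 1.0, -1.0)
        for _, rec in group_pairs.iterrows():
            members = (col_of[rec["first"]], col_of[rec["second"]])
            chosen = np.asarray(
                [members[int(t)] for t in rng.integers(0, 2, size=idx.size)]
            )
            beta[idx, chosen] += sign * cfg.vmp_magnitude

    beta = np.clip(beta, 0.0, 1.0)
    bm = BetaMatrix(
        pd.DataFrame(beta, index=pd.Index(probe_ids, name="probe_id"), columns=sample_ids)
    )
    annotation = _make_annotation(probe_ids, cfg, rng)

    truth_dmp = pd.DataFrame(
        {
            "probe_id": [probe_ids[i] for i in sorted(dmp_idx)],
            "effect": cfg.dmp_effect,
        }
    ).astype({"probe_id": str})
    vmp_rows = []
    for group in GROUPS:
        for i in sorted(vmp_idx[group]):
            vmp_rows.append((probe_ids[i], group, cfg.vmp_magnitude))
    truth_vmp = pd.DataFrame(vmp_rows, columns=["probe_id", "group", "magnitude"])
    return SimResult(bm, design, annotation, truth_dmp, truth_vmp)


def simulate_null(cfg: SimConfig) -> SimResult:
    """As :func:`simulate` but with all planted effects removed."""
    null_cfg = replace(
        cfg, n_dmp=0, n_vmp={"concordant": 0, "discordant": 0, "healthy": 0}
    )
    return simulate(null_cfg)


def make_gene_sets(
    ann: ProbeAnnotation, n_sets: int = 20, set_size: int = 25, seed: int = 0
) -> GeneSetCollection:
    """Random gene sets drawn from an annotation's gene universe (testing aid)."""
    genes = ann.all_genes()
    if not genes:
        raise AnalysisError("annotation contains no genes")
    rng = np.random.default_rng(seed)
    size = min(set_size, len(genes))
    sets = {
        f"SET{i:03d}": tuple(sorted(rng.choice(genes, size=size, replace=False)))
        for i in range(n_sets)
    }
    return GeneSetCollection(sets=sets, universe=tuple(genes))
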