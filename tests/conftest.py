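"""Shared fixtures and small builders used across the suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from twinmeth.datamodel import BetaMatrix, TwinDesign


def make_design(n_concordant=4, n_discordant=6, n_healthy=7) -> TwinDesign:
    """Build a twin design with the given per-group pair counts.

    Sample ids follow the ``<pair>_a`` / ``<pair>_b`` convention with the
    affected co-twin of a discordant pair in slot ``a``.
    """
    rows = []
    for prefix, group, n, affected in [
        ("C", "concordant", n_concordant, (True, True)),
        ("D", "discordant", n_discordant, (True, False)),
        ("H", "healthy", n_healthy, (False, False)),
    ]:
        for i in range(1, n + 1):
            pair = f"{prefix}{i}"
            rows.append((f"{pair}_a", pair, group, affected[0]))
            rows.append((f"{pair}_b", pair, group, affected[1]))
    return TwinDesign(
        pd.DataFrame(rows, columns=["sample_id", "pair_id", "group", "affected"])
    )


def make_beta(values: np.ndarray, design: TwinDesign, probe_ids=None) -> BetaMatrix:
    """Wrap a (probes x samples) array as a BetaMatrix aligned to a design."""
    values = np.asarray(values, dtype=float)
    if probe_ids is None:
        probe_ids = [f"cg{i:08d}" for i in range(values.shape[0])]
    return BetaMatrix(
        pd.DataFrame(
            values,
            index=pd.Index(probe_ids, name="probe_id"),
            columns=design.sample_ids,
        )
    )


@pytest.fixture
def design_467() -> TwinDesign:
    """The study-sized design: 4 concordant, 6 discordant, 7 healthy pairs."""
    return make_design()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
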