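"""Highest-single-agent (HSA) synergy scoring for two-drug dose grids.

The HSA reference model expects a combination at doses (a_i, b_j) to do no
better than the stronger of its two single agents; the synergy surplus is

    surplus[i, j] = effect[i, j] - max(effect[i, 0], effect[0, j])

on growth-inhibition fractions (0 = untreated growth, 1 = complete
inhibition). Positive surplus indicates synergy, negative antagonism; the
single-agent row and column are their own reference and score zero. The
dose-0 row/column must be present in the input — it anchors the single
agents unambiguously. No significance surface is computed; replicate grids
are averaged before scoring (the surplus operator is linear, so the order
does not matter).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def _validate(dr: pd.DataFrame) -> None:
    a = np.asarray(dr.index, dtype=float)
    b = np.asarray(dr.columns, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty dose grid")
    if a[0] != 0 or b[0] != 0:
        raise ValueError("dose grids must include dose 0 first (single-agent anchors)")
    if np.any(np.diff(a) <= 0) or np.any(np.diff(b) <= 0):
        raise ValueError("dose grids must be strictly ascending")


def normalize_effects(raw: pd.DataFrame, control: float) -> pd.DataFrame:
    """Viability readings -> growth-inhibition fractions relative to control.

    effect = clamp(1 - raw/control, 0, 1); readings above the untreated
    control (apparent growth stimulation) clamp to 0 with a logged note.
    The [0, 0] (untreated/untreated) cell is forced to exactly 0.
    """
    if control <= 0:
        raise ValueError("untreated control reading must be > 0")
    _validate(raw)
    eff = 1.0 - raw.astype(float) / control
    n_over = int((eff.to_numpy() < 0).sum())
    if n_over:
        logger.info("%d reading(s) above control clamped to zero inhibition", n_over)
    eff = eff.clip(lower=0.0, upper=1.0)
    eff.iloc[0, 0] = 0.0
    return eff


def hsa_surplus(dr: pd.DataFrame) -> pd.DataFrame:
    """HSA synergy surplus matrix, same dose labels as the effect matrix."""
    _validate(dr)
    eff = dr.to_numpy(dtype=float)
    single_a = eff[:, 0]  # agent A alone, down the rows
    single_b = eff[0, :]  # agent B alone, across the columns
    reference = np.maximum.outer(single_a, single_b)
    return pd.DataFrame(eff - reference, index=dr.index, columns=dr.columns)


def mean_surplus(replicates: Sequence[pd.DataFrame]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean and standard error of HSA surplus over replicate effect grids."""
    if not replicates:
        raise ValueError("no replicate matrices")
    shapes = {r.shape for r in replicates}
    if len(shapes) > 1:
        raise ValueError("replicate matrices differ in shape")
    surpluses = np.stack([hsa_surplus(r).to_numpy() for r in replicates])
    mean = surpluses.mean(axis=0)
    sem = (
        surpluses.std(axis=0, ddof=1) / np.sqrt(len(replicates))
        if len(replicates) > 1
        else np.zeros_like(mean)
    )
    idx, cols = replicates[0].index, replicates[0].columns
    return pd.DataFrame(mean, index=idx, columns=cols), pd.DataFrame(sem, index=idx, columns=cols)


def read_matrix_csv(path) -> pd.DataFrame:
    """Read a dose-response CSV whose first row/column hold the doses."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(float)
    df.columns = df.columns.astype(float)
    return df
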