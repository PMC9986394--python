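"""Hit calling for the inhibitor screen.

Per inhibitor, the log fold change (LFC) compares apoptosis in the
endocrine-resistant lines with the parental line,

    LFC_i = log( mean(TamR_i, LTED_i) / MCF7_i ),

and inhibitors are standardized against the library distribution with a
robust Z-score built from the median and the median absolute deviation,

    RZ_i = 0.6745 * (LFC_i - median(LFC)) / MAD,   MAD = median(|LFC_i - median(LFC)|),

where 0.6745 = Phi^-1(0.75) makes the MAD a consistent estimate of the
standard deviation under normality. Inhibitors with |RZ| >= 2.5 are flagged
significant (one-sided normal tail P <= 0.00621). Independently, each
inhibitor is assigned a phenotype category from its mean per-line scores:
pan-line death (all three lines >= 50%), resistant-only (TamR and LTED
>= 20%, parental below), or responsive-only (MCF7 >= 10%, resistant lines
below).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

MAD_NORMAL_CONSTANT = 0.6745  # Phi^-1(0.75); MAD -> sigma * 1/0.6745 under normality


@dataclass(frozen=True)
class ScreenStatsConfig:
    log_base: float = 2.0
    pseudocount: float = 0.001
    z_constant: float = MAD_NORMAL_CONSTANT
    z_threshold: float = 2.5
    crit_responsive: float = 0.10
    crit_resistant: float = 0.20
    crit_pan: float = 0.50
    replicate_collapse: str = "mean"  # or "median"

    def __post_init__(self) -> None:
        if self.log_base <= 0 or self.log_base == 1:
            raise ValueError("log_base must be positive and != 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be >= 0")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be > 0")
        for name in ("crit_responsive", "crit_resistant", "crit_pan"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} outside (0,1]")


@dataclass(frozen=True)
class InhibitorProfile:
    inhibitor_id: str
    score_mcf7: float
    score_tamr: float
    score_lted: float

    @property
    def resistant_mean(self) -> float:
        return (self.score_tamr + self.score_lted) / 2.0


@dataclass(frozen=True)
class HitResult:
    inhibitor_id: str
    lfc: float
    rz_score: float  # NaN when the library MAD is degenerate
    significant: bool
    category: str  # responsive_only | resistant_only | pan | none


class DivisionDomainError(ValueError):
    """Parental score is zero and no pseudocount guards the ratio."""


def compute_lfc(profile: InhibitorProfile, config: ScreenStatsConfig | None = None) -> float:
    """Log fold change of resistant-line vs parental apoptotic score."""
    config = config or ScreenStatsConfig()
    denom = profile.score_mcf7 + config.pseudocount
    if denom <= 0:
        raise DivisionDomainError(
            f"{profile.inhibitor_id}: MCF7 score {profile.score_mcf7} with "
            f"pseudocount {config.pseudocount} gives non-positive denominator"
        )
    ratio = (profile.resistant_mean + config.pseudocount) / denom
    return math.log(ratio, config.log_base)


def robust_zscores(
    lfcs, z_constant: float = MAD_NORMAL_CONSTANT
) -> tuple[float, float, np.ndarray]:
    """Median, MAD and robust Z-scores of an LFC vector.

    A zero MAD (more than half the values tied at the median) makes the
    scores undefined; they are returned as NaN with a logged warning rather
    than raising, so degenerate screens stay reportable.
    """
    x = np.asarray(list(lfcs), dtype=float)
    if x.size == 0:
        raise ValueError("empty LFC vector")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    if mad == 0.0:
        logger.warning("MAD is zero: robust Z-scores undefined for all %d values", x.size)
        return med, mad, np.full(x.shape, np.nan)
    return med, mad, z_constant * (x - med) / mad


def significance_pvalue(z_threshold: float = 2.5) -> float:
    """One-sided standard-normal tail probability 1 - Phi(z)."""
    if not np.isfinite(z_threshold):
        raise ValueError("z_threshold must be finite")
    return float(norm.sf(z_threshold))


def classify_category(profile: InhibitorProfile, config: ScreenStatsConfig | None = None) -> str:
    """Three-way phenotype category from mean per-line apoptotic scores.

    Priority pan > resistant_only > responsive_only; the "only" categories
    require the other line(s) to fall below that criterion's own threshold.
    """
    c = config or ScreenStatsConfig()
    m, t, l = profile.score_mcf7, profile.score_tamr, profile.score_lted
    if m >= c.crit_pan and t >= c.crit_pan and l >= c.crit_pan:
        return "pan"
    if t >= c.crit_resistant and l >= c.crit_resistant and m < c.crit_resistant:
        return "resistant_only"
    if m >= c.crit_responsive and t < c.crit_responsive and l < c.crit_responsive:
        return "responsive_only"
    return "none"


def build_profiles(
    well_scores: pd.DataFrame, config: ScreenStatsConfig | None = None
) -> pd.DataFrame:
    """Collapse replicates and pivot to one row per inhibitor.

    Expects columns inhibitor_id, cell_line, apoptotic_score and optionally
    role (non-'sample' rows are excluded). Inhibitors missing any of the
    three cell lines are dropped with a logged reason.
    """
    config = config or ScreenStatsConfig()
    df = well_scores
    if "role" in df.columns:
        df = df[df["role"] == "sample"]
    collapse = config.replicate_collapse
    if collapse not in ("mean", "median"):
        raise ValueError("replicate_collapse must be 'mean' or 'median'")
    agg = (
        df.groupby(["inhibitor_id", "cell_line"])["apoptotic_score"]
        .agg(collapse)
        .unstack("cell_line")
    )
    needed = ["MCF7", "TamR", "LTED"]
    missing_lines = [c for c in needed if c not in agg.columns]
    if missing_lines:
        raise ValueError(f"screen table lacks cell line(s): {missing_lines}")
    incomplete = agg[needed].isna().any(axis=1)
    if incomplete.any():
        logger.warning(
            "excluding %d inhibitor(s) missing a cell line: %s",
            int(incomplete.sum()),
            list(agg.index[incomplete][:10]),
        )
        agg = agg[~incomplete]
    out = agg[needed].rename(
        columns={"MCF7": "score_mcf7", "TamR": "score_tamr", "LTED": "score_lted"}
    )
    out["resistant_mean"] = (out["score_tamr"] + out["score_lted"]) / 2.0
    return out.reset_index()


def call_hits(
    well_scores: pd.DataFrame, config: ScreenStatsConfig | None = None
) -> pd.DataFrame:
    """Full hit-calling pipeline on a per-well apoptotic-score table.

    Returns one row per inhibitor with per-line mean scores, LFC, robust
    Z-score, the |RZ| >= threshold significance flag, the phenotype category
    and a mad_degenerate flag, sorted by |RZ| descending (NaN RZ last).
    Control wells never enter the LFC distribution.
    """
    config = config or ScreenStatsConfig()
    profiles = build_profiles(well_scores, config)
    lfcs = []
    for row in profiles.itertuples():
        prof = InhibitorProfile(row.inhibitor_id, row.score_mcf7, row.score_tamr, row.score_lted)
        lfcs.append(compute_lfc(prof, config))
    profiles["lfc"] = lfcs
    _, mad, rz = robust_zscores(profiles["lfc"].to_numpy(), config.z_constant)
    profiles["rz_score"] = rz
    profiles["mad_degenerate"] = mad == 0.0
    profiles["significant"] = np.abs(rz) >= config.z_threshold
    profiles.loc[~np.isfinite(rz), "significant"] = False
    profiles["category"] = [
        classify_category(
            InhibitorProfile(r.inhibitor_id, r.score_mcf7, r.score_tamr, r.score_lted), config
        )
        for r in profiles.itertuples()
    ]
    order = profiles["rz_score"].abs()
    return (
        profiles.assign(_o=order.fillna(-np.inf))
        .sort_values("_o", ascending=False, kind="mergesort")
        .drop(columns="_o")
        .reset_index(drop=True)
    )
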