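"""Seeded synthetic fixtures for every stage of the screen pipeline.

The generators emulate the study conditions of a 954-inhibitor antisense
oligonucleotide screen run in three breast-cancer lines (parental MCF7 and
the endocrine-resistant derivatives TamR and LTED) in biological triplicate,
with five imaged fields per well: two-channel microscopy fields with known
nucleus positions and apoptotic calls, full per-well apoptotic-score tables
with planted hits, differential-expression tables with planted members of a
miRNA target database, and dose-response surfaces with known single-agent
curves and planted synergy surplus.

Every generator is a pure function of its parameters and an integer seed;
ground truth is returned alongside the data so downstream estimates can be
checked against it.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

CELL_LINES = ("MCF7", "TamR", "LTED")
CATEGORIES = ("responsive_only", "resistant_only", "pan", "none")
TARGET_SOURCES = ("miRDB", "TargetScan", "AGO-PAR-CLIP", "miRTarBase")
CONTROL_ROLES = ("mock", "neg_ctrl", "death_ctrl")

# stream tags so one global seed yields independent, stable substreams
_STREAM = {"field": 1, "screen": 2, "targets": 3, "dose": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAM[stream])))


@dataclass(frozen=True)
class FieldTruth:
    """Ground truth for one generated microscope field."""

    n_nuclei: int
    centers: tuple[tuple[int, int], ...]  # (row, col), 0-based
    radii: tuple[float, ...]
    apoptotic_ids: frozenset[int]
    apoptotic_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "nucleus": range(self.n_nuclei),
                "row": [c[0] for c in self.centers],
                "col": [c[1] for c in self.centers],
                "radius": self.radii,
                "apoptotic": [i in self.apoptotic_ids for i in range(self.n_nuclei)],
            }
        )


@dataclass(frozen=True)
class FieldImage:
    """One two-channel field: Hoechst (nuclei) + caspase-3/7 reporter."""

    hoechst: np.ndarray
    caspase: np.ndarray
    well: str = ""
    field_index: int = 0

    def __post_init__(self) -> None:
        if self.hoechst.shape != self.caspase.shape:
            raise ValueError("channel shapes differ")


@dataclass(frozen=True)
class ScreenScenario:
    """Layout and effect sizes of a synthetic inhibitor screen.

    ``planted`` maps inhibitor id -> (category, per-line mean apoptotic
    score); unplanted inhibitors sit at ``baseline_score`` in every line.
    """

    n_inhibitors: int = 954
    n_replicates: int = 3
    baseline_score: float = 0.05
    noise_sd: float = 0.0
    planted: Mapping[str, tuple[str, Mapping[str, float]]] = field(default_factory=dict)
    cell_lines: tuple[str, ...] = CELL_LINES
    include_controls: bool = True

    def __post_init__(self) -> None:
        if self.n_inhibitors < 0 or self.n_replicates < 1:
            raise ValueError("invalid scenario dimensions")
        if not 0.0 <= self.baseline_score <= 1.0:
            raise ValueError("baseline_score outside [0,1]")
        for inh, (cat, scores) in self.planted.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for {inh}")
            for line, s in scores.items():
                if not 0.0 <= s <= 1.0:
                    raise ValueError(f"planted score {s} outside [0,1] for {inh}/{line}")

    def inhibitor_ids(self) -> list[str]:
        return [f"miR-inh-{i:04d}" for i in range(1, self.n_inhibitors + 1)]


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed at the requested density."""


def _place_centers(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_separation: float,
    max_tries: int = 20_000,
) -> list[tuple[int, int]]:
    rows, cols = shape
    lo_r, hi_r = margin, rows - margin
    lo_c, hi_c = margin, cols - margin
    if n > 0 and (hi_r <= lo_r or hi_c <= lo_c):
        raise PlacementError("cannot place nuclei: image too small for margin")
    centers: list[tuple[int, int]] = []
    arr = np.empty((0, 2))
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise PlacementError(
                f"cannot place nuclei: {len(centers)}/{n} placed after {max_tries} tries"
            )
        tries += 1
        r = int(rng.uniform(lo_r, hi_r))
        c = int(rng.uniform(lo_c, hi_c))
        if min_separation > 0 and len(centers):
            d2 = ((arr - (r, c)) ** 2).sum(axis=1)
            if (d2 < min_separation**2).any():
                continue
        centers.append((r, c))
        arr = np.vstack([arr, (r, c)])
    return centers


def _render_blobs(
    shape: tuple[int, int],
    centers: Sequence[tuple[int, int]],
    radii: Sequence[float],
    peaks: Sequence[float],
) -> np.ndarray:
    """Sum of Gaussian-profiled discs (sigma = radius/2, support 2*radius)."""
    img = np.zeros(shape, dtype=np.float64)
    rows, cols = shape
    for (cr, cc), rad, peak in zip(centers, radii, peaks):
        if peak <= 0:
            continue
        ext = int(math.ceil(2 * rad))
        r0, r1 = max(cr - ext, 0), min(cr + ext + 1, rows)
        c0, c1 = max(cc - ext, 0), min(cc + ext + 1, cols)
        rr, cc_ = np.ogrid[r0:r1, c0:c1]
        d2 = (rr - cr) ** 2 + (cc_ - cc) ** 2
        sigma = rad / 2.0
        prof = peak * np.exp(-d2 / (2 * sigma**2))
        prof[d2 > (2 * rad) ** 2] = 0.0
        img[r0:r1, c0:c1] += prof
    return img


def gen_field_image(
    n_nuclei: int,
    apoptotic_fraction: float,
    seed: int,
    image_shape: tuple[int, int] = (600, 600),
    radius: float = 6.0,
    radius_jitter: float = 0.8,
    min_separation: float = 18.0,
    hoechst_peak: float = 30_000.0,
    caspase_peak: float = 20_000.0,
    background: float = 200.0,
    noise_sd: float = 50.0,
    well: str = "",
    field_index: int = 0,
) -> tuple[FieldImage, FieldTruth]:
    """Render one two-channel 16-bit field with known ground truth.

    Nuclei are Gaussian-profiled discs on the Hoechst channel; the caspase
    reporter channel carries an elevated blob at the same position only for
    the apoptotic subset (``round(apoptotic_fraction * n_nuclei)`` nuclei).
    Identical (parameters, seed) give bit-identical arrays.
    """
    if n_nuclei < 0:
        raise ValueError("n_nuclei must be >= 0")
    if not 0.0 <= apoptotic_fraction <= 1.0:
        raise ValueError("apoptotic_fraction outside [0,1]")
    rng = _rng(seed, "field")

    margin = 3 * radius
    centers = _place_centers(rng, n_nuclei, image_shape, margin, min_separation)
    radii = tuple(
        float(max(2.0, radius + rng.uniform(-radius_jitter, radius_jitter)))
        for _ in range(n_nuclei)
    )
    n_apo = int(round(apoptotic_fraction * n_nuclei))
    apo_ids = frozenset(rng.choice(n_nuclei, size=n_apo, replace=False).tolist()) if n_apo else frozenset()

    hoechst = _render_blobs(image_shape, centers, radii, [hoechst_peak] * n_nuclei)
    caspase = _render_blobs(
        image_shape,
        centers,
        radii,
        [caspase_peak if i in apo_ids else 0.0 for i in range(n_nuclei)],
    )
    for chan in (hoechst, caspase):
        chan += background + rng.normal(0.0, noise_sd, size=image_shape)
    hoechst = np.clip(hoechst, 0, 65535).astype(np.uint16)
    caspase = np.clip(caspase, 0, 65535).astype(np.uint16)

    truth = FieldTruth(
        n_nuclei=n_nuclei,
        centers=tuple(centers),
        radii=radii,
        apoptotic_ids=apo_ids,
        apoptotic_fraction=(n_apo / n_nuclei) if n_nuclei else 0.0,
    )
    return FieldImage(hoechst, caspase, well=well, field_index=field_index), truth


def make_planted_scenario(
    n_responsive: int = 4,
    n_resistant: int = 9,
    n_pan: int = 13,
    n_inhibitors: int = 954,
    baseline_score: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
    effect_responsive: float = 0.20,
    effect_resistant: float = 0.30,
    effect_pan: float = 0.60,
) -> ScreenScenario:
    """Scenario with category hits planted at random library positions.

    Defaults mirror the screen's reported category counts (4 parental-only,
    9 resistant-only, 13 pan-line hits among 954 inhibitors).
    """
    rng = _rng(seed, "screen")
    n_hits = n_responsive + n_resistant + n_pan
    ids = [f"miR-inh-{i:04d}" for i in range(1, n_inhibitors + 1)]
    if n_hits > n_inhibitors:
        raise ValueError("more planted hits than inhibitors")
    chosen = rng.choice(n_inhibitors, size=n_hits, replace=False)
    lo = baseline_score * 0.6  # "off" lines sit below baseline, far from thresholds
    planted: dict[str, tuple[str, dict[str, float]]] = {}
    k = 0
    for _ in range(n_responsive):
        planted[ids[chosen[k]]] = (
            "responsive_only",
            {"MCF7": effect_responsive, "TamR": lo, "LTED": lo},
        )
        k += 1
    for _ in range(n_resistant):
        planted[ids[chosen[k]]] = (
            "resistant_only",
            {"MCF7": baseline_score, "TamR": effect_resistant, "LTED": effect_resistant},
        )
        k += 1
    for _ in range(n_pan):
        planted[ids[chosen[k]]] = (
            "pan",
            {"MCF7": effect_pan, "TamR": effect_pan, "LTED": effect_pan},
        )
        k += 1
    return ScreenScenario(
        n_inhibitors=n_inhibitors,
        baseline_score=baseline_score,
        noise_sd=noise_sd,
        planted=planted,
    )


def gen_screen_table(
    scenario: ScreenScenario, seed: int
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Per-well apoptotic-score table for the full screen layout.

    Returns one row per (inhibitor, cell line, replicate) plus control wells
    (mock transfection, negative-control inhibitor, cell-death control), and
    a truth map inhibitor id -> planted category ('none' if unplanted).
    Scores are planted (or baseline) means plus Gaussian replicate noise,
    clamped to [0, 1].
    """
    rng = _rng(seed, "screen")
    rows = []
    ids = scenario.inhibitor_ids()
    truth = {inh: scenario.planted.get(inh, ("none", {}))[0] for inh in ids}
    ctrl_mean = {"mock": scenario.baseline_score, "neg_ctrl": scenario.baseline_score, "death_ctrl": 0.9}

    for line in scenario.cell_lines:
        for rep in range(1, scenario.n_replicates + 1):
            widx = 0
            plate = f"{line}_rep{rep}"
            for inh in ids:
                widx += 1
                cat, per_line = scenario.planted.get(inh, ("none", {}))
                mean = per_line.get(line, scenario.baseline_score)
                score = mean + (rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd else 0.0)
                rows.append(
                    {
                        "well": f"{plate}_W{widx:04d}",
                        "cell_line": line,
                        "inhibitor_id": inh,
                        "role": "sample",
                        "replicate": rep,
                        "apoptotic_score": float(np.clip(score, 0.0, 1.0)),
                    }
                )
            if scenario.include_controls:
                for role in CONTROL_ROLES:
                    widx += 1
                    score = ctrl_mean[role] + (
                        rng.normal(0.0, scenario.noise_sd) if scenario.noise_sd else 0.0
                    )
                    rows.append(
                        {
                            "well": f"{plate}_W{widx:04d}",
                            "cell_line": line,
                            "inhibitor_id": role,
                            "role": role,
                            "replicate": rep,
                            "apoptotic_score": float(np.clip(score, 0.0, 1.0)),
                        }
                    )
    return pd.DataFrame(rows), truth


def gen_targets_and_degs(
    n_genes: int = 2000,
    n_targets: int = 1075,
    n_planted_direct: int = 9,
    seed: int = 0,
    p_threshold: float = 0.05,
    n_offtarget_degs: int = 200,
) -> tuple[pd.DataFrame, dict[str, list[str]], set[str]]:
    """DEG table + per-source target lists with a planted direct-target set.

    Exactly the ``n_planted_direct`` planted genes are both significant
    (p < p_threshold) and members of the target union; other target genes get
    p >= p_threshold, and ``n_offtarget_degs`` non-target genes are made
    significant so the DEG side is realistically large. At least two of the
    four evidence sources are populated.
    """
    if n_targets > n_genes:
        raise ValueError("n_targets exceeds n_genes")
    if n_planted_direct > n_targets:
        raise ValueError("cannot plant more direct targets than target genes")
    if n_planted_direct + n_offtarget_degs > n_genes:
        raise ValueError("infeasible significant-gene counts")
    rng = _rng(seed, "targets")

    genes = [f"GENE{i:05d}" for i in range(1, n_genes + 1)]
    perm = rng.permutation(n_genes)
    target_idx = perm[:n_targets]
    planted_idx = target_idx[:n_planted_direct]
    nontarget_idx = perm[n_targets:]
    offtarget_sig_idx = nontarget_idx[:n_offtarget_degs]

    planted = {genes[i] for i in planted_idx}
    pvals = np.empty(n_genes)
    # default: null p-values strictly above the threshold
    pvals[:] = rng.uniform(p_threshold * 1.2, 1.0, size=n_genes)
    pvals[planted_idx] = rng.uniform(1e-6, p_threshold * 0.5, size=n_planted_direct)
    pvals[offtarget_sig_idx] = rng.uniform(1e-6, p_threshold * 0.8, size=n_offtarget_degs)
    log2fc = rng.normal(0.0, 1.5, size=n_genes)

    from statsmodels.stats.multitest import multipletests

    fdr = multipletests(pvals, method="fdr_bh")[1]
    degs = pd.DataFrame(
        {"gene": genes, "log2fc": log2fc, "pvalue": pvals, "fdr": fdr}
    )

    # assign each target gene to 1-3 evidence sources; guarantee >=2 sources used
    sources: dict[str, list[str]] = {s: [] for s in TARGET_SOURCES}
    for j, gi in enumerate(target_idx):
        n_src = 1 + int(rng.integers(0, 3))
        for s in rng.choice(len(TARGET_SOURCES), size=n_src, replace=False):
            sources[TARGET_SOURCES[s]].append(genes[gi])
        if j < 2:  # pin the first two targets to distinct sources
            sources[TARGET_SOURCES[j]].append(genes[gi])
    sources = {s: sorted(set(g)) for s, g in sources.items() if g}
    return degs, sources, planted


@dataclass(frozen=True)
class DoseResponseTruth:
    """Known single-agent effects and planted HSA surplus of a surface."""

    effect_a: tuple[float, ...]
    effect_b: tuple[float, ...]
    surplus: Mapping[tuple[int, int], float]


def gen_dose_response(
    doses_a: Sequence[float],
    doses_b: Sequence[float],
    seed: int = 0,
    ec50_a: float | None = None,
    ec50_b: float | None = None,
    emax_a: float = 0.7,
    emax_b: float = 0.6,
    hill: float = 1.5,
    planted_surplus: Mapping[tuple[int, int], float] | None = None,
) -> tuple["pd.DataFrame", DoseResponseTruth]:
    """Combination-effect matrix built on monotone Hill single-agent curves.

    Without ``planted_surplus`` every combination cell equals the larger
    single-agent effect (the highest-single-agent reference), so the HSA
    surplus is identically zero by construction; planted cells exceed the
    reference by the stated amount. Returns a DataFrame indexed by doses_a
    with doses_b columns, plus the truth record.
    """
    doses_a = list(doses_a)
    doses_b = list(doses_b)
    if not doses_a or not doses_b:
        raise ValueError("empty dose list")
    if doses_a[0] != 0 or doses_b[0] != 0:
        raise ValueError("dose grids must start at 0")
    if sorted(doses_a) != doses_a or sorted(doses_b) != doses_b:
        raise ValueError("dose grids must be ascending")

    def hill_curve(doses: list[float], ec50: float, emax: float) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        with np.errstate(divide="ignore"):
            e = emax * d**hill / (ec50**hill + d**hill)
        e[d == 0] = 0.0
        return e

    ec50_a = ec50_a if ec50_a is not None else (np.median(doses_a[1:]) if len(doses_a) > 1 else 1.0)
    ec50_b = ec50_b if ec50_b is not None else (np.median(doses_b[1:]) if len(doses_b) > 1 else 1.0)
    ea = hill_curve(doses_a, ec50_a, emax_a)
    eb = hill_curve(doses_b, ec50_b, emax_b)

    effect = np.maximum.outer(ea, eb)
    planted_surplus = dict(planted_surplus or {})
    for (i, j), extra in planted_surplus.items():
        if i == 0 or j == 0:
            raise ValueError("cannot plant surplus on a single-agent row/column")
        effect[i, j] = min(effect[i, j] + extra, 1.0)
    mat = pd.DataFrame(effect, index=pd.Index(doses_a, name="dose_a"), columns=pd.Index(doses_b, name="dose_b"))
    truth = DoseResponseTruth(tuple(ea), tuple(eb), planted_surplus)
    return mat, truth


def truth_round_trip(truth: FieldTruth) -> FieldTruth:
    """Serialize a field truth record to plain dict-of-builtins and back."""
    d = dataclasses.asdict(truth)
    return FieldTruth(
        n_nuclei=d["n_nuclei"],
        centers=tuple(tuple(c) for c in d["centers"]),
        radii=tuple(d["radii"]),
        apoptotic_ids=frozenset(d["apoptotic_ids"]),
        apoptotic_fraction=d["apoptotic_fraction"],
    )
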