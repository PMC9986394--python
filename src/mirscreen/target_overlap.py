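"""Direct-target nomination by DEG x target-database intersection.

Candidate direct miRNA targets are the genes that are both differentially
expressed (raw p-value below a threshold, strictly) and present in the
union of predicted (e.g. miRDB, TargetScan) and experimentally validated
(e.g. AGO-PAR-CLIP, miRTarBase) target sets, with per-gene provenance.

Gene symbols are matched case-insensitively and exactly; no alias
resolution is attempted (that would require an external dictionary), which
is a documented limitation. Direction of change is carried through but not
filtered on — direct targets may be up- or down-regulated after inhibition.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd


def _norm(gene: str) -> str:
    g = str(gene).strip().upper()
    if not g:
        raise ValueError("empty gene symbol")
    return g


def build_target_union(source_lists: dict[str, list[str]]) -> dict[str, set[str]]:
    """Union of per-source gene lists with per-gene source provenance.

    Symbols are case-normalized; duplicates within a source count once.
    """
    union: dict[str, set[str]] = {}
    for source, genes in source_lists.items():
        for g in genes:
            union.setdefault(_norm(g), set()).add(source)
    return union


def load_source_dir(path: str | Path) -> dict[str, list[str]]:
    """Read one single-column TSV per evidence source, named by filename."""
    out: dict[str, list[str]] = {}
    for f in sorted(Path(path).glob("*.tsv")):
        genes = [ln.strip() for ln in f.read_text().splitlines() if ln.strip()]
        out[f.stem] = genes
    return out


def candidate_direct_targets(
    degs: pd.DataFrame,
    union: dict[str, set[str]],
    p_threshold: float = 0.05,
    p_column: str = "pvalue",
) -> pd.DataFrame:
    """Genes with p < p_threshold (strict) AND membership in the target union.

    ``degs`` needs columns gene, log2fc and the chosen p column ("pvalue" by
    default; pass "fdr" to intersect on adjusted values instead). Returns
    one row per candidate, sorted by the p column ascending, with a
    semicolon-joined ``sources`` provenance column.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must lie in (0,1)")
    if p_column not in degs.columns:
        raise ValueError(f"DEG table lacks column {p_column!r}")
    df = degs.copy()
    df["gene"] = df["gene"].map(_norm)
    sig = df[df[p_column] < p_threshold]
    hits = sig[sig["gene"].isin(union.keys())].copy()
    hits["sources"] = hits["gene"].map(lambda g: ";".join(sorted(union[g])))
    return hits.sort_values(p_column, kind="mergesort").reset_index(drop=True)
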