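"""Expressed-gene filtering, fold changes, differential calls, trinary
pattern coding/grouping and sample correlation/clustering."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core.types import AnalysisConfig, ExpressionMatrix

UP, DOWN, INVARIANT = "1", "0", "2"


@dataclass(frozen=True)
class Comparison:
    """A labelled numerator-vs-denominator sample-group contrast."""

    label: str
    numerator: tuple[str, ...]
    denominator: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise ValueError(f"comparison {self.label!r}: empty sample group")
        if set(self.numerator) & set(self.denominator):
            raise ValueError(f"comparison {self.label!r}: groups overlap")


@dataclass
class FoldChangeTable:
    gene_ids: list[str]
    comparisons: list[Comparison]
    log2fc: np.ndarray  # genes x comparisons

    def __post_init__(self) -> None:
        if self.log2fc.shape != (len(self.gene_ids), len(self.comparisons)):
            raise ValueError("log2fc shape inconsistent with gene/comparison lists")
        if not np.isfinite(self.log2fc).all():
            raise ValueError("non-finite log2 fold changes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.log2fc, index=self.gene_ids, columns=[c.label for c in self.comparisons]
        )


@dataclass(frozen=True)
class PatternCode:
    """Per-gene trinary digit string: one digit per ordered comparison.

    '1' = upregulated, '0' = downregulated, '2' = invariant.
    """

    gene_id: str
    code: str

    def __post_init__(self) -> None:
        if set(self.code) - {"0", "1", "2"}:
            raise ValueError(f"invalid pattern code {self.code!r}")


@dataclass
class PatternGroups:
    groups: dict[str, list[str]]  # code -> gene ids
    retained: list[str]  # changing codes above the size threshold
    summaries: pd.DataFrame | None = None  # per retained group: fc quartiles

    def census(self) -> dict[str, int]:
        return {code: len(g) for code, g in sorted(self.groups.items())}


def filter_expressed(m: ExpressionMatrix, cfg: AnalysisConfig | None = None) -> list[str]:
    """Genes whose maximum log2 intensity across samples reaches the
    expressed threshold (inclusive)."""
    cfg = cfg or AnalysisConfig()
    keep = m.values.max(axis=1) >= cfg.expressed_min_log2
    return [g for g, k in zip(m.gene_ids, keep) if k]


def stage_comparisons(m: ExpressionMatrix, induced: bool | None = None) -> list[Comparison]:
    """Consecutive-stage contrasts in the order stages appear in the samples.

    Optionally restricted to samples with the given induction status.
    """
    stages: list[str] = []
    for s in m.samples:
        if induced is not None and s.induced != induced:
            continue
        if s.stage not in stages:
            stages.append(s.stage)
    if len(stages) < 2:
        raise ValueError("need at least two stages for stage comparisons")
    groups = {
        st: tuple(
            s.label
            for s in m.samples
            if s.stage == st and (induced is None or s.induced == induced)
        )
        for st in stages
    }
    return [
        Comparison(f"{b}_vs_{a}", groups[b], groups[a])
        for a, b in zip(stages[:-1], stages[1:])
    ]


def fold_changes(m: ExpressionMatrix, comparisons: Sequence[Comparison]) -> FoldChangeTable:
    """Per-gene log2 fold change: mean(numerator) - mean(denominator)."""
    cols = []
    for c in comparisons:
        num = m.sample_columns(c.numerator).mean(axis=1)
        den = m.sample_columns(c.denominator).mean(axis=1)
        cols.append(num - den)
    return FoldChangeTable(list(m.gene_ids), list(comparisons), np.column_stack(cols))


def call_differential(
    fc: FoldChangeTable,
    pvalues: np.ndarray | None = None,
    cfg: AnalysisConfig | None = None,
) -> dict[str, dict[str, set[str]]]:
    """Up/down gene sets per comparison.

    Up iff log2fc >= log2(fold_threshold) (inclusive: "at least twofold"),
    down symmetrically; when per-gene p-values are given, a call also needs
    p <= p_cutoff.  Everything else is invariant.
    """
    cfg = cfg or AnalysisConfig()
    thr = np.log2(cfg.fold_threshold)
    if pvalues is not None:
        pvalues = np.asarray(pvalues, dtype=float)
        if pvalues.shape[0] != len(fc.gene_ids):
            raise ValueError("pvalues not aligned with genes")
        sig = pvalues <= cfg.p_cutoff
    else:
        sig = np.ones(len(fc.gene_ids), dtype=bool)
    out: dict[str, dict[str, set[str]]] = {}
    gene_arr = np.asarray(fc.gene_ids)
    for j, c in enumerate(fc.comparisons):
        col = fc.log2fc[:, j]
        up = (col >= thr) & sig
        down = (col <= -thr) & sig
        out[c.label] = {
            "up": set(gene_arr[up]),
            "down": set(gene_arr[down]),
            "invariant": set(gene_arr[~(up | down)]),
        }
    return out


def trinarize(
    fc: FoldChangeTable,
    pvalues: np.ndarray | None = None,
    cfg: AnalysisConfig | None = None,
) -> list[PatternCode]:
    """One trinary digit per comparison, per gene, from the differential calls."""
    calls = call_differential(fc, pvalues, cfg)
    codes = []
    for i, g in enumerate(fc.gene_ids):
        digits = []
        for c in fc.comparisons:
            if g in calls[c.label]["up"]:
                digits.append(UP)
            elif g in calls[c.label]["down"]:
                digits.append(DOWN)
            else:
                digits.append(INVARIANT)
        codes.append(PatternCode(g, "".join(digits)))
    return codes


def group_patterns(
    codes: Sequence[PatternCode],
    cfg: AnalysisConfig | None = None,
    fc: FoldChangeTable | None = None,
    strict_min: bool = True,
) -> PatternGroups:
    """Group genes by exact pattern code.

    ``retained`` holds the changing codes (not all-invariant) whose group
    size exceeds ``min_group_size`` — strictly greater by default ("more
    than a minimum of 30 genes"); set ``strict_min=False`` for >=.  The
    full census is always available.  When a fold-change table is supplied,
    per-comparison quartile summaries are computed for retained groups.
    """
    cfg = cfg or AnalysisConfig()
    lengths = {len(c.code) for c in codes}
    if len(lengths) > 1:
        raise ValueError("pattern codes have differing lengths")
    groups: dict[str, list[str]] = {}
    for c in codes:
        groups.setdefault(c.code, []).append(c.gene_id)
    all_invariant = INVARIANT * (lengths.pop() if lengths else 0)
    retained = sorted(
        code
        for code, genes in groups.items()
        if code != all_invariant
        and (len(genes) > cfg.min_group_size if strict_min else len(genes) >= cfg.min_group_size)
    )
    summaries = None
    if fc is not None and retained:
        frame = fc.to_frame()
        rows = []
        for code in retained:
            sub = frame.loc[groups[code]]
            for comp in frame.columns:
                q1, q2, q3 = np.percentile(sub[comp], [25, 50, 75])
                rows.append(
                    {"code": code, "comparison": comp, "n": len(sub),
                     "q1": q1, "median": q2, "q3": q3}
                )
        summaries = pd.DataFrame(rows)
    return PatternGroups(groups, retained, summaries)


# ---------------------------------------------------------------------------
# Sample correlation and clustering
# ---------------------------------------------------------------------------

def sample_correlation(
    values: np.ndarray | pd.DataFrame,
    labels: Sequence[str] | None = None,
    linkage_method: str = "average",
) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Pearson correlation between samples plus a deterministic dendrogram.

    ``values`` is genes x samples.  Agglomerative clustering uses Euclidean
    distance on the sample columns with the given linkage (average for
    expression, complete for TF binding).  Returns (correlation matrix,
    leaf-order labels, scipy linkage matrix).  Samples are processed in
    sorted-label order so that distance ties resolve deterministically.
    """
    if isinstance(values, pd.DataFrame):
        labels = list(values.columns)
        values = values.to_numpy(dtype=float)
    if labels is None:
        labels = [f"s{i}" for i in range(values.shape[1])]
    if values.shape[1] < 2:
        raise ValueError("need at least two samples")
    order = np.argsort(labels)
    labels = [labels[i] for i in order]
    values = values[:, order]
    sds = values.std(axis=0)
    if (sds == 0).any():
        bad = labels[int(np.flatnonzero(sds == 0)[0])]
        raise ValueError(f"zero-variance sample {bad!r}")
    corr = np.corrcoef(values, rowvar=False)
    corr_df = pd.DataFrame(corr, index=labels, columns=labels)
    link = hierarchy.linkage(pdist(values.T, metric="euclidean"), method=linkage_method)
    leaf_order = [labels[i] for i in hierarchy.leaves_list(link)]
    return corr_df, leaf_order, link


def dendrogram_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a newick string with branch lengths."""
    tree = hierarchy.to_tree(link)

    def walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        ld = node.dist - left.dist
        rd = node.dist - right.dist
        return f"({walk(left)}:{ld:.6g},{walk(right)}:{rd:.6g})"

    return walk(tree) + ";"
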