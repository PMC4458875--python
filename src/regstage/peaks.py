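"""Summit-proximity peak comparison, union merging, Venn decomposition and
peak-to-gene allocation.

Two peaks overlap when their summits lie within ``summit_window`` bp on the
same chromosome (inclusive bound).  Merging is single-linkage clustering of
summits at that threshold: chaining is accepted and documented — callers
that must avoid it space their peaks accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core.types import AnalysisConfig, GeneModel, GenomicInterval, Peak, PeakSet


def make_signature(labels: Iterable[str]) -> str:
    """Canonical signature for a set of member labels.

    Single-character labels concatenate ("ABC"); longer labels join with
    '+' ("HE+prog").
    """
    labs = sorted(set(labels))
    if all(len(l) == 1 for l in labs):
        return "".join(labs)
    return "+".join(labs)


@dataclass
class UnionPeak:
    """A single-linkage cluster of peaks across sets.

    The representative summit is the floor of the member-summit median; the
    representative interval spans all member intervals.
    """

    representative: Peak
    members: dict[str, list[Peak]]
    signature: str

    @property
    def summit(self) -> int:
        return self.representative.summit

    @property
    def chrom(self) -> str:
        return self.representative.chrom


@dataclass
class PeakGeneAssignment:
    peak_name: str
    gene_id: str | None
    category: str  # promoter | intragenic | intergenic | unassigned
    distance: int  # summit -> TSS, signed by gene strand; 0 when unassigned

    def __post_init__(self) -> None:
        if (self.category == "unassigned") != (self.gene_id is None):
            raise ValueError("category 'unassigned' iff gene_id is None")


# ---------------------------------------------------------------------------
# Summit-proximity overlap
# ---------------------------------------------------------------------------

def summit_overlap(
    a: PeakSet, b: PeakSet, window: int = 200
) -> tuple[int, list[tuple[Peak, Peak, int]]]:
    """Count peaks of ``a`` with >= 1 partner in ``b`` within ``window`` bp.

    Returns ``(count, pairs)`` where ``pairs`` holds, for each overlapping
    peak of ``a``, its nearest partner in ``b`` and the signed summit
    distance.  The count is directional; swap arguments for the
    counterpart.
    """
    b_by_chrom = b.summits_by_chrom()
    b_peaks_by_chrom: dict[str, list[Peak]] = {}
    for p in b:
        b_peaks_by_chrom.setdefault(p.chrom, []).append(p)
    count = 0
    pairs: list[tuple[Peak, Peak, int]] = []
    for pa in a:
        summits = b_by_chrom.get(pa.chrom)
        if summits is None or len(summits) == 0:
            continue
        i = int(np.searchsorted(summits, pa.summit))
        best_j, best_d = -1, None
        for j in (i - 1, i):
            if 0 <= j < len(summits):
                d = int(summits[j]) - pa.summit
                if best_d is None or abs(d) < abs(best_d):
                    best_j, best_d = j, d
        if best_d is not None and abs(best_d) <= window:
            count += 1
            pairs.append((pa, b_peaks_by_chrom[pa.chrom][best_j], best_d))
    return count, pairs


# ---------------------------------------------------------------------------
# Union merge (single linkage on summits)
# ---------------------------------------------------------------------------

def merge_union(sets: Sequence[PeakSet], window: int = 200) -> list[UnionPeak]:
    """Merge peaks across sets by single-linkage summit clustering.

    Consecutive summits (per chromosome, all sets pooled) are linked when
    their distance is <= ``window``; every connected chain forms one
    :class:`UnionPeak`.  The result is independent of the order of the
    input sets.
    """
    if not sets:
        raise ValueError("merge_union requires at least one PeakSet")
    entries = []  # (chrom, summit, label, peak)
    for ps in sorted(sets, key=lambda s: s.label):
        for p in ps:
            entries.append((p.chrom, p.summit, ps.label, p))
    entries.sort(key=lambda e: (e[0], e[1], e[2], e[3].name))

    clusters: list[list[tuple[str, Peak]]] = []
    prev_chrom, prev_summit = None, None
    for chrom, summit, label, peak in entries:
        if prev_chrom != chrom or summit - prev_summit > window:
            clusters.append([])
        clusters[-1].append((label, peak))
        prev_chrom, prev_summit = chrom, summit

    union: list[UnionPeak] = []
    for idx, cluster in enumerate(clusters):
        members: dict[str, list[Peak]] = {}
        for label, peak in cluster:
            members.setdefault(label, []).append(peak)
        summits = np.array([p.summit for _, p in cluster])
        rep_summit = int(np.floor(np.median(summits)))
        start = min(p.start for _, p in cluster)
        end = max(p.end for _, p in cluster)
        chrom = cluster[0][1].chrom
        rep = Peak(GenomicInterval(chrom, start, end), rep_summit, f"u{idx}")
        union.append(UnionPeak(rep, members, make_signature(members)))
    return union


def venn_counts(union: Sequence[UnionPeak]) -> tuple[dict[str, int], dict[str, float]]:
    """Signature census of a union, plus per-set shared percentages.

    The per-set percentage is the fraction of clusters containing that set
    which also contain at least one other set.
    """
    counts: dict[str, int] = {}
    per_set_total: dict[str, int] = {}
    per_set_shared: dict[str, int] = {}
    for up in union:
        counts[up.signature] = counts.get(up.signature, 0) + 1
        labels = list(up.members)
        for l in labels:
            per_set_total[l] = per_set_total.get(l, 0) + 1
            if len(labels) > 1:
                per_set_shared[l] = per_set_shared.get(l, 0) + 1
    percentages = {
        l: 100.0 * per_set_shared.get(l, 0) / per_set_total[l] for l in per_set_total
    }
    return counts, percentages


def union_as_peakset(union: Sequence[UnionPeak], label: str = "union") -> PeakSet:
    """The representative peaks of a union, as a PeakSet (the bootstrap pool)."""
    return PeakSet(label, [up.representative for up in union])


# ---------------------------------------------------------------------------
# Peak-to-gene allocation
# ---------------------------------------------------------------------------

def _promoter_bounds(gene: GeneModel, cfg: AnalysisConfig) -> tuple[int, int]:
    # Inclusive position bounds for the strand-aware promoter window.
    if gene.strand == "+":
        return gene.tss - cfg.promoter_upstream, gene.tss + cfg.promoter_downstream
    return gene.tss - cfg.promoter_downstream, gene.tss + cfg.promoter_upstream


def _signed_distance(summit: int, gene: GeneModel) -> int:
    # Positive = downstream of the TSS in the gene's reading direction.
    return summit - gene.tss if gene.strand == "+" else gene.tss - summit


def annotate_peaks(
    peaks: PeakSet, genes: Sequence[GeneModel], cfg: AnalysisConfig | None = None
) -> list[PeakGeneAssignment]:
    """Allocate each peak (by its summit) to a gene.

    Precedence: promoter (strand-aware window, upstream ``promoter_upstream``
    / downstream ``promoter_downstream`` of the TSS, bounds inclusive) >
    intragenic (summit inside the gene body) > intergenic (nearest TSS
    within ``intergenic_max_dist``, inclusive).  Ties break by smallest
    |summit - TSS| then lexicographic gene id.  Peaks matching nothing are
    unassigned.
    """
    cfg = cfg or AnalysisConfig()
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    index: dict[str, dict[str, np.ndarray]] = {}
    for chrom, gl in genes_by_chrom.items():
        gl.sort(key=lambda g: (g.tss, g.gene_id))
        index[chrom] = {
            "tss": np.array([g.tss for g in gl], dtype=np.int64),
            "start": np.array([g.interval.start for g in gl], dtype=np.int64),
            "end": np.array([g.interval.end for g in gl], dtype=np.int64),
            "plo": np.array([_promoter_bounds(g, cfg)[0] for g in gl], dtype=np.int64),
            "phi": np.array([_promoter_bounds(g, cfg)[1] for g in gl], dtype=np.int64),
        }

    out: list[PeakGeneAssignment] = []
    for p in peaks:
        gl = genes_by_chrom.get(p.chrom)
        if not gl:
            out.append(PeakGeneAssignment(p.name, None, "unassigned", 0))
            continue
        ix = index[p.chrom]
        s = p.summit
        tss_dist = np.abs(ix["tss"] - s)

        def pick(mask: np.ndarray) -> GeneModel:
            cand = np.flatnonzero(mask)
            order = sorted(cand, key=lambda i: (tss_dist[i], gl[i].gene_id))
            return gl[order[0]]

        promoter = (ix["plo"] <= s) & (s <= ix["phi"])
        if promoter.any():
            g = pick(promoter)
            out.append(PeakGeneAssignment(p.name, g.gene_id, "promoter", _signed_distance(s, g)))
            continue
        intragenic = (ix["start"] <= s) & (s < ix["end"])
        if intragenic.any():
            g = pick(intragenic)
            out.append(PeakGeneAssignment(p.name, g.gene_id, "intragenic", _signed_distance(s, g)))
            continue
        intergenic = tss_dist <= cfg.intergenic_max_dist
        if intergenic.any():
            g = pick(intergenic)
            out.append(PeakGeneAssignment(p.name, g.gene_id, "intergenic", _signed_distance(s, g)))
            continue
        out.append(PeakGeneAssignment(p.name, None, "unassigned", 0))
    return out


def distal_subset(
    peaks: PeakSet, assignments: Sequence[PeakGeneAssignment], label: str | None = None
) -> PeakSet:
    """The non-promoter peaks of ``peaks`` (the motif-analysis substrate)."""
    promoter_names = {a.peak_name for a in assignments if a.category == "promoter"}
    return PeakSet(
        label or f"{peaks.label}_distal",
        [p for p in peaks if p.name not in promoter_names],
    )
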