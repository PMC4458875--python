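"""Tag-count quantification over union peaks, per-million normalization,
composite tag-density profiles around summits and ChIP-sample correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core.types import AnalysisConfig, PeakSet, TagSet
from .expr import sample_correlation
from .peaks import UnionPeak

PER_MILLION = 1e6


@dataclass
class CountMatrix:
    """Raw and per-million-normalized tag counts over union peaks."""

    peak_ids: list[str]
    sample_labels: list[str]
    raw: np.ndarray  # peaks x samples, int
    totals: np.ndarray  # total tags per sample

    @property
    def normalized(self) -> np.ndarray:
        return self.raw / self.totals[None, :] * PER_MILLION

    def to_frame(self, normalized: bool = True) -> pd.DataFrame:
        vals = self.normalized if normalized else self.raw
        return pd.DataFrame(vals, index=self.peak_ids, columns=self.sample_labels)


@dataclass
class ProfileMatrix:
    """Mean per-peak tag density in fixed-width bins around summits,
    normalized per million total tags."""

    bin_centers: np.ndarray
    density: np.ndarray
    label: str = ""
    n_peaks: int = 0

    def __post_init__(self) -> None:
        if self.bin_centers.shape != self.density.shape:
            raise ValueError("bin_centers and density shapes differ")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_center": self.bin_centers, self.label or "density": self.density})


def count_tags(tags: TagSet, union: list[UnionPeak]) -> np.ndarray:
    """Tags per union peak, counted over the representative interval.

    A tag belongs to a peak iff its position lies in [start, end); where
    representative intervals overlap, the tag goes to the first peak in
    (chrom, start) order only.
    """
    order = sorted(range(len(union)), key=lambda i: (union[i].chrom, union[i].representative.start))
    counts = np.zeros(len(union), dtype=np.int64)
    covered_until: dict[str, int] = {}
    for i in order:
        up = union[i]
        pos = tags.positions.get(up.chrom)
        if pos is None:
            continue
        start = max(up.representative.start, covered_until.get(up.chrom, 0))
        end = up.representative.end
        if start < end:
            counts[i] = np.searchsorted(pos, end, side="left") - np.searchsorted(
                pos, start, side="left"
            )
        covered_until[up.chrom] = max(covered_until.get(up.chrom, 0), end)
    return counts


def count_matrix(tag_sets: list[TagSet], union: list[UnionPeak]) -> CountMatrix:
    raw = np.column_stack([count_tags(t, union) for t in tag_sets])
    return CountMatrix(
        [up.representative.name for up in union],
        [t.label for t in tag_sets],
        raw,
        np.array([t.total_count for t in tag_sets], dtype=float),
    )


def composite_profile(
    tags: TagSet, peaks: PeakSet, cfg: AnalysisConfig | None = None
) -> ProfileMatrix:
    """Mean tag density in ``profile_bin``-bp bins over ±``profile_flank``
    around peak summits, per-million normalized.

    Bins are left-closed ``[edge, edge + bin)``; with the defaults this is
    200 bins centred at -4975 … +4975.
    """
    cfg = cfg or AnalysisConfig()
    if len(peaks) == 0:
        raise ValueError("composite_profile requires at least one peak")
    flank, width = cfg.profile_flank, cfg.profile_bin
    n_bins = (2 * flank) // width
    rel_edges = -flank + width * np.arange(n_bins + 1)
    total = np.zeros(n_bins, dtype=np.int64)
    for p in peaks:
        pos = tags.positions.get(p.chrom)
        if pos is None or len(pos) == 0:
            continue
        idx = np.searchsorted(pos, p.summit + rel_edges, side="left")
        total += np.diff(idx)
    mean_per_peak = total / len(peaks)
    density = mean_per_peak / (tags.total_count / PER_MILLION)
    centers = (rel_edges[:-1] + rel_edges[1:]) / 2.0
    return ProfileMatrix(centers, density, label=tags.label, n_peaks=len(peaks))


def peak_sample_correlation(counts: CountMatrix):
    """Pearson correlation of normalized counts between ChIP samples, with
    Euclidean/complete-linkage clustering (the TF-binding convention)."""
    return sample_correlation(
        counts.to_frame(normalized=True), linkage_method="complete"
    )


def profile_compare(a: ProfileMatrix, b: ProfileMatrix, central_bp: int = 500) -> pd.DataFrame:
    """Bin-wise difference and ratio of two profiles (a - b, b / a).

    The summary attribute ``attrs['central_ratio']`` is the ratio of mean
    densities over the central ±``central_bp``, the headline reduction
    statistic.
    """
    if a.bin_centers.shape != b.bin_centers.shape or not np.array_equal(
        a.bin_centers, b.bin_centers
    ):
        raise ValueError("profiles have mismatched binning")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(a.density > 0, b.density / a.density, np.nan)
    df = pd.DataFrame(
        {
            "bin_center": a.bin_centers,
            "density_a": a.density,
            "density_b": b.density,
            "difference": a.density - b.density,
            "ratio_b_over_a": ratio,
        }
    )
    central = np.abs(a.bin_centers) <= central_bp
    mean_a = a.density[central].mean()
    mean_b = b.density[central].mean()
    df.attrs["central_ratio"] = float(mean_b / mean_a) if mean_a > 0 else float("nan")
    df.attrs["central_difference"] = float(mean_a - mean_b)
    return df
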