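"""Shared domain types and the analysis configuration.

All genomic coordinates are 0-based, half-open (BED convention).  GTF input
is converted at the read boundary; nothing downstream ever sees 1-based
coordinates.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, fields, asdict
from typing import Iterable, Iterator, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq enrichment region with an explicit summit.

    The summit is an absolute 0-based position and must lie inside the
    interval; it is the anchor for every overlap, annotation and profile
    computation.
    """

    interval: GenomicInterval
    summit: int
    name: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if not self.interval.contains(self.summit):
            raise ValueError(
                f"summit {self.summit} outside interval "
                f"{self.interval.chrom}:{self.interval.start}-{self.interval.end} "
                f"for peak {self.name!r}"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


class PeakSet:
    """A labelled, summit-sorted collection of peaks.

    Peaks are kept sorted by ``(chrom, summit)`` so that summit-proximity
    operations can rely on ordered traversal.
    """

    def __init__(self, label: str, peaks: Iterable[Peak]):
        if not label:
            raise ValueError("PeakSet label must be non-empty")
        self.label = label
        self.peaks: list[Peak] = sorted(peaks, key=lambda p: (p.chrom, p.summit, p.name))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i: int) -> Peak:
        return self.peaks[i]

    def summits_by_chrom(self) -> dict[str, np.ndarray]:
        """Sorted summit arrays keyed by chromosome."""
        out: dict[str, list[int]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p.summit)
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def __repr__(self) -> str:
        return f"PeakSet({self.label!r}, n={len(self)})"


@dataclass(frozen=True)
class GeneModel:
    """A strand-aware gene body with its derived TSS.

    The TSS is ``start`` on the + strand and ``end - 1`` on the - strand.
    """

    gene_id: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r} requires strand + or -")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")

    @property
    def tss(self) -> int:
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand


class TagSet:
    """Aligned-tag positions (fragment midpoints), sorted per chromosome."""

    def __init__(self, label: str, positions: dict[str, Sequence[int]]):
        self.label = label
        self.positions: dict[str, np.ndarray] = {
            c: np.sort(np.asarray(v, dtype=np.int64)) for c, v in positions.items()
        }
        self.total_count = int(sum(len(v) for v in self.positions.values()))

    def __len__(self) -> int:
        return self.total_count

    def __repr__(self) -> str:
        return f"TagSet({self.label!r}, n={self.total_count})"


@dataclass(frozen=True)
class SampleMeta:
    label: str
    stage: str
    induced: bool
    replicate: int


class ExpressionMatrix:
    """Log2 intensities, genes x samples, with per-sample metadata.

    No missing values are permitted; dimensions and label uniqueness are
    validated at construction.
    """

    def __init__(
        self,
        gene_ids: Sequence[str],
        samples: Sequence[SampleMeta],
        values: np.ndarray,
    ):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(gene_ids), len(samples)):
            raise ValueError(
                f"values shape {values.shape} inconsistent with "
                f"{len(gene_ids)} genes x {len(samples)} samples"
            )
        if np.isnan(values).any():
            raise ValueError("expression matrix contains missing values")
        if len(set(gene_ids)) != len(gene_ids):
            raise ValueError("duplicate gene ids")
        labels = [s.label for s in samples]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate sample labels")
        self.gene_ids = list(gene_ids)
        self.samples = list(samples)
        self.values = values
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self._sample_index = {s.label: i for i, s in enumerate(self.samples)}

    @property
    def sample_labels(self) -> list[str]:
        return [s.label for s in self.samples]

    def sample_columns(self, labels: Sequence[str]) -> np.ndarray:
        try:
            idx = [self._sample_index[l] for l in labels]
        except KeyError as e:
            raise KeyError(f"unknown sample label {e.args[0]!r}") from None
        return self.values[:, idx]

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self._gene_index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), self.samples, self.values[idx])

    def __repr__(self) -> str:
        return f"ExpressionMatrix({len(self.gene_ids)} genes x {len(self.samples)} samples)"


class PWM:
    """A position count matrix with pseudocounted probabilities.

    ``counts`` is a 4 x L array in A, C, G, T row order.  Log-odds scores
    are in bits against the (default uniform) background.
    """

    def __init__(
        self,
        motif_id: str,
        counts: np.ndarray,
        background: Sequence[float] | None = None,
        pseudocount: float = 0.5,
    ):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix")
        if counts.shape[1] < 4:
            raise ValueError("motif length must be >= 4")
        if (counts < 0).any():
            raise ValueError(f"negative counts in motif {motif_id!r}")
        if pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")
        self.motif_id = motif_id
        self.counts = counts
        self.background = bg
        self.pseudocount = float(pseudocount)
        totals = counts.sum(axis=0)
        self.probs = (counts + pseudocount * bg[:, None]) / (totals + pseudocount)
        self.log_odds = np.log2(self.probs / bg[:, None])

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.counts.argmax(axis=0))

    def __repr__(self) -> str:
        return f"PWM({self.motif_id!r}, L={self.length})"


@dataclass
class AnalysisConfig:
    """Every numeric parameter of the pipeline, with published defaults."""

    summit_window: int = 200
    random_peak_width: int = 400
    n_bootstrap: int = 50_000
    pair_distance: int = 20
    fold_threshold: float = 2.0
    expressed_min_log2: float = 6.5
    p_cutoff: float = 0.001
    min_group_size: int = 30
    profile_flank: int = 5000
    profile_bin: int = 50
    intergenic_max_dist: int = 100_000
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for f in (
            "summit_window",
            "random_peak_width",
            "pair_distance",
            "profile_flank",
            "profile_bin",
            "intergenic_max_dist",
            "promoter_upstream",
            "promoter_downstream",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.fold_threshold <= 1:
            raise ValueError("fold_threshold must be > 1")
        if self.n_bootstrap <= 0:
            raise ValueError("n_bootstrap must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def digest(self) -> str:
        """Short stable hash of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
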