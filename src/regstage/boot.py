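"""Bootstrap significance for multi-set peak and gene overlaps.

The empirical null keeps one actual set and replaces the other two by
random draws of matching size from a pool (by default the merged union of
the actual sets), rotating the kept set round-robin across iterations; all
iterations are pooled into a single null mean/sd from which a z score and
a one-sided upper-tail normal P are derived.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

from .core.types import AnalysisConfig, GenomicInterval, Peak, PeakSet
from .peaks import UnionPeak, merge_union

logger = logging.getLogger(__name__)

_LN10 = np.log(10.0)


@dataclass
class BootstrapResult:
    """Observed statistic vs an empirical bootstrap null."""

    observed: int
    null_mean: float
    null_sd: float
    z: float
    p_one_sided: float
    log10_p: float
    n_iterations: int
    seed: int
    degenerate: bool = False
    rotation_stats: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "observed": self.observed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p_one_sided": self.p_one_sided,
            "log10_p": self.log10_p,
            "n_iterations": self.n_iterations,
            "seed": self.seed,
        }


def z_to_p(z: float) -> tuple[float, float]:
    """One-sided upper-tail standard normal probability for a z score.

    Returns ``(p, log10_p)``.  ``p`` is computed with the complementary
    error function (exact well below 1e-300); ``log10_p`` is computed in
    log space so it stays finite and accurate for arbitrarily large z,
    past the double-precision underflow point of ``p`` itself.
    """
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    p = float(0.5 * special.erfc(z / np.sqrt(2.0)))
    log10_p = float(stats.norm.logsf(z) / _LN10)
    if p == 0.0:  # underflow: recover what double precision allows
        p = float(10.0 ** max(log10_p, -323.0))
    return p, log10_p


def _finish(
    observed: int,
    null_stats: np.ndarray,
    n_iterations: int,
    seed: int,
    rotation_stats: dict,
) -> BootstrapResult:
    null_mean = float(null_stats.mean())
    null_sd = float(null_stats.std(ddof=1)) if len(null_stats) > 1 else 0.0
    if null_sd == 0.0:
        logger.warning(
            "bootstrap null has zero variance (mean=%.3f); z undefined", null_mean
        )
        return BootstrapResult(
            observed, null_mean, 0.0, float("nan"), float("nan"), float("nan"),
            n_iterations, seed, degenerate=True, rotation_stats=rotation_stats,
        )
    z = (observed - null_mean) / null_sd
    p, log10_p = z_to_p(z)
    return BootstrapResult(
        observed, null_mean, null_sd, float(z), p, log10_p,
        n_iterations, seed, rotation_stats=rotation_stats,
    )


# ---------------------------------------------------------------------------
# Random peak sets from the union pool
# ---------------------------------------------------------------------------

def sample_random_peakset(
    pool: list[UnionPeak] | PeakSet,
    k: int,
    width: int,
    rng: np.random.Generator,
    replace: bool = False,
    label: str = "random",
) -> PeakSet:
    """Draw ``k`` pool peaks, each emitted ``width`` bp wide, summit-centred."""
    reps = [up.representative for up in pool] if pool and isinstance(pool[0], UnionPeak) else list(pool)
    if not replace and k > len(reps):
        raise ValueError(f"cannot draw {k} peaks without replacement from pool of {len(reps)}")
    idx = rng.choice(len(reps), size=k, replace=replace)
    out = []
    for rank, i in enumerate(idx):
        src = reps[int(i)]
        start = max(0, src.summit - width // 2)
        end = start + width
        out.append(Peak(GenomicInterval(src.chrom, start, end), src.summit, f"{label}_{rank}"))
    return PeakSet(label, out)


# ---------------------------------------------------------------------------
# Peak-overlap bootstrap
# ---------------------------------------------------------------------------

def _encode_positions(
    peaksets_summits: list[tuple[list[str], list[int]]], window: int
) -> list[np.ndarray]:
    """Map (chrom, summit) pairs onto a single integer axis.

    Chromosomes are separated by a stride larger than any summit plus the
    window, so gap-based clustering never links across chromosomes.
    """
    chroms = sorted({c for cl, _ in peaksets_summits for c in cl})
    cidx = {c: i for i, c in enumerate(chroms)}
    max_pos = max((max(sl) for _, sl in peaksets_summits if sl), default=0)
    stride = max_pos + window + 2
    encoded = []
    for cl, sl in peaksets_summits:
        arr = np.array([cidx[c] * stride + s for c, s in zip(cl, sl)], dtype=np.int64)
        encoded.append(np.sort(arr))
    return encoded


def _triple_overlap_count(positions: np.ndarray, bits: np.ndarray, window: int) -> int:
    """Number of single-linkage clusters whose member bits OR to 7."""
    order = np.argsort(positions, kind="stable")
    pos = positions[order]
    b = bits[order]
    if len(pos) == 0:
        return 0
    breaks = np.flatnonzero(np.diff(pos) > window) + 1
    starts = np.concatenate(([0], breaks))
    merged = np.bitwise_or.reduceat(b, starts)
    return int((merged == 7).sum())


def bootstrap_peak_overlap(
    sets: list[PeakSet],
    cfg: AnalysisConfig | None = None,
    pool: list[UnionPeak] | PeakSet | None = None,
    n_iterations: int | None = None,
    seed: int | None = None,
    replace: bool = False,
) -> BootstrapResult:
    """Significance of the three-way summit overlap between three peak sets.

    The observed statistic is the number of union clusters (single-linkage
    summit merge at ``summit_window``) containing all three sets.  Each
    null iteration keeps one actual set (rotating round-robin) and replaces
    the other two by size-matched random draws from ``pool`` — by default
    the merged union of the three sets, as in the published procedure; an
    explicit pool (e.g. a known sampling frame in calibration experiments)
    may be supplied instead.
    """
    cfg = cfg or AnalysisConfig()
    if len(sets) != 3:
        raise ValueError("bootstrap_peak_overlap requires exactly three peak sets")
    if any(len(s) == 0 for s in sets):
        raise ValueError("all peak sets must be non-empty")
    window = cfg.summit_window
    n_iter = int(n_iterations if n_iterations is not None else cfg.n_bootstrap)
    seed = int(seed if seed is not None else cfg.rng_seed)
    rng = np.random.default_rng(seed)

    union = merge_union(sets, window)
    observed = sum(1 for up in union if len(up.members) == 3)

    if pool is None:
        pool_reps = [up.representative for up in union]
    elif pool and isinstance(pool[0], UnionPeak):
        pool_reps = [up.representative for up in pool]
    else:
        pool_reps = list(pool)

    per_set = [
        ([p.chrom for p in s], [p.summit for p in s]) for s in sets
    ]
    pool_cs = ([p.chrom for p in pool_reps], [p.summit for p in pool_reps])
    enc = _encode_positions(per_set + [pool_cs], window)
    enc_sets, enc_pool = enc[:3], enc[3]
    sizes = [len(s) for s in sets]
    n_pool = len(enc_pool)
    if not replace and max(sizes) > n_pool:
        raise ValueError("pool smaller than a set size in without-replacement mode")

    null_stats = np.empty(n_iter, dtype=np.int64)
    rot_stats: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for i in range(n_iter):
        rot = i % 3
        parts = [enc_sets[rot]]
        bits = [np.full(sizes[rot], 1 << rot, dtype=np.uint8)]
        for other in range(3):
            if other == rot:
                continue
            idx = rng.choice(n_pool, size=sizes[other], replace=replace)
            parts.append(enc_pool[idx])
            bits.append(np.full(sizes[other], 1 << other, dtype=np.uint8))
        stat = _triple_overlap_count(
            np.concatenate(parts), np.concatenate(bits), window
        )
        null_stats[i] = stat
        rot_stats[rot].append(stat)

    rotation_stats = {
        r: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
        for r, v in rot_stats.items()
        if v
    }
    return _finish(observed, null_stats, n_iter, seed, rotation_stats)


# ---------------------------------------------------------------------------
# Gene-overlap bootstrap
# ---------------------------------------------------------------------------

def bootstrap_gene_overlap(
    gene_sets: list[set[str]],
    universe: set[str],
    cfg: AnalysisConfig | None = None,
    n_iterations: int | None = None,
    seed: int | None = None,
    replace: bool = False,
) -> BootstrapResult:
    """Significance of a three-way gene-list intersection.

    Same rotate-one / randomize-two scheme as the peak bootstrap, with
    uniform size-matched draws from ``universe``.
    """
    cfg = cfg or AnalysisConfig()
    if len(gene_sets) != 3:
        raise ValueError("bootstrap_gene_overlap requires exactly three gene sets")
    for i, gs in enumerate(gene_sets):
        if not gs <= universe:
            raise ValueError(f"gene set {i} is not contained in the universe")
    n_iter = int(n_iterations if n_iterations is not None else cfg.n_bootstrap)
    seed = int(seed if seed is not None else cfg.rng_seed)
    rng = np.random.default_rng(seed)

    ids = sorted(universe)
    index = {g: i for i, g in enumerate(ids)}
    n = len(ids)
    member = np.zeros((3, n), dtype=np.uint8)
    for si, gs in enumerate(gene_sets):
        member[si, [index[g] for g in gs]] = 1
    observed = int((member.sum(axis=0) == 3).sum())
    sizes = [len(gs) for gs in gene_sets]

    null_stats = np.empty(n_iter, dtype=np.int64)
    rot_stats: dict[int, list[int]] = {0: [], 1: [], 2: []}
    for i in range(n_iter):
        rot = i % 3
        acc = member[rot].copy()
        for other in range(3):
            if other == rot:
                continue
            idx = rng.choice(n, size=sizes[other], replace=replace)
            acc[idx] += 1
        stat = int((acc == 3).sum())
        null_stats[i] = stat
        rot_stats[rot].append(stat)

    rotation_stats = {
        r: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0}
        for r, v in rot_stats.items()
        if v
    }
    return _finish(observed, null_stats, n_iter, seed, rotation_stats)
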