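"""PWM scanning in summit-centred windows, motif density profiles, pairwise
co-localization counting and the bootstrap z-score matrix for motif spacing.

Scanning is done on both strands with log2-odds scores in bits against an
order-0 background.  A motif instance's position is the centre of its
occupied interval, ``start + (L-1)/2``, reported as an offset from the peak
summit; pair distances are centre-to-centre.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core.types import AnalysisConfig, BASE_INDEX, PWM, Peak, PeakSet
from .boot import BootstrapResult, _finish, z_to_p
from .peaks import UnionPeak

DEFAULT_THRESHOLD_FRACTION = 0.8


@dataclass(frozen=True)
class MotifHit:
    peak_name: str
    motif_id: str
    center: float  # offset of the instance centre from the peak summit, bp
    strand: str
    score: float
    start: int  # absolute start of the instance (identity for dedup)


@dataclass
class ColocalizationMatrix:
    """Per-motif-pair observed counts and bootstrap z / P values."""

    motif_ids: list[str]
    pair_stats: dict[tuple[str, str], dict]  # canonical (a<=b) -> stats
    n_iterations: int
    seed: int
    pool_size: int
    order: list[str] = field(default_factory=list)  # clustered display order

    def get(self, a: str, b: str) -> dict:
        return self.pair_stats[tuple(sorted((a, b)))]

    def z_frame(self) -> pd.DataFrame:
        n = len(self.motif_ids)
        z = np.zeros((n, n))
        for i, a in enumerate(self.motif_ids):
            for j, b in enumerate(self.motif_ids):
                z[i, j] = self.get(a, b)["z"]
        return pd.DataFrame(z, index=self.motif_ids, columns=self.motif_ids)


def encode_sequences(seqs: Mapping[str, str]) -> dict[str, np.ndarray]:
    """Encode sequences as uint8 arrays (A=0, C=1, G=2, T=3, other=4)."""
    table = np.full(256, 4, dtype=np.uint8)
    for base, i in BASE_INDEX.items():
        table[ord(base)] = i
        table[ord(base.lower())] = i
    return {name: table[np.frombuffer(s.encode(), dtype=np.uint8)] for name, s in seqs.items()}


def _lookup_tables(pwm: PWM) -> tuple[np.ndarray, np.ndarray]:
    """(forward, reverse-complement) score lookups, shape (L, 5).

    Column 4 (ambiguous base) scores -inf so N-containing windows never hit.
    """
    L = pwm.length
    fwd = np.full((L, 5), -np.inf)
    fwd[:, :4] = pwm.log_odds.T
    rc = np.full((L, 5), -np.inf)
    rc[:, :4] = pwm.log_odds[::-1, ::-1].T  # complement bases, reverse positions
    return fwd, rc


def _scan_positions(window: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Score every start position of ``window`` against a (L,5) lookup."""
    L = table.shape[0]
    n = len(window) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(L):
        scores += table[j][window[j : j + n]]
    return scores


def _prune_overlapping(hits: list[MotifHit], length: int) -> list[MotifHit]:
    """Greedy non-overlap pruning by descending score (tandem-repeat dedup)."""
    kept: list[MotifHit] = []
    for h in sorted(hits, key=lambda h: (-h.score, h.start, h.strand)):
        if all(abs(h.start - k.start) >= length for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: h.start)


def scan_peaks(
    peaks: PeakSet,
    genome: Mapping[str, str] | Mapping[str, np.ndarray],
    pwms: Sequence[PWM],
    threshold_bits: float | Mapping[str, float] | None = None,
    window: int = 200,
) -> list[MotifHit]:
    """Find motif occurrences within ``±window`` bp of each peak summit.

    ``threshold_bits`` is a score cutoff in bits, either one number, a
    per-motif mapping, or None for the default 80% of each PWM's maximum
    attainable score.  Windows running off a chromosome end are truncated.
    Overlapping same-motif hits are greedily pruned by descending score.
    """
    first = next(iter(genome.values()), None)
    encoded = genome if isinstance(first, np.ndarray) else encode_sequences(genome)

    def thr(pwm: PWM) -> float:
        if threshold_bits is None:
            return DEFAULT_THRESHOLD_FRACTION * pwm.max_score
        if isinstance(threshold_bits, Mapping):
            return float(threshold_bits[pwm.motif_id])
        return float(threshold_bits)

    tables = {p.motif_id: (_lookup_tables(p), thr(p)) for p in pwms}
    hits: list[MotifHit] = []
    for peak in peaks:
        seq = encoded.get(peak.chrom)
        if seq is None:
            raise KeyError(f"no sequence for chromosome {peak.chrom!r}")
        lo = max(0, peak.summit - window)
        hi = min(len(seq), peak.summit + window + 1)
        win = seq[lo:hi]
        for pwm in pwms:
            (fwd, rc), cutoff = tables[pwm.motif_id]
            L = pwm.length
            peak_hits = []
            for strand, table in (("+", fwd), ("-", rc)):
                scores = _scan_positions(win, table)
                for pos in np.flatnonzero(scores >= cutoff):
                    start = lo + int(pos)
                    center = start + (L - 1) / 2.0 - peak.summit
                    peak_hits.append(
                        MotifHit(peak.name, pwm.motif_id, center, strand,
                                 float(scores[pos]), start)
                    )
            hits.extend(_prune_overlapping(peak_hits, L))
    return hits


def motif_density(
    hits: Sequence[MotifHit], bin_size: int = 10, window: int = 200
) -> pd.DataFrame:
    """Histogram of hit-centre offsets per motif over [-window, +window].

    Bins are left-closed; the frame has one row per bin centre and one
    column per motif, values are raw hit counts (total = number of hits
    inside the range).
    """
    edges = np.arange(-window, window + bin_size, bin_size)
    centers = (edges[:-1] + edges[1:]) / 2.0
    motif_ids = sorted({h.motif_id for h in hits})
    out = pd.DataFrame(0, index=centers, columns=motif_ids, dtype=int)
    for m in motif_ids:
        offs = np.array([h.center for h in hits if h.motif_id == m])
        counts, _ = np.histogram(offs, bins=edges)
        out[m] = counts
    out.index.name = "bin_center"
    return out


def _hits_by_peak(hits: Sequence[MotifHit]) -> dict[str, dict[str, list[MotifHit]]]:
    by_peak: dict[str, dict[str, list[MotifHit]]] = {}
    for h in hits:
        by_peak.setdefault(h.peak_name, {}).setdefault(h.motif_id, []).append(h)
    return by_peak


def _peak_has_pair(per_motif: dict[str, list[MotifHit]], a: str, b: str, max_dist: int) -> bool:
    ha = per_motif.get(a, [])
    hb = per_motif.get(b, [])
    for x in ha:
        for y in hb:
            if a == b and x.start == y.start and x.strand == y.strand:
                continue  # same physical instance
            if abs(x.center - y.center) <= max_dist:
                return True
    return False


def pair_count(hits: Sequence[MotifHit], motif_a: str, motif_b: str, max_dist: int = 20) -> int:
    """Peaks containing >=1 (a, b) hit pair with centre distance <= max_dist.

    Symmetric in (a, b); for a == b two distinct instances are required.
    """
    return sum(
        1
        for per_motif in _hits_by_peak(hits).values()
        if _peak_has_pair(per_motif, motif_a, motif_b, max_dist)
    )


def bootstrap_colocalization(
    target_peaks: PeakSet,
    pool: Sequence[UnionPeak] | PeakSet,
    genome: Mapping[str, str],
    pwms: Sequence[PWM],
    cfg: AnalysisConfig | None = None,
    n_iterations: int | None = None,
    seed: int | None = None,
    threshold_bits: float | Mapping[str, float] | None = None,
) -> ColocalizationMatrix:
    """Bootstrap z scores for motif-pair co-localization in target peaks.

    Observed: for every motif pair, the number of target peaks with a
    qualifying pair within ``pair_distance`` bp.  Null: random peak sets of
    matching size drawn without replacement from ``pool`` (summit-centred,
    ``random_peak_width`` wide), re-scanned with the same scanner.  The
    pool is scanned once and per-peak pair indicators are resampled, which
    is exactly equivalent to rescanning each draw.
    """
    cfg = cfg or AnalysisConfig()
    n_iter = int(n_iterations if n_iterations is not None else cfg.n_bootstrap)
    seed = int(seed if seed is not None else cfg.rng_seed)
    rng = np.random.default_rng(seed)
    encoded = encode_sequences(genome)

    pool_peaks = (
        [up.representative for up in pool] if pool and isinstance(pool[0], UnionPeak) else list(pool)
    )
    k = len(target_peaks)
    if k > len(pool_peaks):
        raise ValueError("target set larger than pool in without-replacement mode")

    motif_ids = [p.motif_id for p in pwms]
    pairs = list(itertools.combinations_with_replacement(sorted(motif_ids), 2))

    target_hits = scan_peaks(target_peaks, encoded, pwms, threshold_bits, cfg.summit_window)
    target_by_peak = _hits_by_peak(target_hits)
    observed = {
        pr: sum(
            1 for pm in target_by_peak.values()
            if _peak_has_pair(pm, pr[0], pr[1], cfg.pair_distance)
        )
        for pr in pairs
    }

    pool_set = PeakSet("pool", pool_peaks)
    pool_hits = scan_peaks(pool_set, encoded, pwms, threshold_bits, cfg.summit_window)
    pool_by_peak = _hits_by_peak(pool_hits)
    indicator = np.zeros((len(pool_peaks), len(pairs)), dtype=np.uint8)
    for i, peak in enumerate(pool_set):
        pm = pool_by_peak.get(peak.name, {})
        for j, (a, b) in enumerate(pairs):
            if _peak_has_pair(pm, a, b, cfg.pair_distance):
                indicator[i, j] = 1

    null_stats = np.empty((n_iter, len(pairs)), dtype=np.int64)
    for it in range(n_iter):
        idx = rng.choice(len(pool_peaks), size=k, replace=False)
        null_stats[it] = indicator[idx].sum(axis=0)

    pair_stats: dict[tuple[str, str], dict] = {}
    for j, pr in enumerate(pairs):
        col = null_stats[:, j]
        mean = float(col.mean())
        sd = float(col.std(ddof=1)) if n_iter > 1 else 0.0
        if sd == 0.0:
            pair_stats[pr] = {
                "observed": observed[pr], "null_mean": mean, "null_sd": 0.0,
                "z": float("nan"), "p": float("nan"), "degenerate": True,
            }
        else:
            z = (observed[pr] - mean) / sd
            p, _ = z_to_p(z)
            pair_stats[pr] = {
                "observed": observed[pr], "null_mean": mean, "null_sd": sd,
                "z": float(z), "p": p, "degenerate": False,
            }

    result = ColocalizationMatrix(
        sorted(motif_ids), pair_stats, n_iter, seed, len(pool_peaks)
    )
    result.order = _cluster_order(result)
    return result


def _cluster_order(m: ColocalizationMatrix) -> list[str]:
    """Hierarchical display order of motifs by their z-score rows."""
    if len(m.motif_ids) < 3:
        return list(m.motif_ids)
    z = m.z_frame().to_numpy()
    z = np.nan_to_num(z, nan=0.0)
    link = hierarchy.linkage(pdist(z, metric="euclidean"), method="complete")
    return [m.motif_ids[i] for i in hierarchy.leaves_list(link)]
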