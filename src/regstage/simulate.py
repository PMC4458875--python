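"""Synthetic-data generators with known ground truth.

Every generator is a pure function of (parameters, seed): its RNG stream is
derived from the master seed and the operation name, so adding draws to one
generator never perturbs another.  The returned :class:`SimTruth` pieces
are sufficient to score every downstream module.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core.types import (
    AnalysisConfig,
    BASES,
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    PWM,
    Peak,
    PeakSet,
    SampleMeta,
    TagSet,
)
from .peaks import make_signature

UNEXPRESSED_OFFSET = 2.0  # log2 units below the expressed threshold


def derive_rng(seed: int, name: str) -> np.random.Generator:
    """One documented RNG stream per generator: master seed + hashed name."""
    digest = hashlib.sha256(name.encode()).digest()[:8]
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


@dataclass
class SimTruth:
    """Ground truth planted by the generators."""

    planted_overlap_counts: dict[str, int] = field(default_factory=dict)
    planted_pattern_codes: dict[str, str] = field(default_factory=dict)
    planted_motif_pairs: list[dict] = field(default_factory=list)
    planted_enrichment_peaks: list[str] = field(default_factory=list)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def sim_genome(
    n_chroms: int, chrom_length: int, seed: int
) -> tuple[dict[str, str], dict[str, int]]:
    """I.i.d. uniform ACGT chromosomes; returns (sequences, sizes)."""
    if chrom_length < 10_000:
        raise ValueError("chrom_length must be >= 10 kb")
    rng = derive_rng(seed, "sim_genome")
    base_bytes = np.frombuffer("".join(BASES).encode(), dtype=np.uint8)
    seqs = {}
    for i in range(n_chroms):
        draws = rng.integers(0, 4, size=chrom_length)
        seqs[f"chr{i + 1}"] = base_bytes[draws].tobytes().decode()
    return seqs, {c: len(s) for c, s in seqs.items()}


# ---------------------------------------------------------------------------
# Peak sets with planted Venn structure
# ---------------------------------------------------------------------------

def sim_peak_sets(
    membership_spec: Mapping[str, int],
    chrom_sizes: Mapping[str, int],
    seed: int,
    labels: Sequence[str] = ("A", "B", "C"),
    summit_jitter_sd: float = 0.0,
    width: int = 400,
    summit_window: int = 200,
    anchor_margin: int = 100,
) -> tuple[list[PeakSet], SimTruth]:
    """Plant peak sets whose summit-clustering Venn counts are known.

    ``membership_spec`` maps canonical signatures (see
    :func:`regstage.peaks.make_signature`) to cluster counts.  Each cluster
    gets one anchor; member peaks receive summits jittered by a truncated
    Normal(0, ``summit_jitter_sd``) clipped to ±``summit_window``/2, so
    within-cluster summit distances are <= ``summit_window``.  Anchors are
    spaced > 2*``summit_window`` + ``width`` apart, so single-linkage
    clustering can never chain distinct clusters.
    """
    label_set = set(labels)
    signatures: list[str] = []
    for sig, count in sorted(membership_spec.items()):
        members = _parse_signature(sig, labels)
        if not members or not set(members) <= label_set:
            raise ValueError(f"signature {sig!r} does not match labels {labels}")
        if count < 0:
            raise ValueError("membership counts must be non-negative")
        signatures.extend([sig] * count)

    step = 2 * summit_window + width + anchor_margin + 1
    anchors: list[tuple[str, int]] = []
    for chrom in sorted(chrom_sizes):
        pos = width  # keep intervals on-chromosome
        while pos + width < chrom_sizes[chrom]:
            anchors.append((chrom, pos))
            pos += step
    if len(anchors) < len(signatures):
        raise ValueError(
            f"genome too small: need {len(signatures)} anchors, have {len(anchors)}"
        )

    rng = derive_rng(seed, "sim_peak_sets")
    chosen = [anchors[i] for i in sorted(rng.choice(len(anchors), size=len(signatures), replace=False))]
    order = rng.permutation(len(signatures))
    bound = summit_window // 2
    peaks_by_label: dict[str, list[Peak]] = {l: [] for l in labels}
    for cluster_idx, (sig_i, (chrom, anchor)) in enumerate(
        zip((signatures[i] for i in order), chosen)
    ):
        for label in _parse_signature(sig_i, labels):
            if summit_jitter_sd > 0:
                jitter = int(round(float(np.clip(rng.normal(0.0, summit_jitter_sd), -bound, bound))))
            else:
                jitter = 0
            summit = anchor + jitter
            start = summit - width // 2
            peaks_by_label[label].append(
                Peak(
                    GenomicInterval(chrom, start, start + width),
                    summit,
                    f"{label}_{cluster_idx}",
                )
            )
    sets = [PeakSet(l, peaks_by_label[l]) for l in labels]
    truth = SimTruth(planted_overlap_counts=dict(membership_spec), seed=seed)
    return sets, truth


def _parse_signature(sig: str, labels: Sequence[str]) -> list[str]:
    if all(len(l) == 1 for l in labels):
        return [c for c in sig]
    return sig.split("+")


# ---------------------------------------------------------------------------
# Tags
# ---------------------------------------------------------------------------

def sim_tags(
    peaks: PeakSet,
    tags_per_peak: int,
    background_tags: int,
    pileup_sd: float,
    chrom_sizes: Mapping[str, int],
    seed: int,
    label: str = "tags",
) -> TagSet:
    """Tag pileups ~ Normal(summit, pileup_sd) per peak plus uniform
    background over the genome; total = n_peaks*tags_per_peak + background."""
    if pileup_sd <= 0:
        raise ValueError("pileup_sd must be > 0")
    rng = derive_rng(seed, f"sim_tags:{label}")
    positions: dict[str, list[int]] = {c: [] for c in chrom_sizes}
    for p in peaks:
        draws = rng.normal(p.summit, pileup_sd, size=tags_per_peak)
        clipped = np.clip(np.rint(draws), 0, chrom_sizes[p.chrom] - 1).astype(int)
        positions[p.chrom].extend(clipped.tolist())
    if background_tags > 0:
        chroms = sorted(chrom_sizes)
        lengths = np.array([chrom_sizes[c] for c in chroms], dtype=float)
        total = lengths.sum()
        flat = rng.integers(0, int(total), size=background_tags)
        bounds = np.cumsum(lengths)
        which = np.searchsorted(bounds, flat, side="right")
        offsets = flat - np.concatenate(([0], bounds[:-1]))[which]
        for w, off in zip(which, offsets):
            positions[chroms[int(w)]].append(int(off))
    return TagSet(label, positions)


# ---------------------------------------------------------------------------
# Expression with planted trinary codes
# ---------------------------------------------------------------------------

def random_codes(n_genes: int, n_transitions: int, seed: int) -> dict[str, str]:
    rng = derive_rng(seed, "random_codes")
    digits = rng.integers(0, 3, size=(n_genes, n_transitions))
    return {
        f"g{i:05d}": "".join(str(d) for d in row) for i, row in enumerate(digits)
    }


def sim_expression(
    codes: Mapping[str, str],
    stages: Sequence[str],
    seed: int,
    effect_log2: float = 2.0,
    noise_sd: float = 0.0,
    baseline: float = 8.0,
    n_reps: int = 3,
    induced: bool = False,
    unexpressed_gene_ids: Sequence[str] = (),
    cfg: AnalysisConfig | None = None,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Expression matrix realizing planted trinary codes across stages.

    Digit '1' adds +``effect_log2`` across a stage transition, '0' adds
    -``effect_log2``, '2' adds nothing; i.i.d. Normal(0, ``noise_sd``)
    noise per observation.  Genes in ``unexpressed_gene_ids`` sit below the
    expressed threshold at every stage (to exercise the expression filter)
    and are excluded from the planted-code truth.
    """
    cfg = cfg or AnalysisConfig()
    n_transitions = len(stages) - 1
    if n_transitions < 1:
        raise ValueError("need at least two stages")
    gene_ids = sorted(codes)
    for g in gene_ids:
        code = codes[g]
        if len(code) != n_transitions:
            raise ValueError(
                f"gene {g!r}: code length {len(code)} != {n_transitions} transitions"
            )
        if set(code) - {"0", "1", "2"}:
            raise ValueError(f"gene {g!r}: invalid code {code!r}")
    unexpressed = set(unexpressed_gene_ids)
    all_ids = gene_ids + sorted(g for g in unexpressed if g not in codes)

    rng = derive_rng(seed, f"sim_expression:{'dox' if induced else 'ctl'}")
    delta = {"1": effect_log2, "0": -effect_log2, "2": 0.0}
    low = cfg.expressed_min_log2 - UNEXPRESSED_OFFSET
    cond = "dox" if induced else "ctl"
    samples = [
        SampleMeta(f"{stage}_{cond}_r{r + 1}", stage, induced, r + 1)
        for stage in stages
        for r in range(n_reps)
    ]
    values = np.empty((len(all_ids), len(samples)))
    for i, g in enumerate(all_ids):
        if g in unexpressed:
            means = np.full(len(stages), low)
        else:
            means = baseline + np.concatenate(
                ([0.0], np.cumsum([delta[d] for d in codes[g]]))
            )
        row = np.repeat(means, n_reps)
        if noise_sd > 0:
            row = row + rng.normal(0.0, noise_sd, size=row.shape)
        values[i] = row
    matrix = ExpressionMatrix(all_ids, samples, values)
    truth = SimTruth(
        planted_pattern_codes={g: codes[g] for g in gene_ids if g not in unexpressed},
        seed=seed,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------

def default_motifs(count_weight: float = 100.0) -> list[PWM]:
    """Two sharp synthetic PWMs with non-palindromic 8-bp consensuses."""
    return [
        consensus_pwm("motifA", "ACCGCAAT", count_weight),
        consensus_pwm("motifB", "GTTAGGCC", count_weight),
    ]


def consensus_pwm(motif_id: str, consensus: str, count_weight: float = 100.0) -> PWM:
    counts = np.zeros((4, len(consensus)))
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = count_weight
    return PWM(motif_id, counts)


def sim_motif_sequences(
    genome: Mapping[str, str],
    peaks: PeakSet,
    pwm_a: PWM,
    pwm_b: PWM,
    spacing: int,
    n_peaks: int,
    seed: int,
    summit_window: int = 200,
) -> tuple[dict[str, str], SimTruth]:
    """Plant consensus instances of a motif pair in the first ``n_peaks``
    peaks, at centre-to-centre distance ``spacing`` within the ±window.

    Other peaks are untouched.  Fails if the two instances would overlap
    (``spacing`` < mean motif length) or the window cannot hold the pair.
    """
    la, lb = pwm_a.length, pwm_b.length
    if spacing < (la + lb) / 2:
        raise ValueError("spacing too small: motif instances would overlap")
    # start offset between instances realizing the centre distance
    delta2 = 2 * spacing + (la - lb)
    if delta2 % 2 != 0:
        raise ValueError(
            "centre distance not realizable on the integer grid for these lengths"
        )
    delta = delta2 // 2
    w = summit_window
    lo, hi = -w, w - delta - lb + 1
    if hi <= lo:
        raise ValueError("window too small for the motif pair at this spacing")
    if n_peaks > len(peaks):
        raise ValueError("n_peaks exceeds the peak set size")

    rng = derive_rng(seed, "sim_motif_sequences")
    mutable = {c: bytearray(s.encode()) for c, s in genome.items()}
    designated = [peaks[i] for i in range(n_peaks)]
    for p in designated:
        s1_rel = int(rng.integers(lo, hi))
        s1 = p.summit + s1_rel
        s2 = s1 + delta
        seq = mutable[p.chrom]
        seq[s1 : s1 + la] = pwm_a.consensus.encode()
        seq[s2 : s2 + lb] = pwm_b.consensus.encode()
    truth = SimTruth(
        planted_motif_pairs=[
            {
                "motif_a": pwm_a.motif_id,
                "motif_b": pwm_b.motif_id,
                "spacing": spacing,
                "n_peaks": n_peaks,
                "peak_names": [p.name for p in designated],
            }
        ],
        seed=seed,
    )
    return {c: bytes(b).decode() for c, b in mutable.items()}, truth


# ---------------------------------------------------------------------------
# Complete input bundle
# ---------------------------------------------------------------------------

DEFAULT_MEMBERSHIP = {
    "ABC": 30, "AB": 10, "AC": 10, "BC": 10, "A": 20, "B": 20, "C": 20,
}


def combine_matrices(a: ExpressionMatrix, b: ExpressionMatrix) -> ExpressionMatrix:
    """Column-concatenate two matrices over identical gene lists."""
    if a.gene_ids != b.gene_ids:
        raise ValueError("gene lists differ")
    return ExpressionMatrix(
        a.gene_ids, a.samples + b.samples, np.hstack([a.values, b.values])
    )


def write_bundle(
    outdir: str | Path,
    seed: int,
    cfg: AnalysisConfig | None = None,
    membership: Mapping[str, int] | None = None,
    stages: Sequence[str] = ("HE", "HE2", "progenitor"),
    noise_sd: float = 0.2,
    n_extra_genes: int = 200,
) -> SimTruth:
    """Generate and write a complete synthetic input bundle plus truth.json.

    Files: genome.fa, peaks_{A,B,C}.narrowPeak, tags_{ctl,dox}.bed,
    genes.bed, expression.tsv, samples.tsv, motifs.pfm, truth.json.
    """
    from .core import io as _cio

    cfg = cfg or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    membership = dict(membership or DEFAULT_MEMBERSHIP)

    genome, sizes = sim_genome(2, 300_000, seed)
    sets, truth = sim_peak_sets(
        membership, sizes, seed,
        summit_jitter_sd=30.0, width=cfg.random_peak_width,
        summit_window=cfg.summit_window, anchor_margin=3199,
    )
    truth.seed = seed

    pwms = default_motifs()
    set_a = sets[0]
    n_planted = min(25, len(set_a))
    genome, motif_truth = sim_motif_sequences(
        genome, set_a, pwms[0], pwms[1], spacing=15, n_peaks=n_planted,
        seed=seed, summit_window=cfg.summit_window,
    )
    truth.planted_motif_pairs = motif_truth.planted_motif_pairs

    tags_ctl = sim_tags(set_a, 50, 2000, 50.0, sizes, seed, label="ctl")
    tags_dox = sim_tags(set_a, 25, 2000, 50.0, sizes, seed + 1, label="dox")
    truth.planted_enrichment_peaks = [p.name for p in set_a]

    genes = sim_genes(set_a, sizes)
    gene_ids = [g.gene_id for g in genes] + [
        f"x{i:05d}" for i in range(n_extra_genes)
    ]
    rng = derive_rng(seed, "bundle_codes")
    n_tr = len(stages) - 1
    codes_ctl = {
        g: "".join(str(d) for d in rng.integers(0, 3, size=n_tr)) for g in gene_ids
    }
    codes_dox = {
        g: "".join(str(d) for d in rng.integers(0, 3, size=n_tr)) for g in gene_ids
    }
    off_genes = [f"off{i:03d}" for i in range(10)]
    for g in off_genes:
        codes_ctl[g] = "2" * n_tr
        codes_dox[g] = "2" * n_tr
    m_ctl, e_truth = sim_expression(
        codes_ctl, stages, seed, noise_sd=noise_sd,
        unexpressed_gene_ids=off_genes, cfg=cfg,
    )
    m_dox, _ = sim_expression(
        codes_dox, stages, seed, noise_sd=noise_sd, induced=True,
        unexpressed_gene_ids=off_genes, cfg=cfg,
    )
    matrix = combine_matrices(m_ctl, m_dox)
    truth.planted_pattern_codes = {
        g: codes_ctl[g] + "|" + codes_dox[g] for g in e_truth.planted_pattern_codes
    }

    _cio.write_fasta(genome, outdir / "genome.fa")
    for ps in sets:
        _cio.write_peaks(ps, outdir / f"peaks_{ps.label}.narrowPeak")
    _cio.write_tags(tags_ctl, outdir / "tags_ctl.bed")
    _cio.write_tags(tags_dox, outdir / "tags_dox.bed")
    _cio.write_genes_bed(genes, outdir / "genes.bed")
    _cio.write_expression(matrix, outdir / "expression.tsv", outdir / "samples.tsv")
    _cio.write_motifs(pwms, outdir / "motifs.pfm")
    truth.to_json(outdir / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# Gene models around planted clusters
# ---------------------------------------------------------------------------

def sim_genes(
    peaks: PeakSet, chrom_sizes: Mapping[str, int], prefix: str = "g"
) -> list[GeneModel]:
    """One gene per peak, cycling through promoter / intragenic / intergenic
    geometries relative to the summit (all on the + strand).

    Assumes peaks are spaced >= ~4 kb apart (as produced by
    :func:`sim_peak_sets` with a large ``anchor_margin``).
    """
    genes = []
    for i, p in enumerate(peaks):
        s = p.summit
        kind = i % 3
        if kind == 0:  # TSS 100 bp upstream of the summit -> promoter hit
            iv = GenomicInterval(p.chrom, s - 100, s + 900, "+")
        elif kind == 1:  # summit mid-body, outside the promoter window
            iv = GenomicInterval(p.chrom, s - 1500, s + 1500, "+")
        else:  # TSS 3 kb away -> intergenic
            iv = GenomicInterval(p.chrom, s + 3000, s + 3800, "+")
        if iv.end > chrom_sizes[p.chrom]:
            iv = GenomicInterval(p.chrom, max(0, s - 900), s + 100, "+")
        genes.append(GeneModel(f"{prefix}{i:05d}", iv))
    return genes
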