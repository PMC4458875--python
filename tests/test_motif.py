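import numpy as np
import pytest

from regstage.core.types import AnalysisConfig, GenomicInterval, PWM, Peak, PeakSet
from regstage.motif import (
    bootstrap_colocalization,
    encode_sequences,
    motif_density,
    pair_count,
    scan_peaks,
)
from regstage.simulate import (
    consensus_pwm,
    default_motifs,
    sim_genome,
    sim_motif_sequences,
    sim_peak_sets,
)


def peak_at(summit, chrom="chr1", width=500, name="p0"):
    return Peak(GenomicInterval(chrom, summit - width // 2, summit + width - width // 2),
                summit, name)


def revcomp(s):
    return s.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestScanPeaks:
    def test_planted_consensus_center_offset(self):
        # consensus (L=8) planted with centre at summit + 37
        pwm = consensus_pwm("m", "ACCGCAAT")
        summit = 1000
        seq = ["T"] * 3000
        start = summit + 37 - 3  # centre = start + (L-1)/2 = start + 3.5
        for i, b in enumerate(pwm.consensus):
            seq[start + i] = b
        genome = {"chr1": "".join(seq)}
        hits = scan_peaks(PeakSet("t", [peak_at(summit)]), genome, [pwm])
        assert len(hits) == 1
        # centre must equal planted start + (L-1)/2 - summit exactly
        assert hits[0].center == start + 3.5 - summit
        assert hits[0].strand == "+"

    def test_reverse_strand_hit(self):
        pwm = consensus_pwm("m", "ACCGCAAT")
        summit = 1000
        seq = ["T"] * 3000
        rc = revcomp(pwm.consensus)
        start = 950
        for i, b in enumerate(rc):
            seq[start + i] = b
        hits = scan_peaks(PeakSet("t", [peak_at(summit)]), {"chr1": "".join(seq)}, [pwm])
        assert len(hits) == 1 and hits[0].strand == "-"
        assert hits[0].center == start + 3.5 - summit

    def test_uniform_pwm_no_hits_above_zero(self):
        pwm = PWM("u", np.full((4, 6), 5.0))
        genome, _ = sim_genome(1, 20_000, 1)
        hits = scan_peaks(
            PeakSet("t", [peak_at(5000)]), genome, [pwm], threshold_bits=0.1
        )
        assert hits == []

    def test_strand_symmetry(self):
        # reverse-complementing the genome mirrors hits
        genome, _ = sim_genome(1, 30_000, 5)
        pwm = consensus_pwm("m", "ACGTCA")
        n = len(genome["chr1"])
        peaks = PeakSet("t", [peak_at(s) for s in (5000, 12_000, 20_000)])
        hits_fwd = scan_peaks(peaks, genome, [pwm], threshold_bits=pwm.max_score - 1e-9)
        rc_genome = {"chr1": revcomp(genome["chr1"])}
        rc_peaks = PeakSet(
            "t", [peak_at(n - 1 - p.summit, name=p.name) for p in peaks]
        )
        hits_rc = scan_peaks(rc_peaks, rc_genome, [pwm], threshold_bits=pwm.max_score - 1e-9)
        got_f = sorted((h.peak_name, round(h.center, 1), h.strand) for h in hits_fwd)
        flip = {"+": "-", "-": "+"}
        got_r = sorted(
            (h.peak_name, round(-h.center, 1), flip[h.strand]) for h in hits_rc
        )
        assert got_f == got_r

    def test_window_truncated_at_chrom_edge(self):
        pwm = consensus_pwm("m", "ACCGCAAT")
        genome = {"chr1": "T" * 400}
        peak = Peak(GenomicInterval("chr1", 0, 300), 50, "edge")
        assert scan_peaks(PeakSet("t", [peak]), genome, [pwm]) == []

    def test_missing_chromosome_errors(self):
        pwm = consensus_pwm("m", "ACCGCAAT")
        with pytest.raises(KeyError):
            scan_peaks(PeakSet("t", [peak_at(1000)]), {"chrX": "A" * 5000}, [pwm])

    def test_tandem_repeat_pruned(self):
        pwm = consensus_pwm("m", "ACCGCAAT")
        summit = 1000
        seq = ["T"] * 3000
        # two overlapping near-instances cannot both survive pruning
        word = pwm.consensus + pwm.consensus  # adjacent, non-overlapping: both kept
        for i, b in enumerate(word):
            seq[summit + i] = b
        hits = scan_peaks(PeakSet("t", [peak_at(summit)]), {"chr1": "".join(seq)}, [pwm])
        assert len(hits) == 2
        assert abs(hits[0].start - hits[1].start) >= pwm.length


class TestMotifDensity:
    def test_all_central(self):
        pwm = consensus_pwm("m", "ACCGCAAT")
        summit = 1000
        seq = ["T"] * 3000
        start = summit - 3  # centre 0.5
        for i, b in enumerate(pwm.consensus):
            seq[start + i] = b
        hits = scan_peaks(PeakSet("t", [peak_at(summit)]), {"chr1": "".join(seq)}, [pwm])
        dens = motif_density(hits, bin_size=10, window=200)
        assert dens["m"].sum() == 1
        assert dens["m"].loc[5.0] == 1  # bin [0, 10)

    def test_conservation(self):
        genome, _ = sim_genome(1, 500_000, 9)
        sets, _ = sim_peak_sets({"A": 100}, {"chr1": 500_000}, seed=10)
        pwms = default_motifs()
        genome2, _ = sim_motif_sequences(genome, sets[0], *pwms, spacing=20,
                                         n_peaks=50, seed=11)
        hits = scan_peaks(sets[0], genome2, pwms)
        dens = motif_density(hits, bin_size=10, window=200)
        assert dens.to_numpy().sum() == len(hits)


class TestPairCount:
    def test_distance_boundary(self):
        pwm_a, pwm_b = default_motifs()
        genome = {"chr1": "T" * 4000}

        def plant(c1, c2):
            seq = list(genome["chr1"])
            for i, b in enumerate(pwm_a.consensus):
                seq[c1 - 3 + i] = b
            for i, b in enumerate(pwm_b.consensus):
                seq[c2 - 3 + i] = b
            return {"chr1": "".join(seq)}

        peaks = PeakSet("t", [peak_at(1000)])
        hits = scan_peaks(peaks, plant(1000, 1015), [pwm_a, pwm_b])
        assert pair_count(hits, "motifA", "motifB", 20) == 1  # delta 15
        hits = scan_peaks(peaks, plant(1000, 1021), [pwm_a, pwm_b])
        assert pair_count(hits, "motifA", "motifB", 20) == 0  # delta 21

    def test_symmetry_and_monotonicity(self):
        genome, _ = sim_genome(1, 500_000, 13)
        sets, _ = sim_peak_sets({"A": 80}, {"chr1": 500_000}, seed=14)
        pwms = default_motifs()
        genome2, _ = sim_motif_sequences(genome, sets[0], *pwms, spacing=18,
                                         n_peaks=40, seed=15)
        hits = scan_peaks(sets[0], genome2, pwms)
        assert pair_count(hits, "motifA", "motifB", 20) == pair_count(
            hits, "motifB", "motifA", 20
        )
        counts = [pair_count(hits, "motifA", "motifB", d) for d in (5, 18, 30, 100)]
        assert counts == sorted(counts)
        assert counts[1] == 40

    def test_same_motif_needs_distinct_instances(self):
        pwm = consensus_pwm("m", "ACCGCAAT")
        seq = ["T"] * 3000
        for i, b in enumerate(pwm.consensus):
            seq[997 + i] = b
        hits = scan_peaks(PeakSet("t", [peak_at(1000)]), {"chr1": "".join(seq)}, [pwm])
        assert len(hits) == 1
        assert pair_count(hits, "m", "m", 20) == 0
        # two true instances of the same motif within range do count
        for i, b in enumerate(pwm.consensus):
            seq[1010 + i] = b
        hits = scan_peaks(PeakSet("t", [peak_at(1000)]), {"chr1": "".join(seq)}, [pwm])
        assert pair_count(hits, "m", "m", 20) == 1


class TestBootstrapColocalization:
    def _setup(self, spacing, seed=1, n_pool=400, n_target=100, n_planted=70):
        genome, sizes = sim_genome(1, 600_000, seed)
        sets, _ = sim_peak_sets({"A": n_pool}, sizes, seed=seed + 1, anchor_margin=300)
        pool = sets[0]
        target = PeakSet("target", [pool[i] for i in range(n_target)])
        pa, pb = default_motifs()
        pc = consensus_pwm("motifC", "TTGACGGA")
        genome2, _ = sim_motif_sequences(
            genome, target, pa, pb, spacing=spacing, n_peaks=n_planted, seed=seed + 2
        )
        return target, pool, genome2, [pa, pb, pc]

    def test_planted_pair_flagged_others_not(self, cfg):
        target, pool, genome, pwms = self._setup(15)
        coloc = bootstrap_colocalization(
            target, pool, genome, pwms, cfg, n_iterations=300, seed=3
        )
        assert coloc.get("motifA", "motifB")["z"] > 3
        for a, b in [("motifA", "motifC"), ("motifB", "motifC"), ("motifC", "motifC")]:
            z = coloc.get(a, b)["z"]
            assert not (z > 3)

    def test_spacing_25_not_flagged(self, cfg):
        target, pool, genome, pwms = self._setup(25)
        coloc = bootstrap_colocalization(
            target, pool, genome, pwms, cfg, n_iterations=300, seed=4
        )
        z = coloc.get("motifA", "motifB")["z"]
        assert not (z > 3)

    def test_empty_target_non_positive(self, cfg):
        target, pool, genome, pwms = self._setup(15)
        empty = PeakSet("empty", [])
        coloc = bootstrap_colocalization(
            empty, pool, genome, pwms, cfg, n_iterations=100, seed=5
        )
        stats = coloc.get("motifA", "motifB")
        assert stats["observed"] == 0
        assert stats["degenerate"] or stats["z"] <= 0

    def test_null_calibration_target_from_pool(self, cfg):
        # target drawn uniformly from the pool -> no pair should be extreme
        genome, sizes = sim_genome(1, 600_000, 31)
        sets, _ = sim_peak_sets({"A": 300}, sizes, seed=32, anchor_margin=300)
        pool = sets[0]
        pa, pb = default_motifs()
        genome2, _ = sim_motif_sequences(genome, pool, pa, pb, spacing=15,
                                         n_peaks=150, seed=33)
        rng = np.random.default_rng(34)
        zs = []
        for rep in range(10):
            idx = rng.choice(len(pool), 100, replace=False)
            target = PeakSet("t", [pool[int(i)] for i in idx])
            coloc = bootstrap_colocalization(
                target, pool, genome2, [pa, pb], cfg, n_iterations=200, seed=rep
            )
            zs.append(coloc.get("motifA", "motifB")["z"])
        assert np.mean(np.abs(zs)) < 2
        assert max(np.abs(zs)) < 4

    def test_z_frame_symmetric_and_order(self, cfg):
        target, pool, genome, pwms = self._setup(15)
        coloc = bootstrap_colocalization(
            target, pool, genome, pwms, cfg, n_iterations=100, seed=6
        )
        zf = coloc.z_frame()
        np.testing.assert_allclose(zf.to_numpy(), zf.to_numpy().T, equal_nan=True)
        assert sorted(coloc.order) == sorted(coloc.motif_ids)

    def test_determinism(self, cfg):
        target, pool, genome, pwms = self._setup(15)
        c1 = bootstrap_colocalization(target, pool, genome, pwms, cfg,
                                      n_iterations=100, seed=7)
        c2 = bootstrap_colocalization(target, pool, genome, pwms, cfg,
                                      n_iterations=100, seed=7)
        assert repr(sorted(c1.pair_stats.items())) == repr(sorted(c2.pair_stats.items()))
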