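import numpy as np
import pytest
from scipy import integrate as sci_integrate
from scipy import stats

from regstage.boot import (
    bootstrap_gene_overlap,
    bootstrap_peak_overlap,
    sample_random_peakset,
    z_to_p,
)
from regstage.core.types import AnalysisConfig, PeakSet
from regstage.peaks import merge_union
from regstage.simulate import sim_peak_sets

from conftest import make_peak, make_peakset


def log_tail_oracle(z: float) -> float:
    """Independent upper-tail oracle (natural log of P): numeric integration
    of the density for moderate z, the Mills-ratio asymptotic expansion for
    large z.  Accurate to well under 1e-6 in the log over z in [0, 45]."""
    if z < 6:
        val, _ = sci_integrate.quad(
            lambda t: np.exp(-t * t / 2) / np.sqrt(2 * np.pi),
            z, z + 40, epsabs=1e-30, epsrel=1e-12, limit=200,
        )
        return float(np.log(val))
    # error bounded by the first omitted term: < 2e-7 relative at z = 6
    series = sum(
        (-1) ** k * _double_factorial(2 * k - 1) / z ** (2 * k) for k in range(9)
    )
    return float(-z * z / 2 - 0.5 * np.log(2 * np.pi) - np.log(z) + np.log(series))


def _double_factorial(n: int) -> int:
    out = 1
    while n > 1:
        out *= n
        n -= 2
    return out


def tail_oracle(z: float) -> float:
    return float(np.exp(log_tail_oracle(z)))


class TestZToP:
    def test_z_zero(self):
        p, lp = z_to_p(0.0)
        assert p == pytest.approx(0.5)
        assert lp == pytest.approx(np.log10(0.5))

    def test_five_percent_quantile(self):
        p, _ = z_to_p(1.6448536)
        assert p == pytest.approx(0.05, abs=1e-6)
        assert p == pytest.approx(tail_oracle(1.6448536), rel=1e-8)

    def test_published_z_23_36(self):
        # printed bound: P < 5.45e-121
        p, lp = z_to_p(23.36)
        assert f"{p:.1e}" == "5.5e-121"
        assert p == pytest.approx(5.45e-121, rel=0.01)
        assert lp == pytest.approx(np.log10(p), rel=1e-9)

    @pytest.mark.parametrize("z", [0.5, 2.0, 5.0, 8.0, 12.0, 20.0, 30.0, 40.0])
    def test_matches_independent_oracle_six_digits(self, z):
        p, lp = z_to_p(z)
        log_oracle = log_tail_oracle(z)
        if p > 1e-300:
            assert np.log(p) == pytest.approx(log_oracle, abs=2e-6)
        assert lp == pytest.approx(log_oracle / np.log(10), abs=1e-6)

    def test_huge_z_log_domain_finite(self):
        p, lp = z_to_p(100.0)
        assert np.isfinite(lp) and lp < -2000
        assert p > 0  # clamped at the double-precision floor

    def test_monotone_decreasing(self):
        zs = np.linspace(-5, 45, 101)
        lps = [z_to_p(float(z))[1] for z in zs]
        assert all(a > b for a, b in zip(lps, lps[1:]))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            z_to_p(float("nan"))


class TestSampleRandomPeakset:
    def _pool(self, n=50):
        sets, _ = sim_peak_sets({"A": n}, {"chr1": 10_000_000}, seed=5)
        return merge_union(sets, 200)

    def test_full_draw_is_permutation(self):
        pool = self._pool(30)
        rng = np.random.default_rng(0)
        ps = sample_random_peakset(pool, 30, 400, rng)
        assert sorted(p.summit for p in ps) == sorted(u.summit for u in pool)

    def test_width_exact(self):
        pool = self._pool(10)
        ps = sample_random_peakset(pool, 5, 400, np.random.default_rng(1))
        assert all(p.end - p.start == 400 and p.summit == p.start + 200 for p in ps)

    def test_over_draw_errors_without_replacement(self):
        pool = self._pool(10)
        with pytest.raises(ValueError):
            sample_random_peakset(pool, 11, 400, np.random.default_rng(1))
        # with replacement it is fine
        ps = sample_random_peakset(pool, 15, 400, np.random.default_rng(1), replace=True)
        assert len(ps) == 15

    def test_uniform_inclusion_frequency(self):
        pool = self._pool(20)
        rng = np.random.default_rng(2)
        hits = {u.summit: 0 for u in pool}
        n_draws = 2000
        for _ in range(n_draws):
            for p in sample_random_peakset(pool, 10, 400, rng):
                hits[p.summit] += 1
        freqs = np.array(list(hits.values())) / n_draws
        # binomial sd = sqrt(.5*.5/2000) ~ 0.011
        assert np.all(np.abs(freqs - 0.5) < 5 * 0.012)


class TestBootstrapGeneOverlap:
    CFG = AnalysisConfig()

    def test_identical_full_sets_degenerate(self):
        u = {f"g{i}" for i in range(50)}
        res = bootstrap_gene_overlap([set(u), set(u), set(u)], u, self.CFG,
                                     n_iterations=50, seed=1)
        assert res.degenerate and np.isnan(res.z)
        assert res.observed == 50

    def test_disjoint_sets_negative_z(self):
        u = {f"g{i}" for i in range(300)}
        ids = sorted(u)
        sets = [set(ids[:100]), set(ids[100:200]), set(ids[200:300])]
        res = bootstrap_gene_overlap(sets, u, self.CFG, n_iterations=600, seed=2)
        assert res.observed == 0 and res.z < 0

    def test_null_mean_hypergeometric_oracle(self):
        # keeping one size-m set and drawing two more uniformly from N:
        # E|A^B^C| = m * (m/N)^2
        N, m = 400, 120
        u = {f"g{i}" for i in range(N)}
        ids = sorted(u)
        rng = np.random.default_rng(3)
        sets = [set(rng.choice(ids, m, replace=False)) for _ in range(3)]
        res = bootstrap_gene_overlap(sets, u, self.CFG, n_iterations=3000, seed=4)
        expected = m * (m / N) ** 2
        se = res.null_sd / np.sqrt(res.n_iterations)
        assert abs(res.null_mean - expected) < 4 * se + 0.05

    def test_subset_validation(self):
        u = {"a", "b"}
        with pytest.raises(ValueError, match="universe"):
            bootstrap_gene_overlap([{"a"}, {"b"}, {"z"}], u, self.CFG, n_iterations=10)

    def test_determinism(self):
        u = {f"g{i}" for i in range(100)}
        ids = sorted(u)
        sets = [set(ids[:40]), set(ids[20:60]), set(ids[30:70])]
        r1 = bootstrap_gene_overlap(sets, u, self.CFG, n_iterations=200, seed=9)
        r2 = bootstrap_gene_overlap(sets, u, self.CFG, n_iterations=200, seed=9)
        assert (r1.null_mean, r1.null_sd, r1.z) == (r2.null_mean, r2.null_sd, r2.z)


def _pool_10k(n=10_000, seed=100):
    sets, _ = sim_peak_sets(
        {"P": n}, {"chr1": 10_000_000, "chr2": 10_000_000}, seed=seed,
        labels=("P",), anchor_margin=1200,
    )
    return merge_union(sets, 200)


def draw_sets_from_pool(pool, sizes, rng, shared=0):
    """Three peak sets from pool representatives: `shared` common peaks
    plus independent draws for the remainder."""
    reps = [u.representative for u in pool]
    shared_idx = rng.choice(len(reps), size=shared, replace=False) if shared else []
    out = []
    for label, k in zip("ABC", sizes):
        rest = rng.choice(len(reps), size=k - shared, replace=False)
        chosen = list(shared_idx) + list(rest)
        out.append(PeakSet(label, [reps[int(i)] for i in chosen]))
    return out


class TestBootstrapPeakOverlap:
    CFG = AnalysisConfig()

    def test_requires_three_nonempty_sets(self):
        a = make_peakset("A", [1000])
        with pytest.raises(ValueError):
            bootstrap_peak_overlap([a, a], self.CFG, n_iterations=10)

    def test_observed_equals_planted_three_way(self, anchored_sets):
        sets, spec = anchored_sets
        res = bootstrap_peak_overlap(sets, self.CFG, n_iterations=60, seed=1)
        assert res.observed == spec["ABC"]

    def test_planted_null_mean_matches_inclusion_probability_oracle(self):
        # 50 shared clusters drawn from a large pool; kept set has 50 peaks,
        # each matched by a random draw only if that exact pool anchor is
        # drawn (anchors are > 2*window apart), so per rotation
        # E[null] = 50 * P(>=1 of kB draws hits) * P(>=1 of kC draws hits)
        # with P = 1 - C(N-1,k)/C(N,k) = k/N.
        pool = _pool_10k(2000, seed=101)
        rng = np.random.default_rng(7)
        sets = draw_sets_from_pool(pool, [50, 50, 50], rng, shared=50)
        res = bootstrap_peak_overlap(
            sets, self.CFG, pool=pool, n_iterations=4000, seed=8
        )
        N = 2000
        expected = 50 * (50 / N) * (50 / N)
        se = res.null_sd / np.sqrt(res.n_iterations)
        assert res.observed == 50
        assert abs(res.null_mean - expected) < 4 * se + 0.02
        assert res.z > 5

    def test_observed_at_null_mean_gives_z_zero(self):
        p, _ = z_to_p(0.0)
        assert p == 0.5  # degenerate case covered by z_to_p directly

    def test_monotone_in_planted_overlap(self):
        pool = _pool_10k(1000, seed=103)
        zs = []
        for shared in (0, 20, 60):
            rng = np.random.default_rng(50 + shared)
            sets = draw_sets_from_pool(pool, [100, 100, 100], rng, shared=shared)
            res = bootstrap_peak_overlap(sets, self.CFG, pool=pool,
                                         n_iterations=800, seed=5)
            zs.append(res.z)
        assert zs[0] < zs[1] < zs[2]

    def test_quick_null_calibration(self):
        # abbreviated version of the acceptance-scale calibration
        pool = _pool_10k(1000, seed=104)
        zs = []
        for rep in range(25):
            rng = np.random.default_rng(1000 + rep)
            sets = draw_sets_from_pool(pool, [150, 150, 150], rng)
            res = bootstrap_peak_overlap(sets, self.CFG, pool=pool,
                                         n_iterations=500, seed=rep)
            zs.append(res.z)
        zs = np.array(zs)
        assert abs(zs.mean()) < 0.6
        assert 0.5 < zs.std(ddof=1) < 1.7

    def test_halving_iterations_stable(self):
        pool = _pool_10k(500, seed=105)
        rng = np.random.default_rng(3)
        sets = draw_sets_from_pool(pool, [100, 100, 100], rng, shared=20)
        r_full = bootstrap_peak_overlap(sets, self.CFG, pool=pool,
                                        n_iterations=2000, seed=4)
        r_half = bootstrap_peak_overlap(sets, self.CFG, pool=pool,
                                        n_iterations=1000, seed=4)
        assert r_half.z == pytest.approx(r_full.z, rel=0.25)

    def test_determinism_bit_exact(self, anchored_sets):
        sets, _ = anchored_sets
        r1 = bootstrap_peak_overlap(sets, self.CFG, n_iterations=90, seed=77)
        r2 = bootstrap_peak_overlap(sets, self.CFG, n_iterations=90, seed=77)
        assert (r1.null_mean, r1.null_sd, r1.z, r1.p_one_sided) == (
            r2.null_mean, r2.null_sd, r2.z, r2.p_one_sided
        )

    def test_rotation_stats_recorded(self, anchored_sets):
        sets, _ = anchored_sets
        res = bootstrap_peak_overlap(sets, self.CFG, n_iterations=90, seed=2)
        assert set(res.rotation_stats) == {0, 1, 2}
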