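import numpy as np
import pytest

from her2het.config import RunConfig
from her2het.segmentation import (
    max_arc_statistic,
    permutation_pvalue,
    segment_chromosome,
    smooth_track,
)
from her2het.simulate import CohortParams, generate_paired_cohort


def exhaustive_max_arc(vals, mw=2):
    """Independent double-loop oracle for the arc statistic."""
    x = np.asarray(vals, float)
    n = x.size
    if n < 2 * mw:
        return None
    s = x.std(ddof=1)
    if s == 0:
        return (0, mw, 0.0)
    best = None
    for i in range(n + 1):
        for j in range(i + mw, n + 1):
            k = j - i
            if k > n - mw:
                continue
            mi = x[i:j].mean()
            mo = np.concatenate((x[:i], x[j:])).mean()
            t = (mi - mo) / (s * np.sqrt(1 / k + 1 / (n - k)))
            if best is None or abs(t) > abs(best[2]) * (1 + 1e-13):
                best = (i, j, t)
    return best


class TestMaxArc:
    def test_clean_step_statistic(self):
        i, j, t = max_arc_statistic([0, 0, 0, 1, 1, 1])
        # the two mirror arcs (0,3) and (3,6) are exactly tied; both induce
        # the single change point after probe 3
        assert {i, j} <= {0, 3, 6} and j - i == 3
        assert abs(t) == pytest.approx(2.2361, abs=1e-4)
        assert np.std([0, 0, 0, 1, 1, 1], ddof=1) == pytest.approx(0.5477, abs=1e-4)

    def test_constant_sequence_zero_statistic(self):
        i, j, t = max_arc_statistic([5.0] * 8)
        assert t == 0.0 and (i, j) == (0, 2)

    def test_too_short_returns_none(self):
        assert max_arc_statistic([1.0, 2.0, 3.0]) is None

    def test_reversal_maps_to_mirror_arc(self):
        def arc_t(x, i, j):
            n = x.size
            s = x.std(ddof=1)
            k = j - i
            mi = x[i:j].mean()
            mo = np.concatenate((x[:i], x[j:])).mean()
            return (mi - mo) / (s * np.sqrt(1 / k + 1 / (n - k)))

        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=rng.integers(6, 30))
            i, j, t = max_arc_statistic(x)
            ri, rj, rt = max_arc_statistic(x[::-1])
            n = x.size
            assert abs(rt) == pytest.approx(abs(t), rel=1e-9)
            # mapping the reversed optimum back gives an equally good arc
            assert abs(arc_t(x, n - rj, n - ri)) == pytest.approx(abs(t), rel=1e-9)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            x = rng.normal(size=rng.integers(4, 26))
            got = max_arc_statistic(x)
            want = exhaustive_max_arc(x)
            assert got[:2] == want[:2]
            assert got[2] == pytest.approx(want[2], rel=1e-9)


class TestPermutationPvalue:
    def test_clean_step_attains_minimum_p(self):
        x = [0.0] * 20 + [2.0] * 20
        p = permutation_pvalue(x, 20, 40, nperm=199, seed=11)
        assert p == pytest.approx(1 / 200)

    def test_same_seed_identical(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        i, j, _ = max_arc_statistic(x)
        assert permutation_pvalue(x, i, j, 199, seed=5) == \
            permutation_pvalue(x, i, j, 199, seed=5)

    def test_nperm_floor(self):
        with pytest.raises(ValueError, match="nperm"):
            permutation_pvalue([0.0, 1.0, 0.0, 1.0], 1, 2, nperm=50)

    def test_null_calibration(self):
        """Rejection rate at alpha=0.05 on pure noise stays near nominal."""
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 200
        for _ in range(reps):
            x = rng.normal(size=40)
            i, j, _ = max_arc_statistic(x)
            p = permutation_pvalue(x, i, j, nperm=199, rng=rng)
            rejections += p <= 0.05
        assert 0.02 <= rejections / reps <= 0.09


class TestSegmentChromosome:
    def test_noiseless_step(self, config):
        segs = segment_chromosome(np.array([0.0] * 50 + [1.0] * 50), config)
        assert segs == [(0, 50, 0.0), (50, 100, 1.0)]

    def test_constant_input_single_segment(self, config):
        segs = segment_chromosome(np.full(30, 0.3), config)
        assert segs == [(0, 30, pytest.approx(0.3))]

    def test_noiseless_three_segments_match_two_changepoint_oracle(self, config):
        x = np.array([0.0] * 30 + [1.0] * 30 + [0.0] * 30)
        segs = segment_chromosome(x, config)
        # exhaustive two-change-point least-squares oracle
        best, best_sse = None, np.inf
        n = x.size
        for a in range(1, n - 1):
            for b in range(a + 1, n):
                sse = sum(((x[s:e] - x[s:e].mean()) ** 2).sum()
                          for s, e in ((0, a), (a, b), (b, n)))
                if sse < best_sse:
                    best_sse, best = sse, (a, b)
        assert [s[:2] for s in segs] == [(0, best[0]), best, (best[1], n)]
        assert [s[2] for s in segs] == [0.0, 1.0, 0.0]

    def test_alpha_monotonicity(self):
        rng = np.random.default_rng(23)
        x = np.concatenate([rng.normal(m, 0.2, 40) for m in (0, 1, 0, -1)])
        counts = []
        for alpha in (0.001, 0.01, 0.05):
            cfg = RunConfig(cbs_alpha=alpha, cbs_nperm=999, seed=1)
            counts.append(len(segment_chromosome(x, cfg,
                                                 rng=np.random.default_rng(1))))
        assert counts == sorted(counts)


class TestSmoothTrack:
    @pytest.fixture(scope="class")
    def zero_noise_case(self):
        params = CohortParams(n_cases=1, chroms=4, probes_per_chrom=80,
                              noise_sd=0.0, seed=6)
        pairs, truth = generate_paired_cohort(params)
        cfg = RunConfig(cbs_nperm=199, seed=6)
        return pairs[0], truth, cfg

    def test_zero_noise_smoothed_equals_truth(self, zero_noise_case):
        pair, truth, cfg = zero_noise_case
        prof = smooth_track(pair.pos, cfg)
        np.testing.assert_allclose(prof.smoothed,
                                   truth.truth_levels[("T1", "HER2_POS")],
                                   atol=1e-12)

    def test_smoothed_length_and_partition(self, zero_noise_case):
        pair, _, cfg = zero_noise_case
        prof = smooth_track(pair.pos, cfg)
        assert prof.smoothed.size == pair.pos.n_probes
        covered = np.zeros(pair.pos.n_probes, dtype=int)
        for seg in prof.segments:
            covered[seg.istart:seg.iend] += 1
        assert (covered == 1).all()

    def test_segment_means_are_member_means(self, zero_noise_case):
        pair, _, cfg = zero_noise_case
        noisy = pair.pos.probes.copy()
        rng = np.random.default_rng(8)
        noisy["log2ratio"] += rng.normal(0, 0.1, len(noisy))
        from her2het.io import ProbeTrack
        track = ProbeTrack("T1", "HER2_POS", noisy)
        prof = smooth_track(track, cfg)
        vals = track.probes["log2ratio"].to_numpy()
        for seg in prof.segments:
            assert seg.seg_mean == pytest.approx(
                vals[seg.istart:seg.iend].mean(), abs=1e-9)

    def test_missing_probes_reattached(self, zero_noise_case):
        pair, truth, cfg = zero_noise_case
        df = pair.pos.probes.copy()
        holes = [5, 6, 100, 200]
        df.loc[holes, "log2ratio"] = np.nan
        from her2het.io import ProbeTrack
        track = ProbeTrack("T1", "HER2_POS", df)
        prof = smooth_track(track, cfg)
        assert prof.smoothed.size == len(df)
        assert not np.isnan(prof.smoothed).any()
        # observed probes still recover truth exactly
        obs = ~track.missing
        np.testing.assert_allclose(
            prof.smoothed[obs],
            truth.truth_levels[("T1", "HER2_POS")][obs], atol=1e-12)

    def test_amplicon_breakpoint_recovery_with_noise(self):
        """>= 95% of breakpoints of amplification-level events (level 1.0,
        >= 8 probes, noise SD 0.1) are recovered within one probe over 20
        replicates."""
        cfg = RunConfig(cbs_nperm=250, seed=0)
        hits = total = 0
        for seed in range(20):
            params = CohortParams(n_cases=1, chroms=4, probes_per_chrom=120,
                                  noise_sd=0.1, seed=seed,
                                  planted_differential_locus=None)
            pairs, truth = generate_paired_cohort(params)
            offset = {f"chr{c}": (c - 1) * 120 for c in range(1, 5)}
            profs = {"HER2_POS": smooth_track(pairs[0].pos, cfg),
                     "HER2_NEG": smooth_track(pairs[0].neg, cfg)}

            def tally(prof, chrom, lo, hi):
                found = {s.istart for s in prof.segments} | \
                        {s.iend for s in prof.segments}
                n_hit = sum(
                    any(b in found for b in (bp - 1, bp, bp + 1))
                    for bp in (offset[chrom] + lo, offset[chrom] + hi))
                return n_hit, 2

            for chrom, lo, hi, level, _ in truth.truncal_segments["T1"]:
                if level == params.level_amp:
                    for p in profs.values():
                        h, t = tally(p, chrom, lo, hi)
                        hits, total = hits + h, total + t
            for (_, comp), evs in truth.restricted_events.items():
                for chrom, lo, hi in evs:
                    h, t = tally(profs[comp], chrom, lo, hi)
                    hits, total = hits + h, total + t
        assert hits / total >= 0.95
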