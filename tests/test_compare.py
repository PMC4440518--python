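import math

import numpy as np
import pytest

from her2het.compare import (
    pair_discordance,
    per_probe_differential,
    restricted_amplifications,
)
from her2het.io import GeneAnnotation

from conftest import make_state_profile


def _group(label, rows):
    return [make_state_profile(f"T{i+1}", label, r) for i, r in enumerate(rows)]


class TestPerProbeDifferential:
    def test_fully_differential_probe(self):
        # probe 0 amplified in all 12 positive and no negative components:
        # only the two extreme tables are as unlikely, p = 2 / C(24,12)
        a = _group("HER2_POS", [[2, 0]] * 12)
        b = _group("HER2_NEG", [[0, 0]] * 12)
        res = per_probe_differential(a, b, event="amp")
        want = 2 / math.comb(24, 12)
        assert res.loc[0, "p"] == pytest.approx(want, rel=1e-9)
        assert res.loc[0, "p"] == pytest.approx(7.40e-7, rel=5e-3)
        assert res.loc[1, "p"] == 1.0
        assert res.loc[0, "freq_a"] == 1.0 and res.loc[0, "freq_b"] == 0.0

    def test_identical_counts_p_one(self):
        a = _group("HER2_POS", [[1, -1], [0, -1], [1, 0]])
        b = _group("HER2_NEG", [[1, -1], [1, 0], [0, -1]])
        res = per_probe_differential(a, b, event="gain_or_amp")
        assert (res["p"] == 1.0).all()

    def test_mismatched_grids_rejected(self):
        a = _group("HER2_POS", [[0, 0], [0, 0]])
        b = _group("HER2_NEG", [[0], [0]])
        with pytest.raises(ValueError, match="grids"):
            per_probe_differential(a, b)

    def test_requires_two_samples_per_group(self):
        a = _group("HER2_POS", [[0, 0]])
        b = _group("HER2_NEG", [[0, 0], [0, 0]])
        with pytest.raises(ValueError, match="2 samples"):
            per_probe_differential(a, b)

    def test_amp_channel_ignores_plain_gains(self):
        a = _group("HER2_POS", [[1, 2]] * 4)
        b = _group("HER2_NEG", [[0, 2]] * 4)
        res = per_probe_differential(a, b, event="amp")
        assert (res["p"] == 1.0).all()  # gains differ, amplifications do not


class TestPairDiscordance:
    def test_identical_profiles_empty(self):
        p = make_state_profile("T1", "HER2_POS", [0, 1, 2, -1])
        n = make_state_profile("T1", "HER2_NEG", [0, 1, 2, -1])
        assert pair_discordance(p, n) == []

    def test_single_run(self):
        enc_p = [0] * 20
        enc_n = [0] * 20
        for i in range(10, 15):
            enc_n[i] = 2
        p = make_state_profile("T1", "HER2_POS", enc_p)
        n = make_state_profile("T1", "HER2_NEG", enc_n)
        runs = pair_discordance(p, n)
        assert len(runs) == 1
        chrom, lo, hi, sp, sn = runs[0]
        assert (lo, hi) == (10, 15) and sn == [2] * 5 and sp == [0] * 5

    def test_symmetric_probe_count(self):
        rng = np.random.default_rng(1)
        a = make_state_profile("T1", "HER2_POS", rng.integers(-1, 3, 50))
        b = make_state_profile("T1", "HER2_NEG", rng.integers(-1, 3, 50))
        n_ab = sum(hi - lo for _, lo, hi, _, _ in pair_discordance(a, b))
        n_ba = sum(hi - lo for _, lo, hi, _, _ in pair_discordance(b, a))
        assert n_ab == n_ba

    def test_missing_probes_excluded(self):
        miss = [False, True, False]
        p = make_state_profile("T1", "HER2_POS", [0, 0, 0], missing=miss)
        n = make_state_profile("T1", "HER2_NEG", [0, 2, 0])
        assert pair_discordance(p, n) == []


def _annotation(n, chrom="chr1"):
    return [GeneAnnotation(f"g{i}", chrom, i * 50000, (i + 1) * 50000)
            for i in range(n)]


class TestRestrictedAmplifications:
    def test_toy_event_with_genes(self):
        enc_n = [0] * 30
        for i in range(10, 21):
            enc_n[i] = 2
        pairs = [("T1",
                  make_state_profile("T1", "HER2_POS", [0] * 30),
                  make_state_profile("T1", "HER2_NEG", enc_n))]
        events, rec = restricted_amplifications(pairs, _annotation(30))
        assert len(events) == 1
        ev = events[0]
        assert (ev.probe_lo, ev.probe_hi) == (10, 21)
        assert ev.genes == [f"g{i}" for i in range(10, 21)]
        assert set(rec["gene"]) == set(ev.genes)
        assert (rec["n_cases"] == 1).all()

    def test_no_amplification_empty(self):
        pairs = [("T1",
                  make_state_profile("T1", "HER2_POS", [0, 1, -1]),
                  make_state_profile("T1", "HER2_NEG", [1, 0, 0]))]
        events, rec = restricted_amplifications(pairs, _annotation(3))
        assert events == [] and len(rec) == 0

    def test_partner_gain_still_counts_as_restricted(self):
        # restriction contrasts amplification, not gain
        pairs = [("T1",
                  make_state_profile("T1", "HER2_POS", [1, 1]),
                  make_state_profile("T1", "HER2_NEG", [2, 2]))]
        events, _ = restricted_amplifications(pairs, _annotation(2))
        assert len(events) == 1 and events[0].genes == ["g0", "g1"]

    def test_recurrence_counts_distinct_cases(self):
        def pair(case):
            enc = [0] * 10
            enc[4] = enc[5] = 2
            return (case,
                    make_state_profile(case, "HER2_POS", [0] * 10),
                    make_state_profile(case, "HER2_NEG", enc))
        events, rec = restricted_amplifications(
            [pair("T2"), pair("T4")], _annotation(10))
        assert len(events) == 2
        assert dict(zip(rec["gene"], rec["n_cases"])) == {"g4": 2, "g5": 2}

    def test_direction_flag(self):
        pairs = [("T1",
                  make_state_profile("T1", "HER2_POS", [2, 0]),
                  make_state_profile("T1", "HER2_NEG", [0, 0]))]
        ev_neg, _ = restricted_amplifications(pairs, _annotation(2), "neg_only")
        ev_pos, _ = restricted_amplifications(pairs, _annotation(2), "pos_only")
        assert ev_neg == [] and len(ev_pos) == 1

    def test_annotation_genome_mismatch(self):
        pairs = [("T1",
                  make_state_profile("T1", "HER2_POS", [0, 0]),
                  make_state_profile("T1", "HER2_NEG", [2, 2]))]
        with pytest.raises(ValueError, match="genome"):
            restricted_amplifications(pairs, _annotation(2, chrom="scaffold_1"))

    def test_stable_under_grid_subsetting(self):
        """Dropping probes outside an event leaves the event's genes intact."""
        enc_n = [0, 0, 2, 2, 2, 0, 0, 0]
        full = [("T1",
                 make_state_profile("T1", "HER2_POS", [0] * 8),
                 make_state_profile("T1", "HER2_NEG", enc_n))]
        sub = [("T1",
                make_state_profile("T1", "HER2_POS", [0] * 5),
                make_state_profile("T1", "HER2_NEG", [0, 2, 2, 2, 0]))]
        ann = _annotation(8)
        ev_full, _ = restricted_amplifications(full, ann)
        # subset grid starts one probe before the event: shift annotation
        ann_sub = [GeneAnnotation(g.gene, g.chrom, g.start - 50000, g.end - 50000)
                   for g in ann[1:6]]
        ev_sub, _ = restricted_amplifications(sub, ann_sub)
        assert ev_full[0].genes == ev_sub[0].genes
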