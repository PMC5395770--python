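"""Window tiling, per-window pi/Dxy, DR classification and block merging."""
import itertools

import numpy as np
import pandas as pd
import pytest

from ricesweep.io import MISSING
from ricesweep.scan import (DRBlock, Thresholds, Window, classify_window,
                            classify_windows, dxy_in_region, make_windows,
                            merge_blocks, pi_in_region, summarize_blocks,
                            window_stats)

from conftest import make_gm, make_sample_table


class TestMakeWindows:
    def test_partial_terminal_window(self):
        w = make_windows({"chrA": 25_000})
        assert len(w) == 3
        assert (w[-1].start, w[-1].end, w[-1].length) == (20_001, 25_000, 5000)

    def test_exact_multiple(self):
        w = make_windows({"chrA": 10_000})
        assert len(w) == 1 and w[0] == Window("chrA", 1, 10_000)

    def test_tiling_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            L = int(rng.integers(1, 100_000))
            size = int(rng.integers(1, 20_000))
            ws = make_windows({"c": L}, size)
            # brute force: every position covered exactly once
            assert len(ws) == -(-L // size)
            assert ws[0].start == 1 and ws[-1].end == L
            for a, b in zip(ws, ws[1:]):
                assert b.start == a.end + 1
            assert all(w.length <= size for w in ws)

    def test_bad_size_rejected(self):
        with pytest.raises(ValueError):
            make_windows({"c": 100}, 0)


class TestPiDxy:
    def test_two_samples_two_diffs_at_threshold(self):
        gm = make_gm([[0, 1], [0, 1]], pos=[5, 10])
        assert pi_in_region(gm, gm.samples, "japonica",
                            ("chr01", 1, 10_000)) == pytest.approx(0.0002)

    def test_monomorphic_group_is_zero(self):
        gm = make_gm(np.zeros((5, 4), dtype=np.int8))
        assert pi_in_region(gm, gm.samples, "japonica",
                            ("chr01", 1, 1000)) == 0.0

    def test_pi_matches_all_pairs_bruteforce(self):
        rng = np.random.default_rng(7)
        codes = rng.integers(-1, 3, (300, 6)).astype(np.int8)
        gm = make_gm(codes,
                     pos=np.sort(rng.choice(9000, 300, replace=False)) + 1)
        got = pi_in_region(gm, gm.samples, "japonica", ("chr01", 1, 9000))
        dists = []
        for a, b in itertools.combinations(range(6), 2):
            ca, cb = codes[:, a], codes[:, b]
            both = (ca != MISSING) & (cb != MISSING)
            dists.append((both & (ca != cb)).sum() / 9000)
        assert got == pytest.approx(np.mean(dists))

    def test_dxy_fixed_divergent_at_threshold(self):
        st = make_sample_table(n_jap=3, n_ind=2)
        codes = np.zeros((20, 5), dtype=np.int8)
        codes[:, 3:] = 1
        gm = make_gm(codes, pos=np.arange(1, 21) * 100, samples=st)
        assert dxy_in_region(gm, st, "japonica", "indica",
                             ("chr01", 1, 10_000)) == pytest.approx(0.002)

    def test_dxy_same_singleton_is_zero(self):
        st = make_sample_table(n_jap=2, n_ind=1)
        gm = make_gm([[0, 1, 1], [1, 0, 0]], samples=st)
        # indica vs indica-like singleton against itself via cross pairs
        assert dxy_in_region(gm, st, "indica", "indica",
                             ("chr01", 1, 100)) == 0.0

    def test_dxy_matches_cross_pairs_bruteforce(self):
        rng = np.random.default_rng(8)
        st = make_sample_table(n_jap=4, n_ind=3)
        codes = rng.integers(-1, 2, (200, 7)).astype(np.int8)
        gm = make_gm(codes, pos=np.sort(
            rng.choice(5000, 200, replace=False)) + 1, samples=st)
        got = dxy_in_region(gm, st, "japonica", "indica", ("chr01", 1, 5000))
        dists = []
        for a in range(4):
            for b in range(4, 7):
                ca, cb = codes[:, a], codes[:, b]
                both = (ca != MISSING) & (cb != MISSING)
                dists.append((both & (ca != cb)).sum() / 5000)
        assert got == pytest.approx(np.mean(dists))

    def test_dxy_reduces_to_pooled_pi_relation(self):
        """Pooled-cultivar pi decomposes into within + cross terms."""
        rng = np.random.default_rng(9)
        st = make_sample_table(n_jap=3, n_ind=3)
        codes = rng.integers(0, 2, (100, 6)).astype(np.int8)
        gm = make_gm(codes, samples=st)
        reg = ("chr01", 1, 1000)
        pj = pi_in_region(gm, st, "japonica", reg)
        pi_ = pi_in_region(gm, st, "indica", reg)
        dxy = dxy_in_region(gm, st, "japonica", "indica", reg)
        pc = pi_in_region(gm, st, "cultivar", reg)
        # C(6,2)=15 pairs: 3 within each group, 9 cross
        assert pc == pytest.approx((3 * pj + 3 * pi_ + 9 * dxy) / 15)


def _row(pj, pi_, dxy, pw, masked=0.0, n_snps=10):
    return pd.Series({
        "pi_japonica": pj, "pi_indica": pi_, "dxy_japonica_indica": dxy,
        "pi_wild": pw, "masked_fraction": masked, "n_snps": n_snps,
        "callable_japonica": 10.0, "callable_indica": 10.0,
        "callable_wild": 10.0})


class TestClassify:
    def test_dr1_worked_example(self):
        # the block-inventory average profile of the divergent-sweep class
        lab, _ = classify_window(_row(0.00013, 0.00017, 0.00344, 0.00203),
                                 Thresholds())
        assert lab == "DR-I"

    def test_dr2_worked_example(self):
        lab, _ = classify_window(_row(0.00010, 0.00011, 0.00012, 0.00213),
                                 Thresholds())
        assert lab == "DR-II"

    def test_all_zero_is_none(self):
        lab, _ = classify_window(_row(0, 0, 0, 0), Thresholds())
        assert lab == "none"

    def test_boundaries_inclusive(self):
        th = Thresholds()
        assert classify_window(_row(2e-4, 2e-4, 2e-3, 0), th)[0] == "DR-I"
        assert classify_window(_row(2e-4, 2e-4, 2e-4, 1e-3), th)[0] == "DR-II"
        assert classify_window(
            _row(2.0001e-4, 1e-4, 3e-3, 1e-3), th)[0] == "none"

    def test_masked_or_thin_windows_unclassifiable(self):
        th = Thresholds()
        lab, why = classify_window(_row(0, 0, 3e-3, 0, masked=0.5), th)
        assert lab == "unclassifiable" and why == "masked_fraction"
        row = _row(1e-4, 1e-4, 3e-3, 1e-3)
        row["callable_wild"] = 1.0
        lab, why = classify_window(row, th)
        assert lab == "unclassifiable" and "wild" in why

    def test_classification_monotone(self):
        """Raising Dxy never demotes DR-I; lowering cultivar pi never
        demotes either type."""
        rng = np.random.default_rng(4)
        th = Thresholds()
        for _ in range(200):
            pj, pi_ = rng.uniform(0, 4e-4, 2)
            dxy = rng.uniform(0, 4e-3)
            pw = rng.uniform(0, 4e-3)
            lab, _ = classify_window(_row(pj, pi_, dxy, pw), th)
            if lab == "DR-I":
                lab2, _ = classify_window(
                    _row(pj, pi_, dxy * 2, pw), th)
                assert lab2 == "DR-I"
            if lab in ("DR-I", "DR-II"):
                lab3, _ = classify_window(
                    _row(pj / 2, pi_ / 2, dxy, pw), th)
                assert lab3 == lab

    def test_dr_types_disjoint_by_construction(self):
        with pytest.raises(ValueError):
            Thresholds(dxy_max_dr2=0.002, dxy_min_dr1=0.002)


def _frame(rows):
    """Window-stat frame from (start, label-ish stats) tuples, 10-kb grid."""
    recs = []
    for i, (pj, pi_, dxy, pw) in enumerate(rows):
        recs.append({
            "chrom": "chr01", "start": 1 + 10_000 * i, "end": 10_000 * (i + 1),
            "length": 10_000, "eff_length": 10_000.0, "masked_fraction": 0.0,
            "n_snps": 50, "pi_japonica": pj, "pi_indica": pi_,
            "dxy_japonica_indica": dxy, "pi_wild": pw,
            "callable_japonica": 10.0, "callable_indica": 10.0,
            "callable_wild": 10.0})
    return pd.DataFrame(recs)


DR1 = (1e-4, 1e-4, 3e-3, 2e-3)
DR2 = (1e-4, 1e-4, 1e-4, 2e-3)
BG = (1e-3, 1.5e-3, 5e-3, 5e-3)
BRIDGE1 = (2.5e-4, 1.2e-4, 3e-3, 2e-3)     # fails only pi ceilings, <= relax
BAD_BRIDGE = (4e-4, 1e-4, 3e-3, 2e-3)      # above the relaxed ceiling


class TestMerge:
    def test_bridge_absorbed_with_relaxed_flag(self):
        th = Thresholds()
        lab = classify_windows(_frame([BG, DR1, BRIDGE1, DR1, BG]), th)
        blocks = merge_blocks(lab, th)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.type, b.start, b.end, b.relaxed) == (
            "DR-I", 10_001, 40_000, True)
        assert b.n_windows == 3

    def test_bridge_above_relax_not_absorbed(self):
        th = Thresholds()
        lab = classify_windows(_frame([DR1, BAD_BRIDGE, DR1]), th)
        blocks = merge_blocks(lab, th)
        assert [(b.start, b.end) for b in blocks] == [(1, 10_000),
                                                      (20_001, 30_000)]
        assert not any(b.relaxed for b in blocks)

    def test_isolated_window_is_its_own_block(self):
        th = Thresholds()
        lab = classify_windows(_frame([BG, DR2, BG]), th)
        blocks = merge_blocks(lab, th)
        assert len(blocks) == 1
        assert (blocks[0].type, blocks[0].start, blocks[0].end) == (
            "DR-II", 10_001, 20_000)

    def test_type_change_breaks_block(self):
        th = Thresholds()
        lab = classify_windows(_frame([DR1, DR1, DR2, DR2]), th)
        blocks = merge_blocks(lab, th)
        assert [b.type for b in blocks] == ["DR-I", "DR-II"]
        assert [b.n_windows for b in blocks] == [2, 2]

    def test_blocks_cover_member_windows_exactly(self):
        th = Thresholds()
        lab = classify_windows(_frame([DR1, DR1, BG, DR1]), th)
        blocks = merge_blocks(lab, th)
        assert [(b.start, b.end) for b in blocks] == [(1, 20_000),
                                                      (30_001, 40_000)]
        assert sum(b.length for b in blocks) == 30_000

    def test_random_sequences_match_run_merge_oracle(self):
        """Brute-force run merging (no bridging) on random label layouts."""
        rng = np.random.default_rng(12)
        th = Thresholds()
        choices = [DR1, DR2, BG]
        for _ in range(30):
            rows = [choices[i] for i in rng.integers(0, 3, 12)]
            lab = classify_windows(_frame(rows), th)
            blocks = merge_blocks(lab, th)
            # oracle: scan labels, merge equal adjacent
            labels = list(lab["label"])
            expect = []
            i = 0
            while i < len(labels):
                if labels[i] in ("DR-I", "DR-II"):
                    j = i
                    while j + 1 < len(labels) and labels[j + 1] == labels[i]:
                        j += 1
                    expect.append((labels[i], 1 + 10_000 * i, 10_000 * (j + 1)))
                    i = j + 1
                else:
                    i += 1
            assert [(b.type, b.start, b.end) for b in blocks] == expect

    def test_unclassifiable_windows_do_not_bridge(self):
        th = Thresholds()
        df = _frame([DR1, DR1, DR1])
        df.loc[1, "masked_fraction"] = 0.9
        lab = classify_windows(df, th)
        assert lab["label"].iloc[1] == "unclassifiable"
        blocks = merge_blocks(lab, th)
        assert [(b.start, b.end) for b in blocks] == [(1, 10_000),
                                                      (20_001, 30_000)]

    def test_aggregated_stats_are_length_weighted(self):
        th = Thresholds()
        df = _frame([DR1, DR1])
        df.loc[1, "eff_length"] = 5000.0
        df.loc[1, "pi_japonica"] = 2e-4
        lab = classify_windows(df, th)
        b = merge_blocks(lab, th)[0]
        assert b.stats["pi_japonica"] == pytest.approx(
            (1e-4 * 10_000 + 2e-4 * 5000) / 15_000)


class TestSummaries:
    def test_bundled_dr1_inventory_summary(self):
        from ricesweep.tables import inventory_blocks, load_dr1_inventory
        blocks = inventory_blocks(load_dr1_inventory(), "DR-I")
        s = summarize_blocks(blocks).iloc[0]
        assert s["n_blocks"] == 28
        assert s["mean_length"] == pytest.approx(31829, abs=1)
        assert s["max_length"] == 198_172
        assert s["total_length"] == pytest.approx(891_204)

    def test_empty_input(self):
        assert len(summarize_blocks([])) == 0

    def test_window_stats_on_simulation_recovers_truth(self, gm_small):
        params, res, st, _, gmf = gm_small
        th = Thresholds()
        windows = make_windows(params.chrom_lengths)
        lab = classify_windows(window_stats(gmf, st, windows), th)
        blocks = merge_blocks(lab, th)
        got = {(b.chrom, b.start, b.end, b.type) for b in blocks}
        want = {(r.chrom, r.start, r.end, r.type) for r in res.truth}
        assert got == want
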