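from __future__ import annotations

import numpy as np
import pytest

from rohkit.genotype_io import HET, HOM_A, MISSING
from rohkit.roh_detection import (
    ScanParams,
    WindowParams,
    filter_tracts,
    find_homozygous_runs,
    merge_runs,
    scan_roh,
    validate_tracts,
    windowed_roh,
)
from rohkit.synthetic_data import SimConfig, simulate_founders, simulate_pedigree

from reference_impl import brute_force_scan, naive_windowed

P = ScanParams()


class TestFindRuns:
    def test_all_het_chromosome_yields_nothing(self):
        calls = np.full(100, HET, dtype=np.int8)
        pos = np.arange(1, 101) * 20_000
        assert find_homozygous_runs(calls, pos, P) == []

    def test_exact_500kb_span_is_kept(self):
        """A zero-het run spanning exactly the minimum length qualifies (>=)."""
        pos = np.concatenate(([990_000], np.linspace(1_000_000, 1_499_999, 41).astype(int),
                              [1_510_000]))
        calls = np.full(43, HOM_A, dtype=np.int8)
        calls[0] = calls[-1] = HET
        runs = find_homozygous_runs(calls, pos, P)
        assert len(runs) == 1
        start, end, *_ = runs[0]
        assert end - start + 1 == 500_000

    def test_one_bp_short_of_threshold_is_dropped(self):
        pos = np.array([1_000_000, 1_499_998])
        calls = np.array([HOM_A, HOM_A], dtype=np.int8)
        assert find_homozygous_runs(calls, pos, P) == []

    def test_missing_policy_break_vs_ignore(self):
        pos = np.linspace(1_000_000, 2_000_000, 50).astype(int)
        calls = np.full(50, HOM_A, dtype=np.int8)
        calls[25] = MISSING
        broken = find_homozygous_runs(calls, pos, P)
        ignored = find_homozygous_runs(
            calls, pos, ScanParams(missing_policy="IGNORE")
        )
        assert len(ignored) == 1 and ignored[0][1] - ignored[0][0] + 1 == 1_000_001
        assert all(r[1] - r[0] + 1 < 1_000_001 for r in broken)


class TestMergeAndFilter:
    def test_gap_below_threshold_merges(self):
        runs = [(1_000_000, 1_600_000, 0, 0), (1_640_000, 2_240_000, 0, 0)]
        assert merge_runs(runs, P) == [(1_000_000, 2_240_000)]

    def test_gap_exactly_at_threshold_does_not_merge(self):
        runs = [(1_000_000, 1_600_000, 0, 0), (1_650_000, 2_240_000, 0, 0)]
        assert merge_runs(runs, P) == [(1_000_000, 1_600_000), (1_650_000, 2_240_000)]

    def test_chain_merges_transitively(self):
        runs = []
        start = 1_000_000
        for _ in range(6):
            runs.append((start, start + 600_000, 0, 0))
            start += 640_000  # 40 kb gaps
        merged = merge_runs(runs, P)
        assert merged == [(1_000_000, runs[-1][1])]

    def test_marker_count_boundary(self):
        pos = np.linspace(1_000_000, 1_600_000, 41).astype(int)
        kept = filter_tracts([(999_999, 1_600_001)], pos, P)
        assert kept == [(999_999, 1_600_001, 41)]
        assert filter_tracts([(pos[1] - 1, 1_600_001)], pos, P) == []  # 40 markers

    def test_marker_counts_match_linear_scan(self):
        rng = np.random.default_rng(3)
        pos = np.sort(rng.choice(10_000_000, 300, replace=False))
        tracts = [(int(a), int(a) + int(b)) for a, b in
                  zip(rng.integers(0, 9_000_000, 20), rng.integers(1, 1_000_000, 20))]
        loose = ScanParams(min_markers=1)
        for start, end, count in filter_tracts(sorted(tracts), pos, loose):
            assert count == sum(1 for p in pos if start <= p <= end)


class TestScanCaller:
    def test_all_heterozygous_panel_gives_empty_set(self, make_panel):
        pos = {"1": list(np.arange(1, 200) * 10_000)}
        panel = make_panel(np.full((3, 199), HET, dtype=np.int8), pos)
        assert scan_roh(panel).empty

    def test_truth_segments_recovered_on_clean_cohort(self):
        """Every detectable truth segment (>=2.5 Mb, >=41 markers) is hit."""
        cfg = SimConfig(seed=13, n_autosomes=5, autosome_length=48_000_000,
                        marker_spacing=12_800, x_length=None, n_offspring=25,
                        error_rate=0.0, missing_rate=0.0, pedigree="full_sib")
        panel, truth = simulate_pedigree(cfg, simulate_founders(cfg))
        tracts = scan_roh(panel)
        validate_tracts(tracts)
        big = truth[truth["autozygous"] & (truth["end"] - truth["start"] + 1 >= 2_500_000)]
        assert len(big) > 10
        for _, seg in big.iterrows():
            hit = tracts[
                (tracts["sample"] == seg["sample"])
                & (tracts["chrom"] == seg["chrom"])
                & (tracts["start"] <= seg["end"])
                & (tracts["end"] >= seg["start"])
            ]
            assert not hit.empty

    def test_doubling_merge_gap_never_reduces_coverage(self):
        cfg = SimConfig(seed=17, n_autosomes=4, autosome_length=48_000_000,
                        marker_spacing=12_800, x_length=None, n_offspring=20,
                        error_rate=0.01, missing_rate=0.0, pedigree="full_sib")
        panel, _ = simulate_pedigree(cfg, simulate_founders(cfg))
        t50 = scan_roh(panel, ScanParams(max_merge_gap=50_000))
        t100 = scan_roh(panel, ScanParams(max_merge_gap=100_000))
        assert t100["length_bp"].sum() >= t50["length_bp"].sum()

    def test_het_markers_inside_tracts_only_in_merged_gaps(self):
        """Pre-merge runs are het-free; any HET in a tract sits in a gap."""
        cfg = SimConfig(seed=19, n_autosomes=3, autosome_length=48_000_000,
                        marker_spacing=12_800, x_length=None, n_offspring=15,
                        error_rate=0.01, missing_rate=0.0, pedigree="full_sib")
        panel, _ = simulate_pedigree(cfg, simulate_founders(cfg))
        tracts = scan_roh(panel)
        mm = panel.markers
        checked = 0
        for _, row in tracts.iterrows():
            sl = mm.chrom_slice(row["chrom"])
            pos = mm.table["pos"].to_numpy()[sl]
            calls = panel.sample_calls(row["sample"])[sl]
            runs = find_homozygous_runs(calls, pos, P)
            i0 = np.searchsorted(pos, row["start"], side="left")
            i1 = np.searchsorted(pos, row["end"], side="right")
            for j in range(i0, i1):
                if calls[j] == HET:
                    checked += 1
                    assert not any(s <= pos[j] <= e for s, e, *_ in runs)
        assert checked > 0  # the error model did place HETs inside merged tracts


class TestWindowedCaller:
    def test_fully_homozygous_chromosome_is_one_tract(self, make_panel):
        pos = {"1": list(np.linspace(1, 1_000_000, 100).astype(int))}
        panel = make_panel(np.zeros((1, 100), dtype=np.int8), pos)
        tracts = windowed_roh(panel)
        assert len(tracts) == 1
        row = tracts.iloc[0]
        assert row["start"] == 1 and row["end"] == 1_000_000 and row["n_markers"] == 100

    def test_single_het_splits_a_long_tract(self, make_panel):
        pos = {"1": list(np.linspace(1, 10_000_000, 400).astype(int))}
        calls = np.zeros((1, 400), dtype=np.int8)
        calls[0, 200] = HET
        tracts = windowed_roh(panel := make_panel(calls, pos))
        assert len(tracts) == 2
        assert (tracts["end"] < pos["1"][200]).sum() == 1
        assert (tracts["start"] > pos["1"][200]).sum() == 1

    def test_chromosome_shorter_than_window_gives_no_calls(self, make_panel):
        pos = {"1": list(np.linspace(1, 10_000_000, 30).astype(int))}
        panel = make_panel(np.zeros((1, 30), dtype=np.int8), pos)
        assert windowed_roh(panel).empty

    def test_matches_naive_reference_on_edge_cases(self, make_panel):
        rng = np.random.default_rng(23)
        for _ in range(40):
            m = int(rng.integers(41, 150))
            pos = np.cumsum(rng.integers(5_000, 25_000, size=m))
            calls = np.zeros(m, dtype=np.int8)
            calls[rng.random(m) < 0.05] = HET
            calls[rng.random(m) < 0.02] = MISSING
            panel = make_panel(calls[None, :], {"1": list(pos)})
            got = [
                (r["start"], r["end"], r["n_markers"])
                for _, r in windowed_roh(panel).iterrows()
            ]
            assert got == naive_windowed(list(calls), list(pos))


class TestParamValidation:
    def test_merge_gap_must_be_below_min_span(self):
        with pytest.raises(ValueError):
            ScanParams(min_span=500_000, max_merge_gap=500_000)

    def test_density_gap_checks_cannot_be_enabled(self):
        with pytest.raises(NotImplementedError):
            WindowParams(density_kb_per_snp=5000.0)


def test_scan_matches_bruteforce_on_random_chromosomes(make_panel):
    """Spot equivalence with the O(n^2) oracle (full sweep in acceptance)."""
    rng = np.random.default_rng(29)
    for _ in range(50):
        m = int(rng.integers(10, 200))
        pos = np.cumsum(rng.integers(2_000, 30_000, size=m))
        calls = np.zeros(m, dtype=np.int8)
        calls[rng.random(m) < rng.uniform(0, 0.2)] = HET
        calls[rng.random(m) < 0.03] = MISSING
        panel = make_panel(calls[None, :], {"1": list(pos)})
        got = [
            (r["start"], r["end"], r["n_markers"])
            for _, r in scan_roh(panel).iterrows()
        ]
        assert got == brute_force_scan(list(calls), list(pos))
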