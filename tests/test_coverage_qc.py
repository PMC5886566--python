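import numpy as np
import pandas as pd
import pytest

from ffpeqc.coverage_qc import (
    CoverageProfile,
    QcGates,
    TargetRegions,
    duplicate_fraction,
    gene_mean_coverage,
    load_depth_track,
    median_coverage,
    off_target_fraction,
    pct_ge_threshold,
    summarize_coverage,
)
from ffpeqc.simulate import SimulationConfig, make_targets, simulate_depth_track


def write_track(path, rows):
    path.write_text("".join(f"{c}\t{p}\t{d}\n" for c, p, d in rows))
    return path


@pytest.fixture
def targets100():
    return TargetRegions.from_intervals([("chr1", 0, 100)])


class TestTargets:
    def test_overlapping_intervals_merge(self):
        tr = TargetRegions.from_intervals(
            [("chr1", 0, 50), ("chr1", 40, 100), ("chr2", 10, 20)])
        assert tr.total_bases == 110
        assert tr.intervals() == [("chr1", 0, 100), ("chr2", 10, 20)]

    def test_inverted_interval_rejected(self):
        with pytest.raises(ValueError, match="interval"):
            TargetRegions.from_intervals([("chr1", 10, 10)])

    def test_merge_does_not_change_statistics(self, tmp_path):
        rows = [("chr1", p, 40) for p in range(1, 101)]
        track = write_track(tmp_path / "d.tsv", rows)
        merged = TargetRegions.from_intervals([("chr1", 0, 100)])
        split = TargetRegions.from_intervals(
            [("chr1", 0, 30), ("chr1", 30, 60), ("chr1", 50, 100)])
        for stat in (median_coverage, pct_ge_threshold):
            assert stat(load_depth_track(track, merged)) == \
                   stat(load_depth_track(track, split))


class TestDepthTrack:
    def test_uniform_track(self, tmp_path, targets100):
        track = write_track(tmp_path / "d.tsv",
                            [("chr1", p, 50) for p in range(1, 101)])
        profile = load_depth_track(track, targets100)
        assert (profile.all_depths() == 50).all()

    def test_empty_track_is_all_zero(self, tmp_path, targets100):
        profile = load_depth_track(write_track(tmp_path / "d.tsv", []), targets100)
        assert profile.all_depths().sum() == 0

    def test_hand_tally_of_100_base_fixture(self, tmp_path, targets100):
        # 30 bases at depth 10, 30 at depth 40, 40 missing (depth 0)
        rows = ([("chr1", p, 10) for p in range(1, 31)]
                + [("chr1", p, 40) for p in range(31, 61)])
        profile = load_depth_track(write_track(tmp_path / "d.tsv", rows), targets100)
        assert pct_ge_threshold(profile, 30) == 30.0
        assert pct_ge_threshold(profile, 10) == 60.0
        assert median_coverage(profile) == 10.0
        assert profile.all_depths().sum() == 30 * 10 + 30 * 40

    def test_malformed_line_raises(self, tmp_path, targets100):
        p = tmp_path / "bad.tsv"
        p.write_text("chr1\t1\t10\nchr1\toops\t5\n")
        with pytest.raises(ValueError, match="malformed"):
            load_depth_track(p, targets100)


class TestSummaries:
    def test_threshold_worked_examples(self, tmp_path, targets100):
        uniform = load_depth_track(
            write_track(tmp_path / "u.tsv", [("chr1", p, 50) for p in range(1, 101)]),
            targets100)
        assert pct_ge_threshold(uniform, 30) == 100.0
        halves = load_depth_track(
            write_track(tmp_path / "h.tsv",
                        [("chr1", p, 29 if p <= 50 else 31) for p in range(1, 101)]),
            targets100)
        assert pct_ge_threshold(halves, 30) == 50.0

    def test_pct_ge_monotone_in_threshold_and_100_at_zero(self, rng, targets100):
        profile = CoverageProfile.zeros(targets100)
        profile.depths["chr1"][:] = rng.poisson(40, size=100)
        values = [pct_ge_threshold(profile, t) for t in range(0, 120, 10)]
        assert values[0] == 100.0
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_median_even_count_rule(self):
        tr = TargetRegions.from_intervals([("chr1", 0, 4)])
        profile = CoverageProfile.zeros(tr)
        profile.depths["chr1"][:] = [0, 0, 10, 90]
        assert median_coverage(profile) == 5.0

    def test_median_matches_sort_oracle(self, rng, targets100):
        profile = CoverageProfile.zeros(targets100)
        depths = rng.integers(0, 200, size=100)
        profile.depths["chr1"][:] = depths
        s = np.sort(depths)
        assert median_coverage(profile) == (s[49] + s[50]) / 2

    def test_poisson_median_near_lambda(self):
        lam = 45
        tr = TargetRegions.from_intervals([("chr1", 0, 100_000)])
        profile = CoverageProfile.zeros(tr)
        profile.depths["chr1"][:] = np.random.default_rng(31).poisson(lam, 100_000)
        assert abs(median_coverage(profile) - lam) <= 1

    def test_empty_targets_rejected(self):
        tr = TargetRegions.from_intervals([])
        with pytest.raises(ValueError, match="empty"):
            median_coverage(CoverageProfile.zeros(tr))


class TestReadsAndDuplicates:
    def test_off_target_rules(self, targets100):
        reads = pd.DataFrame(
            [("chr1", 10, 110),    # inside
             ("chr1", 99, 199),    # 1-base overlap -> on-target
             ("chr1", 100, 200),   # zero overlap -> off-target
             ("chr2", 0, 100)],    # other chromosome -> off-target
            columns=["chrom", "start", "end"])
        assert off_target_fraction(reads, targets100) == 50.0
        all_in = reads.iloc[:2]
        assert off_target_fraction(all_in, targets100) == 0.0

    def test_zero_reads_rejected(self, targets100):
        with pytest.raises(ValueError, match="no reads"):
            off_target_fraction(pd.DataFrame(columns=["chrom", "start", "end"]),
                                targets100)

    @pytest.mark.parametrize("total,dup,expected",
                             [(100, 10, 10.0), (80_000_000, 0, 0.0)])
    def test_duplicate_fraction(self, total, dup, expected):
        assert duplicate_fraction(total, dup) == expected

    def test_more_duplicates_than_reads_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            duplicate_fraction(10, 11)


class TestGeneCoverage:
    def test_uniform_gene(self, tmp_path, targets100):
        profile = load_depth_track(
            write_track(tmp_path / "d.tsv", [("chr1", p, 40) for p in range(1, 101)]),
            targets100)
        genes = pd.DataFrame([("chr1", 0, 100, "TP53")],
                             columns=["chrom", "start", "end", "name"])
        assert gene_mean_coverage(profile, genes) == {"TP53": 40.0}

    def test_half_covered_gene(self, tmp_path, targets100):
        profile = load_depth_track(
            write_track(tmp_path / "d.tsv", [("chr1", p, 60) for p in range(1, 51)]),
            targets100)
        genes = pd.DataFrame([("chr1", 0, 100, "APC")],
                             columns=["chrom", "start", "end", "name"])
        assert gene_mean_coverage(profile, genes) == {"APC": 30.0}

    def test_brute_force_mean(self, rng, tmp_path, targets100):
        depths = rng.integers(0, 90, size=100)
        profile = load_depth_track(
            write_track(tmp_path / "d.tsv",
                        [("chr1", p + 1, int(d)) for p, d in enumerate(depths)]),
            targets100)
        genes = pd.DataFrame([("chr1", 20, 70, "G1")],
                             columns=["chrom", "start", "end", "name"])
        assert gene_mean_coverage(profile, genes)["G1"] == pytest.approx(
            depths[20:70].mean())


def test_simulated_track_truth_ledger_is_exact(tmp_path):
    cfg = SimulationConfig(n_reads=2000, n_target_intervals=10,
                           target_interval_length=200, seed=13)
    targets_df = make_targets(cfg)
    depth_df, read_df, (total, dup), truth = simulate_depth_track(cfg, targets_df, "FFPE")
    targets = TargetRegions.from_intervals(
        targets_df[["chrom", "start", "end"]].itertuples(index=False))
    track = tmp_path / "depth.tsv"
    depth_df.to_csv(track, sep="\t", header=False, index=False)
    profile = load_depth_track(track, targets)
    assert pct_ge_threshold(profile, cfg.cov_threshold) == pytest.approx(
        100 * truth["exceedance_fraction"])
    assert off_target_fraction(read_df, targets) == pytest.approx(
        100 * truth["n_off_target"] / truth["n_reads"])
    assert duplicate_fraction(total, dup) == 12.2


def test_qc_gates_flags():
    from ffpeqc.coverage_qc import CoverageSummary
    good = CoverageSummary("s", pct_ge_30x=97.0, median_cov=74.3, duplicate_pct=12.2)
    assert all(good.qc_flags(QcGates()).values())
    bad = CoverageSummary("s", pct_ge_30x=70.0, median_cov=50.0, duplicate_pct=30.0)
    assert not any(bad.qc_flags(QcGates()).values())
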