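"""Short-artifact clustering, cutoff derivation, filtering and hotspots."""

import itertools

import numpy as np
import pytest

import mitoqc as m
from mitoqc.read_filter import (
    DegenerateInput,
    InsufficientData,
    cluster_reads_2means,
    derive_length_cutoff,
    filter_reads,
    hotspot_amplicons,
)
from mitoqc.reads import AlignedReadRecord


def rec(length, mapq=50, start=1, amplicon=None, rid="r"):
    return AlignedReadRecord(rid, start, length, mapq, "+", amplicon)


def brute_force_2means(points: np.ndarray):
    """Exact minimum within-cluster SS over all 2-partitions of standardized
    points; independent oracle for the k-means route."""
    mu, sd = points.mean(axis=0), points.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (points - mu) / sd
    n = len(Z)
    best, best_labels = np.inf, None
    for bits in itertools.product([0, 1], repeat=n - 1):
        labels = np.array((0,) + bits)
        if labels.min() == labels.max():
            continue
        ss = 0.0
        for lab in (0, 1):
            grp = Z[labels == lab]
            ss += ((grp - grp.mean(axis=0)) ** 2).sum()
        if ss < best - 1e-12:
            best, best_labels = ss, labels
    return best, best_labels


class TestCluster2Means:
    def test_four_point_example(self):
        reads = [rec(40, 3), rec(45, 5), rec(150, 58), rec(160, 60)]
        result = cluster_reads_2means(reads, seed=0)
        assert result.centroid_short == pytest.approx((42.5, 4.0))
        assert result.centroid_long == pytest.approx((155.0, 59.0))
        assert result.midpoint_length == pytest.approx(98.75)

    def test_two_distinct_points_each_own_centroid(self):
        reads = [rec(50, 10), rec(150, 55)]
        result = cluster_reads_2means(reads, seed=0)
        assert result.centroid_short == pytest.approx((50.0, 10.0))
        assert result.centroid_long == pytest.approx((150.0, 55.0))

    def test_identical_points_degenerate(self):
        with pytest.raises(DegenerateInput):
            cluster_reads_2means([rec(80, 40)] * 5, seed=0)

    def test_single_read_insufficient(self):
        with pytest.raises(InsufficientData):
            cluster_reads_2means([rec(80, 40)], seed=0)

    def test_recovers_generating_modes(self):
        rng = np.random.default_rng(7)
        short = [rec(int(l), int(q)) for l, q in zip(
            rng.normal(60, 8, 1000), rng.uniform(2, 20, 1000))]
        long_ = [rec(int(l), int(q)) for l, q in zip(
            rng.normal(150, 10, 1000), rng.uniform(40, 60, 1000))]
        result = cluster_reads_2means(short + long_, seed=0)
        assert abs(result.centroid_short[0] - 60) < 5
        assert abs(result.centroid_long[0] - 150) < 5

    def test_matches_brute_force_on_small_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(40):
            n = int(rng.integers(3, 13))
            pts = np.column_stack([
                rng.integers(30, 200, n), rng.integers(1, 61, n)
            ]).astype(float)
            if len(np.unique(pts, axis=0)) < 2:
                continue
            reads = [rec(int(l), int(q)) for l, q in pts]
            result = cluster_reads_2means(reads, seed=0)
            ss_exact, _ = brute_force_2means(pts)
            mu, sd = pts.mean(axis=0), pts.std(axis=0)
            sd[sd == 0] = 1.0
            Z = (pts - mu) / sd
            ss_kmeans = sum(
                ((Z[result.assignment == lab]
                  - Z[result.assignment == lab].mean(axis=0)) ** 2).sum()
                for lab in (0, 1)
                if (result.assignment == lab).any()
            )
            assert ss_kmeans == pytest.approx(ss_exact, abs=1e-8)


class TestDeriveCutoff:
    def test_granularity_rounding_of_observed_midpoint(self):
        c = m.ClusterResult((70.0, 5.0), (78.32, 55.0), np.array([0, 1]))
        assert c.midpoint_length == pytest.approx(74.16)
        assert derive_length_cutoff([c], granularity=5) == 75
        assert derive_length_cutoff([c], granularity=10) == 80

    def test_mean_of_midpoints(self):
        c1 = m.ClusterResult((60.0, 5.0), (80.0, 50.0), np.array([0, 1]))
        c2 = m.ClusterResult((70.0, 5.0), (90.0, 50.0), np.array([0, 1]))
        assert derive_length_cutoff([c1, c2], granularity=5) == 75

    def test_exact_multiple_is_noop(self):
        c = m.ClusterResult((60.0, 5.0), (100.0, 50.0), np.array([0, 1]))
        assert derive_length_cutoff([c], granularity=5) == 80

    def test_empty_input(self):
        with pytest.raises(InsufficientData):
            derive_length_cutoff([])


class TestFilterReads:
    @pytest.mark.parametrize(
        "total,short,pct",
        [(7_244, 3_958, 54.6), (6_386, 4_982, 78.0), (6_949, 5_247, 75.5)],
    )
    def test_short_read_percentages(self, total, short, pct):
        reads = [rec(60, rid=f"s{i}") for i in range(short)] + \
                [rec(150, rid=f"l{i}") for i in range(total - short)]
        _, removed, report = filter_reads(reads, cutoff_bp=80)
        assert report.total_mapped == total
        assert report.removed == short == len(removed)
        assert report.pct_short_display == pct

    def test_no_short_reads(self):
        _, removed, report = filter_reads([rec(150)] * 5, cutoff_bp=80)
        assert report.removed == 0 and report.pct_short == 0.0

    def test_empty_input(self):
        kept, removed, report = filter_reads([], cutoff_bp=80)
        assert (kept, removed, report.total_mapped) == ([], [], 0)

    def test_conservation_and_idempotence(self):
        rng = np.random.default_rng(5)
        reads = [rec(int(l), rid=f"r{i}")
                 for i, l in enumerate(rng.integers(30, 200, 500))]
        kept, removed, report = filter_reads(reads, cutoff_bp=80)
        assert len(kept) + len(removed) == len(reads)
        assert {r.read_id for r in kept} | {r.read_id for r in removed} == \
            {r.read_id for r in reads}
        kept2, removed2, _ = filter_reads(kept, cutoff_bp=80)
        assert removed2 == [] and kept2 == kept

    def test_readset_variant_partitions(self, reference, panel):
        cfg = m.make_config(seed=3, sample="N", reference=reference,
                            panel=panel)
        reads, _ = m.simulate_negative(cfg)
        kept, removed, report = filter_reads(reads, cutoff_bp=80)
        assert kept.n_reads + removed.n_reads == reads.n_reads
        assert report.total_mapped == reads.n_reads
        assert (removed.lengths() < 80).all()
        assert (kept.lengths() >= 80).all()

    def test_simulated_negative_recovers_short_fraction(self, reference, panel):
        """pct_short estimates the generating artifact fraction (69%)
        within binomial sampling error."""
        cfg = m.make_config(seed=9, sample="N", reference=reference,
                            panel=panel)
        reads, _ = m.simulate_negative(cfg)
        _, _, report = filter_reads(reads, cutoff_bp=80)
        n = report.total_mapped
        tol = 100 * 4 * np.sqrt(0.69 * 0.31 / n) + 1.0
        assert abs(report.pct_short - 69.0) < tol


class TestHotspots:
    def test_concentrated_removal_recovers_hotspots(self, panel):
        rng = np.random.default_rng(2)
        hot = ["mt_125", "mt_130", "mt_133", "mt_139", "mt_164"]
        reads = []
        for i in range(400):
            name = hot[i % 5] if i < 320 else \
                panel.amplicons[int(rng.integers(0, 120))].name
            a = panel[name]
            reads.append(rec(60, start=a.interval.end - 59, rid=f"r{i}"))
        assert set(hotspot_amplicons(reads, panel)) == set(hot)

    def test_uniform_removal_yields_no_hotspots(self, panel):
        reads = [rec(60, start=a.interval.start, rid=a.name) for a in panel]
        assert hotspot_amplicons(reads, panel) == []

    def test_single_amplicon_hotspot(self, panel):
        a = panel["mt_7"]
        reads = [rec(60, start=a.interval.start, rid=f"r{i}") for i in range(10)]
        assert hotspot_amplicons(reads, panel) == ["mt_7"]

    def test_empty_panel_rejected(self):
        from mitoqc.reference import AmpliconPanel

        with pytest.raises(ValueError):
            hotspot_amplicons([], AmpliconPanel([]))
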