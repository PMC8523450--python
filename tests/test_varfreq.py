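"""VarFreq profiles, ECDF semantics, blacklist, coverage, run-quality band."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitoqc as m
from mitoqc.pileup import build_pileup
from mitoqc.varfreq import (
    InsufficientData,
    VarFreqECDF,
    VarFreqProfile,
    classify_run_quality,
    compute_ecdf,
    compute_varfreq_profile,
    count_below,
    coverage_summary,
    identify_recurrent_noisy_positions,
    load_noisy_position_annotation,
    reference_band,
)

from conftest import make_block, make_readset


def profile(values, sample="s", positions=None):
    values = np.asarray(values, dtype=float)
    pos = np.arange(1, len(values) + 1) if positions is None else positions
    return VarFreqProfile(pos, values, np.full(len(values), 1000), None, sample)


class TestProfile:
    def test_php_position_uses_major_allele(self, reference):
        """Column 830 T / 170 C called as PHP has VarFreq 83."""
        # build a pileup with a PHP-like column at position 50
        b = make_block(1, 100, n=1000)
        ref_base = reference.base(50)
        alt = "ACGT"[("ACGT".index(ref_base) + 1) % 4]
        b.dev_rows = np.arange(170)
        b.dev_offsets = np.full(170, 49)
        b.dev_codes = np.full(170, "ACGT".index(alt), dtype=np.uint8)
        pile = build_pileup(make_readset(reference, [b]))
        callset = m.call_genome(pile)
        assert callset.call_at(50).call_type == "PHP"
        vf = compute_varfreq_profile(pile, callset)
        i = int(np.where(vf.positions == 50)[0][0])
        assert vf.varfreq[i] == pytest.approx(83.0)
        assert vf.second_allele[i] == alt
        # monomorphic positions sit at exactly 100
        j = int(np.where(vf.positions == 10)[0][0])
        assert vf.varfreq[j] == 100.0

    def test_insertion_carriers_reduce_purity(self, reference):
        b = make_block(1, 100, n=1000)
        b.insertions = [(i, 49, "C") for i in range(200)]
        pile = build_pileup(make_readset(reference, [b]))
        callset = m.call_genome(pile)
        vf = compute_varfreq_profile(pile, callset)
        i = int(np.where(vf.positions == 50)[0][0])
        assert vf.varfreq[i] == pytest.approx(80.0)
        assert vf.second_allele[i] == "INS"


class TestECDF:
    def test_all_pure_positions_contribute_nothing(self):
        e = compute_ecdf(profile([100.0] * 50))
        assert (e.proportion_le == 0).all()

    def test_small_enumerated_example(self):
        e = compute_ecdf(profile([90] * 8 + [50, 10]))
        assert e.at(49) == pytest.approx(0.1)
        assert e.at(89) == pytest.approx(0.2)
        assert e.at(99) == pytest.approx(1.0)

    def test_printed_proportion_arithmetic(self):
        """503 impure positions of 16,648 -> proportion 0.0302 at grid 98."""
        values = np.concatenate([np.full(503, 95.0), np.full(16_648 - 503, 100.0)])
        e = compute_ecdf(profile(values))
        assert e.at(98) == pytest.approx(503 / 16_648, abs=1e-6)
        assert round(100 * e.at(98)) == 3

    def test_pooling_across_profiles(self):
        e = compute_ecdf([profile([50.0]), profile([100.0] * 3)])
        assert e.n_positions == 4
        assert e.at(50) == pytest.approx(0.25)

    def test_empty_pool_rejected(self):
        with pytest.raises(InsufficientData):
            compute_ecdf([])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=200))
    def test_monotone_and_bounded(self, values):
        e = compute_ecdf(profile(values))
        assert (np.diff(e.proportion_le) >= 0).all()
        assert ((e.proportion_le >= 0) & (e.proportion_le <= 1)).all()

    def test_count_below_strict_and_inclusive(self):
        p = profile([98.5, 99.0, 100.0])
        assert count_below(p, 99.0) == 1
        assert count_below(p, 99.0, inclusive=True) == 2


class TestBlacklist:
    def test_recurrence_requires_min_samples(self):
        noisy = profile([80.0] + [100.0] * 9, sample="a")
        clean = profile([100.0] * 10, sample="b")
        table = identify_recurrent_noisy_positions(
            {"a": [noisy], "b": [clean]}, numt_positions=set())
        assert len(table) == 0
        table2 = identify_recurrent_noisy_positions(
            {"a": [noisy], "b": [noisy]}, numt_positions=set())
        assert set(table2.position) == {1}

    def test_no_position_below_threshold(self):
        clean = profile([100.0] * 10)
        out = identify_recurrent_noisy_positions(
            {"a": [clean], "b": [clean]}, numt_positions=set())
        assert len(out) == 0

    def test_fewer_groups_than_required_rejected(self):
        with pytest.raises(InsufficientData):
            identify_recurrent_noisy_positions({"a": [profile([100.0])]})

    def test_packaged_annotation_table(self):
        ann = load_noisy_position_annotation()
        assert {"position", "rcrs_base", "sample", "varfreq_mean",
                "varfreq_sd", "second_variant", "numt"} <= set(ann.columns)
        assert ann.position.nunique() == 26
        assert set(ann.loc[ann.numt == 1, "position"]) >= {309, 5752, 13237}

    def test_numt_annotation_applied(self):
        noisy = profile([100.0] * 308 + [70.0], sample="a")
        table = identify_recurrent_noisy_positions(
            {"a": [noisy], "b": [noisy]})
        row = table[table.position == 309].iloc[0]
        assert bool(row.numt) is True


class TestCoverage:
    def test_uniform_depth(self, reference):
        rs = make_readset(
            reference,
            [make_block(s, 200, n=100) for s in range(1, 16_371, 200)]
            + [make_block(16_369, 201, n=100)],
        )
        pile = build_pileup(rs)
        summary = coverage_summary(pile)
        assert summary.mean_base_coverage == pytest.approx(100.0, rel=0.01)
        assert summary.uniformity_pct == pytest.approx(100.0)

    def test_half_zero_half_200(self, reference):
        pile = build_pileup(make_readset(reference, []))
        half = reference.canonical_length // 2
        code = 0
        pile.counts_fwd[code, 1 : half + 1] = 200
        summary = coverage_summary(pile)
        assert summary.mean_base_coverage == pytest.approx(100.0, rel=0.01)
        assert summary.uniformity_pct == pytest.approx(50.0, abs=0.1)

    def test_simulated_sample_hits_configured_depth(self, high_input_result):
        cfg, res = high_input_result
        summary = coverage_summary(res.pileup, cfg.panel,
                                   n_reads=res.filter_report.kept)
        assert abs(summary.mean_base_coverage - cfg.target_depth) \
            < 0.1 * cfg.target_depth

    def test_amplicon_depth_conservation(self, reference):
        """Over a non-overlapping partition, sum(mean depth x length) equals
        the total column depth."""
        from mitoqc.reference import Amplicon, AmpliconPanel, GenomicInterval

        rng = np.random.default_rng(3)
        pile = build_pileup(make_readset(reference, []))
        pile.counts_fwd[0, 1:] = rng.integers(0, 500, reference.canonical_length)
        bounds = [1, 4000, 9000, 13000, reference.canonical_length + 1]
        panel = AmpliconPanel([
            Amplicon(f"a{i}", GenomicInterval(s, e - 1))
            for i, (s, e) in enumerate(zip(bounds, bounds[1:]))
        ])
        summary = coverage_summary(pile, panel)
        total = sum(
            summary.per_amplicon_mean_depth[a.name] * len(a.interval)
            for a in panel
        )
        assert total == pytest.approx(float(pile.depth().sum()))


class TestRunQuality:
    def _ecdf(self, values):
        return compute_ecdf(profile(values))

    def test_inside_band_is_stable(self):
        goods = [self._ecdf([100.0] * 90 + [95.0] * (10 + i)) for i in range(3)]
        band = reference_band(goods)
        verdict = classify_run_quality(goods[0], band)
        assert verdict.verdict == "stable" and verdict.distance == 0.0

    def test_excess_impurity_is_stochastic(self):
        goods = [self._ecdf([100.0] * 97 + [95.0] * 3) for _ in range(3)]
        band = reference_band(goods)
        degraded = self._ecdf([100.0] * 80 + [95.0] * 20)
        verdict = classify_run_quality(degraded, band)
        assert verdict.verdict == "stochastic" and verdict.distance > 0.005

    def test_band_requires_three_replicates(self):
        with pytest.raises(InsufficientData):
            reference_band([self._ecdf([100.0])] * 2)
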