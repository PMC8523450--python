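"""Threshold cascade, EMPOP notation, no-call regions, strand-bias flags."""

import numpy as np
import pytest

import mitoqc as m
from mitoqc.caller import (
    CallerConfig,
    HaplotypeProfile,
    call_haplotype,
    call_insertion,
    call_position,
    detect_nocall_regions,
    flag_strand_bias,
    parse_empop_token,
    write_vcf,
)
from mitoqc.pileup import PileupColumn, build_pileup
from mitoqc.reference import GenomicInterval

from conftest import make_block, make_readset


def col(position=100, ref="T", insertions=None, fwd=None, **counts):
    full = {b: counts.get(b, 0) for b in ("A", "C", "G", "T", "DEL")}
    if fwd is None:
        fwd = {b: full[b] for b in full}  # all forward by default
    return PileupColumn(position, full, fwd, insertions or {}, ref_base=ref)


CFG = CallerConfig()


class TestCascade:
    def test_php_at_seventeen_percent(self):
        call = call_position(col(position=7861, ref="T", T=830, C=170), "T", CFG)
        assert call.call_type == "PHP"
        assert call.empop() == "7861Y"
        assert call.variant_frequency == pytest.approx(17.0)

    def test_below_min_coverage_is_nocall(self):
        call = call_position(col(T=10, C=5), "T", CFG)
        assert call.call_type == "no-call"

    def test_confirmed_substitution(self):
        call = call_position(col(ref="A", G=97, A=3), "A", CFG)
        assert call.call_type == "substitution" and call.alleles == ("G",)

    def test_minor_below_php_threshold_stays_reference(self):
        call = call_position(col(ref="A", A=91, G=9), "A", CFG)
        assert call.call_type == "reference"

    def test_deletion_threshold(self):
        call = call_position(col(ref="A", A=60, DEL=40), "A", CFG)
        assert call.call_type == "deletion"
        assert call.variant_frequency == pytest.approx(40.0)
        below = call_position(col(ref="A", A=75, DEL=25), "A", CFG)
        assert below.call_type == "reference"

    def test_insertion_independent_of_base_call(self):
        c = col(ref="A", A=100, insertions={"C": 25})
        ins = call_insertion(c, CFG)
        assert ins is not None and ins.call_type == "insertion"
        assert ins.variant_frequency == pytest.approx(25.0)
        assert call_insertion(col(ref="A", A=100, insertions={"C": 15}), CFG) is None

    def test_variant_coverage_floor(self):
        # 17% minor but only 17 supporting reads at depth 100 < 20 reads
        call = call_position(col(ref="T", T=83, C=17), "T", CFG)
        assert call.call_type == "reference"

    def test_tie_resolved_deterministically(self):
        call = call_position(col(ref="A", A=50, G=50), "A", CFG)
        # reference-preference puts A first; both alleles reported as PHP
        assert call.call_type == "PHP"
        assert set(call.alleles) == {"A", "G"}

    def test_iupac_codes(self):
        y = call_position(col(ref="T", T=600, C=400), "T", CFG)
        r = call_position(col(ref="G", G=600, A=400), "G", CFG)
        assert y.empop().endswith("Y") and r.empop().endswith("R")

    def test_php_threshold_monotonicity(self):
        """Raising php_threshold can only shrink the PHP set."""
        rng = np.random.default_rng(0)
        cols = []
        for _ in range(300):
            d = int(rng.integers(50, 2000))
            minor = int(d * rng.uniform(0, 0.5))
            cols.append(col(ref="T", T=d - minor, C=minor))
        sets = []
        for thr in (5.0, 10.0, 20.0, 40.0):
            cfg = CallerConfig(php_threshold=thr)
            sets.append({
                i for i, c in enumerate(cols)
                if call_position(c, "T", cfg).call_type == "PHP"
            })
        for bigger, smaller in zip(sets, sets[1:]):
            assert smaller <= bigger


class TestGenomeCalls:
    def test_clean_pileup_yields_empty_profile(self, reference):
        blocks = [make_block(s, 200) for s in range(1, 16_500, 180)]
        pile = build_pileup(make_readset(reference, blocks))
        callset = m.call_genome(pile)
        profile = call_haplotype(callset)
        assert profile.variants == []
        assert len(callset.calls) == reference.canonical_length

    def test_every_position_called_once(self, high_input_result):
        _, res = high_input_result
        types = [c.call_type for c in res.callset.calls]
        assert len(types) == 16_569
        n_nocall = sum(t == "no-call" for t in types)
        assert n_nocall + sum(t != "no-call" for t in types) == 16_569

    def test_high_input_profile_matches_truth(self, high_input_result):
        """0 FP / 0 FN against truth outside the known-noisy blacklist."""
        from mitoqc.sensitivity import score_replicate
        from mitoqc.varfreq import load_noisy_position_annotation

        _, res = high_input_result
        blacklist = set(load_noisy_position_annotation().position)
        sc = score_replicate(res.profile, res.truth,
                             exclude_positions=blacklist)
        assert sc.false_positive_calls == 0
        assert sc.false_negative_calls == 0
        assert sc.pct_mtDNA_covered == 100.0

    def test_strand_bias_region_flagged(self, high_input_result):
        """Noise in the one-strand region yields flagged variant calls."""
        _, res = high_input_result
        flagged = [
            c for c in res.callset.variant_calls()
            if 8_248 <= c.position <= 8_256 and c.call_type != "insertion"
        ]
        assert flagged, "expected variant calls inside the strand-bias region"
        assert all("strand-bias" in c.flags for c in flagged)

    def test_homopolymer_calls_flagged_not_suppressed(self, high_input_result):
        _, res = high_input_result
        call = res.callset.call_at(309)
        assert "homopolymer-adjacent" in call.flags


class TestNocallRegions:
    def test_gap_interval_length(self, reference, panel):
        # dense tiling coverage; the gap of interest is zeroed below
        blocks = []
        for s in range(1, 16_480, 150):
            blocks.append(make_block(s, 160, n=25))
        rs = make_readset(reference, blocks)
        pile = build_pileup(rs)
        pile.counts_fwd[:, 10_062:10_153] = 0
        pile.counts_rev[:, 10_062:10_153] = 0
        callset = m.call_genome(pile)
        gaps = [iv for iv in detect_nocall_regions(callset)
                if iv.start >= 10_000 and iv.end <= 10_200]
        assert len(gaps) == 1
        assert m.interval_length(gaps[0]) == 91

    def test_full_coverage_no_gaps(self, high_input_result):
        _, res = high_input_result
        assert res.nocall_intervals == []

    def test_low_coverage_fraction_of_amplicon_median_flagged(
        self, reference, panel
    ):
        a = panel.amplicons[5]
        blocks = [make_block(a.interval.start, len(a.interval), n=1000)]
        rs = make_readset(reference, blocks)
        pile = build_pileup(rs)
        target = a.interval.start + 10
        base = reference.base(target)
        code = "ACGT".index(base)
        pile.counts_fwd[code, target] = 30  # 3% of the 1000x median
        callset = m.call_genome(pile)
        detect_nocall_regions(callset, pile, panel)
        assert "low-coverage-region" in callset.call_at(target).flags


class TestEmpopNotation:
    def test_substitution_plus_insertion(self):
        subs = m.VariantCall(263, "A", "substitution", ("G",))
        ins = m.VariantCall(309, "C", "insertion", ("C",))
        profile = HaplotypeProfile(variants=[subs, ins])
        assert profile.to_string() == "263G 309.1C"

    def test_round_trip(self):
        text = "249DEL 263G 309.1C 524.AC 7861Y"
        assert HaplotypeProfile.from_string(text).to_string() == text

    @pytest.mark.parametrize("token,ctype,alleles", [
        ("263G", "substitution", ("G",)),
        ("7861Y", "PHP", ("C", "T")),
        ("524.AC", "insertion", ("AC",)),
        ("309.1C", "insertion", ("C",)),
        ("249DEL", "deletion", ("DEL",)),
    ])
    def test_token_parse(self, token, ctype, alleles):
        v = parse_empop_token(token)
        assert (v.call_type, tuple(v.alleles)) == (ctype, alleles)

    def test_unparseable_token(self):
        with pytest.raises(ValueError):
            parse_empop_token("263Z")

    def test_duplicate_position_rejected(self):
        v = m.VariantCall(263, "A", "substitution", ("G",))
        with pytest.raises(ValueError):
            HaplotypeProfile(variants=[v, m.VariantCall(263, "A", "substitution", ("T",))])


class TestStrandBias:
    def test_one_strand_variant_flagged(self):
        c = col(ref="T", T=500, C=100,
                fwd={"A": 0, "C": 100, "G": 0, "T": 250, "DEL": 0})
        assert flag_strand_bias(c) is True

    def test_balanced_variant_not_flagged(self):
        c = col(ref="T", T=500, C=100,
                fwd={"A": 0, "C": 50, "G": 0, "T": 250, "DEL": 0})
        assert flag_strand_bias(c) is False


def test_vcf_output_is_valid(high_input_result, tmp_path):
    import pysam

    cfg, res = high_input_result
    path = tmp_path / "calls.vcf"
    write_vcf(res.callset, cfg.reference, path)
    with pysam.VariantFile(str(path)) as vcf:
        records = list(vcf)
    assert len(records) == len(
        [v for v in res.callset.variant_calls() if v.position > 1]
    )
    assert all("VF" in r.info and "DP" in r.info for r in records)
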