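"""Threshold-based mtDNA variant and point-heteroplasmy calling.

The caller classifies every canonical position from its pileup column with a
fixed decision cascade driven by the validated parameter set (coverage floor
20 reads, 96% confirmation, 10% point-heteroplasmy, 20% insertion, 30%
deletion thresholds, 5% of amplicon-median coverage marking):

1. depth below ``min_total_cov``                      -> no-call
2. top base = reference at >= ``confirm_threshold``   -> reference
3. top base != reference at >= ``confirm_threshold``  -> substitution
4. second base at >= ``php_threshold``                -> PHP (IUPAC code)
5. DEL allele at >= ``del_threshold``                 -> deletion
6. otherwise                                          -> reference, flagged

Insertions are evaluated per inserted sequence against ``ins_threshold``
independently of the base call, anchored to the preceding canonical position
(EMPOP ``pos.N`` convention).  The cascade ordering (substitution before PHP)
is fixed by configuration, not re-derived per sample.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

from .pileup import Pileup, PileupColumn
from .reference import (
    GenomicInterval,
    HOMOPOLYMER_REGIONS,
    MitoReference,
    STRAND_BIAS_REGIONS,
)

IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}
IUPAC_TO_PAIR = {v: tuple(sorted(k)) for k, v in IUPAC.items()}

FLAG_LOW_COV = "low-coverage-region"
FLAG_STRAND_BIAS = "strand-bias"
FLAG_HOMOPOLYMER = "homopolymer-adjacent"
FLAG_BLACKLIST = "blacklisted"


@dataclass
class CallerConfig:
    """Validated caller thresholds (percent scales unless noted)."""

    min_total_cov: int = 20
    min_variant_cov: int = 20
    region_mark_cov: int = 20
    min_pct_of_amplicon_median: float = 5.0
    confirm_threshold: float = 96.0
    php_threshold: float = 10.0
    ins_threshold: float = 20.0
    del_threshold: float = 30.0
    strand_bias_min_ratio: float = 0.10
    homopolymer_regions: tuple = HOMOPOLYMER_REGIONS
    strand_bias_regions: tuple = STRAND_BIAS_REGIONS

    def __post_init__(self):
        if not 0 < self.php_threshold < self.confirm_threshold <= 100:
            raise ValueError(
                "need 0 < php_threshold < confirm_threshold <= 100"
            )

    @classmethod
    def from_yaml(cls, path) -> "CallerConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class VariantCall:
    position: int
    ref_base: str
    call_type: str  # substitution|PHP|insertion|deletion|reference|no-call
    alleles: tuple[str, ...] = ()
    variant_frequency: float | None = None  # percent
    depth: int = 0
    flags: set[str] = field(default_factory=set)

    @property
    def is_variant(self) -> bool:
        return self.call_type in ("substitution", "PHP", "insertion", "deletion")

    def empop(self) -> str:
        """EMPOP-style token for a non-reference call."""
        p = self.position
        if self.call_type == "substitution":
            return f"{p}{self.alleles[0]}"
        if self.call_type == "PHP":
            return f"{p}{IUPAC[frozenset(self.alleles)]}"
        if self.call_type == "deletion":
            return f"{p}DEL"
        if self.call_type == "insertion":
            seq = self.alleles[0]
            return f"{p}.1{seq}" if len(seq) == 1 else f"{p}.{seq}"
        raise ValueError(f"{self.call_type} call has no EMPOP token")


_TOKEN_RE = re.compile(
    r"^(?P<pos>\d+)(?:"
    r"(?P<del>DEL|-)|"
    r"\.(?P<idx>\d+)?(?P<ins>[ACGT]+)|"
    r"(?P<base>[ACGTRYSWKM])"
    r")$"
)


def parse_empop_token(token: str, ref_base: str | None = None) -> VariantCall:
    """Parse one EMPOP-style token (``263G``, ``7861Y``, ``309.1C``,
    ``524.AC``, ``249DEL``) into a VariantCall skeleton."""
    m = _TOKEN_RE.match(token.strip())
    if not m:
        raise ValueError(f"unparseable EMPOP token: {token!r}")
    pos = int(m.group("pos"))
    ref = ref_base or "N"
    if m.group("del"):
        return VariantCall(pos, ref, "deletion", ("DEL",))
    if m.group("ins"):
        return VariantCall(pos, ref, "insertion", (m.group("ins"),))
    base = m.group("base")
    if base in IUPAC_TO_PAIR:
        return VariantCall(pos, ref, "PHP", IUPAC_TO_PAIR[base])
    return VariantCall(pos, ref, "substitution", (base,))


@dataclass
class HaplotypeProfile:
    """Non-reference calls in EMPOP notation plus no-call intervals."""

    variants: list[VariantCall] = field(default_factory=list)
    nocall_intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self):
        self.variants.sort(key=lambda v: (v.position, v.call_type))
        positions = [
            (v.position, v.call_type) for v in self.variants
        ]
        if len(positions) != len(set(positions)):
            raise ValueError("duplicate variant at one position in profile")

    def to_string(self) -> str:
        return " ".join(v.empop() for v in self.variants)

    @classmethod
    def from_string(cls, text: str) -> "HaplotypeProfile":
        tokens = [t for t in text.split() if t]
        return cls(variants=[parse_empop_token(t) for t in tokens])

    def variant_positions(self) -> set[int]:
        return {v.position for v in self.variants}

    def is_nocall(self, position: int) -> bool:
        return any(iv.contains(position) for iv in self.nocall_intervals)


def _ranked_bases(col: PileupColumn, ref_base: str) -> list[tuple[str, int]]:
    """ACGT alleles ranked by (count desc, reference-preference, lex)."""
    items = [(b, col.counts[b]) for b in "ACGT"]
    items.sort(key=lambda t: (-t[1], t[0] != ref_base, t[0]))
    return items


def call_position(
    col: PileupColumn, ref_base: str, cfg: CallerConfig
) -> VariantCall:
    """Classify one position via the threshold cascade (see module docs).

    Frequencies are computed on unrounded counts over column depth.
    """
    depth = col.depth
    if depth < cfg.min_total_cov:
        return VariantCall(col.position, ref_base, "no-call", depth=depth)
    ranked = _ranked_bases(col, ref_base)
    (top, top_n), (second, second_n) = ranked[0], ranked[1]
    top_f = 100.0 * top_n / depth
    second_f = 100.0 * second_n / depth
    del_f = 100.0 * col.counts["DEL"] / depth
    if top == ref_base and top_f >= cfg.confirm_threshold:
        return VariantCall(col.position, ref_base, "reference",
                           (ref_base,), top_f, depth)
    if top != ref_base and top_f >= cfg.confirm_threshold \
            and top_n >= cfg.min_variant_cov:
        return VariantCall(col.position, ref_base, "substitution",
                           (top,), top_f, depth)
    if second_f >= cfg.php_threshold and second_n >= cfg.min_variant_cov:
        return VariantCall(col.position, ref_base, "PHP",
                           tuple(sorted((top, second))), second_f, depth)
    if del_f >= cfg.del_threshold:
        return VariantCall(col.position, ref_base, "deletion",
                           ("DEL",), del_f, depth)
    return VariantCall(col.position, ref_base, "reference",
                       (top,), top_f, depth,
                       flags={"unconfirmed"} if top_f < cfg.confirm_threshold
                       else set())


def call_insertion(
    col: PileupColumn, cfg: CallerConfig
) -> VariantCall | None:
    """Insertion call at a column, independent of the base call."""
    if not col.insertions or col.depth < cfg.min_total_cov:
        return None
    seq, n = max(col.insertions.items(), key=lambda t: (t[1], t[0]))
    freq = 100.0 * n / col.depth
    if freq >= cfg.ins_threshold and n >= cfg.min_variant_cov:
        return VariantCall(col.position, col.ref_base or "N", "insertion",
                           (seq,), freq, col.depth)
    return None


def flag_strand_bias(
    col: PileupColumn,
    min_ratio: float = 0.10,
    allele: str | None = None,
) -> bool:
    """True when the variant-supporting reads sit almost entirely on one
    strand (minority-strand fraction below ``min_ratio``).

    ``allele`` defaults to the second-most-common allele (including DEL),
    i.e. the variant allele at a noisy or heteroplasmic position.
    """
    if allele is None:
        ranked = sorted(col.counts.items(), key=lambda t: (-t[1], t[0]))
        if len(ranked) < 2 or ranked[1][1] == 0:
            return False
        allele = ranked[1][0]
    total = col.counts.get(allele, 0)
    if total == 0:
        return False
    fwd = col.counts_forward.get(allele, 0)
    minority = min(fwd, total - fwd) / total
    return minority < min_ratio


@dataclass
class CallSet:
    """One call per canonical position, plus independent insertion calls."""

    calls: list[VariantCall]
    insertion_calls: list[VariantCall] = field(default_factory=list)

    def call_at(self, position: int) -> VariantCall:
        return self.calls[position - 1]

    def variant_calls(self) -> list[VariantCall]:
        out = [c for c in self.calls if c.is_variant]
        out.extend(self.insertion_calls)
        out.sort(key=lambda v: (v.position, v.call_type))
        return out


def call_genome(
    pile: Pileup,
    ref: MitoReference | None = None,
    cfg: CallerConfig | None = None,
    blacklist: set[int] | None = None,
) -> CallSet:
    """Run the cascade over every canonical position.

    Annotation flags (homopolymer adjacency, strand bias of variant calls,
    blacklist membership) are attached here; flagged calls are emitted, not
    suppressed.
    """
    ref = ref or pile.reference
    cfg = cfg or CallerConfig()
    blacklist = blacklist or set()
    homopolymer = set()
    for iv in cfg.homopolymer_regions:
        homopolymer.update(range(iv.start, iv.end + 1))
    calls: list[VariantCall] = []
    insertion_calls: list[VariantCall] = []
    for pos in range(1, ref.canonical_length + 1):
        col = pile.column(pos)
        call = call_position(col, ref.base(pos), cfg)
        if pos in homopolymer:
            call.flags.add(FLAG_HOMOPOLYMER)
        if pos in blacklist:
            call.flags.add(FLAG_BLACKLIST)
        if call.is_variant and flag_strand_bias(
            col, cfg.strand_bias_min_ratio,
            allele=call.alleles[-1] if call.call_type != "PHP" else None,
        ):
            call.flags.add(FLAG_STRAND_BIAS)
        ins = call_insertion(col, cfg)
        if ins is not None:
            if pos in homopolymer:
                ins.flags.add(FLAG_HOMOPOLYMER)
            insertion_calls.append(ins)
        calls.append(call)
    return CallSet(calls, insertion_calls)


def detect_nocall_regions(
    callset: CallSet,
    pile: Pileup | None = None,
    panel=None,
    cfg: CallerConfig | None = None,
) -> list[GenomicInterval]:
    """Maximal runs of no-call positions as 1-based inclusive intervals.

    When a pileup and panel are supplied, positions whose depth falls below
    ``min_pct_of_amplicon_median`` percent of their amplicon's median depth
    are additionally flagged ``low-coverage-region`` (calls mutated in
    place).
    """
    cfg = cfg or CallerConfig()
    intervals: list[GenomicInterval] = []
    run_start = None
    for call in callset.calls:
        if call.call_type == "no-call":
            if run_start is None:
                run_start = call.position
        elif run_start is not None:
            intervals.append(GenomicInterval(run_start, call.position - 1))
            run_start = None
    if run_start is not None:
        intervals.append(
            GenomicInterval(run_start, callset.calls[-1].position)
        )
    if pile is not None and panel is not None:
        depth = pile.depth()
        L = pile.reference.canonical_length
        for a in panel:
            s, e = a.interval.start, a.interval.end
            if e <= L:
                positions = np.arange(s, e + 1)
            else:
                positions = np.concatenate(
                    [np.arange(s, L + 1), np.arange(1, e - L + 1)]
                )
            med = float(np.median(depth[positions]))
            if med <= 0:
                continue
            lim = cfg.min_pct_of_amplicon_median / 100.0 * med
            for p in positions[depth[positions] < lim]:
                callset.call_at(int(p)).flags.add(FLAG_LOW_COV)
    return intervals


def call_haplotype(
    callset: CallSet, nocall_intervals: list[GenomicInterval] | None = None
) -> HaplotypeProfile:
    """EMPOP-style profile of all non-reference calls."""
    if nocall_intervals is None:
        nocall_intervals = detect_nocall_regions(callset)
    return HaplotypeProfile(
        variants=[replace(v, flags=set(v.flags)) for v in callset.variant_calls()],
        nocall_intervals=list(nocall_intervals),
    )


def write_vcf(callset: CallSet, ref: MitoReference, path) -> None:
    """Minimal VCF 4.2 of the non-reference calls (INFO VF, DP, FLAGS)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={ref.name},length={ref.canonical_length}>\n")
        fh.write('##INFO=<ID=VF,Number=1,Type=Float,'
                 'Description="Variant frequency percent">\n')
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=TYPE,Number=1,Type=String,Description="Call type">\n')
        fh.write('##INFO=<ID=FLAGS,Number=.,Type=String,Description="QC flags">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in callset.variant_calls():
            pos = v.position
            refb = ref.base(pos)
            if v.call_type == "substitution":
                alt = v.alleles[0]
            elif v.call_type == "PHP":
                alt = next(a for a in v.alleles if a != refb)
            elif v.call_type == "deletion":
                if pos == 1:
                    continue  # no anchor base before position 1
                refb, alt = ref.base(pos - 1) + ref.base(pos), ref.base(pos - 1)
                pos = pos - 1
            else:  # insertion
                alt = refb + v.alleles[0]
            info = f"VF={v.variant_frequency:.1f};DP={v.depth};TYPE={v.call_type}"
            if v.flags:
                info += ";FLAGS=" + ",".join(sorted(v.flags))
            fh.write(f"{ref.name}\t{pos}\t.\t{refb}\t{alt}\t.\tPASS\t{info}\n")


def write_nocall_bed(
    intervals: list[GenomicInterval], path, chrom: str = "chrM"
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{chrom}\t{iv.start - 1}\t{iv.end}\tno-call\n")
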