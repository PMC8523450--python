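"""Seeded synthetic amplicon-panel mtDNA sequencing data with ground truth.

The generator reproduces the statistical structure the analysis pipeline
assumes, with every injected feature recorded in a :class:`SimulationTruth`:

* **Template-count stochasticity** — the mtDNA template pool is
  ``Poisson(copies_from_input(input_pg))``; each amplicon captures templates
  by binomial thinning.  Heteroplasmic alleles are assigned per *template*
  (not per read), which is what makes low-input heteroplasmy quantification
  unstable: with few templates the carrier fraction is coarse and can be 0.
* **Library normalization** — sequencing depth per amplicon is set by
  ``target_depth`` (with lognormal per-amplicon bias) independent of input
  mass, as in a workflow that normalizes libraries before pooling; reads are
  distributed over captured templates (Poisson reads per template with mean
  ``target_depth / n_captured``).
* **Jackpot PCR noise** — the per-position error fraction is
  Gamma-distributed with mean ``base_error_rate`` and shape proportional to
  the captured template count: at high input it collapses to a uniform error
  rate, at low input single early errors are amplified to visible impurity,
  degrading the VarFreq distribution.  Additionally each captured template
  may carry founder errors shared by all its reads; with a single template
  these surface as clean false-positive calls.
* **Micro-amplicon artifacts** — short (40–79 bp), low-MAPQ (0–20) reads at
  the overlap junctions of configured hotspot amplicons.
* **NUMT-like recurrent noise** — at each configured position a per-sample
  fraction ``~ Normal(100 - mean_varfreq, sd)/100`` (truncated to [0, 1]) of
  reads carries a fixed second allele; inside strand-bias regions those
  reads are emitted on a single strand.
* **Homopolymer indel noise** — elevated per-read deletion rate inside the
  configured C-stretch regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .caller import HaplotypeProfile, VariantCall
from .reads import BASE_TO_CODE, CODE_DEL, ReadBlock, ReadSet, sequence_codes
from .reference import (
    AmpliconPanel,
    Amplicon,
    GenomicInterval,
    HOMOPOLYMER_REGIONS,
    InvalidConfiguration,
    MitoReference,
    STRAND_BIAS_REGIONS,
    synthetic_reference,
)
from .sensitivity import copies_from_input

DEFAULT_HOTSPOTS = ("mt_125", "mt_130", "mt_133", "mt_139", "mt_164")


@dataclass(frozen=True)
class PhpSite:
    """A heteroplasmic site: the alternate allele is carried by
    ``true_frequency`` percent of templates."""

    position: int
    ref: str
    alt: str
    true_frequency: float  # percent in (0, 100)

    def __post_init__(self):
        if not 0 < self.true_frequency < 100:
            raise ValueError("PHP frequency must be in (0, 100)")


@dataclass(frozen=True)
class NoisePosition:
    """Recurrent noise at a fixed position: ``second_allele`` is a base,
    ``DEL``, or ``INS`` (duplication of the reference base)."""

    position: int
    second_allele: str
    mean_varfreq: float  # percent
    sd_varfreq: float


@dataclass
class SimulationConfig:
    """Everything the generator needs; ``seed`` is mandatory."""

    reference: MitoReference
    panel: AmpliconPanel
    seed: int
    truth_haplotype: list[VariantCall] = field(default_factory=list)
    php_sites: list[PhpSite] = field(default_factory=list)
    numt_noise: list[NoisePosition] = field(default_factory=list)
    input_pg: float = 100.0
    target_depth: float = 1400.0
    per_template_reads: float | None = None  # overrides depth normalization
    capture_prob: float = 0.9
    amplicon_depth_cv: float = 0.25
    base_error_rate: float = 0.005
    noise_shape_per_template: float = 3.0
    template_error_rate: float = 2e-4
    founder_cycle_range: tuple[int, int] = (1, 4)
    homopolymer_regions: tuple = HOMOPOLYMER_REGIONS
    homopolymer_del_rate: float = 0.01
    strand_bias_regions: tuple = STRAND_BIAS_REGIONS
    artifact_hotspots: tuple[str, ...] = DEFAULT_HOTSPOTS
    artifact_rate: float = 0.027  # fraction of mapped reads that are artifacts
    artifact_length_range: tuple[int, int] = (40, 79)
    artifact_mapq_range: tuple[int, int] = (0, 20)
    genuine_mapq_range: tuple[int, int] = (40, 60)
    negative_background_depth: float = 9.4
    negative_short_fraction: float = 0.69
    sample: str = "sample"

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for v in self.truth_haplotype:
            if v.call_type != "substitution":
                raise InvalidConfiguration(
                    "simulated truth haplotypes support substitutions only"
                )
        for s in self.php_sites:
            if not 1 <= s.position <= self.reference.canonical_length:
                raise InvalidConfiguration(f"PHP position {s.position} off axis")


@dataclass
class SimulationTruth:
    """Ground truth for everything the generator injected."""

    sample: str
    haplotype: HaplotypeProfile
    php_sites: list[PhpSite]
    template_count: int
    captured_per_amplicon: dict[str, int]
    php_template_fraction: dict[int, float]
    noise_fractions: dict[int, float]
    artifact_read_ids: set[str] = field(default_factory=set)
    noise_read_ids: set[str] = field(default_factory=set)
    genuine_read_ids: set[str] = field(default_factory=set)

    def category_of(self, read_id: str) -> str:
        if read_id in self.artifact_read_ids:
            return "artifact"
        if read_id in self.noise_read_ids:
            return "noise-carrying"
        if read_id in self.genuine_read_ids:
            return "genuine"
        raise KeyError(read_id)

    def to_dict(self) -> dict:
        return {
            "sample": self.sample,
            "haplotype": self.haplotype.to_string(),
            "php_sites": [
                {"position": s.position, "ref": s.ref, "alt": s.alt,
                 "true_frequency": s.true_frequency}
                for s in self.php_sites
            ],
            "template_count": self.template_count,
            "captured_per_amplicon": self.captured_per_amplicon,
            "php_template_fraction": {
                str(k): v for k, v in self.php_template_fraction.items()
            },
            "noise_fractions": {
                str(k): v for k, v in self.noise_fractions.items()
            },
            "n_artifact_reads": len(self.artifact_read_ids),
            "n_noise_reads": len(self.noise_read_ids),
            "n_genuine_reads": len(self.genuine_read_ids),
        }


# --------------------------------------------------------------------- panel


def simulate_panel(
    reference: MitoReference,
    n_amplicons: int = 164,
    length_range: tuple[int, int] = (125, 174),
    target_overlap: int = 11,
    seed: int = 0,
    name_prefix: str = "mt_",
) -> AmpliconPanel:
    """Tile the circle with overlapping amplicons.

    Per-amplicon advances partition the canonical length; each amplicon then
    extends past the next amplicon's start by an overlap drawn around the
    feasible target.  When ``target_overlap`` is geometrically impossible
    for the requested ``n_amplicons`` (mean length would leave the allowed
    range) the midpoint of the feasible overlap range is used instead; if no
    positive overlap keeps lengths in range, the configuration is rejected.
    Pools alternate 1/2 along the circle, as in a 2-pool multiplex assay.
    """
    if n_amplicons < 2:
        raise InvalidConfiguration("need at least 2 amplicons")
    rng = np.random.default_rng(seed)
    L = reference.canonical_length
    lo, hi = length_range
    adv_lo, adv_hi = L // n_amplicons, -(-L // n_amplicons)
    ov_hi = hi - adv_hi
    ov_lo = max(1, lo - adv_lo)
    if ov_hi < 1 or ov_lo > ov_hi:
        raise InvalidConfiguration(
            f"{n_amplicons} amplicons of {lo}-{hi} bp cannot tile a "
            f"{L} bp circle with positive overlap"
        )
    if ov_lo <= target_overlap <= ov_hi:
        target = target_overlap
    else:
        target = (ov_lo + ov_hi) // 2
    advances = np.full(n_amplicons, adv_lo, dtype=np.int64)
    extra = rng.choice(n_amplicons, size=L - adv_lo * n_amplicons,
                       replace=False)
    advances[extra] += 1
    jitter = max(0, min(5, target - ov_lo, ov_hi - target))
    overlaps = target + rng.integers(-jitter, jitter + 1, size=n_amplicons)
    overlaps = np.clip(overlaps, np.maximum(1, lo - advances), hi - advances)
    # the last amplicon wraps into the extension; keep it inside the axis
    overlaps[-1] = min(overlaps[-1], reference.extension_length)
    lengths = advances + overlaps
    if lengths[-1] < lo:
        raise InvalidConfiguration(
            "extension too short for the wrap amplicon's overlap"
        )
    starts = np.concatenate([[1], 1 + np.cumsum(advances[:-1])])
    amplicons = [
        Amplicon(
            f"{name_prefix}{i + 1}",
            GenomicInterval(int(starts[i]), int(starts[i] + lengths[i] - 1)),
            pool=1 + i % 2,
        )
        for i in range(n_amplicons)
    ]
    panel = AmpliconPanel(amplicons, chrom=reference.name)
    return panel


# ------------------------------------------------------------------- helpers


def _positions_in_amplicon(
    positions, start: int, length: int, canonical_length: int
) -> list[tuple[int, int]]:
    """(canonical position, 0-based offset) pairs falling inside the span."""
    out = []
    for p in positions:
        for cand in (p, p + canonical_length):
            off = cand - start
            if 0 <= off < length:
                out.append((p, off))
    return out


def _dedup_last(rows, offs, codes):
    """Keep the last deviation per (row, offset)."""
    rows = np.asarray(rows, dtype=np.int64)
    offs = np.asarray(offs, dtype=np.int64)
    codes = np.asarray(codes, dtype=np.uint8)
    if len(rows) == 0:
        return rows, offs, codes
    key = rows * (offs.max() + 1) + offs
    _, first_of_reversed = np.unique(key[::-1], return_index=True)
    sel = np.sort(len(key) - 1 - first_of_reversed)
    return rows[sel], offs[sel], codes[sel]


def _random_alt(rng, ref_codes: np.ndarray) -> np.ndarray:
    return (ref_codes + rng.integers(1, 4, size=len(ref_codes))) % 4


# ------------------------------------------------------------------ defaults


def default_reference(seed: int = 4321) -> MitoReference:
    return synthetic_reference(seed=seed)


def default_panel(reference: MitoReference, seed: int = 97) -> AmpliconPanel:
    return simulate_panel(reference, seed=seed)


def default_numt_noise() -> list[NoisePosition]:
    """Recurrent-noise model positions from the packaged annotation table."""
    from .varfreq import load_noisy_position_annotation

    ann = load_noisy_position_annotation()
    first = ann[ann["sample"] == ann["sample"].iloc[0]]
    return [
        NoisePosition(int(r.position), str(r.second_variant),
                      float(r.varfreq_mean), float(r.varfreq_sd))
        for r in first.itertuples(index=False)
    ]


def _avoided_positions(config_like: dict) -> set[int]:
    avoid: set[int] = {1}
    for np_ in config_like.get("numt_noise", []):
        avoid.add(np_.position)
    for s in config_like.get("php_sites", []):
        avoid.add(s.position)
    for regions in (HOMOPOLYMER_REGIONS, STRAND_BIAS_REGIONS):
        for iv in regions:
            avoid.update(range(iv.start, iv.end + 1))
    return avoid


def random_haplotype(
    reference: MitoReference,
    n_variants: int = 30,
    seed: int = 11,
    avoid: set[int] | None = None,
) -> list[VariantCall]:
    """Seeded random substitution haplotype (EMPOP-style truth profile)."""
    rng = np.random.default_rng(seed)
    avoid = avoid or set()
    candidates = np.array(
        [p for p in range(1, reference.canonical_length + 1) if p not in avoid]
    )
    positions = np.sort(rng.choice(candidates, size=n_variants, replace=False))
    variants = []
    for p in positions:
        ref_b = reference.base(int(p))
        alt = "ACGT"[(BASE_TO_CODE[ref_b] + int(rng.integers(1, 4))) % 4]
        variants.append(
            VariantCall(int(p), ref_b, "substitution", (alt,))
        )
    return variants


def default_php_sites(reference: MitoReference) -> list[PhpSite]:
    """A mid-level site (17%, reliably detectable at high input) and a
    low-level site (3%, below the 10% calling threshold)."""
    sites = []
    for pos, freq in ((7861, 17.0), (3242, 3.0)):
        ref_b = reference.base(pos)
        alt = "ACGT"[(BASE_TO_CODE[ref_b] + 1) % 4]
        sites.append(PhpSite(pos, ref_b, alt, freq))
    return sites


def make_config(
    seed: int,
    input_pg: float = 100.0,
    sample: str = "S1",
    reference: MitoReference | None = None,
    panel: AmpliconPanel | None = None,
    haplotype_seed: int = 11,
    n_haplotype_variants: int = 30,
    include_php: bool = True,
    **overrides,
) -> SimulationConfig:
    """Study-default configuration: shared reference/panel, a seeded truth
    haplotype, the two default PHP sites and the packaged noise model."""
    reference = reference or default_reference()
    panel = panel or default_panel(reference)
    numt = overrides.pop("numt_noise", default_numt_noise())
    php = overrides.pop(
        "php_sites", default_php_sites(reference) if include_php else []
    )
    avoid = _avoided_positions({"numt_noise": numt, "php_sites": php})
    haplotype = overrides.pop(
        "truth_haplotype",
        random_haplotype(reference, n_haplotype_variants, haplotype_seed, avoid),
    )
    return SimulationConfig(
        reference=reference,
        panel=panel,
        seed=seed,
        truth_haplotype=haplotype,
        php_sites=php,
        numt_noise=numt,
        input_pg=input_pg,
        sample=sample,
        **overrides,
    )


# ---------------------------------------------------------------- simulation


def simulate_sample(config: SimulationConfig) -> tuple[ReadSet, SimulationTruth]:
    """Generate one sample's reads plus ground truth (see module docs)."""
    rng = np.random.default_rng(config.seed)
    ref = config.reference
    L = ref.canonical_length
    ext_codes = sequence_codes(ref.extended_sequence())
    copies, _ = copies_from_input(config.input_pg)
    n_templates = int(rng.poisson(copies))

    carriers = {
        s.position: rng.random(n_templates) < s.true_frequency / 100.0
        for s in config.php_sites
    }
    php_by_pos = {s.position: s for s in config.php_sites}
    truth_sub = {v.position: BASE_TO_CODE[v.alleles[0]]
                 for v in config.truth_haplotype}
    noise_by_pos = {np_.position: np_ for np_ in config.numt_noise}
    noise_frac = {
        np_.position: float(np.clip(
            rng.normal((100.0 - np_.mean_varfreq) / 100.0,
                       np_.sd_varfreq / 100.0), 0.0, 1.0))
        for np_ in config.numt_noise
    }
    bias_positions: set[int] = set()
    for iv in config.strand_bias_regions:
        bias_positions.update(range(iv.start, iv.end + 1))
    homopolymer_positions: set[int] = set()
    for iv in config.homopolymer_regions:
        homopolymer_positions.update(range(iv.start, iv.end + 1))

    mq_lo, mq_hi = config.genuine_mapq_range
    sigma = float(np.sqrt(np.log(1.0 + config.amplicon_depth_cv ** 2)))
    # target_depth is the genome-wide mean base coverage; per-amplicon read
    # depth is scaled down by the panel's overlap factor so overlaps do not
    # inflate base coverage above the target
    panel_bases = sum(len(a.interval) for a in config.panel)
    amplicon_depth = config.target_depth * L / panel_bases
    blocks: list[ReadBlock] = []
    captured_per_amplicon: dict[str, int] = {}
    noise_ids: set[str] = set()
    genuine_ids: set[str] = set()

    for a in config.panel:
        s0, e0 = a.interval.start, a.interval.end
        len_a = e0 - s0 + 1
        k = int(rng.binomial(n_templates, config.capture_prob)) \
            if n_templates else 0
        captured_per_amplicon[a.name] = k
        if k == 0:
            continue
        captured = rng.choice(n_templates, size=k, replace=False)
        if config.per_template_reads is not None:
            n = int(rng.poisson(config.per_template_reads * k))
        else:
            depth = amplicon_depth * float(
                rng.lognormal(-sigma ** 2 / 2.0, sigma))
            n = int(rng.poisson(depth))
        if n == 0:
            continue
        t_idx = rng.integers(0, k, size=n)
        forward = rng.random(n) < 0.5
        ref_codes_a = ext_codes[s0 - 1 : s0 - 1 + len_a]
        prefix = f"{config.sample}:{a.name}"

        rows: list[np.ndarray] = []
        offs: list[np.ndarray] = []
        codes: list[np.ndarray] = []

        def add(r, o, c):
            rows.append(np.asarray(r, dtype=np.int64))
            offs.append(np.asarray(o, dtype=np.int64))
            codes.append(np.asarray(c, dtype=np.uint8))

        # truth haplotype: every read carries the sample's substitutions
        for p, off in _positions_in_amplicon(truth_sub, s0, len_a, L):
            add(np.arange(n), np.full(n, off), np.full(n, truth_sub[p]))
        # heteroplasmy: reads inherit their template's allele
        for p, off in _positions_in_amplicon(carriers, s0, len_a, L):
            r = np.flatnonzero(carriers[p][captured[t_idx]])
            if len(r):
                alt = BASE_TO_CODE[php_by_pos[p].alt]
                add(r, np.full(len(r), off), np.full(len(r), alt))
        # founder (template-lineage) errors: an error arising in PCR cycle c
        # is shared by ~2^-c of that template's reads
        n_founder = int(rng.poisson(k * len_a * config.template_error_rate))
        c_lo, c_hi = config.founder_cycle_range
        for _ in range(n_founder):
            t = int(rng.integers(k))
            off = int(rng.integers(len_a))
            alt = int((ref_codes_a[off] + rng.integers(1, 4)) % 4)
            cycle = int(rng.integers(c_lo, c_hi + 1))
            r = np.flatnonzero(t_idx == t)
            r = r[rng.random(len(r)) < 2.0 ** -cycle]
            if len(r):
                add(r, np.full(len(r), off), np.full(len(r), alt))
        # jackpot PCR/sequencing noise: Gamma-overdispersed per-position rate
        shape = config.noise_shape_per_template * k
        q = rng.gamma(shape, config.base_error_rate / shape, size=len_a)
        err_counts = rng.binomial(n, np.clip(q, 0.0, 1.0))
        total_err = int(err_counts.sum())
        if total_err:
            o = np.repeat(np.arange(len_a), err_counts)
            r = rng.integers(0, n, size=total_err)
            alt_of_off = _random_alt(rng, ref_codes_a)
            add(r, o, alt_of_off[o])
        # recurrent NUMT-like noise at fixed positions
        ins_events: list[tuple[int, int, str]] = []
        for p, off in _positions_in_amplicon(noise_by_pos, s0, len_a, L):
            c = int(rng.binomial(n, noise_frac[p]))
            if c == 0:
                continue
            r = rng.choice(n, size=c, replace=False)
            allele = noise_by_pos[p].second_allele
            if allele == "INS":
                base = "ACGT"[ref_codes_a[off]]
                ins_events.extend((int(ri), off, base) for ri in r)
            elif allele == "DEL":
                add(r, np.full(c, off), np.full(c, CODE_DEL))
            else:
                code = BASE_TO_CODE[allele]
                if code == ref_codes_a[off]:
                    # the configured second allele must differ from the
                    # (synthetic) reference base to be visible
                    code = (code + 1) % 4
                add(r, np.full(c, off), np.full(c, code))
            if p in bias_positions:
                forward[r] = True
            noise_ids.update(f"{prefix}:{int(ri)}" for ri in r)
        # homopolymer-region deletion noise
        for p, off in _positions_in_amplicon(
            homopolymer_positions, s0, len_a, L
        ):
            c = int(rng.binomial(n, config.homopolymer_del_rate))
            if c:
                r = rng.choice(n, size=c, replace=False)
                add(r, np.full(c, off), np.full(c, CODE_DEL))

        if rows:
            d_rows, d_offs, d_codes = _dedup_last(
                np.concatenate(rows), np.concatenate(offs),
                np.concatenate(codes))
        else:
            d_rows = d_offs = np.empty(0, dtype=np.int64)
            d_codes = np.empty(0, dtype=np.uint8)
        blocks.append(ReadBlock(
            starts=np.full(n, s0, dtype=np.int64),
            lengths=np.full(n, len_a, dtype=np.int64),
            mapq=rng.integers(mq_lo, mq_hi + 1, size=n),
            forward=forward,
            id_prefix=prefix,
            amplicon=a.name,
            dev_rows=d_rows,
            dev_offsets=d_offs,
            dev_codes=np.asarray(d_codes, dtype=np.uint8),
            insertions=ins_events,
        ))
        genuine_ids.update(f"{prefix}:{i}" for i in range(n))
    genuine_ids -= noise_ids

    n_genuine = sum(b.n for b in blocks)
    artifact_ids: set[str] = set()
    if config.artifact_rate > 0 and n_genuine:
        rate = config.artifact_rate
        n_art = int(rng.poisson(rate / (1.0 - rate) * n_genuine))
        blocks.extend(_artifact_blocks(config, rng, n_art, artifact_ids))

    truth = SimulationTruth(
        sample=config.sample,
        haplotype=HaplotypeProfile(
            variants=[replace(v) for v in config.truth_haplotype]),
        php_sites=list(config.php_sites),
        template_count=n_templates,
        captured_per_amplicon=captured_per_amplicon,
        php_template_fraction={
            p: (float(c.mean()) if n_templates else 0.0)
            for p, c in carriers.items()
        },
        noise_fractions=noise_frac,
        artifact_read_ids=artifact_ids,
        noise_read_ids=noise_ids,
        genuine_read_ids=genuine_ids,
    )
    return ReadSet(ref, blocks, sample=config.sample), truth


def _artifact_blocks(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_art: int,
    artifact_ids: set[str],
) -> list[ReadBlock]:
    """Micro-amplicon reads at hotspot overlap junctions (anchored at the
    hotspot amplicon's 3' end, so maximal-overlap assignment recovers the
    hotspot)."""
    panel_names = set(config.panel.names())
    hotspots = [h for h in config.artifact_hotspots if h in panel_names]
    if not hotspots or n_art == 0:
        return []
    lo, hi = config.artifact_length_range
    mq_lo, mq_hi = config.artifact_mapq_range
    counts = rng.multinomial(n_art, np.full(len(hotspots), 1 / len(hotspots)))
    blocks = []
    for name, c in zip(hotspots, counts):
        if c == 0:
            continue
        a = config.panel[name]
        lengths = rng.integers(lo, hi + 1, size=c)
        starts = a.interval.end - lengths + 1
        prefix = f"{config.sample}:art:{name}"
        blocks.append(ReadBlock(
            starts=starts.astype(np.int64),
            lengths=lengths.astype(np.int64),
            mapq=rng.integers(mq_lo, mq_hi + 1, size=c),
            forward=rng.random(c) < 0.5,
            id_prefix=prefix,
            amplicon=name,
        ))
        artifact_ids.update(f"{prefix}:{i}" for i in range(c))
    return blocks


def simulate_negative(config: SimulationConfig) -> tuple[ReadSet, SimulationTruth]:
    """Amplification negative: no genuine templates — a trace uniform
    background of full-length reads plus micro-amplicon artifacts at the
    hotspots, at a short-read fraction matching real negatives."""
    rng = np.random.default_rng(config.seed)
    ref = config.reference
    mq_lo, mq_hi = config.genuine_mapq_range
    blocks: list[ReadBlock] = []
    genuine_ids: set[str] = set()
    panel_bases = sum(len(a.interval) for a in config.panel)
    per_amplicon_bg = (config.negative_background_depth
                       * ref.canonical_length / panel_bases)
    for a in config.panel:
        n = int(rng.poisson(per_amplicon_bg))
        if n == 0:
            continue
        len_a = len(a.interval)
        prefix = f"{config.sample}:bg:{a.name}"
        blocks.append(ReadBlock(
            starts=np.full(n, a.interval.start, dtype=np.int64),
            lengths=np.full(n, len_a, dtype=np.int64),
            mapq=rng.integers(mq_lo, mq_hi + 1, size=n),
            forward=rng.random(n) < 0.5,
            id_prefix=prefix,
            amplicon=a.name,
        ))
        genuine_ids.update(f"{prefix}:{i}" for i in range(n))
    n_bg = sum(b.n for b in blocks)
    artifact_ids: set[str] = set()
    f = config.negative_short_fraction
    if f > 0:
        n_art = int(rng.poisson(f / (1.0 - f) * max(n_bg, 1)))
        blocks.extend(_artifact_blocks(config, rng, n_art, artifact_ids))
    truth = SimulationTruth(
        sample=config.sample,
        haplotype=HaplotypeProfile(),
        php_sites=[],
        template_count=0,
        captured_per_amplicon={a.name: 0 for a in config.panel},
        php_template_fraction={},
        noise_fractions={},
        artifact_read_ids=artifact_ids,
        noise_read_ids=set(),
        genuine_read_ids=genuine_ids,
    )
    return ReadSet(ref, blocks, sample=config.sample), truth
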