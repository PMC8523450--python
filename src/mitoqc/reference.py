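"""Circular mitochondrial reference, coordinate remapping and the amplicon panel.

The human mitochondrial genome is circular; short-read aligners want a linear
reference, so the canonical 16,569 bp rCRS axis is linearized with its first
``extension_length`` bases repeated after position 16,569 ("rCRS + 80").  Reads
spanning the origin then align contiguously to the extension, and every
extended-axis position maps back onto the canonical axis via
:func:`remap_position`.

All public coordinates are 1-based inclusive on the canonical axis, matching
forensic mtDNA nomenclature (np positions).  BED I/O converts half-open
0-based coordinates at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RCRS_LENGTH = 16_569
DEFAULT_EXTENSION = 80

#: Control region used for restricted haplotype comparisons: HVS segments span
#: the origin, so the region is two intervals on the canonical axis.
CONTROL_REGION = None  # set after GenomicInterval is defined

#: Homopolymer C-stretches where flow-based chemistry miscalls indels.
HOMOPOLYMER_REGIONS = None

#: Region affected by extreme read strand bias (putative NUMT co-amplification).
STRAND_BIAS_REGIONS = None


class InvalidConfiguration(ValueError):
    """Raised when reference or panel parameters are internally inconsistent."""


class InvalidInterval(ValueError):
    pass


class BedParseError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive interval; ``start <= end`` on the extended axis."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InvalidInterval(f"end {self.end} < start {self.start}")
        if self.start < 1:
            raise InvalidInterval(f"start {self.start} < 1")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of shared positions (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


def interval_length(iv: GenomicInterval) -> int:
    """Length of a 1-based inclusive interval (``end - start + 1``)."""
    return len(iv)


CONTROL_REGION = (GenomicInterval(16_024, RCRS_LENGTH), GenomicInterval(1, 576))
HOMOPOLYMER_REGIONS = (GenomicInterval(303, 310), GenomicInterval(16_184, 16_193))
STRAND_BIAS_REGIONS = (GenomicInterval(8_248, 8_256),)


@dataclass
class MitoReference:
    """Circular reference sequence plus its linearization extension.

    Parameters
    ----------
    sequence
        Canonical (unextended) nucleotide sequence, uppercase ACGT.
    extension_length
        Number of leading bases repeated after the canonical end.
    name
        Contig name used in SAM/BED/FASTA output.
    """

    sequence: str
    extension_length: int = DEFAULT_EXTENSION
    name: str = "chrM"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if self.extension_length < 0:
            raise InvalidConfiguration("extension_length must be >= 0")
        if self.extension_length > self.canonical_length:
            raise InvalidConfiguration(
                f"extension_length {self.extension_length} exceeds canonical "
                f"length {self.canonical_length}"
            )

    @property
    def canonical_length(self) -> int:
        return len(self.sequence)

    @property
    def extended_length(self) -> int:
        return self.canonical_length + self.extension_length

    def extended_sequence(self) -> str:
        return extend_reference(self)

    def base(self, position: int) -> str:
        """Base at a canonical 1-based position."""
        if not 1 <= position <= self.canonical_length:
            raise IndexError(f"position {position} outside canonical axis")
        return self.sequence[position - 1]


def extend_reference(ref: MitoReference) -> str:
    """Linearized sequence: canonical bases followed by the first
    ``extension_length`` bases repeated."""
    return ref.sequence + ref.sequence[: ref.extension_length]


def remap_position(p: int, ref: MitoReference) -> int:
    """Map an extended-axis position back onto the canonical axis.

    Identity on ``1..canonical_length``; positions in the wrap extension map
    onto ``1..extension_length``.
    """
    if not 1 <= p <= ref.extended_length:
        raise IndexError(
            f"position {p} outside extended axis 1..{ref.extended_length}"
        )
    return p if p <= ref.canonical_length else p - ref.canonical_length


def synthetic_reference(
    seed: int = 4321,
    length: int = RCRS_LENGTH,
    extension_length: int = DEFAULT_EXTENSION,
    name: str = "chrM",
) -> MitoReference:
    """Seeded random reference of canonical length.

    Position-level logic throughout the package is sequence-agnostic, so tests
    and simulations run against this synthetic stand-in rather than the true
    rCRS sequence.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return MitoReference(seq, extension_length=extension_length, name=name)


def read_fasta(path) -> MitoReference:
    """Load a single-record FASTA as a (canonical) reference."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise InvalidConfiguration(
            f"expected a single FASTA record, found {len(records)}"
        )
    rec = records[0]
    return MitoReference(str(rec.seq), name=rec.id)


def write_fasta(ref: MitoReference, path, extended: bool = False) -> None:
    seq = ref.extended_sequence() if extended else ref.sequence
    rec = SeqRecord(Seq(seq), id=ref.name, description="")
    SeqIO.write([rec], str(path), "fasta")


@dataclass(frozen=True)
class Amplicon:
    name: str
    interval: GenomicInterval
    pool: int = 1

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class AmpliconPanel:
    """Ordered tiling of the circle by overlapping amplicons.

    ``warnings`` records invariant violations found at load time (non-tiling
    panels are accepted with a flag rather than rejected).
    """

    amplicons: list[Amplicon]
    chrom: str = "chrM"
    warnings: list[str] = field(default_factory=list)

    @property
    def count(self) -> int:
        return len(self.amplicons)

    def __iter__(self):
        return iter(self.amplicons)

    def __getitem__(self, name: str) -> Amplicon:
        for a in self.amplicons:
            if a.name == name:
                return a
        raise KeyError(name)

    def names(self) -> list[str]:
        return [a.name for a in self.amplicons]

    def covers_circle(self, canonical_length: int) -> bool:
        """True when every canonical position lies in >= 1 amplicon
        (extended-axis intervals are remapped onto the canonical circle)."""
        import numpy as np

        hit = np.zeros(canonical_length + 1, dtype=bool)
        for a in self.amplicons:
            s, e = a.interval.start, a.interval.end
            if e <= canonical_length:
                hit[s : e + 1] = True
            else:  # wraps through the extension
                hit[s : canonical_length + 1] = True
                hit[1 : e - canonical_length + 1] = True
        return bool(hit[1:].all())

    def assign(self, start: int, end: int) -> str | None:
        """Amplicon with maximal overlap of the span [start, end]; ties break
        by panel order. None when the span overlaps no amplicon."""
        span = GenomicInterval(start, end)
        best, best_ov = None, 0
        for a in self.amplicons:
            ov = a.interval.overlap(span)
            if ov > best_ov:
                best, best_ov = a.name, ov
        return best


def validate_panel(
    panel: AmpliconPanel,
    canonical_length: int = RCRS_LENGTH,
    length_bounds: tuple[int, int] = (125, 174),
) -> list[str]:
    """Check panel invariants, returning human-readable warnings."""
    warnings: list[str] = []
    lo, hi = length_bounds
    for a in panel:
        if not lo <= len(a) <= hi:
            warnings.append(f"{a.name}: length {len(a)} outside [{lo}, {hi}]")
    for a, b in zip(panel.amplicons, panel.amplicons[1:]):
        if b.interval.start > a.interval.end + 1:
            warnings.append(f"gap between {a.name} and {b.name}")
    if not panel.covers_circle(canonical_length):
        warnings.append("panel does not tile the full circle")
    return warnings


def load_panel(bed_source, chrom: str = "chrM") -> AmpliconPanel:
    """Read an amplicon panel from BED (0-based half-open -> 1-based inclusive).

    Columns: chrom, start, end, name[, score, strand/pool].  A fifth "pool"
    column (1 or 2) is honored when present.  Non-tiling panels load with a
    warning flag; an empty file is an error.
    """
    close = False
    if isinstance(bed_source, (str,)) or hasattr(bed_source, "__fspath__"):
        fh = open(bed_source)
        close = True
    else:
        fh = bed_source
    amplicons: list[Amplicon] = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"line {lineno}: fewer than 3 columns")
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"line {lineno}: non-integer coordinates") from exc
            if end0 <= start0:
                raise BedParseError(f"line {lineno}: end <= start")
            name = fields[3] if len(fields) > 3 else f"amplicon_{lineno}"
            pool = 1
            if len(fields) > 4:
                try:
                    pool = int(fields[4])
                except ValueError:
                    pool = 1
            amplicons.append(
                Amplicon(name, GenomicInterval(start0 + 1, end0), pool=pool)
            )
    finally:
        if close:
            fh.close()
    if not amplicons:
        raise BedParseError("empty panel BED")
    panel = AmpliconPanel(amplicons, chrom=chrom)
    panel.warnings = validate_panel(panel)
    return panel


def write_panel_bed(panel: AmpliconPanel, path) -> None:
    """Write the panel as 5-column BED (name, pool); inverse of load_panel."""
    with open(path, "w") as fh:
        for a in panel:
            fh.write(
                f"{panel.chrom}\t{a.interval.start - 1}\t{a.interval.end}"
                f"\t{a.name}\t{a.pool}\n"
            )
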