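"""Aligned-read containers.

Reads live on the *extended* axis (canonical + wrap extension).  The in-memory
layout is columnar: a :class:`ReadBlock` holds many reads as numpy arrays plus
a sparse list of deviations from the reference (substitutions, deletions,
insertions), which keeps simulation and pileup construction vectorized.  SAM
and a plain-text read-table dialect are supported at the boundary.

Base codes: 0=A 1=C 2=G 3=T 4=DEL.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pysam

from .reference import MitoReference

BASES = "ACGT"
CODE_DEL = 4
BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}
CODE_TO_SYMBOL = {0: "A", 1: "C", 2: "G", 3: "T", 4: "DEL"}

READ_TABLE_COLUMNS = ["read_id", "start", "length", "mapq", "strand", "amplicon"]


def sequence_codes(seq: str) -> np.ndarray:
    """ACGT string -> uint8 codes 0..3."""
    lut = np.full(128, 255, dtype=np.uint8)
    for b, c in BASE_TO_CODE.items():
        lut[ord(b)] = c
        lut[ord(b.lower())] = c
    codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError("non-ACGT base in sequence")
    return codes


@dataclass(frozen=True)
class AlignedReadRecord:
    """One aligned read's metadata (the substrate of length/MAPQ filtering)."""

    read_id: str
    start: int  # extended-axis 1-based leftmost reference position
    aligned_length: int  # reference span consumed by the alignment
    mapq: int
    strand: str  # '+' or '-'
    amplicon: str | None = None

    def __post_init__(self):
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")
        if not 0 <= self.mapq <= 60:
            raise ValueError("mapq must be in 0..60")


@dataclass
class ReadBlock:
    """A batch of reads with per-read start/length and sparse deviations.

    ``dev_rows/dev_offsets/dev_codes`` encode substitutions and deletions as
    (read index, 0-based offset from that read's start, base code); bases not
    listed match the reference.  ``insertions`` holds (read index, offset of
    the preceding reference base, inserted sequence).
    """

    starts: np.ndarray
    lengths: np.ndarray
    mapq: np.ndarray
    forward: np.ndarray
    id_prefix: str = "read"
    amplicon: str | None = None
    dev_rows: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    dev_offsets: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    dev_codes: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.uint8))
    insertions: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.starts)

    def read_id(self, i: int) -> str:
        return f"{self.id_prefix}:{i}"

    def subset(self, mask: np.ndarray) -> "ReadBlock":
        idx = np.flatnonzero(mask)
        remap = -np.ones(self.n, dtype=np.int64)
        remap[idx] = np.arange(len(idx))
        keep_dev = mask[self.dev_rows]
        return ReadBlock(
            starts=self.starts[idx],
            lengths=self.lengths[idx],
            mapq=self.mapq[idx],
            forward=self.forward[idx],
            id_prefix=self.id_prefix,
            amplicon=self.amplicon,
            dev_rows=remap[self.dev_rows[keep_dev]],
            dev_offsets=self.dev_offsets[keep_dev],
            dev_codes=self.dev_codes[keep_dev],
            insertions=[
                (int(remap[r]), off, seq)
                for r, off, seq in self.insertions
                if mask[r]
            ],
        )

    def sequence_of(self, i: int, ext_codes: np.ndarray) -> tuple[str, str]:
        """(SEQ, CIGAR) of read ``i`` given the extended reference codes."""
        s = int(self.starts[i]) - 1
        L = int(self.lengths[i])
        codes = ext_codes[s : s + L].copy()
        sel = self.dev_rows == i
        for off, code in zip(self.dev_offsets[sel], self.dev_codes[sel]):
            codes[off] = code
        ins = {off: seq for r, off, seq in self.insertions if r == i}
        seq_parts: list[str] = []
        cigar: list[tuple[str, int]] = []

        def push(op: str, length: int) -> None:
            if cigar and cigar[-1][0] == op:
                cigar[-1] = (op, cigar[-1][1] + length)
            else:
                cigar.append((op, length))

        for off in range(L):
            c = codes[off]
            if c == CODE_DEL:
                push("D", 1)
            else:
                seq_parts.append(BASES[c])
                push("M", 1)
            if off in ins:
                seq_parts.append(ins[off])
                push("I", len(ins[off]))
        return "".join(seq_parts), "".join(f"{n}{op}" for op, n in cigar)


@dataclass
class ReadSet:
    """All reads of one sample: a list of blocks against one reference."""

    reference: MitoReference
    blocks: list[ReadBlock] = field(default_factory=list)
    sample: str = "sample"

    @property
    def n_reads(self) -> int:
        return sum(b.n for b in self.blocks)

    def lengths(self) -> np.ndarray:
        if not self.blocks:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([b.lengths for b in self.blocks])

    def mapqs(self) -> np.ndarray:
        if not self.blocks:
            return np.empty(0, dtype=np.int64)
        return np.concatenate([b.mapq for b in self.blocks])

    def iter_records(self) -> Iterator[AlignedReadRecord]:
        for b in self.blocks:
            for i in range(b.n):
                yield AlignedReadRecord(
                    read_id=b.read_id(i),
                    start=int(b.starts[i]),
                    aligned_length=int(b.lengths[i]),
                    mapq=int(b.mapq[i]),
                    strand="+" if b.forward[i] else "-",
                    amplicon=b.amplicon,
                )

    def subset_by_length(self, min_length: int) -> tuple["ReadSet", "ReadSet"]:
        """(kept, removed) split at ``aligned_length >= min_length``."""
        kept, removed = [], []
        for b in self.blocks:
            mask = b.lengths >= min_length
            if mask.all():
                kept.append(b)
            elif not mask.any():
                removed.append(b)
            else:
                kept.append(b.subset(mask))
                removed.append(b.subset(~mask))
        return (
            ReadSet(self.reference, kept, sample=self.sample),
            ReadSet(self.reference, removed, sample=self.sample),
        )

    # ------------------------------------------------------------------ I/O

    def to_sam(self, path) -> None:
        """Write all reads as SAM against the extended reference axis."""
        ref = self.reference
        ext_codes = sequence_codes(ref.extended_sequence())
        header = {
            "HD": {"VN": "1.6", "SO": "unknown"},
            "SQ": [{"SN": ref.name, "LN": ref.extended_length}],
        }
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for b in self.blocks:
                for i in range(b.n):
                    seq, cigar = b.sequence_of(i, ext_codes)
                    a = pysam.AlignedSegment(out.header)
                    a.query_name = b.read_id(i)
                    a.query_sequence = seq
                    a.flag = 0 if b.forward[i] else 16
                    a.reference_id = 0
                    a.reference_start = int(b.starts[i]) - 1
                    a.mapping_quality = int(b.mapq[i])
                    a.cigarstring = cigar
                    a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                    if b.amplicon is not None:
                        a.set_tag("XA", b.amplicon)
                    out.write(a)

    def to_table(self, path=None):
        """Plain-text read-table dialect (metadata only)."""
        import pandas as pd

        rows = [
            (r.read_id, r.start, r.aligned_length, r.mapq, r.strand,
             r.amplicon if r.amplicon is not None else ".")
            for r in self.iter_records()
        ]
        df = pd.DataFrame(rows, columns=READ_TABLE_COLUMNS)
        if path is not None:
            df.to_csv(path, sep="\t", index=False)
        return df


def records_from_table(path) -> list[AlignedReadRecord]:
    """Load the TSV read-table dialect as AlignedReadRecord metadata."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    missing = set(READ_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"read table missing columns: {sorted(missing)}")
    return [
        AlignedReadRecord(
            read_id=str(r.read_id),
            start=int(r.start),
            aligned_length=int(r.length),
            mapq=int(r.mapq),
            strand=str(r.strand),
            amplicon=None if str(r.amplicon) == "." else str(r.amplicon),
        )
        for r in df.itertuples(index=False)
    ]


def records_from_sam(path) -> list[AlignedReadRecord]:
    """Aligned-read metadata from SAM/BAM (unmapped reads skipped)."""
    records = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            records.append(
                AlignedReadRecord(
                    read_id=a.query_name,
                    start=a.reference_start + 1,
                    aligned_length=a.reference_length or len(a.query_sequence or ""),
                    mapq=a.mapping_quality,
                    strand="-" if a.is_reverse else "+",
                    amplicon=a.get_tag("XA") if a.has_tag("XA") else None,
                )
            )
    return records
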