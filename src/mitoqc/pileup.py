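"""Per-position pileups on the canonical mtDNA axis.

Columns are stored as dense numpy count arrays (allele x position, split by
strand) so that whole-genome pileups from hundreds of thousands of reads are
cheap.  Reads aligned into the wrap extension contribute to the canonical
positions they remap to.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pysam

from .reads import BASES, CODE_DEL, CODE_TO_SYMBOL, ReadSet, sequence_codes
from .reference import MitoReference


class MalformedRead(ValueError):
    pass


@dataclass
class PileupColumn:
    """Lightweight per-position view of the pileup arrays."""

    position: int  # canonical 1-based
    counts: dict[str, int]  # {A, C, G, T, DEL} -> reads
    counts_forward: dict[str, int]
    insertions: dict[str, int]  # inserted sequence -> reads
    ref_base: str | None = None

    @property
    def depth(self) -> int:
        return sum(self.counts.values())

    @property
    def strand_depth(self) -> tuple[int, int]:
        fwd = sum(self.counts_forward.values())
        return fwd, self.depth - fwd


class Pileup:
    """Allele counts per canonical position, strand-resolved.

    ``counts[code, pos]`` with code 0..4 = A,C,G,T,DEL and ``pos`` 1-based
    (index 0 unused).  Insertions are keyed by the canonical position of the
    preceding reference base.
    """

    def __init__(self, ref: MitoReference):
        self.reference = ref
        L = ref.canonical_length
        self.counts_fwd = np.zeros((5, L + 1), dtype=np.int64)
        self.counts_rev = np.zeros((5, L + 1), dtype=np.int64)
        self.insertions: dict[int, Counter] = {}

    @property
    def counts(self) -> np.ndarray:
        return self.counts_fwd + self.counts_rev

    def depth(self) -> np.ndarray:
        """Depth per canonical position (index 0 unused)."""
        return self.counts.sum(axis=0)

    def column(self, position: int) -> PileupColumn:
        total = self.counts[:, position]
        fwd = self.counts_fwd[:, position]
        return PileupColumn(
            position=position,
            counts={CODE_TO_SYMBOL[c]: int(total[c]) for c in range(5)},
            counts_forward={CODE_TO_SYMBOL[c]: int(fwd[c]) for c in range(5)},
            insertions=dict(self.insertions.get(position, {})),
            ref_base=self.reference.base(position),
        )

    def columns(self):
        for pos in range(1, self.reference.canonical_length + 1):
            yield self.column(pos)


def _canonical_index(ref: MitoReference) -> np.ndarray:
    """Extended-axis 1-based position -> canonical 1-based position."""
    L, E = ref.canonical_length, ref.extension_length
    idx = np.empty(L + E + 1, dtype=np.int64)
    idx[1 : L + 1] = np.arange(1, L + 1)
    if E:
        idx[L + 1 :] = np.arange(1, E + 1)
    idx[0] = 0
    return idx


def build_pileup(reads: ReadSet, ref: MitoReference | None = None) -> Pileup:
    """Pileup from an in-memory read set (vectorized per block)."""
    ref = ref or reads.reference
    pile = Pileup(ref)
    canon = _canonical_index(ref)
    ext_codes = sequence_codes(ref.extended_sequence())
    ext_len = ref.extended_length

    for b in reads.blocks:
        if b.n == 0:
            continue
        if (b.starts + b.lengths - 1 > ext_len).any() or (b.starts < 1).any():
            raise MalformedRead("read extends beyond the extended axis")
        # reference-matching contribution: per-position coverage by strand
        for strand_counts, mask in (
            (pile.counts_fwd, b.forward),
            (pile.counts_rev, ~b.forward),
        ):
            if not mask.any():
                continue
            starts = b.starts[mask]
            ends = starts + b.lengths[mask]  # exclusive, extended axis
            diff = np.zeros(ext_len + 2, dtype=np.int64)
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
            cov = np.cumsum(diff)[: ext_len + 1]  # cov[p] = depth at ext pos p
            covered = np.flatnonzero(cov)
            np.add.at(
                strand_counts,
                (ext_codes[covered - 1], canon[covered]),
                cov[covered],
            )
        # sparse deviations: move counts from the ref allele to the dev allele
        if len(b.dev_rows):
            pos_ext = b.starts[b.dev_rows] + b.dev_offsets
            pos_can = canon[pos_ext]
            ref_code = ext_codes[pos_ext - 1]
            fwd = b.forward[b.dev_rows]
            for strand_counts, m in (
                (pile.counts_fwd, fwd),
                (pile.counts_rev, ~fwd),
            ):
                if not m.any():
                    continue
                np.add.at(strand_counts, (ref_code[m], pos_can[m]), -1)
                np.add.at(strand_counts, (b.dev_codes[m], pos_can[m]), 1)
        for row, off, seq in b.insertions:
            pos = int(canon[int(b.starts[row]) + off])
            pile.insertions.setdefault(pos, Counter())[seq] += 1
    return pile


def pileup_from_sam(path, ref: MitoReference) -> Pileup:
    """Pileup from SAM/BAM aligned to the extended axis.

    Walks each alignment's CIGAR against the reference; intended for files of
    moderate size (validation runs), not for production-scale BAMs.
    """
    pile = Pileup(ref)
    canon = _canonical_index(ref)
    code_of = {b: i for i, b in enumerate(BASES)}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped or a.query_sequence is None:
                continue
            counts = pile.counts_rev if a.is_reverse else pile.counts_fwd
            rpos = a.reference_start  # 0-based extended
            qpos = 0
            seq = a.query_sequence
            if a.reference_end and a.reference_end > ref.extended_length:
                raise MalformedRead(f"{a.query_name} extends beyond extended axis")
            for op, length in a.cigartuples:
                if op in (0, 7, 8):  # M/=/X
                    for k in range(length):
                        base = seq[qpos + k].upper()
                        if base in code_of:
                            counts[code_of[base], canon[rpos + k + 1]] += 1
                    rpos += length
                    qpos += length
                elif op == 1:  # I — anchored to preceding reference base
                    pos = int(canon[rpos])
                    pile.insertions.setdefault(pos, Counter())[
                        seq[qpos : qpos + length].upper()
                    ] += 1
                    qpos += length
                elif op == 2:  # D
                    for k in range(length):
                        counts[CODE_DEL, canon[rpos + k + 1]] += 1
                    rpos += length
                elif op == 4:  # S
                    qpos += length
                elif op == 3:  # N
                    rpos += length
    return pile
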