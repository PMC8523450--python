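"""VarFreq (haplotype purity) profiling and run-quality QC.

VarFreq at a position is the percentage of reads supporting the called
(consensus) allele — at a heteroplasmic position, the major allele.  Purity
dips mark noise: NUMT co-amplification, homopolymer miscalls, PCR artifacts.
This module computes per-position profiles, their empirical cumulative
distribution on the integer 0–99 grid, a cross-sample recurrent-noisy-position
blacklist, coverage summaries, and an envelope-based run-reliability check.

A packaged table of recurrently impure positions observed on forensic control
DNAs (with NUMT annotations) ships as the default annotation list
(``mitoqc/data/noisy_positions.tsv``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .caller import CallSet
from .pileup import Pileup
from .reference import AmpliconPanel, GenomicInterval, MitoReference


class InsufficientData(ValueError):
    pass


@dataclass
class VarFreqProfile:
    """Per-position consensus-allele purity for one replicate.

    Positions with zero depth are absent.  ``second_allele`` names the
    runner-up signal at each position: a base, ``DEL``, or ``INS``.
    """

    positions: np.ndarray  # canonical 1-based, sorted
    varfreq: np.ndarray  # percent in [0, 100]
    depth: np.ndarray
    second_allele: np.ndarray | None = None  # dtype=object / str
    sample: str = "sample"

    def __post_init__(self):
        if not (len(self.positions) == len(self.varfreq) == len(self.depth)):
            raise ValueError("profile arrays must align")

    def __len__(self) -> int:
        return len(self.positions)

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"position": self.positions, "varfreq": self.varfreq,
             "depth": self.depth}
        )
        if self.second_allele is not None:
            df["second_allele"] = self.second_allele
        return df


def compute_varfreq_profile(
    pile: Pileup, callset: CallSet, sample: str = "sample"
) -> VarFreqProfile:
    """VarFreq = frequency of the called allele (major allele for PHPs).

    The runner-up allele at each position is the strongest competing signal
    among the other bases, DEL, and the top inserted sequence.
    """
    counts = pile.counts  # (5, L+1)
    depth = counts.sum(axis=0)
    L = pile.reference.canonical_length
    positions = np.flatnonzero(depth[1:]) + 1
    if len(callset.calls) != L:
        raise ValueError("callset does not cover every canonical position")
    symbols = np.array(["A", "C", "G", "T", "DEL"])
    vf = np.empty(len(positions))
    second = np.empty(len(positions), dtype=object)
    for i, pos in enumerate(positions):
        call = callset.call_at(int(pos))
        col_counts = counts[:, pos]
        d = int(depth[pos])
        if call.call_type in ("substitution", "reference") and call.alleles:
            allele = call.alleles[0]
        elif call.call_type == "PHP":
            a, b = call.alleles
            allele = a if col_counts[_code(a)] >= col_counts[_code(b)] else b
        elif call.call_type == "deletion":
            allele = "DEL"
        else:  # no-call: fall back to the raw consensus
            allele = symbols[int(np.argmax(col_counts))]
        called_n = int(col_counts[_code(allele)])
        ins = pile.insertions.get(int(pos))
        if ins and allele != "DEL":
            # reads carrying an insertion at this anchor do not support the
            # clean haplotype allele
            called_n = max(0, called_n - sum(ins.values()))
        vf[i] = 100.0 * called_n / d
        rest = [(int(n), s) for s, n in zip(symbols, col_counts) if s != allele]
        ins = pile.insertions.get(int(pos))
        if ins:
            rest.append((max(ins.values()), "INS"))
        rest.sort(key=lambda t: (-t[0], t[1]))
        second[i] = rest[0][1] if rest and rest[0][0] > 0 else "."
    return VarFreqProfile(positions, vf, depth[positions], second, sample)


def _code(symbol: str) -> int:
    return {"A": 0, "C": 1, "G": 2, "T": 3, "DEL": 4}[symbol]


@dataclass
class VarFreqECDF:
    """Proportion of positions with VarFreq <= g for integer g in 0..99.

    Positions at exactly 100 contribute to the denominator but to no grid
    point (the distribution is reported over the 0–99 range).
    """

    grid: np.ndarray
    proportion_le: np.ndarray
    n_positions: int

    def at(self, g: int) -> float:
        return float(self.proportion_le[int(g)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"varfreq": self.grid, "proportion_le": self.proportion_le}
        )


def compute_ecdf(profiles) -> VarFreqECDF:
    """Pooled ECDF of VarFreq across one or more profiles."""
    if isinstance(profiles, VarFreqProfile):
        profiles = [profiles]
    values = np.concatenate([p.varfreq for p in profiles]) if profiles else \
        np.empty(0)
    if len(values) == 0:
        raise InsufficientData("no positions to pool")
    grid = np.arange(100)
    prop = np.searchsorted(np.sort(values), grid, side="right") / len(values)
    return VarFreqECDF(grid, prop, len(values))


def count_below(profiles, threshold: float, inclusive: bool = False) -> int:
    """Number of pooled positions with VarFreq < threshold (or <=)."""
    if isinstance(profiles, VarFreqProfile):
        profiles = [profiles]
    values = np.concatenate([p.varfreq for p in profiles])
    return int((values <= threshold).sum() if inclusive
               else (values < threshold).sum())


def load_noisy_position_annotation() -> pd.DataFrame:
    """Packaged table of recurrently impure positions (NUMT-annotated)."""
    with resources.files("mitoqc.data").joinpath("noisy_positions.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def identify_recurrent_noisy_positions(
    replicate_profiles: dict[str, list[VarFreqProfile]],
    reference: MitoReference | None = None,
    threshold: float = 90.0,
    min_samples: int = 2,
    numt_positions: set[int] | None = None,
) -> pd.DataFrame:
    """Cross-sample blacklist of recurrently impure positions.

    A position qualifies when its mean VarFreq across the replicates of a
    sample group falls below ``threshold`` in at least ``min_samples``
    distinct groups.  Output mirrors the validation report layout: one row
    per (position, sample) with mean, SD, the second most common variant and
    a NUMT annotation.  ``numt_positions`` defaults to the packaged list.
    """
    if len(replicate_profiles) < min_samples:
        raise InsufficientData(
            f"need >= {min_samples} sample groups, got {len(replicate_profiles)}"
        )
    if numt_positions is None:
        ann = load_noisy_position_annotation()
        numt_positions = set(ann.loc[ann.numt == 1, "position"])
    stats: dict[str, pd.DataFrame] = {}
    for sample, profiles in replicate_profiles.items():
        frames = [p.as_frame().assign(replicate=i)
                  for i, p in enumerate(profiles)]
        df = pd.concat(frames)
        g = df.groupby("position")["varfreq"].agg(["mean", "std", "count"])
        if "second_allele" in df.columns:
            g["second"] = df.groupby("position")["second_allele"].agg(
                lambda s: s.mode().iloc[0]
            )
        else:
            g["second"] = "."
        stats[sample] = g
    below = {
        sample: set(g.index[g["mean"] < threshold])
        for sample, g in stats.items()
    }
    recurrent = sorted(
        p for p in set().union(*below.values())
        if sum(p in s for s in below.values()) >= min_samples
    )
    rows = []
    for pos in recurrent:
        for sample, g in stats.items():
            if pos not in g.index:
                continue
            rows.append(
                {
                    "position": pos,
                    "ref_base": reference.base(pos) if reference else "N",
                    "sample": sample,
                    "varfreq_mean": round(float(g.loc[pos, "mean"]), 2),
                    "varfreq_sd": round(float(g.loc[pos, "std"]), 2)
                    if g.loc[pos, "count"] > 1 else 0.0,
                    "second_variant": g.loc[pos, "second"],
                    "numt": pos in numt_positions,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["position", "ref_base", "sample", "varfreq_mean",
                 "varfreq_sd", "second_variant", "numt"],
    )


@dataclass
class CoverageSummary:
    total_mapped_reads: int
    mean_base_coverage: float
    uniformity_pct: float
    mean_amplicon_coverage: float
    median_amplicon_coverage: float
    per_amplicon_mean_depth: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total_mapped_reads": self.total_mapped_reads,
            "mean_base_coverage": self.mean_base_coverage,
            "uniformity_pct": self.uniformity_pct,
            "mean_amplicon_coverage": self.mean_amplicon_coverage,
            "median_amplicon_coverage": self.median_amplicon_coverage,
        }


def coverage_summary(
    pile: Pileup,
    panel: AmpliconPanel | None = None,
    n_reads: int | None = None,
    uniformity_fraction: float = 0.2,
) -> CoverageSummary:
    """Depth summaries: mean base coverage over canonical positions,
    uniformity (% of positions at >= ``uniformity_fraction`` x mean depth),
    and per-amplicon mean depths."""
    depth = pile.depth()[1:]
    mean_cov = float(depth.mean())
    uniformity = (
        100.0 * float((depth >= uniformity_fraction * mean_cov).mean())
        if mean_cov > 0 else 0.0
    )
    per_amp: dict[str, float] = {}
    if panel is not None:
        L = pile.reference.canonical_length
        full = pile.depth()
        for a in panel:
            s, e = a.interval.start, a.interval.end
            if e <= L:
                idx = np.arange(s, e + 1)
            else:
                idx = np.concatenate([np.arange(s, L + 1),
                                      np.arange(1, e - L + 1)])
            per_amp[a.name] = float(full[idx].mean())
    amp_means = np.array(list(per_amp.values())) if per_amp else np.array([0.0])
    return CoverageSummary(
        total_mapped_reads=n_reads if n_reads is not None else 0,
        mean_base_coverage=mean_cov,
        uniformity_pct=uniformity,
        mean_amplicon_coverage=float(amp_means.mean()),
        median_amplicon_coverage=float(np.median(amp_means)),
        per_amplicon_mean_depth=per_amp,
    )


@dataclass
class RunQualityVerdict:
    verdict: str  # "stable" | "stochastic"
    distance: float
    grid_window: tuple[int, int]

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "distance": self.distance,
            "grid_window": list(self.grid_window),
        }


def reference_band(
    ecdfs: list[VarFreqECDF], grid_window: tuple[int, int] = (93, 99)
) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise min/max envelope of known-good ECDFs over the window."""
    if len(ecdfs) < 3:
        raise InsufficientData("need >= 3 known-good replicates for the band")
    lo, hi = grid_window
    stack = np.stack([e.proportion_le[lo : hi + 1] for e in ecdfs])
    return stack.min(axis=0), stack.max(axis=0)


def classify_run_quality(
    ecdf: VarFreqECDF,
    band: tuple[np.ndarray, np.ndarray],
    grid_window: tuple[int, int] = (93, 99),
    tolerance: float = 0.005,
) -> RunQualityVerdict:
    """Envelope test for run reliability.

    A degraded run accumulates impure positions, lifting its cumulative
    VarFreq curve above the band of known-good runs in the high-purity
    window.  distance = max over the window of (ecdf − band upper), clipped
    at zero; ``stochastic`` when it exceeds ``tolerance``.
    """
    lo, hi = grid_window
    band_lo, band_hi = band
    seg = ecdf.proportion_le[lo : hi + 1]
    if len(seg) != len(band_hi):
        raise ValueError("band and window size mismatch")
    distance = float(np.clip(seg - band_hi, 0.0, None).max())
    return RunQualityVerdict(
        verdict="stochastic" if distance > tolerance else "stable",
        distance=distance,
        grid_window=grid_window,
    )
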