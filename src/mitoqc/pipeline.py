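"""End-to-end convenience pipeline: reads -> filter -> pileup -> calls -> QC.

These helpers wire the modules together the way a validation run uses them:
length-filter the reads, build the pileup, run the threshold caller, derive
the haplotype profile and the VarFreq profile.  The dilution-series driver
replays the whole ladder with per-replicate seeds derived from one master
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

from .caller import (
    CallerConfig,
    CallSet,
    HaplotypeProfile,
    call_genome,
    call_haplotype,
    detect_nocall_regions,
)
from .pileup import Pileup, build_pileup
from .read_filter import DEFAULT_CUTOFF_BP, FilterReport, filter_reads
from .reads import ReadSet
from .reference import AmpliconPanel
from .sensitivity import (
    DilutionSpec,
    SensitivityResult,
    default_ladder,
    score_replicate,
)
from .simulate import SimulationConfig, SimulationTruth, make_config, simulate_sample
from .varfreq import VarFreqProfile, compute_varfreq_profile


def child_seed(master_seed: int, index: int) -> int:
    """Deterministic per-replicate seed below 2**31."""
    return (master_seed * 1_000_003 + 7919 * index + 1) % (2 ** 31 - 1)


@dataclass
class SampleResult:
    truth: SimulationTruth | None
    filter_report: FilterReport
    pileup: Pileup
    callset: CallSet
    nocall_intervals: list
    profile: HaplotypeProfile
    varfreq: VarFreqProfile


def process_reads(
    reads: ReadSet,
    panel: AmpliconPanel | None = None,
    caller_cfg: CallerConfig | None = None,
    cutoff_bp: int = DEFAULT_CUTOFF_BP,
    truth: SimulationTruth | None = None,
    sample: str | None = None,
) -> SampleResult:
    """Standard analysis of one sample's aligned reads."""
    caller_cfg = caller_cfg or CallerConfig()
    kept, _removed, report = filter_reads(reads, cutoff_bp=cutoff_bp)
    pile = build_pileup(kept)
    callset = call_genome(pile, cfg=caller_cfg)
    nocall = detect_nocall_regions(callset, pile, panel, caller_cfg)
    profile = call_haplotype(callset, nocall)
    vf = compute_varfreq_profile(pile, callset,
                                 sample=sample or reads.sample)
    return SampleResult(truth, report, pile, callset, nocall, profile, vf)


def run_simulated_sample(
    config: SimulationConfig,
    caller_cfg: CallerConfig | None = None,
    cutoff_bp: int = DEFAULT_CUTOFF_BP,
) -> SampleResult:
    reads, truth = simulate_sample(config)
    return process_reads(reads, config.panel, caller_cfg, cutoff_bp,
                         truth=truth, sample=config.sample)


def run_dilution_series(
    master_seed: int,
    ladder: list[DilutionSpec] | None = None,
    caller_cfg: CallerConfig | None = None,
    target_depth: float | None = None,
    **config_overrides,
) -> tuple[list[SensitivityResult], dict[tuple[str, int], SampleResult]]:
    """Simulate and score the full dilution ladder.

    Returns the per-replicate scores and the full per-replicate results
    keyed by (dilution label, replicate index).  Reference, panel, truth
    haplotype and PHP sites are shared across the ladder; only the input
    mass and the per-replicate seed vary.
    """
    ladder = ladder or default_ladder()
    if target_depth is not None:
        config_overrides["target_depth"] = target_depth
    # FP/FN accounting applies the packaged recurrent-noisy-position
    # blacklist, as an analyst would
    from .varfreq import load_noisy_position_annotation

    blacklist = set(load_noisy_position_annotation().position)
    results: list[SensitivityResult] = []
    samples: dict[tuple[str, int], SampleResult] = {}
    idx = 0
    for spec in ladder:
        for rep in range(spec.replicates):
            cfg = make_config(
                seed=child_seed(master_seed, idx),
                input_pg=spec.input_pg,
                sample=f"{spec.label}.{rep + 1}",
                **config_overrides,
            )
            res = run_simulated_sample(cfg, caller_cfg)
            results.append(score_replicate(
                res.profile, res.truth, label=spec.label, replicate=rep,
                input_pg=spec.input_pg,
                canonical_length=cfg.reference.canonical_length,
                exclude_positions=blacklist,
            ))
            samples[(spec.label, rep)] = res
            idx += 1
    return results, samples
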