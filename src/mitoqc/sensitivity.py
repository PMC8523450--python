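"""Dilution-series sensitivity scoring and haplotype concordance.

Orchestrates the validation experiments: converts gDNA input mass to mtDNA
template copies (0.1 ng of gDNA ~ 2,900 copies), scores called profiles
against a known truth (false positives/negatives, genome completeness, PHP
recovery), and compares haplotype profiles position-by-position with
forensic conventions (control-region restriction, PHP-vs-homoplasmy
leniency, homopolymer tagging).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .caller import HaplotypeProfile, IUPAC_TO_PAIR, VariantCall
from .reference import (
    CONTROL_REGION,
    GenomicInterval,
    HOMOPOLYMER_REGIONS,
    RCRS_LENGTH,
)

#: pg of gDNA per the standard copy-number equation's reference input.
_REFERENCE_INPUT_PG = 100.0
_COPIES_AT_REFERENCE = 2900.0

#: 13-step gDNA dilution ladder (pg), 3 replicates each.
DILUTION_LADDER_PG = (
    100.0, 20.0, 10.0, 5.0, 2.5, 1.2, 0.6, 0.3, 0.15,
    0.075, 0.0375, 0.01875, 0.009375,
)


@dataclass(frozen=True)
class DilutionSpec:
    label: str
    input_pg: float
    replicates: int = 3


def default_ladder(replicates: int = 3) -> list[DilutionSpec]:
    return [
        DilutionSpec(f"X{i + 1}", pg, replicates)
        for i, pg in enumerate(DILUTION_LADDER_PG)
    ]


def copies_from_input(input_pg: float) -> tuple[float, int]:
    """mtDNA copy number for a gDNA input mass.

    Linear in mass: ``copies = input_pg / 100 * 2900``.  Returns the real
    value and its round-half-to-even integer (0.6 pg -> 17.4 -> 17 copies).
    """
    if input_pg < 0:
        raise ValueError("input mass must be >= 0")
    real = input_pg / _REFERENCE_INPUT_PG * _COPIES_AT_REFERENCE
    return real, int(round(real))


@dataclass
class SensitivityResult:
    """Per-replicate scoring against truth."""

    label: str
    replicate: int
    input_pg: float
    pct_mtDNA_covered: float
    false_positive_calls: int
    false_negative_calls: int
    php_detected: dict[int, float | None]  # site -> observed minor %, or None
    false_positive_positions: list[int] = field(default_factory=list)
    false_negative_positions: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "replicate": self.replicate,
            "input_pg": self.input_pg,
            "pct_mtDNA_covered": self.pct_mtDNA_covered,
            "false_positive_calls": self.false_positive_calls,
            "false_negative_calls": self.false_negative_calls,
            "php_detected": {str(k): v for k, v in self.php_detected.items()},
        }


def _profile_variant_map(profile: HaplotypeProfile) -> dict[tuple[int, str], VariantCall]:
    return {(v.position, v.call_type): v for v in profile.variants}


def score_replicate(
    profile: HaplotypeProfile,
    truth,
    label: str = "",
    replicate: int = 0,
    input_pg: float = float("nan"),
    canonical_length: int = RCRS_LENGTH,
    exclude_positions: set[int] | None = None,
) -> SensitivityResult:
    """Score one called profile against simulation truth.

    False positives: called variants absent from truth (positions inside
    no-call intervals never count).  False negatives: truth variants at
    covered positions that were not called.  A truth PHP site called as a
    PHP (any frequency) is neither FP nor FN; its observed minor frequency
    is reported separately.  ``exclude_positions`` (typically the workflow's
    recurrent-noisy-position blacklist) removes those positions from FP/FN
    accounting, mirroring how an analyst interprets calls there with
    caution rather than at face value.
    """
    exclude_positions = exclude_positions or set()
    nocall = profile.nocall_intervals
    covered = np.ones(canonical_length + 1, dtype=bool)
    covered[0] = False
    for iv in nocall:
        covered[iv.start : min(iv.end, canonical_length) + 1] = False
    truth_variants = {(v.position, v.call_type): v for v in truth.haplotype.variants}
    php_sites = {s.position: s for s in truth.php_sites}
    called = _profile_variant_map(profile)
    fp_positions: list[int] = []
    fn_positions: list[int] = []
    php_detected: dict[int, float | None] = {}
    for key in called:
        pos, ctype = key
        if pos in exclude_positions:
            continue
        if pos in php_sites and ctype == "PHP":
            continue  # scored via php_detected below
        if key not in truth_variants:
            fp_positions.append(pos)
    for key in truth_variants:
        pos = key[0]
        if pos in exclude_positions:
            continue
        if covered[pos] and key not in called:
            fn_positions.append(pos)
    for pos, site in php_sites.items():
        if not covered[pos]:
            php_detected[pos] = None
            continue
        hit = called.get((pos, "PHP"))
        php_detected[pos] = (
            float(hit.variant_frequency) if hit is not None else None
        )
    pct_covered = 100.0 * covered[1:].sum() / canonical_length
    return SensitivityResult(
        label=label,
        replicate=replicate,
        input_pg=input_pg,
        pct_mtDNA_covered=float(pct_covered),
        false_positive_calls=len(fp_positions),
        false_negative_calls=len(fn_positions),
        php_detected=php_detected,
        false_positive_positions=sorted(fp_positions),
        false_negative_positions=sorted(fn_positions),
    )


@dataclass
class ConcordanceResult:
    shared_range: list[GenomicInterval]
    concordant: int
    concordant_with_note: list[tuple[int, str, str]]
    discordant: list[tuple[int, str, str]]
    excluded_nocall: list[int]
    verdict: str  # full | partial | discordant

    @property
    def comparable_positions(self) -> int:
        return self.concordant + len(self.discordant)


def _restrict_positions(restrict_to, canonical_length: int) -> np.ndarray:
    mask = np.zeros(canonical_length + 1, dtype=bool)
    if restrict_to is None:
        mask[1:] = True
    else:
        for iv in restrict_to:
            mask[iv.start : min(iv.end, canonical_length) + 1] = True
    return mask


def _call_token(v: VariantCall | None) -> str:
    if v is None:
        return "ref"
    return v.empop()


def compare_haplotypes(
    a: HaplotypeProfile,
    b: HaplotypeProfile,
    restrict_to: list[GenomicInterval] | None = None,
    strict_php: bool = False,
    canonical_length: int = RCRS_LENGTH,
) -> ConcordanceResult:
    """Position-wise concordance between two haplotype profiles.

    Positions inside either profile's no-call intervals are excluded and
    listed.  A PHP in one profile whose major allele matches the other
    profile's homoplasmic call counts as concordant-with-note unless
    ``strict_php``.  Indel mismatches inside homopolymer tracts are tagged.
    ``restrict_to=control_region_intervals()`` limits to the CR.
    """
    mask = _restrict_positions(restrict_to, canonical_length)
    for profile in (a, b):
        seen = set()
        for v in profile.variants:
            key = (v.position, v.call_type)
            if key in seen:
                raise ValueError(f"duplicate variant {key} within one profile")
            seen.add(key)
    excluded: set[int] = set()
    for profile in (a, b):
        for iv in profile.nocall_intervals:
            excluded.update(range(iv.start, min(iv.end, canonical_length) + 1))
    map_a = {}
    map_b = {}
    for m, profile in ((map_a, a), (map_b, b)):
        for v in profile.variants:
            m.setdefault(v.position, []).append(v)
    homopolymer = set()
    for iv in HOMOPOLYMER_REGIONS:
        homopolymer.update(range(iv.start, iv.end + 1))
    discordant: list[tuple[int, str, str]] = []
    with_note: list[tuple[int, str, str]] = []
    positions = sorted(set(map_a) | set(map_b))
    n_variant_positions = 0
    for pos in positions:
        if not mask[pos] or pos in excluded:
            continue
        n_variant_positions += 1
        va, vb = map_a.get(pos, []), map_b.get(pos, [])
        ta = " ".join(_call_token(v) for v in va) or "ref"
        tb = " ".join(_call_token(v) for v in vb) or "ref"
        if ta == tb:
            continue
        if not strict_php and _php_vs_major_match(va, vb):
            with_note.append((pos, ta, tb))
            continue
        tag = " [homopolymer]" if pos in homopolymer and _has_indel(va + vb) else ""
        discordant.append((pos, ta + tag, tb + tag))
    n_comparable = int(mask[1:].sum()) - sum(1 for p in excluded if mask[p])
    concordant = n_comparable - len(discordant)
    if discordant:
        verdict = "discordant"
    elif excluded:
        verdict = "partial"
    else:
        verdict = "full"
    shared = restrict_to if restrict_to is not None else [
        GenomicInterval(1, canonical_length)
    ]
    return ConcordanceResult(
        shared_range=list(shared),
        concordant=concordant,
        concordant_with_note=with_note,
        discordant=discordant,
        excluded_nocall=sorted(excluded),
        verdict=verdict,
    )


def _has_indel(variants: list[VariantCall]) -> bool:
    return any(v.call_type in ("insertion", "deletion") for v in variants)


def _php_vs_major_match(va: list[VariantCall], vb: list[VariantCall]) -> bool:
    """PHP on one side whose allele pair contains the other side's call."""
    def alleles_of(vs: list[VariantCall]) -> set[str] | None:
        if not vs:
            return None  # reference call; allele unknown without ref base
        v = vs[0]
        if v.call_type == "PHP":
            return set(v.alleles)
        if v.call_type == "substitution":
            return set(v.alleles)
        return None

    if len(va) > 1 or len(vb) > 1:
        return False
    pa, pb = (va[0] if va else None), (vb[0] if vb else None)
    if pa is not None and pa.call_type == "PHP":
        other = alleles_of(vb)
        if other is not None and other <= set(pa.alleles):
            return True
        if pb is None and pa.ref_base in pa.alleles:
            return True
    if pb is not None and pb.call_type == "PHP":
        other = alleles_of(va)
        if other is not None and other <= set(pb.alleles):
            return True
        if pa is None and pb.ref_base in pb.alleles:
            return True
    return False


def control_region_intervals() -> list[GenomicInterval]:
    """Forensic control region: np 16,024–16,569 plus 1–576."""
    return list(CONTROL_REGION)


def php_recovery_curve(
    results: list[SensitivityResult], site: int
) -> pd.DataFrame:
    """Long-format table of observed PHP frequency vs input mass."""
    rows = [
        {
            "label": r.label,
            "input_pg": r.input_pg,
            "replicate": r.replicate,
            "observed_frequency": r.php_detected.get(site),
            "detected": r.php_detected.get(site) is not None,
        }
        for r in results
        if site in r.php_detected
    ]
    return pd.DataFrame(
        rows,
        columns=["label", "input_pg", "replicate", "observed_frequency",
                 "detected"],
    )


def results_table(results: list[SensitivityResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_dict() for r in results])


def markdown_report(
    results: list[SensitivityResult],
    blacklist: pd.DataFrame | None = None,
    concordances: dict[str, ConcordanceResult] | None = None,
) -> str:
    """Human-readable validation-run summary."""
    lines = ["# mitoqc validation summary", "", "## Dilution series", ""]
    df = results_table(results)
    if len(df):
        agg = df.groupby("label", sort=False).agg(
            input_pg=("input_pg", "first"),
            mean_pct_covered=("pct_mtDNA_covered", "mean"),
            total_fp=("false_positive_calls", "sum"),
            total_fn=("false_negative_calls", "sum"),
        )
        lines.append(agg.round(2).to_markdown())
    if concordances:
        lines += ["", "## Concordance", ""]
        for name, c in concordances.items():
            lines.append(
                f"- {name}: {c.verdict} "
                f"({len(c.discordant)} discordant, "
                f"{len(c.concordant_with_note)} with note)"
            )
    if blacklist is not None and len(blacklist):
        lines += ["", "## Recurrent noisy positions", "",
                  blacklist.to_markdown(index=False)]
    return "\n".join(lines) + "\n"
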