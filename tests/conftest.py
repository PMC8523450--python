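"""Shared fixtures: study reference/panel and reusable seeded simulations."""

from __future__ import annotations

import numpy as np
import pytest

import mitoqc as m
from mitoqc.reads import ReadBlock, ReadSet


@pytest.fixture(scope="session")
def reference():
    return m.synthetic_reference()


@pytest.fixture(scope="session")
def panel(reference):
    return m.simulate_panel(reference)


@pytest.fixture(scope="session")
def high_input_result(reference, panel):
    """One fully processed 100 pg sample (seed fixed)."""
    cfg = m.make_config(seed=11, input_pg=100.0, sample="HI",
                        reference=reference, panel=panel)
    return cfg, m.run_simulated_sample(cfg)


@pytest.fixture(scope="session")
def ladder(reference, panel):
    """Scored 13-step dilution ladder, 3 replicates each (seed fixed)."""
    results, samples = m.run_dilution_series(
        1234, reference=reference, panel=panel)
    return results, samples


@pytest.fixture(scope="session")
def blacklist_experiment(reference, panel):
    """Two sample groups x 6 replicates at high input for the recurrent-
    noisy-position blacklist (second group: different haplotype, no PHP)."""
    groups = {}
    for g, (name, hseed, php) in enumerate(
        [("groupA", 11, True), ("groupB", 23, False)]
    ):
        profs = []
        for rep in range(6):
            cfg = m.make_config(
                seed=5000 + 100 * g + rep, input_pg=100.0, sample=name,
                reference=reference, panel=panel,
                haplotype_seed=hseed, include_php=php,
            )
            profs.append(m.run_simulated_sample(cfg).varfreq)
        groups[name] = profs
    return groups


def make_block(
    start: int,
    length: int,
    n: int = 1,
    mapq: int = 50,
    forward=None,
    amplicon=None,
    prefix: str = "t",
) -> ReadBlock:
    """Uniform block of reference-matching reads (test helper)."""
    fwd = np.ones(n, dtype=bool) if forward is None else np.asarray(forward)
    return ReadBlock(
        starts=np.full(n, start, dtype=np.int64),
        lengths=np.full(n, length, dtype=np.int64),
        mapq=np.full(n, mapq, dtype=np.int64),
        forward=fwd,
        id_prefix=prefix,
        amplicon=amplicon,
    )


def make_readset(reference, blocks) -> ReadSet:
    return ReadSet(reference, list(blocks), sample="test")
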