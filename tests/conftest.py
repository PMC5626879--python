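"""Shared fixtures: tiny hand-built references and seeded simulations."""

from __future__ import annotations

import pytest

from cpedit import simdata


@pytest.fixture(scope="session")
def small_sim():
    """Deterministic small library with one planted site, no errors."""
    cfg = simdata.SimConfig(
        seed=11,
        read_count=4000,
        error_rate=0.0,
        edit_sites=(simdata.EditSiteSpec("gene01", None, 0.5),),
    )
    sim = simdata.simulate_references(cfg)
    reads = simdata.simulate_reads(sim)
    return sim, reads


@pytest.fixture(scope="session")
def small_sim_mapped(small_sim):
    from cpedit import mapper

    sim, reads = small_sim
    partition, retained = mapper.hierarchical_partition(reads.reads, sim.refset)
    return sim, reads, partition, retained
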