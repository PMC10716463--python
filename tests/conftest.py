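"""Shared fixtures: small seeded synthetic scenarios reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from ecotyper import preprocess, synthio

MG_MARKERS = ["P2RY12", "TMEM119", "CX3CR1", "SALL1"]
BMDM_MARKERS = ["TGFBI", "ITGA4", "F13A1", "CD163"]


@pytest.fixture(scope="session")
def programs_fragile():
    return synthio.default_programs()


@pytest.fixture(scope="session")
def tme_datasets(programs_fragile):
    """Four labeled T/Myeloid/Oligo datasets, two per platform, normalized."""
    programs, fragile = programs_fragile
    cfg = synthio.SimulationConfig(
        datasets=[
            synthio.DatasetSpec("x1", "droplet-count", "MB", 400,
                                {"T": 0.4, "Myeloid": 0.3, "Oligo": 0.3}),
            synthio.DatasetSpec("x2", "droplet-count", "EPN", 400,
                                {"T": 0.4, "Myeloid": 0.3, "Oligo": 0.3}),
            synthio.DatasetSpec("s1", "full-length-tpm", "MB", 300,
                                {"T": 0.4, "Myeloid": 0.3, "Oligo": 0.3}),
            synthio.DatasetSpec("s2", "full-length-tpm", "EPN", 300,
                                {"T": 0.4, "Myeloid": 0.3, "Oligo": 0.3}),
        ],
        programs=programs, fragile_genes=fragile, seed=0,
    )
    return [preprocess.normalize(ds) for ds in synthio.simulate_single_cell(cfg)]


@pytest.fixture(scope="session")
def myeloid_platform_trio(programs_fragile):
    """Two labeled full-length MG/BMDM datasets plus one droplet target."""
    programs, fragile = programs_fragile
    cfg = synthio.SimulationConfig(
        datasets=[
            synthio.DatasetSpec("ss_epn", "full-length-tpm", "EPN", 200,
                                {"MG": 0.5, "BMDM": 0.5}),
            synthio.DatasetSpec("ss_idhw", "full-length-tpm", "IDH-W", 200,
                                {"MG": 0.6, "BMDM": 0.4}),
            synthio.DatasetSpec("tenx_mb", "droplet-count", "MB", 300,
                                {"MG": 0.5, "BMDM": 0.5}),
        ],
        programs=programs, fragile_genes=fragile, seed=3,
    )
    return [preprocess.normalize(ds) for ds in synthio.simulate_single_cell(cfg)]


def archetype_plan(n_per_arm: int = 40) -> synthio.BulkPlan:
    """Four well-separated planted archetypes with private gene programs."""
    def excl(i):
        return [f"BG{j:04d}" for j in range(i * 15 + 1, i * 15 + 16)]

    return synthio.BulkPlan(archetypes=[
        synthio.ArchetypeSpec("immune_rich", n_per_arm,
                              {"T": 0.4, "Myeloid": 0.3, "Tumor": 0.3},
                              hazard=0.01, exclusive_genes=excl(0)),
        synthio.ArchetypeSpec("immune_desert", n_per_arm,
                              {"Tumor": 0.9, "Oligo": 0.1},
                              hazard=0.03, exclusive_genes=excl(1)),
        synthio.ArchetypeSpec("stromal_centric", n_per_arm,
                              {"Oligo": 0.6, "Tumor": 0.4},
                              hazard=0.02, exclusive_genes=excl(2)),
        synthio.ArchetypeSpec("myeloid_centric", n_per_arm,
                              {"Myeloid": 0.6, "Tumor": 0.4},
                              hazard=0.015, exclusive_genes=excl(3)),
    ], noise_sd=0.3)


@pytest.fixture(scope="session")
def bulk_cohort(programs_fragile):
    programs, _ = programs_fragile
    cfg = synthio.SimulationConfig(
        datasets=[synthio.DatasetSpec("tiny", "droplet-count", "MB", 10,
                                      {"MG": 0.5, "BMDM": 0.5})],
        programs=programs, seed=0,
    )
    return synthio.simulate_bulk_cohort(cfg, archetype_plan())


@pytest.fixture
def rng():
    return np.random.default_rng(0)
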