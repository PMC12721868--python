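"""Shared fixtures: small simulated datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import ribopause as rp

settings.register_profile(
    "suite", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("suite")


def make_annotation(n_codons: int = 40, tid: str = "g1", seed: int = 0) -> rp.TranscriptAnnotation:
    """A single random transcript with the required 21-nt flanks."""
    rng = np.random.default_rng(seed)
    internal = rng.choice(rp.SENSE_CODONS, size=n_codons - 2)
    cds = "ATG" + "".join(internal) + "TAA"
    flank = "".join(rng.choice(list("ACGT"), size=21))
    flank2 = "".join(rng.choice(list("ACGT"), size=21))
    return rp.TranscriptAnnotation(tid, flank + cds + flank2, 21, 21 + len(cds))


@pytest.fixture(scope="session")
def flat_config() -> rp.SimulationConfig:
    """Flat dwell model: no stalls, no initiation/termination occupancy."""
    return rp.SimulationConfig(
        seed=0,
        n_genes=30,
        cds_length_range=(120, 240),
        read_depth=200_000,
        disome_read_depth=2_000,
        n_replicates=1,
        initiation_weight=0.0,
        termination_weight=0.0,
        termination_queue_weight=0.0,
        genotypes={"wildtype": rp.GenotypeSpec()},
    )


@pytest.fixture(scope="session")
def flat_tx(flat_config) -> rp.Transcriptome:
    return rp.generate_transcriptome(flat_config)


@pytest.fixture(scope="session")
def flat_footprints(flat_config, flat_tx):
    return rp.simulate_footprints(flat_tx, flat_config)


@pytest.fixture(scope="session")
def stall_dataset():
    """Two genotypes; the mutant carries explicit depth-2 stalls at known
    codon-pair sites, deep enough in the CDS for a -35..+10 window."""
    sites = [
        rp.StallSite("g0001", 100, {2: 1.0}, weight=120.0),
        rp.StallSite("g0002", 80, {2: 1.0}, weight=120.0),
        rp.StallSite("g0003", 120, {2: 1.0}, weight=120.0),
    ]
    cfg = rp.SimulationConfig(
        seed=1,
        n_genes=40,
        cds_length_range=(200, 300),
        read_depth=400_000,
        disome_read_depth=40_000,
        n_replicates=2,
        genotypes={"wildtype": rp.GenotypeSpec(), "mutant": rp.GenotypeSpec(stall_sites=sites)},
    )
    tx = rp.generate_transcriptome(cfg)
    fp = rp.simulate_footprints(tx, cfg)
    return cfg, tx, fp, sites
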