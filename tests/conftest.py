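"""Shared fixtures: the reference synthetic genome and planted families.

Heavy objects are session-scoped so the detection and acceptance tests share
one simulation and one self-alignment run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pytest

from ldprscan.alignments import self_align
from ldprscan.caller import CallParams, calibrate_threshold, call_ldprs
from ldprscan.simulate import SimConfig, SimResult, simulate_genome


@dataclass
class GenomeBundle:
    sim: SimResult
    alignments: list
    chrom_lengths: dict
    params: CallParams
    ldprs: list


@pytest.fixture(scope="session")
def seed7() -> GenomeBundle:
    """The reference planted genome: 2 chromosomes x 2 Mbp, 6 tandem arrays
    of 2-4 Kbp units (4-8 units each), LTR-like elements, background gene
    families — with the density threshold calibrated against the truth."""
    sim = simulate_genome(SimConfig(seed=7))
    chrom_lengths = {c: len(s) for c, s in sim.genome.items()}
    alignments = self_align(sim.genome)
    mult, _ = calibrate_threshold(alignments, chrom_lengths, sim.truth.planted_ldprs)
    params = CallParams(threshold_multiplier=mult)
    ldprs = call_ldprs(alignments, chrom_lengths, params)
    return GenomeBundle(sim, alignments, chrom_lengths, params, ldprs)


@pytest.fixture(scope="session")
def planted_proteins():
    """20 planted protein families (within-family identity ~0.9)."""
    from ldprscan.simulate import simulate_protein_families

    return simulate_protein_families(seed=0)


@pytest.fixture(scope="session")
def planted_clusters(planted_proteins):
    from ldprscan.cluster import greedy_cluster

    proteins, labels = planted_proteins
    return greedy_cluster(proteins, cutoff=0.5), labels


@pytest.fixture(autouse=True)
def _quiet_separation_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*separation.*", category=RuntimeWarning)
        yield
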