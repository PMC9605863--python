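"""Shared fixtures: one seeded reference community, scanned once per session."""

from __future__ import annotations

import numpy as np
import pytest

from borgtools import (
    default_community_config,
    find_tandem_arrays,
    simulate_community,
)
from borgtools.borg_screen import compute_contig_features, evaluate_criteria

COMMUNITY_SEED = 42


@pytest.fixture(scope="session")
def community():
    """The reference simulated community: 4 Borg-like genomes (two per host
    population), 2 hosts, 20 background contigs, 50 samples."""
    return simulate_community(default_community_config(seed=COMMUNITY_SEED))


@pytest.fixture(scope="session")
def borg_arrays(community):
    """Tandem-array scan at default parameters for every Borg contig."""
    return {
        bid: find_tandem_arrays(community.contig(bid))
        for bid in community.truth.borg_ids
    }


@pytest.fixture(scope="session")
def coverage(community):
    """Mean per-sample depth per contig, from the simulated count matrix."""
    return (
        community.counts.div(community.lengths, axis=0).mean(axis=1)
        * community.config.read_length
    )


@pytest.fixture(scope="session")
def screen_results(community, coverage):
    """Five-criterion screen over every contig of the reference community."""
    feats = compute_contig_features(community.contigs, community.genes, coverage)
    return {f.contig_id: evaluate_criteria(f) for f in feats}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
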