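import numpy as np
import pytest

from netseq.annotation import Gene, GeneAnnotationSet
from netseq.occupancy import OccupancyTrack
from netseq.simulate import (SimulationConfig, generate_toy_genome,
                             simulate_occupancy)


@pytest.fixture(scope="session")
def toy_cfg():
    return SimulationConfig(n_genes=40, seed=11)


@pytest.fixture(scope="session")
def toy_world(toy_cfg):
    """(genome, annotation, rep1, rep2, truth) under the default regime."""
    genome, ann = generate_toy_genome(toy_cfg)
    rep1, rep2, truth = simulate_occupancy(ann, toy_cfg)
    return genome, ann, rep1, rep2, truth


@pytest.fixture
def single_gene_world():
    """One 1 kb plus-strand gene on a 2 kb chromosome with a blank track."""
    gene = Gene("gA", "chr1", 200, 1200, "+")
    ann = GeneAnnotationSet([gene], {"chr1": 2000})
    track = OccupancyTrack({"chr1": 2000})
    return gene, ann, track


def uniform_track(ann, value=1.0, normalized=True):
    track = OccupancyTrack(ann.chrom_lengths)
    for key in track.data:
        track.data[key][:] = value
    track.normalized = normalized
    track.library_size = 0.0 if normalized else track.total()
    return track
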