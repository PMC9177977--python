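"""Shared fixtures: session-scoped simulations reused across test modules."""

import pytest

from acylstall import ribo
from acylstall.simulate import RiboSimSpec, gen_genome, simulate_footprints


@pytest.fixture(scope="session")
def null_sim():
    """Stall-free footprint library at the standard study scale."""
    spec = RiboSimSpec(seed=1)
    genome, _ = gen_genome(spec)
    aln, truth = simulate_footprints(genome, spec)
    track = ribo.density_track(aln, genome.contig_lengths)
    retained = ribo.filter_orfs(genome, track)
    return dict(spec=spec, genome=genome, alignments=aln, truth=truth,
                track=track, retained=retained)


@pytest.fixture(scope="session")
def gga_stall_sim():
    """Library with an 8x dwell at GGA codons in the A site, offset -11."""
    spec = RiboSimSpec(seed=1, stalls={"GGA": 8.0}, offset=-11)
    genome, _ = gen_genome(spec)
    aln, truth = simulate_footprints(genome, spec)
    track = ribo.density_track(aln, genome.contig_lengths)
    retained = ribo.filter_orfs(genome, track)
    return dict(spec=spec, genome=genome, alignments=aln, truth=truth,
                track=track, retained=retained)
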