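import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers.py

from rddbench.calling import pileup
from rddbench.genome import GenomeConfig, generate_genome
from rddbench.rdds import apply_rdds_to_reads, place_rdds, stratify_by_coverage
from rddbench.reads import coverage_track, simulate_reads


@pytest.fixture(scope="session")
def small_model():
    """300 kb genome with transcripts, duplicons, pseudogenes, homopolymers."""
    cfg = GenomeConfig(
        genome_size=300_000, n_chromosomes=2, n_transcripts=30,
        n_duplicons=6, n_pseudogenes=4, n_planted_homopolymers=20,
    )
    return generate_genome(cfg, 11)


@pytest.fixture(scope="session")
def clean_run(small_model):
    """Clean-mode reads with planted RDDs, truth-aligned pileup."""
    rs = simulate_reads(small_model, n_pairs=25_000, mode="clean", seed=21)
    cov = coverage_track(rs)
    strata = stratify_by_coverage(cov, "quartile")
    truth = place_rdds(small_model, strata, cov, 1_500, seed=22)
    truth = apply_rdds_to_reads(rs, truth, seed=23)
    return dict(model=small_model, reads=rs, coverage=cov, strata=strata,
                truth=truth, pileup=pileup(rs))


@pytest.fixture(scope="session")
def realistic_run(small_model):
    """Realistic-mode reads with planted RDDs, truth-aligned pileup."""
    rs = simulate_reads(small_model, n_pairs=30_000, mode="realistic", seed=31)
    cov = coverage_track(rs)
    strata = stratify_by_coverage(cov, "quartile")
    truth = place_rdds(small_model, strata, cov, 2_000, seed=32)
    truth = apply_rdds_to_reads(rs, truth, seed=33)
    return dict(model=small_model, reads=rs, coverage=cov, strata=strata,
                truth=truth, pileup=pileup(rs))


@pytest.fixture(scope="session")
def plain_realistic_reads(small_model):
    """Realistic-mode reads with no RDDs planted (for error-rate work)."""
    rs = simulate_reads(small_model, n_pairs=15_000, mode="realistic", seed=41)
    return dict(model=small_model, reads=rs, pileup=pileup(rs))
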