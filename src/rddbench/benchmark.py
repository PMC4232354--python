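"""End-to-end benchmark orchestration.

Wires the pipeline together: genome generation, read simulation, coverage
stratification, RDD planting, optional misalignment injection at planted
duplicons, pileup, calling and scoring — all from one seed. This is the
entry point the acceptance analyses and the CLI `benchmark` command use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import inject_misalignment
from .calling import PileupCounts, Thresholds, call_rdds, pileup
from .evaluate import EvalReport, score_calls
from .genome import GenomeConfig, GenomeModel, generate_genome
from .rdds import ClusterConfig, CoverageStrata, apply_rdds_to_reads, place_rdds, stratify_by_coverage
from .reads import ErrorModel, ReadSet, coverage_track, simulate_reads, simulator_stats


@dataclass
class BenchmarkConfig:
    genome: GenomeConfig = field(default_factory=GenomeConfig)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    n_pairs: int = 100_000
    n_rdds: int = 5_000
    mode: str = "realistic"
    stratify_mode: str = "quartile"
    p_move: float = 0.0  # misalignment injection probability at duplicons
    thresholds: Thresholds = field(default_factory=Thresholds)
    truth_min_coverage: int = 20
    truth_min_level: float = 0.20


@dataclass
class BenchmarkResult:
    config: BenchmarkConfig
    model: GenomeModel
    reads: ReadSet
    coverage: dict[str, np.ndarray]
    strata: CoverageStrata
    truth: pd.DataFrame
    pileup: PileupCounts
    calls: pd.DataFrame
    report: EvalReport
    sim_stats: dict[str, float]


def run_benchmark(cfg: BenchmarkConfig, seed: int) -> BenchmarkResult:
    """Run the full pipeline deterministically from one seed."""
    ss = np.random.SeedSequence(int(seed))
    sub = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]

    model = generate_genome(cfg.genome, sub[0])
    reads = simulate_reads(model, cfg.error_model, cfg.n_pairs,
                           mode=cfg.mode, seed=sub[1])
    sim_stats = simulator_stats(reads, model)
    cov = coverage_track(reads)
    strata = stratify_by_coverage(cov, cfg.stratify_mode)
    truth = place_rdds(model, strata, cov, cfg.n_rdds, cfg.cluster, seed=sub[2])
    truth = apply_rdds_to_reads(reads, truth, seed=sub[3])
    if cfg.p_move > 0:
        inject_misalignment(reads, model, cfg.p_move, seed=sub[4])
    pc = pileup(reads)
    calls = call_rdds(pc, model, cfg.thresholds)
    report = score_calls(
        calls, truth,
        truth_min_coverage=cfg.truth_min_coverage,
        truth_min_level=cfg.truth_min_level,
        coverage=cov,
        strata_columns=("bin",),
    )
    return BenchmarkResult(cfg, model, reads, cov, strata, truth, pc, calls,
                           report, sim_stats)


def desk_scale_config(**overrides) -> BenchmarkConfig:
    """The package's standard scaled-down benchmark: ~2 Mb genome, ~400k
    realistic-mode read pairs, ~20k planted RDDs."""
    genome = GenomeConfig(
        genome_size=2_000_000,
        n_chromosomes=2,
        n_transcripts=250,
        n_duplicons=20,
        n_pseudogenes=10,
        n_planted_homopolymers=50,
    )
    cfg = BenchmarkConfig(genome=genome, n_pairs=400_000, n_rdds=20_000)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg
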