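"""Nonrandom sequencing-error machinery.

Per-site error levels (mismatching reads / coverage) against a known
template, an overall error rate, a Kolmogorov-Smirnov test of the observed
level distribution against a binomial null simulated from that rate, and
the frequency of high-level errors reproducible across datasets.

The null is built by drawing, for each observed site's coverage c_i, an
error count from Binomial(c_i, overall rate) and converting to a level; the
test is the two-sample KS test of observed vs simulated levels. Both
distributions are discrete, which makes the test conservative at small
coverage; the analytic binomial-mixture CDF backend avoids the simulation
but shares the discreteness caveat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _seq
from .calling import PileupCounts
from .genome import GenomeModel


@dataclass
class ErrorLevelProfile:
    sites: pd.DataFrame  # chrom, pos, coverage, errors, level
    overall_rate: float  # total errors / total bases at qualifying sites
    min_coverage: int

    def __len__(self) -> int:
        return len(self.sites)


def error_profile(pc: PileupCounts, model: GenomeModel,
                  min_coverage: int = 1) -> ErrorLevelProfile:
    """Per-site sequencing-error levels against the template genome.

    Every read base differing from the template at a site with coverage >=
    min_coverage counts as an error.
    """
    rows = []
    for chrom, arr in pc.counts.items():
        ref = model.chromosomes[chrom]
        cov = arr.sum(axis=0)
        ref_count = arr[ref, np.arange(arr.shape[1])]
        errors = cov - ref_count
        pos = np.flatnonzero(cov >= max(min_coverage, 1))
        rows.append(pd.DataFrame({
            "chrom": chrom, "pos": pos,
            "coverage": cov[pos], "errors": errors[pos],
            "level": errors[pos] / cov[pos],
        }))
    sites = (pd.concat(rows, ignore_index=True) if rows
             else pd.DataFrame(columns=["chrom", "pos", "coverage", "errors", "level"]))
    if len(sites) == 0:
        warnings.warn("no sites meet the coverage cutoff; empty profile")
        overall = 0.0
    else:
        overall = float(sites["errors"].sum() / sites["coverage"].sum())
    return ErrorLevelProfile(sites=sites, overall_rate=overall,
                             min_coverage=min_coverage)


def _ks_two_sample_stat(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample KS statistic, tie-safe."""
    grid = np.sort(np.concatenate([a, b]))
    fa = np.searchsorted(np.sort(a), grid, side="right") / a.size
    fb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.abs(fa - fb).max())


def _mixture_cdf(levels: np.ndarray, cov: np.ndarray, rate: float) -> np.ndarray:
    """CDF of the binomial-mixture null (coverages as in the profile)."""
    out = np.zeros_like(levels, dtype=float)
    for c, n_c in zip(*np.unique(cov, return_counts=True)):
        out += n_c * stats.binom.cdf(np.floor(levels * c + 1e-9), c, rate)
    return out / cov.size


def ks_nonrandom_test(profile: ErrorLevelProfile, n_null_draws: int = 1,
                      seed: int = 0, backend: str = "simulation",
                      n_bootstrap: int = 0) -> tuple[float, float]:
    """KS test of observed error levels against the random-error null.

    backend="simulation" (default): two-sample statistic against binomial
    draws conditioned on the observed coverages, with the asymptotic
    two-sample p-value. Because the null rate is the plug-in estimate from
    the same data and the levels are discrete, that p-value is conservative;
    pass n_bootstrap > 0 for a parametric-bootstrap p-value that is
    calibrated to nominal level.

    backend="analytic": statistic of the observed levels against the exact
    binomial-mixture CDF (discrete-safe sup over the pooled support), with
    the conservative Kolmogorov asymptotic p-value.
    """
    if len(profile) == 0:
        raise ValueError("empty profile")
    obs = profile.sites["level"].to_numpy()
    cov = profile.sites["coverage"].to_numpy()
    rate = profile.overall_rate
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE5]))
    cov_sorted = np.sort(cov)  # canonical order: site order must not matter

    if backend == "simulation":
        if n_null_draws < 1:
            raise ValueError("n_null_draws must be >= 1")
        cc = np.tile(cov_sorted, n_null_draws)
        null = rng.binomial(cc, rate) / cc
        stat = _ks_two_sample_stat(obs, null)
        if n_bootstrap > 0:
            exceed = 0
            for _ in range(n_bootstrap):
                sim = rng.binomial(cov_sorted, rate)
                sim_rate = sim.sum() / cov_sorted.sum()
                sim_obs = sim / cov_sorted
                sim_null = rng.binomial(cc, sim_rate) / cc
                if _ks_two_sample_stat(sim_obs, sim_null) >= stat:
                    exceed += 1
            p = (1 + exceed) / (n_bootstrap + 1)
        else:
            n, m = obs.size, cc.size
            en = n * m / (n + m)
            p = float(stats.kstwobign.sf(np.sqrt(en) * stat))
    elif backend == "analytic":
        # sup over the pooled support of both the empirical and null CDFs
        support = np.unique(np.concatenate(
            [obs] + [np.arange(c + 1) / c for c in np.unique(cov)]
        ))
        emp = np.searchsorted(np.sort(obs), support, side="right") / obs.size
        null_cdf = _mixture_cdf(support, cov, rate)
        stat = float(np.abs(emp - null_cdf).max())
        p = float(stats.kstwobign.sf(np.sqrt(obs.size) * stat))
    else:
        raise ValueError(f"unknown backend {backend!r}")
    return stat, min(float(p), 1.0)


def reproducible_high_level_errors(profiles: list[ErrorLevelProfile],
                                   level_min: float = 0.20) -> float | None:
    """Fraction of shared sites whose error level is >= level_min in every
    profile; None (with a warning) when the profiles share no sites."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    merged = profiles[0].sites[["chrom", "pos", "level"]].rename(
        columns={"level": "level_0"})
    for i, p in enumerate(profiles[1:], start=1):
        merged = merged.merge(
            p.sites[["chrom", "pos", "level"]].rename(columns={"level": f"level_{i}"}),
            on=["chrom", "pos"], how="inner",
        )
    if len(merged) == 0:
        warnings.warn("profiles share no sites; frequency undefined")
        return None
    level_cols = [c for c in merged.columns if c.startswith("level_")]
    qualifying = (merged[level_cols] >= level_min).all(axis=1)
    return float(qualifying.mean())
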