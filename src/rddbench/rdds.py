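"""Planting RNA-DNA sequence differences (RDDs) into simulated reads.

Sites are chosen after stratifying covered positions by sequencing depth so
every coverage group receives approximately the same number of RDDs. Each
site gets a uniformly drawn level f in (0, 1] and an alt base uniform over
the three non-reference bases; the realised alt-read count is
k = round(f*c) clamped to [1, c]. A configurable fraction of sites (5% by
default) seed hyperediting clusters: within 100 bp of the seed, positions
sharing the seed's reference base and coverage group become same-type RDDs
with probability 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seq
from .genome import GenomeModel
from .reads import ReadSet, iter_aligned_bases

TRUTH_COLUMNS = ["chrom", "pos", "ref", "alt", "level", "k", "coverage", "bin", "cluster_id"]


@dataclass
class ClusterConfig:
    seed_fraction: float = 0.05  # fraction of RDDs seeding hyperediting clusters
    window: int = 100  # recruit positions within this many bp of the seed
    same_type_prob: float = 0.5


@dataclass
class CoverageStrata:
    mode: str  # "quartile" | "low_tertile"
    boundaries: np.ndarray  # upper-inclusive boundaries of bins 0..n-2
    bins: dict[str, np.ndarray]  # per-chrom int8 bin index, -1 where uncovered
    n_bins: int

    def bin_of(self, chrom: str, pos: int) -> int:
        return int(self.bins[chrom][pos])


def stratify_by_coverage(coverage: dict[str, np.ndarray],
                         mode: str = "quartile", low_cutoff: int = 10) -> CoverageStrata:
    """Partition covered sites into coverage groups.

    quartile: four equal-count bins (ties go to the lower bin).
    low_tertile: one bin for coverage <= low_cutoff, the rest in tertiles.
    """
    chroms = list(coverage)
    concat = np.concatenate([coverage[c] for c in chroms])
    covered = concat[concat > 0]
    if covered.size == 0:
        raise ValueError("coverage track has no covered sites")

    def _equal_count_bounds(values: np.ndarray, n_bins: int) -> np.ndarray:
        srt = np.sort(values)
        ranks = [srt.size * k // n_bins - 1 for k in range(1, n_bins)]
        bounds = np.unique(srt[[max(r, 0) for r in ranks]]).astype(np.int64)
        return bounds[bounds < srt[-1]]  # a bound at the max would empty the top bin

    if mode == "quartile":
        bounds = _equal_count_bounds(covered, 4)
    elif mode == "low_tertile":
        rest = covered[covered > low_cutoff]
        if rest.size == 0:
            bounds = np.array([], dtype=np.int64)
        else:
            bounds = np.concatenate(
                ([low_cutoff], _equal_count_bounds(rest, 3))
            )
            bounds = np.unique(bounds)
    else:
        raise ValueError(f"unknown stratification mode {mode!r}")
    if bounds.size == 0:
        warnings.warn("all covered sites share one coverage value; single bin")

    bins: dict[str, np.ndarray] = {}
    for c in chroms:
        cov = coverage[c]
        b = np.searchsorted(bounds, cov, side="left").astype(np.int8)
        b[cov == 0] = -1
        bins[c] = b
    return CoverageStrata(mode=mode, boundaries=bounds, bins=bins,
                          n_bins=int(bounds.size) + 1)


def place_rdds(model: GenomeModel, strata: CoverageStrata,
               coverage: dict[str, np.ndarray], n_rdds: int,
               cluster_config: ClusterConfig | None = None,
               seed: int = 0) -> pd.DataFrame:
    """Draw the truth table of RDD sites.

    Independent sites are split evenly (within +-1) across coverage bins;
    cluster recruits are added afterwards. Cluster ordering in the table is
    the processing order, so eligibility can be replayed exactly.
    """
    cc = cluster_config or ClusterConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xEDD5]))
    chroms = list(coverage)
    lengths = np.array([coverage[c].size for c in chroms])
    offsets = np.concatenate(([0], np.cumsum(lengths)))[:-1]
    cov_all = np.concatenate([coverage[c] for c in chroms])
    bin_all = np.concatenate([strata.bins[c] for c in chroms])
    genome_all = np.concatenate([model.chromosomes[c] for c in chroms])

    n_bins = strata.n_bins
    per_bin = np.full(n_bins, n_rdds // n_bins, dtype=np.int64)
    per_bin[: n_rdds % n_bins] += 1
    chosen: list[np.ndarray] = []
    for b in range(n_bins):
        pool = np.flatnonzero(bin_all == b)
        want = int(per_bin[b])
        if pool.size < want:
            warnings.warn(f"coverage bin {b} holds only {pool.size} sites; filled to capacity")
            want = pool.size
        chosen.append(rng.choice(pool, size=want, replace=False))
    sites = np.concatenate(chosen)
    occupied = set(sites.tolist())

    n = sites.size
    ref = genome_all[sites]
    alt = (ref + rng.integers(1, 4, size=n).astype(np.uint8)) % 4
    f = 1.0 - rng.random(n)  # uniform on (0, 1]
    rows = {
        "gidx": sites,
        "ref": ref,
        "alt": alt,
        "level": f,
        "cluster_id": np.full(n, -1, dtype=np.int64),
        "is_seed": np.zeros(n, dtype=bool),
    }
    df_parts = [pd.DataFrame(rows)]

    # hyperediting clusters: seeds are a random subset of the placed sites
    n_seeds = int(round(cc.seed_fraction * n))
    seed_rows = rng.choice(n, size=n_seeds, replace=False) if n_seeds else np.array([], int)
    df_parts[0].loc[seed_rows, "cluster_id"] = np.arange(n_seeds)
    df_parts[0].loc[seed_rows, "is_seed"] = True
    rec_rows = {k: [] for k in ("gidx", "ref", "alt", "level", "cluster_id")}
    for cid, sr in enumerate(seed_rows):
        g = int(sites[sr])
        ci = int(np.searchsorted(offsets, g, side="right") - 1)
        lo = max(g - cc.window, int(offsets[ci]))
        hi = min(g + cc.window + 1, int(offsets[ci] + lengths[ci]))
        window = np.arange(lo, hi)
        eligible = window[
            (genome_all[window] == ref[sr])
            & (bin_all[window] == bin_all[g])
        ]
        for p in eligible:
            p = int(p)
            if p in occupied:
                continue
            if rng.random() < cc.same_type_prob:
                occupied.add(p)
                rec_rows["gidx"].append(p)
                rec_rows["ref"].append(int(ref[sr]))
                rec_rows["alt"].append(int(alt[sr]))
                rec_rows["level"].append(1.0 - rng.random())
                rec_rows["cluster_id"].append(cid)
    if rec_rows["gidx"]:
        rec = pd.DataFrame(rec_rows)
        rec["is_seed"] = False
        df_parts.append(rec)

    df = pd.concat(df_parts, ignore_index=True)
    gidx = df["gidx"].to_numpy()
    ci = np.searchsorted(offsets, gidx, side="right") - 1
    df["chrom"] = np.asarray(chroms, dtype=object)[ci]
    df["pos"] = gidx - offsets[ci]
    df["coverage"] = cov_all[gidx]
    df["bin"] = bin_all[gidx]
    df["k"] = np.clip(np.rint(df["level"] * df["coverage"]).astype(np.int64),
                      1, df["coverage"])
    df["ref"] = df["ref"].map(lambda c: _seq.BASES[c])
    df["alt"] = df["alt"].map(lambda c: _seq.BASES[c])
    df = df[TRUTH_COLUMNS + ["is_seed"]].sort_values(
        ["chrom", "pos"], kind="stable", ignore_index=True
    )
    df["realized_level"] = df["k"] / df["coverage"]
    return df


def apply_rdds_to_reads(rs: ReadSet, truth: pd.DataFrame, seed: int = 0) -> pd.DataFrame:
    """Flip exactly k spanning reads to the alt base at each truth site.

    Reads are chosen uniformly without replacement among mates whose aligned
    bases span the site. Sequences are modified in place (genome-forward
    orientation, so the FASTQ output shows the complement on reverse-strand
    mates). Returns the truth table, with k/coverage corrected downward in
    the (logged) case where fewer than k spanning reads exist.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA1D5]))
    off = rs.chrom_offsets
    chrom_of = {c: i for i, c in enumerate(rs.chrom_names)}
    gidx_site = (
        off[[chrom_of[c] for c in truth["chrom"]]] + truth["pos"].to_numpy()
    )
    total = int(rs.chrom_lengths.sum())
    site_of = np.full(total, -1, dtype=np.int64)
    site_of[gidx_site] = np.arange(gidx_site.size)

    hit_site: list[np.ndarray] = []
    hit_row: list[np.ndarray] = []
    hit_col: list[np.ndarray] = []
    for rows, cols, gpos in iter_aligned_bases(rs):
        s = site_of[gpos]
        m = s >= 0
        hit_site.append(s[m])
        hit_row.append(rows[m])
        hit_col.append(cols[m])
    sites = np.concatenate(hit_site)
    rows = np.concatenate(hit_row)
    cols = np.concatenate(hit_col)
    order = np.argsort(sites, kind="stable")
    sites, rows, cols = sites[order], rows[order], cols[order]
    starts = np.searchsorted(sites, np.arange(gidx_site.size))
    ends = np.searchsorted(sites, np.arange(gidx_site.size) + 1)

    alt_codes = np.array([_seq.BASES.index(b) for b in truth["alt"]], dtype=np.uint8)
    k_arr = truth["k"].to_numpy().copy()
    cov_arr = truth["coverage"].to_numpy().copy()
    short = 0
    for si in range(gidx_site.size):
        a, b = starts[si], ends[si]
        avail = b - a
        k = int(k_arr[si])
        if avail < k:
            short += 1
            k = avail
            k_arr[si] = k
            cov_arr[si] = avail
        if k == 0:
            continue
        pick = a + rng.permutation(avail)[:k]
        rs.seqs[rows[pick], cols[pick]] = alt_codes[si]
    if short:
        warnings.warn(f"{short} truth sites had fewer spanning reads than k; k reduced")
    truth = truth.copy()
    truth["k"] = k_arr
    truth["coverage"] = cov_arr
    truth["realized_level"] = np.where(cov_arr > 0, k_arr / np.maximum(cov_arr, 1), 0.0)
    return truth


def neighbor_distance_stats(truth: pd.DataFrame) -> pd.DataFrame:
    """Nearest-neighbour distances between RDD sites, split by cluster
    membership; distances are computed against all sites on the chromosome."""
    if len(truth) < 2:
        raise ValueError("need at least two sites")
    dists = np.full(len(truth), np.nan)
    for chrom, grp in truth.groupby("chrom"):
        pos = np.sort(grp["pos"].to_numpy())
        if pos.size < 2:
            continue
        gaps = np.diff(pos)
        nn = np.minimum(np.concatenate((gaps, [np.inf])),
                        np.concatenate(([np.inf], gaps)))
        order = np.argsort(grp["pos"].to_numpy(), kind="stable")
        idx = grp.index.to_numpy()[order]
        dists[truth.index.get_indexer(idx)] = nn
    truth = truth.assign(nn_distance=dists)
    truth["clustered"] = truth["cluster_id"] >= 0
    out = (
        truth.dropna(subset=["nn_distance"])
        .groupby("clustered")["nn_distance"]
        .agg(["count", "mean", "median"])
        .reset_index()
    )
    return out


def write_truth_table(truth: pd.DataFrame, path: str) -> None:
    out = truth.copy()
    out["pos"] = out["pos"] + 1  # 1-based in the TSV
    out.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"] - 1
    return df


def write_truth_vcf(truth: pd.DataFrame, model: GenomeModel, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in model.chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write('##INFO=<ID=LEVEL,Number=1,Type=Float,Description="Simulated RDD level">\n')
        fh.write('##INFO=<ID=K,Number=1,Type=Integer,Description="Assigned alt-read count">\n')
        fh.write('##INFO=<ID=CLUSTER,Number=1,Type=Integer,Description="Cluster id, -1 if none">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in truth.itertuples():
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t.\t{row.ref}\t{row.alt}\t.\t.\t"
                f"LEVEL={row.level:.6f};K={row.k};CLUSTER={row.cluster_id}\n"
            )
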