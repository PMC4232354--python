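"""RDD planting: stratification, level realisation, clusters, exactness."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rddbench.calling import pileup
from rddbench.evaluate import cluster_recruitment_stats
from rddbench.genome import GenomeConfig, generate_genome
from rddbench.rdds import (ClusterConfig, apply_rdds_to_reads,
                           neighbor_distance_stats, place_rdds,
                           read_truth_table, stratify_by_coverage,
                           write_truth_table)
from rddbench.reads import simulate_reads


def test_quartile_stratification_boundaries():
    cov = {"c": np.arange(0, 101)}  # coverage values 0..100; 0 is uncovered
    st = stratify_by_coverage(cov, "quartile")
    assert list(st.boundaries) == [25, 50, 75]
    bins = st.bins["c"]
    assert bins[0] == -1  # uncovered
    assert bins[25] == 0 and bins[26] == 1  # ties go to the lower bin
    assert bins[50] == 1 and bins[75] == 2 and bins[100] == 3
    counts = [int((bins == b).sum()) for b in range(4)]
    assert counts == [25, 25, 25, 25]


def test_low_tertile_stratification():
    cov = {"c": np.arange(1, 101)}
    st = stratify_by_coverage(cov, "low_tertile")
    bins = st.bins["c"]
    assert set(np.flatnonzero(bins == 0) + 1) == set(range(1, 11))
    counts = [int((bins == b).sum()) for b in range(st.n_bins)]
    assert counts == [10, 30, 30, 30]


def test_stratification_is_order_invariant():
    rng = np.random.default_rng(4)
    vals = rng.integers(1, 200, size=500)
    st1 = stratify_by_coverage({"c": vals}, "quartile")
    perm = rng.permutation(500)
    st2 = stratify_by_coverage({"c": vals[perm]}, "quartile")
    assert np.array_equal(st1.bins["c"][perm], st2.bins["c"])


def test_degenerate_uniform_coverage_warns():
    with pytest.warns(UserWarning, match="single bin"):
        st = stratify_by_coverage({"c": np.full(50, 7)}, "quartile")
    assert st.n_bins == 1


def _synthetic_placement(n_rdds=4000, coverage_value=None, seed=5,
                         cluster=ClusterConfig(seed_fraction=0.0)):
    cfg = GenomeConfig(genome_size=200_000, n_chromosomes=1, n_transcripts=10,
                       n_duplicons=0, n_pseudogenes=0)
    model = generate_genome(cfg, 8)
    rng = np.random.default_rng(9)
    if coverage_value is None:
        cov = {"chr1": rng.integers(0, 300, size=200_000).astype(np.int32)}
    else:
        cov = {"chr1": np.full(200_000, coverage_value, dtype=np.int32)}
    strata = stratify_by_coverage(cov, "quartile")
    truth = place_rdds(model, strata, cov, n_rdds, cluster, seed=seed)
    return model, cov, strata, truth


def test_k_realisation_rule_and_bounds():
    model, cov, strata, truth = _synthetic_placement()
    k = truth["k"].to_numpy()
    c = truth["coverage"].to_numpy()
    f = truth["level"].to_numpy()
    assert np.array_equal(k, np.clip(np.rint(f * c), 1, c).astype(int))
    assert np.all((k >= 1) & (k <= c))
    assert np.all((f > 0) & (f <= 1))
    assert np.all(truth["ref"] != truth["alt"])
    # f=0.5, c even -> k = c/2; f small -> clamped to 1
    even = (np.abs(f - 0.5) < 1e-12)  # no exact draw expected; test the rule directly
    assert np.all(truth["realized_level"] > 0)


def test_per_bin_counts_equal_within_one():
    _, _, _, truth = _synthetic_placement(n_rdds=4001)
    counts = truth[truth["cluster_id"].lt(0) | truth["is_seed"]].groupby("bin").size()
    assert counts.max() - counts.min() <= 1


def test_realized_levels_uniform_at_high_coverage():
    # coverage 150 everywhere: k/c discretisation is fine enough for a KS
    # test of uniformity on (0, 1] to pass at alpha = 0.01
    _, _, _, truth = _synthetic_placement(n_rdds=10_000, coverage_value=150)
    stat, p = stats.kstest(truth["realized_level"], "uniform")
    assert p > 0.01


def test_realized_levels_discrete_at_low_coverage():
    _, _, _, truth = _synthetic_placement(n_rdds=3000, coverage_value=5)
    support = set(np.round(truth["realized_level"], 10))
    assert support <= {round(k / 5, 10) for k in range(1, 6)}


def test_cluster_recruits_share_type_and_window(realistic_run):
    truth = realistic_run["truth"]
    seeds = truth[truth["is_seed"]].set_index("cluster_id")
    recruits = truth[(truth["cluster_id"] >= 0) & ~truth["is_seed"]]
    assert len(recruits) > 0
    for r in recruits.itertuples():
        s = seeds.loc[r.cluster_id]
        assert r.chrom == s["chrom"]
        assert abs(r.pos - s["pos"]) <= 100
        assert r.ref == s["ref"] and r.alt == s["alt"]
        assert r.bin == s["bin"]


def test_cluster_same_type_fraction_near_half():
    model, cov, strata, truth = _synthetic_placement(
        n_rdds=8000, seed=6, cluster=ClusterConfig(seed_fraction=0.05))
    cs = cluster_recruitment_stats(truth, strata, model)
    assert cs["n_clusters"] >= 200
    sd = np.sqrt(0.25 / cs["n_eligible"])
    assert abs(cs["same_type_fraction"] - 0.5) <= 3 * sd


def test_pileup_alt_counts_equal_k_in_clean_mode(clean_run):
    pc, truth, model = clean_run["pileup"], clean_run["truth"], clean_run["model"]
    for r in truth.itertuples():
        sc = pc.site(model, r.chrom, r.pos)
        assert sc.counts[r.alt] == r.k
        assert sc.coverage == r.coverage


def test_apply_rdds_is_deterministic(small_model):
    out = []
    for _ in range(2):
        rs = simulate_reads(small_model, n_pairs=4_000, mode="clean", seed=51)
        from rddbench.reads import coverage_track

        cov = coverage_track(rs)
        strata = stratify_by_coverage(cov, "quartile")
        truth = place_rdds(small_model, strata, cov, 400, seed=52)
        apply_rdds_to_reads(rs, truth, seed=53)
        out.append(rs.seqs.copy())
    assert np.array_equal(out[0], out[1])


def test_neighbor_distance_examples():
    truth = pd.DataFrame({
        "chrom": ["c"] * 3, "pos": [10, 13, 100],
        "cluster_id": [-1, -1, -1],
    })
    out = neighbor_distance_stats(truth)
    row = out[out["clustered"] == False].iloc[0]
    assert row["count"] == 3
    assert row["median"] == 3.0
    assert row["mean"] == pytest.approx((3 + 3 + 87) / 3)
    # unsorted input gives the same answer
    shuffled = truth.sample(frac=1, random_state=1).reset_index(drop=True)
    out2 = neighbor_distance_stats(shuffled)
    assert out2.equals(out)


def test_clustered_sites_are_closer_than_background(realistic_run):
    out = neighbor_distance_stats(realistic_run["truth"]).set_index("clustered")
    assert out.loc[True, "median"] < out.loc[False, "median"]


def test_truth_table_round_trip(tmp_path, clean_run):
    path = tmp_path / "truth.tsv"
    write_truth_table(clean_run["truth"], str(path))
    again = read_truth_table(str(path))
    assert np.array_equal(again["pos"], clean_run["truth"]["pos"])
    # written file is 1-based
    first = path.read_text().splitlines()[1].split("\t")
    assert int(first[1]) == clean_run["truth"]["pos"].iloc[0] + 1
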