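"""Pileup and caller: examples, oracle equivalence, monotonicity, exclusion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_force_calls, make_readset
from rddbench._seq import BASES
from rddbench.calling import (PileupCounts, Thresholds, call_rdds,
                              intersect_replicates, load_known_variants,
                              pileup, pileup_sam, write_calls, read_calls)
from rddbench.genome import GenomeConfig, GenomeModel, generate_genome
from rddbench.reads import write_truth_sam


def _tiny_model(seq_len=60, seed=3):
    cfg = GenomeConfig(genome_size=seq_len * 2, n_chromosomes=2, n_transcripts=1,
                       n_duplicons=0, n_pseudogenes=0, n_planted_homopolymers=0,
                       exons_per_transcript=(1, 1), exon_length=(20, 20))
    # hand-build a deterministic model instead of the generator
    rng = np.random.default_rng(seed)
    chroms = {"chr1": rng.integers(4, size=seq_len).astype(np.uint8),
              "chr2": rng.integers(4, size=seq_len).astype(np.uint8)}
    from rddbench.genome import Transcript

    return GenomeModel(chromosomes=chroms,
                       transcripts=[Transcript("t0", "chr1", "+", [(0, 20)])])


def _counts_fixture(model, rng):
    counts = {}
    for c, codes in model.chromosomes.items():
        n = codes.size
        arr = np.zeros((4, n), dtype=np.int32)
        cov = rng.integers(0, 40, size=n)
        for pos in range(n):
            if cov[pos] == 0:
                continue
            probs = np.full(4, 0.05)
            probs[codes[pos]] = 0.85
            arr[:, pos] = rng.multinomial(cov[pos], probs)
        counts[c] = arr
    return PileupCounts(counts)


def test_threshold_validation():
    with pytest.raises(ValueError):
        Thresholds(min_level=1.5)
    with pytest.raises(ValueError):
        Thresholds(min_coverage=-1)


def test_boundary_thresholds_inclusive():
    model = _tiny_model()
    arr = np.zeros((4, 60), dtype=np.int32)
    ref = model.chromosomes["chr1"]
    alt0 = (ref[10] + 1) % 4
    arr[ref[10], 10] = 16
    arr[alt0, 10] = 4  # c=20, k=4, level exactly 0.20
    alt1 = (ref[11] + 1) % 4
    arr[ref[11], 11] = 15
    arr[alt1, 11] = 4  # c=19: below min coverage
    pc = PileupCounts({"chr1": arr, "chr2": np.zeros((4, 60), np.int32)})
    calls = call_rdds(pc, model, Thresholds(20, 0.20, 4))
    assert list(zip(calls["chrom"], calls["pos"], calls["alt"])) == [
        ("chr1", 10, BASES[alt0])
    ]


def test_caller_matches_brute_force_enumeration_on_random_fixtures():
    model = _tiny_model()
    rng = np.random.default_rng(12)
    for trial in range(30):
        pc = _counts_fixture(model, rng)
        th = Thresholds(int(rng.integers(0, 25)),
                        float(rng.choice([0.0, 0.1, 0.2, 0.5])),
                        int(rng.integers(0, 6)))
        got = set(zip(*(call_rdds(pc, model, th)[k] for k in ("chrom", "pos", "alt"))))
        want = brute_force_calls(pc, model.chromosomes, th)
        assert got == want, (trial, th)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    cov=st.integers(1, 60),
    frac=st.floats(0.0, 1.0),
    cmin=st.integers(0, 40),
    fmin=st.floats(0.0, 1.0),
    kmin=st.integers(0, 10),
)
def test_tightening_thresholds_never_adds_calls(cov, frac, cmin, fmin, kmin):
    model = _tiny_model()
    rng = np.random.default_rng(cov * 1000 + kmin)
    pc = _counts_fixture(model, rng)
    loose = call_rdds(pc, model, Thresholds(cmin, fmin, kmin))
    for tighter in (
        Thresholds(min(cmin + 5, 100), fmin, kmin),
        Thresholds(cmin, min(fmin + 0.1, 1.0), kmin),
        Thresholds(cmin, fmin, kmin + 2),
    ):
        tight = call_rdds(pc, model, tighter)
        loose_keys = set(zip(loose["chrom"], loose["pos"], loose["alt"]))
        tight_keys = set(zip(tight["chrom"], tight["pos"], tight["alt"]))
        assert tight_keys <= loose_keys


def test_pileup_examples_and_clipping():
    model = _tiny_model()
    ref_str = "".join(BASES[c] for c in model.chromosomes["chr1"])
    # 4 mates matching the reference at [0, 100)? chrom len is 60; use segments of 30
    mates = []
    seq30 = ref_str[:30]
    for _ in range(2):
        mates.append({"seq": seq30 + "A" * 70, "chrom": "chr1",
                      "segments": [(0, 0, 30)]})  # final 70 bases soft-clipped
    mates.append({"seq": "G" * 100, "chrom": "chr1", "segments": [(40, 0, 10)]})
    mates.append({"seq": "G" * 100, "chrom": "chr1", "segments": [(40, 0, 10)]})
    rs = make_readset({"chr1": 60, "chr2": 60}, mates)
    pc = pileup(rs)
    ref = model.chromosomes["chr1"]
    for pos in range(30):
        sc = pc.site(model, "chr1", pos)
        assert sc.coverage == 2 and sc.counts[BASES[ref[pos]]] == 2
    # clipped bases contributed nothing anywhere else in [30, 40)
    assert pc.coverage("chr1")[30:40].sum() == 0
    sc = pc.site(model, "chr1", 45)
    assert sc.coverage == 2 and sc.counts["G"] == 2


def test_pileup_sam_agrees_with_readset_pileup(tmp_path, clean_run):
    rs, model = clean_run["reads"], clean_run["model"]
    sam = tmp_path / "truth.sam"
    write_truth_sam(rs, model, str(sam))
    pc_sam = pileup_sam(str(sam), model.chrom_lengths)
    pc_rs = clean_run["pileup"]
    for c in model.chrom_names:
        assert np.array_equal(pc_sam.counts[c], pc_rs.counts[c]), c


def test_known_variant_exclusion(tmp_path, clean_run):
    model, pc, truth = clean_run["model"], clean_run["pileup"], clean_run["truth"]
    th = Thresholds(5, 0.05, 1)
    baseline = call_rdds(pc, model, th)
    # a synthetic VCF listing a subset of the planted RDDs
    subset = truth.head(50)
    vcf = tmp_path / "known.vcf"
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, ln in model.chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in subset.itertuples():
            fh.write(f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\t.\t.\n")
    known = load_known_variants(str(vcf))
    assert len(known) == 50
    filtered = call_rdds(pc, model, th, known_variants=known)
    excluded_pos = set(zip(subset["chrom"], subset["pos"]))
    assert not any((r.chrom, r.pos) in excluded_pos for r in filtered.itertuples())
    kept = {(r.chrom, r.pos, r.alt) for r in baseline.itertuples()
            if (r.chrom, r.pos) not in excluded_pos}
    assert kept == {(r.chrom, r.pos, r.alt) for r in filtered.itertuples()}


def test_intersect_replicates_examples():
    a = pd.DataFrame({"chrom": ["c", "c"], "pos": [1, 2], "alt": ["G", "T"],
                      "ref": ["A", "A"], "alt_count": [5, 5],
                      "coverage": [10, 10], "level": [0.5, 0.5]})
    assert intersect_replicates([a, a.copy()]).equals(a)
    b = a.copy()
    b["pos"] = [5, 6]
    assert len(intersect_replicates([a, b])) == 0
    c = a.copy()
    c.loc[0, "alt"] = "C"  # same position, different alt: not retained
    out = intersect_replicates([a, c])
    assert list(out["pos"]) == [2]
    with pytest.raises(ValueError):
        intersect_replicates([a])


def test_calls_tsv_round_trip(tmp_path, clean_run):
    calls = call_rdds(clean_run["pileup"], clean_run["model"], Thresholds(5, 0.05, 1))
    path = tmp_path / "calls.tsv"
    write_calls(calls, str(path))
    again = read_calls(str(path))
    assert np.array_equal(again["pos"], calls["pos"])
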