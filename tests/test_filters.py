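"""Homology search and the false-positive filter suite."""

import numpy as np
import pandas as pd
import pytest

from rddbench._seq import BASES, decode, encode, revcomp
from rddbench.filters import (GenomeIndex, apply_filters, concordance_filter,
                              exhaustive_homology_scan, homology_explains,
                              homology_filter, homopolymer_filter,
                              junction_proximity_filter, mismatch_cap,
                              pseudogene_filter, uniqueness_annotation)
from rddbench.genome import GenomeModel, GenomicInterval, Transcript


@pytest.mark.parametrize("length,cap", [(100, 6), (76, 4), (151, 10),
                                        (101, 6), (51, 2), (25, 0)])
def test_mismatch_cap_formula(length, cap):
    assert mismatch_cap(length) == cap


@pytest.fixture(scope="module")
def index(small_model):
    return GenomeIndex(small_model)


def test_unique_flank_hits_only_origin(small_model, index):
    # a flank from ordinary (non-repeat) sequence aligns only to itself
    t = small_model.transcripts[0]
    pos = t.start + 40
    q = small_model.sequence(t.chrom, pos, pos + 101)
    hits = index.search(q, mismatch_cap(101))
    assert len(hits) == 1
    assert (hits[0].chrom, hits[0].start, hits[0].strand) == (t.chrom, pos, "+")


def test_duplicon_flank_hits_both_copies(small_model, index):
    d = small_model.duplicons[0]
    q = small_model.sequence(d.source.chrom, d.source.start, d.source.start + 101)
    hits = index.search(q, mismatch_cap(101))
    starts = {(h.chrom, h.start) for h in hits}
    assert (d.source.chrom, d.source.start) in starts
    assert (d.target.chrom, d.target.start) in starts


def test_seeded_search_equals_exhaustive_scan(small_model, index):
    rng = np.random.default_rng(7)
    queries = []
    for d in small_model.duplicons[:3]:
        queries.append(small_model.sequence(d.source.chrom, d.source.start + 10,
                                            d.source.start + 10 + 51))
    for _ in range(3):
        c = rng.choice(small_model.chrom_names)
        p = int(rng.integers(0, small_model.chrom_lengths[c] - 151))
        queries.append(small_model.sequence(c, p, p + 151))
    queries.append(revcomp(queries[-1]))  # reverse-strand query
    for q in queries:
        cap = mismatch_cap(q.size)
        got = {(h.chrom, h.start, h.strand, h.mismatches)
               for h in index.search(q, cap)}
        want = {(h.chrom, h.start, h.strand, h.mismatches)
                for h in exhaustive_homology_scan(small_model, q, cap)}
        assert got == want


def test_search_rejects_bad_queries(index):
    with pytest.raises(ValueError, match="non-ACGT"):
        index.search("ACGTN" * 11, 2)
    with pytest.raises(ValueError, match="shorter"):
        index.search("ACGT", 0)


def test_uniqueness_annotation(small_model, index):
    d = small_model.duplicons[0]
    inside = d.target.start + len(d.target) // 2
    assert uniqueness_annotation(index, d.target.chrom, inside) is False
    src_mid = d.source.start + len(d.source) // 2
    assert uniqueness_annotation(index, d.source.chrom, src_mid) is False
    # ordinary intergenic sequence is unique at this genome size
    t = small_model.transcripts[1]
    assert uniqueness_annotation(index, t.chrom, t.start + 60) is True


def _explainable_site(model):
    """A duplicon divergence where the copy's base differs from the source's:
    calling the copy base at the source site is 'explained' by the copy."""
    for d in model.duplicons:
        src = model.sequence(d.source.chrom, d.source.start, d.source.end)
        tgt = model.sequence(d.target.chrom, d.target.start, d.target.end)
        for off in d.divergent_offsets:
            off = int(off)
            if not (75 <= off < len(src) - 75):
                continue
            return (d.source.chrom, d.source.start + off,
                    BASES[src[off]], BASES[tgt[off]])
    raise RuntimeError("fixture genome lacks an interior divergent offset")


def test_homology_explains_alt_at_homologous_offset(small_model, index):
    chrom, pos, ref, alt = _explainable_site(small_model)
    assert alt != ref
    # the copy carries `alt` at the homologous offset: call removed
    assert homology_explains(index, chrom, pos, alt) is True
    # an alt carried by neither copy is not explained
    others = [b for b in BASES if b not in (ref, alt)]
    unexplained = [b for b in others
                   if not homology_explains(index, chrom, pos, b)]
    assert unexplained  # at least one other alt passes
    # a call in unique sequence passes regardless of alt
    t = small_model.transcripts[1]
    upos = t.start + 80
    uref = small_model.base(t.chrom, upos)
    for b in BASES:
        if b != uref:
            assert homology_explains(index, t.chrom, upos, b) is False


def _call_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"]).assign(
        alt_count=5, coverage=20, level=0.25)


def test_pseudogene_filter_boundaries():
    pgs = [GenomicInterval("c", 100, 200, "pg")]
    calls = _call_frame([("c", 100, "A", "G"), ("c", 199, "A", "G"),
                         ("c", 99, "A", "G"), ("c", 200, "A", "G")])
    removed = pseudogene_filter(calls, pgs)
    assert list(removed) == [True, True, False, False]
    assert not pseudogene_filter(calls, []).any()


def test_junction_proximity_filter():
    tx = Transcript("t", "c", "+", [(100, 200), (300, 400)])  # intron [200, 300)
    calls = _call_frame([
        ("c", 202, "A", "G"),  # 3 bp into the intron -> removed
        ("c", 206, "A", "G"),  # 7 bp in -> pass
        ("c", 294, "A", "G"),  # 6 bp from the downstream junction -> removed
        ("c", 293, "A", "G"),  # 7 bp -> pass
        ("c", 199, "A", "G"),  # exonic, 1 bp from the junction -> pass
        ("c", 150, "A", "G"),  # exonic -> pass
    ])
    removed = junction_proximity_filter(calls, [tx], window=6)
    assert list(removed) == [True, False, True, False, False, False]


def test_homopolymer_filter():
    seq = encode("ACGTACGGGGGTACGTACGTAAAATACG" + "ACGT" * 100)
    model = GenomeModel(chromosomes={"c": seq}, transcripts=[])
    # run of 5 Gs at [6, 11); run of 4 As at [21, 25) is too short
    calls = _call_frame([
        ("c", 5, "A", "G"),   # adjacent to the G run -> removed
        ("c", 11, "T", "G"),  # adjacent on the right -> removed
        ("c", 8, "G", "A"),   # inside the run -> removed
        ("c", 13, "A", "G"),  # 2 bp away -> pass
        ("c", 20, "T", "A"),  # next to a run of 4 -> pass
        ("c", 50, "A", "G"),  # far away -> pass
    ])
    removed = homopolymer_filter(calls, model, min_run=5, adjacency=1)
    assert list(removed) == [True, True, True, False, False, False]


def test_concordance_filter():
    calls = _call_frame([("c", 1, "A", "G"), ("c", 2, "A", "T")])
    other1 = _call_frame([("c", 1, "A", "G")])
    other2 = _call_frame([("c", 1, "A", "G"), ("c", 2, "A", "C")])  # wrong alt at 2
    removed = concordance_filter(calls, [other1, other2], min_other=1)
    assert list(removed) == [False, True]
    removed2 = concordance_filter(calls, [other1, other2], min_other=2)
    assert list(removed2) == [False, True]
    # vacuous requirement passes everything
    assert not concordance_filter(calls, [other1], min_other=0).any()
    with pytest.raises(ValueError):
        concordance_filter(calls, [other1], min_other=2)


def test_apply_filters_is_intersection_of_survivors():
    calls = _call_frame([("c", i, "A", "G") for i in range(6)])
    f1 = pd.Series([True, False, True, False, False, False], index=calls.index)
    f2 = pd.Series([False, True, True, False, False, False], index=calls.index)
    verdicts = apply_filters(calls, {"a": f1, "b": f2})
    assert list(verdicts["removed"]) == [True, True, True, False, False, False]
    survivors = set(verdicts.loc[~verdicts["removed"], "pos"])
    assert survivors == (set(calls["pos"][~f1]) & set(calls["pos"][~f2]))
    assert verdicts.loc[2, "removing_filters"] == "a,b"
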