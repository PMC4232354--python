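"""Shared test utilities: a manual ReadSet builder and independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd

from rddbench._seq import BASES, encode
from rddbench.calling import PileupCounts, Thresholds
from rddbench.reads import ReadSet


def make_readset(chrom_lengths: dict[str, int], mates: list[dict],
                 read_length: int = 100) -> ReadSet:
    """Build a ReadSet from explicit mate specs.

    Each mate dict: seq (str), chrom (str), segments [(gstart, rstart, len)],
    reverse (bool, default False), degraded (bool, default False).
    Mates 2i, 2i+1 form pairs; supply an even number.
    """
    names = list(chrom_lengths)
    n = len(mates)
    assert n % 2 == 0, "supply an even number of mates"
    L = read_length
    seqs = np.zeros((n, L), dtype=np.uint8)
    chrom_id = np.zeros(n, dtype=np.int16)
    is_reverse = np.zeros(n, dtype=bool)
    degraded = np.zeros(n, dtype=bool)
    seg_counts, seg_g, seg_r, seg_len = [], [], [], []
    for i, m in enumerate(mates):
        codes = encode(m["seq"])
        assert codes.size == L
        seqs[i] = codes
        chrom_id[i] = names.index(m["chrom"])
        is_reverse[i] = m.get("reverse", False)
        degraded[i] = m.get("degraded", False)
        segs = m["segments"]
        seg_counts.append(len(segs))
        for g, r, ln in segs:
            seg_g.append(g)
            seg_r.append(r)
            seg_len.append(ln)
    return ReadSet(
        read_length=L,
        chrom_names=names,
        chrom_lengths=np.array([chrom_lengths[c] for c in names]),
        seqs=seqs,
        chrom_id=chrom_id,
        is_reverse=is_reverse,
        degraded=degraded,
        from_premrna=np.zeros(n, dtype=bool),
        seg_index=np.concatenate(([0], np.cumsum(seg_counts))).astype(np.int64),
        seg_g=np.asarray(seg_g, dtype=np.int64),
        seg_r=np.asarray(seg_r, dtype=np.int32),
        seg_len=np.asarray(seg_len, dtype=np.int32),
        err_index=np.zeros(n + 1, dtype=np.int64),
        err_offsets=np.zeros(0, dtype=np.int16),
        frag_len=np.full(n // 2, 2 * L, dtype=np.int32),
    )


def brute_force_calls(pc: PileupCounts, ref_codes: dict[str, np.ndarray],
                      th: Thresholds) -> set[tuple[str, int, str]]:
    """Independent enumeration oracle for the caller: loop over every site
    and base, apply the threshold definitions literally."""
    out = set()
    for chrom, arr in pc.counts.items():
        for pos in range(arr.shape[1]):
            cov = int(arr[:, pos].sum())
            if cov < th.min_coverage or cov == 0:
                continue
            ref = int(ref_codes[chrom][pos])
            for b in range(4):
                if b == ref:
                    continue
                k = int(arr[b, pos])
                if k >= th.min_alt_reads and k >= 1 and k / cov >= th.min_level:
                    out.add((chrom, pos, BASES[b]))
    return out


def brute_force_confusion(calls: pd.DataFrame, truth: pd.DataFrame,
                          min_cov: int, min_level: float,
                          level_col: str = "realized_level") -> tuple[int, int, int]:
    """Independent set-algebra oracle for score_calls: (tp, fp, fn)."""
    truth_all = {(r.chrom, r.pos, r.alt) for r in truth.itertuples()}
    restricted = {
        (r.chrom, r.pos, r.alt)
        for r in truth.itertuples()
        if r.coverage >= min_cov and getattr(r, level_col) >= min_level
    }
    call_keys = {(r.chrom, r.pos, r.alt) for r in calls.itertuples()}
    tp = len(restricted & call_keys)
    fn = len(restricted - call_keys)
    fp = len(call_keys - truth_all)
    return tp, fp, fn
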