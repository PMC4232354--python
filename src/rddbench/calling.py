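"""Pileup construction and threshold-based RDD calling.

A call at a site requires coverage >= Cmin, an alt-base count >= Kmin and an
alt level (alt count / total coverage) >= Fmin; all comparisons inclusive.
Sites present in a known-variant (dbSNP-style) VCF can be excluded before
calling, and call sets from replicates can be intersected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from . import _seq
from .genome import GenomeModel
from .reads import ReadSet, iter_aligned_bases

CALL_COLUMNS = ["chrom", "pos", "ref", "alt", "alt_count", "coverage", "level"]


@dataclass(frozen=True)
class Thresholds:
    min_coverage: int = 20
    min_level: float = 0.20
    min_alt_reads: int = 4

    def __post_init__(self):
        if self.min_coverage < 0 or self.min_alt_reads < 0:
            raise ValueError("thresholds must be non-negative")
        if not 0.0 <= self.min_level <= 1.0:
            raise ValueError(f"min_level={self.min_level} outside [0, 1]")


@dataclass
class SiteCounts:
    chrom: str
    pos: int
    ref: str
    counts: dict[str, int]  # A/C/G/T counts
    deletions: int

    @property
    def coverage(self) -> int:
        return sum(self.counts.values())


class PileupCounts:
    """Per-chromosome (4, chrom_len) base-count matrices plus deletion counts."""

    def __init__(self, counts: dict[str, np.ndarray],
                 deletions: dict[str, np.ndarray] | None = None):
        self.counts = counts
        self.deletions = deletions or {
            c: np.zeros(a.shape[1], dtype=np.int32) for c, a in counts.items()
        }

    @property
    def chrom_names(self) -> list[str]:
        return list(self.counts)

    def coverage(self, chrom: str) -> np.ndarray:
        return self.counts[chrom].sum(axis=0)

    def site(self, model_or_ref, chrom: str, pos: int) -> SiteCounts:
        ref = (model_or_ref.base(chrom, pos)
               if isinstance(model_or_ref, GenomeModel) else model_or_ref)
        col = self.counts[chrom][:, pos]
        return SiteCounts(chrom, pos, ref,
                          {b: int(col[i]) for i, b in enumerate(_seq.BASES)},
                          int(self.deletions[chrom][pos]))


def pileup(rs: ReadSet) -> PileupCounts:
    """Pileup of a ReadSet at its truth placements. Clipped bases contribute
    nothing; both mates are counted independently."""
    lengths = rs.chrom_lengths
    off = rs.chrom_offsets
    total = int(lengths.sum())
    flat = np.zeros(4 * total, dtype=np.int64)
    for rows, cols, gpos in iter_aligned_bases(rs):
        codes = rs.seqs[rows, cols].astype(np.int64)
        flat += np.bincount(codes * total + gpos, minlength=4 * total)
    stacked = flat.reshape(4, total)
    counts = {
        c: stacked[:, off[i] : off[i] + lengths[i]].astype(np.int32)
        for i, c in enumerate(rs.chrom_names)
    }
    # deletion-spanning reads: ref gaps between consecutive M blocks < MIN_INTRON
    from .reads import MIN_INTRON
    deletions = {c: np.zeros(int(l), dtype=np.int32) for c, l in zip(rs.chrom_names, lengths)}
    seg_mate = np.repeat(np.arange(rs.n_mates), np.diff(rs.seg_index))
    g, ln = rs.seg_g, rs.seg_len
    same_mate = seg_mate[1:] == seg_mate[:-1]
    gap = g[1:] - (g[:-1] + ln[:-1])
    is_del = same_mate & (gap > 0) & (gap < MIN_INTRON)
    for j in np.flatnonzero(is_del):
        c = rs.chrom_names[rs.chrom_id[seg_mate[j]]]
        deletions[c][g[j] + ln[j] : g[j + 1]] += 1
    return PileupCounts(counts, deletions)


def _cigar_m_segments(pos: int, cigartuples) -> list[tuple[int, int, int]]:
    """(gstart, rstart, length) per M block of a SAM record."""
    out = []
    g, r = pos, 0
    for op, ln in cigartuples:
        if op in (0, 7, 8):  # M, =, X
            out.append((g, r, ln))
            g += ln
            r += ln
        elif op == 1 or op == 4:  # I, S consume query
            r += ln
        elif op in (2, 3):  # D, N consume reference
            g += ln
    return out


def pileup_sam(path: str, chrom_lengths: dict[str, int],
               require_primary: bool = True) -> PileupCounts:
    """Pileup from a SAM/BAM file; records with reference overhang are
    rejected and logged."""
    names = list(chrom_lengths)
    counts = {c: np.zeros((4, l), dtype=np.int32) for c, l in chrom_lengths.items()}
    deletions = {c: np.zeros(l, dtype=np.int32) for c, l in chrom_lengths.items()}
    rejected = 0
    with pysam.AlignmentFile(path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or (require_primary and (rec.is_secondary or rec.is_supplementary)):
                continue
            chrom = rec.reference_name
            if chrom not in counts:
                continue
            segs = _cigar_m_segments(rec.reference_start, rec.cigartuples or [])
            if segs and segs[-1][0] + segs[-1][2] > chrom_lengths[chrom]:
                rejected += 1
                continue
            codes = _seq.encode(rec.query_sequence)
            arr = counts[chrom]
            for gs, rs_, ln in segs:
                block = codes[rs_ : rs_ + ln]
                np.add.at(arr, (block, np.arange(gs, gs + ln)), 1)
            prev = None
            for gs, _, ln in segs:
                if prev is not None and 0 < gs - prev < 20:
                    deletions[chrom][prev:gs] += 1
                prev = gs + ln
    if rejected:
        warnings.warn(f"{rejected} records extended past chromosome ends; rejected")
    return PileupCounts({c: counts[c] for c in names}, deletions)


def load_known_variants(path: str) -> pd.DataFrame:
    """Positions (and alts) from a VCF of known variants."""
    rows = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            for alt in rec.alts or ("",):
                rows.append((rec.chrom, rec.pos - 1, rec.ref, alt))
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])


def call_rdds(pc: PileupCounts, model: GenomeModel, thresholds: Thresholds,
              known_variants: pd.DataFrame | None = None,
              known_match: str = "position") -> pd.DataFrame:
    """Threshold-based calling over a pileup.

    Every non-reference base passing all three thresholds yields a call, so
    one site can contribute up to three calls. known_variants (as returned by
    load_known_variants) are excluded before calling, matching by position
    (default) or by (position, alt).
    """
    if known_match not in ("position", "alt"):
        raise ValueError("known_match must be 'position' or 'alt'")
    th = thresholds
    out = []
    for chrom, arr in pc.counts.items():
        ref = model.chromosomes[chrom]
        cov = arr.sum(axis=0)
        for b in range(4):
            k = arr[b]
            with np.errstate(invalid="ignore", divide="ignore"):
                level = k / cov
            mask = (
                (ref != b)
                & (cov >= th.min_coverage)
                & (k >= th.min_alt_reads)
                & (k > 0)
                & (level >= th.min_level)
            )
            pos = np.flatnonzero(mask)
            if pos.size:
                out.append(pd.DataFrame({
                    "chrom": chrom,
                    "pos": pos,
                    "ref": [_seq.BASES[c] for c in ref[pos]],
                    "alt": _seq.BASES[b],
                    "alt_count": k[pos],
                    "coverage": cov[pos],
                    "level": level[pos],
                }))
    calls = (pd.concat(out, ignore_index=True) if out
             else pd.DataFrame(columns=CALL_COLUMNS))
    calls = calls.sort_values(["chrom", "pos", "alt"], ignore_index=True)
    if known_variants is not None and len(known_variants) and len(calls):
        if known_match == "position":
            key = pd.MultiIndex.from_frame(known_variants[["chrom", "pos"]])
            drop = pd.MultiIndex.from_frame(calls[["chrom", "pos"]]).isin(key)
        else:
            key = pd.MultiIndex.from_frame(known_variants[["chrom", "pos", "alt"]])
            drop = pd.MultiIndex.from_frame(calls[["chrom", "pos", "alt"]]).isin(key)
        calls = calls[~drop].reset_index(drop=True)
    return calls


def intersect_replicates(call_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Calls matching on (chrom, pos, alt) in every replicate; counts and
    levels are taken from the first replicate."""
    if len(call_sets) < 2:
        raise ValueError("need at least two call sets")
    keep = call_sets[0]
    for other in call_sets[1:]:
        if len(keep) == 0 or len(other) == 0:
            return keep.iloc[0:0]
        key = pd.MultiIndex.from_frame(other[["chrom", "pos", "alt"]])
        mask = pd.MultiIndex.from_frame(keep[["chrom", "pos", "alt"]]).isin(key)
        keep = keep[mask]
    return keep.reset_index(drop=True)


def write_calls(calls: pd.DataFrame, path: str) -> None:
    out = calls.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_calls(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["pos"] = df["pos"] - 1
    return df
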