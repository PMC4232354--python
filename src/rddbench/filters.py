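"""False-positive filter suite for RDD calls.

The homology machinery is a from-scratch seed-and-extend search (exact
12-mer seeds tiled across the query, both strands, ungapped extension) with
the aligner-style mismatch cap floor((L+2)/12) - 2. Because the cap is
always smaller than the number of non-overlapping 12-mer tiles, every locus
within the cap shares at least one exact tile with the query, so the seeded
search finds exactly the hit set of an exhaustive Hamming scan (which is
also provided, as the slow reference implementation).

Built on it are the two flank analyses: uniqueness (51/101/151 bp flanks
centred on a site; more than one hit for any flank means non-unique) and
the explanation filter (25/50/75 bp flanks ending/starting at the site; a
non-origin hit whose aligned base at the site offset equals the call's alt
removes the call). Simpler annotation filters handle pseudogenes, intronic
sites near splice junctions, homopolymer-adjacent sites, and cross-aligner
concordance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _seq
from .genome import GenomeModel, GenomicInterval, Transcript

SEED_K = 12


def mismatch_cap(length: int) -> int:
    """Aligner-style mismatch allowance for a query of the given length."""
    return max((length + 2) // 12 - 2, 0)


@dataclass
class HomologyHit:
    chrom: str
    start: int  # 0-based start of the aligned window on the forward strand
    strand: str  # "+" or "-"
    mismatches: int

    def target_index(self, query_offset: int, query_len: int) -> int:
        """Genomic position aligned to a given query offset."""
        if self.strand == "+":
            return self.start + query_offset
        return self.start + (query_len - 1 - query_offset)


class GenomeIndex:
    """Exact k-mer index over all chromosomes for seed-and-extend search."""

    def __init__(self, model: GenomeModel, k: int = SEED_K):
        self.model = model
        self.k = k
        self.chrom_names = model.chrom_names
        self._lengths = np.array([model.chrom_lengths[c] for c in self.chrom_names])
        self._offsets = np.concatenate(([0], np.cumsum(self._lengths)))[:-1]
        self.genome = np.concatenate(
            [model.chromosomes[c] for c in self.chrom_names]
        )
        codes = _seq.kmer_codes(self.genome, k)
        # mask k-mers spanning a chromosome boundary
        valid = np.ones(codes.size, dtype=bool)
        for off, ln in zip(self._offsets, self._lengths):
            lo = max(off + ln - k + 1, 0)
            valid[lo : off + ln] = False
        self._order = np.argsort(codes, kind="stable")
        self._sorted = codes[self._order]
        self._valid = valid

    def _chrom_of(self, gidx: np.ndarray) -> np.ndarray:
        return np.searchsorted(self._offsets, gidx, side="right") - 1

    def global_index(self, chrom: str, pos: int) -> int:
        return int(self._offsets[self.chrom_names.index(chrom)] + pos)

    def _seed_candidates(self, query: np.ndarray) -> np.ndarray:
        """Candidate window starts (global coords) from tiled exact seeds."""
        L = query.size
        cands = []
        for off in range(0, L - self.k + 1, self.k):
            code = int(_seq.kmer_codes(query[off : off + self.k], self.k)[0])
            lo = np.searchsorted(self._sorted, code, side="left")
            hi = np.searchsorted(self._sorted, code, side="right")
            pos = self._order[lo:hi]
            pos = pos[self._valid[pos]]
            cands.append(pos - off)
        starts = np.unique(np.concatenate(cands)) if cands else np.zeros(0, np.int64)
        ci = self._chrom_of(starts)
        ok = (starts >= self._offsets[ci]) & (
            starts + L <= self._offsets[ci] + self._lengths[ci]
        )
        return starts[ok]

    def search(self, query: np.ndarray | str, max_mismatches: int,
               both_strands: bool = True) -> list[HomologyHit]:
        """All loci aligning the full query ungapped with <= max_mismatches."""
        if isinstance(query, str):
            query = _seq.encode(query)
        if query.size > int(self._lengths.max()):
            raise ValueError("query longer than every chromosome")
        if query.size < self.k:
            raise ValueError(f"query shorter than seed size {self.k}")
        L = query.size
        hits: list[HomologyHit] = []
        strands = [("+", query)] + ([("-", _seq.revcomp(query))] if both_strands else [])
        for strand, q in strands:
            starts = self._seed_candidates(q)
            if starts.size == 0:
                continue
            windows = self.genome[starts[:, None] + np.arange(L)[None, :]]
            mm = (windows != q[None, :]).sum(axis=1)
            keep = np.flatnonzero(mm <= max_mismatches)
            ci = self._chrom_of(starts[keep])
            for s, c, m in zip(starts[keep], ci, mm[keep]):
                hits.append(HomologyHit(self.chrom_names[c],
                                        int(s - self._offsets[c]), strand, int(m)))
        hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
        return hits


def exhaustive_homology_scan(model: GenomeModel, query: np.ndarray | str,
                             max_mismatches: int,
                             both_strands: bool = True) -> list[HomologyHit]:
    """Reference implementation: Hamming distance of the query against every
    window of every chromosome (O(L * genome)); for validating the seeded
    search on small genomes."""
    if isinstance(query, str):
        query = _seq.encode(query)
    L = query.size
    hits: list[HomologyHit] = []
    strands = [("+", query)] + ([("-", _seq.revcomp(query))] if both_strands else [])
    for chrom, codes in model.chromosomes.items():
        n = codes.size
        if n < L:
            continue
        for strand, q in strands:
            mm = np.zeros(n - L + 1, dtype=np.int32)
            for off in range(L):
                mm += codes[off : n - L + 1 + off] != q[off]
            for s in np.flatnonzero(mm <= max_mismatches):
                hits.append(HomologyHit(chrom, int(s), strand, int(mm[s])))
    hits.sort(key=lambda h: (h.chrom, h.start, h.strand))
    return hits


# ---------------------------------------------------------------------------
# flank analyses
# ---------------------------------------------------------------------------

def _centered_flank(model, chrom, pos, total_len):
    """Flank of odd total length centred on pos, truncated at chromosome
    ends; returns (codes, start)."""
    half = total_len // 2
    n = model.chrom_lengths[chrom]
    start = max(pos - half, 0)
    end = min(pos + half + 1, n)
    return model.chromosomes[chrom][start:end], start


def uniqueness_annotation(index: GenomeIndex, chrom: str, pos: int,
                          flank_lengths: tuple[int, ...] = (51, 101, 151)) -> bool:
    """True if the site is unique: no centred flank aligns to more than one
    locus under the per-length mismatch cap."""
    for total in flank_lengths:
        q, _ = _centered_flank(index.model, chrom, pos, total)
        if q.size < index.k:
            continue
        hits = index.search(q, mismatch_cap(total))
        if len(hits) > 1:
            return False
    return True


def homology_explains(index: GenomeIndex, chrom: str, pos: int, alt: str,
                      flank_lengths: tuple[int, ...] = (25, 50, 75),
                      offset_tolerance: int = 0) -> bool:
    """True if some non-origin homologous locus carries the call's alt base
    at the position aligned to the site (the hit "explains" the call)."""
    alt_code = _seq.BASES.index(alt)
    comp_alt = int(_seq.COMPLEMENT[alt_code])
    n = index.model.chrom_lengths[chrom]
    seq = index.model.chromosomes[chrom]
    for total in flank_lengths:
        for side in ("up", "down"):
            if side == "up":
                origin_start = max(pos - total + 1, 0)
                q = seq[origin_start : pos + 1]
                site_off = pos - origin_start
            else:
                origin_start = pos
                q = seq[pos : min(pos + total, n)]
                site_off = 0
            if q.size < index.k:
                continue
            for hit in index.search(q, mismatch_cap(total)):
                if hit.strand == "+" and hit.chrom == chrom and hit.start == origin_start:
                    continue  # the site's own locus does not explain anything
                want = alt_code if hit.strand == "+" else comp_alt
                gseq = index.model.chromosomes[hit.chrom]
                for d in range(-offset_tolerance, offset_tolerance + 1):
                    ti = hit.target_index(site_off + d, q.size)
                    if 0 <= ti < gseq.size and gseq[ti] == want:
                        return True
    return False


def annotate_uniqueness(calls: pd.DataFrame, index: GenomeIndex, **kw) -> pd.Series:
    return pd.Series(
        [uniqueness_annotation(index, r.chrom, r.pos, **kw) for r in calls.itertuples()],
        index=calls.index, name="unique",
    )


# ---------------------------------------------------------------------------
# call-set filters: each returns a boolean Series, True = removed
# ---------------------------------------------------------------------------

def concordance_filter(calls: pd.DataFrame, other_call_sets: list[pd.DataFrame],
                       min_other: int) -> pd.Series:
    """Removed unless the call is matched on (chrom, pos, alt) in at least
    min_other of the other call sets."""
    if min_other > len(other_call_sets):
        raise ValueError("min_other exceeds the number of other call sets")
    matches = np.zeros(len(calls), dtype=np.int64)
    key = pd.MultiIndex.from_frame(calls[["chrom", "pos", "alt"]])
    for other in other_call_sets:
        ok = pd.MultiIndex.from_frame(other[["chrom", "pos", "alt"]])
        matches += key.isin(ok).astype(int)
    return pd.Series(matches < min_other, index=calls.index, name="concordance")


def homology_filter(calls: pd.DataFrame, index: GenomeIndex,
                    flank_lengths: tuple[int, ...] = (25, 50, 75),
                    offset_tolerance: int = 0) -> pd.Series:
    """BLAT-style explanation filter: removed if a homologous locus explains
    the sequence difference."""
    return pd.Series(
        [homology_explains(index, r.chrom, r.pos, r.alt, flank_lengths,
                           offset_tolerance)
         for r in calls.itertuples()],
        index=calls.index, name="homology",
    )


def pseudogene_filter(calls: pd.DataFrame,
                      pseudogenes: list[GenomicInterval]) -> pd.Series:
    removed = np.zeros(len(calls), dtype=bool)
    for i, r in enumerate(calls.itertuples()):
        removed[i] = any(p.contains(r.chrom, r.pos) for p in pseudogenes)
    return pd.Series(removed, index=calls.index, name="pseudogene")


def junction_proximity_filter(calls: pd.DataFrame, transcripts: list[Transcript],
                              window: int = 6) -> pd.Series:
    """Removed iff the call is intronic and within `window` bp of an
    exon-intron boundary. Exonic calls always pass."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in transcripts:
        for s, e in t.introns:
            by_chrom.setdefault(t.chrom, []).append((s, e))
    removed = np.zeros(len(calls), dtype=bool)
    for i, r in enumerate(calls.itertuples()):
        for s, e in by_chrom.get(r.chrom, ()):
            if s <= r.pos < e:
                dist = min(r.pos - s + 1, e - r.pos)  # 1-based bp into the intron
                if dist <= window:
                    removed[i] = True
                    break
    return pd.Series(removed, index=calls.index, name="junction")


def homopolymer_filter(calls: pd.DataFrame, model: GenomeModel,
                       min_run: int = 5, adjacency: int = 1) -> pd.Series:
    """Removed iff a run of >= min_run identical bases lies within
    `adjacency` bp of the site (the site inside a run also counts)."""
    runs = {}
    for c, codes in model.chromosomes.items():
        runs[c] = _seq.run_length_runs(codes, min_run)
    removed = np.zeros(len(calls), dtype=bool)
    for i, r in enumerate(calls.itertuples()):
        for s, e in runs.get(r.chrom, ()):
            if s - adjacency <= r.pos <= e - 1 + adjacency:
                removed[i] = True
                break
    return pd.Series(removed, index=calls.index, name="homopolymer")


def apply_filters(calls: pd.DataFrame,
                  filter_flags: dict[str, pd.Series]) -> pd.DataFrame:
    """Combine per-filter removal flags into a verdict table.

    A call is removed iff at least one filter flags it; the surviving set is
    therefore the intersection of the per-filter survivor sets.
    """
    verdicts = calls.copy()
    removed = np.zeros(len(calls), dtype=bool)
    for name, flags in filter_flags.items():
        verdicts[f"removed_{name}"] = flags.to_numpy()
        removed |= flags.to_numpy()
    verdicts["removed"] = removed
    verdicts["removing_filters"] = [
        ",".join(n for n in filter_flags if verdicts[f"removed_{n}"].iloc[i])
        for i in range(len(calls))
    ]
    return verdicts
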