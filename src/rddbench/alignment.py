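"""Alignment normalisation, misalignment injection, and alignment quality.

normalize_sam applies the standard cleanup — drop non-primary records and
pairs in incorrect (non forward/reverse) orientation. inject_misalignment is
the package's surrogate for aligner error: read pairs originating inside a
planted duplicon's source region are relocated to the homologous copy with
a configurable probability, coordinates remapped through the stored
source-to-target offset. bases_aligned_properly generalises the "bases
neither clipped nor aligned with a mismatch or indel" metric to the run's
read length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pysam

from . import _seq
from .genome import GenomeModel
from .reads import ReadSet


@dataclass
class NormalizeStats:
    kept: int = 0
    removed_secondary: int = 0
    removed_orientation: int = 0
    orphans_kept: int = 0


def _correct_orientation(rec: pysam.AlignedSegment) -> bool:
    """Proper forward/reverse pair: mates on opposite strands, the forward
    mate leftmost (inclusive of equal starts)."""
    if rec.is_reverse == rec.mate_is_reverse:
        return False
    if rec.reference_id != rec.next_reference_id:
        return False
    if rec.is_reverse:
        return rec.reference_start >= rec.next_reference_start
    return rec.reference_start <= rec.next_reference_start


def normalize_sam(in_path: str, out_path: str) -> NormalizeStats:
    """Remove non-primary records and wrongly oriented pairs; orphan mates
    (mate unmapped) are retained and counted."""
    stats = NormalizeStats()
    with pysam.AlignmentFile(in_path, "r", check_sq=False) as src:
        with pysam.AlignmentFile(out_path, "wh", template=src) as dst:
            for rec in src:
                if rec.is_secondary or rec.is_supplementary:
                    stats.removed_secondary += 1
                    continue
                if rec.is_paired and not rec.mate_is_unmapped and not rec.is_unmapped:
                    if not _correct_orientation(rec):
                        stats.removed_orientation += 1
                        continue
                elif rec.is_paired:
                    stats.orphans_kept += 1
                dst.write(rec)
                stats.kept += 1
    return stats


def inject_misalignment(rs: ReadSet, model: GenomeModel, p_move: float,
                        seed: int = 0) -> int:
    """Surrogate for aligner error at homologous loci, applied in place.

    Read pairs whose truth placement lies inside a duplicon's source region
    are relocated to the homologous copy with probability p_move; spliced
    (all-exonic) pairs from a pseudogene parent are likewise relocated into
    the processed copy through the spliced-coordinate map. Returns the
    number of pairs moved. Divergent bases between source and copy then
    surface as mismatches in any pileup at the copy.
    """
    if not 0.0 <= p_move <= 1.0:
        raise ValueError(f"p_move={p_move} outside [0, 1]")
    if p_move == 0.0 or not (model.duplicons or model.pseudogenes):
        return 0
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x30FE]))
    chrom_index = {c: i for i, c in enumerate(rs.chrom_names)}
    first = rs.seg_index[:-1]
    last = rs.seg_index[1:] - 1
    mate_gmin = rs.seg_g[first]
    mate_gmax = rs.seg_g[last] + rs.seg_len[last]
    pair_gmin = np.minimum(mate_gmin[0::2], mate_gmin[1::2])
    pair_gmax = np.maximum(mate_gmax[0::2], mate_gmax[1::2])
    pair_chrom = rs.chrom_id[0::2]
    same_chrom = rs.chrom_id[0::2] == rs.chrom_id[1::2]
    n_seg_per_mate = np.diff(rs.seg_index)
    already = np.zeros(rs.n_pairs, dtype=bool)
    moved = 0
    for dup in model.duplicons:
        src, dst = dup.source, dup.target
        inside = (
            ~already
            & same_chrom
            & (pair_chrom == chrom_index[src.chrom])
            & (pair_gmin >= src.start)
            & (pair_gmax <= src.end)
        )
        move = inside & (rng.random(rs.n_pairs) < p_move)
        already |= move
        if not move.any():
            continue
        mate_move = np.repeat(move, 2)
        seg_move = np.repeat(mate_move, n_seg_per_mate)
        rs.seg_g[seg_move] += dst.start - src.start
        rs.chrom_id[mate_move] = chrom_index[dst.chrom]
        moved += int(move.sum())

    # pseudogenes: spliced pairs of the parent transcript relocate into the
    # intronless copy through the exon -> spliced-offset map
    parents = {t.id: t for t in model.transcripts}
    for pg in model.pseudogenes:
        t = parents.get(pg.label.replace("pseudo_", ""))
        if t is None:
            continue
        exon_starts = np.array([s for s, _ in t.exons])
        exon_ends = np.array([e for _, e in t.exons])
        spliced_off = np.concatenate(([0], np.cumsum(exon_ends - exon_starts)))[:-1]
        cand = np.flatnonzero(
            ~already
            & same_chrom
            & (pair_chrom == chrom_index[t.chrom])
            & (pair_gmin >= t.start)
            & (pair_gmax <= t.end)
        )
        if cand.size == 0:
            continue
        coins = rng.random(cand.size) < p_move
        for ci, p in enumerate(cand):
            if not coins[ci]:
                continue
            segs = slice(rs.seg_index[2 * p], rs.seg_index[2 * p + 2])
            g = rs.seg_g[segs]
            ln = rs.seg_len[segs]
            ei = np.searchsorted(exon_starts, g, side="right") - 1
            if np.any(ei < 0) or np.any(g + ln > exon_ends[ei]):
                continue  # a segment crosses an intron: not a spliced pair
            rs.seg_g[segs] = pg.start + spliced_off[ei] + (g - exon_starts[ei])
            rs.chrom_id[2 * p : 2 * p + 2] = chrom_index[pg.chrom]
            already[p] = True
            moved += 1
    return moved


def bases_aligned_properly(cigartuples, query_codes: np.ndarray,
                           chrom_codes: np.ndarray, pos: int) -> int:
    """L minus clipped, mismatched and inserted bases.

    Deletions and splice gaps consume no query bases and are not charged
    beyond the clip/mismatch/insert terms.
    """
    g, r = pos, 0
    proper = 0
    for op, ln in cigartuples:
        if op in (0, 7, 8):  # M/=/X: count matches only
            if r + ln > query_codes.size or g + ln > chrom_codes.size:
                raise ValueError("CIGAR extends past sequence bounds")
            proper += int(np.count_nonzero(
                query_codes[r : r + ln] == chrom_codes[g : g + ln]))
            r += ln
            g += ln
        elif op == 1:  # I: not properly aligned
            r += ln
        elif op in (4, 5):  # clips: not properly aligned (H consumes nothing)
            if op == 4:
                r += ln
        elif op in (2, 3):  # D/N
            g += ln
        else:
            raise ValueError(f"unsupported CIGAR op {op}")
    if r != query_codes.size:
        raise ValueError("CIGAR query length does not match sequence")
    return proper


def bases_aligned_properly_sam(rec: pysam.AlignedSegment, model: GenomeModel) -> int:
    codes = _seq.encode(rec.query_sequence)
    return bases_aligned_properly(rec.cigartuples or [], codes,
                                  model.chromosomes[rec.reference_name],
                                  rec.reference_start)


def alignment_quality_stats(rs: ReadSet, model: GenomeModel) -> np.ndarray:
    """bases_aligned_properly for every mate of a ReadSet."""
    out = np.zeros(rs.n_mates, dtype=np.int32)
    for i in range(rs.n_mates):
        chrom = rs.chrom_names[rs.chrom_id[i]]
        g, r, ln = rs.mate_segments(i)
        genome = model.chromosomes[chrom]
        proper = 0
        for gs, rstart, l in zip(g, r, ln):
            proper += int(np.count_nonzero(
                rs.seqs[i, rstart : rstart + l] == genome[gs : gs + l]))
        out[i] = proper
    return out
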