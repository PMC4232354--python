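"""Paired-end RNA-Seq read simulation with truth alignments.

Fragments are drawn from expressed transcripts (Poisson counts per
transcript), placed uniformly, and sequenced as 100 bp mate pairs. The
realistic error model applies a 0.5% uniform substitution rate, raised to
20% in the final 10 sequenced bases of a 25% subset of reads (degraded 3'
tails), plants indel polymorphisms in the sample's transcript copies at
0.1% per base, and draws a calibrated fraction of fragments from unspliced
pre-mRNA so that a target share (~30%) of read bases is intronic. Fragment
lengths are normal with mean 330 bp. Clean mode disables all of these.

Every mate carries its true genomic placement as a list of aligned (M)
segments, from which CIGAR strings (with splice gaps and indels) and truth
SAM records are derived. Reads are stored genome-forward; reverse-strand
mates are reverse-complemented only when writing FASTQ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace, field

import numpy as np
import pysam

from . import _seq
from ._seq import decode
from .genome import GenomeModel

MIN_INTRON = 20  # ref-skip at least this long is written as N, shorter as D


@dataclass(frozen=True)
class ErrorModel:
    substitution_rate: float = 0.005
    tail_rate: float = 0.20
    tail_length: int = 10
    tail_read_fraction: float = 0.25
    indel_rate: float = 0.001
    indel_max_len: int = 3
    intron_signal_fraction: float = 0.30
    fragment_length_mean: float = 330.0
    fragment_length_sd: float = 50.0

    def __post_init__(self):
        for name in ("substitution_rate", "tail_rate", "tail_read_fraction",
                     "indel_rate", "intron_signal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def as_clean(self) -> "ErrorModel":
        return replace(self, substitution_rate=0.0, tail_rate=0.0,
                       tail_read_fraction=0.0, indel_rate=0.0,
                       intron_signal_fraction=0.0)


@dataclass
class ExpressionProfile:
    """Per-transcript expected read-pair counts (Poisson means)."""

    transcript_ids: list[str]
    means: np.ndarray

    def __post_init__(self):
        if np.any(self.means < 0):
            raise ValueError("negative expression mean")


@dataclass
class IndelEvent:
    transcript_id: str
    chrom: str
    ref_pos: int  # 0-based genomic position of the event
    kind: str  # "I" or "D"
    length: int


@dataclass
class ReadSet:
    """Simulated mates with truth placements; mates 2i, 2i+1 form pair i."""

    read_length: int
    chrom_names: list[str]
    chrom_lengths: np.ndarray  # per chrom id
    seqs: np.ndarray  # (n_mates, L) uint8, genome-forward orientation
    chrom_id: np.ndarray  # (n_mates,) int16
    is_reverse: np.ndarray  # (n_mates,) bool
    degraded: np.ndarray  # (n_mates,) bool
    from_premrna: np.ndarray  # (n_mates,) bool
    seg_index: np.ndarray  # (n_mates+1,) offsets into seg_* arrays
    seg_g: np.ndarray  # genomic start of each aligned (M) block
    seg_r: np.ndarray  # read offset of each aligned block
    seg_len: np.ndarray
    err_index: np.ndarray  # (n_mates+1,) offsets into err_offsets
    err_offsets: np.ndarray  # substitution-error read offsets (forward orientation)
    frag_len: np.ndarray  # (n_pairs,)
    indel_events: list[IndelEvent] = field(default_factory=list)
    transcript_bases: int = 0  # bases over which indel polymorphisms were planted

    @property
    def n_mates(self) -> int:
        return self.seqs.shape[0]

    @property
    def n_pairs(self) -> int:
        return self.n_mates // 2

    @property
    def chrom_offsets(self) -> np.ndarray:
        """Offset of each chromosome in the concatenated-genome coordinate."""
        return np.concatenate(([0], np.cumsum(self.chrom_lengths)))[:-1]

    def mate_segments(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        a, b = self.seg_index[i], self.seg_index[i + 1]
        return self.seg_g[a:b], self.seg_r[a:b], self.seg_len[a:b]

    def mate_errors(self, i: int) -> np.ndarray:
        return self.err_offsets[self.err_index[i] : self.err_index[i + 1]]

    def cigar(self, i: int) -> list[tuple[int, int]]:
        """CIGAR as (op, len) tuples; ops follow pysam numbering
        (0=M, 1=I, 2=D, 3=N, 4=S)."""
        g, r, ln = self.mate_segments(i)
        L = self.read_length
        out: list[tuple[int, int]] = []
        if r[0] > 0:
            out.append((4, int(r[0])))
        for j in range(g.size):
            out.append((0, int(ln[j])))
            if j + 1 < g.size:
                rgap = int(r[j + 1] - (r[j] + ln[j]))
                ggap = int(g[j + 1] - (g[j] + ln[j]))
                if rgap > 0:
                    out.append((1, rgap))
                if ggap > 0:
                    out.append((3, ggap) if ggap >= MIN_INTRON else (2, ggap))
        tail = L - int(r[-1] + ln[-1])
        if tail > 0:
            out.append((4, tail))
        return out

    def cigar_string(self, i: int) -> str:
        return "".join(f"{n}{'MIDNS'[op]}" for op, n in self.cigar(i))


def expression_profile(model: GenomeModel, n_pairs: int,
                       expressed_fraction: float = 0.7, rng=None) -> ExpressionProfile:
    """Poisson means per transcript: an expressed subset with exponential
    relative abundances, normalised so the total equals n_pairs."""
    rng = np.random.default_rng(rng)
    n = len(model.transcripts)
    expressed = rng.random(n) < expressed_fraction
    w = rng.exponential(1.0, n) * expressed
    if w.sum() == 0:
        w = np.ones(n)
    means = w / w.sum() * n_pairs
    return ExpressionProfile([t.id for t in model.transcripts], means)


def _plant_indels(model: GenomeModel, em: ErrorModel, rng) -> tuple[list[IndelEvent], int]:
    """Plant indel polymorphisms on every transcript's pre-mRNA.

    Events are kept >=5 bp away from exon boundaries and transcript ends and
    are non-overlapping, so truth CIGAR ref-skips stay unambiguous (D vs N).
    """
    events: list[IndelEvent] = []
    total = 0
    for t in model.transcripts:
        span = t.span_length
        total += span
        if em.indel_rate == 0:
            continue
        pos = np.flatnonzero(rng.random(span) < em.indel_rate)
        if pos.size == 0:
            continue
        boundaries = np.array(
            [b for s, e in t.exons for b in (s - t.start, e - t.start)], dtype=np.int64
        )
        near = np.min(np.abs(pos[:, None] - boundaries[None, :]), axis=1) < 5
        pos = pos[~near & (pos >= 5) & (pos < span - 5)]
        last_end = -10
        for p in pos:
            kind = "I" if rng.random() < 0.5 else "D"
            length = min(int(rng.geometric(0.5)), em.indel_max_len)
            if p <= last_end + 1:
                continue
            events.append(IndelEvent(t.id, t.chrom, t.start + int(p), kind, length))
            last_end = int(p) + (length if kind == "D" else 0)
    return events, total


def _sample_transcript_arrays(model, t, events, rng):
    """Sample (indel-bearing) pre-mRNA and mRNA of a transcript.

    Returns (pre_seq, pre_g, mrna_seq, mrna_g) where *_g give genomic
    positions of each sample base (-1 for inserted bases).
    """
    ref = model.chromosomes[t.chrom][t.start : t.end]
    g = np.arange(t.start, t.end, dtype=np.int64)
    if events:
        seq_parts, g_parts = [], []
        cur = t.start
        for ev in sorted(events, key=lambda e: e.ref_pos):
            p = ev.ref_pos
            if ev.kind == "D":
                seq_parts.append(ref[cur - t.start : p - t.start])
                g_parts.append(g[cur - t.start : p - t.start])
                cur = p + ev.length
            else:
                seq_parts.append(ref[cur - t.start : p + 1 - t.start])
                g_parts.append(g[cur - t.start : p + 1 - t.start])
                seq_parts.append(rng.integers(4, size=ev.length).astype(np.uint8))
                g_parts.append(np.full(ev.length, -1, dtype=np.int64))
                cur = p + 1
        seq_parts.append(ref[cur - t.start :])
        g_parts.append(g[cur - t.start :])
        pre_seq = np.concatenate(seq_parts)
        pre_g = np.concatenate(g_parts)
    else:
        pre_seq, pre_g = ref, g

    exonic, _ = model.region_masks(t.chrom)
    mask = np.zeros(pre_g.size, dtype=bool)
    valid = pre_g >= 0
    mask[valid] = exonic[pre_g[valid]]
    if not valid.all():  # inserted bases inherit the class of the previous base
        idx = np.arange(pre_g.size)
        idx[~valid] = 0
        src = np.maximum.accumulate(idx)
        mask = mask[src]
    midx = np.flatnonzero(mask)
    return pre_seq, pre_g, pre_seq[midx], pre_g[midx]


def _premrna_probability(model, means: np.ndarray, em: ErrorModel, L: int) -> float:
    """Per-fragment probability of sampling unspliced pre-mRNA, calibrated so
    the expected intronic read-base fraction hits the configured target."""
    target = em.intron_signal_fraction
    if target == 0:
        return 0.0
    flen = int(round(em.fragment_length_mean))
    shares = np.zeros(len(model.transcripts))
    for i, t in enumerate(model.transcripts):
        if means[i] == 0 or not t.introns:
            continue
        Lu = t.span_length
        S = max(Lu - flen, 0)
        x = np.arange(Lu)
        c1 = np.maximum(np.minimum(x, S) - np.maximum(0, x - L + 1) + 1, 0)
        c2 = np.maximum(
            np.minimum(x - flen + L, S) - np.maximum(0, x - flen + 1) + 1, 0
        )
        w = (c1 + c2).astype(float)
        intron = np.ones(Lu, dtype=bool)
        for s, e in t.exons:
            intron[s - t.start : e - t.start] = False
        shares[i] = (w * intron).sum() / w.sum()
    s_bar = float((means * shares).sum() / means.sum())
    if s_bar == 0:
        warnings.warn("no intronic sequence available; intron target unreachable")
        return 0.0
    p = target / s_bar
    if p > 1:
        warnings.warn(
            f"intron target {target:.2f} unreachable (max {s_bar:.2f}); capping at 1"
        )
        p = 1.0
    return p


def _extract_segments(sl_g: np.ndarray):
    """Decompose a read's genomic-position slice into aligned (M) blocks."""
    if (
        sl_g[0] >= 0
        and sl_g[-1] == sl_g[0] + sl_g.size - 1
        and bool((np.diff(sl_g) == 1).all())
    ):
        return [0], [int(sl_g[0])], [sl_g.size]  # fast path: contiguous
    midx = np.flatnonzero(sl_g >= 0)
    gm = sl_g[midx]
    brk = np.flatnonzero((np.diff(midx) != 1) | (np.diff(gm) != 1))
    starts = np.concatenate(([0], brk + 1))
    ends = np.concatenate((brk + 1, [midx.size]))
    return midx[starts].tolist(), gm[starts].tolist(), (ends - starts).tolist()


def simulate_reads(model: GenomeModel, error_model: ErrorModel | None = None,
                   n_pairs: int = 100_000, mode: str = "realistic",
                   seed: int = 0, read_length: int = 100,
                   expressed_fraction: float = 0.7) -> ReadSet:
    """Simulate paired-end reads from a GenomeModel.

    mode="clean" forces zero substitution/indel/intron/tail rates; the truth
    placements of clean reads match the genome exactly.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    em = error_model or ErrorModel()
    if mode == "clean":
        em = em.as_clean()
    elif mode != "realistic":
        raise ValueError(f"unknown mode {mode!r}")
    L = int(read_length)
    if em.tail_length > L:
        raise ValueError("tail_length exceeds read length")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EAD]))

    profile = expression_profile(model, n_pairs, expressed_fraction, rng)
    counts = rng.poisson(profile.means)
    if counts.sum() == 0:
        warnings.warn("no transcript sampled; returning empty ReadSet")
    indels, tx_bases = _plant_indels(model, em, rng)
    indels_by_tx: dict[str, list[IndelEvent]] = {}
    for ev in indels:
        indels_by_tx.setdefault(ev.transcript_id, []).append(ev)
    p_pre = _premrna_probability(model, profile.means, em, L)

    chrom_names = model.chrom_names
    chrom_index = {c: i for i, c in enumerate(chrom_names)}
    n_mates_max = int(counts.sum()) * 2
    seqs = np.zeros((n_mates_max, L), dtype=np.uint8)
    chrom_id = np.zeros(n_mates_max, dtype=np.int16)
    from_premrna = np.zeros(n_mates_max, dtype=bool)
    frag_lens: list[int] = []
    seg_counts: list[int] = []
    seg_g: list[int] = []
    seg_r: list[int] = []
    seg_len: list[int] = []
    mate = 0

    for ti in np.flatnonzero(counts):
        t = model.transcripts[ti]
        m = int(counts[ti])
        pre_seq, pre_g, mr_seq, mr_g = _sample_transcript_arrays(
            model, t, indels_by_tx.get(t.id, []), rng
        )
        pre = rng.random(m) < p_pre
        flen = np.rint(rng.normal(em.fragment_length_mean, em.fragment_length_sd, m)).astype(int)
        cid = chrom_index[t.chrom]
        for j in range(m):
            seq_arr, g_arr = (pre_seq, pre_g) if pre[j] else (mr_seq, mr_g)
            n = g_arr.size
            if n < L:
                continue  # transcript too short for a read; extremely unlikely by config
            fl = min(max(int(flen[j]), L), n)
            s = int(rng.integers(0, n - fl + 1))
            for a in (s, s + fl - L):
                sl_g = g_arr[a : a + L]
                seqs[mate] = seq_arr[a : a + L]
                chrom_id[mate] = cid
                from_premrna[mate] = pre[j]
                r0, g0, l0 = _extract_segments(sl_g)
                seg_counts.append(len(r0))
                seg_r.extend(r0)
                seg_g.extend(g0)
                seg_len.extend(l0)
                mate += 1
            frag_lens.append(fl)

    seqs = seqs[:mate]
    chrom_id = chrom_id[:mate]
    from_premrna = from_premrna[:mate]

    # orientation: one mate forward from the left end, one reverse from the
    # right end; which physical mate is which is random (non strand-specific)
    n_p = mate // 2
    is_reverse = np.zeros(mate, dtype=bool)
    is_reverse[1::2] = True  # left mate forward, right mate reverse (FR pair)
    mate1_is_left = rng.random(n_p) < 0.5  # random physical mate order (non-strand-specific)

    rs = ReadSet(
        read_length=L,
        chrom_names=chrom_names,
        chrom_lengths=np.array([model.chrom_lengths[c] for c in chrom_names]),
        seqs=seqs,
        chrom_id=chrom_id,
        is_reverse=is_reverse,
        degraded=np.zeros(mate, dtype=bool),
        from_premrna=from_premrna,
        seg_index=np.concatenate(([0], np.cumsum(seg_counts))).astype(np.int64),
        seg_g=np.asarray(seg_g, dtype=np.int64),
        seg_r=np.asarray(seg_r, dtype=np.int32),
        seg_len=np.asarray(seg_len, dtype=np.int32),
        err_index=np.zeros(mate + 1, dtype=np.int64),
        err_offsets=np.zeros(0, dtype=np.int16),
        frag_len=np.asarray(frag_lens, dtype=np.int32),
        indel_events=indels,
        transcript_bases=tx_bases,
    )
    rs.mate1_is_left = mate1_is_left
    _apply_substitution_errors(rs, em, rng)
    return rs


def _apply_substitution_errors(rs: ReadSet, em: ErrorModel, rng) -> None:
    """Vectorised application of the substitution error model, in place."""
    n, L = rs.seqs.shape
    if n == 0:
        return
    rs.degraded = rng.random(n) < em.tail_read_fraction
    err_counts = np.zeros(n, dtype=np.int64)
    offsets: list[np.ndarray] = []
    chunk = 200_000
    tl = em.tail_length
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        rate = np.full((b - a, L), em.substitution_rate)
        deg = rs.degraded[a:b]
        rev = rs.is_reverse[a:b]
        # sequencing 3' tail: last tl columns for forward mates, first tl for reverse
        rate[deg & ~rev, L - tl :] = em.tail_rate
        rate[deg & rev, : tl] = em.tail_rate
        mask = rng.random((b - a, L)) < rate
        rows, cols = np.nonzero(mask)
        if rows.size:
            sub = rs.seqs[a:b]
            sub[rows, cols] = (sub[rows, cols] + rng.integers(1, 4, rows.size).astype(np.uint8)) % 4
            np.add.at(err_counts, a + rows, 1)
            offsets.append(cols.astype(np.int16))
        else:
            offsets.append(np.zeros(0, dtype=np.int16))
    rs.err_index = np.concatenate(([0], np.cumsum(err_counts))).astype(np.int64)
    rs.err_offsets = np.concatenate(offsets) if offsets else np.zeros(0, dtype=np.int16)


# ---------------------------------------------------------------------------
# derived tracks and statistics
# ---------------------------------------------------------------------------

def coverage_track(rs: ReadSet) -> dict[str, np.ndarray]:
    """Per-position count of reads whose aligned (M) bases span the position."""
    off = rs.chrom_offsets
    total = int(rs.chrom_lengths.sum())
    diff = np.zeros(total + 1, dtype=np.int64)
    seg_chrom = np.repeat(rs.chrom_id, np.diff(rs.seg_index))
    gstart = off[seg_chrom] + rs.seg_g
    np.add.at(diff, gstart, 1)
    np.add.at(diff, gstart + rs.seg_len, -1)
    cov = np.cumsum(diff[:-1])
    return {
        c: cov[off[i] : off[i] + rs.chrom_lengths[i]].astype(np.int32)
        for i, c in enumerate(rs.chrom_names)
    }


def iter_aligned_bases(rs: ReadSet, chunk_segments: int = 250_000):
    """Yield (rows, cols, gpos_global, chrom_of_row) chunks expanding every
    aligned (M) base of every mate; the workhorse for pileups and stats."""
    off = rs.chrom_offsets
    seg_mate = np.repeat(
        np.arange(rs.n_mates, dtype=np.int64), np.diff(rs.seg_index)
    )
    n_seg = rs.seg_g.size
    for a in range(0, n_seg, chunk_segments):
        b = min(a + chunk_segments, n_seg)
        lens = rs.seg_len[a:b].astype(np.int64)
        total = int(lens.sum())
        if total == 0:
            continue
        reps = np.repeat(np.arange(b - a), lens)
        within = np.arange(total) - np.repeat(np.cumsum(lens) - lens, lens)
        rows = seg_mate[a:b][reps]
        cols = rs.seg_r[a:b].astype(np.int64)[reps] + within
        gpos = (off[rs.chrom_id[rows]] + rs.seg_g[a:b][reps]) + within
        yield rows, cols, gpos


def simulator_stats(rs: ReadSet, model: GenomeModel) -> dict[str, float]:
    """Measure the realised generative parameters of a ReadSet against the
    genome: substitution rates (non-tail and degraded-tail), intronic base
    fraction, degraded-read fraction, mean fragment length, indel rate."""
    L = rs.read_length
    tl = 10
    genome = np.concatenate([model.chromosomes[c] for c in rs.chrom_names])
    intronic = np.concatenate(
        [(~model.region_masks(c)[0]) & model.region_masks(c)[1] for c in rs.chrom_names]
    )
    nontail_bases = nontail_mm = tail_bases = tail_mm = 0
    intr = tot = 0
    for rows, cols, gpos in iter_aligned_bases(rs):
        mm = rs.seqs[rows, cols] != genome[gpos]
        deg = rs.degraded[rows]
        rev = rs.is_reverse[rows]
        in_tail = deg & np.where(rev, cols < tl, cols >= L - tl)
        nontail_bases += int((~in_tail).sum())
        nontail_mm += int(mm[~in_tail].sum())
        tail_bases += int(in_tail.sum())
        tail_mm += int(mm[in_tail].sum())
        intr += int(intronic[gpos].sum())
        tot += gpos.size
    return {
        "substitution_rate_nontail": nontail_mm / nontail_bases if nontail_bases else 0.0,
        "substitution_rate_tail": tail_mm / tail_bases if tail_bases else 0.0,
        "intronic_base_fraction": intr / tot if tot else 0.0,
        "degraded_read_fraction": float(rs.degraded.mean()) if rs.n_mates else 0.0,
        "mean_fragment_length": float(rs.frag_len.mean()) if rs.frag_len.size else 0.0,
        "indel_rate": len(rs.indel_events) / rs.transcript_bases if rs.transcript_bases else 0.0,
        "n_mates": rs.n_mates,
        "aligned_bases": tot,
        "nontail_bases": nontail_bases,
        "tail_bases": tail_bases,
        "n_indel_events": len(rs.indel_events),
        "transcript_bases": rs.transcript_bases,
    }


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_fastq(rs: ReadSet, path1: str, path2: str) -> None:
    """Paired FASTQ; reverse-strand mates are reverse-complemented and their
    qualities reversed so files reflect the sequencing orientation."""
    L = rs.read_length
    hi, lo = "I", "#"
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in range(rs.n_pairs):
            for k, fh in ((0, f1), (1, f2)):
                i = 2 * p + k
                codes = rs.seqs[i]
                qual = [hi] * L
                if rs.degraded[i]:
                    for j in range(L - 10, L):
                        qual[j] = lo  # sequencing-orientation tail
                if rs.is_reverse[i]:
                    s = decode(_seq.revcomp(codes))
                else:
                    s = decode(codes)
                fh.write(f"@sim{p}/{k + 1}\n{s}\n+\n{''.join(qual)}\n")


def write_truth_sam(rs: ReadSet, model: GenomeModel, path: str) -> None:
    """Truth alignments as SAM with XE (error count) and XT (e/i) tags."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": int(model.chrom_lengths[c])} for c in rs.chrom_names],
    }
    exonic = {c: model.region_masks(c)[0] for c in rs.chrom_names}
    mate1_is_left = getattr(rs, "mate1_is_left", np.ones(rs.n_pairs, dtype=bool))
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for p in range(rs.n_pairs):
            idx = (2 * p, 2 * p + 1) if mate1_is_left[p] else (2 * p + 1, 2 * p)
            recs = []
            for nth, i in enumerate(idx):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"sim{p}"
                g, r, ln = rs.mate_segments(i)
                chrom = rs.chrom_names[rs.chrom_id[i]]
                flag = 0x1 | 0x2 | (0x40 if nth == 0 else 0x80)
                if rs.is_reverse[i]:
                    flag |= 0x10
                if rs.is_reverse[idx[1 - nth]]:
                    flag |= 0x20
                a.flag = flag
                a.reference_id = out.header.get_tid(chrom)
                a.reference_start = int(g[0])
                a.mapping_quality = 60
                a.cigartuples = rs.cigar(i)
                a.query_sequence = decode(rs.seqs[i])
                a.query_qualities = pysam.qualitystring_to_array("I" * rs.read_length)
                n_err = int(rs.err_index[i + 1] - rs.err_index[i])
                any_intron = bool(
                    np.any(~exonic[chrom][np.concatenate(
                        [np.arange(gs, gs + l) for gs, l in zip(g, ln)])])
                )
                a.set_tag("XE", n_err)
                a.set_tag("XT", "i" if any_intron else "e", value_type="A")
                recs.append((i, a))
            (i0, a0), (i1, a1) = recs
            a0.next_reference_id = a1.reference_id
            a0.next_reference_start = a1.reference_start
            a1.next_reference_id = a0.reference_id
            a1.next_reference_start = a0.reference_start
            lo = min(a0.reference_start, a1.reference_start)
            hi2 = max(a0.reference_end, a1.reference_end)
            tlen = hi2 - lo
            a0.template_length = tlen if a0.reference_start <= a1.reference_start else -tlen
            a1.template_length = -a0.template_length
            out.write(a0)
            out.write(a1)
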