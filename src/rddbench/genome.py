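"""Synthetic reference genome with transcript models and planted repeat structure.

The generator builds a desk-scale surrogate for a real annotated genome: an
order-1 Markov background sequence, non-overlapping transcript models
(exons/introns), processed-pseudogene copies (spliced, slightly divergent),
"duplicon" copies of transcript sequence at configurable identity (the
substrate for homology and misalignment analyses), and homopolymer runs.
Every planted element is recorded, so uniqueness, pseudogene, junction and
homopolymer filters downstream have exact ground truth.

Coordinates are 0-based half-open internally; GTF output is 1-based
inclusive and BED output 0-based half-open, per the format conventions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pyfaidx

from . import _seq
from ._seq import encode, decode


class GenomeConfigError(ValueError):
    """Raised when a genome configuration cannot be realised."""


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


@dataclass
class Transcript:
    id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]  # sorted, disjoint, half-open genomic intervals
    is_pseudogene_parent: bool = False

    def __post_init__(self):
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if not (s0 < e0 <= s1 < e1):
                raise ValueError(f"exons of {self.id} not sorted/disjoint")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span_length(self) -> int:
        return self.end - self.start


@dataclass
class DupliconRecord:
    """A planted homologous copy: target is a divergent copy of source."""

    source: GenomicInterval
    target: GenomicInterval
    identity: float
    divergent_offsets: np.ndarray  # offsets (within the interval) where bases differ


@dataclass
class GenomeConfig:
    genome_size: int = 1_000_000
    n_chromosomes: int = 2
    gc_content: float = 0.41
    markov_persistence: float = 0.15  # probability the next base repeats the last
    n_transcripts: int = 100
    exons_per_transcript: tuple[int, int] = (4, 8)
    exon_length: tuple[int, int] = (150, 300)
    intron_length: tuple[int, int] = (200, 1500)
    n_duplicons: int = 10
    duplicon_length: int = 500
    duplicon_identity: float = 0.98
    n_pseudogenes: int = 5
    pseudogene_divergence: tuple[float, float] = (0.01, 0.03)
    n_planted_homopolymers: int = 30
    homopolymer_min_len: int = 5
    homopolymer_max_len: int = 12


@dataclass
class GenomeModel:
    chromosomes: dict[str, np.ndarray]  # name -> uint8 base codes
    transcripts: list[Transcript]
    duplicons: list[DupliconRecord] = field(default_factory=list)
    pseudogenes: list[GenomicInterval] = field(default_factory=list)
    homopolymers: list[GenomicInterval] = field(default_factory=list)
    config: GenomeConfig | None = None

    def __post_init__(self):
        self._mask_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chromosomes)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: seq.size for c, seq in self.chromosomes.items()}

    @property
    def repeats(self) -> list[GenomicInterval]:
        """Planted repetitive elements: duplicon targets plus pseudogenes."""
        return [d.target for d in self.duplicons] + list(self.pseudogenes)

    def sequence(self, chrom: str, start: int, end: int) -> np.ndarray:
        seq = self.chromosomes[chrom]
        if not (0 <= start <= end <= seq.size):
            raise IndexError(f"{chrom}:{start}-{end} out of bounds")
        return seq[start:end]

    def base(self, chrom: str, pos: int) -> str:
        return _seq.BASES[self.chromosomes[chrom][pos]]

    def region_masks(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(exonic, transcribed) boolean masks over the chromosome."""
        if chrom not in self._mask_cache:
            n = self.chromosomes[chrom].size
            exonic = np.zeros(n, dtype=bool)
            transcribed = np.zeros(n, dtype=bool)
            for t in self.transcripts:
                if t.chrom != chrom:
                    continue
                transcribed[t.start : t.end] = True
                for s, e in t.exons:
                    exonic[s:e] = True
            self._mask_cache[chrom] = (exonic, transcribed)
        return self._mask_cache[chrom]

    def validate(self) -> None:
        lengths = self.chrom_lengths
        for iv in self.repeats + self.homopolymers:
            if iv.end > lengths[iv.chrom]:
                raise ValueError(f"interval {iv} exceeds chromosome bounds")
        for t in self.transcripts:
            if t.end > lengths[t.chrom]:
                raise ValueError(f"transcript {t.id} exceeds chromosome bounds")


def _markov_sequence(n: int, gc: float, persistence: float, rng) -> np.ndarray:
    """Order-1 Markov chain: repeat the previous base with prob `persistence`,
    otherwise draw iid from the GC-balanced stationary distribution."""
    pi = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    iid = rng.choice(4, size=n, p=pi).astype(np.uint8)
    keep = rng.random(n) < persistence
    keep[0] = False
    idx = np.arange(n)
    idx[keep] = 0
    src = np.maximum.accumulate(idx)
    return iid[src]


def _draw_transcript_structure(cfg: GenomeConfig, rng) -> tuple[list[int], list[int]]:
    n_ex = int(rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1))
    ex = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_ex).tolist()
    iv = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, size=max(n_ex - 1, 0)).tolist()
    return ex, iv


def _mutate_exact(codes: np.ndarray, n_mut: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Copy with exactly n_mut positions changed to a different base."""
    out = codes.copy()
    if n_mut == 0:
        return out, np.zeros(0, dtype=np.int64)
    offs = np.sort(rng.choice(codes.size, size=n_mut, replace=False))
    out[offs] = (out[offs] + rng.integers(1, 4, size=n_mut).astype(np.uint8)) % 4
    return out, offs


def generate_genome(config: GenomeConfig, seed: int) -> GenomeModel:
    """Deterministically generate a GenomeModel from a config and seed."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB10C]))

    n_chrom = cfg.n_chromosomes
    base_len = cfg.genome_size // n_chrom
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    chrom_sizes = {c: base_len for c in chrom_names}
    chrom_sizes[chrom_names[-1]] += cfg.genome_size - base_len * n_chrom

    # --- draw element structures ---------------------------------------
    tx_structs = [_draw_transcript_structure(cfg, rng) for _ in range(cfg.n_transcripts)]
    tx_spans = [sum(ex) + sum(iv) for ex, iv in tx_structs]

    multi = [i for i, (ex, _) in enumerate(tx_structs) if len(ex) >= 2]
    if cfg.n_pseudogenes > 0 and not multi:
        raise GenomeConfigError("pseudogenes require multi-exon transcripts")
    pg_parents = [int(rng.choice(multi)) for _ in range(cfg.n_pseudogenes)]
    pg_lens = [sum(tx_structs[p][0]) for p in pg_parents]

    dup_sources = [int(rng.integers(cfg.n_transcripts)) for _ in range(cfg.n_duplicons)]
    dup_lens = [min(cfg.duplicon_length, tx_spans[s]) for s in dup_sources]

    hp_lens = rng.integers(
        cfg.homopolymer_min_len, cfg.homopolymer_max_len + 1, size=cfg.n_planted_homopolymers
    ).tolist()

    blocks: list[tuple[str, int, int]] = []  # (kind, index, length)
    blocks += [("tx", i, l) for i, l in enumerate(tx_spans)]
    blocks += [("pg", i, l) for i, l in enumerate(pg_lens)]
    blocks += [("dup", i, l) for i, l in enumerate(dup_lens)]
    blocks += [("hp", i, l) for i, l in enumerate(hp_lens)]

    total = sum(l for _, _, l in blocks)
    if total > cfg.genome_size:
        raise GenomeConfigError(
            f"annotated elements need {total} bases but the genome has only "
            f"{cfg.genome_size}; shrink counts/lengths or grow the genome"
        )

    # --- place blocks: balance across chromosomes, stick-break the gaps --
    order = rng.permutation(len(blocks))
    per_chrom: dict[str, list[tuple[str, int, int]]] = {c: [] for c in chrom_names}
    free = dict(chrom_sizes)
    for bi in order:
        kind, idx, length = blocks[bi]
        target = max(chrom_names, key=lambda c: free[c])
        if free[target] < length:
            raise GenomeConfigError("cannot pack annotated elements into chromosomes")
        per_chrom[target].append((kind, idx, length))
        free[target] -= length

    placements: dict[tuple[str, int], tuple[str, int]] = {}  # (kind, idx) -> (chrom, start)
    for c in chrom_names:
        blist = per_chrom[c]
        nb = len(blist)
        gaps = rng.multinomial(free[c], np.full(nb + 1, 1.0 / (nb + 1)))
        pos = 0
        for g, (kind, idx, length) in zip(gaps, blist):
            pos += int(g)
            placements[(kind, idx)] = (c, pos)
            pos += length

    # --- background sequence --------------------------------------------
    chroms = {
        c: _markov_sequence(chrom_sizes[c], cfg.gc_content, cfg.markov_persistence, rng)
        for c in chrom_names
    }

    # --- transcripts ------------------------------------------------------
    transcripts: list[Transcript] = []
    for i, (ex_lens, in_lens) in enumerate(tx_structs):
        chrom, start = placements[("tx", i)]
        exons = []
        pos = start
        for j, el in enumerate(ex_lens):
            exons.append((pos, pos + el))
            pos += el + (in_lens[j] if j < len(in_lens) else 0)
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts.append(Transcript(f"tx{i:04d}", chrom, strand, exons))

    # --- homopolymers (plant, then annotate all qualifying runs) ---------
    for i, length in enumerate(hp_lens):
        chrom, start = placements[("hp", i)]
        chroms[chrom][start : start + length] = rng.integers(4, dtype=np.uint8)

    # --- pseudogenes: spliced divergent copies of multi-exon transcripts --
    pseudogenes: list[GenomicInterval] = []
    for i, parent in enumerate(pg_parents):
        t = transcripts[parent]
        t.is_pseudogene_parent = True
        spliced = np.concatenate([chroms[t.chrom][s:e] for s, e in t.exons])
        div = rng.uniform(*cfg.pseudogene_divergence)
        copy, _ = _mutate_exact(spliced, int(round(div * spliced.size)), rng)
        chrom, start = placements[("pg", i)]
        chroms[chrom][start : start + copy.size] = copy
        pseudogenes.append(GenomicInterval(chrom, start, start + copy.size, f"pseudo_{t.id}"))

    # --- duplicons: contiguous divergent copies of transcript sequence ---
    duplicons: list[DupliconRecord] = []
    for i, src_tx in enumerate(dup_sources):
        t = transcripts[src_tx]
        length = dup_lens[i]
        src_start = t.start + int(rng.integers(0, t.span_length - length + 1))
        src_seq = chroms[t.chrom][src_start : src_start + length]
        n_mut = int(round((1 - cfg.duplicon_identity) * length))
        copy, offs = _mutate_exact(src_seq, n_mut, rng)
        chrom, start = placements[("dup", i)]
        chroms[chrom][start : start + length] = copy
        duplicons.append(
            DupliconRecord(
                source=GenomicInterval(t.chrom, src_start, src_start + length, f"dupsrc{i}"),
                target=GenomicInterval(chrom, start, start + length, f"dup{i}"),
                identity=1 - n_mut / length,
                divergent_offsets=offs,
            )
        )

    homopolymers = [
        GenomicInterval(c, s, e, f"hp_{_seq.BASES[chroms[c][s]]}{e - s}")
        for c in chrom_names
        for s, e in _seq.run_length_runs(chroms[c], cfg.homopolymer_min_len)
    ]

    model = GenomeModel(
        chromosomes=chroms,
        transcripts=transcripts,
        duplicons=duplicons,
        pseudogenes=pseudogenes,
        homopolymers=homopolymers,
        config=cfg,
    )
    model.validate()
    return model


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _iv_to_json(iv: GenomicInterval) -> dict:
    return {"chrom": iv.chrom, "start": iv.start, "end": iv.end, "label": iv.label}


def _iv_from_json(d: dict) -> GenomicInterval:
    return GenomicInterval(d["chrom"], d["start"], d["end"], d.get("label", ""))


def write_annotations(model: GenomeModel, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA/GTF/BED (+ a JSON sidecar for exact reload) to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "genome.fa",
        "gtf": out / "transcripts.gtf",
        "repeats": out / "repeats.bed",
        "duplicons": out / "duplicons.bed",
        "homopolymers": out / "homopolymers.bed",
        "model": out / "model.json",
    }

    with open(paths["fasta"], "w") as fh:
        for chrom, codes in model.chromosomes.items():
            fh.write(f">{chrom}\n")
            s = decode(codes)
            for i in range(0, len(s), 70):
                fh.write(s[i : i + 70] + "\n")

    with open(paths["gtf"], "w") as fh:
        for t in model.transcripts:
            attrs = (
                f'gene_id "{t.id}"; transcript_id "{t.id}"; '
                f'pseudogene "false"; pseudogene_parent "{str(t.is_pseudogene_parent).lower()}";'
            )
            for s, e in t.exons:
                fh.write(
                    f"{t.chrom}\trddbench\texon\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
                )
        for pg in model.pseudogenes:
            attrs = (
                f'gene_id "{pg.label}"; transcript_id "{pg.label}"; '
                f'pseudogene "true"; pseudogene_parent "false";'
            )
            fh.write(
                f"{pg.chrom}\trddbench\texon\t{pg.start + 1}\t{pg.end}\t.\t+\t.\t{attrs}\n"
            )

    def _write_bed(path: Path, ivs: list[GenomicInterval]) -> None:
        with open(path, "w") as fh:
            for iv in sorted(ivs, key=lambda v: (v.chrom, v.start)):
                name = iv.label or "."
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")

    _write_bed(paths["repeats"], model.repeats)
    _write_bed(paths["duplicons"], [d.target for d in model.duplicons])
    _write_bed(paths["homopolymers"], model.homopolymers)

    sidecar = {
        "config": asdict(model.config) if model.config else None,
        "transcripts": [
            {
                "id": t.id,
                "chrom": t.chrom,
                "strand": t.strand,
                "exons": [list(e) for e in t.exons],
                "is_pseudogene_parent": t.is_pseudogene_parent,
            }
            for t in model.transcripts
        ],
        "duplicons": [
            {
                "source": _iv_to_json(d.source),
                "target": _iv_to_json(d.target),
                "identity": d.identity,
                "divergent_offsets": d.divergent_offsets.tolist(),
            }
            for d in model.duplicons
        ],
        "pseudogenes": [_iv_to_json(p) for p in model.pseudogenes],
        "homopolymers": [_iv_to_json(h) for h in model.homopolymers],
    }
    with open(paths["model"], "w") as fh:
        json.dump(sidecar, fh, sort_keys=True, indent=1)
    return paths


def read_gtf(path: str | Path) -> list[Transcript]:
    """Read exon records from a GTF written by write_annotations."""
    exons: dict[str, list] = {}
    meta: dict[str, tuple[str, str, bool]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if f[2] != "exon":
                continue
            attrs = dict(
                (kv.split(" ", 1)[0], kv.split(" ", 1)[1].strip('"'))
                for kv in (x.strip() for x in f[8].split(";"))
                if " " in kv
            )
            tid = attrs["transcript_id"]
            exons.setdefault(tid, []).append((int(f[3]) - 1, int(f[4])))
            meta[tid] = (f[0], f[6], attrs.get("pseudogene_parent") == "true")
    out = []
    for tid, ex in exons.items():
        chrom, strand, is_parent = meta[tid]
        out.append(Transcript(tid, chrom, strand, sorted(ex), is_parent))
    return out


def load_genome(indir: str | Path) -> GenomeModel:
    """Reload a GenomeModel from a directory written by write_annotations."""
    indir = Path(indir)
    fa = pyfaidx.Fasta(str(indir / "genome.fa"))
    chroms = {name: encode(str(fa[name][:])) for name in fa.keys()}
    with open(indir / "model.json") as fh:
        sc = json.load(fh)
    transcripts = [
        Transcript(t["id"], t["chrom"], t["strand"], [tuple(e) for e in t["exons"]],
                   t["is_pseudogene_parent"])
        for t in sc["transcripts"]
    ]
    duplicons = [
        DupliconRecord(
            source=_iv_from_json(d["source"]),
            target=_iv_from_json(d["target"]),
            identity=d["identity"],
            divergent_offsets=np.asarray(d["divergent_offsets"], dtype=np.int64),
        )
        for d in sc["duplicons"]
    ]
    cfg = GenomeConfig(**{**sc["config"],
                          **{k: tuple(v) for k, v in sc["config"].items()
                             if isinstance(v, list)}}) if sc.get("config") else None
    model = GenomeModel(
        chromosomes=chroms,
        transcripts=transcripts,
        duplicons=duplicons,
        pseudogenes=[_iv_from_json(p) for p in sc["pseudogenes"]],
        homopolymers=[_iv_from_json(h) for h in sc["homopolymers"]],
        config=cfg,
    )
    model.validate()
    return model
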