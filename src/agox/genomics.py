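"""Transcript models, exon-aware splicing, and genomic file readers.

Coordinates are 0-based half-open throughout.  Exons of a
:class:`TranscriptModel` are stored in transcript orientation (5'->3'),
i.e. in descending genome order for minus-strand transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnnotationError, InputError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TranscriptModel:
    """A spliced transcript with its annotated stop-codon position.

    Parameters
    ----------
    transcript_id, gene_id : str
        Identifiers; transcript ids must be unique within an annotation.
    chrom : str
    strand : str
        ``"+"`` or ``"-"``.
    exons : list of (start, end)
        Genome intervals in transcript orientation (5'->3').
    cds_end_tx : int
        Transcript coordinate of the first base of the annotated stop codon.
    mrna_seq : str, optional
        Spliced sense-strand sequence; filled by :func:`splice_transcript`.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds_end_tx: int
    mrna_seq: str | None = None
    coord_map: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError(f"{self.transcript_id}: empty exon [{s},{e})")
        genome_order = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(genome_order, genome_order[1:]):
            if s2 < e1:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")

    @property
    def tx_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def validate_stop(self) -> None:
        """Check the codon at ``cds_end_tx`` is a canonical stop."""
        if self.mrna_seq is None:
            raise AnnotationError(f"{self.transcript_id}: mRNA not spliced yet")
        codon = self.mrna_seq[self.cds_end_tx : self.cds_end_tx + 3].upper()
        if codon not in STOP_CODONS:
            raise AnnotationError(
                f"{self.transcript_id}: codon at cds_end_tx is {codon!r}, not a stop"
            )


def splice_transcript(
    genome: dict[str, str], model: TranscriptModel
) -> tuple[str, np.ndarray]:
    """Build the mature mRNA and its transcript->genome coordinate map.

    Returns the spliced sense-strand sequence and an integer array
    ``coord_map`` with ``coord_map[i]`` the genome position of transcript
    base ``i``.  Minus-strand exons are reverse-complemented.  The model's
    ``mrna_seq`` and ``coord_map`` fields are filled in place.
    """
    try:
        chrom_seq = genome[model.chrom]
    except KeyError:
        raise AnnotationError(f"{model.transcript_id}: unknown chrom {model.chrom}")
    pieces: list[str] = []
    coords: list[np.ndarray] = []
    for s, e in model.exons:
        if s < 0 or e > len(chrom_seq):
            raise AnnotationError(
                f"{model.transcript_id}: exon [{s},{e}) outside chrom of "
                f"length {len(chrom_seq)}"
            )
        block = chrom_seq[s:e]
        if model.strand == "+":
            pieces.append(block)
            coords.append(np.arange(s, e))
        else:
            pieces.append(reverse_complement(block))
            coords.append(np.arange(e - 1, s - 1, -1))
    seq = "".join(pieces)
    coord_map = np.concatenate(coords) if coords else np.empty(0, dtype=int)
    model.mrna_seq = seq
    model.coord_map = coord_map
    return seq, coord_map


def genome_intervals_of(
    model: TranscriptModel, tx_start: int, tx_end: int
) -> list[tuple[int, int]]:
    """Project a transcript interval onto the genome as merged intervals.

    The result is a list of 0-based half-open genome intervals, sorted by
    genome coordinate, covering exactly the exonic bases of
    ``[tx_start, tx_end)``.
    """
    if model.coord_map is None:
        raise AnnotationError(f"{model.transcript_id}: splice before projecting")
    positions = model.coord_map[tx_start:tx_end]
    if positions.size == 0:
        return []
    pos = np.sort(positions)
    breaks = np.where(np.diff(pos) != 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [pos.size - 1]))
    return [(int(pos[a]), int(pos[b]) + 1) for a, b in zip(starts, ends)]


class ConservationTrack:
    """Sparse per-base conservation scores in [0, 1], e.g. PhastCons.

    Internally a ``chrom -> {position: score}`` mapping; positions 0-based.
    """

    def __init__(self, scores: dict[str, dict[int, float]] | None = None):
        self.scores: dict[str, dict[int, float]] = scores or {}

    def add(self, chrom: str, pos: int, score: float) -> None:
        if not 0.0 <= score <= 1.0:
            raise InputError(f"track score {score} at {chrom}:{pos} outside [0,1]")
        self.scores.setdefault(chrom, {})[pos] = score

    def values_over(self, chrom: str, intervals: list[tuple[int, int]]) -> np.ndarray:
        """Scores over the union of intervals; NaN where the track is absent."""
        chrom_scores = self.scores.get(chrom, {})
        out = []
        for s, e in intervals:
            for p in range(s, e):
                out.append(chrom_scores.get(p, np.nan))
        return np.asarray(out, dtype=float)

    @classmethod
    def from_bedgraph(cls, path) -> "ConservationTrack":
        track = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("track", "#", "browser")):
                    continue
                chrom, start, end, value = line.split("\t")
                start, end, value = int(start), int(end), float(value)
                if not 0.0 <= value <= 1.0:
                    raise InputError(f"bedGraph value {value} outside [0,1]")
                chrom_scores = track.scores.setdefault(chrom, {})
                for p in range(start, end):
                    chrom_scores[p] = value
        return track

    @classmethod
    def from_bigwig(cls, path) -> "ConservationTrack":
        import pyBigWig  # optional dependency

        track = cls()
        bw = pyBigWig.open(str(path))
        try:
            for chrom, length in bw.chroms().items():
                vals = bw.values(chrom, 0, length, numpy=True)
                idx = np.where(~np.isnan(vals))[0]
                chrom_scores = track.scores.setdefault(chrom, {})
                for p in idx:
                    chrom_scores[int(p)] = float(vals[p])
        finally:
            bw.close()
        return track

    @classmethod
    def from_file(cls, path) -> "ConservationTrack":
        p = str(path)
        if p.endswith((".bw", ".bigwig", ".bigWig")):
            return cls.from_bigwig(path)
        return cls.from_bedgraph(path)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into a name -> sequence dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path, records: list[tuple[str, str]], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _tx_coord_of_genome_pos(model: TranscriptModel, gpos: int) -> int:
    """Transcript coordinate of a genome position (must be exonic)."""
    offset = 0
    for s, e in model.exons:
        if s <= gpos < e:
            if model.strand == "+":
                return offset + (gpos - s)
            return offset + (e - 1 - gpos)
        offset += e - s
    raise AnnotationError(f"{model.transcript_id}: position {gpos} not exonic")


def read_bed12(path) -> list[TranscriptModel]:
    """Read a BED12 annotation into transcript models.

    The BED name field is used as ``transcript_id`` (``gene_id`` defaults to
    it, or to the part before the first ``|`` when the name is
    ``transcript|gene``).  ``thickStart``/``thickEnd`` delimit the CDS
    including the stop codon, per UCSC convention.
    """
    models = []
    seen: set[str] = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise InputError(f"expected 12 BED columns, got {len(f)}")
            chrom, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            block_count = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != block_count or len(starts) != block_count:
                raise InputError(f"{name}: blockCount mismatch")
            exons_genome = [
                (chrom_start + st, chrom_start + st + sz)
                for st, sz in zip(starts, sizes)
            ]
            exons = exons_genome if strand == "+" else exons_genome[::-1]
            if "|" in name:
                tid, gid = name.split("|", 1)
            else:
                tid = gid = name
            if tid in seen:
                raise InputError(f"duplicate transcript id {tid!r}")
            seen.add(tid)
            model = TranscriptModel(tid, gid, chrom, strand, exons, cds_end_tx=0)
            # first base of the stop codon in transcript orientation
            stop_first = thick_end - 3 if strand == "+" else thick_start + 2
            model.cds_end_tx = _tx_coord_of_genome_pos(model, stop_first)
            models.append(model)
    return models


def read_gtf(path) -> list[TranscriptModel]:
    """Read a GTF annotation (exon + stop_codon features) via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    exons: dict[str, list] = {}
    stops: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "stop_codon"):
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        meta[tid] = (feat.seqid, feat.strand, gid)
        target = exons if feat.featuretype == "exon" else stops
        target.setdefault(tid, []).append((feat.start - 1, feat.end))  # to 0-based
    models = []
    for tid, ex in exons.items():
        if tid not in stops:
            continue
        chrom, strand, gid = meta[tid]
        ex_sorted = sorted(ex)
        exon_list = ex_sorted if strand == "+" else ex_sorted[::-1]
        model = TranscriptModel(tid, gid, chrom, strand, exon_list, cds_end_tx=0)
        stop_parts = sorted(stops[tid])
        stop_first = stop_parts[0][0] if strand == "+" else stop_parts[-1][1] - 1
        model.cds_end_tx = _tx_coord_of_genome_pos(model, stop_first)
        models.append(model)
    return models


def read_annotation(path) -> list[TranscriptModel]:
    p = str(path)
    if p.endswith((".gtf", ".gff")):
        return read_gtf(path)
    return read_bed12(path)
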