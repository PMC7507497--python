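"""Detection and conservation scoring of translational-readthrough regions.

A readthrough (TR) region is the mature-mRNA interval between a
transcript's annotated stop codon and the next in-frame stop codon,
exclusive of both stops.  Under this convention the AGO1 extension is 33
codons = 99 nt.  Regions are scored by the mean of a per-base
conservation track (e.g. PhastCons) over their genomic footprint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnnotationError, InputError
from .genomics import (
    STOP_CODONS,
    ConservationTrack,
    TranscriptModel,
    genome_intervals_of,
    splice_transcript,
)

#: standard genetic code, indexed by uppercase codon
from Bio.Data.CodonTable import standard_dna_table as _TABLE

STATUS_OK = "ok"
STATUS_NO_STOP = "no_downstream_stop"
STATUS_LOW_COV = "low_coverage"


@dataclass
class ReadthroughRegion:
    """Candidate C-terminal extension of one transcript."""

    transcript_id: str
    tx_interval: tuple[int, int]
    genome_intervals: list[tuple[int, int]] = field(default_factory=list)
    length_nt: int = 0
    mean_score: float | None = None
    coverage: float | None = None
    status: str = STATUS_OK

    @property
    def ok(self) -> bool:
        return self.status == STATUS_OK


def find_readthrough_region(model: TranscriptModel) -> ReadthroughRegion:
    """Scan codons after the annotated stop for the next in-frame stop.

    The region starts at the first base after the annotated stop codon and
    ends immediately before the first downstream TAA/TAG/TGA read in the
    annotated frame.  If no stop occurs before the transcript end, the
    region extends to the last complete codon and the status is
    ``no_downstream_stop``.
    """
    seq = model.mrna_seq
    if seq is None:
        raise AnnotationError(f"{model.transcript_id}: mRNA not spliced")
    if len(seq) < model.cds_end_tx + 3:
        raise AnnotationError(
            f"{model.transcript_id}: mRNA ends before the annotated stop codon"
        )
    model.validate_stop()
    start = model.cds_end_tx + 3
    seq_u = seq.upper()
    pos = start
    status = STATUS_NO_STOP
    while pos + 3 <= len(seq_u):
        if seq_u[pos : pos + 3] in STOP_CODONS:
            status = STATUS_OK
            break
        pos += 3
    end = pos
    region = ReadthroughRegion(
        transcript_id=model.transcript_id,
        tx_interval=(start, end),
        length_nt=end - start,
        status=status,
    )
    if model.coord_map is not None:
        region.genome_intervals = genome_intervals_of(model, start, end)
    return region


def scan_post_stop_sequence(seq: str) -> tuple[ReadthroughRegion, str | None, str]:
    """Run the region scanner on a sequence downstream of an annotated stop.

    Builds a minimal one-exon transcript (start codon, annotated stop,
    then ``seq``), scans it, and returns the region, the terminating stop
    codon (``None`` when no downstream stop exists), and the region's
    nucleotide sequence.  Convenient for worked examples such as the
    102-nt sequence appended to the AGO1 stop codon in the AGO1x construct.
    """
    mrna = "ATG" + "TGA" + seq.upper()
    model = TranscriptModel("query", "query", "chrQ", "+", [(0, len(mrna))], 3)
    splice_transcript({"chrQ": mrna}, model)
    region = find_readthrough_region(model)
    _, end = region.tx_interval
    stop = mrna[end : end + 3] if region.status == STATUS_OK else None
    return region, stop, region_sequence(model, region)


def region_sequence(model: TranscriptModel, region: ReadthroughRegion) -> str:
    s, e = region.tx_interval
    return model.mrna_seq[s:e]


def mean_conservation(
    region: ReadthroughRegion,
    chrom: str,
    track: ConservationTrack,
    min_coverage: float = 0.8,
) -> ReadthroughRegion:
    """Score a region by the mean track value over its covered bases.

    Positions absent from the track are excluded from the mean, not imputed
    as zero.  If fewer than ``min_coverage`` of the region's bases carry a
    value (or the region is empty) the status becomes ``low_coverage`` and
    the mean is left missing.
    """
    if region.status != STATUS_OK:
        return region
    values = track.values_over(chrom, region.genome_intervals)
    if values.size == 0:
        region.coverage = 0.0
        region.status = STATUS_LOW_COV
        return region
    covered = ~np.isnan(values)
    region.coverage = float(covered.mean())
    if region.coverage < min_coverage:
        region.status = STATUS_LOW_COV
        region.mean_score = None
    else:
        region.mean_score = float(values[covered].mean())
    return region


def translate_extension(seq: str) -> str:
    """Translate a stop-free readthrough region with the standard code."""
    seq = seq.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise InputError(f"sequence length {len(seq)} not divisible by 3")
    aa = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            raise InputError(f"internal stop codon {codon} at nt {i}")
        aa.append(_TABLE.forward_table[codon])
    return "".join(aa)


def histogram_of_scores(
    scores: np.ndarray, bin_width: float = 0.05
) -> pd.DataFrame:
    """Proportion histogram of mean conservation scores on [0, 1]."""
    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(scores, bins=edges)
    props = counts / counts.sum() if counts.sum() else counts.astype(float)
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts,
         "proportion": props}
    )


def scan(
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
    track: ConservationTrack,
    min_coverage: float = 0.8,
    bin_width: float = 0.05,
    conserved_threshold: float = 0.5,
    highlight: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genome-wide TR-region scan: one row per transcript plus a histogram.

    Returns ``(region_table, histogram)``.  The histogram covers status-ok
    regions only and its proportions sum to 1.  ``conserved_threshold`` is a
    report-time cutoff marking "highly conserved" regions; ``highlight``
    flags named transcripts of interest in the report.
    """
    ids = [m.transcript_id for m in transcripts]
    if len(set(ids)) != len(ids):
        raise InputError("duplicate transcript ids in annotation")
    highlight = set(highlight or [])
    rows = []
    for model in transcripts:
        if model.mrna_seq is None:
            splice_transcript(genome, model)
        region = find_readthrough_region(model)
        if region.ok:
            region = mean_conservation(region, model.chrom, track, min_coverage)
        rows.append(
            {
                "transcript_id": model.transcript_id,
                "gene_id": model.gene_id,
                "status": region.status,
                "length_nt": region.length_nt,
                "coverage": region.coverage,
                "mean_score": region.mean_score,
                "highly_conserved": (
                    region.mean_score is not None
                    and region.mean_score >= conserved_threshold
                ),
                "highlighted": model.transcript_id in highlight,
                "genome_intervals": ";".join(
                    f"{s}-{e}" for s, e in region.genome_intervals
                ),
            }
        )
    table = pd.DataFrame(rows)
    ok_scores = table.loc[table.status == STATUS_OK, "mean_score"].to_numpy(float)
    if ok_scores.size == 0:
        warnings.warn("no status-ok regions; empty histogram")
    hist = histogram_of_scores(ok_scores, bin_width)
    return table, hist
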