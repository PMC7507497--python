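"""Frame-preservation analysis of multi-species readthrough alignments.

The codon frame is anchored to a reference species (the human sequence in
the motivating AGO1 example): columns where the reference is gapped belong
to no codon.  For each other species the module counts nonsense codons
(reference-frame codons spelling TAA/TAG/TGA with no gap), classifies
indel events by their length modulo 3, and reports whether the species'
reading frame is intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table as _TABLE

from .errors import InputError
from .genomics import STOP_CODONS

GAP = "-"


@dataclass
class SpeciesAlignment:
    """An aligned set of nucleotide sequences, one per species."""

    records: list[tuple[str, str]]
    reference: str | None = None

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("empty alignment")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise InputError(f"aligned lengths differ: {sorted(lengths)}")
        if self.reference is None:
            self.reference = self.records[0][0]
        names = [name for name, _ in self.records]
        if self.reference not in names:
            raise InputError(f"reference {self.reference!r} not in alignment")
        if len(set(names)) != len(names):
            raise InputError("duplicate species names")
        ref = self.get(self.reference).replace(GAP, "")
        if len(ref) % 3 != 0:
            raise InputError(
                f"reference gap-stripped length {len(ref)} not divisible by 3"
            )

    def get(self, species: str) -> str:
        for name, seq in self.records:
            if name == species:
                return seq
        raise KeyError(species)

    @property
    def species(self) -> list[str]:
        return [name for name, _ in self.records]

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    @classmethod
    def from_fasta(cls, path, reference: str | None = None) -> "SpeciesAlignment":
        from Bio import SeqIO

        records = [
            (rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(records, reference=reference)


@dataclass
class IndelEvent:
    species: str
    start_column: int
    length_nt: int
    kind: str  # "insertion" | "deletion"

    @property
    def frame_preserving(self) -> bool:
        return self.length_nt % 3 == 0


@dataclass
class FrameReport:
    """Per-species nonsense/indel summary of one alignment."""

    nonsense: dict[str, int]
    indels: dict[str, list[IndelEvent]]
    frame_intact: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frame_intact:
            self.frame_intact = {
                sp: self.nonsense[sp] == 0
                and all(ev.frame_preserving for ev in self.indels[sp])
                for sp in self.nonsense
            }

    @property
    def n_species_frame_intact(self) -> int:
        return sum(self.frame_intact.values())

    @property
    def total_nonsense(self) -> int:
        return sum(self.nonsense.values())

    @property
    def total_indels(self) -> int:
        return sum(len(v) for v in self.indels.values())


def reference_codon_columns(aln: SpeciesAlignment) -> list[tuple[int, int, int]]:
    """Column-index triplets of successive reference codons, 5'->3'.

    Columns where the reference carries a gap belong to no triplet.
    """
    ref = aln.get(aln.reference)
    cols = [i for i, c in enumerate(ref) if c != GAP]
    if len(cols) % 3 != 0:
        raise InputError("reference frame violated")
    return [tuple(cols[i : i + 3]) for i in range(0, len(cols), 3)]


def count_nonsense(aln: SpeciesAlignment) -> dict[str, int]:
    """Count reference-frame stop codons per species.

    A codon counts only when all three of its reference-frame columns are
    gap-free in the species; partially gapped codons are skipped rather
    than guessed.  The reference itself is counted the same way (expected
    zero for a valid readthrough region).
    """
    triplets = reference_codon_columns(aln)
    counts = {}
    for name, seq in aln.records:
        n = 0
        for (a, b, c) in triplets:
            codon = (seq[a] + seq[b] + seq[c]).upper()
            if GAP not in codon and codon in STOP_CODONS:
                n += 1
        counts[name] = n
    return counts


def classify_indels(aln: SpeciesAlignment) -> dict[str, list[IndelEvent]]:
    """Maximal gap runs per species relative to the reference.

    A deletion is a maximal run of columns where the species is gapped and
    the reference is not; an insertion the converse.  An event is
    frame-preserving iff its length is a multiple of 3.  The reference
    itself never has events.
    """
    ref = aln.get(aln.reference)
    events: dict[str, list[IndelEvent]] = {}
    for name, seq in aln.records:
        sp_events: list[IndelEvent] = []
        if name != aln.reference:
            state = None  # "deletion" | "insertion" | None
            run_start = 0
            for i in range(len(seq) + 1):
                if i < len(seq):
                    sp_gap, ref_gap = seq[i] == GAP, ref[i] == GAP
                    if sp_gap and not ref_gap:
                        col_state = "deletion"
                    elif ref_gap and not sp_gap:
                        col_state = "insertion"
                    else:
                        col_state = None
                else:
                    col_state = None
                if col_state != state:
                    if state is not None:
                        sp_events.append(
                            IndelEvent(name, run_start, i - run_start, state)
                        )
                    state = col_state
                    run_start = i
        events[name] = sp_events
    return events


def frame_report(aln: SpeciesAlignment) -> FrameReport:
    """Aggregate nonsense counts and indel events into a frame report."""
    return FrameReport(nonsense=count_nonsense(aln), indels=classify_indels(aln))


def translate_alignment(aln: SpeciesAlignment) -> list[tuple[str, str]]:
    """Codon-resolution amino-acid alignment in the reference frame.

    Per species: codons containing any gap render as ``-``, stop codons as
    ``*``, everything else by the standard genetic code.
    """
    triplets = reference_codon_columns(aln)
    out = []
    for name, seq in aln.records:
        aa = []
        for (a, b, c) in triplets:
            codon = (seq[a] + seq[b] + seq[c]).upper()
            if GAP in codon:
                aa.append(GAP)
            elif codon in STOP_CODONS:
                aa.append("*")
            else:
                aa.append(_TABLE.forward_table.get(codon, "X"))
        out.append((name, "".join(aa)))
    return out


def report_table(report: FrameReport):
    """Flatten a FrameReport to a per-species pandas DataFrame."""
    import pandas as pd

    rows = []
    for sp in report.nonsense:
        evs = report.indels[sp]
        rows.append(
            {
                "species": sp,
                "nonsense_count": report.nonsense[sp],
                "n_indels": len(evs),
                "indel_events": ";".join(
                    f"{e.kind}@{e.start_column}+{e.length_nt}" for e in evs
                ),
                "frame_intact": report.frame_intact[sp],
            }
        )
    return pd.DataFrame(rows)
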