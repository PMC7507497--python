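"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the statistical structure one analysis stage
assumes: a transcriptome whose readthrough regions carry planted
conservation, codon alignments with controlled substitution/nonsense/indel
injection, negative-binomial count matrices in which dsRNA-pulldown fold
changes track total-RNA fold changes except for a planted G/C-biased
subset, and 3D image stacks of ellipsoidal nuclei with nucleoli at a known
nucleolar:nucleoplasm intensity factor, plus punctate foci images.

All randomness flows from ``SimConfig.seed`` through one numpy Generator
stream per output, so identical configurations give byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AgoxError, ConfigurationError
from .genomics import (
    STOP_CODONS,
    ConservationTrack,
    TranscriptModel,
    genome_intervals_of,
    reverse_complement,
    splice_transcript,
    write_fasta,
)

_BASES = "ACGT"
_NON_STOP_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
]

# numbered substreams, one per output artifact
_STREAMS = {
    "transcriptome": 11,
    "msa": 12,
    "counts": 13,
    "stacks": 14,
    "foci": 15,
}


def _rng(config: "SimConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], config.seed])


@dataclass
class SimConfig:
    """All tunable parameters of the synthetic generators."""

    seed: int = 0

    # transcriptome
    n_transcripts: int = 100
    frac_conserved_tr: float = 0.05
    frac_no_downstream_stop: float = 0.02
    conserved_score_range: tuple[float, float] = (0.8, 1.0)
    background_score_range: tuple[float, float] = (0.0, 0.4)
    track_dropout: float = 0.02

    # multi-species alignment
    n_species: int = 20
    msa_n_codons: int = 33
    subst_rate: float = 0.02
    nonsense_injections: list[tuple[str, int]] = field(default_factory=list)
    indel_injections: list[tuple] = field(default_factory=list)

    # count matrices
    n_genes: int = 2000
    n_reps: int = 3
    nb_dispersion: float = 0.05
    frac_enriched: float = 0.01
    frac_depleted: float = 0.01
    enrichment_lfc_shift: float = 2.0
    gc_low: float = 0.4
    gc_high: float = 0.6
    lfc_sd: float = 0.5
    base_mean: float = 500.0
    base_mean_sigma: float = 0.5

    # image stacks
    n_cells: int = 20
    stack_shape: tuple[int, int, int] = (16, 256, 256)
    nucleolar_factor: float = 3.0
    noise_sd: float = 100.0
    noise_model: str = "gaussian"  # or "poisson"

    # foci images
    foci_per_cell: int | dict = 3
    foci_min_separation: float = 6.0
    foci_sigma: float = 1.5
    foci_amplitude: float = 8000.0

    def validate(self) -> None:
        for name in (
            "frac_conserved_tr",
            "frac_no_downstream_stop",
            "track_dropout",
            "frac_enriched",
            "frac_depleted",
            "gc_low",
            "gc_high",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0,1]")
        if self.frac_enriched + self.frac_depleted >= 1.0:
            raise ConfigurationError("frac_enriched + frac_depleted must be < 1")
        for name in ("conserved_score_range", "background_score_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(f"{name}=({lo},{hi}) invalid")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.nucleolar_factor <= 0:
            raise ConfigurationError("nucleolar_factor must be positive")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ConfigurationError(f"unknown noise model {self.noise_model!r}")


@dataclass
class TruthTables:
    """Ground truth recorded alongside each generated dataset."""

    conserved_tr_ids: set[str] = field(default_factory=set)
    no_downstream_stop_ids: set[str] = field(default_factory=set)
    true_mean_scores: dict[str, float] = field(default_factory=dict)
    tr_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    planted_indels: list[tuple] = field(default_factory=list)
    planted_nonsense: list[tuple[str, int]] = field(default_factory=list)

    enriched_ids: set[str] = field(default_factory=set)
    depleted_ids: set[str] = field(default_factory=set)
    true_lfc_total: pd.DataFrame | None = None

    true_nucleolar_factor: float | None = None
    true_masks: dict[str, np.ndarray] = field(default_factory=dict)
    true_assignment: dict[int, int] = field(default_factory=dict)

    true_foci_counts: dict[int, int] = field(default_factory=dict)
    foci_positions: dict[int, list[tuple[float, float]]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------


@dataclass
class SimTranscriptome:
    genome: dict[str, str]
    transcripts: list[TranscriptModel]
    bed_rows: list[str]
    track: ConservationTrack
    truth: TruthTables

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "annotation": outdir / "transcripts.bed",
            "track": outdir / "conservation.bedGraph",
            "truth": outdir / "truth_transcriptome.json",
        }
        write_fasta(paths["genome"], sorted(self.genome.items()))
        with open(paths["annotation"], "w") as fh:
            fh.write("\n".join(self.bed_rows) + "\n")
        with open(paths["track"], "w") as fh:
            for chrom in sorted(self.track.scores):
                for pos in sorted(self.track.scores[chrom]):
                    fh.write(
                        f"{chrom}\t{pos}\t{pos + 1}\t"
                        f"{self.track.scores[chrom][pos]:.6f}\n"
                    )
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "conserved_tr_ids": sorted(self.truth.conserved_tr_ids),
                    "no_downstream_stop_ids": sorted(
                        self.truth.no_downstream_stop_ids
                    ),
                    "true_mean_scores": self.truth.true_mean_scores,
                    "tr_intervals": {
                        k: [list(iv) for iv in v]
                        for k, v in self.truth.tr_intervals.items()
                    },
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        return paths


def _random_codons(rng: np.random.Generator, n: int) -> str:
    return "".join(
        _NON_STOP_CODONS[i] for i in rng.integers(0, len(_NON_STOP_CODONS), n)
    )


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _bed12_row(model: TranscriptModel, thick: tuple[int, int]) -> str:
    genome_exons = sorted(model.exons)
    chrom_start = genome_exons[0][0]
    chrom_end = genome_exons[-1][1]
    sizes = ",".join(str(e - s) for s, e in genome_exons)
    starts = ",".join(str(s - chrom_start) for s, e in genome_exons)
    name = f"{model.transcript_id}|{model.gene_id}"
    return "\t".join(
        [
            model.chrom,
            str(chrom_start),
            str(chrom_end),
            name,
            "0",
            model.strand,
            str(thick[0]),
            str(thick[1]),
            "0",
            str(len(genome_exons)),
            sizes,
            starts,
        ]
    )


def gen_transcriptome(config: SimConfig) -> SimTranscriptome:
    """Genome + BED12 annotation + conservation track with planted truth.

    Each transcript sits on its own chromosome with 1-3 exons, a CDS
    ending in a canonical stop, and a stop-free readthrough (TR) region
    followed (except for a configured fraction) by a downstream in-frame
    stop.  TR bases of planted conserved transcripts score in
    ``conserved_score_range``; all other exonic bases in
    ``background_score_range``.  A dropout fraction of exonic bases is
    omitted from the track.  Truth records the planted ids and the exact
    mean of emitted track values over each TR region.
    """
    config.validate()
    if config.n_transcripts < 1:
        raise ConfigurationError("n_transcripts must be >= 1")
    rng = _rng(config, "transcriptome")
    n_conserved = int(round(config.frac_conserved_tr * config.n_transcripts))
    n_nostop = int(round(config.frac_no_downstream_stop * config.n_transcripts))
    ids = [f"tx{i:04d}" for i in range(config.n_transcripts)]
    special = rng.choice(config.n_transcripts, n_conserved + n_nostop, replace=False)
    conserved = {ids[i] for i in special[:n_conserved]}
    nostop = {ids[i] for i in special[n_conserved:]}

    genome: dict[str, str] = {}
    transcripts: list[TranscriptModel] = []
    bed_rows: list[str] = []
    track = ConservationTrack()
    truth = TruthTables(conserved_tr_ids=conserved, no_downstream_stop_ids=nostop)

    for i, tid in enumerate(ids):
        gid = f"gene{i:04d}"
        chrom = f"chr{i:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        utr5 = _random_seq(rng, int(rng.integers(10, 31)))
        cds = "ATG" + _random_codons(rng, int(rng.integers(20, 51)))
        stop1 = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
        tr_len_codons = int(rng.integers(10, 41))
        tr = _random_codons(rng, tr_len_codons)
        if tid in nostop:
            tail = _random_seq(rng, int(rng.integers(0, 3)))  # incomplete codon
            mrna = utr5 + cds + stop1 + tr + tail
        else:
            stop2 = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
            utr3 = _random_seq(rng, int(rng.integers(5, 21)))
            mrna = utr5 + cds + stop1 + tr + stop2 + utr3
        cds_end_tx = len(utr5) + len(cds)
        tr_start_tx = cds_end_tx + 3
        tr_end_tx = tr_start_tx + len(tr)

        # split the mRNA into 1-3 exons separated by random introns; never
        # cut inside the annotated stop codon (keeps BED12 thick bounds
        # mapping to a genome-contiguous stop)
        n_exons = int(rng.integers(1, 4))
        allowed = np.setdiff1d(
            np.arange(1, len(mrna)), [cds_end_tx + 1, cds_end_tx + 2]
        )
        cuts = sorted(rng.choice(allowed, n_exons - 1, replace=False))
        exon_seqs = [
            mrna[a:b] for a, b in zip([0] + list(cuts), list(cuts) + [len(mrna)])
        ]
        pad = _random_seq(rng, 10)
        pieces = [pad]
        exons_layout: list[tuple[int, int]] = []
        pos = len(pad)
        for j, es in enumerate(exon_seqs):
            if j > 0:
                intron = _random_seq(rng, int(rng.integers(20, 101)))
                pieces.append(intron)
                pos += len(intron)
            pieces.append(es)
            exons_layout.append((pos, pos + len(es)))
            pos += len(es)
        pieces.append(_random_seq(rng, 10))
        chrom_seq = "".join(pieces)

        if strand == "-":
            L = len(chrom_seq)
            chrom_seq = reverse_complement(chrom_seq)
            exons = [(L - e, L - s) for s, e in exons_layout]  # tx orientation
        else:
            exons = exons_layout
        genome[chrom] = chrom_seq

        model = TranscriptModel(tid, gid, chrom, strand, exons, cds_end_tx)
        spliced, _ = splice_transcript(genome, model)
        if spliced != mrna:  # pragma: no cover - generator invariant
            raise AgoxError(f"{tid}: splice round-trip failed")
        transcripts.append(model)

        cds_intervals = genome_intervals_of(model, len(utr5), cds_end_tx + 3)
        thick = (min(s for s, _ in cds_intervals), max(e for _, e in cds_intervals))
        bed_rows.append(_bed12_row(model, thick))

        # conservation track over exonic bases, TR bases planted if conserved
        tr_positions = set()
        for s, e in genome_intervals_of(model, tr_start_tx, tr_end_tx):
            tr_positions.update(range(s, e))
        lo_b, hi_b = config.background_score_range
        lo_c, hi_c = config.conserved_score_range
        tr_scores = []
        for s, e in sorted(model.exons):
            for p in range(s, e):
                if rng.random() < config.track_dropout:
                    continue
                if tid in conserved and p in tr_positions:
                    score = round(float(rng.uniform(lo_c, hi_c)), 6)
                else:
                    score = round(float(rng.uniform(lo_b, hi_b)), 6)
                if p in tr_positions:
                    tr_scores.append(score)
                track.add(chrom, p, score)
        if tid not in nostop:
            truth.tr_intervals[tid] = genome_intervals_of(model, tr_start_tx, tr_end_tx)
            if tr_scores:
                truth.true_mean_scores[tid] = float(np.mean(tr_scores))

    return SimTranscriptome(genome, transcripts, bed_rows, track, truth)


# ---------------------------------------------------------------------------
# multi-species alignment
# ---------------------------------------------------------------------------

_SPECIES_POOL = [
    "chimp", "gorilla", "orangutan", "gibbon", "macaque", "baboon",
    "marmoset", "squirrel_monkey", "tarsier", "mouse_lemur", "bushbaby",
    "mouse", "rat", "guinea_pig", "rabbit", "cow", "pig", "dog", "cat",
    "horse", "elephant", "opossum", "platypus", "chicken", "zebra_finch",
    "lizard", "frog", "zebrafish",
]


@dataclass
class SimMSA:
    alignment: "SpeciesAlignment"
    truth: TruthTables

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "alignment": outdir / "tr_region.aln.fa",
            "truth": outdir / "truth_msa.json",
        }
        write_fasta(paths["alignment"], self.alignment.records)
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "planted_indels": [list(t) for t in self.truth.planted_indels],
                    "planted_nonsense": [
                        list(t) for t in self.truth.planted_nonsense
                    ],
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        return paths


def _substitute_no_stop(
    rng: np.random.Generator, seq: list[str], rate: float
) -> None:
    """Point substitutions at per-site probability `rate`, never creating a
    reference-frame stop codon (stops arise only by explicit injection)."""
    for i in range(len(seq)):
        if rng.random() >= rate:
            continue
        codon_start = 3 * (i // 3)
        options = []
        for b in _BASES:
            if b == seq[i]:
                continue
            codon = seq[codon_start:codon_start + 3]
            codon[i - codon_start] = b
            if "".join(codon) not in STOP_CODONS:
                options.append(b)
        if options:
            seq[i] = options[int(rng.integers(0, len(options)))]


def gen_msa(config: SimConfig, preset: str | None = None) -> SimMSA:
    """Codon alignment of a readthrough region across species.

    The reference ("human") is a random stop-free codon sequence.  Other
    species differ by point substitutions (which never create stops),
    explicitly injected nonsense codons, and injected indels.  The preset
    ``"tarsier_like"`` plants exactly one codon-aligned 3-nt deletion in
    the tarsier and nothing else, mimicking the conservation pattern of
    the AGO1 readthrough region.
    """
    config.validate()
    if config.n_species < 2:
        raise ConfigurationError("n_species must be >= 2")
    rng = _rng(config, "msa")
    n_codons = config.msa_n_codons
    nonsense = list(config.nonsense_injections)
    indels = [tuple(t) for t in config.indel_injections]
    subst_rate = config.subst_rate

    names = ["human"] + _SPECIES_POOL[: config.n_species - 1]
    if preset == "tarsier_like":
        if "tarsier" not in names:
            raise ConfigurationError("tarsier_like preset needs >=10 species")
        nonsense = []
        codon = int(rng.integers(1, n_codons - 1))
        indels = [("tarsier", codon, 3, "deletion")]
    elif preset is not None:
        raise ConfigurationError(f"unknown preset {preset!r}")

    ref = _random_codons(rng, n_codons)
    rows: dict[str, list[str]] = {"human": list(ref)}
    for name in names[1:]:
        seq = list(ref)
        _substitute_no_stop(rng, seq, subst_rate)
        rows[name] = seq

    truth = TruthTables()

    # deletions first (they do not shift columns)
    insertions = []
    for inj in indels:
        species, start_codon, length_nt = inj[0], int(inj[1]), int(inj[2])
        kind = inj[3] if len(inj) > 3 else "deletion"
        if species not in rows or species == "human":
            raise ConfigurationError(f"cannot inject indel into {species!r}")
        col = 3 * start_codon
        if kind == "deletion":
            if col + length_nt > 3 * n_codons:
                raise ConfigurationError("deletion extends past alignment end")
            for c in range(col, col + length_nt):
                rows[species][c] = "-"
            truth.planted_indels.append((species, col, length_nt, "deletion"))
        elif kind == "insertion":
            insertions.append((species, col, length_nt))
        else:
            raise ConfigurationError(f"unknown indel kind {kind!r}")

    for species, codon_idx in nonsense:
        if species not in rows:
            raise ConfigurationError(f"unknown species {species!r}")
        col = 3 * int(codon_idx)
        target = rows[species][col:col + 3]
        if "-" in target:
            raise ConfigurationError(
                f"nonsense injection at gapped codon {codon_idx} of {species}"
            )
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
        rows[species][col:col + 3] = list(stop)
        truth.planted_nonsense.append((species, int(codon_idx)))

    # insertions last; they shift every column at or right of their site
    for species, col, length_nt in sorted(insertions, reverse=True):
        ins = [
            _BASES[i] for i in rng.integers(0, 4, length_nt)
        ]
        for name in rows:
            if name == species:
                rows[name][col:col] = ins
            else:
                rows[name][col:col] = ["-"] * length_nt
    for species, col, length_nt in insertions:
        shift = sum(
            ln for sp2, c2, ln in insertions if c2 < col
        )
        truth.planted_indels.append((species, col + shift, length_nt, "insertion"))

    from .msa import SpeciesAlignment  # deferred to avoid a module cycle

    records = [(name, "".join(rows[name])) for name in names]
    aln = SpeciesAlignment(records, reference="human")
    return SimMSA(aln, truth)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


@dataclass
class SimCounts:
    total: pd.DataFrame
    dsrna: pd.DataFrame
    samples: pd.DataFrame
    gene_gc: pd.Series
    truth: TruthTables

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "total": outdir / "total_counts.tsv",
            "dsrna": outdir / "dsrna_counts.tsv",
            "samples": outdir / "samples.tsv",
            "gc": outdir / "gene_gc.tsv",
            "truth": outdir / "truth_counts.json",
        }
        self.total.to_csv(paths["total"], sep="\t", index_label="gene_id")
        self.dsrna.to_csv(paths["dsrna"], sep="\t", index_label="gene_id")
        self.samples.to_csv(paths["samples"], sep="\t", index=False)
        self.gene_gc.rename("gc").to_csv(paths["gc"], sep="\t", index_label="gene_id")
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "enriched_ids": sorted(self.truth.enriched_ids),
                    "depleted_ids": sorted(self.truth.depleted_ids),
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        return paths


def _nb_counts(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Negative-binomial draws with variance mu + mu^2 * dispersion."""
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    return rng.poisson(lam)


def gen_counts(config: SimConfig) -> SimCounts:
    """Paired total-RNA and dsRNA-pulldown count matrices with planted calls.

    For background genes the expected dsRNA log2 fold change (mutant vs
    control) equals the total-RNA fold change; planted enriched (depleted)
    genes have it shifted by +(-) ``enrichment_lfc_shift``, shared between
    mutant1 and mutant2.  Planted genes draw their G/C proportion around
    ``gc_high``, background around ``gc_low``.  Counts are
    negative-binomial (gamma-Poisson) around condition means.
    """
    config.validate()
    if config.n_reps < 2:
        raise ConfigurationError("n_reps must be >= 2 (fold-change SD undefined)")
    rng = _rng(config, "counts")
    n = config.n_genes
    genes = [f"gene{i:05d}" for i in range(n)]
    n_enr = int(round(config.frac_enriched * n))
    n_dep = int(round(config.frac_depleted * n))
    planted = rng.choice(n, n_enr + n_dep, replace=False)
    enriched = {genes[i] for i in planted[:n_enr]}
    depleted = {genes[i] for i in planted[n_enr:]}

    gc = np.clip(rng.normal(config.gc_low, 0.05, n), 0.05, 0.95)
    planted_mask = np.zeros(n, dtype=bool)
    planted_mask[planted] = True
    gc[planted_mask] = np.clip(
        rng.normal(config.gc_high, 0.05, planted_mask.sum()), 0.05, 0.95
    )

    base = np.exp(rng.normal(np.log(config.base_mean), config.base_mean_sigma, n))
    base = np.clip(base, 50.0, None)
    shift = np.zeros(n)
    shift[[i for i in range(n) if genes[i] in enriched]] = config.enrichment_lfc_shift
    shift[[i for i in range(n) if genes[i] in depleted]] = -config.enrichment_lfc_shift

    lfc_total = {m: rng.normal(0.0, config.lfc_sd, n) for m in ("mutant1", "mutant2")}

    cols: dict[str, dict[str, np.ndarray]] = {"total": {}, "dsrna": {}}
    sheet_rows = []
    for assay in ("total", "dsrna"):
        for cond in ("control", "mutant1", "mutant2"):
            if cond == "control":
                mu = base
            else:
                lfc = lfc_total[cond] + (shift if assay == "dsrna" else 0.0)
                mu = base * np.exp2(lfc)
            for r in range(1, config.n_reps + 1):
                name = f"{assay}_{cond}_r{r}"
                cols[assay][name] = _nb_counts(rng, mu, config.nb_dispersion)
                sheet_rows.append(
                    {"sample": name, "assay": assay, "condition": cond,
                     "replicate": r}
                )

    total = pd.DataFrame(cols["total"], index=genes)
    dsrna = pd.DataFrame(cols["dsrna"], index=genes)
    samples = pd.DataFrame(sheet_rows)
    truth = TruthTables(
        enriched_ids=enriched,
        depleted_ids=depleted,
        true_lfc_total=pd.DataFrame(lfc_total, index=genes),
    )
    return SimCounts(total, dsrna, samples, pd.Series(gc, index=genes), truth)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------


@dataclass
class SimStacks:
    dapi: np.ndarray
    nucleolin: np.ndarray
    signal: np.ndarray
    truth: TruthTables

    def write(self, outdir) -> dict[str, Path]:
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "dapi": outdir / "dapi.tif",
            "nucleolin": outdir / "nucleolin.tif",
            "signal": outdir / "signal.tif",
            "truth_nuclei": outdir / "truth_nuclei_labels.tif",
            "truth_nucleoli": outdir / "truth_nucleoli_labels.tif",
        }
        tifffile.imwrite(paths["dapi"], self.dapi)
        tifffile.imwrite(paths["nucleolin"], self.nucleolin)
        tifffile.imwrite(paths["signal"], self.signal)
        tifffile.imwrite(
            paths["truth_nuclei"], self.truth.true_masks["nuclei"].astype("uint16")
        )
        tifffile.imwrite(
            paths["truth_nucleoli"],
            self.truth.true_masks["nucleoli"].astype("uint16"),
        )
        return paths


_BG = {"dapi": 200.0, "nucleolin": 100.0, "signal": 100.0}
_NUCLEUS = {"dapi": 10000.0, "nucleolin": 300.0, "signal": 2000.0}
_NUCLEOLIN_BRIGHT = 8000.0


def _place_nuclei(
    rng: np.random.Generator, config: SimConfig
) -> list[tuple[float, float, float, float, float, float]]:
    """Ellipsoid parameters (cz, cy, cx, rz, ry, rx) on a jittered grid."""
    nz, ny, nx = config.stack_shape
    n = config.n_cells
    ncols = int(np.ceil(np.sqrt(n * nx / ny)))
    nrows = int(np.ceil(n / ncols))
    cell_h, cell_w = ny / nrows, nx / ncols
    r_hi = min(16.0, cell_h / 2 - 3, cell_w / 2 - 3)
    r_lo = 0.8 * r_hi
    if r_hi < 8:
        raise ConfigurationError("stack too small for the requested cell count")
    out = []
    for i in range(n):
        r, c = divmod(i, ncols)
        ry = float(rng.uniform(r_lo, r_hi))
        rx = float(rng.uniform(r_lo, r_hi))
        rz = float(rng.uniform(0.25 * nz, 0.35 * nz))
        jy = (cell_h / 2 - ry - 2) * float(rng.uniform(-1, 1))
        jx = (cell_w / 2 - rx - 2) * float(rng.uniform(-1, 1))
        cy = (r + 0.5) * cell_h + jy
        cx = (c + 0.5) * cell_w + jx
        cz = nz / 2 + float(rng.uniform(-1, 1))
        out.append((cz, cy, cx, rz, ry, rx))
    return out


def _ellipsoid_mask(shape, cz, cy, cx, rz, ry, rx) -> np.ndarray:
    zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
    return (
        ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
    ) <= 1.0


def _add_noise(
    rng: np.random.Generator, image: np.ndarray, config: SimConfig
) -> np.ndarray:
    if config.noise_model == "poisson":
        noisy = rng.poisson(image).astype(float)
    else:
        noisy = image + rng.normal(0.0, config.noise_sd, image.shape)
    return np.clip(noisy, 0, 65535).astype("uint16")


def gen_image_stacks(config: SimConfig) -> SimStacks:
    """Three-channel z-stacks of nuclei with nucleoli at a known factor.

    Nuclei are non-touching ellipsoids away from the (y, x) image border,
    each containing 1-3 spherical nucleoli strictly inside.  Before noise,
    the signal channel is uniform at a base level over the nucleoplasm and
    ``nucleolar_factor`` times that level over nucleoli, so the true
    nucleolar:nucleoplasm mean ratio equals the factor exactly.
    """
    config.validate()
    rng = _rng(config, "stacks")
    shape = tuple(config.stack_shape)
    nuclei = _place_nuclei(rng, config)
    nuclei_labels = np.zeros(shape, dtype=int)
    nucleoli_labels = np.zeros(shape, dtype=int)
    assignment: dict[int, int] = {}
    next_nucleolus = 1
    for label, (cz, cy, cx, rz, ry, rx) in enumerate(nuclei, start=1):
        mask = _ellipsoid_mask(shape, cz, cy, cx, rz, ry, rx)
        nuclei_labels[mask] = label
        n_nucleoli = int(rng.integers(1, 4))
        placed: list[tuple[float, float, float, float]] = []
        for _ in range(n_nucleoli):
            for _attempt in range(100):
                r = float(rng.uniform(3.0, 5.0))
                min_axis = min(rz, ry, rx)
                s = 1.0 - (r + 1.0) / min_axis
                if s <= 0:
                    continue
                # uniform point in the shrunken ellipsoid
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                frac = float(rng.uniform(0, 1)) ** (1 / 3)
                pz = cz + u[0] * frac * s * rz
                py = cy + u[1] * frac * s * ry
                px = cx + u[2] * frac * s * rx
                if all(
                    np.hypot(np.hypot(pz - q[0], py - q[1]), px - q[2])
                    > r + q[3] + 2.0
                    for q in placed
                ):
                    placed.append((pz, py, px, r))
                    nmask = _ellipsoid_mask(shape, pz, py, px, r, r, r)
                    if not np.all(mask[nmask]):  # pragma: no cover
                        raise AgoxError("nucleolus escaped its nucleus")
                    nucleoli_labels[nmask] = next_nucleolus
                    assignment[next_nucleolus] = label
                    next_nucleolus += 1
                    break

    dapi = np.full(shape, _BG["dapi"])
    dapi[nuclei_labels > 0] = _NUCLEUS["dapi"]
    nucleolin = np.full(shape, _BG["nucleolin"])
    nucleolin[nuclei_labels > 0] = _NUCLEUS["nucleolin"]
    nucleolin[nucleoli_labels > 0] = _NUCLEOLIN_BRIGHT
    signal = np.full(shape, _BG["signal"])
    signal[nuclei_labels > 0] = _NUCLEUS["signal"]
    signal[nucleoli_labels > 0] = _NUCLEUS["signal"] * config.nucleolar_factor

    truth = TruthTables(
        true_nucleolar_factor=config.nucleolar_factor,
        true_masks={"nuclei": nuclei_labels, "nucleoli": nucleoli_labels},
        true_assignment=assignment,
    )
    return SimStacks(
        dapi=_add_noise(rng, dapi, config),
        nucleolin=_add_noise(rng, nucleolin, config),
        signal=_add_noise(rng, signal, config),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# foci images
# ---------------------------------------------------------------------------


@dataclass
class SimFoci:
    dapi: np.ndarray
    foci: np.ndarray
    truth: TruthTables

    def write(self, outdir) -> dict[str, Path]:
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "dapi": outdir / "foci_dapi.tif",
            "foci": outdir / "foci_signal.tif",
            "truth_cells": outdir / "truth_cell_labels.tif",
            "truth": outdir / "truth_foci.json",
        }
        tifffile.imwrite(paths["dapi"], self.dapi)
        tifffile.imwrite(paths["foci"], self.foci)
        tifffile.imwrite(
            paths["truth_cells"], self.truth.true_masks["cells"].astype("uint16")
        )
        with open(paths["truth"], "w") as fh:
            json.dump(
                {str(k): v for k, v in sorted(self.truth.true_foci_counts.items())},
                fh,
                indent=1,
                sort_keys=True,
            )
        return paths


def _foci_count(rng: np.random.Generator, spec) -> int:
    if isinstance(spec, dict):
        if "poisson" in spec:
            return int(rng.poisson(spec["poisson"]))
        raise ConfigurationError(f"unknown foci_per_cell spec {spec!r}")
    if spec < 0:
        raise ConfigurationError("foci_per_cell must be nonnegative")
    return int(spec)


def gen_foci_images(config: SimConfig) -> SimFoci:
    """DAPI + foci channel stacks with a known focus count per cell.

    Foci are Gaussian spots of width ``foci_sigma`` placed inside each
    cell footprint with a minimum pairwise separation.  Truth maps each
    cell label to its exact planted count.
    """
    config.validate()
    rng = _rng(config, "foci")
    shape = tuple(config.stack_shape)
    nuclei = _place_nuclei(rng, config)
    nuclei_labels = np.zeros(shape, dtype=int)
    for label, (cz, cy, cx, rz, ry, rx) in enumerate(nuclei, start=1):
        nuclei_labels[_ellipsoid_mask(shape, cz, cy, cx, rz, ry, rx)] = label

    dapi = np.full(shape, _BG["dapi"])
    dapi[nuclei_labels > 0] = _NUCLEUS["dapi"]
    foci_img = np.full(shape, _BG["signal"])

    yy, xx = np.mgrid[: shape[1], : shape[2]]
    truth = TruthTables(true_masks={"cells": nuclei_labels})
    for label, (cz, cy, cx, rz, ry, rx) in enumerate(nuclei, start=1):
        n_foci = _foci_count(rng, config.foci_per_cell)
        margin = 3.0  # keeps every spot maximum inside the footprint
        positions: list[tuple[float, float]] = []
        for _restart in range(20):
            positions = []
            for _ in range(n_foci):
                for _attempt in range(200):
                    ang = float(rng.uniform(0, 2 * np.pi))
                    frac = np.sqrt(float(rng.uniform(0, 1)))
                    py = cy + frac * max(ry - margin, 0.5) * np.sin(ang)
                    px = cx + frac * max(rx - margin, 0.5) * np.cos(ang)
                    if all(
                        np.hypot(py - q[0], px - q[1])
                        >= config.foci_min_separation
                        for q in positions
                    ):
                        positions.append((py, px))
                        break
                else:
                    break  # dead end; restart this cell's configuration
            if len(positions) == n_foci:
                break
        else:
            raise ConfigurationError(
                f"cannot place {n_foci} foci at separation "
                f"{config.foci_min_separation} in cell {label}"
            )
        z_slice = int(rng.integers(max(0, int(cz) - 2), min(shape[0], int(cz) + 3)))
        for (py, px) in positions:
            spot = config.foci_amplitude * np.exp(
                -((yy - py) ** 2 + (xx - px) ** 2) / (2 * config.foci_sigma**2)
            )
            foci_img[z_slice] += spot
        truth.true_foci_counts[label] = n_foci
        truth.foci_positions[label] = positions

    return SimFoci(
        dapi=_add_noise(rng, dapi, config),
        foci=_add_noise(rng, foci_img, config),
        truth=truth,
    )
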