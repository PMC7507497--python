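"""Readthrough-region detection, conservation scoring, and translation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agox.data import AGO1X_APPENDED_NT, AGO1X_TRYPTIC_PEPTIDES
from agox.errors import InputError
from agox.genomics import (
    STOP_CODONS,
    ConservationTrack,
    TranscriptModel,
    reverse_complement,
    splice_transcript,
)
from agox.readthrough import (
    STATUS_LOW_COV,
    STATUS_NO_STOP,
    STATUS_OK,
    find_readthrough_region,
    mean_conservation,
    region_sequence,
    scan,
    scan_post_stop_sequence,
    translate_extension,
)

# independent oracle: standard genetic code written out by hand
_ORACLE_CODE = {}
_B = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for i1, b1 in enumerate(_B):
    for i2, b2 in enumerate(_B):
        for i3, b3 in enumerate(_B):
            _ORACLE_CODE[b1 + b2 + b3] = _AA[16 * i1 + 4 * i2 + i3]


def _oracle_translate(seq):
    return "".join(_ORACLE_CODE[seq[i : i + 3]] for i in range(0, len(seq), 3))


def _oracle_region_length(post_stop: str) -> tuple[int, bool]:
    """Naive single-pass codon scan; returns (length, found_stop)."""
    for i in range(0, len(post_stop) - len(post_stop) % 3, 3):
        if post_stop[i : i + 3] in STOP_CODONS:
            return i, True
    return len(post_stop) - len(post_stop) % 3, False


def test_ago1_worked_example():
    """The 102-nt AGO1x appended sequence yields a 99-nt region ending in
    TAG whose translation is the 33-aa extension with both tryptic
    peptides."""
    region, stop, seq = scan_post_stop_sequence(AGO1X_APPENDED_NT)
    assert region.status == STATUS_OK
    assert region.length_nt == 99
    assert stop == "TAG"
    peptide = translate_extension(seq)
    assert len(peptide) == 33
    for tryptic in AGO1X_TRYPTIC_PEPTIDES:
        assert tryptic in peptide


def test_post_stop_sequence_starting_with_stop_gives_empty_region():
    region, stop, seq = scan_post_stop_sequence("TAAACGACG")
    assert region.length_nt == 0
    assert stop == "TAA"
    assert seq == ""


def test_no_downstream_stop_extends_to_last_complete_codon():
    region, stop, seq = scan_post_stop_sequence("ACGACGAC")  # 8 nt, no stop
    assert region.status == STATUS_NO_STOP
    assert region.length_nt == 6
    assert stop is None


def test_region_boundaries_match_naive_oracle_on_random_sequences():
    rng = np.random.default_rng(11)
    for _ in range(500):
        n = int(rng.integers(0, 120))
        post = "".join("ACGT"[b] for b in rng.integers(0, 4, n))
        region, stop, seq = scan_post_stop_sequence(post)
        length, found = _oracle_region_length(post)
        assert region.length_nt == length
        assert (region.status == STATUS_OK) == found
        # frame invariant: the region's own sequence has no internal stop
        for i in range(0, len(seq), 3):
            assert seq[i : i + 3] not in STOP_CODONS


def test_translation_matches_independent_codon_table():
    rng = np.random.default_rng(5)
    non_stop = [c for c in _ORACLE_CODE if _ORACLE_CODE[c] != "*"]
    for _ in range(300):
        n = int(rng.integers(0, 40))
        seq = "".join(non_stop[i] for i in rng.integers(0, len(non_stop), n))
        assert translate_extension(seq) == _oracle_translate(seq)


def test_translation_rejects_bad_input():
    assert translate_extension("") == ""
    with pytest.raises(InputError):
        translate_extension("ACGTA")
    with pytest.raises(InputError):
        translate_extension("ACGTAAACG")


def _toy_model(post_stop, track_scores):
    """One-exon transcript with given post-stop sequence and track values."""
    mrna = "ATG" + "TGA" + post_stop
    model = TranscriptModel("t", "g", "chr1", "+", [(0, len(mrna))], 3)
    splice_transcript({"chr1": mrna}, model)
    track = ConservationTrack()
    for pos, score in track_scores.items():
        track.add("chr1", pos, score)
    return model, track


def test_mean_conservation_trivial_extremes():
    post = "ACGACGACGTAG"
    for value in (0.0, 1.0):
        model, track = _toy_model(post, {p: value for p in range(6, 15)})
        region = find_readthrough_region(model)
        region = mean_conservation(region, "chr1", track)
        assert region.status == STATUS_OK
        assert region.coverage == 1.0
        assert region.mean_score == value


def test_low_coverage_blanks_the_mean():
    post = "ACGACGACGTAG"
    model, track = _toy_model(post, {6: 0.5})  # 1 of 9 bases covered
    region = mean_conservation(find_readthrough_region(model), "chr1", track)
    assert region.status == STATUS_LOW_COV
    assert region.mean_score is None
    assert region.coverage == pytest.approx(1 / 9)


def test_scan_recovers_planted_conserved_transcripts(transcriptome):
    table, hist = scan(
        transcriptome.transcripts, transcriptome.genome, transcriptome.track
    )
    ok = table[table.status == STATUS_OK].sort_values(
        "mean_score", ascending=False
    )
    truth = transcriptome.truth
    top = set(ok.transcript_id.head(len(truth.conserved_tr_ids)))
    assert top == truth.conserved_tr_ids
    # every planted region outranks every background region
    planted = ok.transcript_id.isin(truth.conserved_tr_ids)
    assert ok[planted].mean_score.min() > ok[~planted].mean_score.max()
    assert hist.proportion.sum() == pytest.approx(1.0, abs=1e-9)
    # transcripts lacking a downstream stop are reported but unscored
    nostop = table[table.transcript_id.isin(truth.no_downstream_stop_ids)]
    assert (nostop.status == STATUS_NO_STOP).all()
    assert hist["count"].sum() == (table.status == STATUS_OK).sum()


def test_scan_mean_scores_match_generator_truth(transcriptome):
    table, _ = scan(
        transcriptome.transcripts, transcriptome.genome, transcriptome.track
    )
    scored = table.set_index("transcript_id")
    for tid, true_mean in transcriptome.truth.true_mean_scores.items():
        if scored.loc[tid, "status"] == STATUS_OK:
            assert scored.loc[tid, "mean_score"] == pytest.approx(
                true_mean, abs=1e-12
            )


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_strand_symmetry(seed):
    """A transcript and its reverse-complement mirror give identical
    region lengths and conservation scores."""
    rng = np.random.default_rng(seed)
    post = "".join("ACGT"[b] for b in rng.integers(0, 4, int(rng.integers(6, 60))))
    mrna = "ATG" + "TGA" + post
    L = len(mrna)
    fwd = TranscriptModel("f", "g", "chr1", "+", [(0, L)], 3)
    splice_transcript({"chr1": mrna}, fwd)
    rev = TranscriptModel("r", "g", "chr1", "-", [(0, L)], 3)
    splice_transcript({"chr1": reverse_complement(mrna)}, rev)
    assert fwd.mrna_seq == rev.mrna_seq
    rf, rr = find_readthrough_region(fwd), find_readthrough_region(rev)
    assert rf.length_nt == rr.length_nt
    assert rf.status == rr.status
    track_f, track_r = ConservationTrack(), ConservationTrack()
    scores = rng.random(L).round(6)
    for p in range(L):
        track_f.add("chr1", p, scores[p])
        track_r.add("chr1", L - 1 - p, scores[p])
    if rf.status == STATUS_OK and rf.length_nt:
        mf = mean_conservation(rf, "chr1", track_f).mean_score
        mr = mean_conservation(rr, "chr1", track_r).mean_score
        assert mf == pytest.approx(mr, abs=1e-12)
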