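# agox

Analysis toolkit for stop-codon readthrough and double-stranded-RNA biology,
built around the AGO1x story: the translational-readthrough isoform of
Argonaute 1 that carries a 33-amino-acid C-terminal extension, localizes to
nucleoli, and binds structured (double-stranded) RNA.

The package is for computational biologists who want to reproduce or reuse
four analyses that are usually re-implemented ad hoc:

1. **Readthrough-region scanning** (`agox.readthrough`). For every
   transcript, the region between the annotated stop codon and the next
   in-frame stop in the mature mRNA (both stops excluded) is located by a
   codon scan, projected exon-aware onto the genome, and scored by the mean
   of a per-base conservation track (e.g. PhastCons, scores in [0, 1]).
2. **Frame-preservation analysis of multi-species alignments**
   (`agox.msa`). With the codon frame anchored to a reference species, the
   module counts nonsense codons (reference-frame TAA/TAG/TGA), classifies
   indel events as frame-preserving iff their length ≡ 0 (mod 3), and
   reports which species keep the reading frame intact.
3. **dsRNA enrichment calling** (`agox.dsrna`). Per-gene log2 fold changes
   (mutant vs control) are computed for a total RNA-seq and a dsRNA-pulldown
   assay after median-of-ratios normalization; dsRNA fold changes are
   regressed on total fold changes by OLS, and genes with
   |standardized residual| > 2.5 are called enriched or depleted. Calls
   consistent across two mutants are intersected, and G/C composition of the
   call sets is compared with a Mann–Whitney U test.
4. **Nucleolar image quantification** (`agox.imaging`). A three-step
   z-stack procedure — DAPI maximum-projection nuclei mask, per-slice
   nucleus and nucleolus segmentation, nucleolus-to-nucleus assignment by
   projected overlap — yields per-cell nucleolar and nucleoplasm mean
   intensities, their ratio, and a paired t-test; a separate routine counts
   non-overlapping foci per cell in projected images and bins counts into
   <1 / 1–5 / >5.

`agox.simulate` generates every input format the pipeline consumes (FASTA,
BED12, bedGraph, aligned FASTA, count TSVs, multi-page TIFF) with known
ground truth, so all stages are testable without downloads.

## Worked example

The AGO1x expression construct appends 102 nucleotides directly downstream
of the AGO1 stop codon. Scanning it:

```python
from agox.data import AGO1X_APPENDED_NT
from agox.readthrough import scan_post_stop_sequence, translate_extension

region, stop, seq = scan_post_stop_sequence(AGO1X_APPENDED_NT)
print(region.length_nt, stop)          # 99 TAG
peptide = translate_extension(seq)
print(len(peptide), peptide)
# 33 RQNAVTSLDRRKLSKPQELCHPNPEEARRREVG
```

The scan stops at the first in-frame stop codon (a TAG after 99 nt), and
the 33-residue translation contains both tryptic peptides observed by
targeted mass spectrometry (`QNAVTSLDR`, `LSKPQELCHPNPEEAR`).

A full synthetic image-quantification run:

```
$ agox simulate stacks --seed 1 --out sim
$ agox quantify-stacks --dapi sim/dapi.tif --nucleolin sim/nucleolin.tif \
      --signal sim/signal.tif --out quant
20 cells, mean ratio 3.00, p = 2.45e-53
```

i.e. the pipeline recovers the generator's default 3-fold
nucleolar:nucleoplasm enrichment from 20 noisy synthetic cells, with a
highly significant paired t-test.

Every stage has a matching CLI verb: `agox simulate
{transcriptome|msa|counts|stacks|foci}`, `agox scan-readthrough`,
`agox msa-frames`, `agox dsrna-call`, `agox quantify-stacks`,
`agox count-foci`.

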