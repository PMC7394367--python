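# capture3c

Calling locus-specific long-range chromatin interactions from dCas9
capture-3C paired-end sequencing. The pipeline takes two single-end
alignment files (one per mate), rescues unmapped reads containing a DpnII
`GATC` junction, filters on MAPQ > 30, pairs mates into paired-end tags
(PETs) and removes PCR duplicates; defines the bait region adaptively from
the local read-depth enrichment around the sgRNA target site (its width
sets the intra-chromosomal bin size); classifies PETs as self-ligated /
bait-linked / background; fits distance-stratified negative-binomial noise
models (one per bin-separation stratum up to 20 kb, one pooled beyond, and
one per chromosome pair at 1 Mb resolution for inter-chromosomal contacts);
and scores each contacted bin with a left-tail probability and a Bayes
factor (significant at BF > 20 with prior odds 0.001). Output formats:
PET table TSV, calls TSV, background-model JSON, QC JSON, and WashU
longrange text for browser visualization.

A fully seeded synthetic-data module generates libraries with the assumed
statistical structure (self-ligation bulk, decaying NB intra noise, uniform
inter noise, spiked true interactions, chimeric junction reads, PCR
duplicates) plus a per-read truth table, so the entire pipeline is testable
offline.

## CLI

```sh
# synthetic library: SAM x2, rescue SAMs, chrom.sizes, truth table
capture3c simulate --seed 21 --out-dir sim/ --n-pets 12000 \
    --duplication-rate 0.1 --chimera-fraction 0.03

# rescue + filter + pair + dedup -> PET table
capture3c process --sam1 sim/mate1.sam --sam2 sim/mate2.sam \
    --rescue-sam1 sim/rescue1.sam --rescue-sam2 sim/rescue2.sam \
    --min-mapq 30 --min-fragment 20 --out pets.tsv

# adaptive bait definition around the sgRNA target (or --peaks peaks.bed)
capture3c bait --sam sim/mate1.sam --sam sim/mate2.sam \
    --target chr1:5001250 --out bait.bed

# classification, background fitting and significance calling
capture3c call --pets pets.tsv --bait bait.bed --chrom-sizes sim/chrom.sizes \
    --seed 9 --prior-odds 0.001 --bf-threshold 20 --out-prefix results/run1
```

`results/run1.longrange` can be loaded in the WashU browser after the usual
bgzip/tabix post-step (not performed here; the file is plain text).

Note on P-values: the reported `p_left` is the left tail P(X < x), where
*larger* is more significant; the conventional upper tail is reported
alongside as `p_survival`.

## Layout

- `src/capture3c/genomic_io.py` — SAM/BAM, chrom.sizes, BED, longrange, JSON I/O
- `src/capture3c/read_processing.py` — junction trimming, MAPQ filter, pairing, dedup
- `src/capture3c/bait_definition.py` — depth track, local background, bait heuristic
- `src/capture3c/pet_classification.py` — bin grid, PET categories, contact counts, QC
- `src/capture3c/background_models.py` — NB fitting, intra/inter background construction
- `src/capture3c/significance.py` — left-tail P, Bayes factor, interaction calls
- `src/capture3c/synthetic_data.py` — seeded library simulator + truth table
- `src/capture3c/pipeline.py`, `cli.py` — orchestration and `capture3c` commands
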