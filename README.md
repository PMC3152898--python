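# digikaryo

Digital karyotyping analysis in Python: genome-wide copy-number profiling by
counting 21-bp restriction tags, with a full synthetic-data generator, a
Monte-Carlo power/PPV estimator, and the qPCR ΔCt statistics used to validate
copy-number calls in tumor cohorts.

## The problem and the method

Subchromosomal amplifications and deletions are among the most common
genomic alterations in solid tumors such as hepatocellular carcinoma.
Digital karyotyping measures them *digitally*: instead of array
hybridization intensities, it counts short sequence tags released from the
genome at a fixed restriction-enzyme geometry, so local tag density is a
direct estimate of local copy number.

The geometry: every **mapping-enzyme** site (SacI, `GAGCTC`) contributes one
tag on each side, anchored at the nearest **fragmenting-enzyme** site
(NlaIII, `CATG`). A tag is the 21 bases starting at that CATG anchor and
reading toward the mapping site. The analysis chain is:

1. **Virtual tag database** (`digikaryo.tagdb`) — predict every tag the
   genome can release and flag the ones whose 21-mer occurs at exactly one
   locus genome-wide.
2. **Tag extraction** (`digikaryo.extract`) — sequencing reads are
   concatemers of *ditags* (two tags ligated tail-to-tail, `CATG` + 34 bp +
   `CATG`, adjacent ditags sharing their punctuating anchor); a greedy
   left-to-right scan recovers both 21-bp tags from each ditag, with
   optional ditag deduplication as PCR-duplicate control.
3. **Mapping** (`digikaryo.mapping`) — observed tags are joined to virtual
   tags by exact match; only tags matching exactly one unique virtual tag
   ("filtered tags") carry positional information. The mapped fraction F/T
   is the library's headline quality number.
4. **Detection** (`digikaryo.cnv`) — slide a window of W = 20 consecutive
   unique virtual tags (step 1) along each chromosome and form the fold
   change FC = O/E with E = W·F/U (U = unique virtual tags genome-wide).
   FC ≥ 3 calls amplification, FC ≤ 0.1 calls deletion; maximal runs of
   qualifying windows merge into amplicons reported with 1-based start/end,
   size = end − start, and overlapping genes from a BED annotation.
5. **Power/PPV** (`digikaryo.power`) — for a lesion of given fold and size
   at a given sequencing depth, multinomial simulation of the whole caller
   yields detection power and positive predictive value with Monte-Carlo
   standard errors.
6. **qPCR validation** (`digikaryo.qpcr`) — relative DNA/mRNA levels
   2^(Ct_ref − Ct_target) (LINE-1 reference for DNA, GAPDH for RNA), the
   mean + 2 SD cohort rule for per-tumor amplification calls, frequency
   percentages, and Student's t tests with Bonferroni correction.

Because no public digital-karyotyping dataset accompanies the HCC study
system this package models, `digikaryo.simulate` generates every input with
exact ground truth: genomes with planted enzyme sites, spiked copy-number
segments, multinomially sampled ditag-concatemer reads, and triplicate Ct
tables for normal/tumor cohorts.

## Worked example

Simulate a 300 kb genome carrying a 10-fold amplification of
chr1:60,000–100,000, sequence 100,000 tags, and run the whole chain:

```python
from digikaryo import SimConfig, CnvSegment
from digikaryo.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    outdir="hcc_demo",
    seed=1,
    dedup=False,  # simulated duplicates are genuine resamples
    sim=SimConfig(
        genome_length=300_000,
        mapping_spacing=2000,
        site_spacing=400,
        depth=100_000,
        cnv_profile=[CnvSegment("chr1", 60_000, 100_000, 10.0)],
    ),
)
manifest = run_pipeline(cfg)
print(open("hcc_demo/calls.tsv").read())
```

which prints

```
chrom	start	end	size	direction	mean_fold	n_windows	genes
chr1	52316	106163	53847	amplification	4.190	35	--
```

and `hcc_demo/mapping.json` reports 100,000 of 100,000 tags mapped (100%) —
error-free reads against an all-unique tag database lose nothing. The
single amplification call covers the planted segment; its boundaries
overshoot by roughly half a window on each side because every window
containing enough spiked tags qualifies, and its mean fold (4.19) sits
below the planted 10 because the spike itself inflates the genome-wide
expected density against which fold change is measured. The same run also
leaves `tagdb.tsv`, `tags.tsv`, `counts.tsv`, `windows.tsv`, `calls.bed`
and a `manifest.json` whose checksums are identical across reruns with the
same seed.

The same stages are exposed as a CLI:

```sh
digikaryo simulate --outdir sim --seed 1
digikaryo build-tagdb --genome sim/genome.fa --out tags.tsv
digikaryo extract-tags --reads sim/reads.fa --out observed.tsv --no-dedup
digikaryo map-tags --tags observed.tsv --tagdb tags.tsv --out counts.tsv
digikaryo detect-cnv --counts counts.tsv --tagdb tags.tsv --window 20 --amp 3 --del 0.1
digikaryo power --fold 3 --lesion-bp 38000 --depth 890628 --sims 500 --seed 1
digikaryo qpcr-call --table ct.tsv --mode dna --m 4
```

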