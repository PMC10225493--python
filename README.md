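# xykit

Tools for studying sex-linked regions and genome evolution in dioecious
plants at desk scale:

* **`xykit.sim`** — simulators with machine-readable truth: an XY genome
  pair with a diverged sex-determining region (SDR) and a Y-only insertion;
  shotgun read sets for sexed cohorts; wild/domestic genotype matrices with
  planted selective sweeps; diverged 5′/3′ LTR pairs; derived karyotypes
  built from an ancestral one by known fusion/fission events.
* **`xykit.kmers`** — prefix-subsampled k-mer cataloguing (default: 40-mers
  starting with `AG`), male-/female-specific k-mer (MSK/FSK) classification,
  and sex-specific read labeling.
* **`xykit.sdr`** — read placement (internal exact-seed placer or external
  SAM/BAM), windowed depth tracks (counts-per-million), candidate SDR
  calling, per-sex variant-density tracks, log2 coverage ratios.
* **`xykit.popgen`** — Weir–Cockerham FST (per-site components, weighted and
  mean window summaries), windowed nucleotide diversity π, π ln-ratio,
  Tajima's D, dual top-quantile sweep selection, GFF3 gene overlap.
* **`xykit.ltr`** — global pairwise LTR alignment, Kimura two-parameter
  distance, insertion age T = K/(2r) (default r = 1.8e-8 /site/year).
* **`xykit.karyotype`** — synteny-block tables, evolutionary fusion region
  (EFR) detection, parsimony fusion/fission counts, repeat-class enrichment
  of EFRs.
* **`xykit.pipeline`** — end-to-end simulated-cohort SDR recovery
  (simulate → count → classify → label → place → window → call).

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end parameter-recovery and
oracle-equivalence criteria (≈10 min dominated by the 10-seed SDR recovery
run); the rest of the suite finishes in well under a minute.

The acceptance report script is run as

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

(The target list for this build is empty — published dataset-scale numbers
are not recomputable offline — so the script performs an install sanity
check and writes an empty JSON object.)

## CLI

One entry point, `xykit`, with grouped subcommands:

```sh
# simulators (JSON --params files override dataclass defaults)
xykit simulate genome  --seed 1 --out-dir sim/genome --params genome.json
xykit simulate reads   --seed 1 --genome-dir sim/genome --out-dir sim/reads
xykit simulate popvcf  --seed 1 --out-dir sim/pop
xykit simulate ltr     --seed 1 --out-dir sim/ltr --n-pairs 200
xykit simulate karyotype --seed 1 --out-dir sim/karyo --n-fusions 15 --n-fissions 1

# k-mer sex classification
xykit kmers count --fastq M1.fastq.gz --sample-id M1 --sex male --out M1.kmers.tsv
xykit kmers classify --manifest counts.tsv --out-dir sets/ --k 40 --prefix AG --min-total 10
xykit kmers label-reads --fastq M1.fastq.gz --msk sets/msk.fasta --fsk sets/fsk.fasta --out-dir labeled/

# SDR scan
xykit sdr place --fastq labeled/male.fastq --reference male.fasta --out placements.tsv
xykit sdr depth --placements placements.tsv --chrom-sizes male.chrom.sizes --window 100000 --out male.bedgraph
xykit sdr call  --male-bedgraph male.bedgraph --female-bedgraph female.bedgraph \
                --chrom-sizes male.chrom.sizes --out sdr.bed
xykit sdr variant-density --vcf cohort.vcf --manifest samples.tsv --out density.tsv

# sweep scan
xykit sweep stats  --vcf pop.vcf --populations pops.tsv --chrom-length 100000000 \
                   --window 50000 --step 50000 --out stats.tsv
xykit sweep select --stats stats.tsv --quantile 0.99 --out sweeps.bed
xykit sweep annotate --regions sweeps.bed --gff3 genes.gff3 --out sweeps.genes.tsv

# LTR insertion dating
xykit ltrage --fasta ltr_pairs.fasta --rate 1.8e-8 --out ages.tsv

# karyotype / EFR analysis
xykit karyo efr     --blocks blocks.tsv --min-block 1200000 --out efr.bed
xykit karyo events  --blocks blocks.tsv --min-block 1200000
xykit karyo repeats --blocks blocks.tsv --repeats repeats.bed --chrom-sizes sizes.tsv --out enrichment.tsv
```

## Conventions

Coordinates are 0-based half-open internally (BED on output; 1-based VCF/GFF3
positions converted on ingestion). All simulators take a single integer seed
and use independent named generator streams, so identical parameters and seed
give byte-identical outputs. FASTQ qualities are constant Q40 ('I'); the
pipeline never reads them.
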