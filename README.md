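# dmscompete

Analysis of **barcoded deep-mutational-scanning bulk competitions**: from raw
sequencing reads to per-variant selection coefficients, fitness classes across
environments, positional-clustering significance, and distance-to-optimum
estimates under Fisher's geometric model.

The package targets experiments in which every single-codon variant of a gene
(for a 709-codon ORF mutagenized at positions 2–709: 44,604 codon variants
encoding 14,160 amino-acid variants) is tagged with 10–20 unique 18-mer DNA
barcodes, pooled, and grown in bulk competition under one or more
environmental conditions, with barcode sequencing at ~8 timepoints per
competition. It is aimed at groups running such competitions who need a
tested, reusable pipeline rather than one-off scripts.

## The model

Lineage *i* grows exponentially at rate *r<sub>i</sub>* from initial size
*n<sub>i</sub>*(0); sequencing at time *t* draws reads multinomially with

&nbsp;&nbsp;&nbsp;&nbsp;*p<sub>i</sub>(t) = n<sub>i</sub> e^(r<sub>i</sub> t) / Σ<sub>j</sub> n<sub>j</sub> e^(r<sub>j</sub> t)*.

All (*r<sub>i</sub>*, log *n<sub>i</sub>*) are sampled jointly by
Metropolis–Hastings with the wild-type reference pinned (*r* = 1 in
wild-type-generation units), 10,000 retained posterior samples by default, and
point estimates taken as the median of 1,000 thinned samples. Raw selection
coefficients *s* = median(*r*) − 1 are then **anchor-scaled** so that the mean
wild-type synonym is 0 (neutral) and the mean stop codon is −1 (null):

&nbsp;&nbsp;&nbsp;&nbsp;*s*<sub>norm</sub> = (*s* − mean<sub>wt</sub>) / (mean<sub>wt</sub> − mean<sub>stop</sub>).

Downstream, variants are classified per condition (wild-type-like /
beneficial / intermediate / strongly deleterious, by 2-SD bands around the
anchor distributions), temperature-sensitive variants are screened across
condition pairs, mutation classes are tested for positional clustering
against a random-placement null, and each environment's neutral + beneficial
DFE is fit with a displaced gamma, *s* = *d* − *X*, *X* ~ Gamma(α, θ),
whose displacement *d* estimates the distance to the fitness optimum.

A first-class synthetic-data module generates ground-truth libraries,
association reads, and competition reads with the statistical structure the
analysis assumes, so every stage is testable with known answers.

## Worked example

Simulate a compact competition (16-codon protein, 200 variants, 8 timepoints,
200,000 reads per timepoint), infer selection coefficients, and normalize:

```python
import numpy as np
from dmscompete import (SelectionModel, SimulationConfig, enumerate_library,
                        sample_true_dfe, simulate_competition_counts)

cfg = SimulationConfig(protein_length=16, mutagenized_range=(2, 16), seed=1,
                       depth_per_timepoint=200_000, dispensable_c_terminal=0)
lib = enumerate_library(cfg.protein_length, cfg.mutagenized_range, orf_seed=1)
rng = np.random.default_rng(1)
truth = sample_true_dfe(cfg, lib.variants.sample(200, random_state=1)
                        .reset_index(drop=True), rng)
table = simulate_competition_counts(truth, cfg, rng)

results = SelectionModel(table).fit(samples=4000, seed=1)
results.normalize()
print(results.summary())
```

```
Selection inference (exponential growth / multinomial sampling, MH)
====================================================================
condition: standard   variants: 201   timepoints: 8
posterior samples: 4000 (thin 10 -> 400 for summaries)
median acceptance (r): 0.23
anchors: 10 wild-type synonyms (mean s_raw -0.0015), 12 stops (mean s_raw -1.0050)
normalized: wt-synonym mean +0.000, stop mean -1.000
--------------------------------------------------------------------
 position codon aa  s_raw  s_norm
       14   CTG  L -1.034  -1.029
        3   CTT  L -0.994  -0.989
        6   ATG  M -1.077  -1.072
       13   TAC  Y +0.028  +0.030
...
```

The `s_norm` column is the anchor-scaled selection coefficient: values near 0
are wild-type-like, values near −1 are null alleles (here, nonsense variants
and strongly deleterious missense variants), and positive values are
candidate beneficial mutations. On this run the Pearson correlation between
the planted and the estimated normalized coefficients is 0.999.

The same stages are exposed as a CLI for file-based pipelines:

```bash
dmscompete simulate --config config.yaml --outdir sim/
dmscompete map-barcodes --r1 sim/assoc_R1.fastq --r2 sim/assoc_R2.fastq \
    --wt-fasta sim/wt_orf.fasta --out barcode_map.tsv
dmscompete count --fastq sim/competition.fastq --samples sim/samples.tsv \
    --barcode-map barcode_map.tsv --wt-fasta sim/wt_orf.fasta \
    --condition standard --out counts.tsv
dmscompete infer --counts counts.tsv --out selection.tsv
dmscompete classify --selection standard selection.tsv --outdir classes/
dmscompete cluster --mutations ts_positions.tsv --n-positions 708 --out clust.tsv
dmscompete fgm --classes standard classes/classes_standard.tsv --out fgm.tsv
```

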