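# editome

Comparative analysis of A-to-I RNA editing across genotypes from base-count
evidence.

ADAR enzymes deaminate adenosine to inosine in double-stranded RNA; because
sequencers read inosine as guanosine, an edited site appears as an A→G
mismatch between RNA reads and the reference (or T→C for a minus-strand
transcript). `editome` implements the comparative editome workflow used to
characterize mouse models in which chronic dsRNA sensing (a viral
RdRp transgene activating MDA5) is combined with *Adar* haploinsufficiency:

1. **Germline masking** — whole-exome base counts identify colony SNPs
   (any non-reference allele ≥ 10% at ≥ 10× DNA depth), which are excluded
   from edit calling; positions without adequate DNA evidence can be dropped
   conservatively. A supplied known-variant list can be merged in.
2. **Per-animal edit calling** — A>G / T>C RNA–DNA differences passing
   depth ≥ 10, variant reads ≥ 3, editing fraction ∈ [0.05, 0.95], with
   strand consistency enforced inside annotated genes and a "complex
   position" exclusion for likely unmasked variants.
3. **Replicate consensus** — a *site* counts for a genotype only if the
   identical (contig, position, change) is called in **all** animals of that
   genotype; a *gene* counts if every animal has ≥ 1 passing call anywhere
   in the gene's full span (UTRs, exons and introns), so per-animal sites
   need not coincide.
4. **Annotation** — each site gets one feature class by fixed precedence
   3′UTR > 5′UTR > CDS > intron (else intergenic) plus an independent repeat
   class (SINE / LINE / DNA transposon / other retrotransposon).
5. **Comparison** — per-genotype counts, the 15-cell four-way Venn partition
   of genes and sites, uniquely edited sets (Venn singleton cells), and
   percent change in site counts versus wild type,
   `100 × (n_g − n_WT)/n_WT`.
6. **ISG statistics** — interferon-stimulated-gene membership is an input
   list; the package summarizes DEG tables against it and tests whether
   uniquely edited sites are enriched in ISG transcripts with a two-sided
   Fisher exact test on the 2×2 table (ISG vs not) × (unique vs shared),
   reporting the odds ratio (with a Haldane-corrected companion for
   degenerate margins).

A first-class synthetic-data generator (`editome.simulate`) produces a
ground-truthed study — four genotypes (`WT`, `Adar_het`, `RdRp_tg`,
`DoubleHet`) × four animals, colony-shared SNPs, genotype-structured planted
edit sites concentrated in intergenic regions and 3′UTRs — together with
closed-form binomial detection probabilities that act as an analytic oracle
for parameter-recovery testing.

## Worked example

```python
from editome import (SimConfig, simulate_genome, plant_truth, simulate_pileups,
                     call_exome_snps, call_edit_sites, GenotypeEditome,
                     percent_change, venn_partition, unique_sets, GENOTYPES)

cfg = SimConfig(seed=1)                      # default study conditions
genome, features = simulate_genome(cfg)
truth = plant_truth(cfg, genome, features)
rna, dna = simulate_pileups(genome, truth, cfg)

mask = call_exome_snps(list(dna.values()))
editomes = {}
for g in GENOTYPES:
    per = {s: call_edit_sites(rna[s], mask, features, genome=genome,
                              animal_id=s, genotype=g)
           for s in (f"{g}_{i+1}" for i in range(4))}
    editomes[g] = GenotypeEditome.build(g, per, features)

counts = {g: len(e.consensus_sites) for g, e in editomes.items()}
print(counts)
print({g: round(v, 1) for g, v in percent_change(counts, "WT").items()})
print({g: len(s) for g, s in
       unique_sets(venn_partition({g: e.consensus_sites
                                   for g, e in editomes.items()})).items()})
```

prints

```
{'WT': 383, 'Adar_het': 383, 'RdRp_tg': 385, 'DoubleHet': 599}
{'WT': 0.0, 'Adar_het': 0.0, 'RdRp_tg': 0.5, 'DoubleHet': 56.4}
{'WT': 25, 'Adar_het': 24, 'RdRp_tg': 25, 'DoubleHet': 239}
```

i.e. the double heterozygote carries ~56% more consensus edit sites than the
other genotypes and by far the largest uniquely edited set — the structure
the generator's defaults encode — while the analytic oracle
(`truth.expected_consensus_sites`) predicts 384.8 / 599.7 sites for the two
regimes.

The same analysis runs from files via the CLI:

```
editome simulate --seed 1 --out data/
editome run-all --config pipeline.json
```

where `pipeline.json` is a serialized `PipelineConfig` naming the FASTA,
BEDs, per-sample pileup TSVs, sample sheet entries and thresholds. Every run
writes per-animal call VCFs, consensus tables, feature/Venn summaries,
`report.json` and a provenance manifest; reruns with the same config are
byte-identical.

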