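# bepsifind

Discovery and characterization of endo-siRNA loci born from convergent
transcription, from small-RNA sequencing data.

## The problem

When two genes on opposite strands are transcribed toward each other
(a *cis*-NAT arrangement), their nascent transcripts — including the
unstable readthrough RNA that RNA polymerase II produces downstream of the
polyadenylation site — can anneal into double-stranded RNA. Dicer-2 converts
such dsRNA into 21-nt endo-siRNAs that load into Argonaute-2 and acquire a
protective 3'-terminal 2'-O-methyl group. A nucleo-cytoplasmic export factor
(in *Drosophila*, the dsRBD protein Blanks) is required for the biogenesis
of a subset of these siRNAs ("bepsiRNAs"). `bepsifind` implements the
complete computational workflow used to find and characterize such loci:

1. **Region compilation** — from a GFF3 annotation, list every plus-strand
   gene whose body plus a 300-nt 3' extension overlaps the body of a
   minus-strand gene by ≥ 1 bp (one candidate region per distinct
   anchor/partner pair), or alternatively one region per gene with
   symmetric 150-nt flanks.
2. **Read processing** — 3'-adapter trimming, size selection to 21-mers,
   removal of reads matching transposon consensus sequences exactly on
   either strand, and exact-match mapping that keeps only reads with a
   single occurrence across both genome strands.
3. **Quantification** — per-region counts split by orientation, normalized
   to parts per million (ppm) of genome-matching reads.
4. **Classification** — a locus is *expressed* at > 5 ppm in the reference
   library and *dependent* on a factor when the reference/test ppm ratio is
   ≥ 5; duplex origin is diagnosed by the sense fraction
   f = n_sense / n_total ≈ 0.5 (loci with ≥ 10 reads in every library);
   cross-dataset overlaps are summarized as exact set statistics.
5. **Loading state** — per-class retention between untreated and
   periodate-oxidized libraries: 2'-O-methylated (Ago2-loaded) classes
   survive oxidation (retention ≈ 1), unmethylated miRNAs are depleted.
6. **Binding affinity** — the dissociation constant of a dsRBD–dsRNA
   interaction from fluorescence-anisotropy titrations, using the
   ligand-depletion (quadratic) isotherm

   fb = ((P + L + K_D) − √((P + L + K_D)² − 4·P·L)) / (2·L),

   r(P) = r_free + (r_bound − r_free)·fb, fitted per replicate by
   nonlinear least squares and reported as mean ± sd.

A synthetic-data module generates genomes, annotations (convergent pairs in
five geometries), transposon families, miRNA loci and condition-specific
FASTQ libraries with planted ground truth, so the whole pipeline is testable
end to end without external data.

## Worked example

```python
import bepsifind as b

cfg = b.ScenarioConfig(seed=7, read_depth=200_000)
res = b.run_pipeline(cfg, "demo_run")
print(b.report(res))
```

prints

```
bepsifind run report
====================

genes annotated:        220
candidate regions:      100
distinct anchors:       100
expressed (> ppm floor): 100
dependent (ratio >= 5):  20

library funnels:
  wt: total=200000 trimmed=200000 sized=200000 TE=69952 genome=130048 unique=130048
  blanks_shutdown: total=200000 trimmed=200000 sized=200000 TE=75280 genome=124720 unique=124720

loading state (oxidation retention per class):
  miRNA: 0.052
  TE_siRNA: 1.000
  bepsiRNA: 1.000

sense fraction (defined at 100 loci): median 0.498
```

Reading the output: the synthetic annotation contains 110 planted gene
pairs, of which exactly the 100 with a duplex-competent geometry are
compiled into candidate regions; the 20 loci planted with an 8-fold
reduction in the shutdown library are the 20 called dependent at the
ratio ≥ 5 / > 5 ppm cutoffs. Per-library funnels show the read attrition
from raw reads to uniquely mapped 21-mers (the genome-matching count is
each library's ppm denominator). Oxidation retention near 1.0 for the
siRNA classes and near the planted 0.05 survival for miRNAs reproduces the
loading-state signature, and the median sense fraction of ≈ 0.5 is the
expected duplex signature.

The same stages are available from the shell:

```sh
bepsifind run --seed 7 --depth 200000 --out demo_run
bepsifind regions --gff genes.gff3 --ext 300 --out regions.bed
bepsifind fit-kd --csv titration.csv --ligand-nm 20
```

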