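# myosplice

Integrative analysis of pre-mRNA alternative splicing (AS) and
N6-methyladenosine (m6A) methylation in a two-muscle study design —
an oxidative, soleus-like condition (SOL) versus a glycolytic,
extensor-digitorum-longus-like condition (EDL), three biological
replicates each, with paired MeRIP-seq IP/input libraries. The package
is aimed at transcriptomics researchers who want to reproduce or probe
this style of multi-omic splicing analysis end to end on data with known
ground truth.

The pipeline covers:

1. **AS event cataloguing** — SE / A5SS / A3SS / MXE / RI events
   classified from gene models by pairwise transcript comparison, with
   per-type and per-gene bookkeeping.
2. **Quantification** — FPKM with an expressed-gene filter
   (FPKM ≥ 0.5 in ≥ 1 library) and percent-spliced-in

       ψ = (I/l_I) / (I/l_I + S/l_S)

   from length-normalised inclusion/skipping junction counts.
3. **Differential tests** — NB Wald test for expression
   (DEG: |log2FC| ≥ 1 and FDR < 0.05) and a pooled binomial
   likelihood-ratio test for splicing (DAS: FDR < 0.05), with
   Benjamini–Hochberg adjustment throughout.
4. **MeRIP enrichment** — a windowed Fisher-test peak caller, m6A
   enrichment as MFPKM = FPKM_IP / FPKM_INPUT averaged over replicates,
   and differential methylation (padj < 0.05).
5. **Integration** — AS fractions in modified vs unmodified genes,
   AS-count quartile analysis, four-quadrant SE-DMAS classification
   (ΔPSI direction × m6A direction on cassette-exon peaks),
   methyltransferase-knockdown intersection, RRACH
   ([AG][AG]AC[ACU]) motif scanning and the RT-PCR inclusion formula.
6. **Network** — splicing-factor ↔ event Spearman correlation network
   (|ρ| ≥ 0.9, padj < 0.05) with GraphML/SIF export.
7. **Synthetic data** — a generator that emulates the whole study with
   planted ΔPSI, expression and m6A effects and machine-readable truth,
   so every stage is testable without downloads.

## Worked example

Simulate a 120-gene study and run the full pipeline:

```sh
myosplice demo --n-genes 120 --seed 7 --outdir demo_run
```

which prints the SE-DMAS quadrant summary:

```json
{"n_decreased": 6, "n_genes": 10, "n_increased": 7, "n_records": 13,
 "quadrants": {"decreased/hyper": 4, "decreased/hypo": 2,
               "increased/hyper": 5, "increased/hypo": 2}}
```

and writes `demo_run/results/report.json`. For this seed the report
shows a catalogue of 117 AS events (SE+RI share 67.52%), 27 DAS events
and 16 DEGs, 63 called m6A peaks of which 38 are differentially
methylated, and 13 SE-DMAS records: skipped exons whose inclusion *and*
cassette-exon m6A enrichment both change between the two muscle types,
split into the four direction quadrants shown above. The knockdown
intersection (5/13 shared events, 38.5%) mimics asking which of those
events are reproduced when the m6A writer is silenced, and the network
stage links splicing factors to the DAS events their expression tracks.

Individual stages are also exposed (`myosplice simulate / classify /
quantify / diff / merip / integrate / network / run-all`), and the
library functions under `myosplice.*` take ordinary pandas objects.

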