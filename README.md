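# vdp — virome & defense-system profiling for metagenomes

`vdp` is a Python library, analysis pipeline and CLI for community-level
analysis of **prokaryotic antiviral systems** and **prokaryote–phage
interactions** in assembled metagenomes, built around the kind of
two-condition comparison used in drinking-water distribution studies
(disinfected vs non-disinfected systems). It is aimed at microbiome
researchers who have contig-level annotation tables (defense systems,
prophage coordinates, lifestyle labels, tRNA genes, per-gene taxonomy hits)
and per-read alignment records, and want reproducible, testable versions of
the common downstream computations.

## What it computes

* **Abundance** — TPM quantification with an aligned-length filter
  (records with fewer than 30 aligned bp are discarded):
  `TPM_i = (c_i/L_i) / Σ_j (c_j/L_j) × 10⁶`; every sample column sums to 10⁶.
* **Dereplication** — greedy longest-first clustering at ≥95% identity and
  ≥80% coverage of the shorter sequence (CD-HIT-style semantics).
* **Viral taxonomy** — contig-level majority vote over per-gene database
  hits: eligible if ≥20% of genes have hits (or ≥2 hits when the contig has
  <10 genes), assigned at the deepest rank where one taxon collects ≥60% of
  hit genes.
* **CRISPR** — exact repeat-spacer array detection, spacer extraction, and
  the length- and abundance-normalised spacer burden
  `M = Σ (N/L · A)` (N spacers on a contig, L its length, A its TPM).
* **Host linkage** — three in-situ evidence channels (CRISPR
  spacer↔protospacer matching on either strand, perfect full-length tRNA
  matches, prophage localization), genus-level merging, and **polyvalent
  phage** classification (a phage linked to ≥2 host genera), by count and by
  abundance.
* **Defense profiling** — carrier fractions, per-family TPM and proportions,
  RM / CRISPR-Cas subtype shares, lysogen-restricted and phage-carried
  profiles.
* **Statistics** — Shannon diversity, Bray–Curtis dissimilarity, classical
  PCoA, Mantel permutation tests (Spearman ρ), Pearson correlation,
  Student's/Welch's t-tests, BH-FDR.
* **Synthetic communities** — a seeded generator that plants ground truth
  for every stage (prophages, viral-sourced spacers, shared tRNAs, defense
  carriers, condition effects on lysogeny and defense-carrier abundance), so
  the whole pipeline can be validated end-to-end.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
community (seed 42) and write their tables under `results/`:

```bash
python analysis/01_simulate_community.py
python analysis/02_quantify_abundance.py
python analysis/03_profile_defense.py
python analysis/04_link_hosts.py
python analysis/05_compare_conditions.py
```

Script 01 plants a community of 96 prokaryotic contigs in 8 genera and 60
viral contigs (5 embedded as prophages), with 29 CRISPR arrays and 108
ground-truth host links, sampled in 20 samples of 20 000 reads. The
downstream scripts then print, among other things:

```
defense-carrier TPM share by condition:
disinfected        13.95%
non_disinfected     2.03%
fold change: 6.9x
...
108 links: {'crispr': 88, 'trna': 15, 'prophage': 5} (16 phages linked by >= 2 channels)
polyvalent phages: 60% by count, 62% by abundance
vs planted truth: precision 1.000, recall 1.000
...
mantel:chlorine: stat=+0.755 p=0.001 q=0.0012
PCoA: PCo1 83.7%, PCo2 2.0% of positive-eigenvalue variance
```

Reading this: the configured ~7-fold disinfection effect on defense-carrier
abundance is recovered from raw alignment records; all 108 planted host
links are found with no false positives; and chlorine concentration is a
significant driver of community dissimilarity (Mantel on Bray–Curtis vs
covariate distance).

The same computation is available as a single command:

```bash
vdp run --synthetic --seed 42 --out results/pipeline
```

and stage-by-stage as `vdp synth | derep | quant | taxa | crispr | link |
profile | stats`.

## Layout

```
src/vdp/        library: io, synth, abundance, derep, taxonomy, crispr,
                linkage, defense, stats, pipeline, cli
analysis/       numbered narrative drivers over the library
tests/          pytest suite (unit, property and end-to-end tests)
scripts/        acceptance.py
docs/methods.md model, parameter and design notes
```
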