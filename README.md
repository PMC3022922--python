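# ap2erf

Tools for genome-wide surveys of the **AP2/ERF transcription-factor
superfamily** and for qPCR expression profiling of its members, modeled
on the workflow used to characterize the family in grapevine
(*Vitis vinifera*) berry ripening.

The AP2/ERF superfamily comprises every protein carrying at least one
AP2 DNA-binding domain. Architecture defines the families: a single AP2
domain (ERF family), a tandem double AP2 domain (AP2 family), or an AP2
domain plus a B3 domain (RAV family), with a single divergent "Soloist"
gene conserved across plant genomes. ERF-family genes are further
subdivided into whole-protein similarity groups I–X (plus VI-L and
Xb-L). The package is aimed at plant genomicists who want to run this
survey on a predicted proteome and at anyone analyzing qPCR Ct data
with the ΔCt/ΔΔCt formalism.

## What it does

* **Domain scanning** — position-specific scoring matrices built from
  gap-free seed alignments; weight of residue *a* at column *c* is
  `log2(((n_ac + κ·bg_a)/(n + κ)) / bg_a)` bits; sliding-window scoring
  with greedy non-overlap resolution and a relative-score threshold.
* **Gene-model QC** — flags introns > 10 kb as unreliable, splits gene
  models encoding ≥ 2 single-domain ERF proteins at inter-domain
  midpoints, and excludes probable pseudogenes (protein < 100 aa with
  ≥ 2 introns > 10 kb).
* **Family/group classification** — architecture rules for the family;
  nearest labeled reference under global alignment (BLOSUM62, affine
  gaps, gap columns excluded from identity) for the ERF group, with
  conserved-motif corroboration and Soloist resolution.
* **Phylogeny** — Saitou–Nei neighbor joining on pairwise-deletion
  p-distances, with column-bootstrap edge supports; Newick output.
* **Chromosomal landscape** — per-chromosome counts, tandem clusters of
  same-group genes (adjacent gaps ≤ 100 kb), paralogous-segment
  annotation from a BED file.
* **Expression** — relative expression ΔCt = Ct_HK − Ct_gene against the
  arithmetic mean of four housekeeping genes; detectability flags;
  average-linkage expression clustering; primer-efficiency QC
  (window 1.7–2.0).
* **Differential expression & enrichment** — ΔΔCt log2 fold changes
  between ripening stages, |log2FC| ≥ 2 (4-fold) DEG calls, one-sided
  Fisher's exact group-overrepresentation tests, cross-tissue DEG set
  algebra, Spearman/Pearson profile correlations.
* **Synthetic data** — a generator that plants all of the above
  structure (domains, defects, clusters, fold changes, an enriched
  group) with full ground truth, so the pipeline is testable end to end.

The published skin/flesh differential-expression tables and the
cross-species family-size comparison are bundled as TSV fixtures
(`src/ap2erf/fixtures/`) and can be re-analyzed directly.

## Worked example

```bash
ap2erf simulate --seed 3 --out study/
ap2erf survey --out survey/ \
    --panel study/panel.fasta --panel-labels study/panel_labels.tsv \
    --proteome study/proteome.fasta --gff3 study/models.gff3
ap2erf expression --out fixtures-run/ --fixtures
```

The survey prints `survey outputs in survey/` and writes the domain-hit
table, QC report (the two planted fused models split into `_a`/`_b`…
products, the planted pseudogene excluded), the family/group catalogue,
an NJ tree and the tandem-cluster report. The fixtures run writes
`fixture_report.json` containing:

```json
"deg_counts": {"flesh": {"down": 30, "up": 18},
               "skin": {"down": 18, "up": 31}},
"fisher_ix_skin_up": {"K": 40, "N": 149, "k": 13, "n": 31,
                      "p": 0.03120608949288659}
```

i.e. 31 genes ≥ 4-fold up and 18 down in ripening berry skin (18 up /
30 down in flesh), and group ERF-IX — 13 of the 31 skin-up genes
against a genome background of 40/149 — significantly overrepresented
(one-sided Fisher p ≈ 0.031). Three genes rise in both tissues and one
(VvERF018) falls in both.

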