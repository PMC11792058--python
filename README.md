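# chromdyn

Analysis toolkit for chromatin dynamics during a primed-to-naive pluripotent
stem-cell conversion under an shRNA knockdown, covering the downstream
computations such a study needs once peaks, coverage tracks, expression
tables and AP-MS intensities are on disk:

* **Peak atlas & occupancy patterns** — unify per-sample peak calls
  (single-linkage merge of ≥ 1 bp overlaps) into a locus atlas, build the
  binary presence matrix over the ordered samples (two arms × four time
  points), select dynamic loci, and classify each locus's
  (control, knockdown) bit-pattern pair into a nine-category taxonomy:
  permanently open, accelerated/decelerated opening/closing,
  knockdown-specific open/closed, stable-other, complex.
* **Cell-type specificity** — naive/primed-specific gene sets from an
  ESC-vs-EpiSC contrast (moderated t on log2 values, BH correction,
  2-fold / q < 0.01); a per-gene specificity Z-score
  `z_g = (log2FC_g − mean)/SD` (positive = naive-high); association of atlas
  loci to genes with a TSS within 2 kb; per-category enrichment of
  associated genes' Z-scores by two-sided Mann–Whitney U against the
  permanently-open reference; gene-set time-course scoring as the
  per-sample sum of per-gene Z with Welch tests against unchanged genes.
* **Coverage quantification** — bedGraph tracks binned and CPM-normalized;
  scaled metagene profiles (3 kb flanks at native resolution, body rescaled
  to 100 bins) stratified by expression quartile (expressed = normalized
  tag count > 100); the per-gene TSS(±500 bp)/gene-body coverage ratio;
  summit-centered ±2 kb pileup matrices.
* **AP-MS interactor filter** — ≥ 1 unique peptide, bait intensity ≥ 1e6,
  bait ≥ 2× control, and exclusion of 18 common-contaminant name prefixes
  (Rpl, Rps, Tub, Gapdh, Act, Myh, Ighg, Iglv, Col, Golga, Kif, Myl, Krt,
  Eif, Vim, Atp, Igkv, Ighv); cell-type set comparison and TF/epigenetic
  annotation.
* **Synthetic-data generator** — a single-chromosome study with planted
  ground truth (gene labels, locus categories, true interactors) emulating
  the 8-sample design, so every stage is testable without downloads.

## Worked example

Run the end-to-end pipeline on the default synthetic study:

```bash
chromdyn run --seed 5 --out run_out
# wrote run_out (stages: simulate, atlas, specificity, metagene, interactome)
```

`run_out/` then contains the atlas (`atlas.bed`), presence matrix,
per-locus categories, the category-enrichment table, gene-set time-course
scores, metagene/ratio/pileup tables, filtered interactor tables and a
reproducibility manifest. The same analyses are available as library calls:

```python
from chromdyn import (SimConfig, simulate_study, unify_peaks, presence_matrix,
                      specificity_z, associate_loci, category_enrichment)
from chromdyn.atlas import classify_matrix

data = simulate_study(SimConfig(seed=1), with_tracks=False)
atlas = unify_peaks(data.peak_sets.values())
pm = presence_matrix(atlas, data.peak_sets, data.cfg.samples)
cats = classify_matrix(pm)
ed = data.expression
z = specificity_z(ed.table, ed.esc_cols, ed.episc_cols)
assoc = associate_loci(atlas, data.genes, 2000, locus_ids=pm.locus_ids)
print(category_enrichment(dict(cats["category"]), assoc, z)
      [["n_loci", "n_genes", "median_z", "q"]])
```

prints (seed 1):

```
                     n_loci  n_genes  median_z             q
category
accelerated_closing      97       94  0.028735  1.000000e+00
accelerated_opening      97       87 -0.013048  1.000000e+00
complex                 127       90  0.002210  1.000000e+00
decelerated_closing      86       78  0.002210  1.000000e+00
decelerated_opening     105       99  0.029226  1.000000e+00
kd_specific_closed      116       95  0.023498  1.000000e+00
kd_specific_open        221       64  1.673969  1.898974e-09
permanently_open         82       74  0.027631  1.000000e+00
stable_other             66       65 -0.010590  1.000000e+00
```

Only the knockdown-specific open loci — planted within 2 kb of
naive-specific TSSs by the generator — carry associated genes with strongly
positive specificity Z-scores (median 1.67, BH-adjusted Mann–Whitney
q ≈ 2e-9 versus the permanently-open reference); every other category sits
at |median z| < 0.03, exactly the planted structure.

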