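# mirenrich

Cell-type-enriched miRNA calling and bulk-profile deconvolution for
sorted-population small-RNA sequencing of injured and repairing kidney,
plus cross-species miRNA harmonization and urinary-biomarker
statistics.

## The problem

A miRNA's abundance in bulk tissue mixes two signals: its expression
within each cell type and the proportion of that cell type in the
sample. In kidney injury both change at once — macrophages flood in,
proximal tubules are lost — so a bulk fold change alone cannot say
*which cells* changed or *what* changed in them. This package
implements the analysis for a design that resolves the ambiguity:
small-RNA counts from four FACS-sorted populations (proximal tubule
PT, macrophage Mac, endothelial EC, PDGFR-β⁺ stroma PDGFRB) across four
conditions of a reversible obstruction time course (sham, UUO2, UUO7,
RUUO).

The core steps, in the field's standard notation:

* **Normalization** — CPM with TMM between-sample factors; log2-CPM
  with a library-scaled prior count.
* **Enrichment calling, per condition** — standardize each miRNA over
  the condition's samples, z = (x − mean)/SD; cluster the standardized
  profiles by fuzzy c-means (c = 16, fuzzifier m = 1.18), keeping
  clusters elevated in a single cell type; independently threshold the
  mean cell-type z-score at z > 1.15; a miRNA is enriched in a cell
  type only when *both* routes agree, and enrichment for more than one
  cell type is Not Cell Specific.
* **Consistency tiers** — same single-cell call in 1 / 2–3 / 4
  conditions → low / moderate / high; different cells → switching.
* **Deconvolution** — two-group DE (simplified NB conditional exact
  test; significant iff |FC| > 1.5 and Benjamini–Hochberg FDR < 0.05),
  then the ECDF of each high-consistency enriched set's logFCs is
  compared against the non-enriched background with a two-sample
  Kolmogorov–Smirnov test. A shift in bulk without a matching shift in
  the isolated population flags a cell-composition change.
* **Cross-species matching** — mouse↔human mature miRNAs paired on an
  identical seed (nucleotides 2–7) plus name similarity, with strict
  one-to-one uniqueness and an ambiguity report.
* **Biomarker statistics** — 2^−ΔΔCt relative quantification against a
  spike-in or endogenous reference, Mann–Whitney tests, ROC with
  DeLong confidence intervals, and a multivariable logistic marker
  combination.

A first-class synthetic-data module generates all inputs with known
ground truth (planted enriched sets, controlled bulk mixture
proportions, Ct tables), which is what the test suite validates the
pipeline against. See `docs/methods.md` for the full model description
and design rationale.

## Worked example

Run the whole staged workflow on the built-in synthetic preset (800
miRNAs, 4 × 4 × 4 samples, 8-fold planted enrichment, macrophage
fraction rising 0.05 → 0.30 with injury):

```sh
mirenrich run --seed 1 --out demo
# wrote 13 artifacts to demo (manifest.json holds content hashes)
```

`demo/enrichment_table.tsv` holds the per-condition assignment and
tier of every miRNA:

```text
mirna_id         sham    UUO2    UUO7    RUUO    tier  cell    n_conditions_enriched
mmu-miR-1001-5p  PDGFRB  PDGFRB  PDGFRB  PDGFRB  high  PDGFRB  4
mmu-miR-1004-5p  EC      EC      EC      EC      high  EC      4
mmu-miR-1005-5p  Mac     Mac     Mac     Mac     high  Mac     4
```

`demo/set_shifts.tsv` is the deconvolution readout for the bulk
UUO7-vs-sham contrast — each high-consistency enriched set's KS
statistic D, p-value, and median logFC shift against the non-enriched
background:

```text
set     n   D       p_value    median_shift
PT      64  0.716   4.4e-30    -0.727
Mac     64  0.881   3.8e-53     1.278
EC      64  0.121   0.35       -0.070
PDGFRB  64  0.517   1.1e-14     0.456
```

Read: macrophage-enriched miRNAs shift strongly upward in bulk
(composition: macrophage influx), PT-enriched miRNAs shift downward
(tubule loss), endothelial miRNAs do not move — exactly the planted
mixture dynamics, recovered from counts alone. The paired
bulk-vs-isolated-population comparison
(`deconvolution.bulk_vs_population_shift`) confirms the Mac shift is
compositional: the same set shows no shift within the sorted
macrophages themselves.

Individual stages are available as subcommands (`simulate`,
`preprocess`, `enrich`, `deconvolute`, `match-species`, `overlay`,
`biomarker`) and as library functions under `mirenrich.*`.

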