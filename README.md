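# cgdist

Quantification of cortical granule (CG) distribution in confocal images of
mammalian oocytes, with a synthetic-data generator that makes every stage
testable without real microscopy data.

## The scientific problem

Cortical granules are secretory vesicles (0.2–0.6 µm across) that oocytes
accumulate during growth. As an oocyte acquires meiotic competence, CGs
migrate from the ooplasm interior to the cortex; after sperm fusion their
exocytosis hardens the zona pellucida and blocks polyspermy. Where the
granules sit is therefore a readout of cytoplasmic maturity, routinely
assayed with FITC-labelled peanut agglutinin (PNA) on confocal sections.

This package implements the two standard measurements and the companion
transcript summary:

* **I_cgd (index of cortical granule distribution).** On an equatorial
  optical section, the ooplasm is split into a central region holding 80%
  of the section area and a peripheral band holding the remaining 20%.
  Then

  $$I_{cgd} = \frac{\overline{I}_{\text{peripheral}}}{\overline{I}_{\text{central}}}$$

  the ratio of mean raw fluorescence intensities. Values near 1 indicate a
  homogeneous distribution; values well above 1 indicate cortical
  concentration. The split is realized by thresholding the Euclidean
  distance to the mask boundary (a uniform-width band, which coincides
  with the radial construction on a disc: central radius $\sqrt{0.8}\,R$).

* **Peripheral CG density.** On a section tangential to the apical pole,
  granules are detected with a multi-scale Laplacian-of-Gaussian detector
  and counted in three disjoint sampling windows; the per-oocyte density
  is the mean of the three window densities in CGs per 100 µm².

* **Two-group comparison.** Independent-samples Student's t-test (pooled
  variance by default, Welch by flag), reported as mean ± SD (n) per
  group with a two-sided p-value.

* **Transcript summary.** From a differential-expression table (fold
  change as the after/before ratio, corrected p-values), genes are called
  up (fold ≥ 2, p < 0.05) or down (fold ≤ 0.5, p < 0.05); each Gene
  Ontology term is summarized by the net-direction Z-score
  $z = (n_{up} - n_{down})/\sqrt{count}$ and a gene-by-term occurrence
  matrix. A 39-gene table and an illustrative five-term membership file
  are packaged.

Because no raw imaging data are publicly deposited for this assay, the
package ships a **synthetic confocal generator** with exact ground truth:
disc-shaped equatorial sections whose granules are placed with a tunable
peripheral bias `p` (fraction placed in the outer 20%-area annulus), and
flat cortical-surface fields with Poisson-placed granules at a target
density. Every estimator in the pipeline is validated against this
generative model.

## Worked example

The numbered drivers under `analysis/` run the whole pipeline on a
simulated demonstration cohort (two groups of 10 oocytes whose peripheral
biases were chosen so the cohort means land near the low/high-competence
regime):

```
$ python analysis/01_simulate_cohorts.py
$ python analysis/02_icgd_comparison.py
measured 20/20 oocytes (truth masks)
                           count   mean    std
mask      group
segmented high_competence     10  1.488  0.046
          low_competence      10  1.275  0.045
truth     high_competence     10  2.243  0.136
          low_competence      10  1.473  0.059
high_competence: 2.243 ± 0.136 (n=10) vs low_competence: 1.473 ± 0.059 (n=10) |
t=16.429 df=18.0 p=2.785e-12 (significant at alpha=0.05)
```

Read: on the true ooplasm masks the low-competence group averages
I_cgd ≈ 1.47 (granules mildly cortical) and the high-competence group
≈ 2.24 (strongly cortical); the t-test separates them decisively. The
`segmented` rows show the same images measured through automatic
segmentation — the segmented boundary sits a few percent outside the true
disc, which dilutes the peripheral band and pulls the index down; both
conventions are reported so the effect is visible.

```
$ python analysis/05_de_summary.py
39 genes: {'up': 6, 'down': 33, 'unchanged': 0}
                                       term  count  n_up  n_down      z
          branching morphogenesis of a tube      7     0       7 -2.646
           cellular component morphogenesis     15     6       9 -0.775
...
```

Read: 6 of the 39 genes rise after in vitro maturation and 33 fall; every
GO term trends downward (negative z), least so for "cellular component
morphogenesis", which contains all six upregulated genes.

`analysis/03_density_recovery.py` and `analysis/04_bias_recovery.py` run
lighter versions of the simulation studies (density recovery through the
detector; bias ordering, power, type-I error).

A command-line interface mirrors the drivers for one-off use:
`cgdist simulate | segment | icgd | density | compare | de-summary`
(see `cgdist --help`).

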