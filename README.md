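# psipath

Exon-level splicing analysis for paired-tissue bulk RNA-seq cohorts:
junction-based percent-spliced-in (PSI) quantification, a staged
filtering cascade, principal-component variance analysis, per-bin
linear mixed models for differential exon usage, compartment
(cell-type) scoring of bulk biopsies, and detection of "spliceopathy"
outliers — samples whose transcriptome-wide splicing profile resembles
the wrong tissue.

The package is written for transcriptomics analysts working with
cohorts of paired biopsies (here: ileum and rectum from pediatric IBD
patients) who want exon-usage analysis that is junction-only (no
exon-body counting, no isoform model) and robust to the low exclusion
counts typical of whole-mRNA sequencing depth.

## The method

**PSI.** For each exonic bin *b* (obtained by splitting the union of a
gene's transcript exons at every exon boundary), inclusion reads IR are
junction reads whose intron ends at the bin's upstream edge or starts
at its downstream edge (two flanks, averaged), and exclusion reads ER
come from junctions whose intron spans the bin:

    PSI = IR / (IR + ER)  ∈ [0, 1]

Low-count handling: when ER < 10 the ratio is unstable, so PSI is
rounded **up** to the nearest tenth if IR ≥ 10 and reported missing
(NA) if IR < 10. Junctions need ≥ 5 unique reads; multi-mapping reads
are ignored.

**Filtering.** Bins with any missing sample are removed, then bins
identically 0 or 1, then bins where 40% of samples sit above 0.95 or
below 0.05 PSI. A relaxed variant (for the outlier analysis) tolerates
up to five missing ileal and five missing rectal samples per bin,
imputing them with the tissue-location mean.

**PCVA.** For each of the top 10 PCs of the expression (log₂ CPM) or
PSI matrix, a linear model on ancestry + location + disease +
location×disease attributes a fraction of that PC's variance to each
term (Type-II sums of squares / total SS); fractions are summed over
PCs weighted by each PC's share of total variance.

**Differential splicing.** Per bin,
`PSI ~ disease + location + ancestry + disease:location + (1 | individual)`,
likelihood-ratio tests per term, Benjamini–Hochberg control at 5% FDR.
Singular random-intercept fits fall back to OLS and are flagged.

**Spliceopathy detection.** In the top-2 PC space of the filtered PSI
matrix, a sample whose distance ratio (own-tissue centroid /
opposite-tissue centroid) exceeds 1 is flagged as tissue-discordant;
flagged samples are then characterized with a three-group mixed model
(ileum / rectum / spliceopathy + ancestry), and the divergent bins that
are also tissue-differential ("rectal-like" sites) suffice to classify
samples by tissue.

Every stage is exercised end to end on a synthetic cohort generator
(`psipath.simulate`) with known ground truth: planted tissue/ancestry
effects on the logit-PSI scale, per-individual random intercepts,
negative-binomial junction coverage split binomially into IR/ER, and
planted spliceopathy individuals.

## Worked example

```bash
python analysis/01_simulate_cohort.py
python analysis/02_quantify_psi.py
python analysis/03_filter_cascade.py
python analysis/04_pcva.py
python analysis/05_differential_splicing.py
python analysis/06_compartment_scores.py
python analysis/07_spliceopathy.py
```

Output of the first four steps (seed 1):

```
  samples: 125 from 34 individuals
  spliceopathy samples: ['IND28_I1', 'IND28_I2', 'IND34_I1', 'IND34_I2']
  variable exonic bins: 300 (18 tissue-differential, 15 discordant in the outliers)
      complete:   660 ->   651 (-9)
      constant:   651 ->   293 (-358)
  constitutive:   293 ->   293 (-0)
mean PSI after filtering: 0.53
psi: PC1-PC10 hold 43.6% of variance
              ancestry:   3.4%
              location:  18.4%
               disease:   0.5%
      location:disease:   0.0%
```

Reading: of the 660 flattened bins (anchors included), 293 survive the
cascade; tissue location is by far the largest variance component of
splicing, ancestry is a smaller but visible one, and disease is near
zero — the planted structure of the cohort. Step 7 then flags exactly
the four planted discordant ileal samples, and classifies them as
"rectum" using the rectal-like site subset alone.

The same run is available as a single command via the pipeline CLI:

```bash
psipath run --seed 1 --out psipath_run
```

## Layout

- `src/psipath/` — library: `simulate`, `annotation`, `psi`, `filters`,
  `pcva`, `diff_splice`, `compartments`, `outliers`, `pipeline`, `cli`
- `analysis/` — numbered narrative drivers reproducing the study on the
  synthetic cohort
- `tests/` — unit, property and acceptance tests (brute-force oracles
  in `tests/oracles.py`)
- `docs/methods.md` — modeling assumptions, parameter choices, and
  limitations
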