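# Methods

This note records the models behind `psipath`, the defaults and why
they were chosen, what the synthetic cohort does and does not emulate,
and the numerical conventions that make results reproducible.

## PSI quantification

The unit of quantification is the *exonic bin*: the union of a gene's
transcript exons split at every exon boundary occurring in any
transcript, numbered `E001, E002, ...` in genomic-coordinate order
(strand does not affect numbering; coordinates are 1-based inclusive
throughout, matching GTF and STAR junction files). Bins overlapping
two genes are excluded as ambiguous.

Inclusion reads (IR) for a bin are junction reads whose intron ends at
`start − 1` or begins at `end + 1`. When both flanks carry junctions,
IR is the **mean** of the two flank totals, keeping IR commensurate
with the single skipping junction that supplies exclusion reads (ER:
total reads over junctions whose intron strictly contains the bin).
An `ir_mode="sum"` switch is provided because flank handling is a
genuine convention choice. Junctions below 5 unique reads are dropped
at parse time; multi-mapping reads are never counted.

Low-count rules: with ER ≥ 10, PSI = IR/(IR+ER) exactly; with ER < 10
and IR ≥ 10 the ratio is rounded up to the nearest tenth (a deliberate
upward bias that prevents a handful of exclusion reads from creating
spurious variability at well-covered, near-constitutive bins); with
both under 10 the bin is missing in that sample. Boundary values
resolve to the favorable branch (ER = 10 exact, IR = 10 round-up),
since the demotion rules are written as strict `< 10`. The ceiling is
computed in integer arithmetic (counts are integers or halves), so a
ratio that is exactly 0.8 never drifts to 0.9 by a float epsilon.

## Filtering cascade

1. **complete** — drop bins missing in ≥ 1 sample;
2. **constant** — drop bins identically 0 or identically 1 (the rule
   is implemented as printed: constant rows at other values are kept,
   though the constitutive stage usually removes near-extreme ones);
3. **constitutive** — drop bins where the count of samples with
   PSI > 0.95, or separately with PSI < 0.05, reaches
   `ceil(0.40 · n_samples)`.

The 40% rule is interpreted per direction, with `ceil` so the
threshold is attainable at any cohort size; both the direction
combination and the ≥-vs-> boundary are exposed as switches because
the natural-language rule does not pin them down.

The relaxed variant for the outlier analysis drops bins with more than
five missing ileal samples, more than five missing rectal samples, or
any missing outlier-group sample; surviving missing values are imputed
with the mean over non-missing samples of the same tissue location
(outlier samples excluded from the imputation pool because they form
their own analysis group), then stages 2–3 reapply. Every bin passing
the strict coverage rule passes the relaxed one by construction.

## PCVA

PCA is computed over samples with feature centering but no unit-
variance scaling (PSI already lives on [0, 1]; log₂ CPM on a common
log scale). Each PC is oriented so its largest-magnitude loading is
positive — an arbitrary but deterministic convention. Per PC, an OLS
model on `C(ancestry) + C(location) + C(disease) +
C(location):C(disease)` is fitted and each term's Type-II sum of
squares is divided by the PC score's total sum of squares. Type-II
(each main effect adjusted for the others, interaction adjusted for
mains) avoids order dependence in the approximately-but-not-exactly
balanced cohort; sequential SS would make the table depend on term
order. Repeated biopsies of an individual are deliberately ignored
here, matching the four-term factor list of the analysis this package
reproduces. Components are combined across the top 10 PCs weighted by
each PC's variance fraction, so no component can exceed the summed
PC variance. Expression is normalized as log₂(CPM + 1) after dropping
genes with mean count ≤ 5.

## Differential splicing

Per bin: `PSI ~ disease + location + ancestry + disease:location`
with a random intercept per individual, fitted by maximum likelihood
(statsmodels MixedLM). PSI is modeled untransformed — the estimates
are then directly PSI differences; a logit option exists. Term
p-values are likelihood-ratio tests: the interaction against the
main-effects model; disease and location between models *without* the
interaction (they are marginal to it); ancestry with the interaction
retained. LRT was chosen over Wald/Satterthwaite because it is
reproducible across mixed-model implementations; `test="wald"` is
available. When the random-intercept variance estimates to zero
(relative tolerance 1e-6 of the residual variance) or the fit fails,
the bin is refit by OLS and flagged `fallback` — three-sample outlier
groups invite singular fits and silent failure is unacceptable.
Constant rows return p = 1, estimate 0, flagged. Multiplicity is
controlled per term by Benjamini–Hochberg at q = 0.05 (configurable).

The outlier-group variant swaps fixed effects for `group`
(ileum / rectum / spliceopathy) + ancestry: the group term gets a 2-df
LRT, and the spliceopathy−ileum and spliceopathy−rectum contrasts get
Wald tests from the full fit.

## Compartment scoring

A gene is a compartment marker iff it exceeds 5 CPM in that cell type
and stays below 1 CPM in the other two (strict inequalities), which
forces disjoint sets. Sample scores are PC1 over the marker submatrix
of the log-CPM expression matrix, sign-oriented to correlate
positively with mean marker expression — a proportion surrogate, not a
deconvolution. Group comparisons use Welch's two-sided t-test
(group sizes and variances differ).

## Spliceopathy detection and characterization

Visual identification of discordant samples on PC plots is formalized
as: in the top-2 PC space of the filtered PSI matrix, score = distance
to own-tissue centroid ÷ distance to opposite-tissue centroid; flag
when score > 1 (strictly). Centroids are estimated once from all
samples and once more excluding the initially flagged ones, so an
outlier cannot drag its own centroid. |ΔPSI| profiles between group
means use half-open 0.05-wide classes (a difference of exactly 0.05
counts in the second class; the last class is closed). The heatmap
takes the 50 most location-significant bins (ties by |estimate|, then
bin id) and clusters both axes with complete linkage on Euclidean
distance, rows/columns pre-sorted by id so leaf orders are
deterministic under ties. "Rectal-like" sites are the set
intersection of outlier-divergent and tissue-differential bins;
classification on those sites assigns each sample to the nearer tissue
centroid computed from non-outlier samples.

The "intermediate" sample group (extreme on PC2 of expression) is
accepted as metadata rather than auto-called: no explicit rule for it
is available to formalize.

## Synthetic cohort

The generator emulates the study design: 34 individuals, paired ileal
and rectal biopsies in duplicate with ~12.5% of replicates lost to QC
(every individual keeps at least one biopsy per location — the
post-QC cohorts this mirrors retained both tissues for everyone),
18/34 European vs African ancestry, 20/34 CD vs UC, 20/34 established
vs at diagnosis. True PSI per bin starts from a uniform baseline on
[0.1, 0.9]; planted effects move the second tissue (or ancestry
group) by exactly `location_delta_psi` (resp. `ancestry_delta_psi`)
on the PSI scale, with baselines re-drawn at effect bins so the
shifted value stays inside [0.05, 0.95]; per-individual random
intercepts (SD 0.2) act on the logit scale and the result is clipped
to [0.001, 0.999] to keep binomial parameters valid. Location- and
ancestry-effect bins are disjoint so each component is separately
recoverable. Coverage per bin and sample is negative binomial (mean
170 — a realistic informative-read depth for whole-mRNA sequencing —
size 5), split binomially into IR/ER.

Genome layout: one synthetic chromosome; each gene alternates
constitutive anchor exons with variable exons (100 bp exons, 200 bp
introns), five variable bins per gene. Every variable bin gets two
flanking inclusion junctions (both written with the inclusion count)
and one anchor-to-anchor skipping junction, making junction→bin
assignment exactly invertible — the flattened GTF the generator writes
reproduces its own bin layout, which is what the end-to-end oracle
tests rely on.

Spliceopathy: `n_spliceopathy_individuals` individuals' ileal samples
take the *rectal* true PSI at a subset of the location-effect bins
(a rectal draw at a bin with no tissue difference would be a no-op,
so discordant bins are sampled among tissue-differential ones).
Defaults — 6% of bins tissue-differential at ΔPSI 0.25, 5% of bins
discordant — were fixed from the geometry of the phenotype being
emulated: a sample discordant at a fraction *r* of the
tissue-differential bins sits at *r* of the way along the tissue axis
in PC space, and only crosses to the opposite tissue's side (the
defining phenotype of these outliers, and what the centroid-ratio
rule detects at threshold 1) when *r* > 0.5 with margin over the
individual-level noise. Effect-size *distributions* in real data are
unknown; all of these are honest placeholders exposed via `SimConfig`,
not claims about real cohorts.

Gene expression is a three-compartment mixture: disjoint marker
blocks (12.5% of genes each) expressed at 50–500 CPM in their own
compartment and < 0.5 CPM elsewhere, background genes at 20–100 CPM
everywhere; per-sample compartment proportions are Dirichlet around
per-tissue baselines (concentration 100), spliceopathy ileal samples
get intermediate proportions (their expression is between tissues even
though their splicing is rectal-like), counts are Poisson around the
log-normally perturbed mixture at a 150–250k library size.

**What the generator does not emulate** — and hence what passing
tests cannot show about real data: no sequence content or read-level
artifacts (mapping bias, overhang effects), no correlated effect
sizes across bins of one gene, no novel/cryptic junctions, no
intermediate-expression sample group beyond the planted outliers, no
library-preparation batch structure, and compartment mixing does not
feed back into the splicing profiles (in real tissue, cell-type
composition itself shifts exon usage).

## Problem sizes

Default synthetic cohorts use 300 variable bins (660 flattened bins
with anchors) and ~119–125 samples. Replicated checks use 200-bin
cohorts over 50 seeds (variance-component recovery), 500 simulated
bins (mixed-model calibration), and 20 cohorts (outlier recovery);
`scripts/acceptance.py` re-runs the same computations at a reduced
replicate count (20 PCVA runs, 200 null bins, 6 cohorts) chosen to
keep a full from-scratch reproduction comfortably under half an hour
on one core.

## Known limitations

- PSI is modeled with Gaussian errors on [0, 1]; heteroscedasticity
  near the boundaries is absorbed, not modeled (no beta/binomial GLMM).
- The round-up rule biases PSI upward at low ER by design; estimates
  at near-constitutive bins are not unbiased.
- The LRT χ² reference is asymptotic; at ~119 samples its null
  rejection rate is verified empirically but small-sample corrections
  (Kenward–Roger) are not implemented.
- The centroid-ratio outlier rule assumes exactly two locations and
  detects only wholesale discordance; a sample discordant at a small
  minority of tissue-differential bins will not cross the threshold.
- Marker derivation trusts the reference CPM table; no cross-dataset
  normalization is attempted.
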