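# Methods

## The experimental design being modeled

A DNA-SIP experiment pairs a *labeled* gradient (community fed an
isotopically heavy substrate) with a *control* gradient (same community,
light substrate). Each gradient is ultracentrifuged to equilibrium in
CsCl and collected drop-wise from the bottom of the tube, so fraction 1
is the densest; a 4.8 ml gradient gives 12 fractions at 400 µl or 24 at
200 µl. Per-fraction DNA mass (fluorometry) and 16S rRNA gene copies
(qPCR) are measured, fractions are grouped into named pooled density
fractions, and pooled fractions are amplicon-sequenced. Taxa that
assimilated the heavy substrate shift their DNA into denser fractions of
the labeled gradient only; everything downstream is built to detect that
shift.

## Buoyant-density model

Unlabeled double-stranded DNA bands at

    BD0 = 1.660 + 0.098 · GC      [g/ml]

and incorporation of heavy isotope at atom-fraction excess *x* adds a
shift *x* · Δmax, with Δmax = 0.036 g/ml for ¹³C and 0.016 g/ml for ¹⁵N.
These constants are the standard values used in quantitative-SIP work;
they are keyword-overridable in `mean_buoyant_density`. The smaller ¹⁵N
shift is the physical reason ¹⁵N experiments need finer fractionation
(24 × 200 µl) and longer centrifugation than ¹³C ones.

Within a taxon the band is a single Gaussian with standard deviation
`band_sigma` (default 0.006 g/ml), a deliberate simplification that
ignores diffusion kinetics, rotor geometry and fragment-length effects
while still producing the overlapping light/heavy bands the statistic
must resolve. Partial labeling shifts the whole band; the model does not
currently represent a bimodal labeled/unlabeled split within one taxon,
which would arise from short feeding times (long feeding, broad
population labeling is the regime assumed).

## Synthetic-experiment generator

`simulate_dataset` composes, per gradient:

1. per-taxon fraction masses: `total_dna_ng · base_abundance ·`
   Gaussian-integral proportions over the collection windows
   (renormalized over collected windows; mass is conserved to 1e-6
   before noise). Atom excess is applied in the labeled gradient only.
2. per-fraction 16S copies: mass-weighted by each taxon's 16S copy
   number, converted at 1.85·10⁵ genome equivalents per ng (a 5 Mb
   genome at 650 g/mol per bp), then multiplied by mean-one lognormal
   noise with coefficient of variation `qpcr_cv` (default 0.10) to
   emulate qPCR measurement error.
3. pooled-fraction reads: for each pooling window, a multinomial draw of
   `reads_per_pool` reads (default 50,000) over taxa, with probabilities
   proportional to pooled DNA mass × 16S copy number. Amplicon noise is
   multinomial only; there is no PCR-bias or sequencing-error term, so
   passing detection benchmarks here bounds performance under ideal
   library conditions, not under primer bias or chimera contamination.

All draws derive from one root seed through `numpy.random.SeedSequence`
spawning (four independent streams: qPCR noise and read counts, labeled
and control), so a config is exactly reproducible.

The reference community (`default_community`) has 30 taxa with
Dirichlet(1) abundances (uneven, a few dominant and many rare members,
as in real gut communities), GC content uniform on 0.35–0.65 (the
typical bacterial range, giving unlabeled buoyant densities
1.694–1.724 g/ml), integer 16S copy numbers 1–7, and 3 labeled members
at atom excess 0.75. `total_dna_ng` defaults to 750, inside the
500–1,000 ng range typically recovered from such gradients; only
relative masses matter downstream.

## Pooling windows

Pooled fractions are half-open density windows [low, high); a fraction
on a shared boundary goes to the denser window, and the densest window
also accepts its own upper edge. Percent-of-gradient normalization
always uses *all* recovered fractions as the denominator, including any
left unpooled, and unpooled fractions are reported rather than dropped.

The shipped default schemes (3 windows for cellulose with medium+lower
dense; 4 for urea with the three densest dense) place the dense-window
edges *above* the buoyant-density range of a typical unlabeled community
(first dense edge at 7/12 of the collected span, 1.73 g/ml for the
default 1.66–1.78 range). This implements the selection rule that pooled
ranges are chosen where labeled and control gradients visibly differ:
control DNA reaches the dense windows only as band tails, so a taxon's
share there can rise only by genuine density shift. Placing dense
windows inside the unlabeled band instead creates compositional
spillover — when labeled taxa vacate a window, every remaining taxon's
relative share in it rises, and at 50,000 reads such closure effects are
statistically significant — inflating false discoveries. Window bounds
are ordinary config values; real experiments should set them from their
own gradient profiles exactly as the visual-difference rule prescribes.

## Activity statistic and significance

Activity is computed on the table collapsed to one rank per run (family
or genus); taxa missing from one gradient are zero-filled, taxa missing
from both are dropped. For each taxon × dense pool, the 2×2 table
[[tNS_lab, NS_lab−tNS_lab], [tNS_ctl, NS_ctl−tNS_ctl]] is tested with
the two-sided Fisher exact test; p-values are adjusted by
Benjamini–Hochberg within each dense pooled fraction (configurable to a
single pooled adjustment across fractions — whether correction should
pool fractions is genuinely open, and within-fraction is the more
conservative reading of per-fraction activity values). Significance
tiers (** / * / +) are read from adjusted values by default, with a flag
for raw p, since heatmap "p" annotations in this literature are
ambiguous post-correction. Fisher + BH is implemented directly rather
than through METASTATS, the tool this test is often run with in the SIP
literature (its FDR pipeline adds a permutation t-statistic for
abundant taxa, which is deliberately not reproduced here).

Zero-sum is an identity of the statistic: both percentage columns sum to
100, so Σ_taxa A = 0 in every pool, and a simulated null is calibrated
(≈0.01 % of tests flagged at q<0.05 in 200 unlabeled replicates, far
under the nominal 5 %, because most null tables are identical-proportion
draws where Fisher is conservative).

## KO-profile arithmetic

Counts are divided by per-taxon 16S copy numbers (missing taxa use a
configurable default or fail loudly), non-labeled families are filtered
out with a removed-row report, and the predicted KO profile is the exact
cross product Σ_taxa abundance(taxon, sample) · gene_count(taxon, KO) on
user-supplied reference tables — no reference database, tree placement
or NSTI is bundled, so prediction quality is entirely that of the
supplied tables. KO enrichment applies the activity formula to KO
*shares*; the share denominator defaults to the curated KO subset under
study (configurable to all KOs), since enrichment among a
substrate-relevant panel is the question being asked. Shares make the
result invariant to uniform copy-number scaling and per-sample
abundance scaling, both verified as properties.

## IRMS computations

δ = (R_sample/R_standard − 1)·1000 ‰. Two-point normalization is the
affine map sending two anchors' measured readings exactly to their
certified values (IAEA-N1 +0.43 ‰, IAEA-N2 +20.40 ‰ for δ¹⁵N);
working-standard chaining composes two affine maps. No m/z = 30 (¹⁵N₂)
trace correction is applied, and no blank/drift correction is in scope.
Technical replicates (3 per biological replicate) are averaged before
any testing; groups are compared by Mann–Whitney U, exact when both
groups have ≤8 untied observations, normal approximation otherwise, with
mean ± SEM (sd/√n, n−1 denominator) reported. With n = 3 biological
replicates per group the exact two-sided p cannot fall below 0.10, so
the default significance call is one-sided (¹⁵N group greater) with an
inclusive threshold: full separation gives exactly p = 0.05 and is
called significant at α = 0.05.

## Numerical and validation choices

- Fisher p, BH-FDR and Mann–Whitney p are each checked against
  independent brute-force oracles (hypergeometric enumeration over all
  2×2 tables with margins ≤30, naive step-up, full rank-assignment
  enumeration for group sizes ≤6) to 1e-12.
- The validation suite sizes were chosen to run on one CPU in a few
  minutes: 50 simulated experiments for the power benchmark (mean
  sensitivity ≥0.9, mean false discovery proportion ≤0.1 at FDR<0.05)
  and 200 for the null flag rate, at the reference scenario's 50,000
  reads per pool.
- Gaussian window masses use `scipy.stats.norm.cdf` differences; a band
  whose captured mass underflows to zero (many σ outside all windows) is
  rejected rather than silently renormalized.
- Detection (`evaluate_detection`) flags a taxon when any dense-pool
  record has q < α *and* A > 0; requiring positive activity matters
  because dilution by incoming labeled DNA gives unlabeled taxa
  systematically negative A in dense pools.

## Known limitations

- No read-level simulation (FASTQ), chimeras, sequencing error, PCR
  bias, or rotor physics; no OTU picking or rarefaction — inputs are
  post-clustering count tables.
- Single-Gaussian bands; no within-taxon labeled/unlabeled bimodality.
- The KO reference tables and curated KO lists are user inputs; shipped
  fixtures are synthetic placeholders, not database extracts.
- Tissue-level δ¹⁵N values depend on instrument data not modeled here;
  the comparison machinery is validated on synthetic measurements only.
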