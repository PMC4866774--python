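# Methods

## Label-propagation model

The tracer simulator treats each metabolite pool as a probability
distribution over the 2ⁿ positional labeling patterns of its n carbons
and iterates a synchronous fixed-point update: every interior pool is
replaced by the flux-weighted mixture of its producing routes, where a
condensation (citrate synthase) takes the product distribution of
independent substrate states, a decarboxylation or cleavage marginalises
the lost carbons, and rotationally symmetric molecules (succinate,
fumarate) are averaged over their two orientations.  MIDs are obtained
by marginalising pattern probabilities over the number of labeled
positions.  Working positionally rather than directly on MIDs makes the
atom bookkeeping exact for positional tracers such as [1-¹³C]glutamine.

Assumptions:

* **Isotopic and metabolic steady state.**  No kinetics are modeled; the
  fixed point is reached by synchronous iteration (tolerance 1e-9 on any
  pattern probability, at most 10 000 iterations — the network converges
  in far fewer).
* **Branch fractions, not absolute fluxes.**  MIDs depend only on the
  relative contribution of routes producing each pool, so the scenario
  is parameterised by: `f_mpc` (fraction of acetyl-CoA from glycolytic
  pyruvate via MPC/PDH; the remainder arrives unlabeled from fatty-acid
  or ketone-body oxidation), `f_gln` (fraction of α-ketoglutarate from
  glutamine), `f_reductive` (fraction of α-KG carboxylated back to
  citrate), `f_anaplerotic_pc` (fraction of oxaloacetate from pyruvate
  carboxylase) and `dilution` (per-iteration exchange of each interior
  pool with unlabeled medium).  All default scenarios live in
  `tracer_sim.SCENARIOS`; the wild-type and carrier-null values encode
  the qualitative directions of the biology (carrier-null: `f_mpc = 0`,
  higher glutamine anaplerosis and reductive fraction) — the underlying
  fluxes were never published, so these are plausible settings, not fits.
* **Open CO₂ pool.**  Released ¹³CO₂ is not refixed; carboxylation
  reactions introduce unlabeled carbon.
* **Atom maps** follow standard TCA stereochemistry: the citrate carbons
  split 4 (oxaloacetate C1–C4) + 2 (acetyl C1–C2); oxidative isocitrate
  dehydrogenase releases the OAA-C1 carboxyl and α-KG dehydrogenase
  releases α-KG C1 (OAA C4 on oxidative turns), so the acetyl carbons
  occupy α-KG C4/C5 and survive into succinate; reductive carboxylation
  is the exact inverse of the oxidative IDH map with the incoming
  carboxyl unlabeled; glutamine C1 (the α-carboxyl) is the carbon lost
  on the oxidative route and retained into oxaloacetate on the reductive
  route.  Citrate production balances CS (weight `1 − f_gln`) against
  reductive carboxylation (`f_reductive`); when both weights vanish the
  CS route is retained so the pool stays defined.  Cleavage-derived
  acetyl-CoA is treated as exported to lipogenesis rather than recycled.

**Known limitation.**  The network contains no reverse
malate-dehydrogenase / fumarase / succinate-dehydrogenase exchange, so
reductive label ([1-¹³C]glutamine M+1, [U-¹³C]glutamine M+3) reaches
oxaloacetate and aspartate but not malate or succinate.  In real cells
near-equilibrium exchange spreads that label into malate, fumarate and
succinate as well; interpreting those specific fractions requires the
exchange reactions this model deliberately omits.

## Natural-abundance correction

With j tracer-labeled carbons, each of the remaining n−j positions is
naturally ¹³C with probability p (default 0.0107), giving the
lower-triangular binomial contamination matrix.  Correction solves the
triangular system exactly, clamps negative entries (noise) to zero and
renormalises; on the well-conditioned n ≤ 6 systems used here exact
inversion and least squares agree, and round-trips recover random MIDs
to 1e-10.  Only carbon is corrected; H/N/O isotopes and tracer impurity
are out of scope (fragment-specific acquisition is supported by letting
n be the fragment carbon count).

## Annotation

Tolerance is absolute (0.001 Da), not ppm.  Adduct deltas: −1.007276
([M−H]⁻), +18.998403 ([M+F]⁻), +20.974666 ([M+Na−2H]⁻), +36.948606
([M+K−2H]⁻); isotope peaks add k × 1.003355.  "F⁻" is read as a fluoride
adduct; the adduct set is configurable, so reading it as formate is a
configuration change, not a code change.  Ambiguous matches are all
retained with the smallest-error one flagged primary, because the
downstream unit is the annotated ion, not a unique compound.  The
packaged library is a synthetic stand-in (see README); its masses are at
least 0.0025 Da apart so zero-noise fixtures annotate unambiguously, and
generated decoy peaks are kept ≥ 0.005 Da from any candidate so they can
never be annotated at the default tolerance.

## Differential statistics

The genotype screen computes Student's (pooled-variance) t on
log₂-transformed intensities — the generators' noise is log-normal, so
the log-scale test is exact-model; Welch's test is available behind
`equal_var=False`.  Fold changes are ratios of raw group means, mutant
over wild type.  FDR control is Benjamini–Hochberg (a q-value estimator
would be less conservative; BH is the default).  A metabolite passes at
q < 0.01 and |log₂FC| > 0.5, and the headline count is the union of
passing sets across the two diets.  Degenerate zero-variance/equal-mean
metabolites get p = 1 by convention.  PCA is a plain SVD of the
column-centred (optionally unit-scaled) matrix, so scores × loadingsᵀ
reconstructs the centred data exactly.

## Respirometry

fCCP-driven OCR is defined as the mean of the fCCP phase minus the mean
of the antimycin A phase; the literature does not always subtract the
non-mitochondrial floor, so `subtract_floor=False` exposes the other
convention.  Oligomycin is present from assay start in the emulated
permeabilized-cell protocol, so no coupling phase is modeled.

## Synthetic data: what it emulates, and what it does not

Generators emulate the *statistical structure* of each acquisition:
log-normal multiplicative intensity noise (default CV 10%, the standard
regime for MS intensities), Gaussian m/z error on centroids, Gaussian
noise on OCR plateaus and Cq values.  The packaged profiles encode the
published effect sizes: `paper_mef_targeted` (n = 3/group) programs the
four-fold aspartate increase, near-complete citrate depletion and
elevated glycolytic intermediates; `paper_brain_normal` (n = 4/group)
programs exactly 46 differential ions among the 222 library ions — 13
named metabolites with their reported directions (lactate, pyruvate,
aspartate, malate, fumarate up; citrate, glutamine, glutamate, GABA,
glutathione, phosphocreatine down; NAAG, proline up) and 33 filler ions
at 2-fold magnitude; `paper_brain_keto` nulls everything except a 30%
residual lactate and aspartate elevation; `paper_qpcr` programs MPC1 at
5% (homozygous) and 50% (heterozygous) of wild type with MPC2 unchanged.
Brain replicate count (n = 4/group) and all magnitudes beyond the
printed ones are free parameters chosen once and documented here.
Per-ion baselines are fixed by an internal constant seed — they are a
property of the emulated tissue, not of the sampling noise.

What passing tests therefore show: the pipeline's arithmetic is correct
and recovers programmed effects at realistic noise and sample sizes.
What they do not show: robustness to real-data pathologies the
generators omit — ionisation suppression, batch effects, missing values,
chromatographic drift, heteroscedastic low-intensity noise, isomer
coelution.

With the profile-fixed conditions (n = 4/group, CV 10%), the ratio-of-
means estimator of the keto-diet lactate increase has a standard error
of ≈ 9 percentage points, so single-seed values scatter accordingly
around the programmed 30%; the screen's union hit count is exactly 46
for most seeds (occasionally one marginal hit drops to 45).

## Numerical choices

Fixed-point tolerance 1e-9 / 10 000 iterations; MID validation at 1e-9
(simulator) and 1e-6 (measured data); correction-matrix singularity
rejected for p → 1; calibration requires ≥ 2 standards and positive
slope, with negative concentrations floored to 0 and flagged; annotation
ties broken by smallest |mass error|, ion tables ordered by m/z with a
stable sort; TSV output uses a fixed float format so identical seeds
give byte-identical files.  Study seeds are expanded into per-stage
child seeds via `numpy.random.SeedSequence`.

## Problem sizes

The packaged studies run at the sizes stated above (222 ions, 3–4
replicates per group, three tracer experiments × two scenarios, three
OCR conditions × three loops per phase); the full test suite and the
reproduction script each complete in seconds on one CPU.
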