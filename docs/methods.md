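# Methods

## Differential HDX-MS model

Backbone amide hydrogens exchange with solvent deuterium at a rate set by
their intrinsic chemistry and their structural environment. In the EX2
limit the observed rate for residue *i* is `k_int,i / P_i`, where `P_i ≥ 1`
is the protection factor, so the deuterium fraction after labeling time *t*
in a bath with deuterium fraction *f* is

    d_i(t) = f · (1 − exp(−k_int,i · t / P_i))

A peptide's noiseless centroid mass shift is `b · 1.006277 Da · Σ d_i`,
summed over its exchange-contributing residues, with `b ∈ (0, 1]` a
back-exchange retention factor (default 1: no correction). The 1.006277 Da
constant is the monoisotopic ²H−¹H mass difference, used both to synthesize
shifts and to convert measured shifts to deuteron counts (#D).

**Normalization.** `%HDX = 100 · #D / N_max`, where `N_max` counts the
peptide's theoretically exchangeable amides: peptide length minus
`skip_first` N-terminal residues (default 1; 2 is offered because many
pipelines also exclude position 2, where the amide exchanges back too fast
to retain label) minus prolines, which have no backbone amide hydrogen. The
convention is a configuration key and is echoed into output metadata.
%HDX values above the labeling ceiling (100·f) can arise under noise and
are flagged-but-retained rather than clipped.

**Differential statistic.** For each peptide shared between two states,
replicate %HDX values are averaged per timepoint and differenced
(bound − free). ΔHDX is the signed difference of maximal magnitude across
timepoints, ties broken toward the earliest timepoint. A peptide is called
significant when all three criteria hold:

* |ΔHDX| > 10 % — strict, following the more detailed prose form of the
  threshold (">10 %") over the figure-legend shorthand;
* two-sample Student's t-test (pooled variance, two-tailed) p < 0.05,
  computed on replicate #D values at the ΔHDX timepoint;
* |Δmass| ≥ 0.5 Da at that timepoint — inclusive ("at least 0.5 Da").

The t-test is scale-invariant within a peptide, so computing it on #D, Da
or %HDX is equivalent; tests assert this. Degenerate zero-variance inputs
give p = 1 (equal means) or p = 0. No multiple-testing correction is
applied; the run report records the number of tests so users can apply
their own. `t_test_scope="any_timepoint"` (minimum p over timepoints) is
available as an alternative to the default max-timepoint scope.

A consequence of testing at the max-|ΔHDX| timepoint is post-selection:
under the null with several timepoints, the marginal fraction of peptides
with p < α exceeds α. The t-test calibration check in the test suite
therefore uses a single-timepoint design, where the selected timepoint is
the only one and the p-value is exact; the multi-timepoint null is checked
on the stricter claim that the full three-criterion call yields zero
significant peptides.

## Synthetic data

The generator emulates the study conditions of a two-state comparison:
80 % D₂O labeling at 3/30/300/3000 s, three replicates, Gaussian replicate
noise of 0.1 Da on the centroid shift (typical centroid repeatability,
small against the 0.5 Da filter). Intrinsic rates default to a per-residue
log-uniform draw over 10⁻²–10² s⁻¹, spanning the labeling window; a
constant-rate option exists for closed-form checks. Planted interface
regions multiply the free-state protection factor by a chosen factor
(>1 protection/decrease, <1 deprotection/increase; for factors <1 the
free-state protection is raised to 1/factor so both states keep P ≥ 1).
Replicate count, noise level and rate model are stand-ins chosen at
realistic values, not literature-derived constants.

What the generator does **not** emulate: EX1/bimodal exchange, isotope
envelopes (only centroids are produced), pH/temperature dependence of
intrinsic rates (residue-specific Bai-type rate tables are out of scope),
back-exchange gradients along the peptide, and chromatographic artifacts.
Passing tests therefore demonstrate the correctness of the statistics and
bookkeeping under idealized EX2 kinetics, not robustness to those
real-data effects.

**Peptide map.** Synthetic pepsin maps tile the protein with overlapping
spans: starts advance by `step` (default 2), lengths are `mean_len ± jitter`
(defaults 7 ± 1), clamped so coverage is complete. The short default length
is a deliberate resolution choice: under mean projection, a residue at
distance *d* outside a protected region receives roughly
`(m − d)² / (2 m²)` of the in-region signal from straddling peptides of
contributing length *m*, so the 10 % threshold localizes region boundaries
to within ~3 residues only when *m* ≈ 6–7. Longer (more typical) peptides
simply blur region edges proportionally; users simulating coarser maps
should expect that.

**Problem sizes.** The end-to-end recovery study uses a 563-residue protein
with 100× protection planted on residues 88–114, 20 seeded replicate runs;
the null-calibration study uses 1000 single-peptide proteins. These sizes
give stable pass/fail statistics while keeping the default suite fast.

## Peptide-to-residue projection

A residue's track value is the mean ΔHDX over all analyzed peptides whose
exchange-contributing span (start+`skip_first` … end, prolines excluded)
covers it — the same positions that carry signal in `N_max`. Including all
peptides (not only significant ones) is the default because it yields
continuous traces; `significant_only` is available. Residues with no
covering peptide are "no data" (NaN, coverage 0), never silently zero.
When a residue is covered by peptides of both signs the signed mean is
reported and the residue is flagged `mixed_sign`. Regions are maximal runs
of covered residues with |value| above threshold (default 10 %) and
constant sign, of length ≥ `min_len` (default 2, suppressing single-residue
speckle).

**Structure export** writes track values into the B-factor column
(fixed-width columns 61–66, two decimals, clipped to [−99.99, 999.99]) of
PDB ATOM/HETATM records for a chosen chain, preserving every other byte of
the file so the output stays faithful to the input model. Uncovered
residues — and atoms outside the selected chain — get the sentinel
B = 0.00 with occupancy 0.00, letting viewers distinguish "no data" from a
measured zero. An `offset` parameter bridges construct-local and
full-length numbering (`track_position = pdb_residue_number − offset`).

## Crosslink candidate matching

Tryptic digestion cleaves after K/R except before P, enumerating peptides
with up to 2 missed cleavages by default (a crosslinked lysine necessarily
blocks cleavage, creating a missed cleavage). Linkable sites are lysine
side chains — excluding a peptide's C-terminal lysine unless it is the
protein C-terminus, since a crosslinked lysine could not have been
cleaved — plus the protein N-terminal α-amine. A BS3 crosslink adds the
C₈H₁₀O₂ suberate bridge, 138.06808 Da (d0); the d4 heavy form sits
4 × 1.006277 = 4.025108 Da higher (the standard assumption for the
tetra-deuterated reagent). Hydrolyzed dead-end links (+156.07864 Da) are
supported behind a flag, off by default.

A candidate (all site-resolved pairs of amine-bearing peptides, order
normalized, loop-links on overlapping same-protein spans excluded) is
confirmed when an observed neutral mass matches its theoretical mass within
a ppm tolerance (default 10) **and** a partner mass is present at the d4
offset within `doublet_tol` (default 0.02 Da). Matching is on neutral
monoisotopic masses; charge deconvolution and MS/MS fragment scoring are
upstream/out of scope. The matcher is binary-search based but is asserted
equal to an exhaustive brute-force oracle in the tests. Note that adjacent
lysines within one peptide give mass-identical candidates: MS1 doublet
matching cannot distinguish them, and all such site assignments are
reported.

## SEC-MALS stoichiometry

Sequence masses for MALS comparison use average (not monoisotopic) residue
masses, since MALS measures average molar mass; extinction coefficients at
280 nm follow Gill & von Hippel (5500·W + 1490·Y, optionally 125 per
cystine). Purification-tag remnants contribute mass and must be part of the
supplied sequences; they are never inferred. Copy numbers are found by
exhaustive search over {0..max_copies}ᵏ (defaults: ≤5 components, 4 copies
— desk-scale, covering homotrimers), ranked by |predicted − measured| with
ties broken by fewer total copies; an optional UV term
`uv_weight · |ε_pred − ε_obs|/ε_obs` re-ranks solutions when an
extinction-based estimate is available. Exact integer combinations of the
measured mass therefore always rank first with zero residual, though with
commensurable component masses several vectors can tie and the fewest-copy
one wins.

## Numerical and formatting choices

Coordinates are 1-based inclusive throughout. Randomness uses NumPy's
`default_rng`; identical inputs + seed give byte-identical outputs. Output
tables begin with a commented metadata header (version, configuration
hash, seed). Display precision: %HDX 2 decimals, Da 4, masses 5; the
uptake CSV keeps full precision as it is the interchange format.

## Known limitations

Residue-level ΔHDX is a smoothed view: mean projection cannot localize
boundaries better than about half a peptide length, and overlapping
decrease/increase signals average rather than compete. The significance
rule is the classic per-peptide three-criterion filter without global FDR
control. Crosslink confirmation is MS1-level candidate mapping, not an
identification with spectral evidence. Stoichiometry inference assumes a
monodisperse peak and exact component masses.
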