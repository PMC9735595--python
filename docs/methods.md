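# Methods

## The problem and the model

A free cysteine near the C-terminus of the EPI-X4-derived CXCR4
antagonists WSC02 and JM#21 reacts in plasma with the reduced-thiol pool:
mostly albumin Cys34 (~0.4 mM active thiol), plus low-molecular-weight
thiols (cysteine, homocysteine, cysteinylglycine, glutathione; <20 µM
combined). The package models the measurable consequences of that
chemistry at three levels: exact masses of the covalent products,
LC-MS signal of each species over an incubation time course, and the
functional activity read out by antibody competition.

### Mass arithmetic

All masses are monoisotopic, computed from one constant table (the NIST
element masses and abundances shipped with pyteomics; H = 1.00782503,
proton = 1.00727647). A peptide is the sum of residue compositions plus
water. One disulfide bridge removes exactly two hydrogens (−2.015650 Da);
a thiol adduct contributes the free compound's mass minus the same two
hydrogens; carbamidomethylation adds C2H3NO (+57.02146 Da) to a cysteine.
Every modification delta is stored as an elemental-composition change and
its mass is always recomputed from it, so the library is self-consistent
by construction. Oxidized forms are implemented as dioxidation
(+31.98983 Da) and trioxidation (+47.98474 Da); a literature value of
"+47.94 Da" for the triply oxidized form is treated as a suspected
misprint of trioxidation — the chemistry offers no standard +47.94
modification, and the package does not invent one.

The composite-mass audit (`component_sum_report`) exists because printed
crosslink masses are occasionally internally inconsistent: the reported
3100.753 Da JM#21-albumin fragment differs from the sum of its own stated
components (2432.256 + 643.336 = 3075.593 Da) by 25.16 Da, which no
standard modification explains. The pipeline reproduces the component
arithmetic and flags the discrepancy rather than forcing a match.

### Digestion

Trypsin cleaves C-terminal to K/R except before proline (the field
default; both identified fragments VPCVS and KLPCVS are consistent with
it). Fragments carry 1-based inclusive positions so that the Cys34
fragment of mature albumin comes out as residues 21-41, and an explicit
missed-cleavage count. Default `max_missed_cleavages` is 2 — the
identifications require 1, and the extra headroom costs nothing at
peptide scale. Digestion is sequence-agnostic: any carrier sequence can
be supplied; albumin is not hard-coded.

### Identification

Species are identified at the precursor-mass level: observed monoisotopic
masses are assigned to enumerated candidates within a ppm tolerance
(default 20 ppm, the XIC window; crosslink confirmations are additionally
reported at a strict 5 ppm tier by the conjugates CLI workflow). Ties are
all reported ranked by |ppm|; nothing is silently dropped — unmatched
masses are listed and audited against the nearest candidate. Only
pairwise disulfide links are enumerated (no intra-peptide bridges, no 3+
assemblies). The reduction/alkylation control encodes the chemical logic
that a true disulfide crosslink must disappear under DTT + iodoacetamide
while the carbamidomethylated carrier fragment appears; with no reduced
data the control reports "not evaluated", never a silent pass. MS/MS
fragment-ion scoring is out of scope by design.

### Quantification

Isotope distributions are aggregated at nominal (neutron-count) offsets
by per-element multinomial convolution over natural abundances, with
binary exponentiation over atom counts; fine structure within an offset
is unresolvable at ±20 ppm and is ignored. Isotopologue spacing uses the
averaged 1.00336 Da (charge-scaled). XICs sum centroided peak intensities
within the ppm window per retention-time scan (scans with no matching
peak contribute zero), and areas are trapezoidal integrals — the vendor
browser's proprietary integrator is not reproducible bit-exactly, so
trapezoidal integration over the full run is used and stated as such; an
optional automatic window (contiguous region above 5% of the apex) is
provided and clips ~1.4% of a Gaussian peak's mass. Default charge states
are {3, 4} for conjugate-sized species and {1, 2, 3} for the free
peptide and its small adducts; charges are summed by default. Retention
time carries no identity information in this pipeline — species are
distinguished by mass alone.

### Kinetics

One-phase decay Y(t) = (Y0 − Plateau)·exp(−K·t) + Plateau is fitted by
damped least squares (lmfit) with deterministic initialization (Y0 =
first value, plateau = minimum or 0, K from a log-linear regression over
the first decade of signal) and fixed bounds K ∈ (1e-6, 10] /min — no
random restarts, so fits are exactly reproducible. The plateau is fixed
at 0 for MS peak-area decays (free peptide is eventually consumed) and
free, bounded [0, max(Y)], for functional-activity decays, where a
residual active protein-bound pool (~10–20%) is expected. A fitted K at
the lower bound means the data do not decay on the observed window; the
half-life is then flagged "not determined" rather than reported.
Half-life standard errors use the covariance-matrix delta method
(se(t½) = ln2/K² · se(K)); profile likelihood is out of scope.

4PL competition curves are fitted on log10 concentration with
deterministic initialization (top = max, bottom = min, IC50 at the
half-range crossing, hill = −1, bounded negative). Raw MFI must be
normalized upstream to percent (vehicle = 100, isotype = 0). Data with a
non-negative dose trend, or whose responses never fall below the
half-range, are flagged "no inhibition" instead of yielding an
extrapolated IC50.

Remaining activity: the package's default convention is
IC50(0)/IC50(t) × 100, so activity falls as potency is lost; the literal
ratio IC50(t)/IC50(0) × 100 — a fold-change of IC50 that *rises* with
inactivation, though it appears in the literature labeled as remaining
activity — is emitted alongside as `as_printed_pct`. When IC50(t) is
undetermined, remaining activity is 0% only if the top tested dose showed
no inhibition (response above 50 on the normalized scale); otherwise it
is "not determined".

## The synthetic generator

The generator reproduces the statistical structure of the experiment,
not plasma mechanism. Free peptide decays by first-order degradation plus
first-order conversion into bound pools (conjugate, LMW adducts), each
pool with its own degradation rate; the two-compartment system is solved
in closed form. Defaults encode the study conditions: sampling at 0, 5,
10, 20, 30, 45, 60, 90, 120 min; a net free-peptide half-life of 1.7 min
(the JM#21 MS observation), split equally between degradation and
conversion because the experiment identifies only the net disappearance
rate; bound pools stable on the 2 h window (conjugates retain ~70% of the
flux, the cysteine adduct 30% — illustrative splits, as the underlying
branching is not measured); 10% log-normal intensity noise and 3 ppm m/z
jitter (plausible Orbitrap-class behavior); 100 decoy peaks per run
placed at least 50 ppm from every true isotopologue. Elution is Gaussian
(σ = 0.08 min, scans every 0.02 min, apexes staggered 3 min apart) with
the emitted support wide enough (±8σ) that the intensity floor, not the
window edge, terminates each peak — this keeps XIC trapezoids unbiased
when scans are sparse between peaks. Noise is mean-one log-normal
(σ² = ln(1+CV²)), so intensity expectations are unbiased. All randomness
flows from explicit seeds; identical (scenario, seed) gives byte-identical
peak lists.

What the generator does **not** emulate — profile spectra, chromatographic
tailing, ion suppression, retention-time drift, correlated replicate
structure — bounds what passing tests show: they validate the
computational chain (masses → matching → XIC → kinetics) under realistic
statistical noise, not robustness to every instrument artifact.

## Problem sizes and numerical choices

Parameter-recovery checks use 200 seeded replicates per condition at CV
10% (mean fitted half-life within 5% of truth for t½ of 0.7, 1.7, 6 and
9 min) and 50 replicates for IC50 recovery (median within 10% at 5%
noise); the full end-to-end run (scenario → peak lists → XIC → fit) uses
six seeds, which is ample to pin the mean at the percent level while
keeping the suite fast. The 0.7 min regime adds t = 1 and 2 min points to
the early sampling grid — with a first nonzero sample at 2.5 min (3.6
half-lives in), the rate would otherwise be estimated from a single
~8%-of-initial point. Isotope distributions prune below 1e-4 relative
abundance after normalization bookkeeping; pruning never drops the
monoisotopic peak. Masses are carried at full double precision and
rounded only for display (3–4 decimals).

## Known limitations

- Identification is precursor-mass-only; isobaric candidates within
  tolerance are reported as ties, and distinguishing them needs MS/MS
  evidence outside this package's scope.
- The two-compartment kinetic model cannot represent reversible exchange
  (re-release of free peptide from conjugates); the study system treats
  conjugation as effectively irreversible on the 2 h window.
- The 4PL fitter assumes descending competition curves on a 0–100
  normalized scale; partial agonists or bell-shaped responses are not
  modeled.
- Average (isotope-weighted) masses, non-canonical residues and intact
  albumin (66 kDa) isotope envelopes are out of scope; only peptide-scale
  species are quantified.
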