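# Methods

## Mass model

All arithmetic is monoisotopic. Atomic masses are fixed to the standard
values (C 12.000000, H 1.0078250319, N 14.0030740052, O 15.9949146221,
S 31.97207069); the proton is 1.00728 Da (five decimals, enough to keep
reported m/z stable to the 3rd decimal at m/z < 2500), isotopologue spacing
1.00335 Da. Residue masses (amino acid − H₂O) derive from elemental formulas
in the registry, so every registry mass is checkable against an independent
atom-by-atom sum. Leu and Ile are a single isobaric entry: MS cannot separate
them and the pipeline never pretends otherwise.

The neutral mass of a PVD species is

    M = m(chromophore-acyl) + Σ residue masses (after substitution)

with **no terminal-water term**: the chromophore acylates the N-terminus and
the C-terminal macrolactam consumes the C-terminal water. On deliberately
linear toy scaffolds the fragment code restores the water so the textbook
complement identity b_n + y_(N−n) = [M+H]⁺ + proton + H₂O holds and serves
as an oracle for the bookkeeping.

### Chromophore-acyl composition

No elemental formula for the chromophore-acyl unit (quinoline core plus
side chain, as an acyl block) is tabulated anywhere convenient, so it is
fixed here once, by back-calculation: the doubly-protonated native precursor
observed by ESI (m/z 667.8) gives M = 1333.585, and subtracting the eight
known residue masses leaves 357.091 Da, matched by C17H15N3O6 (357.09609)
for the succinamide form. The succinate form is the amide→acid exchange,
C17H14N2O7 (+0.98402 Da). With this one constant the model reproduces every
observed species in one consistent frame: ESI doubly-charged precursors
within 0.03 Da, MALDI reflectron peaks within the ~0.2-0.3 Da calibration
offsets those spectra show. That offset is handled by matching *tolerances*
(MALDI 0.3 Da, ESI 0.02 Da), never by recalibrating inputs.

### Retro-Diels-Alder companion

In-source rearrangement of the chromophore produces a companion ion at a
fixed offset below each singly-charged precursor. The loss composition is
not modeled; the offset is a configurable constant, default 303.13 Da (the
native precursor/companion difference; the independently observed conjugate
pair gives 303.19, i.e. the constant is good to < 0.07 Da). Companions are
defined only on z = 1 species. A companion peak corroborates a species but
never confirms it: confirmation requires the main precursor.

## Fragmentation rules

Only b- and y-series ions are generated — the series the localization logic
uses. The macrocycle is atomic: one backbone cleavage cannot open a ring, so
y-ions smaller than the cycle and b-ions cutting inside it do not exist.
Ring-containing y-ions are flagged `low_ce_only` (they survive only gentle
collisional activation). m/z is reported to 3 decimals; matching always uses
tolerances, not rounding.

## Matching, inference, localization

Peak↔ion matching is greedy nearest-mass, one-to-one, fully deterministic:
pairs within tolerance are taken in order of increasing |error|, ties broken
by lower candidate m/z then lower peak m/z; a peak whose best error is
attained by two candidates (within 1 µDa) is flagged ambiguous. On spectra
whose candidate masses are separated by more than twice the tolerance — the
regime this matcher serves — greedy assignment coincides with the exhaustive
minimum-total-error assignment, and the tests enforce exactly that; heavily
overlapping candidate sets are collapsed into isobaric mass groups *before*
matching rather than fought over afterwards.

Substitution inference compares an observed mass shift against exact
residue-mass differences over a candidate alphabet (default: the 19
mass-distinct proteinogenic residues; azHA is added when relevant), reports
all blocks within tolerance (isobars together) plus the nominal integer
shift, and never ranks candidates by biological plausibility. Localization
intersects the spans of shifted fragments, subtracts the spans of unshifted
ones, and keeps only positions whose reference residue can yield the shift.
Inconsistent evidence (a shifted fragment nested inside an unshifted one)
yields an ambiguity flag carrying both windows — no silent guessing. For the
canonical pattern (y4 and y7 at −14, b-series unshifted) the window is the
two in-cycle threonines {7, 8} with candidate Ser; the method cannot and
does not pick one of the two.

## Titration quantification

Species intensity = sum of the isotopic envelope (nearest peak within 0.3 Da
of mono + k·1.00335, k = 0..4; missing isotopologues contribute zero) plus,
by default, the same sum rooted at the RDA companion. K = 4 covers the
visually complete envelope at m/z ≈ 1300. The response factor is calibrated
by OLS of measured on known ratios, intercept included (a through-origin
variant is exposed behind a flag; the ordinary fit is the default because
nothing in the procedure guarantees a zero intercept). R² is the ordinary
coefficient of determination. Inversion is (measured − intercept)/slope.

The default calibration design is five known ratios in geometric steps,
(0.1, 0.25, 0.5, 1.0, 2.0). The design brackets the regime the inversion is
used in — a minor species against a major one. A wider symmetric design
(up to 4:1) was tried first and rejected: with unweighted OLS the largest
ratio dominates the intercept noise, which is then amplified when inverting
small ratios (median recovery error 7% instead of 3% at 5% intensity noise).

Photometric quantification is plain Beer-Lambert: c = A400/(ε·l) with
ε = 19,000 (mol·L)⁻¹·cm⁻¹ and a 1-cm path by default.

## Specificity-code conservation

Inputs are an aligned FASTA (the alignment itself is upstream and out of
scope), a label per sequence (T = threonine-specific, NT = non-threonine),
and a column map: eight 1-based code columns plus the invariant-Asp anchor
column. Sequences without Asp at the anchor are removed before profiling.
Frequencies are counts over category size; **gaps stay in the denominator**
(a gapped column dilutes conservation — the conservative choice). A residue
is a key residue iff f_T > 0.90 **and** f_NT < 0.05, both strict. The
mapping of code columns to protein residue numbering is configuration, never
hard-coded; the generated-data layout (anchor at column 1, code at 2–9) is a
convention of the generator, not of the analysis.

## Synthetic data

The sequence generator plants residues per-category as Bernoulli draws at
the stated frequency, filling misses from a background distribution
renormalized to exclude the planted residue (so empirical frequencies
converge to the planted values at the binomial rate); default sizes mirror a
small specific category against a large background (39 T / 1507 NT). The
spectrum generator gives each species a Poisson-shaped envelope with mean
λ·M/1000 (λ = 0.65 per 1000 Da, a carbon-count proxy), an RDA companion
envelope at a configurable fraction (default 0.3), Gaussian m/z jitter and
unit-mean log-normal intensity noise. The envelope shape is deliberately
simple: the pipeline sums envelopes and never fits their form, so fidelity
beyond "several isotopologues of plausible relative intensity" would add
parameters without adding test power. What the generators do **not**
emulate: MALDI baseline and detector noise physics, adduct or chimeric
peaks, alignment errors, phylogenetic correlation between sequences.
Passing round-trip tests therefore demonstrates the *logic* of the pipeline
under controlled noise, not robustness to every artifact of real spectra.

All generators take one explicit integer seed (no global random state);
titration series derive per-point seeds from the master seed via
`numpy.random.SeedSequence.spawn`.

## Numerical and degenerate-input choices

* Tolerances: MALDI 0.3 Da, ESI 0.02 Da, isotopologue pick-up 0.3 Da,
  isobaric grouping 1 µDa, matcher tie detection 1 µDa.
* A constant measured-ratio series fits a flat line exactly; its R² is
  reported as 1 when residuals vanish (0 otherwise) instead of NaN.
* Zero-slope calibrations and absent reference species raise errors rather
  than returning infinities.
* Empty peak lists annotate to empty reports; an empty candidate list leaves
  all peaks unmatched without error.
* Registry formulas must agree with stated masses within 0.1 mDa at
  construction time.

## Problem sizes

The test suite and reproduction script run entirely on generated data:
spectra of ≤ ~40 peaks, sequence sets up to 500 T / 1250 NT, 40-100
repetitions for the recovery studies. These sizes put the binomial/CLT
concentration the assertions rely on well inside their asymptotic regime
while keeping the whole suite around two seconds.

## Known limitations

* Average-mass mode, non-proton adducts, iron-bound (ferri-PVD) species and
  isotope fine structure are out of scope.
* The chromophore-acyl formula is inferred from one precursor mass, not from
  a structure determination; any revision shifts all absolute precursor
  masses by a constant but no *relative* quantity (shifts, windows, ratios).
* The greedy matcher is optimal only on well-separated candidate sets (see
  above); it is not a general assignment solver.
* Fragment intensity is not modeled; `low_ce_only` is a qualitative flag.
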