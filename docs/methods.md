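# Methods

This note documents the models, parameters and design choices behind
`dacmet`, and what the synthetic experiments do and do not establish.

## Scope and assumptions

The package consumes *aligned* feature tables (peak detection and
cross-sample alignment are upstream concerns) and annotates
administration-dependent metabolites. It assumes singly charged ions with
a known or guessable adduct, retention times in minutes from a
reversed-phase gradient, and intensities on a common scale across
samples. Compound-database searching and formula prediction from mass are
out of scope; a user-supplied annotation table (standards and literature
entries) stands in for both.

## Mass arithmetic

Neutral monoisotopic masses are used throughout; ionization bookkeeping
(±1.007276 Da for protonation, plus a small adduct map) is confined to
the I/O layer. Atomic masses are embedded constants at six decimals,
which keeps formula sums accurate to ~1e-5 Da — an order of magnitude
below the 5 ppm working tolerance at 200 Da; a unit test cross-checks
them against pyteomics.

The ppm tolerance for a mass-difference match is applied to the residual
of the *difference*, normalized by the heavier member's neutral mass.
Normalizing by the heavier mass matches how instrument accuracy scales
and keeps the criterion stable for small deltas (a raw-difference ppm
would be absurdly tight for an 80 Da delta between 400 Da peaks).

## The biotransformation table

Default reactions, each with a formula-derived delta and an RT-shift
window signed as (product RT − source RT):

| reaction | moiety | delta (Da) | window (min) | reference shift |
|---|---|---|---|---|
| glucuronidation | C6H8O6 | +176.03209 | −3.0 … +0.2 | −1.9 |
| sulfation | SO3 | +79.95682 | −3.0 … +0.2 | −1.4 |
| glycine conjugation | C2H3NO | +57.02146 | −5 … +5 | — |
| glutamine conjugation | C5H8N2O2 | +128.05858 | −5 … +5 | — |
| glutathione conjugation | C10H15N3O6S | +305.06816 | −5 … +5 | — |
| deglycosylation (hexose loss) | C6H10O5 | −162.05282 | −5 … +5 | — |
| glucuronide loss | C6H8O6 | −176.03209 | −5 … +5 | — |

Window boundaries are closed at both ends (the permissive reading; no
open/closed convention is standard). The glutathione delta defaults to
the dehydro form; the reduced form (C10H17N3O6S, +307.08381) is a named
variant. Loss-type reactions direct edges heavier→lighter, so a
hydrolysis edge points from glycoside to aglycone. A hexose *gain* entry
is deliberately omitted: it would duplicate every deglycosylation pair
with the direction reversed, and glycoside formation is not an expected
in-vivo route here. The whole table can be replaced from YAML.

Reference shifts are the RT changes of a calibrant's conjugates
(7-hydroxycoumarin: sulfation ≈ −1.4 min, glucuronidation ≈ −1.9 min on
the emulated gradient); they can be overridden per run, as they are
column- and gradient-specific.

## Filtration

Rules evaluate in a fixed order, and the first failing rule is recorded
per peak: (i) detected in ≥ 2 samples; (ii) never detected in a mock
(solvent blank); (iii) never detected pre-dose; (iv) detected in a
*strict* majority of subjects at ≥ 1 post timepoint; (v) maximum post
intensity ≥ 1000 counts. "Detected" means a positive recorded intensity —
blank cells and zeros are *not detected*, a distinction the later
imputation step depends on. Rules (ii) and (iii) are absolute (zero
tolerated detections), not intensity-relative; rule (iv) reads "more than
half of all samples at some timepoint" per-timepoint across subjects;
rule (v) uses the maximum because a peak qualifying at any timepoint
qualifies outright. The machine-readable report replaces a manual
chromatogram review; a curation step can be layered on via keep/drop
lists, but is not automated.

Duplicate-ion merging collapses alternate ion forms of one metabolite:
opposite-mode peaks whose deionized masses agree within 5 ppm and which
co-elute within 0.2 min, plus user-declared adduct/in-source-fragment
relations. Declared exception pairs (e.g. two diastereomers that co-elute
at the same mass) never merge; links that would indirectly join an
exception pair are skipped in deterministic (sorted) order.

## Network construction

Nodes are metabolites (merged peak groups; the most intense member
supplies mass and RT). Pair finding is exhaustive over unordered node
pairs — implemented with a sorted-mass bisection but verified in tests to
equal the O(n²) brute force exactly. Same-mass nodes co-eluting within
0.2 min merge (greedy chain by ascending RT with transitive closure),
*before* edge finding, so edges connect metabolites rather than peaks.
Out-of-window edges are flagged, never deleted: subnetwork extraction and
co-clustering use only within-window edges, but exports keep the full
audit trail.

Source scoring: for each (target, reaction) group, every edge gets
`shift_score = |rt_shift − reference_shift|`; the within-window edge with
the smallest score is `preferred`, exact ties are all preferred and
flagged ambiguous, and reactions without a reference are left unscored.
Out-of-window edges can never be preferred.

Subnetworks are connected components over within-window edges, labelled
A, B, C… by descending size then ascending smallest member mass — an
arbitrary but deterministic rule.

Origin overlay marks each node with the set of herbs whose single-herb
rat-plasma samples detect any member peak, plus extract and human-plasma
presence; multi-origin nodes are retained and logged rather than
resolved.

## Spectral evidence and MSI levels

³⁴S: a hit needs an isotopologue at +1.99580 ± 0.01 Da whose per-sulfur
relative intensity lies in 2–8 % (natural abundance 4.25 %). The offset
tolerance excludes the ¹³C₂ isotopologue at +2.00671 Da; the band
tolerates ion-statistics noise. The inferred sulfur count is capped at 4 —
a far larger apparent ratio is interference, not sulfur. An empty pattern
is absence of evidence, never counter-evidence.

Neutral losses are matched as precursor-minus-fragment differences
(80/176/162 Da for SO₃/glucuronide/hexose) with a 0.5 Da default
tolerance suited to ion-trap product-ion spectra (0.01 Da is appropriate
for high-resolution MS/MS).

The MSI rubric is explicit where practice is usually judgement:
level 1 = mass (≤ 5 ppm) + RT (≤ 0.2 min) match to an authentic standard
(ties broken by closest RT); level 2 = preferred within-window conjugate
edge plus ≥ 1 orthogonal support (³⁴S, matching neutral loss, or
reference-shift agreement within 0.5 min); level 3 = database/literature
mass match without a standard; level 4 = formula only. Levels are
monotone in evidence, and missing spectra never downgrade a node below
what the network supports. Positional isomers (which ring position
carries the conjugate) are out of scope — that requires synthesized
standards.

## Kinetics

The matrix is metabolite × (subject, timepoint), columns sorted subject-
then-time, pre-dose entering as t = 0. Missing values become half the
row's minimum observed value; rows are then z-scored with the sample
(n−1) standard deviation. The description "standard deviation of the
mean" in common protocol language is read as ordinary auto-scaling (the
row SD), not the standard error — SEM would not give unit-variance rows,
and auto-scaling is the named procedure. Zero-variance and all-missing
rows are rejected by name. Clustering is Ward linkage on Euclidean
distances via scipy; merge heights are asserted non-decreasing on every
run; the flat cut (count or height) is a user parameter since no single
cut is canonical. Externally quantified concentration series can replace
intensity rows and are scaled identically.

## Synthetic experiments

The generator emulates the study design the pipeline targets: 4 subjects,
plasma pre-dose and at 0.25/0.5/1/2/4/8 h, two solvent blanks, one
extract sample, and four single-herb rat-plasma samples at 1 h. Source
compounds (drawn from a small library of real natural products with exact
formulas) get log-normal-shaped time profiles; conjugates inherit their
source's profile (scaled) with an RT shifted by the reaction's reference
amount ± 0.15 min jitter; sulfates get a ³⁴S isotopologue and an 80 Da
neutral loss; every sulfur-free compound still gets realistic ¹³C
isotopologues. Decoys violate exactly one filtration rule each
(background, blank contaminant, sporadic, minority, sub-threshold) and
their masses are rejection-sampled away from all planted masses and
deltas (25 ppm guard) unless delta-coincident decoys are requested for
false-positive studies.

Mass noise: `mass_noise_ppm` (default 2) is the per-acquisition m/z error
(sd); the reported feature m/z is the mean over the samples in which the
peak was detected, as in aligned feature tables, so feature-level error
shrinks roughly with √(detection count). All randomness flows from one
seed; a fixed spec reproduces byte-identical files.

The preset licorice-family fixture pins every mass to its formula and
every RT to the characteristic shift geometry (conjugates 1.3/1.7 min
before one aglycone and 2.8/3.2 min before the other, implying a constant
1.5 min offset between the aglycones), with one metabolite planted in
both ion modes and one co-eluting isomer pair protected by a merge
exception. It is noise-free by construction.

What passing these tests shows: the arithmetic, rule logic, network
recovery and clustering behave exactly as specified under controlled
conditions, at problem sizes of ~10–50 metabolites and tens of samples
(chosen to keep the default suite fast). What they do not show: behavior
under real chromatographic drift, co-elution-induced misalignment,
intensity-dependent mass error, matrix effects, or imperfect upstream
peak picking — the generator models none of these, and real-data counts
(how many peaks survive filtration, how many edges are true) will depend
on them.

## Known limitations

- Adduct handling covers a small fixed map plus a ±H fallback; exotic
  adducts and multiply charged species need user remapping.
- Merge exceptions block direct links; a pathological chain of
  intermediates could still join an exception pair indirectly.
- Reference shifts are treated as constants per reaction; on strongly
  non-isocratic behavior a per-RT-region calibration would be needed.
- The co-clustering check is qualitative (same flat label), inheriting
  the arbitrariness of the chosen cut.
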