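# Methods

`biotransid` implements a mass-driven metabolite-identification workflow for
a single parent compound analysed by high-resolution LC-MS/MS across several
biological matrices. The shipped configuration targets neobavaisoflavone
(C20H18O4), an isoflavone whose in-vivo fate is dominated by phase I
functionalization (hydroxylation, reduction, hydration, demethylation,
dehydrogenation, decarbonylation) and phase II conjugation (glucuronidation,
sulfation, N-acetylcysteine adduction), but every layer is configurable.

## Formula algebra and ion masses

Formulas are integer element-count vectors over {C, H, N, O, S} (extensible
via `register_element`). Monoisotopic masses come from a fixed packaged
table (C 12 exactly, H 1.00782503, N 14.00307401, O 15.99491462,
S 31.97207117, electron 0.00054858 Da), not from a runtime dependency, so
golden values are bit-stable.

Ion m/z for singly charged (de)protonated species includes the electron
mass:

    m/z([M-H]-) = M - m(H) + m(e),    m/z([M+H]+) = M + m(H) - m(e)

This is the convention under which the packaged reference table recomputes
to five decimal places (e.g. 321.11323 for the deprotonated parent =
321.11268 + 0.00055). Ring-and-double-bond equivalents use
RDB = C + 1 + N/2 − H/2, giving the familiar half-integer values for
even-electron ions.

ppm errors are signed, (observed − theoretical)/theoretical × 1e6. The
reference table's own printed error column is not reproducible from its
printed masses, so the pipeline always reports its own computed errors.

## Candidate enumeration

A reaction is a formula delta (atoms added, atoms removed) with a
multiplicity bound; the default library (16 entries, `data/reactions.tsv`)
covers the reaction vocabulary observed for this scaffold, including the
composite sulfonate-level reductions (+SO3−O+H2 and relatives) whose
mechanistic decomposition the literature does not state — these ship as
single composite reactions rather than guessed multi-step mechanisms.

Because formula arithmetic is commutative, the candidate space is exactly
the set of feasible multisets of reaction applications: each reaction used
at most `max_multiplicity` times in total, an application at multiplicity n
counting as n steps, with the total step count bounded by `max_steps`
(default 4) and no element count going negative. One candidate is kept per
distinct product formula, carrying the minimal generating path (fewest
steps, ties broken by the lexicographically smallest reaction-name
sequence). Candidates are screened by the composition filter
C 5–40, H 5–60, O 2–20, S 0–2, N 0–3, RDB 3–20.

`max_steps = 4` because the deepest observed composite —
sulfation plus triple hydroxylation — is four atomic transformations; depth
3 recovers 71 of the 72 reference metabolites and misses exactly that one.
At depth 4 the default library yields 870 candidate formulas, enumerated in
well under a second.

Deliberately *not* pruned: mass-consistent but chemically exotic
combinations beyond the composition filter. The search is mass-driven, as
in the underlying acquisition software; plausibility judgement is left to
the analyst reading the reported reaction paths.

## MS1 matching and MS2 confirmation

Peaks below the polarity-specific selection intensity (40,000 positive,
10,000 negative; inclusive bounds) are discarded. Each surviving peak is
matched to the candidate minimising |ppm| within the 10-ppm tolerance, ties
broken by fewest reaction steps then Hill formula; in-tolerance alternates
are retained on the match record. Negative-mode peaks are matched against
[M−H]− masses; positive mode is consulted only for the parent, since the
conjugates of this scaffold ionise in negative mode.

MS2 spectra are associated to a matched peak by polarity, precursor m/z
(20 ppm) and retention time (0.2 min). Two evidence types are scored:

* **Diagnostic product ions** (`data/dpi_library.tsv`): class-characteristic
  fragments — m/z 175.02 and 113.02 for glucuronides, 96.96 (HSO4−) and
  79.96 (SO3−·) for sulfates, the retro-Diels-Alder core ions 135.01/137.02,
  and the parent-core fragments 265.05 ([M−H−C4H8]−) and 253.05
  ([M−H−C5H8]−). Two-decimal literature targets are matched within
  ±0.01 Da; formula-defined targets within 10 ppm.
* **Neutral losses** (`data/neutral_losses.tsv`): precursor-minus-fragment
  deltas — glucuronyl 176.03209, SO3 79.95682, H2O, CO, CO2, CH2O, C4H8,
  C5H8, and the radical losses CH3· and C4H7· (flagged `radical_allowed`).
  Matched within ±0.01 Da; optionally also between fragment pairs to pick
  up successive losses.

Confidence tiers are this package's convention (the source study reports
only qualitative "tentative" identifications): A = at least two distinct
evidence items, B = exactly one, C = MS1 match only.

## Isomer consolidation

Matches sharing a formula are split into distinct metabolites when their
retention times differ by more than `rt_tol` (single-linkage clustering)
and merged across matrices otherwise, yielding the metabolite × matrix
presence table. The default `rt_tol` = 0.2 min; the closest same-formula
pair in the reference data elutes 0.06 min apart, so fully resolving all 72
reference isomers by retention time alone requires tightening to 0.05 min —
a documented limit of RT-only resolution. Alternatively, grouping can use
feature labels carried on the peaks (`consolidate_by="feature_id"`), the
natural mode for PRM-style acquisitions with an inclusion list and for
synthetic runs, where the generator tags each peak with its originating
row. Consolidation never changes the number of observations, only their
grouping.

Per-matrix summary counts follow the study's convention: "plasma" is the
union of the three plasma preparations (PM, PA, PS), and the parent
compound is excluded from metabolite counts.

## Synthetic runs

The generator regenerates the study conditions from the packaged table: one
MS1 peak per (metabolite, matrix-where-detected) at the row's experimental
m/z perturbed by seeded uniform jitter (default ±5 ppm, the magnitude of
the study's observed errors), intensities drawn above the selection
threshold (base 50,000; absolute intensities are not published, so any
supra-threshold scale is equivalent), one MS2 spectrum per row from its
published truncated fragment list (base peak rescaled to 100), and
uniformly drawn decoy peaks. Decoys are true negatives by construction:
rejected within 20 ppm (2 × the matching tolerance) of every reference mass
and of any supplied exclusion masses — callers pass the full candidate-set
ion masses so that no decoy can legitimately satisfy the matcher, making
"zero decoy annotations" a property of the method rather than of chance.
Runs are byte-deterministic given the seed.

Not emulated: chromatographic peak shape, isotope envelopes, correlated
noise, matrix effects and ion suppression. Perfect recovery on these runs
therefore validates the pipeline's bookkeeping and tolerances, not
instrument-level performance on raw data.

### Reference-table integrity

The packaged table (`data/metabolites.tsv`, 74 rows: 72 metabolites + the
parent in both polarities) was audited against recomputation when packaged:

* the RDB column and the per-matrix presence counts (plasma 28 as the
  PM/PA/PS union, urine 43, feces 18, liver 6, liver microsome 4) recompute
  exactly;
* 20 printed theoretical masses deviate from the ion-formula value by more
  than 1.5e-5 Da (one by ~1 Da); these carry a frozen `theoretical_anomaly`
  flag and are excluded from the golden-mass suite, which covers the
  remaining 54 rows at five decimals;
* 11 printed experimental masses imply errors above 5 ppm, contradicting
  the table's own error column (one is ~6 Da off, an evident typo); for
  these the working `experimental_mz` is reconstructed as
  computed-theoretical × (1 + printed-error-ppm × 1e-6) and flagged
  `experimental_anomaly`, with the printed value retained alongside.

## Numerical and design choices

* Intensity thresholds are inclusive ("not less than").
* Retention times are minutes everywhere; MGF `RTINSECONDS` is converted on
  read. MGF is the MS2 interchange format; peak tables are CSV written at
  fixed precision (m/z 5 dp, intensity 2 dp) for byte-stable round trips.
* MS2 relative intensities are base-peak-normalised to 100; published
  fragment entries above the precursor (in-source artifacts) are dropped
  when constructing spectra.
* The pathway graph has one node per formula on any annotated candidate's
  minimal path and one labelled edge per reaction step, exported as
  GraphML; the parent is the unique source.
* Problem sizes throughout (870 candidates, ~130 true peaks + 56 decoys per
  run, 20-seed recall studies) keep the complete test suite and the
  acceptance script in the low seconds.

## Known limitations

* Identification is at the formula level; positional isomers are separated
  only by retention time (or carried feature labels), never by structure.
* The A/B/C confidence tiers are a counting convention, not a calibrated
  false-discovery control.
* Only ±H adducts and singly charged ions are supported; no isotope-pattern
  scoring, no Na+/K+/NH4+ adducts, no multiply charged species.
* The synthetic generator replays published peak lists; it cannot surface
  failure modes that only raw profile data exhibits (centroiding errors,
  coeluting isobars, saturation).
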