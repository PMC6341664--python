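# Methods

## Conservation census

The census operates on a fixed master alignment; nothing is realigned.
Percent identity between two rows is defined over *mutually aligned*
columns — columns where both rows carry a residue — as matches divided by
that column count. 'X' placeholders (ambiguity codes B/Z/J/U/O are
normalised to 'X' on input) count in the denominator but never as a
match, so they cannot inflate identity. Rows sharing no mutually aligned
column have identity 0.

Redundancy removal is greedy single-pass clustering in input order: each
row joins the first existing cluster whose *representative* is at least
`threshold` (default 0.98) identical to it, else founds a new cluster.
This is deterministic and order-stable; reordering the input can change
the clustering, which is inherent to greedy redundancy filters.

The anchor column is the column maximising the frequency of the anchor
residue (histidine by default), with ties broken to the lowest index and
an error if the best frequency is below `min_freq` (default 0.5) — an
alignment without a conserved histidine column is not an HPt family
alignment. Rows lacking the anchor residue at that column are removed
before counting.

The H+k offset (k = 4 by default) is measured in *ungapped sequence
coordinates*: gap columns downstream of the anchor are skipped, matching
the biological meaning of "four residues after the phosphorylatable
histidine" (H64 → G68). Rows whose sequence ends within k residues of the
anchor are tallied separately as `n_short`, so
`total + n_short + |removed|` always equals the row count. Percentages
are half-up rounded to 2 decimals (the convention of the published
table); 'X' at H+k is counted and kept in the denominator by default,
with an `exclude_x` option.

Logo information content per column uses gap-excluded frequencies:
info = log₂20 − H, with H the Shannon entropy in bits, optionally minus
the small-sample correction e_n = (s−1)/(2n·ln2) with s = 20, clamped at
zero. Letter heights are p·info. Columns with no residues report missing
information. The numeric matrix is the product; no graphical rendering is
attempted.

## Binding model and fitting

With receptor at R_T ≈ 15.8 nM (30 pmol in 1.9 mL) and titrant spanning
10 nM–6 μM, free ligand cannot be approximated by total ligand, so the
complex concentration is the physical root of the mass-action quadratic.
It is evaluated in the product form 2·R_T·L_T/(b + √(b² − 4·R_T·L_T)),
b = R_T + L_T + K_d, which avoids catastrophic cancellation in the
tight-binding limit.

Each raw series is normalised to its own pre-titration intensity F₀ and
the buffer-only series subtracted point-wise; this cancels dilution and
instrument drift, and any common intensity scale (the fit is exactly
invariant to multiplying both raw series by a constant). The fitted model
is Δ = A·[RL]/R_T with two parameters: K_d and the amplitude A (the
fractional fluorescence change of the fully bound receptor; free-state
fluorescence is absorbed by the F₀ normalisation). A may be negative
(quenching).

Numerical choices: K_d is parameterised as log K_d, bounded to
[1 pM, 10 mM]; initial K_d is the ligand concentration nearest the
half-maximal observed Δ and initial A the largest-magnitude Δ; unweighted
least squares (scipy `least_squares`, tolerances 1e-15) with optional
1/variance weights and an optional drift nuisance slope (off by default).
Standard errors come from the Jacobian at the optimum, with the delta
method mapping se(log K_d) → se(K_d). Degenerate data (all Δ equal) is an
error, and a titration that does not bracket the response midpoint earns
a warning. Across replicate titrations the reported constant is the mean
± sample SD of per-replicate estimates.

On noise-free generator output the fit recovers (K_d, A) to better than
1e-6 relative across the 0.5–2.9 μM span; with 1% multiplicative
intensity noise and 20 points the median K_d over 100 replicates stays
within a few percent of truth (the test budget allows 15%).

## Gel quantification

Percent-of-wild-type is computed per replicate (each replicate's
reference lane defines 100%), then averaged; the spread is the sample
(n−1) SD, undefined for n = 1. The reference therefore reports exactly
100 ± 0, and rescaling any replicate's intensities by a constant changes
nothing. An optional per-lane background is subtracted (clipped at zero)
before normalisation. Densitometry itself is out of scope — intensities
enter as a table.

## Structural comparison

PDB files are read with gemmi: first MODEL only, alternate locations
resolved to the highest-occupancy conformer (ties prefer blank/'A'),
waters and hetero groups retained but flagged and excluded from
superposition selections. Atoms are paired across models by (chain,
residue number, insertion code, atom name), with an optional chain map;
the default selection is Cα, with backbone/heavy/all available.

Superposition is the Kabsch SVD solution restricted to proper rotations
(a reflection is corrected by flipping the smallest singular direction);
near-collinear point sets are rejected as degenerate. Regional RMSD comes
in two modes: **global_frame** superposes on all matched atoms and then
measures the region without refitting (how far the region moved relative
to the rest of the structure), and **local_fit** superposes on the region
alone (its internal distortion); local_fit never exceeds global_frame.

One property of the global frame worth knowing: because the displaced
region participates in the fit, a rigid displacement d of a fraction f of
the atoms is recovered attenuated — by roughly f·d from the centroid
shift, plus whatever part a small rotation can absorb, which grows when
the region is large or peripheral or the structure is elongated. The
quantitative recovery check therefore uses an 800-residue globular trace
with 6-residue displaced regions (f ≈ 0.75%, recovery error ≈ 1–2%);
on the 167-residue default emulation the 11-residue displaced helix is
recovered at ~1.5–1.6 Å for a planted 1.7 Å shift, the same attenuation
a real whole-structure superposition would show.

Clash scanning uses a Bondi-style radius table (C 1.70, N 1.55, O 1.52,
S/P 1.80 Å, default 1.70) and reports atom pairs across the two
selections with overlap r_a + r_b − d above 0.4 Å — the common
severe-clash convention — sorted by overlap, hydrogens excluded by
default. The scan assumes the models already share a frame; superpose
first.

## Synthetic-data generators

All generators are pure functions of (design, seed) built on numpy's
PCG64; identical inputs give byte-identical outputs, and each returns a
ground-truth record carrying every downstream expected value.

**Alignment**: background columns are i.i.d. uniform over the 20 residues
— there is no phylogenetic correlation, no conservation gradient, and
gaps (rate 0.1 by default, kept out of the anchor..anchor+k window so the
planted composition is exact) are independent across rows. Anchored
template rows carry 'H' at the anchor column and the designed residue at
anchor+k; near-duplicates copy a template and mutate background columns
with the mutation count capped at 2% of the non-gap length, so duplicate
identity stays ≥ 0.98 by construction; anchor-less and truncated rows are
generated on top of the composition. Passing tests on this generator
shows the pipeline arithmetic is right, not that a real Pfam alignment —
with correlated columns, fragmentary sequences and match-state structure
— would give the published counts; those depend on the database release
and are treated as an input table, not a reproduction target.

**Titration**: ligand intensity F₀·(1 + Δ_model + drift)·(1 + ε) and
buffer F₀·(1 + drift)·(1 + ε′), with ε multiplicative Gaussian
(instrument-like, default 1%) and drift linear in addition index (default
0). Real titrations also carry cumulative dilution; the package assumes
buffer subtraction cancels it (an optional per-point dilution correction
hook exists in the design but real dilution series are not emulated).

**Gel lanes**: per replicate, a reference intensity drawn uniformly
within ±20% of nominal, and each variant's percent level drawn
N(level, sd) truncated at zero — emulating replicate-to-replicate
variability, not densitometry artefacts (saturation, background
gradients).

**Structure pair**: an idealised Cα trace — ~40-residue ideal helices
(2.3 Å radius, 1.5 Å rise, 100°/residue) tiled antiparallel on an ~11 Å
grid so the trace stays globular at any size — with designated residue
ranges rigidly displaced along seeded random directions, isotropic
coordinate noise, and an overall random rigid transform so superposition
is non-trivial. The default design emulates the mutant-vs-wild-type
comparison: 167 residues, the N-terminal helix and turn (residues 11–21)
displaced 1.7 Å, and 0.115 Å per-coordinate noise, which yields ≈ 0.2 Å
(√3·0.115) Cα RMSD in undisplaced regions — the reported core deviation.
No side chains or realistic covalent geometry are modelled, so all-atom
selections and real rotamer clashes are outside what these fixtures can
exercise; comparing real coordinate files is supported directly
(`analysis/04_structure_compare.py --ref ... --mob ...`).

## Problem sizes

The shipped runs use: a 1,000-row synthetic alignment (300 templates ×
(1 + 2 duplicates) + 70 anchor-less + 30 truncated) for the census
pipeline; 20-point titrations, 3 replicates per variant and a
100-replicate recovery study for binding; 3 gel replicates; and
167-residue (emulation) / 800-residue (recovery check) traces for
structure. These sizes were chosen to make every statistical check stable
across seeds while keeping the full suite and the acceptance script fast
on a single CPU.

## Known limitations

- The greedy redundancy filter is O(n·clusters) and intended for
  10³–10⁴-row alignments, not millions.
- The census treats all alignment columns uniformly; a Pfam match-state
  census (insert columns excluded) could differ slightly on real family
  alignments.
- The binding model fits one curve at a time with a single amplitude; no
  global multi-curve fitting, anisotropy or FRET models.
- Clash scanning is a fixed-radius overlap test; it knows nothing of
  bonding, so covalently bonded neighbours within one selection pair
  would be reported if the two selections overlap — scan disjoint
  selections.
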