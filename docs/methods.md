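# Methods

## Problem and model

`crpmap` analyzes overlapping-peptide microarrays used to map linear
B-cell epitopes on a protein monomer — here the 206-residue mature human
C-reactive protein (CRP) monomer, whose "hidden" neoepitopes become
antibody-accessible when the native pentamer dissociates. The array prints
every 15-mer window of the monomer at a one-residue step (14-residue
overlap), with a 7-residue glycine/serine linker (`GSGSGSG`) elongating
both termini so that terminal residues appear in full-length peptides.
With flank length `f`, tile length `k` and monomer length `L`, the library
holds `L + 2f − k + 1` tiles (206 for the CRP defaults). All public
coordinates are 1-based inclusive spans on the mature monomer, matching
the label convention `MOTIF^start-end` (e.g. `PDE^168-170`).

An IgG autoantibody recognizing a contiguous epitope binds every tile
whose peptide contains that epitope. The analysis inverts this:

1. **Positivity.** A tile is seropositive when its serum-scan fluorescence
   is at least `factor` (default 2.0; boundary inclusive) times the
   array's background level, defined as the **median of the pre-serum
   background scan**. The per-array scalar is robust to isolated bright
   pre-scan spots; a per-spot comparison mode is available for sensitivity
   analysis. Control spots (the hemagglutinin grid framing the array) feed
   an advisory QC: the median control intensity should reach twice
   background; failures are flagged, not dropped, unless exclusion is
   requested.
2. **Consensus calling.** Positive tiles are sorted by array index and
   grouped into *runs* of immediate neighbours whose mature spans share at
   least `min_overlap` (default 3) residues. A run whose spans have a
   non-empty common intersection yields one epitope call: that
   intersection, the minimal region shared by all supporting peptides. A
   gap of even one negative tile breaks a run: under the containment
   binding model a single epitope always lights a contiguous stretch of
   tiles, so gaps mark distinct epitopes whose spans may nevertheless
   overlap across the gap.
3. **Over-long runs.** A contiguous run of more than `k` tiles has an
   empty intersection and therefore spans more than one epitope. The exact
   decomposition is not identifiable from the positivity pattern alone, so
   the run is split at the cut point that maximizes the shorter of the two
   sides' intersection lengths, ties resolved toward the smaller left
   segment, recursively. This balanced rule recovers both spans exactly in
   the realistic adjacent-run case (e.g. epitopes at 155–158 and 168–170,
   whose reactive tile runs abut), and always produces calls overlapping
   the true spans so that cohort harmonization absorbs residual ambiguity.
   Calls shorter than `min_overlap` residues are emitted with a warning.
4. **Harmonization.** Subject-level calls are clustered across the cohort
   by single linkage on span overlap ≥ `min_overlap`. A cluster's
   canonical span is the intersection of member spans when non-empty,
   otherwise the most frequent member span. The result is a set of cohort
   epitopes with per-group positive counts plus a subject-by-epitope
   boolean/intensity matrix whose margins are consistent by construction.

### Terminal flank geometry

With a 7-residue flank, no tile's mature span can start after residue
`L − 7` (199). The consensus over all tiles containing the C-terminal
epitope `QLWP^203-206` is therefore `199–206` — the call contains the
motif and ends at the final residue, but cannot be narrowed further by any
intersection rule; the same ramp exists at the N-terminus for epitopes
ending before residue `k − f` (8). This is a property of the printed
geometry, not of the implementation; a flank of `k − 1` residues would
remove it. Exact-recovery guarantees below are stated for spans away from
this terminal margin.

## Serology conventions

* Anti-CRP IgG in arbitrary units: `100 × sample OD / reference OD`
  against a high-titer positive reference serum.
* Positivity cutoff: the empirical 95th percentile of a healthy-donor AU
  panel, **nearest-rank convention** (`ceil(p·n)`-th order statistic; the
  interpolation choice is config-exposed). Positivity is strict
  (`value > cutoff`).
* netOD: coated-well OD minus uncoated-well OD, floored at 0.
* aPL positivity: any of aCL IgG/IgM, anti-β2GPI IgG/IgM strictly above
  its kit cutoff (defaults 10 U/ml, JSON-configurable); missing assays
  never count. Active disease: SLEDAI-2K ≥ 5.

## Statistical battery

* Group comparisons: two-sided Mann-Whitney U; exact null when the
  smaller group has ≤ 12 observations and there are no ties, otherwise
  the normal approximation with tie correction and no continuity
  correction (so symmetric inputs give p = 1). Summaries report medians
  and IQRs under the same nearest-rank quantile convention as the
  serology cutoff.
* Correlation: Spearman's rho with tie-aware (average) ranks.
* 2×2 contingencies: Fisher's exact test, two-sided by the
  point-probability method — the standard exact treatment of small-cell
  tables. The reported effect is the sample odds ratio with a 0.5
  continuity correction when any cell is zero.
* Paired comparisons: Wilcoxon signed-rank, zeros dropped; all-zero
  differences return p = 1 with a warning.
* Multiple paired conditions: Friedman chi-square computed directly from
  within-subject ranks with tie correction (valid down to k = 2, where it
  reduces to a sign-test ordering), followed by Dunn's pairwise z tests
  with Bonferroni adjustment over the tested pairs.
* Association tables run the declared (lhs, rhs, test) rows with
  automatic test selection by variable type and **no multiplicity
  correction across rows** by default (a Benjamini-Hochberg switch
  exists but is off), flagging p < 0.05.

## Functional assay metrics

* Oxidative burst: trapezoidal AUC of the luminol chemiluminescence
  kinetics on the native 30-s grid over 15 min, expressed as a percentage
  of the unstimulated negative control. No baseline subtraction — the
  ratio already cancels instrument gain (a config switch exists). Only
  the stimulated window is integrated.
* Chemotaxis: per cell, origin-zeroed net displacement along the
  chemoattractant axis (`sign · (x_end − x_0)`, µm; the axis sign is a
  parameter, +x by convention) summarized as mean ± SD, and velocity as
  total path length over total time (µm/min, 1-min sampling) summarized
  as median with range. Velocity ≥ |net displacement| / time always
  (path ≥ chord). Tracks with fewer than two samples are skipped with a
  warning.
* NET release: extracellular-DNA (Sytox) fluorescence as a fold index
  over control; values near 1 mean no effect. Quantification of DNA-MPO
  ELISA against a standard curve is out of scope.

## Synthetic data

The generator emulates the array experiment under a **containment
reactivity model**: a tile is reactive for a subject iff its mature span
contains one of the subject's planted epitope spans — the unique simple
model under which intersection calling returns exactly the planted span
(away from the terminal margin). Per subject, the pre-serum background
scan is lognormal (log-mean ln 100, log-SD 0.25 by default); non-reactive
serum intensities equal the background level times multiplicative
lognormal noise; reactive tiles are further multiplied by `gain`
(default 4, comfortably above the 2× cutoff); false positives are
injected per non-reactive tile at `fp_rate`. A fixed seed gives
bit-identical output. Planted spans longer than a tile are rejected as
unreachable.

Clinical covariates are drawn from documented distributions chosen to
resemble the cohort's descriptive summaries (e.g. anti-CRP AU lognormal
with median 17.5 for patients; a minority of patients active) — they
exist so the statistical battery can be exercised end-to-end; no analysis
conclusion depends on them and no association between covariates and
planted epitopes is introduced beyond disease group.

### The frozen fixture cohort

`fixture_cohort()` is a deterministic, noise-free 42-patient + 11-donor
cohort whose planted assignment simultaneously satisfies the reported
marginals: per-epitope patient counts {PDE 13, DIGN 12, SFGGNFEGSQSL 10,
SEIL 10, ILGQ 8, SWE 7, YEVQG 5, QLWP 3, CLH 2, EILIF 2, VRKSLKK 1}
(sum 73), donor counts {PDE 2, VRKSLKK 2, ILGQ 1, DIGN 1, SFGGNFEGSQSL 1,
SEIL 1}, exactly 24 patients and 4 donors positive for ≥ 1 epitope,
patient totals with median 1 and maximum 7, donor totals with median 0
and maximum 4. Donor counts for DIGN/SFGGNFEGSQSL/SEIL are not pinned
individually by the cohort margins; the fixture uses 1 each, the minimum
consistent with six epitopes being shared between groups.

The assignment was constructed by hand under one additional constraint:
epitope pairs whose reactive tile runs interact are co-assigned to a
subject only where the marginals force it. Because 12 + 13 > 24, at least
one patient must carry both DIGN^155-158 and PDE^168-170, whose runs are
adjacent; exactly one does, and the balanced split recovers both spans
exactly. All other interacting pairs (VRKSLKK/ILGQ, SFGGNFEGSQSL/DIGN,
YEVQG/QLWP) are never co-assigned. A self-check re-verifies every
marginal at load and fails loudly if the frozen table is edited into
infeasibility.

What the simulator does *not* emulate: real per-spot intensity structure
(spatial artifacts, duplicate spots, dye effects), partial-containment or
conformation-dependent binding, cross-reactivity, and any coupling
between serology covariates and epitope reactivity. Passing tests
therefore demonstrate correctness of the calling and statistical
machinery under the stated binding model, not biological validity on real
arrays.

## Problem sizes and numerical choices

The test suite and the reproduction script run the full 53-subject
fixture pipeline (206 tiles per subject), 200 randomized planted
configurations, a 50-subject false-positive simulation (> 10⁴ tiles),
and exhaustive enumeration oracles for the exact tests at n ≤ 10 — sizes
chosen so each stage's behaviour is measured with tight bounds while the
whole suite completes in seconds. Fluorescence comparisons are exact
(integer-friendly, no tolerances); statistical oracles are compared at
1e-9; stochastic rates are tested against 99% binomial bounds.

## Known limitations

* Terminal epitopes are called to the terminus (see above); labels for
  such epitopes carry the widened span.
* The decomposition of merged runs longer than one tile window is not
  identifiable in principle; the balanced split is a documented heuristic
  that is exact for the adjacent-run cases the cohort marginals force.
* Per-subject calling is the default; pooled/mean-intensity calling over
  a group is available but reports no subject-level positivity.
* Printed p-values from the original serum cohort are not reproducible
  because raw intensities are not public; statistics are validated
  against enumeration oracles instead.
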