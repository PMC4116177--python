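# Methods

## Scope and model

`erdesign` implements a rational point-mutant design loop for a
nuclear-receptor ligand-binding domain and the analytics of the two assays
used to validate such designs. The package treats the receptor backbone as
rigid throughout: docking, energy minimisation, homology modelling and
binding-free-energy estimation are deliberately outside its scope. What it
computes are *geometric* and *statistical* statements: which residues line
the pocket, which substitutions nature tolerates there, whether a rebuilt
side chain fits sterically, and what parameters best explain measured
binding and melting curves.

## Pocket extraction

A residue is a pocket member when the minimum heavy-atom center-to-center
distance between the residue and the ligand is ≤ the cutoff (default
6.0 Å, closed interval). The 6 Å default is deliberately generous: it
yields a conservative, inclusive pocket description rather than a tight
contact shell. Distances use atom centers without van der Waals radii,
because crystal-structure coordinates are what the rule is applied to;
hydrogens are excluded so the answer does not depend on whether a
structure was deposited with them. Waters and a fixed ion/buffer list
(NA, CL, MG, ZN, CA, K, SO4, PO4, GOL, EDO) are never auto-selected as the
ligand; crystallographic waters are likewise not counted as part of the
ligand — a choice that slightly shrinks pockets relative to a
water-inclusive reading and is exposed through the explicit `het_code`
argument for sensitivity checks.

Pockets from multiple complexes are expressed in a common reference
numbering and unioned, so a position qualifies if it contacts the ligand
in any source structure. When author numbering already matches the
reference register (≥95% agreement at shared numbers) the identity map is
used; otherwise a global pairwise alignment (match +1, mismatch −1, gap
open −2, extend −1; Biopython's `PairwiseAligner`) supplies the mapping,
rejected below 30% identity. The set of source structures is
configuration (a YAML manifest), not code: pocket size depends on which
complexes are included, so no structure list is hard-coded. No reference
sequence ships with the package; the manifest may point at one, and ERα
LBD crystal structures conventionally carry author numbering that already
matches the canonical 303–547 register, in which case none is needed.

## Conservation and candidate mutations

Conservation at an alignment column is the modal-residue fraction over
counted symbols. Gaps ('-', '.') are absence of evidence and ambiguity
codes (X/B/Z) carry none, so both are excluded from counts and from the
effective depth; conservation is therefore in (0, 1] and equals 1 exactly
when one residue is observed. This is the simplest metric consistent with
reading a full bar as 100% conservation; a Shannon-entropy column could be
added but plays no role in any decision.

Candidate mutations are non-reference residues with support ≥
`min_support` (default 2 — a singleton may be a sequencing artefact; two
independent occurrences start to look like tolerated variation), ranked by
variant fraction, then position, then residue letter, making the output
invariant under row permutation. The wild type at a position is the
*reference* sequence's residue, not the column's modal residue: an
ortholog set can out-vote the reference (human ERα carries L349 where most
species have M), and the design question is what to change the reference
to. Alignment cleaning (exact-duplicate removal; rows covering <80% of
reference columns dropped) is available but opt-in, because redundancy
filtering is a judgement about the input set, not part of the statistic.

## Rotamer-based mutant modelling

A mutation replaces everything beyond CB and rebuilds the target side
chain from ideal internal coordinates (bond lengths/angles from standard
amino-acid geometry; aromatic rings idealised to exact planar hexagons
with 1.39 Å bonds) using the natural-extension (NeRF) construction. An
existing CB is kept as the chi1 axis anchor; a missing one is built with
the L-configuration improper (C–N–CA–CB = −123°, N–CA–CB = 110.5°). The
embedded backbone-independent rotamer set enumerates canonical staggered
chi minima (gauche−/trans/gauche+, aromatic chi2 at ±90°-class
orientations): 6 rotamers for F/Y, 9 for I/L, 27 for M, 3 for V, and
single trivial entries for A/G. Templates ship for G, A, V, L, I, M, F
and Y — the residue types this design space needs — and the template
mechanism (a plain data table of internal coordinates) extends to the
rest. Mutating a residue to itself with its native chi angles reproduces
the native heavy atoms to within the idealisation error (≲0.2 Å on
idealised fixtures; 0.5 Å is the documented bound).

Clash scoring is a soft-sphere overlap: `o = r_A + r_B − d − tolerance`
summed over positive terms, with element radii C 1.70, N 1.55, O 1.52,
S 1.80 Å and a 0.4 Å tolerance (the conventional soft allowance;
configurable). Pairs within 3 bonds of the placed atoms are excluded via
template bond depths, as are hydrogens and waters. The bound state scores
against protein plus ligand; the unbound state ignores hetero atoms
entirely — the distinction matters because a large side chain may be
accommodated in an empty pocket yet clash with a bound ligand. Rotamer
selection is lexicographic: minimum total overlap, then minimum worst
overlap, then library order.

Aromatic proximity is the centroid-to-centroid distance between the placed
F/Y/W ring and a ligand ring. Ligand rings are either named explicitly or
auto-detected as 5/6-membered cycles of a distance-based bond graph
(heavy-atom pairs ≤1.85 Å), taking the nearest ring. The metric is
reported, not thresholded: π-stacking geometry is richer than one
distance, and the package makes no energetic claim.

## Assay analytics

Polarization is computed exactly as `(F∥ − F⊥)/(F∥ + F⊥)`; note that this
expression is often called *anisotropy* in the photophysics literature —
the implemented formula is the one above, whatever the label.

Competition curves are fit by unweighted least squares
(`scipy.optimize.curve_fit`) in log10-concentration space with
`y = min + (max − min)/(1 + 10^(hill(log₁₀x − logIC₅₀)))`. Both a
three-parameter mode (hill ≡ 1, the default) and a four-parameter mode
(hill free) are provided, since both parameterisations are in common use;
the mode is recorded in every fit. Initialisation: min/max from the data
extremes, logIC₅₀ by interpolating the half-range crossing, hill 1.
Zero-concentration control wells are excluded (log undefined) but
retained for inspection. Standard errors come from the fit covariance;
non-convergence, a collapsed window (max ≤ min) or a non-finite parameter
is reported through an honest `converged` flag, never an exception. With
12 points and 3% noise the nominal 95% intervals cover the truth at
roughly their nominal rate (≈91–95% across seed sets — slightly
anticonservative, as expected for asymptotic SEs at n = 12).

Melt curves are fit with the two-state Boltzmann sigmoid
`y(T) = u + (f − u)/(1 + e^((T − Tm)/w))`; a fit only counts as converged
when Tm lies inside the measured range and w > 0. Unweighted least
squares is used for both fits; no replicate weighting scheme is assumed
because none is defined for the input format.

Fold change for a (reference, variant) receptor pair and a shared ligand
is `IC₅₀(variant)/IC₅₀(reference)` after normalising units to mol/L; a
value below 1 means the variant binds tighter. Significance uses a
±1·SE interval-overlap rule: improved if the variant interval lies
entirely below the reference interval, worsened if entirely above,
otherwise not significant. This is an explicit convention (reported SEs
summarise four replicates; no distributional test is defined for them),
and it is symmetric: exchanging the receptors inverts the fold and flips
the direction. The published wt/M421F/M421I × six-ligand IC₅₀ table ships
as input data (`erdesign/data/published_ic50.tsv`); these are measured
quantities the package classifies but cannot recompute.

## Synthetic data: what it emulates, what it does not

The generators are pure functions of their specs (seed included), and
every artefact they emit is accepted unmodified by the corresponding
reader or fitter.

* `make_complex` plants small (1–5 heavy atom) pseudo-residues along
  well-spread directions at exact minimum distances (binary search to
  <1e-6 Å, verified to 0.05 Å after coordinate rounding) from a 12-atom
  hetero ligand, with far residues beyond cutoff + 2 Å. It validates the
  distance bookkeeping of pocket extraction exhaustively, but contains no
  realistic protein geometry — passing says nothing about mapping or
  chain-tracing subtleties of real crystal structures.
* `make_alignment` produces exact per-column residue counts (default
  depth 200; the 421 column defaults in the examples use
  M:170/L:5/I:3/F:22, the documented ortholog composition) with all
  unspecified columns invariant. Rows are otherwise identical, so it
  exercises counting, not phylogenetic structure; conclusions about
  database-derived ortholog sets (which are version-dependent) do not
  follow.
* Assay generators add Gaussian noise — expressed as a fraction of the
  dynamic range (3% for competition, 2% for melts in the recovery
  studies, matching visually clean published curves) — to the exact model
  curves on the assay's native grids (12 log-spaced concentrations
  spanning 10 pM–10 µM; 25–90 °C at 1 °C). Recovery under Gaussian noise
  does not certify robustness to the heteroscedastic or drifting errors of
  real plate readers and CD instruments.

## Problem sizes

The recovery studies use 100 seeded complexes for the pocket oracle,
500 competition replicates and 200 melt replicates — sizes at which the
medians and coverage rates are stable to well within the tolerances they
are compared against, while the whole suite runs in seconds.

## Known limitations

* Backbone rigidity: no accommodation of strain introduced by a larger
  side chain; a rotamer that clashes here might relax in reality.
* The embedded rotamer set is minimal and backbone-independent; it brackets
  the conformational choices coarsely and does not claim equivalence to
  any published fine-grained library.
* mmCIF input, multi-model averaging, assembly expansion and bond-order
  perception are unimplemented; PDB-format single models only.
* IC₅₀ values are reported as fitted, with no Cheng–Prusoff conversion to
  Ki and no G-factor instrument correction.
* The real-structure union pocket depends on the manifest chosen; the
  shipped manifest names three ERα LBD complexes whose coordinates must be
  fetched separately.
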