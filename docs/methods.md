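# Methods

`rna3dcons` quantifies how RNA 3D structure conservation relates to
sequence conservation.  It aligns pairs of RNA structures by their C3'
backbone traces, scores each alignment with three identity percentages
and a Gumbel-based significance, builds non-redundant / high-accuracy
pair datasets from an all-against-all comparison, fits the exponential
decay of structural divergence with sequence identity, and fits the
"twilight zone" boundary that separates detectable from undetectable
homology in (alignment length, e-value) space.  Everything runs end to
end on synthetic helical folds, so no structure downloads are needed to
exercise or test the pipeline.

## Structure model

A chain is the ordered C3' trace of its nucleotides: sequence over
{A, C, G, U, N}, one coordinate per residue, resolution and method
metadata.  Modified nucleotides map to their parent base through a
fixed lookup (PSU→U, 1MA→A, ...); unknown nucleotide-like residues
become N, and N never counts as identical in sequence identity.
Multi-model files contribute model 1 only; alternate locations resolve
to the highest-occupancy atom (ties to altloc A).

Dataset filters: chains shorter than 20 nt or with fewer than 4 base
pairs are removed (length checked first; one chain is counted under one
removal reason), then chains 100% identical in sequence to another are
deduplicated, keeping the entry with the best (numerically smallest)
resolution.  A pair is a structure/substructure pair when the shorter
sequence is a contiguous exact substring of the longer — a deterministic
reading of "substructure" that covers fragment-versus-full-entry pairs.

## Base pairing

Pairings come from an annotation file (two-column residue-number lists
or DSSR JSON) or from a built-in geometric detector that stands in for
a full-atom annotator on C3'-only data: complementary bases (A-U, G-C,
G-U) whose C3'-C3' distance falls in [16, 20] Å (the antiparallel-helix
window; the synthetic template places true pairs at 18 Å) pair up, one
partner per residue, best (closest-to-centre) distance first.  At the
minimum sequence separation of 3 a *straight* backbone also reaches
18 Å, so separation-3 candidates must additionally have antiparallel
local backbone directions.  When full-atom N1/N3 coordinates are
supplied, a 2.6–3.3 Å donor–acceptor distance takes precedence over the
backbone window.  The detector reports canonical pairs only; edge
classification and multiplets are out of scope.

## Alignment

1. **Unit-vector profile.**  For residues i = 1..n−1 (of the
   base-paired subset; unpaired residues are excluded before profiling)
   the vector to residue i+1 is normalised to unit length.
2. **Window similarity.**  Windows of 6 consecutive unit vectors
   (7 residues), truncated identically on both chains near the termini
   to no fewer than 3 vectors, are compared by URMS — the RMSD of the
   two vector sets after the optimal rotation, computed from the signed
   singular-value sum of the 3×3 correlation matrix.  The similarity is
   S = max(0, 10·(1 − URMS/URMS_R)), where URMS_R is the Monte-Carlo
   mean URMS of 10,000 random window pairs of the same effective length
   (seed 20100615, cached per length).  Cells whose common window would
   drop below 3 vectors score 0.
3. **Dynamic programming.**  A global alignment of the two window
   profiles with affine internal gaps (open 4.0, extend 0.2 in score
   units) and free end gaps.  Ties break diagonal > up > left, and the
   traceback starts at the best cell with the largest (i+j, i), so an
   all-zero matrix yields the pure diagonal.  A window cell (i, j)
   aligns residues (i+1, j+1); the head cell also contributes its own
   (i, j) pair so a perfect diagonal covers every residue.
4. **MaxSub refinement.**  Every run of 4 consecutive path pairs seeds
   an iterative superpose-and-extend search admitting path pairs within
   3.5 Å, up to 20 iterations; the largest stable core wins (ties by
   lower core RMSD).  Superpositions are least-squares proper rotations
   (reflections rejected by the determinant correction).
5. **Reporting.**  The final superposition is fitted on the 3.5 Å core;
   the reported aligned core is the set of path pairs within 4.0 Å
   under that superposition, and the reported RMSD is computed over it.

Chain order is canonicalised (fewer paired residues first, ties by
length then key), so scores are symmetric in the caller's argument
order.  Alignment needs at least 5 paired residues per chain (4 unit
vectors, the smallest comparable window); the dataset filters already
guarantee at least 8 on real inputs.

Window length, gap penalties and the 10·(1 − URMS/URMS_R) transform are
package conventions in the unit-vector alignment lineage; alternative
values are exposed through `AlignConfig`.

## Scores and significance

With N the number of base-paired residues of the shorter chain and NP
the smaller base-pair count:

* PSI = 100·n_al/N, n_al = aligned C3' pairs within 4.0 Å;
* PSS = 100·p_al/NP, where a base pair counts as aligned when both of
  its C3' atoms map to a base pair of the other chain with both
  distances below 4.0 Å (each pair counted once);
* PID = 100·n_id/N over all aligned columns (N bases never match).

Scores of unrelated-pair alignments are modelled by a Gumbel
(extreme-value) law per score type.  The moments estimator uses
σ = sd·√6/π and μ = mean − γσ with γ = 0.5772; maximum likelihood is
available as an alternative.  The p-value is the exceedance
p = 1 − exp(−e^(−z)), z = (x − μ)/σ, clamped at 1e−300 so −ln(p) stays
finite.

The default calibration background is the all-against-all comparison of
120 generated decoy folds of 30–300 nt (seed 20100615); a table of real
background scores can be supplied instead.  A caveat measured and kept
visible in the test suite: because the background mixes decoy lengths
and the identity scores are ratios of small integers, one global (μ, σ)
per score type leaves a residual lack of fit — held-out background
p-values are uniform only to ~0.06–0.08 KS distance, not the stricter
0.05 the uniformity test asserts.  The p-values are accordingly
well-calibrated in rank order but approximate in absolute value near
the centre of the null distribution; tail significance (the 4.5 cutoff
on −ln p) is far from the misfit region.

## Datasets

The all-against-all comparison produces one record per unordered chain
pair (failures recorded, never dropped; a JSON-lines cache keyed by
pair and parameter hash makes re-runs byte-identical).  The NR subset
keeps pairs with PID strictly below 25% and is the calibration
background in the paper-style setting.  The HA subset keeps pairs with
all three −ln(p) ≥ 4.5, both resolutions ≤ 5.0 Å (entries without
resolution, e.g. NMR, are excluded) and no structure/substructure
relation.

## Conservation analysis

The decay of structural similarity with sequence identity is fitted as
y = c + a·e^(−bx) by least squares from a fixed multi-start grid
(a ∈ {±range(y)}, b ∈ {0.001, 0.01, 0.1}, c = min(y)); the reported
"correlation coefficient" of a fit is the Pearson r between observed
and fitted responses.  The summary reports medians of PID/PSI/PSS,
Pearson r with two-sided p (t transform) for (PID, PSI), (PID, RMSD),
(PSS, PSI), (PID, PSS), the (PID, RMSD) correlation inside the 30–60%
and 90–100% identity subgroups, and a sensitivity correlation excluding
pairs above 95% identity.

## Twilight zone

Pairs are labelled TP (all three −ln(p) strictly above 4.5), TN (all at
or below 4.5) or MEDIUM (mixed).  In (N, −log10 e-value) space the
boundary family is A + B·e^(−kN); a pair is predicted homologous when
its −log10 e-value strictly exceeds the curve.  The fit maximises the
Matthews correlation coefficient over TP/TN points (MEDIUM excluded) by
a coarse grid (A ∈ [0, 10] step 0.25; B ∈ [1, 1000] and k ∈ [0.005,
0.3] log-spaced), deterministic local grid refinement around the best
cells — the MCC surface is piecewise constant, which defeats a
simplex-only polish — and a final Nelder–Mead pass.  Ties break by
fewer false positives, then smaller B.  E-values are consumed from
(query, target, N, e-value) tables or Infernal `cmsearch --tblout`
files; covariance-model search itself is out of scope and enters only
through its e-values.

## Synthetic data

The generator emulates what the analysis needs and nothing more:

* **Folds.**  Stems are two antiparallel C3' strands on a cylinder
  (radius 9 Å, twist 32.7°, rise 2.81 Å per pair), giving 5.8 Å
  consecutive spacing and exactly 18 Å across each pair; hairpin loops
  and internal-loop connectors are equal-step circular arcs (5.9 Å
  steps); top-level linkers are seeded 5.9 Å random walks.  All
  consecutive C3'–C3' distances land in [5, 7] Å by construction.
  Supported topologies are pseudoknot-free: hairpins (loop ≥ 2 nt),
  one nested stem per stem with symmetric internal loops, and
  linker-joined units; the validator rejects anything else.  These
  template constants are package conventions for a recognisable helix,
  not claims about real A-form geometry.
* **Homologs.**  Seeded mutations accumulate until the realised
  identity reaches the target; stem partners mutate jointly to another
  Watson–Crick pair (compensatory co-variation), so the pairing and its
  index set survive divergence.  Isotropic Gaussian coordinate noise
  and an optional rigid domain shift model structural divergence.  The
  ladder helper couples noise to divergence as 0.05·(100 − PID) Å per
  coordinate, producing a monotone sequence–structure relationship; a
  decoupled mode exists for null experiments (set `coord_noise`
  directly).
* **Decoys.**  Independent random layouts with uniform sequences;
  alignment identity between decoys concentrates near the 4-letter
  random expectation (~25%).
* **Twilight clouds.**  Positives sit at least `margin` −log10 units
  above the generating curve (negatives below), plus a uniform offset
  up to `spread` (default 3).  `margin` is a guaranteed clearance: with
  any positive margin the cloud is separable by an open set of curves,
  so recovery to MCC 1.0 is a well-posed target; with margin 0 the
  generating curve still separates strictly.

What the generator does **not** emulate: real loop/junction geometry,
non-canonical pairing, pseudoknots, crystallographic noise structure,
length-correlated base composition, or realistic e-value/length joint
distributions.  Passing tests therefore demonstrate correctness of the
algorithms and the qualitative behaviour of the analysis, not
quantitative agreement with any real structure set.

## Numerical choices

* URMS uses the signed singular-value sum; the batched kernel computes
  the 3×3 singular values from closed-form Gram-matrix eigenvalues
  (error ~1e−13 generic, ~1e−8 absolute in the degenerate limit);
  the reference `urms_distance` uses LAPACK SVD.
* Zero-valued URMS on self-comparisons is exact only to ~1e−7 (square
  root of accumulated float error).
* Proper rotations are enforced everywhere (no reflections).
* p-values are clamped to [1e−300, 1]; the exceedance uses `expm1` for
  right-tail stability.
* Problem sizes in the tests and the acceptance script — 120-decoy
  background, 2,000 (tests) or 500 (script) held-out pairs, 48-pair
  homolog ladders, 3,000–5,000-point twilight clouds — are the
  package's desk-scale defaults chosen to exercise every stage at
  stable statistics.

## Known limitations

* The geometric pair detector is a C3'-only stand-in; on real
  structures an external annotation (3DNA/DSSR) is preferable and can
  be supplied as a file.
* A single Gumbel per score type leaves the held-out p-value
  uniformity at ~0.06–0.08 KS (see above).
* The reported core RMSD is computed over a 4.0 Å-capped core, so it is
  not monotone in divergence once noise approaches the cap: the
  surviving core is then a selection of well-fitting atoms.
* Sub-structure detection is sequence-based (exact substring); a
  structural-superposition definition would also catch fragments with
  sequence variants.
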