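# rna3dcons

Quantifying the relationship between sequence and 3D structure
conservation in RNA.

Structural biologists and RNA bioinformaticians routinely assume that
RNA structure is more conserved than sequence, and that below some
sequence identity — a "twilight zone" — homology can no longer be
detected from sequence alone.  `rna3dcons` turns those assumptions into
measurable quantities: it aligns RNA 3D structures pairwise from their
C3' backbone traces, scores each alignment, calibrates significance on
unrelated-pair backgrounds, fits the decay of structural similarity
with sequence identity, and fits the curve in (alignment length,
e-value) space that best separates genuinely related pairs from
unrelated ones.

## The method in brief

A chain restricted to its base-paired residues is represented by unit
vectors between consecutive C3' atoms.  Windows of 6 vectors are
compared by **URMS** (the RMSD of two unit-vector sets after the
optimal rotation), scored as `S = max(0, 10·(1 − URMS/URMS_R))`, and
aligned by dynamic programming with affine internal gaps and free end
gaps.  A MaxSub-style search refines the path to the largest core
superposable within 3.5 Å; the reported core counts aligned C3' pairs
within 4.0 Å.  Three percentages summarise each alignment (N = length
of the shorter paired structure, NP = smaller base-pair count):

    PSI = 100 · n_al / N      aligned C3' atoms within 4.0 Å
    PSS = 100 · p_al / NP     aligned base pairs
    PID = 100 · n_id / N      identical aligned nucleotides

Score significance uses the Gumbel law fitted on unrelated-pair
backgrounds: `p = 1 − exp(−e^(−z))` with `z = (x − μ)/σ`, the moments
estimator `σ = sd·√6/π`, `μ = mean − 0.5772·σ`.  Pairs with all three
`−ln(p) ≥ 4.5` form the high-accuracy set used for conservation
analysis; the twilight boundary `−log10(e-value) = A + B·e^(−kN)` is
fitted by direct Matthews-correlation maximisation.

A synthetic-data module generates helical RNA folds with known
Watson–Crick pairing, homolog pairs with controlled sequence identity
(compensatory mutations preserve pairing) and coordinate noise, decoy
sets for backgrounds, and labelled twilight point clouds — so the whole
pipeline runs and is testable offline.

## Worked example

```python
from rna3dcons import (FoldSpec, Segment, generate_fold, derive_homolog,
                       HomologParams, align_pair, score_alignment)

spec = FoldSpec(
    segments=[Segment("stem", 12, 0), Segment("loop", 4), Segment("stem", 12, 0),
              Segment("linker", 3),
              Segment("stem", 8, 1), Segment("loop", 5), Segment("stem", 8, 1)],
    seed=7,
)
parent, pairs = generate_fold(spec)
homolog, hpairs = derive_homolog(
    parent, pairs,
    HomologParams(target_pid=60.0, coord_noise=1.0, seed=13),
)
aln = align_pair(parent, homolog, pairs, hpairs)
scores = score_alignment(aln, parent, homolog, pairs, hpairs)
print(f"chain length {len(parent)} nt, {len(pairs)} base pairs")
print(f"PSI = {scores.psi:.1f}  PSS = {scores.pss:.1f}  PID = {scores.pid:.1f}")
print(f"aligned core: {scores.n_al}/{scores.N} nt at {scores.core_rmsd:.2f} A RMSD")
```

prints

```
chain length 52 nt, 20 base pairs
PSI = 100.0  PSS = 100.0  PID = 50.0
aligned core: 40/40 nt at 1.70 A RMSD
```

The homolog was mutated to ~60% global sequence identity with 1 Å
coordinate noise: every paired residue still superposes within 4 Å
(PSI 100), all base pairs align (PSS 100), and the aligned-column
identity over the paired core is 50% — structure is conserved while
sequence diverges, the relationship the package quantifies.  The same
operations are available from the shell via `rna3dcons parse`,
`rna3dcons align`, `rna3dcons pipeline`, `rna3dcons twilight` and
`rna3dcons synth`.

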