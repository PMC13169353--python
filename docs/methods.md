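# Methods

## Contact model

A residue–residue contact `u_ij` is formed when *any* atom of residue *i*
(hydrogens included, when present) lies within the cutoff (default 4.2 Å)
of any atom of residue *j*.  Distances use the minimum-image convention
under an orthorhombic box when one is supplied; a warning is emitted when a
box edge is smaller than twice the cutoff, where minimum-image distances
become ambiguous.  All pairs `i < j` are evaluated with no
sequence-separation exclusion: covalently adjacent pairs have contact
frequency ≈ 1 and are removed by the static filter anyway.  The kernel
computes squared distances against the squared cutoff with a two-stage
block minimum (atoms → residues); its contract is exact agreement with the
naive all-pairs double loop, which the tests enforce on random fixtures
with and without periodic wrapping.

**Static filter.**  Contacts formed in more than `u_high` or less than
`u_low` of frames (defaults 0.9 / 0.1) are static.  The inequalities are
*strict*: a pair at exactly 0.9 is excluded.  This matches the
"more than / less than" reading of the filter and is measure-zero on real
data; it only matters for synthetic inputs engineered to sit on a bound.

## Contact PCA

Frames from all conditions are pooled and centered by the pooled mean —
for a mixture of ensembles the PCs are collective contact coordinates that
capture *differences between ensembles*, not dynamic modes of any single
run.  The sample covariance uses the conventional unbiased 1/(N−1)
normalization and is diagonalized directly (binary variables need no
correlation rescaling).  Eigenvalues are clipped at zero (they are
non-negative up to round-off), sorted decreasingly; each loading's sign is
fixed so its largest-magnitude coefficient is positive.  Degenerate
eigenvalue ties keep the solver's stable ordering; the tests avoid exact
ties.  Constant (zero-variance) columns are permitted and simply
contribute zero-eigenvalue directions.

Amplitude-scaled loadings default to the λ convention (loading × its
eigenvalue), with `sqrt-lambda` (RMS-amplitude, the more common choice)
and `none` available; the two conventions differ only by a per-PC positive
factor, so back-mapped map *patterns* are identical and only the color
scale of a rendered heatmap changes.  Default truncation for downstream
analysis is k = 8 PCs, overridable via `RunConfig.n_pcs`.

## Discriminant analysis

Fisher LDA is used as a coordinate transform, not a classifier: rows of C
solve the generalized eigenproblem `S_b w = λ S_w w`, are ordered by
discriminative eigenvalue, normalized to unit length, and sign-fixed so
the class listed first has the lower mean on each discriminant.  At most
`min(n_classes − 1, k)` discriminants exist.  A numerically singular
within-class scatter is ridge-regularized with `1e-6 · trace(S_w)/k` and a
loud warning.  LDA inputs are raw (variance-bearing) PC scores — the
transform is defined directly on PC projections, so no per-PC
standardization is applied.  Frames are treated as independent
observations; autocorrelation in real trajectories would widen the
effective class densities and is *not* corrected for here.

Per-class score densities use a Gaussian kernel with Silverman's rule
evaluated on the pooled scores.  The shared grid spans the pooled range
padded by six bandwidths so that each class density integrates to 1 within
1e-6 under the trapezoid rule (a three-bandwidth pad would truncate ~0.3%
of the mass).  The overlap coefficient is ∫ min(f_A, f_B).  Note the KDE
bandwidth biases the overlap of well-separated unit-variance classes
upward by roughly `2Φ(−Δ/2√(1+h²)) − 2Φ(−Δ/2)`; at the sample sizes the
tests use (5 × 10⁴ per class for the closed-form check) this bias is below
0.005.

## Membrane analytics

* **Superposition** is Kabsch SVD with the determinant correction
  (proper rotations only); degenerate/collinear subsets are rejected.  The
  test oracle is Horn's quaternion method.  RMSD series apply no
  chain-swap minimization for multimers — atom correspondence is literal.
* **Hydrogen bonds** use the donor-centered convention: donor-heavy to
  acceptor distance ≤ 3.5 Å *and* angle between D→H and D→A ≤ 20°.  Many
  packages instead require the D–H···A angle ≥ ~160°; the two conventions
  agree on ideal geometries but diverge for long D–H bonds.  Donors whose
  hydrogen is not covalently consistent (≥ 1.3 Å) are skipped with a
  warning.
* **Unwrapping** accumulates minimal-image frame-to-frame increments;
  displacements of half a box or more per frame are ambiguous by
  construction and resolved toward the smaller jump with a warning.  The
  slab-world generator enforces step sizes below half the box, so
  wrap → unwrap recovers its hidden continuous paths to ~1e-14 Å
  (floating-point accumulation; exactness in the bit sense is not
  promised).
* **Crossing events** are detected by a three-state automaton
  (below / inside / above; boundary ties count as inside).  A crossing is
  a complete passage from strictly below the lower bound to strictly above
  the upper bound (+1) or the reverse (−1); entering and retreating is no
  event.  In a periodic box the membrane recurs every box length along the
  unwrapped coordinate, so the default trajectory-level counter treats the
  slab as periodically replicated (gap-index bookkeeping); this is what
  makes net crossings equal net displacement in units of slab images — the
  conservation law the tests check.  Fixed literal bounds (non-periodic
  mode) are available and support per-frame bound arrays; automatic
  leaflet-based bound detection from lipid phosphates is not implemented —
  synthetic slab worlds use explicit numeric bounds.
* **Lipid radial density** measures each marker's distance to the
  *nearest* protein atom (minimum image), bins into spherical shells,
  averages counts over frames and divides by shell volume.  The marker is
  whatever atom subset the caller selects (phosphorus headgroup atoms in
  typical use).

## Synthetic generators

All generators are seed-deterministic (NumPy `default_rng`): identical
spec + seed gives bit-identical output.

**Switching ensembles.**  Residues are rigid bead clusters (first bead on
the residue center, others jittered ≤ 0.12 Å) on a coarse grid with 16 Å
spacing, so non-planted inter-residue distances stay ≥ 8 Å.  Contacts are
planted *geometrically*: per frame, each latent mode draws a Bernoulli
state with its class's occupancy and places its pairs at 3.8 Å
(nearest-atom, formed) or 8.0 Å (broken) along the pair axis — both safely
on opposite sides of the 4.2 Å cutoff, so re-deriving contacts through the
full distance kernel recovers the latent states exactly up to the
independent per-pair flip noise ε.  Background pairs toggle independently
with occupancies drawn uniformly in (0.2, 0.8) to give PCA genuine
nuisance variance.  Every dynamic pair must be residue-disjoint from every
other (a matching): this is stronger than pair-set disjointness, and is
what lets each pair move geometrically without perturbing any other; it is
a deliberate layout constraint of the generator, not of the analysis.

Two planted-structure idioms are used in the study conditions: a *single
collective mode* spanning 12 pairs (for PCA recovery, where
λ₁ = 12·p(1−p) = 3.0 at p = 0.5 up to the (1−2ε)² noise shrinkage), and
*12 independent single-pair modes* with class-dependent occupancy 0.9 vs
0.1 (for LDA recovery).  The distinction matters: with one shared latent
mode at 0.9/0.1 occupancy the class score densities are two-point mixtures
and their overlap is bounded below by ~0.2 no matter how good the
discriminant is; with independent pairs the class scores are binomial sums
and near-perfect separation (< 0.05 overlap) is achievable and achieved.
Latent states are i.i.d. across frames, matching the analysis's
independence assumption.

**What the generators do not emulate:** force fields, thermostats, real
lipid chemistry, frame-to-frame autocorrelation (no AR structure by
default), conformational strain coupling between contacts sharing a
residue, or solvent.  Passing tests therefore demonstrate correctness of
the *statistical machinery* under its own assumptions, not fidelity to any
physical system.

**Slab worlds** simulate biased Gaussian random walks (steps clipped below
half the box), extract true crossing events from the *continuous* paths
against the periodically replicated slab, then wrap.  **H-bond fixtures**
place each triad 40 Å from its neighbors and draw distance/angle either
inside (2.6–3.4 Å, < 18°) or outside (distance or angle violation chosen
at random) the criteria, recording the satisfying set.  **Lipid shells**
thin a uniform point cloud outside the enrichment radius by 1/enrichment,
so inner/outer density ratio equals the enrichment factor in expectation.

## Problem sizes

The shipped study conditions use 36–45 bead residues with 2–3 atoms each,
2 000–5 000 frames per ensemble, 500-walker / 400-frame slab worlds,
50-triad H-bond fixtures and 2×10⁴–6×10⁴-marker lipid fixtures.  These
sizes put every stochastic recovery statistic (PC1 cosine ≥ 0.95, λ₁
within 10%, LD1 overlap < 0.05, planted-mass ≥ 90%, enrichment within 20%)
comfortably inside its tolerance while keeping the full suite and the
acceptance script around half a minute each.

## Known limitations

* Orthorhombic boxes only; triclinic cells are not supported.
* The CLI's hydrogen-bond donor/acceptor assignment (N/O heavy atoms,
  hydrogen = next atom named `H*`) is a convenience heuristic; programmatic
  use should supply explicit `HBondCriteria`.
* Multi-model PDB is the only supported trajectory *output* dialect;
  binary formats are read (via MDAnalysis) but not written.
* LD score densities assume approximately unimodal per-class
  distributions; strongly multimodal classes make the overlap coefficient
  hard to interpret (see the mixture floor discussed above).
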