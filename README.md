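# contactmodes

Contact-based conformational-dynamics analysis for membrane-embedded
peptides, built around the antimicrobial peptide hBD-3 (human β-defensin 3,
45 residues, net formal charge +11e) interacting with lipid bilayers.

MD ensembles of a peptide under different conditions — low vs high salt,
oxidized wild-type vs reduced linear analog, different membrane
compositions — differ in subtle, collective rearrangements of which
residue–residue contacts are formed.  This package extracts those
differences:

1. **Contact states.**  For each frame, the binary contact
   `u_ij = 1` iff any atom of residue *i* lies within 4.2 Å of any atom of
   residue *j* (minimum-image convention under a periodic box).
2. **Dynamic contacts.**  Averaging over frames gives the mean contact
   matrix ⟨u⟩; pairs with ⟨u⟩_L < ⟨u⟩_ij < ⟨u⟩_H (defaults 0.1 and 0.9)
   are the *dynamic contact degrees of freedom*; everything else is static
   and dropped.
3. **Contact PCA.**  The covariance matrix of the pooled, mean-centered
   frames × contacts matrix is diagonalized.  The orthonormal eigenvectors
   d^(k) (loadings) with eigenvalues λ_k, ordered decreasingly, are the
   principal components; frame projections are PC scores, and the loading
   scaled by its fluctuation amplitude is PC_k × λ_k (a √λ_k variant is
   available).
4. **Supervised discrimination.**  Fisher LDA on the top-k PC scores
   (default k = 8) finds, for each labeled condition, coefficients C_l^j
   maximizing between- over within-class scatter:
   LD_l = Σ_j PC_j · C_l^j.  Because the d^(k) are orthonormal,
   Σ_k C_l^k d^(k) is the LD loading *in contact space* and is rendered as
   a signed symmetric residue×residue map (positive = contact formation,
   negative = contact breaking) or a 3-D cylinder edge list.
5. **Membrane analytics.**  Kabsch-superposition RMSD, radius of gyration,
   protein–bilayer COM displacement, hydrogen-bond counting (3.5 Å
   donor–acceptor distance, 20° donor-centered angle), PBC-aware water
   crossing counting on the unwrapped membrane normal, and lipid radial
   number density around the protein.

Because real μs-scale trajectories are too large to ship, the package
includes first-class, seed-deterministic synthetic generators
(`contactmodes.synth`) that plant known collective contact modes with
class-dependent occupancies, membrane-slab crossing worlds with exact
ground-truth events, hydrogen-bond triads with a planned satisfied
fraction, and radially enriched lipid shells — every pipeline stage is
validated against those ground truths.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data and write tables under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_contacts.py
python analysis/03_contact_pca.py
python analysis/04_discriminant.py
python analysis/05_membrane_analytics.py
```

Output of the PCA and discriminant steps:

```
20 dynamic contact DOFs selected (generator planted 20); recovered = True
20 contact DOFs; top-8 PCs explain 74.7% of the total variance
eigenvalue-sum / trace conservation: 2.22e-15 relative
|cos(PC1, planted set)| = 0.9995
redox: LD1 overlap = 0.0030; planted-set share of LD1 map mass = 0.999
redox: planted entries share one sign = True (negative = contacts broken going wild-type -> analog)
membrane: 2 discriminants for 3 classes
membrane: LD1 gpos-vs-gneg overlap = 0.0397 (separated)
membrane: LD2 gneg-vs-mixed overlap = 0.9424 (planted indistinguishable)
```

Reading this: the static filter recovered exactly the 20 pairs the
generator made dynamic; PC1 aligns with the planted 12-contact redox set
(cosine 0.9995); LDA separates wild-type from analog frames almost
perfectly (density overlap 0.003) and puts 99.9% of the LD1 contact map's
squared mass on the planted contacts, all with one sign — the analog class
breaks them.  For three membrane classes of which two are statistically
identical, LDA returns two discriminants: LD1 separates the distinct
composition while LD2 cannot separate the indistinguishable pair (overlap
0.94), as it should.

The same pipeline is scriptable from a shell:

```bash
contactmodes simulate ensemble --params spec.yaml --seed 5 --out-dir sim
contactmodes contacts --structure sim/structure.pdb --trajectory sim/ensemble.pdb --out-dir con
contactmodes pca --contacts-dir con --structure sim/structure.pdb --k 8 --out-dir pca
contactmodes lda --contacts-dir con --labels sim/frame_labels.tsv --condition condition --out-dir lda
contactmodes membrane --structure s.pdb --trajectory t.pdb --analysis crossings --slab 22,38 --out-dir mem
```

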