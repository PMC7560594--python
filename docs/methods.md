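# Methods

## Scope and model

`ncpdyn` quantifies the conformational dynamics of abasic lesions (AP and the
THF analog) in short nucleosomal-DNA duplex sections from trajectory
ensembles. It does not run molecular dynamics; it analyses coordinates and,
for testing, generates synthetic coordinates with a stated statistical
structure. All analyses operate on 13–15-bp sections: replicate 15-bp windows
are trimmed by one base pair at each end (the `trim` option, default 1) so
that fraying termini do not contaminate the descriptors.

## Descriptors

**Extrahelicity.** A lesion is classified extrahelical in a frame when the
distance between its C1′ atom and the facing nucleotide's C1′ atom exceeds
14 Å (strict `>`). The percentage is over all frames, with no contiguity
requirement. Abasic residues retain their C1′, so the criterion applies
unchanged to AP and THF.

**Orphan-base ejection.** Distance between the mass-weighted centres of mass
of the nucleobase heavy atoms of the orphan base and of its would-be
Watson–Crick partner; ejected when strictly above 10 Å. In canonical B-DNA
the reference value of this descriptor is 6.8 Å. Sugar, phosphate and
hydrogen atoms are excluded from the COM by default (configurable via
`subset="heavy"`), a choice calibrated so the canonical builder reproduces
the 6.8 Å reference.

**Bend angle (simplified).** Per frame, base-pair centres are taken as
midpoints of paired C1′ atoms; least-squares lines are fitted through the
first four and last four centres and the bend is the angle between the two
directions, each oriented along the 5′→3′ progression of the first strand.
This is deliberately simpler than a full helicoidal-axis analysis
(Curves+-style); reports label it "simplified end-segment axis fit". It is
exactly invariant under rigid-body motion and recovers designed arcs within
±2° (tested at 0°, 27°, 55°, 60°). It requires ≥ 10 bp and ≥ 4 pairs per end
segment.

**Coupling.** The φ (phi) coefficient — Pearson correlation of two binary
series — computed from the 2×2 contingency counts of the thresholded
extrahelicity and ejection indicators. Undefined (returned as `None`) when
either indicator is constant.

**Contact residence.** Charged groups are lysine NZ, the arginine
guanidinium triplet (NE, NH1, NH2), and the backbone N of each chain's first
residue (N-terminal amine). Arginine groups are detected even though typical
residence tables report only Lys/N-term pairs; the table layout selects
pairs explicitly. A frame counts as contact when the minimum over all
group-atom × site-atom distances is strictly below the cutoff (default 6 Å).
"Site atoms" default to *all* heavy atoms of the damaged residue, backbone
and phosphate included — the inclusive reading; any atom index set can be
passed instead (e.g. a specific NZ–C1′ pair).

**Replicate aggregation.** The "All" value is the equal-weight arithmetic
mean of the per-replicate percentages (replicates have equal length in the
emulated design), rounded half-away-from-zero to one decimal, rounding
applied last. This convention reproduces every internally consistent bundled
reference row; one row (K13(H2A)-THF7, reported All = 12.8 vs replicate
values 1.8/6.2/6.6) is inconsistent with every such convention and is
flagged in `ncpdyn.reference_tables` and excluded from consistency checks.
The spread reported alongside is the sample standard deviation (ddof = 1)
across replicates.

**Clustering.** Pairwise minimum RMSD (Kabsch superposition per frame pair,
proper rotations only, batched 3×3 SVDs) over the heavy atoms of the trimmed
section, then average-linkage hierarchical clustering cut at a distance
threshold ε (default 2.5 Å) or into k clusters. The per-pair superposition
means the matrix need not satisfy the triangle inequality. Occupancies are
percentages of all frames; representatives are medoids (minimum mean
intra-cluster RMSD, ties to the lower frame index). With the default ε the
conformers must be separated by more than ε over the clustered atom set;
subtle flips diluted across a large selection may need a focused selection
or `k`.

**Internal-coordinate PCA and importance.** Features are inverse distances
(Å⁻¹) between unweighted heavy-atom geometric centres of residue pairs, in
stable lexicographic pair order — exactly rigid-body invariant, so no
superposition is needed. The covariance of mean-centred features (ddof = 1)
is diagonalised; eigenvalues descend and tiny negative values are clipped.
Per-residue importance over the first `n_components` (default 10)
components: each component's squared loadings are summed over the features
containing a residue (each pair feature credits both members), weighted by
the component's eigenvalue share, and the residue scores are normalised to
sum to 100 %. Squared loadings are the standard variance-contribution
reading of "mapping loadings back"; an absolute-value variant
(`loading_power="abs"`) and unweighted component averaging
(`weighting="uniform"`) are available behind flags. Note that neighbours of
a mobile residue inherit importance through their shared pair features; the
mover still dominates.

## Synthetic generator

The generator states a world and the analyses must recover it.

* **Duplex builder.** Nucleotide geometry comes from idealized
  chemical-component templates (biotite's bundled CCD), heavy atoms only.
  Pairs are placed in a common frame (C1′ atoms at ±D/2 on the pair axis,
  glycosidic bonds at in-plane angle λ, strand B rotated 180° about the
  pair pseudo-dyad) and stacked with fiber-model helical parameters
  (3.38 Å rise, 36° twist — a convention, not a fitted value). D = 10.8 Å
  and λ = 62° are calibrated so the built dA:dT base-COM distance equals the
  6.8 Å canonical reference; ideal Watson–Crick geometry would give ~5.8 Å,
  so the calibrated pair is slightly opened (N1···N3 ≈ 3.6 Å). Successive
  backbone units are not covalently continuous. None of the analyses depend
  on hydrogen bonding or backbone continuity.
* **Lesions.** `apply_lesion` removes the nucleobase heavy atoms, renames
  the residue, and for AP adds an O1′ hydroxyl pseudo-atom 1.43 Å along the
  former glycosidic vector; THF lacks it — the two lesions differ by exactly
  that atom.
* **Flipping.** The extrahelical conformer rotates the whole residue about
  the axis through its P atom and the next residue's P (default 110°), with
  the rotation sense that carries the residue away from the duplex centroid.
  With the default geometry this moves the monitored distances ≥ 2 Å beyond
  their thresholds, so classification against ground truth agrees on
  ≥ 99 % of frames for coordinate noise σ ≤ 0.3 Å (tested at 100 %).
  Kinetics are either a first-order Markov chain (start intrahelical;
  stationary occupancy p_out/(p_out+p_in)) or `exact_fraction`
  (round(fraction·n_frames) extrahelical frames, evenly spaced — explicitly
  non-consecutive, which also exercises the indicator bookkeeping). Coupled
  sites copy a driver site's hidden state with an independent per-frame
  emission-flip probability, mirroring observed lesion/orphan correlation
  without asserting a mechanism.
* **Bends.** `bend_arc` maps the helix axis onto a planar curve whose end
  tangents differ by the designed angle: straight caps of 4 base pairs at
  each end joined by a circular arc. Each base pair is transported rigidly.
  The straight caps exist so that the end-segment line-fit metric measures
  the *full* designed tangent change; a pure arc would attenuate the chord
  fit by (n−4)/(n−1) and make the construction unusable as its own oracle.
* **Tail probe.** A rigid 3-atom Lys-like (or N-terminal) probe whose
  contact atom is placed, per frame, at the scripted distance from the
  site's outermost heavy atom along the outward radial direction — making
  the scripted distance the exact minimum distance. Episodes are disjoint
  half-open frame windows.
* **Determinism.** All randomness flows from `numpy.random.default_rng`
  seeded by the caller; identical seeds give bit-identical trajectories.
  Noise uses a derived stream (seed+1) so state sequences are invariant to
  the noise level.

### What the generator does *not* emulate

No force field, no thermodynamics, no solvent, no superhelical wrapping of
the full 145-bp nucleosomal path (sections are generated straight or with a
designed bend), no sequence-dependent base-pair step geometry, no backbone
continuity, no gradual flipping pathways (the two conformers are discrete).
A green test therefore establishes that the *analysis* recovers a stated
statistical structure — occupancies, designed angles, scripted contacts —
not that the generator reproduces real nucleosomal mechanics. Reported MD
statistics from the emulated study (extrahelicity tables, contact tables,
55 ± 9° bends) enter only as *designed values* for the generator or as
aggregation worked examples; they are not recomputed from physics.

## Numerical choices

* Threshold comparisons are strict (`>` for flipping/ejection, `<` for
  contacts); frames exactly at threshold count as the null state.
* Superposition requires ≥ 3 non-collinear atoms; reflections are corrected
  via the SVD determinant. RMSD oracles: an independent quaternion
  (Horn) implementation in the tests.
* The Markov-occupancy convergence test uses a 3σ band with the chain's
  autocorrelation correction, Var ≈ p(1−p)/n · (1+ρ)/(1−ρ) with
  ρ = 1 − p_out − p_in: the naive i.i.d. binomial σ understates the error of
  a correlated time average (for the tested chain the corrected 3σ ≈ 1 %,
  matching the designed ±1 % band).
* Degenerate PCA inputs (constant features) yield a flagged model with zero
  eigenvalues; importance on such a model is an error rather than NaN.
* `exact_fraction` placement uses `round()` at the frame count, so designed
  occupancies are recovered exactly only when fraction·n_frames is integral.

## Configuration defaults

| parameter | default | meaning |
|---|---|---|
| extrahelical threshold | 14 Å | lesion C1′–facing C1′ |
| ejection threshold | 10 Å | orphan/partner base-COM |
| canonical COM reference | 6.8 Å | built-pair calibration target |
| contact cutoff | 6 Å | min heavy-atom distance, strict |
| trim | 1 bp | 15-bp section → 13-bp analysis window |
| cluster ε | 2.5 Å | average-linkage distance cut |
| PCA components | 10 | importance truncation |
| helical rise / twist | 3.38 Å / 36° | fiber-model convention |
| flip angle | 110° | extrahelical conformer rotation |
| noise σ | 0.1 Å (pipeline) | per-coordinate Gaussian |

## Known limitations

* The bend angle is a section-geometry proxy, not a helicoidal-axis bend;
  absolute values from other axis definitions can differ by several degrees.
* Multi-model PDB is the only trajectory format; binary formats must be
  converted upstream.
* The importance map's equal split of a pair feature between its two
  residues is a convention; alternatives change absolute percentages but
  not, in the tested regimes, the top-ranked residues.
* `find_charged_groups` trusts residue naming (Amber-style variants
  included); non-standard protonation names outside that set are ignored.
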