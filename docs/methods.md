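# Methods

## Problem setting

`pocketgauge` assesses AI-predicted structures of a multi-subdomain protein
against an experimental reference, with the NLRP3 inflammasome sensor as the
shipped preset. NLRP3's subdomains (PYD 3–95, FISNA 96–218, NBD 219–372,
HD1 373–434, WHD 435–541, HD2 542–651, LRR 652–1036, author numbering) are
individually well predicted by AlphaFold/RoseTTAFold-class methods, but the
MCC950 binding pocket forms at the NBD/HD1/WHD/HD2/LRR interface, so model
usefulness for ligand work hinges on inter-domain packing. The package
separates the two questions — domain fold quality and domain packing — and
quantifies pocket formation directly.

## Coordinate system and mapping

Author (deposited) residue numbering is the universal coordinate system;
no renumbering is ever performed, so residues are addressed the way the
field names them (A228, R578) across predicted and experimental structures.
Model↔reference correspondences default to number+insertion-code identity
with matching 3-letter codes (mismatches excluded with a warning); a global
sequence alignment (match +1, mismatch −1, gap open −5, extend −0.5, via
Biopython's PairwiseAligner) is available for renumbered inputs. Atoms are
matched by name within mapped residues; atoms present on only one side
(truncated experimental side chains) are skipped, never imputed.
Alternate locations resolve to the highest-occupancy conformer, file order
breaking ties, for reproducibility. Hydrogens are kept on read (needed for
H-bond angles on MD frames) but excluded from all heavy-atom/RMSD work.

## Superposition and domain-partitioned RMSD

Rigid superposition is the closed-form SVD (Kabsch) solution with the
reflection corrected through the sign of the smallest singular value, so the
fit is always a proper rotation — biological coordinates are chiral. RMSD is
the plain, unweighted root-mean-square coordinate deviation over paired
atoms. Degenerate (collinear, N<3) point sets are rejected rather than
regularized, since the rotation is not identifiable there.

The domain RMSD table superposes each subdomain's paired atoms
*independently*; the Full-length row uses all mapped atoms, including
residues outside every named domain (its value should exceed any single
domain's row exactly when packing, not folding, is wrong). Both heavy-atom
and Cα variants are reported with their atom counts. Because incomplete
experimental side chains shrink the shared-atom set, heavy-atom counts are a
property of the pair of structures, not of the model alone. A guaranteed
inequality — each domain's separately-superposed RMSD cannot exceed the RMSD
of the same atoms under the full-length fit — is enforced by construction
and verified as a property test.

## Pocket metrics

Pocket formation is summarized by the Cα separation of the two anchor
residues the inhibitor must bridge (A228–R578 for NLRP3/MCC950). Verdict
thresholds default to formed ≤ 14 Å, loose ≤ 18 Å, unformed above; these
are heuristics anchored to known exemplars (~12.7 Å in the inhibitor-bound
experimental structure, 14.5 Å in the best predicted model, ~20 Å where the
subdomains are unpacked) and are fully configurable. Bounds are inclusive,
so the verdict is monotone in the distance.

Side-chain distances use heavy atoms excluding backbone (N, CA, C, O, OXT;
CB counts as side chain). Two definitions ship: minimum pairwise atom
distance (`min-heavy`, the common contact convention and the default) and
centroid distance. Published heat-map figures of such matrices rarely state
their convention, so deviation matrices (model − reference, signed) are
expected to reproduce sign patterns rather than be cell-exact. Glycine and
truncated residues fall back to Cα with a warning; unresolvable residues
yield masked (NaN) rows, reported and never imputed.

## Contacts

Salt bridge: any side-chain N of Arg/Lys (His only in protonated forms
HIP/HSP, or via flag) within 4.0 Å of a side-chain carboxylate O of
Asp/Glu; one record per residue pair at the minimum-distance atom pair
(full atom-pair list by flag). Hydrogen bond: donor–acceptor heavy-atom
distance ≤ 3.5 Å, plus D–H···A angle ≥ 135° whenever an explicit hydrogen
is bonded to the donor (≤1.25 Å); without hydrogens the criterion is
distance-only. The cutoffs are stated conventions — common literature
defaults, configurable — chosen because reproducibility requires committing
to definite criteria. Both detectors are monotone in their cutoffs
(relaxing a criterion never removes a contact), a property under test.
Trajectory occupancy is the fraction of frames in which a contact key
(donor/acceptor atoms, not geometry) satisfies the criteria; counts are
integer-exact. Occupancies are reported as fractions of all supplied
frames.

## Trajectories

Trajectories are consumed, never produced: frames come from standard MD
formats through MDAnalysis (or from the synthetic generator) into a plain
frames×atoms×3 array over a topology structure. RMSD series superpose every
frame onto frame 1 over a fit selection (protein Cα by default, including
when the measured selection is the ligand — the standard convention) and
measure over a possibly different selection; the first value is identically
zero. Periodic-boundary unwrapping is not performed; trajectories must be
supplied imaged. The indicator-distance series evaluates the anchor-residue
Cα distance per frame with first/last/mean summaries.

## Confidence aggregation

Per-residue pLDDT is read from the Cα B-factor (mean over atoms as
fallback); 0–1 encodings are auto-detected (all values ≤ 1) and rescaled,
since some predictors write the 0–1 convention. Domain rows are arithmetic
means over residues present; the Whole row equals the residue-count-weighted
mean of the domain rows (an identity verified to 1e-9). Interpretation
bands: >90 high, 70–90 moderate, 50–70 low, <50 disordered, with boundary
scores assigned to the higher band. Across a model set both population and
sample standard deviations are available (default population): published
five-model summaries for NLRP3 are internally inconsistent about which
convention they used (the AF spread matches the population formula, the RF
spread the sample formula), so the package exposes both rather than guess.
pTM is pass-through metadata only; computing it requires the predictor
network and is out of scope.

## Synthetic ground truth

The generator builds an idealized helical poly-alanine trace (2.3 Å radius,
100°/residue, 1.5 Å rise — ~3.8 Å Cα spacing) with template backbone/CB
offsets, partitioned into labelled domains. The model applies per-domain
rigid transforms (axis-angle about the domain centroid plus translation)
and isotropic Gaussian coordinate noise; the reference instead deletes a
per-domain fraction of residues (count = ⌊f·n + 0.5⌋, so 31.8% of a
110-residue domain is exactly 35 residues — the scale of HD2's missing
density in the NLRP3–NEK7 structure). Planted per-domain confidence means
are written into B-factors verbatim so recovery is exact. Pocket toys embed
a complete pairwise Cα distance set by classical MDS with a 1e-6
feasibility check, attach template side chains pointing away from the
pocket centroid, and can plant an Arg–Glu N–O pair at an exact distance.
Toy trajectories realize drift/oscillation motion programs exactly and
place each planted contact in exactly round(fraction·n_frames) seeded
frames. Everything is deterministic per seed, to the byte after PDB
round-trip.

What the toys do *not* emulate: real predictor error statistics,
stereochemical realism (bond lengths/angles beyond the templates),
solvent, or ligand force-field behaviour. Passing tests therefore
demonstrate correctness of the measurement pipeline — mapping, fitting,
distances, criteria, bookkeeping — not accuracy claims about any
predictor.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: toys of 16–110 residues,
trajectories of 10–100 frames, which exercise every code path in seconds.
The Kabsch implementation is cross-checked against direct Nelder-Mead
minimisation over axis-angle parameters (12 restarts) to ≤1e-4 Å on point
sets of up to 10 atoms. Collinearity is detected via the second singular
value (≤1e-10 relative). PDB round-trip precision is the format's 1e-3 Å.
Integration against the real accessions (6NPY, 7PZC, published AF/RF model
files) is wired into the test suite but requires the user to place those
files under `tests/data/accessions/` — they are not redistributed.

## Known limitations

- Heavy-atom counts in the RMSD table depend on the shared-atom convention
  (no imputation), so they may differ slightly from published tables whose
  conventions are unstated.
- Residue 629 of NLRP3 appears in the literature both as E629 (salt
  bridge) and G629 (H-bond partner); the key-residue table deliberately
  keeps both labels and leaves sequence validation to the user.
- H-bond donor/acceptor role tables cover standard residues and
  element-derived ligand roles; exotic chemistry needs explicit role lists.
- No TM-score/GDT, no outlier-rejecting superposition, no pocket-volume or
  druggability scoring, no π-stacking/hydrophobic contact scoring.
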