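# Methods

This note documents the models implemented in fibrilscope, the defaults
that matter, and the reasoning behind the genuinely open design choices.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Spectrum simulation

**Cross-peak model.**  Full spin-physics back-calculation of DARR
polarization transfer is out of scope; fibrilscope uses an explicit
distance-cutoff model.  A ¹³C–¹³C DARR experiment with mixing time τ
correlates an ordered pair of assigned carbons when their minimum
interatomic distance — evaluated over chain offsets {0, +1, −1}, i.e.
intra-protomer and the two adjacent protomers of the stack (strict fibril
symmetry, nearest neighbours) — is within a cutoff c(τ): 6 Å at 50 ms, 8 Å
at 125/200 ms, 10 Å at 500 ms.  These are the transfer ranges commonly
quoted for DARR; no default is claimed for other mixing times.  The 200 ms
value is interpolated between the 125 and 500 ms regimes and is a package
choice.

**Amplitude ramp.**  Cross-peak amplitude is a(r) = 1 − r/c, the simplest
*strictly monotone* stand-in for DARR buildup; diagonal peaks have
amplitude 1.  Monotonicity is load-bearing: it keeps intensity an
invertible proxy for distance, which the calibrated restraint-binning mode
exploits (below).  A flat-topped ramp (constant to 0.8 c, then falling) was
considered and rejected because it makes all short contacts isointense, so
intensity bins could never soundly map onto the shorter upper bounds.

**NCA.**  One peak per residue with assigned N and Cα, uniform amplitude
(no CP-efficiency modelling).  In the default CP mode, proline gives no
NCA peak — it has no amide proton to cross-polarize from — while DP mode
(`cp_mode=False`) keeps it; proline's backbone ¹⁵N sits near 136 ppm.

**Lineshape.**  Pure Gaussians, FWHM 0.23 ppm for ¹³C (the conventional
matching tolerance of 0.35 ppm is ~1.5× the average ¹³C linewidth) and
0.8 ppm for ¹⁵N (a typical uniformly-labelled fibril value; no literature
anchor, package default).  Peak integral equals its amplitude.  Because
polymorph comparisons always score identically processed pairs, the
lineshape family cancels in ZNCC comparisons; no apodization emulation is
attempted, which mainly affects *absolute* scores against externally
processed data.

**Peak picking.**  Local maxima above 6× the noise floor, with 3-point
parabolic interpolation per axis for sub-grid positions.  The noise floor
is 1.4826 × the median absolute deviation of all intensities — a robust σ
that ignores the sparse strong peaks typical of these spectra.  On
noiseless synthetic images the MAD is zero and the threshold falls back to
a tiny fraction of the maximum so simulate→pick round trips work.
Restricted 3D picking keeps candidates whose (ω₁, ω₂) lie within 0.3 ppm
of a short-mixing 2D seed peak in both dimensions.

## ZNCC comparison and clustering

ZNCC is the Pearson correlation of the flattened intensity images
(population σ), exactly 1 on self, symmetric, and invariant under separate
affine intensity transforms.  Standard ZNCC spans [−1, 1]; because
nonnegative spectral images essentially never anticorrelate, the raw
signed value is reported, with an optional rectification mapping negatives
to 0 for display.

Spectra on different grids are bilinearly resampled onto the intersection
of their ppm windows at the finer step per axis; intensities are not
renormalized (ZNCC is affine-invariant anyway).  Pairwise matrices are
clustered agglomeratively on d = 1 − score with average linkage (UPGMA) —
a robust default for similarity matrices; no linkage is canonical for this
task — and flat clusters are cut at d = 0.5, the complement of the
convention that scores below 0.50 do not indicate structural similarity.

## Restraint generation

Matching uses a tight 0.25 ppm tolerance per ¹³C dimension.  Candidates
are every atom combination within tolerance in all dimensions; each
cross-residue atom pair is expanded over chain offsets {0, ±1}, while
same-residue pairs stay intra-protomer (an N(i)–Cα(i) peak is one
candidate, not three).  The network filter then (i) always retains peaks
with an intraresidue/sequential/short-range (|i−j| ≤ 2) candidate,
(ii) deletes peaks whose candidates span more than two distinct chain
offsets, and (iii) deletes peaks with more than 20 candidates.  Surviving
assignments carry a network-support score (other retained peaks linking a
residue pair within ±1 on both indices) for ranking only — the full
probabilistic likelihood machinery of PASD is out of scope.

**Intensity → upper bound.**  Two binning modes:

* *quartile* (default of `bin_to_bounds`, intended for experimental peak
  lists): within-spectrum intensity quartiles, top quartile = strong;
  boundary ties fall to the weaker (larger-bound) bin.  Whether bins should
  be global or per-spectrum is not standardized; per-spectrum is used.
* *calibrated* (default of the `generate_restraints` pipeline, intended for
  simulated peak lists): inverts the amplitude ramp, r̂ = c·(1 − I/I_max),
  and assigns the smallest tabulated bound ≥ r̂.  For noiseless simulated
  peaks this reproduces the generating distance exactly, so every restraint
  is satisfied by construction; quartile binning cannot guarantee this for
  any amplitude model, because the top intensity quartile may contain
  contacts longer than the strongest bound.

Bounds per category and mixing time: 3/4/5/6 Å (50 ms), 4/5/6/8 Å
(125 ms), 4/6/8/10 Å (500 ms).  3D peaks yield two restraints — the ω₁–ω₂
pair at short-mixing bounds and the ω₂–ω₃ pair at long-mixing bounds
(`split_3d`).  A restraint is satisfied in a model when the minimum over
its candidate assignments (first atom in the middle reference chain, later
atoms at their recorded chain offsets) is within the bound plus a 10⁻⁶ Å
numerical slack; violations are averaged over ensemble models.  Ambiguity
statistics support uniform (default) and intensity weighting — the
weighting behind published "weighted average ambiguity" numbers is not
standardized.

## Structure classification

Residue correspondence uses pairwise global (Needleman–Wunsch) alignment
with match +1 / mismatch −1 / gap −2 via Biopython's `PairwiseAligner`
rather than an external multiple-alignment binary: only a pairwise mapping
to a reference numbering is needed, and for near-identical fibril
sequences the mapping is the same.  Chains under 50% identity are rejected
with a report.  Cα coordinates over the core window (default 40–96,
configurable) form one row per protomer; rows with any missing Cα are
excluded and reported.

Superposition iteratively fits every row to the evolving mean (Kabsch SVD
with reflection guard) until the mean RMSD changes by < 10⁻⁶ Å, then
centres the frame.  PCA is the standard centred decomposition
(scikit-learn).  DBSCAN (scikit-learn) clusters the PC scores; when eps is
unset it derives from the sorted (min_pts−1)-nearest-neighbour distance
curve — if the curve spans less than a factor of 5 there is a single
density regime and eps is its maximum (every point becomes core), else eps
sits at the kneedle-style elbow.  The factor-5 rule matters for small
balanced designs (e.g. two clusters of three), where the min_pts-th
neighbour is always a cross-cluster point and a naive elbow merges
everything.

Ensemble pairwise RMSD superposes every unordered model pair independently
on the selected atoms (backbone = N, Cα, C, O; heavy = non-H) before
averaging — the matchmaker-like convention, which differs numerically from
a common-frame fit.  RMSF is per-residue over the 3D displacement norm.
The protomer rise projects adjacent chain-centroid differences onto the
principal axis of the centroid stack.

## Synthetic fixtures

`make_fibril` builds an idealized serpentine protomer: strands at 3.8 Å
Cα–Cα spacing reversing direction at each turn, loops on semicircular
arcs, pseudo-backbone (N, C, O) at fixed local offsets, and pleated
pseudo-Cβ (plus a single sidechain tip atom for E/K/T/V) pointing into the
inter-sheet gap.  Copies stack along z at the 4.7 Å cross-β rise (default
5 protomers, optional twist), with seeded per-atom Gaussian jitter.  Two
deliberate idealizations:

* the inter-sheet spacing is compressed to 5.8 Å — the tight end of
  steric-zipper packing — so that Cα–Cα contact maps at the conventional
  6 Å cutoff carry the fold topology, as interdigitated mated sheets do in
  real cores;
* the pseudo-geometry is not sterically relaxed; local clashes can occur in
  turns.  All in-scope operations are distance-threshold logic, which such
  clashes do not affect.

`make_resonances` draws shifts as random-coil base values per residue type
(an embedded fixture convention, not a scientific claim), β-strand offsets
of −2 ppm (Cα) / +2 ppm (Cβ) inside strand segments, a fold-specific
packing perturbation (σ = 1.0 ppm) and per-atom scatter (σ = 0.1 ppm).
The random seed derives from a CRC of the fold topology, so templates
differing only in jitter seed share an identical shift list — chemical
shifts are a property of the fold — while different topologies draw
independent packing environments.  The 1.0 ppm packing σ encodes the
observation that distinct polymorphs differ in shifts across the whole
core (of order 1–2 ppm) and score below the 0.50 ZNCC similarity rule,
whereas replicates of one polymorph agree closely.  Spectrum noise is
Gaussian with σ = (max peak amplitude)/SNR.

**What passing tests do and do not show.**  The fixtures emulate contact
topology, shift statistics and noise — not real lineshapes, apodization,
spinning sidebands, relaxation, site-specific dynamics or sidechain
rotamers.  Classification-recovery and restraint-soundness results on
fixtures therefore demonstrate the correctness of the *machinery* (the
scores, filters and geometry are computed as specified), not the absolute
ZNCC levels or restraint counts expected from experimental fibril spectra,
which depend on those unmodelled factors.

## Problem sizes and numerics

Default end-to-end runs use the 66-residue core template with 5 protomers:
~3 400 cross peaks at 50 ms and ~7 500 at 500 ms, a few × 10⁶ candidate
assignments held in compact integer arrays, and 2D grids of 0.1 ppm per
point (0.25 ppm for CLI fixture output).  The polymorph-recovery analyses
use 2 folds × 3 seeds.  Degenerate shifts co-add rather than deduplicate.
Ties: quartile binning demotes boundary intensities to the weaker bin;
altloc ties keep the first conformer in file order; DBSCAN noise is
labelled −1.  Axis convention is ppm decreasing with index (negative
step); spectra are row-major with axis 1 the indirect dimension.

## Known limitations

* The distance-cutoff cross-peak model has no mixing-time-dependent
  amplitude physics beyond the cutoff/ramp; relative intensities at long
  mixing are approximate.
* The text spectrum format (CSV matrix + JSON axes) is a documented
  stand-in; no NMRPipe/UCSF binary support.
* The NMR-STAR reader handles the standard `Atom_chem_shift` loop only.
* Restraint likelihood refinement (multi-pass structure-calculation
  feedback) and torsion-angle restraints are out of scope.
* Quantities that require experimental spectra (absolute validation ZNCC
  levels, restraint-count tables, assignment-ambiguity magnitudes) are not
  reproduced by the synthetic pipeline and are not claimed.
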