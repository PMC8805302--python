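# Methods

This note records the models and conventions behind each score, the
parameters that matter, what the synthetic data does and does not emulate,
and the numerical choices made where the design was genuinely open.

## Density grids and coordinates

Volumes are normalized on read to x-fastest axis order regardless of the
axis permutation stored in the MRC/CCP4 header. The position of voxel
(0,0,0) comes from the MRC2014 ORIGIN words when any is nonzero, otherwise
from `start × voxel_size` per axis. Model coordinates map to fractional
voxel indices as `(coord − origin) / voxel_size`, 0-based, everywhere in the
package; fixing this convention once avoids the classic half-voxel and
axis-order disagreements between tools. Output is always mode-2 (float32),
P1, with the origin written back into the ORIGIN words.

## Automatic contour level

The default contour is `m + 1.5 s`, where `m` is the center of the modal
bin of a 128-bin histogram over the full value range and `s` is the standard
deviation of voxels at or below `m`, mirrored about it. The mirrored
below-mode estimator isolates the noise lobe of the histogram so the
molecular-signal tail does not inflate the spread; how σ should be computed
is otherwise underdetermined, and this estimator is a declared choice.
It is shift-equivariant and scales linearly with the map, which the tests
assert. A user-supplied contour always overrides it.

## Simulated density

Each non-hydrogen atom with positive occupancy contributes an isotropic
Gaussian with real-space variance σ² = B_total/8π², B_total = (per-atom B if
enabled) + a global blur, normalized so the integrated density is
occupancy × atomic number, truncated at 4σ (≈0.1% mass loss). The global
blur default is B = 4 ln2 · R², the value at which an atom's Fourier
amplitude exp(−B s²/4) falls to one half at the cutoff s = 1/R; it keeps
maps meaningful for unrefined (B = 0) models and ties the atom width to the
stated resolution in a reproducible way. The summed map is then band-limited
at R. Electron scattering form factors and solvent are deliberately out of
scope; the Gaussian approximation is the model.

The low-pass filter applies a raised-cosine edge two Fourier shells wide
(shell = coarsest frequency step of the box) beyond 1/R, leaving DC — and
hence the mean — untouched. The two-shell edge suppresses the ringing a hard
cutoff would inject into residue-sized footprints. A multiplicative taper is
idempotent only on maps whose spectrum vanishes inside the edge band; the
tests therefore assert exact identity on a pre-band-limited map and
contraction (not identity) on re-filtering, which is what a cosine taper can
honestly guarantee.

## FSC and FSCavg

Fourier coefficients are taken from the Hermitian half-spectrum so each
structure factor counts once; the DC term is excluded. Shells are equal-width
in spatial frequency up to the smallest axis Nyquist (so every shell is fully
sampled), default count = min(grid)/2 capped at 64. Shell correlation is
Re Σ A·B̄ / √(Σ|A|² Σ|B|²). FSCavg weights shells by their coefficient count
and uses only shells with d_min at or coarser than the reported resolution
limit; if that excludes every shell the average falls back to all shells with
a warning.

## Contoured real-space scores

CCC and MI are computed over the **union** of the two above-contour voxel
sets: density present in only one map should hurt the score, and the union
makes the comparison symmetric. MI uses 20 equal-width bins per map spanning
that map's above-contour value range (natural log, so nats). OV is
|A ∩ B| / min(|A|, |B|), so a model fully contained in a larger molecular
volume scores 1. These normalizations are package choices (the combined-score
literature leaves them open) and are switchable in code.

Ensemble-combined scores standardize each raw score across ≥3 models to zero
mean and unit spread, then add the standardized OV to the standardized CCC or
MI. A spread that is zero up to floating-point roundoff (≤1e−12 relative) is
treated as zero, mapping constant score vectors to zeros rather than ±1
artifacts of roundoff.

## SMOC and local Z-scores

A residue's footprint is the union of voxels within r of any of its atoms;
r defaults to max(2.5 Å, 1.5 × voxel) to cover backbone plus Cβ density at
typical sampling. The score is the Manders' overlap coefficient between the
simulated and the experimental density restricted to the footprint, with
experimental values clamped below at zero (cryo-EM maps have negative
ripples; MOC presumes non-negative signals) so SMOC ∈ [0, 1] and is invariant
under positive scaling of the map.

Z-scores compare each residue with the residues whose Cα lies within 12 Å of
its own Cα, itself included (including it slightly shrinks |Z| and makes a
size-1 neighborhood well-defined); the spread is the population SD with the
same roundoff guard as above, and Z < −1.5 flags an outlier.

**Known edge artifact:** residues at chain termini have footprints half
filled with background, so under appreciable noise their SMOC is
systematically a little lower than the chain interior while the local spread
stays tiny — at noise ≥ 10% of peak the first/last residue can cross
Z < −1.5 without being misplaced. Such flags land in the unclustered row of
the report rather than forming a cluster. Fixtures that assert *unique*
outlier identification therefore use a mild-noise map (5% of peak) and a
3.5 Å footprint, conditions under which termini behave.

## FDR confidence map and backbone score

Background noise is estimated from twelve periphery windows (8 corner cubes
plus 4 z-centered edge windows, edge = dim/8, minimum 2 voxels), assuming a
centered particle; heterogeneous window spreads (>3× ratio) trigger a
warning. A map with ≥5% exactly-zero voxels is rejected as masked — masking
destroys the background statistics this method depends on.

For each resolution in the scan (default: nominal R, 1.5R, 2R) the map is
low-passed, noise re-estimated, right-tail p-values computed under the noise
Gaussian, and the Benjamini–Yekutieli adjustment (valid under arbitrary
dependence, which smoothed voxels certainly have) applied across all voxels
as one family per pass. Confidence = 1 − adjusted q, pooled by voxel-wise
maximum over the scan: genuine density is confident at whichever blur
matches its local scale, while noise stays controlled at every pass.

A residue's backbone score is the fraction of its backbone atoms (N/CA/C/O;
P/C3'/C4'/C5'/O3'/O5' for nucleotides) whose trilinearly interpolated
confidence reaches 1 − q; atoms outside the grid count as unconfident.
Thresholding per atom (rather than averaging atom confidences) keeps the
score an interpretable fraction; the mean-confidence alternative would be
smoother but mixes evidence levels. Residues below 0.9 are flagged, and the
overall metric is the fraction of residues **strictly above** 0.9.

## Model checks

B factors: Gaussian KDE with Silverman bandwidth evaluated at 256 points over
the padded data range; peaks are local maxima with prominence ≥5% of the KDE
maximum (below that, sampling wiggles masquerade as modes). Two or more peaks
warn about partial occupancies, domain motions or inconsistent refinement;
an exactly constant distribution raises a distinct unrefined-B warning;
fewer than 10 atoms skip peak analysis.

Clashes: pairs whose van-der-Waals overlap (r_a + r_b − d, fixed radii table
C 1.70 / N 1.55 / O 1.52 / S 1.80 / H 1.20 / P 1.80 Å) reaches 0.4 Å, found
with a KD-tree. Excluded are all intra-residue pairs and pairs within three
bonds across the peptide (C–N) or phosphodiester (O3'–P) link, counted on a
standard backbone bond graph — this keeps normal 1-3/1-4 contacts such as
O(i)–Cα(i+1) out of the list while retaining genuine side-chain collisions.
This is a deliberately simplified screen, not a MolProbity clashscore, and
the report labels it as such. The rate is 1000 × clashes / atoms.

## Outlier clustering and report

"Within 7 Å of each other" is read as single-linkage connectivity of Cα–Cα
distances (transitive closure); a strict-clique reading would split visually
contiguous problem regions. Components of ≥2 residues are ranked by
descending size with ties broken by the first member's file order; singletons
and residues lacking a Cα/P pool into a final unclustered group. The JSON
report carries tool version, input hashes and all parameters, and is
byte-stable for identical inputs (no timestamps), which the end-to-end test
asserts.

## Synthetic data

The generator builds polyalanine chains (N, CA, C, O, CB) from ideal internal
coordinates — bonds N–CA 1.46, CA–C 1.52, C–N 1.33 Å, trans peptides,
helical (−57.8°, −47°) or extended (−139°, 135°) torsions, L-chirality — with
B factors drawn from N(30, 5²) Å², then simulates a 3 Å map on a grid padded
10 Å around the model (1 Å voxels) and adds i.i.d. Gaussian noise at 20% of
the clean peak by default. Everything derives from one integer seed.

What this emulates: per-atom B-factor blur, realistic backbone geometry and
spacing, additive background noise, and misfit via rigid displacement of
chosen residues. What it does not: structured noise (CTF, masking artifacts,
local resolution variation), side chains beyond Cβ, solvent, and map
post-processing. Passing tests therefore demonstrate correctness of the
scoring machinery and its statistical calibration under homogeneous Gaussian
noise — not performance on pathological experimental maps.

Problem sizes in the test and acceptance runs (20-residue chains, 40–64³
voxel grids, 5-seed replications) were chosen to exercise every code path
at desk scale; all scores are O(voxels) or O(atoms log atoms) and transfer
unchanged to full-size maps.

## Limitations

- The Gaussian-atom map is not a scattering-factor calculation; absolute
  global scores are comparable between models on the same map, not across
  software.
- Background estimation assumes a centered particle; off-center particles
  need explicit background windows.
- The clash screen has no hydrogen placement and a minimal exclusion graph;
  it under-reports relative to a full contact-dot analysis.
- Terminal-residue SMOC Z-scores are biased low at high noise (see above).
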