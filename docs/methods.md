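# Methods

This package computes the free-energy cost of forming a trefoil (3₁)
knot in the unfolded state of a polypeptide, combining two independent
routes: a thermodynamic cycle built from single-molecule pulling
measurements, and a random-chain Monte Carlo prediction of the entropic
knotting cost. A synthetic-data generator stands in for the
optical-tweezers experiment so every analysis step can be tested against
known ground truth.

## The random-chain knotting model

The unfolded chain is modeled as a freely-jointed chain of N rigid
segments, one Kuhn length each, with hard-cylinder excluded volume: two
non-adjacent segments may not approach closer than the effective
diameter D (minimum distance between segment midlines; segments sharing
a vertex are exempt). Defaults map the 120-residue construct onto
N = 32 segments of 1.4 nm (≈3.7 residues per segment) with D = 0.49 nm.
The published bookkeeping is not fully self-consistent here (3.7
residues × 0.35 nm/residue = 1.295 nm, and a persistence length of
0.65 nm implies a 1.3 nm Kuhn length); we follow the 1.4 nm convention
used for the D/2P ↔ D mapping (0.35 × 1.4 = 0.49 nm) and expose the
Kuhn length as a parameter.

**Ensembles.** Two equilibrium ensembles are implemented, and the choice
matters at the ±0.5 kcal/mol level:

* **Closed polygons ("ring", the default for ΔG_S).** Equilateral rings
  sampled by hard-core Metropolis crankshaft moves: two hinge vertices
  are chosen, the shorter arc between them is rigidly rotated by a
  uniform angle, and the move is accepted iff no cylinder overlap
  results. Moves preserve closure and bond lengths exactly; large-angle
  rotations perform strand passages, so all knot types are reachable and
  the chain samples the equilibrium topology distribution. This is the
  ensemble of the classical circular-DNA knotting calculations that the
  chain model descends from. Validation: the phantom-ring knot fraction
  at N = 100 is 0.293, matching the canonical 1 − exp(−N/N₀) law with
  N₀ ≈ 290 for random equilateral polygons.
* **Open chains closed post hoc ("open").** I.i.d. open chains; the knot
  type is assigned after closing each chain by two rays that leave the
  termini radially away from the chain centroid and meet on a far sphere
  ("closure at infinity", deterministic given the chain). Direct
  end-joining is available as a cross-check; the two closures agree
  within sampling error on phantom chains at N = 32. At very short
  lengths the closure construction itself produces a tiny knotted
  fraction (≈3×10⁻⁴ at N = 6, confirmed by an independent symbolic
  implementation), which is an intrinsic ambiguity of defining knots on
  open chains, not a defect of either closure.

Open chains are sampled by dimerization: a chain of n segments is the
concatenation of two independent self-avoiding halves, rejected whenever
an inter-half overlap occurs, with direct rejection growth below 16
segments. This draws from exactly the same uniform self-avoiding
ensemble as naive rejection (verified: identical Rg at N = 32,
D = 0.49 nm) but keeps the cost polynomial — naive rejection has
acceptance ~10⁻⁵ at N = 100, D = 0.49 nm. A Metropolis
crankshaft/pivot sampler for open chains is retained purely as an
independent cross-check.

**Knot detection.** Closed polygons are first reduced by
topology-preserving vertex elimination (a vertex is removed when no
other edge pierces its triangle; borderline geometry — near-coplanar
edges, degenerate triangles — is treated conservatively, except that a
vertex lying exactly on the chord of its neighbours is always
removable). Reduction to ≤3 vertices certifies the unknot. Remaining
polygons are projected along a direction drawn deterministically from
the geometry; crossings feed the Alexander matrix via the underpass
(Burau-type) relations, and |Δ(−1)| and |Δ(−2)| (the latter normalized
by stripping powers of two, the polynomial being defined only up to
±t^k) classify: (1, ·) unknot, (3, 7) trefoil, anything else "other".
|Δ(−1)| alone cannot separate 3₁ from 8₁₉-type knots, hence the second
evaluation; at these chain lengths non-trefoil knots are a few percent
of knotted states at D = 0 and essentially absent at D = 0.49 nm.
Non-generic projections (a crossing at a vertex, overlapping parallel
edges) trigger re-projection with fresh deterministic directions.
Determinants are evaluated by partially pivoted Gaussian elimination in
float64; after simplification the matrices are small and the integer
results exact.

**From knot fraction to free energy.** With p the equilibrium trefoil
fraction, ΔG_S = −RT ln[p/(1−p)] (R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹,
T = 298.15 K, RT ≈ 0.593 kcal/mol). Counting uncertainty uses a Wilson
score interval; for ring ensembles consecutive samples can be
correlated, so the interval is based on the number of distinct knotting
*events* (maximal runs of knotted samples) rather than raw counts. The
delta method propagates the interval to ΔG_S. Zero observed knots yield
an unbounded ΔG_S with the one-sided lower bound reported. Default
decorrelation stride is max(40, 0.6 N) moves with a 100 N-move burn-in;
measured knot-state lifetimes are ~5–20 moves, so samples at this
stride carry negligible clumping.

**Scans.** ΔG_S versus D/2P (at fixed N) is fitted by weighted least
squares to a straight line, the per-point delta-method errors supplying
the weights and an absolute-sigma covariance (no residual rescaling);
solving the line at a target ΔG_S gives the effective diameter with a
delta-method CI, and extrapolation outside the scanned free-energy
range is refused. ΔG_S versus N (at fixed D) is summarized by an
exponential fit A·exp(−N/N₀) valid only on the sampled interval.

**Problem sizes.** The headline numbers use 5×10⁴ ring samples at
N = 100 (ΔG_S at the fitted diameter), 2×10⁴ open chains at N = 32 (mean
radius of gyration), and a five-point diameter scan at N = 32 with
0.5–7×10⁵ samples per point, larger at larger D where knots are rarer.

**A known discrepancy.** The open-chain ensemble at the stated
parameters (N = 32, l = 1.4 nm, D = 0.49 nm) has mean Rg ≈ 3.98 nm —
phantom-chain theory (l√(N/6) ≈ 3.2 nm) times the expected ~1.25
excluded-volume swelling — while the experiment's reported simulated
value is 3.5 ± 0.06 nm, and the ring ensemble gives 2.94 nm. Neither
ensemble reproduces 3.5 at these parameters; a finer-grained chain
representation (or a growth-biased sampler) would. We report the
open-chain value unmodified.

## Worm-like-chain mechanics

The Marko–Siggia interpolation formula gives the force law; persistence
length is fixed at 0.65 nm (never fitted) and contour length is 0.35 nm
per residue (42 nm for the 120-residue construct, 36.05 nm for the
103-residue control). The inverse (extension at force) is found by
bracketed root-finding at 10⁻¹² relative tolerance; the stretching work
W_s integrates the force law by adaptive quadrature (10⁻¹⁰ relative),
tested against the analytic antiderivative. Rip work uses the rectangle
convention W_obs = F·Δx at the transition force, in which the
DNA-handle stretching work cancels; W^(F=0) = W_obs − W_s. Units are
pN/nm internally with 1 kcal/mol = 6.948 pN·nm. Experimental contour
length per rip is L_c,exp = (Δx_exp/Δx_WLC(F)) · L_c,theory.

The rip detector looks, within each constant-speed ramp, for the
largest force discontinuity of the transition's sign (a drop while
pulling, a rise while relaxing) spanning at most 3 samples and at least
1 pN (both configurable; the default suits the generator's noise of
0.15 pN at 1 kHz), and reports the branch force just before the jump
and the extension change across it.

## Free-energy extraction and the cycle

Work distributions are fitted as Gaussians by maximum likelihood
(sample mean/SD) — bin-free, matching the Gaussian model. With
refolding works sign-flipped onto the unfolding-work axis, the Crooks
crossing is the root of the equal-density quadratic lying between the
two means (the midpoint when the spreads are equal); fits admitting no
such root raise an error rather than returning a number. The
coexistence route fits ln τ versus F for folded and unfolded lifetimes
and evaluates ΔG = F₁/₂·Δx(F₁/₂) − W_s(F₁/₂) with the class's contour
length. Native-state knotting uses ΔG_N = −RT ln(P_unknotted/P_knotted)
from Boltzmann-weighted conformer energies (kT = 1 REU ≈ 0.57 kcal/mol
in the Rosetta convention) or direct molecule counts. The cycle closes
as ΔG_U = ΔG_unfold(knotted) − ΔG_unfold(unknotted) − ΔG_N with
quadrature error propagation; because the published arithmetic route to
the headline 5.8 kcal/mol is not fully specified, the pipeline reports
ΔG_U for CFT-only, F₁/₂-only and averaged stabilities.

## Kinetics

Bell and Dudko–Hummer–Szabo rate laws (ν fixed at 1/2 by default; 2/3
optional; ν = 1 collapses to Bell exactly and ΔG‡ → ∞ asymptotically).
Rupture-force histograms (bin count 3 + log₂N, rounded) transform to
rates as k(F_i) = r(F_i)·h(F_i)/S(F_i) with the direction-appropriate
survival fraction; the loading rate is speed × stiffness, optionally
with the WLC compliance in series. Fits are weighted least squares on
ln k: linear for Bell, nonlinear with ν held fixed for DHS (free-ν
three-parameter fits on a 2–30 pN window are ill-conditioned — ΔG‡
alone is already heavy-tailed on narrow windows). First-passage
simulation integrates the hazard along the ramp into a cumulative
hazard and inverts it on uniform deviates; refolding runs down the ramp
with the negative-Δx convention, under which shrinking |Δx≠| by ~4 nm
raises and broadens the refolding force distribution, reproducing the
knotted class's signature.

## Clustering

The two-step ("biphasic") procedure: greedy sequential preclustering in
the (F_R, F_U) plane (a point joins the nearest precluster centroid
within a threshold of 0.5 × the pooled SD by default), then
centroid-linkage agglomeration of precluster centroids (member-weighted
centroids, lowest-index tie-break) cut at k = 2 by merge order — never
by merge height, since centroid linkage can invert. Points are
preclustered in canonical lexicographic order, making the labels
invariant to input ordering. Isolated extreme points would otherwise
survive the k-cut as single-member "classes", so the cut is deepened
until k substantive clusters (≥5% of points each) exist and smaller
outlier clusters are folded into the nearest class; this mirrors the
noise handling of the commercial two-step implementation. Axes are not
standardized (both are pN); as a consequence the point-level boundary
under-weights the well-separated refolding axis and point accuracy on
the printed mixture parameters is ~85–95%, while the per-molecule
majority vote — the quantity of scientific interest — is ≥97%. A
Gaussian-mixture report is available strictly as a cross-check, never
the primary method. k is fixed at 2; a silhouette report never
auto-selects it.

## Synthetic data

The generator emulates: two-class pulling cycles at 100 nm/s
(trap stiffness 0.1 pN/nm, 1 kHz, 2–30 pN window, Gaussian force noise
0.15 pN — chosen so rips are unambiguous at the experiment's force
scale) with class-specific contour lengths (40.2/36.9 nm) and
transition forces drawn from the printed class distributions
(truncated to the instrument window; rips outside it are never
recorded) or from attached kinetic models via first-passage sampling;
molecules keep one class for all cycles. CFT work pairs are Gaussians
N(ΔG ± W_dis, σ²) with σ² = 2RT·W_dis — the unique symmetric Gaussian
pair satisfying the Crooks identity exactly, so the crossing is ΔG by
construction and recovery is an analytically controlled test. Labeled
force pairs use the printed bimodal fit parameters (refold 4.7 ± 0.5
and 7.3 ± 1.0 pN; unfold 10 ± 3 and 16.5 ± 2.5 pN). Canonical knot
polygons (planar unknot, 60-vertex torus trefoil, 80-vertex
figure-eight) carry their table invariants. All generators are
bit-reproducible given their seed.

What the generator does **not** emulate: instrument drift, bead
rotation, handle-compliance transients, DNA overstretching, missed or
multi-step rips, and any force-dependence of the noise. Passing tests
therefore demonstrate the correctness of the analysis chain on ideal
two-state data, not robustness to every artifact of real traces.

## Numerical conventions

RT = 0.593 kcal/mol at 298.15 K; 1 kcal/mol = 6.948 pN·nm;
1 REU ≈ 0.57 kcal/mol. Wilson intervals at 95%; all fits weighted where
per-point errors exist. Master seeds derive per-component streams
(sub-seeds kept below 2³¹); numba kernels consume one legacy-RNG seed
per batch, so ensembles are reproducible end to end.
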