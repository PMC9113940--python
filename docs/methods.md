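# Methods

This note records the models, conventions and numerical choices behind
`axokit`, and what the synthetic benchmarks do and do not establish.

## Residue-size fingerprints

**Model.** The 20 canonical amino acids are partitioned by apparent
side-chain size into LARGE {W,Y,R,F,H}, MIDDLE {L,Q,N,I,M,K}, SMALL
{P,V,S,T,C,E,D,A} and GLY {G}. A fingerprint is an ordered list of
per-position allowed-class sets read off a density map by a practitioner;
a position may be a single class, a union, or a wildcard (all four classes,
flagged non-confident). The partition is configurable; the default is the
one above.

**Search.** A window of a database sequence mismatches position *i* when its
residue's class is not in the allowed set. The scan reports every window
with at most *m* mismatches, implemented as a vectorised shifted-lookup sum
over an integer-encoded concatenation of the database (sentinel-separated,
windows crossing record boundaries masked out). Non-canonical letters
(X, B, Z, U, \*) always mismatch, including against wildcards: a wildcard
models uncertain *density*, not uncertain *sequence*. Offsets are 0-based,
half-open. Hits sort by (n_mismatches, e_value, seq_id, start), a total
order with no ties across different windows of one ranking level.

**Random-match expectation.** Under a background composition (uniform, or
empirical over canonical residues of the database) the per-position match
probability is the summed frequency of the allowed residues, and the
probability that a window has ≤ m mismatches is a Poisson-binomial tail
computed by an O(k·m) dynamic program. Multiplying by the window count
gives the E-value attached to hits and used to judge a pattern's
specificity. The calibration is verified against simulation (2,000
replicate random databases) in the test suite.

**Iterative policy.** The hit count steers the loop: more than `max_hits`
(default 20) hits → STRICTEN; zero hits → RELAX while budget remains, then
ESCALATE_DB to the next (larger) database; otherwise ACCEPT. Relaxation
first widens non-confident positions to the union with adjacent size
classes (LARGE↔MIDDLE↔SMALL chain, GLY adjacent to SMALL — a misread shifts
apparent size by one step), then raises *m* one unit per remaining budget
step (default budget 2). Strictening a density-derived pattern cannot be
automated (it needs re-reading the map), so the automated loop instead
steps the mismatch tolerance back toward zero — hit sets are nested in
*m*, so this is a filter, not a re-search — and truncates to the top
`max_hits` if the list is still too long at m = 0, recording a note. With
zero hits and nothing left to try the loop terminates and the region is
reported unresolved.

**Cross-verification.** A region *contributes* when its top hit is unique
(no tie at the best (n_mismatches, e_value) level). IDENTIFIED requires all
contributing regions to name the same sequence (a single-region consensus
is flagged as such); disagreement between contributing regions is a
CONFLICT and discards the candidate; no contributing region leaves the
chain UNRESOLVED. Homolog exclusion uses the same class-level scorer:
candidates differing only by within-class substitutions are
indistinguishable by construction, and the tests assert this invariance.

## Filament geometry

**Curve model.** An independent least-squares cubic per axis over t ∈ [0,1],
parameterised by normalized cumulative chord length of the picked points.
No regularisation. The reported `rms_residual` is the per-coordinate RMS,
so isotropic noise of width σ yields a residual ≈ σ. Chord-length and
arc-length parameterisations agree only for near-constant-speed curves;
for the gently curved filaments this targets (curvature radii well above
250 nm over ~100–500 nm spans) the difference is far below the picking
noise, and the exact-recovery and refit-stability tests are run in that
regime.

**Arc length and resampling.** Arc length is adaptive quadrature of |r′(t)|
(absolute tolerance 1e-4 nm); inversion is monotone root bracketing in t
(tolerance 1e-4). Resampling places particles at arc positions 0, s, 2s, …
≤ total length; a spacing longer than the curve yields the single start
particle. Verified spacing error on test curves is below 0.05 nm.

**Euler angles.** Intrinsic ZYZ with R = Rz(psi)·Ry(tilt)·Rz(rot) and
R·ẑ = tangent at rot = 0, i.e. tilt = arccos t_z ∈ [0,180]°,
psi = atan2(t_y, t_x) ∈ (−180,180]° (0 at the poles). A filament tangent
determines only these two; rot is emitted as 0 and flagged undetermined
(STAR output carries a comment). The mapping matches STAR-format angle
tags and is covered by a 1,000-tangent round-trip test.

**Inter-protofilament angles.** The rotation axis point is the algebraic
(Kåsa) least-squares circle centre of the protofilament centres; coplanar
3D input is projected onto its SVD plane first. Angles are the absolute
wrapped differences of consecutive polar angles about that centre — cyclic
for a closed ring (sum 360° by construction), n−1 values for an open
section. Collinear centres are a degenerate-geometry error; a numerically
failed fit falls back to the centroid and flags the section. This
central-angle convention is one defensible reading of "rotation between
adjacent protofilaments" and is labelled as such in outputs.

## C1–C2 relative motion

**Sliding and twist.** Pairing is by repeat index. Sliding is the C2−C1
arc-position difference minus a baseline — FIRST repeat (default; repeats
are mutually aligned but carry no absolute zero), MEDIAN, or NONE. Twist
is the wrapped orientation difference in (−180,180]°.

**Mode detection.** Gaussian KDE with Silverman bandwidth by default (an
absolute kernel σ can be supplied); modes are density maxima with
prominence ≥ 5% of the peak, refined by parabolic interpolation on a
1,024-point grid extended 3 bandwidths beyond the data. A degenerate
all-equal sample reports one mode at that value. Mode locations, pairwise
separations, densities and the bandwidth used are all reported.

**Motor step.** Two heads bound 8 nm apart (the tubulin-dimer spacing) on
one protofilament, tail attached at the head midpoint. One hand-over-hand
step moves the trailing head 16 nm plus-ward — one site past the formerly
leading head — keeps the leading head fixed, toggles the binding-state
label (MTBS-1 ↔ MTBS-2), conserves the 8-nm head spacing, and displaces
the tail by 8 nm. The midpoint tail is the single assumption that links
the 16-nm head step to the 8-nm arm displacement with no free parameter.

**Convex side.** Over a matched span, the filament on the convex (outer)
side of a common bend has the strictly greater arc length; the comparison
uses polyline lengths with a 0.1% relative tolerance below which the case
is UNDETERMINED (straight/parallel). Arc length was chosen over signed
curvature because it needs no plane and is robust for 3D tracks.

## Synthetic data

Each generator is a pure function of its spec, including the seed; a master
seed expands to per-stream child seeds via `SeedSequence([seed, stream_id])`
with fixed stream ids, so adding one generator call never perturbs another.

- **Proteome**: 5,000 sequences by default, shifted-geometric lengths
  (mean 500, min 50), i.i.d. residues from a uniform (default) or supplied
  composition; planted targets are ordinary random member sequences of
  fixed length (400 by default) registered with their identity. This
  emulates database *scale and composition* only — real proteomes have
  repeats, homolog families and biased local composition, so planted
  recovery rates here bound the easy part of the problem, not homolog
  discrimination (which the class-level scorer addresses separately).
- **Fingerprint noise**: per position, wildcard with probability α
  (unreadable density, non-confident), adjacent-class misread with
  probability ε, else the true class. Defaults ε = 0.03, α = 0.05 model an
  experienced reader on a good map; the benchmark identification setting
  (length-20 regions, two regions per chain, m = 2, H = 20) recovers ≥ 90%
  of 45 planted targets with zero false consensus.
- **Filament**: points at nominal spacing along a known cubic plus
  isotropic Gaussian noise — no anisotropic (missing-wedge) error, no
  outlier picks.
- **Lattice**: centres at planted central angles on a circle plus 2D noise.
- **Paired repeats**: C1 at exact 32-nm repeats; C2 offsets CONSTANT,
  LINEAR, or TWO_STATE (a Markov chain over the two binding states whose
  offset difference is one motor-step tail displacement; switch probability
  0.5 by default), plus Gaussian jitter (benchmark 1.5 nm); twists are a
  Gaussian core (σ 0.5°) with an outlier fraction (10% at 8° in the
  benchmark) — a stylised version of the observed "mostly small, rarely
  large" twist behaviour, not a mechanical model of the bridge.

## Problem sizes and determinism

The shipped benchmarks use a 5,000 × ~500-residue proteome with 45 planted
targets for identification, 100 random database/pattern cases for the
search oracle, 2,000 replicates for E-value calibration, and 400–1,000
repeats for the motion statistics — sizes chosen to make binomial error
bars small relative to the tolerances being checked. All stochastic tests
fix seeds; hypothesis-based property tests run derandomised.

## Known limitations

- Fingerprint reading itself (density → classes) is out of scope; the
  package starts from user-supplied class calls.
- The cubic is a global fit: strongly S-shaped tracks are better split at
  inflections before fitting.
- The empirical composition is database-wide; no local or per-sequence
  background model.
- The inter-protofilament angle convention (central angles about a fitted
  circle centre) is one of several possible axis definitions; absolute
  values depend on it, though symmetry deviations largely do not.
- STAR I/O covers the single-block particle loop used here, not the full
  multi-block STAR grammar.
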