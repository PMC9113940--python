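# axokit

Computational companions to a high-resolution structural study of the
axonemal **central apparatus** (CA) — the C1/C2 microtubule pair at the core
of the "9+2" motile cilium. When a cryo-EM density map resolves backbones but
not full side chains, when sub-tomogram workflows need regularly spaced
particles along hand-picked filaments, and when paired C1/C2 repeat tables
must be turned into sliding and twist distributions, the steps in between
are small, specific computations. `axokit` implements them as a tested
library with a thin CLI, plus synthetic-data generators with planted ground
truth so every step can be validated end to end without any microscope data.

## What it computes

**Side-chain-size fingerprint identification.** A confidently traced
backbone region yields, per residue, only the approximate side-chain size.
With the 20 amino acids partitioned into four classes —
LARGE = {W, Y, R, F, H}, MIDDLE = {L, Q, N, I, M, K},
SMALL = {P, V, S, T, C, E, D, A}, GLY = {G} — the observed size sequence is
a degenerate pattern ("fingerprint") searched against a protein database.
For a pattern of allowed sets A₁…A_k and background composition p, a window
matches position i with probability p(Aᵢ) = Σ_{r∈Aᵢ} p(r), and the expected
number of random windows with ≤ m mismatches is

E = Σ_seq max(0, L − k + 1) · P(B ≤ m),  B ~ PoissonBinomial(1 − p(A₁), …, 1 − p(A_k)).

The search runs with a mismatch tolerance, iterates a policy
(stricten / relax / escalate to a larger database), and cross-verifies
multiple regions of the same chain: a protein is identified only when every
contributing region names the same sequence.

**Filament geometry.** Picked 3D coordinates of a filament are fitted by an
independent cubic per axis over the normalized cumulative chord-length
parameter; the curve is resampled at fixed arc spacing (32 nm for the CA
repeat, 8 nm for tubulin dimers), each particle carrying the two Euler
angles a tangent determines (ZYZ convention: tilt = arccos t_z,
psi = atan2(t_y, t_x); rot undetermined). Inter-protofilament angles are the
central angles between adjacent protofilament centres about the
least-squares circle centre of a lattice cross-section.

**C1–C2 relative motion.** Paired 32-nm repeats give per-repeat sliding
s_i = (arc₂,ᵢ − arc₁,ᵢ) − baseline (nm) and twist τ_i = wrap(θ₂,ᵢ − θ₁,ᵢ)
(deg). A Gaussian-KDE mode summary characterises the sliding distribution;
a tail fraction counts twists beyond a threshold; `convex_side` identifies
the outer filament of a bend by arc length. The two-state kinesin (KLP1)
step model makes the lattice arithmetic explicit: with both heads bound
8 nm apart and the tail attached at their midpoint, a hand-over-hand step
of the trailing head by 16 nm displaces the tail by 8 nm — exactly the
separation of the two peaks in the sliding distribution.

## Worked example

```python
import numpy as np
from axokit import (MotorStepModel, motor_step, SyntheticPairSpec,
                    gen_paired_repeats, compute_sliding_twist, detect_modes,
                    derive_seed)

model = MotorStepModel(leading=8.0, trailing=0.0)
stepped, d = motor_step(model)
print(f"tail displacement after one step: {d:.1f} nm "
      f"({model.state} -> {stepped.state})")

spec = SyntheticPairSpec(n_repeats=400, sliding_model="TWO_STATE",
                         switch_prob=0.5, jitter_sigma=1.5,
                         seed=derive_seed(1, 5))
series, truth = gen_paired_repeats(spec)
profile = compute_sliding_twist(series, baseline_mode="NONE")
summary = detect_modes(profile.sliding)
print(f"sliding modes: {np.round(summary.modes, 2)} nm "
      f"(separation {summary.separations[0]:.2f} nm)")
```

prints

```
tail displacement after one step: 8.0 nm (MTBS-1 -> MTBS-2)
sliding modes: [-0.17  8.31] nm (separation 8.48 nm)
```

The first line is the step geometry: the trailing head's 16-nm advance moves
the head midpoint — and with it the tail-attached motor arm — by half that.
The second line recovers the same 8-nm spacing as the distance between the
two modes of a simulated sliding distribution in which 400 repeat pairs
alternate between the two binding states under 1.5-nm measurement jitter.

The same flows are available from the shell:

```
axokit --seed 11 simulate pairs --spec pairs.yaml --out pairs
axokit relmotion --pairs pairs.csv --baseline none --out rm
axokit search --db proteome.fasta --fingerprint region.json --max-mismatch 2 --out hits.tsv
axokit fit-filament --points track.csv --spacing 32 --out resampled.star
```

## Layout

- `src/axokit/fingerprint.py` — classes, fingerprints, window scan, E-values,
  policy iteration, cross-verification
- `src/axokit/geometry.py` — curve fitting, arc-length resampling, Euler
  angles, inter-protofilament angles
- `src/axokit/motion.py` — sliding/twist, KDE modes, motor step, convexity
- `src/axokit/synth.py` — synthetic generators with planted truth
- `src/axokit/io.py` — FASTA, fingerprint JSON, CSV/STAR particle tables,
  YAML config
- `docs/methods.md` — models, conventions, parameter defaults and
  limitations
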