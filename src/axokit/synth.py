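"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to this package come from a cryo-EM/cryo-ET study: protein
databases, density-read fingerprints, hand-picked filament tracks, lattice
cross-sections and paired repeat tables.  The generators here emulate each
of those with planted, machine-readable truth so that recovery can be scored
end to end:

* random proteomes with planted target sequences;
* fingerprints read off a planted target with wildcard (unreadable) and
  adjacent-class misread noise;
* noisy 3D tracks sampled from a known cubic curve;
* protofilament cross-sections with planted inter-protofilament angles;
* paired C1/C2 repeat series whose sliding offsets follow a constant,
  linear, or two-state (kinesin-step) model and whose twists mix a Gaussian
  core with a heavy-tailed outlier component.

Every generator is a pure function of its spec including the seed.  A single
top-level seed expands into per-generator child seeds through fixed stream
ids (`derive_seed`), so adding one generator call never perturbs another's
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .fingerprint import (
    ADJACENT_CLASSES,
    CANONICAL_RESIDUES,
    DEFAULT_SCHEME,
    Fingerprint,
    FingerprintPosition,
    ProteomeDB,
    ResidueClassScheme,
)
from .geometry import (
    FilamentTrack,
    LatticeCrossSection,
    Polynomial3,
    arc_length,
    chord_parameters,
    _invert_arc_length,
)
from .motion import MotorStepModel, PairedRepeatSeries, motor_step

#: Fixed stream ids of the seed-derivation scheme (documented contract:
#: child = SeedSequence([master_seed, stream_id])).
STREAM_PROTEOME = 1
STREAM_FINGERPRINT = 2
STREAM_FILAMENT = 3
STREAM_LATTICE = 4
STREAM_PAIRS = 5


def derive_seed(master_seed: int, stream_id: int) -> int:
    """Deterministic child seed (< 2**31) for one generator stream."""
    ss = np.random.SeedSequence(entropy=[int(master_seed), int(stream_id)])
    return int(ss.generate_state(1)[0] % (2**31))


# --------------------------------------------------------------------------
# Proteomes with planted targets
# --------------------------------------------------------------------------

@dataclass
class PlantedTarget:
    """Registry entry for one planted target sequence."""

    seq_id: str
    sequence: str


@dataclass
class SyntheticProteomeSpec:
    """Random proteome with planted targets.

    Sequence lengths follow a shifted geometric distribution with the given
    mean and minimum (a crude but adequate stand-in for real protein-length
    distributions); residues are i.i.d. from the composition.  Planted
    targets are ordinary random sequences of exactly ``target_length``
    residues whose identity is recorded in the registry.
    """

    n_sequences: int = 5000
    length_mean: float = 500.0
    length_min: int = 50
    composition: str | dict[str, float] = "UNIFORM"
    n_targets: int = 0
    target_length: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < self.n_targets:
            raise ValidationError("n_sequences must be >= n_targets")
        if self.length_mean <= self.length_min:
            raise ValidationError("length_mean must exceed length_min")
        if self.target_length < self.length_min:
            raise ValidationError("target_length must be >= length_min")


def _composition_vector(composition) -> tuple[list[str], np.ndarray]:
    letters = sorted(CANONICAL_RESIDUES)
    if isinstance(composition, str):
        if composition != "UNIFORM":
            raise ValidationError(f"unknown composition {composition!r}")
        probs = np.full(20, 1.0 / 20.0)
    else:
        probs = np.array([composition.get(r, 0.0) for r in letters], dtype=float)
        if probs.sum() <= 0:
            raise ValidationError("composition must have positive mass")
        probs = probs / probs.sum()
    return letters, probs


def gen_proteome(spec: SyntheticProteomeSpec) -> tuple[ProteomeDB, list[PlantedTarget]]:
    """Generate a random proteome and the registry of planted targets."""
    rng = np.random.default_rng(spec.seed)
    letters, probs = _composition_vector(spec.composition)
    letter_arr = np.frombuffer("".join(letters).encode("ascii"), dtype=np.uint8)

    mean_excess = spec.length_mean - spec.length_min
    lengths = spec.length_min + rng.geometric(1.0 / (mean_excess + 1.0), spec.n_sequences) - 1
    target_rows = set(
        rng.choice(spec.n_sequences, size=spec.n_targets, replace=False).tolist()
    )
    lengths = np.where(
        np.isin(np.arange(spec.n_sequences), list(target_rows)), spec.target_length, lengths
    )

    records: dict[str, str] = {}
    registry: list[PlantedTarget] = []
    for i, length in enumerate(lengths):
        draws = rng.choice(20, size=int(length), p=probs)
        seq = letter_arr[draws].tobytes().decode("ascii")
        seq_id = f"syn{i:05d}"
        records[seq_id] = seq
        if i in target_rows:
            registry.append(PlantedTarget(seq_id=seq_id, sequence=seq))
    return ProteomeDB(records=records, name=f"synthetic(seed={spec.seed})"), registry


# --------------------------------------------------------------------------
# Noisy fingerprints
# --------------------------------------------------------------------------

@dataclass
class FingerprintNoiseSpec:
    """Noise model of reading side-chain sizes off density.

    With probability ``alpha`` a position is unreadable (wildcard, flagged
    non-confident); otherwise, with probability ``epsilon`` its class is
    misread as an adjacent size class (density misreads shift the apparent
    size by one step); otherwise the true class is recorded.
    """

    region_length: int = 20
    epsilon: float = 0.03
    alpha: float = 0.05
    confusion_model: str = "ADJACENT_CLASS"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon < 1.0:
            raise ValidationError("epsilon must lie in [0, 1)")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValidationError("alpha must lie in [0, 1]")
        if self.epsilon + self.alpha > 1.0:
            raise ValidationError("epsilon + alpha must be <= 1")
        if self.confusion_model != "ADJACENT_CLASS":
            raise ValidationError(f"unknown confusion model {self.confusion_model!r}")
        if self.region_length < 1:
            raise ValidationError("region_length must be >= 1")


@dataclass
class FingerprintTruth:
    """Where a synthetic fingerprint came from and which positions are wrong."""

    seq_id: str
    start: int
    end: int
    wildcard_positions: list[int] = field(default_factory=list)
    misread_positions: list[int] = field(default_factory=list)


def gen_fingerprint(
    target: PlantedTarget,
    noise: FingerprintNoiseSpec,
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
    start: int | None = None,
    region_id: str = "",
) -> tuple[Fingerprint, FingerprintTruth]:
    """Read a noisy fingerprint off a region of a planted target."""
    rng = np.random.default_rng(noise.seed)
    k = noise.region_length
    max_start = len(target.sequence) - k
    if max_start < 0:
        raise ValidationError(
            f"region length {k} exceeds target length {len(target.sequence)}"
        )
    if start is None:
        start = int(rng.integers(0, max_start + 1))
    elif not 0 <= start <= max_start:
        raise ValidationError(f"region [{start}, {start + k}) out of target bounds")

    positions: list[FingerprintPosition] = []
    truth = FingerprintTruth(seq_id=target.seq_id, start=start, end=start + k)
    for i, residue in enumerate(target.sequence[start : start + k]):
        true_class = scheme.class_of(residue)
        u = rng.random()
        if u < noise.alpha:
            positions.append(FingerprintPosition.wildcard())
            truth.wildcard_positions.append(i)
        elif u < noise.alpha + noise.epsilon:
            neighbours = ADJACENT_CLASSES[true_class]
            wrong = neighbours[int(rng.integers(0, len(neighbours)))]
            positions.append(FingerprintPosition(frozenset([wrong]), confident=True))
            truth.misread_positions.append(i)
        else:
            positions.append(FingerprintPosition(frozenset([true_class]), confident=True))
    fp = Fingerprint(
        positions=tuple(positions),
        region_id=region_id or f"{target.seq_id}:{start}-{start + k}",
        chain_label=target.seq_id,
    )
    return fp, truth


# --------------------------------------------------------------------------
# Filament tracks
# --------------------------------------------------------------------------

@dataclass
class SyntheticFilamentSpec:
    """Noisy picked track along a known cubic curve.

    Points sit at the nominal arc spacing along the truth curve, each
    displaced by isotropic Gaussian noise of width ``noise_sigma`` —
    emulating a hand-picked start-to-end trace.
    """

    curve: Polynomial3
    n_points: int = 100
    spacing: float = 8.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValidationError("need at least 4 points")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")
        if self.spacing <= 0:
            raise ValidationError("spacing must be positive")


def cubic_through_points(points: np.ndarray) -> Polynomial3:
    """Exact cubic through ordered waypoints (least squares if more than 4)."""
    pts = np.asarray(points, dtype=float)
    t = chord_parameters(pts)
    vander = np.vander(t, 4, increasing=True)
    coeffs, *_ = np.linalg.lstsq(vander, pts, rcond=None)
    return Polynomial3(coeffs=coeffs.T)


def circular_arc_curve(radius: float, angle_span: float, n_fit: int = 50) -> Polynomial3:
    """Cubic approximation of a planar circular arc (radius nm, span radians)."""
    if radius <= 0 or angle_span <= 0:
        raise ValidationError("radius and angle_span must be positive")
    theta = np.linspace(0.0, angle_span, n_fit)
    pts = np.column_stack(
        [radius * np.sin(theta), radius * (1.0 - np.cos(theta)), np.zeros_like(theta)]
    )
    return cubic_through_points(pts)


def gen_filament(spec: SyntheticFilamentSpec) -> tuple[FilamentTrack, Polynomial3]:
    """Sample a noisy track from the truth curve; returns (track, truth)."""
    rng = np.random.default_rng(spec.seed)
    total = arc_length(spec.curve, 0.0, 1.0)
    needed = spec.spacing * (spec.n_points - 1)
    if needed > total + 1e-9:
        raise ValidationError(
            f"{spec.n_points} points at {spec.spacing} nm need {needed:.1f} nm "
            f"but the curve is only {total:.1f} nm long"
        )
    ts = [_invert_arc_length(spec.curve, i * spec.spacing, total) for i in range(spec.n_points)]
    clean = spec.curve.point(np.array(ts))
    noisy = clean + rng.normal(0.0, spec.noise_sigma, size=clean.shape)
    return FilamentTrack(points=noisy, label=f"synthetic(seed={spec.seed})"), spec.curve


# --------------------------------------------------------------------------
# Lattice cross-sections
# --------------------------------------------------------------------------

def gen_lattice(
    n_pf: int = 13,
    angles: np.ndarray | None = None,
    radius: float = 11.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    closed: bool = True,
    center: tuple[float, float] = (0.0, 0.0),
) -> tuple[LatticeCrossSection, np.ndarray]:
    """Protofilament centres at planted central angles on a circle.

    ``angles[i]`` is the central angle (deg) from centre *i* to centre
    *i+1*; for a closed ring the list has ``n_pf`` entries summing to 360
    (default: the 13-fold-symmetric 360/13).  Returns the section and the
    planted angle list.
    """
    if n_pf < 3:
        raise ValidationError("need at least 3 protofilaments")
    if angles is None:
        angles = np.full(n_pf if closed else n_pf - 1, 360.0 / n_pf)
    angles = np.asarray(angles, dtype=float)
    expected_len = n_pf if closed else n_pf - 1
    if len(angles) != expected_len:
        raise ValidationError(
            f"expected {expected_len} angles for n_pf={n_pf}, closed={closed}"
        )
    if closed and not np.isclose(angles.sum(), 360.0, atol=1e-6):
        raise ValidationError(f"closed ring angles must sum to 360, got {angles.sum()}")

    rng = np.random.default_rng(seed)
    theta = np.concatenate([[0.0], np.cumsum(np.radians(angles))])[:n_pf]
    centers = np.column_stack(
        [
            center[0] + radius * np.cos(theta),
            center[1] + radius * np.sin(theta),
        ]
    )
    centers = centers + rng.normal(0.0, noise_sigma, size=centers.shape)
    return LatticeCrossSection(pf_centers=centers, closed=closed), angles


# --------------------------------------------------------------------------
# Paired repeat series
# --------------------------------------------------------------------------

@dataclass
class SyntheticPairSpec:
    """Paired C1/C2 repeats with planted sliding and twist structure.

    C1 repeats sit at exact multiples of ``repeat_spacing`` (the 32-nm
    repeating unit).  The C2 offset follows the sliding model: CONSTANT
    (fixed value), LINEAR (value × index, accumulating sliding along a
    bend), or TWO_STATE (offsets alternate between the tail positions of
    the two kinesin binding states, i.e. 0 and one motor-step tail
    displacement, switching state with ``switch_prob`` per repeat).  Twists
    are drawn from a Gaussian core of width ``twist_sigma`` except for an
    ``outlier_fraction`` of repeats displaced to ±``outlier_magnitude``.
    Gaussian jitter of width ``jitter_sigma`` is added to the C2 arc
    positions.
    """

    n_repeats: int = 400
    sliding_model: str = "CONSTANT"  # CONSTANT | LINEAR | TWO_STATE
    sliding_value: float = 0.0  # CONSTANT offset or LINEAR slope (nm)
    switch_prob: float = 0.5  # TWO_STATE only
    motor: MotorStepModel | None = None  # TWO_STATE geometry; default standard
    twist_sigma: float = 0.5
    outlier_fraction: float = 0.0
    outlier_magnitude: float = 8.0
    jitter_sigma: float = 0.0
    repeat_spacing: float = 32.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValidationError("n_repeats must be >= 1")
        if self.sliding_model not in ("CONSTANT", "LINEAR", "TWO_STATE"):
            raise ValidationError(f"unknown sliding model {self.sliding_model!r}")
        for name in ("switch_prob", "outlier_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.twist_sigma < 0 or self.jitter_sigma < 0:
            raise ValidationError("sigmas must be >= 0")


def gen_paired_repeats(
    spec: SyntheticPairSpec,
) -> tuple[PairedRepeatSeries, dict]:
    """Generate a paired repeat series; returns (series, truth).

    Truth records the planted per-repeat offsets, the two-state labels (for
    TWO_STATE), the inter-state tail displacement, and the twist-outlier
    mask — enough to score downstream sliding/twist recovery directly.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_repeats
    idx = np.arange(n)
    arc_c1 = spec.repeat_spacing * idx.astype(float)

    truth: dict = {"sliding_model": spec.sliding_model}
    if spec.sliding_model == "CONSTANT":
        offsets = np.full(n, spec.sliding_value)
    elif spec.sliding_model == "LINEAR":
        offsets = spec.sliding_value * idx.astype(float)
    else:  # TWO_STATE
        motor = spec.motor or MotorStepModel(leading=8.0, trailing=0.0)
        stepped, tail_shift = motor_step(motor)
        states = np.empty(n, dtype=int)
        states[0] = 0
        switches = rng.random(n - 1) < spec.switch_prob
        for i in range(1, n):
            states[i] = states[i - 1] ^ int(switches[i - 1])
        offsets = tail_shift * states
        truth["states"] = states
        truth["tail_shift"] = tail_shift
        truth["state_models"] = (motor, stepped)
    truth["offsets"] = offsets

    jitter = rng.normal(0.0, spec.jitter_sigma, size=n)
    arc_c2 = arc_c1 + offsets + jitter

    twist = rng.normal(0.0, spec.twist_sigma, size=n)
    outliers = rng.random(n) < spec.outlier_fraction
    signs = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    twist = np.where(outliers, signs * spec.outlier_magnitude + twist, twist)
    truth["outlier_mask"] = outliers

    # jitter must not break the strict ordering of arc positions
    if np.any(np.diff(arc_c2) <= 0):
        raise ValidationError(
            "jitter too large for the repeat spacing: C2 positions not increasing"
        )
    series = PairedRepeatSeries(
        index=idx,
        arc_c1=arc_c1,
        angle_c1=np.zeros(n),
        arc_c2=arc_c2,
        angle_c2=twist,
    )
    return series, truth
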