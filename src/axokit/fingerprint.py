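"""Side-chain-size fingerprint search against protein databases.

Proteins traced in a cryo-EM density map expose, residue by residue, only the
approximate *size* of each side chain.  Reading those sizes along a confident
stretch of backbone yields a degenerate sequence pattern — a "fingerprint" —
over four residue-size classes (LARGE, MIDDLE, SMALL, GLY).  Searching that
pattern against a protein database with a small mismatch tolerance, iterating
the search policy (stricten / relax / escalate to a larger database) and
cross-verifying several regions of the same chain against each other
identifies the protein that the density belongs to.

This module implements the fingerprint data model, the mismatch-tolerant
window scan, an analytic expectation for the number of random matches, the
iterative search policy, and the multi-region consensus step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import ValidationError

# --------------------------------------------------------------------------
# Residue classes
# --------------------------------------------------------------------------

#: The 20 canonical one-letter amino-acid codes.
CANONICAL_RESIDUES: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: The four side-chain-size class labels, in decreasing size order
#: (GLY last: no side chain at all).
CLASS_LABELS: tuple[str, ...] = ("LARGE", "MIDDLE", "SMALL", "GLY")

#: Relaxation neighbours: a misread or uncertain side chain is most likely
#: confused with the adjacent size class.  LARGE-MIDDLE-SMALL form a chain;
#: GLY (no side chain) neighbours only SMALL.
ADJACENT_CLASSES: Mapping[str, tuple[str, ...]] = {
    "LARGE": ("MIDDLE",),
    "MIDDLE": ("LARGE", "SMALL"),
    "SMALL": ("MIDDLE", "GLY"),
    "GLY": ("SMALL",),
}


@dataclass(frozen=True)
class ResidueClassScheme:
    """Partition of the 20 canonical residues into side-chain-size classes.

    The four class sets must be pairwise disjoint and cover exactly the
    canonical alphabet.
    """

    classes: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        labels = set(self.classes)
        if labels != set(CLASS_LABELS):
            raise ValidationError(
                f"scheme must define exactly the classes {CLASS_LABELS}, got {sorted(labels)}"
            )
        union: set[str] = set()
        for label, members in self.classes.items():
            if union & members:
                raise ValidationError(f"class {label} overlaps another class")
            union |= members
        if union != CANONICAL_RESIDUES:
            raise ValidationError(
                "classes must partition the 20 canonical residues; "
                f"missing {sorted(CANONICAL_RESIDUES - union)}, "
                f"extra {sorted(union - CANONICAL_RESIDUES)}"
            )
        object.__setattr__(
            self,
            "_class_of",
            {r: label for label, members in self.classes.items() for r in members},
        )

    def class_of(self, residue: str) -> str | None:
        """Class label of a one-letter residue, or None if non-canonical."""
        return self._class_of.get(residue)

    def residues(self, labels: Iterable[str]) -> frozenset[str]:
        """Union of the residue sets of the given class labels."""
        out: set[str] = set()
        for label in labels:
            try:
                out |= self.classes[label]
            except KeyError:
                raise ValidationError(f"unknown residue class label {label!r}") from None
        return frozenset(out)


#: Default scheme: LARGE = aromatic/basic bulky side chains, MIDDLE =
#: medium-size, SMALL = short/compact, GLY = glycine alone.
DEFAULT_SCHEME = ResidueClassScheme(
    classes={
        "LARGE": frozenset("WYRFH"),
        "MIDDLE": frozenset("LQNIMK"),
        "SMALL": frozenset("PVSTCEDA"),
        "GLY": frozenset("G"),
    }
)


# --------------------------------------------------------------------------
# Fingerprints
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FingerprintPosition:
    """One residue position of a fingerprint.

    ``allowed_classes`` is the non-empty set of size classes compatible with
    the observed density; a position allowing all four classes is a wildcard
    (unreadable density).  ``confident`` marks positions whose class call is
    trusted; relaxation widens only the non-confident ones.
    """

    allowed_classes: frozenset[str]
    confident: bool = True

    def __post_init__(self) -> None:
        if not self.allowed_classes:
            raise ValidationError("allowed_classes must be non-empty")
        unknown = set(self.allowed_classes) - set(CLASS_LABELS)
        if unknown:
            raise ValidationError(f"unknown residue class label(s) {sorted(unknown)}")

    @property
    def is_wildcard(self) -> bool:
        return set(self.allowed_classes) == set(CLASS_LABELS)

    @classmethod
    def wildcard(cls) -> "FingerprintPosition":
        return cls(frozenset(CLASS_LABELS), confident=False)


@dataclass(frozen=True)
class Fingerprint:
    """Ordered per-position size-class observations for one backbone region."""

    positions: tuple[FingerprintPosition, ...]
    region_id: str = ""
    chain_label: str = ""

    def __post_init__(self) -> None:
        if len(self.positions) < 1:
            raise ValidationError("fingerprint must have at least one position")
        object.__setattr__(self, "positions", tuple(self.positions))

    def __len__(self) -> int:
        return len(self.positions)


def fingerprint_from_classes(
    labels: Sequence[Iterable[str] | str],
    region_id: str = "",
    chain_label: str = "",
    confident: Sequence[bool] | None = None,
) -> Fingerprint:
    """Build a fingerprint from per-position class labels.

    Each entry is a class label, an iterable of labels (a union), or the
    string ``"WILDCARD"``.
    """
    positions = []
    for i, entry in enumerate(labels):
        conf = True if confident is None else bool(confident[i])
        if isinstance(entry, str):
            entry_set = frozenset(CLASS_LABELS) if entry == "WILDCARD" else frozenset([entry])
        else:
            entry_set = frozenset(entry)
        positions.append(FingerprintPosition(entry_set, confident=conf))
    return Fingerprint(tuple(positions), region_id=region_id, chain_label=chain_label)


# --------------------------------------------------------------------------
# Protein database
# --------------------------------------------------------------------------

_ALPHABET_SIZE = 27  # codes 0..25 for A..Z, 26 = record separator sentinel


@dataclass
class ProteomeDB:
    """Named amino-acid sequences plus background residue composition.

    ``records`` preserves insertion order.  The empirical composition is
    computed lazily over canonical residues only.
    """

    records: dict[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for seq_id, seq in self.records.items():
            if not seq:
                raise ValidationError(f"sequence {seq_id!r} is empty")
            clean[seq_id] = seq.upper()
        self.records = clean
        self._composition: dict[str, float] | None = None
        self._encoded: tuple | None = None

    def __len__(self) -> int:
        return len(self.records)

    @property
    def composition(self) -> dict[str, float]:
        """Empirical per-residue background frequency (canonical letters only)."""
        if self._composition is None:
            counts = {r: 0 for r in sorted(CANONICAL_RESIDUES)}
            for seq in self.records.values():
                for r in seq:
                    if r in counts:
                        counts[r] += 1
            total = sum(counts.values())
            if total == 0:
                raise ValidationError(
                    f"database {self.name!r} contains no canonical residues"
                )
            self._composition = {r: c / total for r, c in counts.items()}
        return self._composition

    def encoded(self) -> tuple[np.ndarray, np.ndarray, list[str], np.ndarray]:
        """Concatenated integer encoding for the vectorised window scan.

        Returns ``(codes, offsets, ids, lengths)`` where ``codes`` holds
        A..Z as 0..25 with a sentinel 26 between records, and record *j*
        occupies ``codes[offsets[j] : offsets[j] + lengths[j]]``.
        """
        if self._encoded is None:
            ids = list(self.records)
            lengths = np.array([len(self.records[i]) for i in ids], dtype=np.int64)
            total = int(lengths.sum()) + len(ids)  # sentinel after each record
            codes = np.full(total, 26, dtype=np.uint8)
            offsets = np.empty(len(ids), dtype=np.int64)
            pos = 0
            for j, seq_id in enumerate(ids):
                seq = self.records[seq_id]
                offsets[j] = pos
                raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
                enc = raw - ord("A")
                enc[(raw < ord("A")) | (raw > ord("Z"))] = 26  # e.g. '*' gaps
                codes[pos : pos + len(seq)] = enc
                pos += len(seq) + 1
            self._encoded = (codes, offsets, ids, lengths)
        return self._encoded


def uniform_composition() -> dict[str, float]:
    """Uniform background: every canonical residue at frequency 1/20."""
    return {r: 1.0 / 20.0 for r in sorted(CANONICAL_RESIDUES)}


# --------------------------------------------------------------------------
# Search policy and hits
# --------------------------------------------------------------------------

@dataclass
class SearchPolicy:
    """Knobs of the iterative fingerprint search.

    ``max_mismatches`` is the class-mismatch tolerance of the window scan;
    ``max_hits`` the hit-count ceiling above which a pattern is judged too
    promiscuous; ``database_chain`` the escalation order of databases
    (smallest, most enriched first); ``relax_budget`` the number of
    relaxation steps allowed before escalating (step 1 widens non-confident
    positions to the union with adjacent size classes, later steps raise the
    mismatch tolerance by one each).
    """

    max_mismatches: int = 0
    max_hits: int = 20
    composition_model: str = "EMPIRICAL"
    database_chain: tuple[str, ...] = ()
    relax_budget: int = 2

    def __post_init__(self) -> None:
        if self.max_mismatches < 0:
            raise ValidationError("max_mismatches must be >= 0")
        if self.max_hits < 1:
            raise ValidationError("max_hits must be >= 1")
        if self.composition_model not in ("UNIFORM", "EMPIRICAL"):
            raise ValidationError(
                f"composition_model must be UNIFORM or EMPIRICAL, got {self.composition_model!r}"
            )
        self.database_chain = tuple(self.database_chain)


@dataclass(frozen=True)
class MatchHit:
    """One window of one database sequence matching the pattern."""

    seq_id: str
    start: int  # 0-based
    end: int  # exclusive
    n_mismatches: int
    e_value: float
    matched_subsequence: str

    def sort_key(self) -> tuple:
        return (self.n_mismatches, self.e_value, self.seq_id, self.start)


# --------------------------------------------------------------------------
# Pattern compilation and window scan
# --------------------------------------------------------------------------

def compile_pattern(
    fp: Fingerprint, scheme: ResidueClassScheme = DEFAULT_SCHEME
) -> list[frozenset[str]]:
    """Expand a fingerprint into per-position allowed-residue sets.

    A wildcard position maps to all 20 canonical residues; non-canonical
    letters in database sequences never match any position.
    """
    return [scheme.residues(pos.allowed_classes) for pos in fp.positions]


def _pattern_allowed_matrix(pattern: Sequence[frozenset[str]]) -> np.ndarray:
    """Boolean (k, 27) table: allowed[i, code] for codes 0..25 = A..Z."""
    k = len(pattern)
    allowed = np.zeros((k, _ALPHABET_SIZE), dtype=bool)
    for i, residues in enumerate(pattern):
        for r in residues:
            allowed[i, ord(r) - ord("A")] = True
    return allowed


def search_pattern(
    pattern: Sequence[frozenset[str]],
    db: ProteomeDB,
    policy: SearchPolicy | None = None,
    *,
    max_mismatches: int | None = None,
) -> list[MatchHit]:
    """Report every database window within the class-mismatch tolerance.

    Each window of each sequence is scored by the number of positions whose
    residue falls outside the allowed set; windows with at most
    ``max_mismatches`` mismatches become hits.  Residues outside the
    canonical 20-letter alphabet (X, B, Z, U, *) count as mismatches even
    against wildcards: a wildcard models uncertain density, not uncertain
    sequence.  Hits are sorted by (n_mismatches, e_value, seq_id, start).
    """
    if len(pattern) < 1:
        raise ValidationError("pattern must have at least one position")
    if max_mismatches is None:
        max_mismatches = policy.max_mismatches if policy is not None else 0
    if max_mismatches > len(pattern):
        raise ValidationError("max_mismatches exceeds pattern length")
    comp_model = policy.composition_model if policy is not None else "UNIFORM"

    codes, offsets, ids, lengths = db.encoded()
    k = len(pattern)
    n_windows = len(codes) - k + 1
    if n_windows <= 0:
        return []

    allowed = _pattern_allowed_matrix(pattern)
    mism = np.zeros(n_windows, dtype=np.int32)
    for i in range(k):
        mism += ~allowed[i][codes[i : i + n_windows]]

    # Windows must lie entirely inside one record (sentinels separate them).
    valid = np.zeros(n_windows, dtype=bool)
    for j in range(len(ids)):
        if lengths[j] >= k:
            valid[offsets[j] : offsets[j] + lengths[j] - k + 1] = True

    hit_idx = np.nonzero(valid & (mism <= max_mismatches))[0]
    if hit_idx.size == 0:
        return []

    # E-value per mismatch level (expected random windows with <= that level).
    e_by_level = {
        level: expected_random_matches(
            pattern, db, composition_model=comp_model, max_mismatches=level
        )
        for level in range(max_mismatches + 1)
    }

    record_of = np.searchsorted(offsets, hit_idx, side="right") - 1
    hits = []
    for w, j in zip(hit_idx.tolist(), record_of.tolist()):
        seq_id = ids[j]
        start = w - int(offsets[j])
        nm = int(mism[w])
        hits.append(
            MatchHit(
                seq_id=seq_id,
                start=start,
                end=start + k,
                n_mismatches=nm,
                e_value=e_by_level[nm],
                matched_subsequence=db.records[seq_id][start : start + k],
            )
        )
    hits.sort(key=MatchHit.sort_key)
    return hits


def expected_random_matches(
    pattern: Sequence[frozenset[str]],
    db: ProteomeDB,
    composition_model: str = "UNIFORM",
    max_mismatches: int = 0,
) -> float:
    """Expected number of random windows matching within the tolerance.

    Under the background composition, position *i* matches with probability
    p_i = sum of the background frequencies of its allowed residues.  The
    probability that a random window has at most ``max_mismatches``
    mismatching positions is a Poisson-binomial tail computed by dynamic
    programming; the expectation multiplies it by the number of windows,
    sum over sequences of max(0, len - k + 1).
    """
    if composition_model == "UNIFORM":
        comp = uniform_composition()
    elif composition_model == "EMPIRICAL":
        comp = db.composition
    else:
        raise ValidationError(f"unknown composition model {composition_model!r}")

    k = len(pattern)
    n_windows = sum(max(0, len(seq) - k + 1) for seq in db.records.values())
    if n_windows == 0:
        return 0.0

    p_match = [sum(comp.get(r, 0.0) for r in residues) for residues in pattern]
    # dist[j] = P(exactly j mismatches among positions so far), truncated at m.
    m = max_mismatches
    dist = np.zeros(m + 1)
    dist[0] = 1.0
    for p in p_match:
        q = 1.0 - p
        new = dist * p
        new[1:] += dist[:-1] * q
        dist = new
    return float(n_windows * dist.sum())


# --------------------------------------------------------------------------
# Iterative policy, relaxation, scoring
# --------------------------------------------------------------------------

def refine_policy(
    n_hits: int,
    policy: SearchPolicy,
    relaxation_left: bool = True,
    database_left: bool = True,
) -> str:
    """Decide the next move of the iterative search from a hit count.

    Returns one of ``STRICTEN`` (too many hits: tighten the pattern or use a
    longer one), ``RELAX`` (no hits, relaxation budget remains),
    ``ESCALATE_DB`` (no hits, relaxation exhausted, a larger database
    remains) or ``ACCEPT``.  With zero hits and nothing left to try the
    search terminates: ``ACCEPT`` is returned and the empty hit list marks
    the region unresolved downstream.
    """
    if n_hits < 0:
        raise ValidationError("n_hits must be >= 0")
    if n_hits > policy.max_hits:
        return "STRICTEN"
    if n_hits == 0:
        if relaxation_left:
            return "RELAX"
        if database_left:
            return "ESCALATE_DB"
    return "ACCEPT"


def relax_fingerprint(
    fp: Fingerprint, scheme: ResidueClassScheme = DEFAULT_SCHEME
) -> Fingerprint:
    """Widen the non-confident positions to include adjacent size classes.

    The confident positions are left untouched; this is the first rung of
    the relaxation ladder (later rungs raise the mismatch tolerance).
    """
    new_positions = []
    for pos in fp.positions:
        if pos.confident:
            new_positions.append(pos)
            continue
        widened = set(pos.allowed_classes)
        for label in pos.allowed_classes:
            widened.update(ADJACENT_CLASSES[label])
        new_positions.append(FingerprintPosition(frozenset(widened), confident=False))
    return replace(fp, positions=tuple(new_positions))


def score_candidate(
    fp: Fingerprint,
    candidate_window: str,
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
) -> tuple[list[bool], int]:
    """Per-position class-mismatch vector for a candidate window.

    Used for homolog exclusion: two candidate sequences that differ only by
    within-class substitutions are indistinguishable at the side-chain-size
    level and score identically.  Returns (mismatch flags, total count).
    """
    window = candidate_window.upper()
    if len(window) != len(fp):
        raise ValidationError(
            f"candidate window length {len(window)} != fingerprint length {len(fp)}"
        )
    mismatches = []
    for pos, residue in zip(fp.positions, window):
        label = scheme.class_of(residue)
        mismatches.append(label is None or label not in pos.allowed_classes)
    return mismatches, sum(mismatches)


# --------------------------------------------------------------------------
# Multi-region identification
# --------------------------------------------------------------------------

@dataclass
class IdentificationReport:
    """Outcome of a multi-region identification run."""

    region_hits: dict[str, list[MatchHit]]
    consensus_candidate: str | None
    status: str  # IDENTIFIED | CONFLICT | UNRESOLVED
    databases_searched: list[str]
    notes: list[str] = field(default_factory=list)


def cross_verify(
    region_hits: Mapping[str, Sequence[MatchHit]],
) -> tuple[str | None, str, str]:
    """Consensus across regions of the same chain.

    A region *contributes* when its top hit is unique (no tie at the best
    (n_mismatches, e_value) level).  The chain is IDENTIFIED when all
    contributing regions name the same sequence; disagreement between two or
    more contributing regions is a CONFLICT and the candidate is discarded;
    no contributing region at all leaves the chain UNRESOLVED.  An
    identification supported by a single region carries a
    ``single-region`` provenance note.
    """
    contributing: dict[str, str] = {}
    ambiguous: list[str] = []
    for region, hits in region_hits.items():
        if not hits:
            continue
        best = hits[0]
        top_ids = {
            h.seq_id
            for h in hits
            if (h.n_mismatches, h.e_value) == (best.n_mismatches, best.e_value)
        }
        if len(top_ids) == 1:
            contributing[region] = best.seq_id
        else:
            ambiguous.append(region)

    if not contributing:
        note = "ambiguous top hits" if ambiguous else ""
        return None, "UNRESOLVED", note
    ids = set(contributing.values())
    if len(ids) > 1:
        return None, "CONFLICT", "top hits disagree across regions"
    consensus = ids.pop()
    note = "single-region" if len(contributing) == 1 else ""
    return consensus, "IDENTIFIED", note


def _relaxation_ladder(
    fp: Fingerprint, policy: SearchPolicy, scheme: ResidueClassScheme
) -> Iterator[tuple[Fingerprint, int, str]]:
    """Yield (fingerprint, tolerance, note) in relaxation order."""
    yield fp, policy.max_mismatches, ""
    if policy.relax_budget >= 1:
        widened = relax_fingerprint(fp, scheme)
        yield widened, policy.max_mismatches, "relaxed classes"
        for extra in range(1, policy.relax_budget):
            yield widened, policy.max_mismatches + extra, f"relaxed m+{extra}"


def _stricten_or_truncate(
    hits: list[MatchHit], policy: SearchPolicy, notes: list[str], region: str
) -> list[MatchHit]:
    """Apply the automated STRICTEN response to an over-long hit list.

    Because hits(m) is nested in hits(m+1), stepping the tolerance down just
    filters the list; if the list is still too long at zero mismatches it is
    truncated to the top max_hits entries (the pattern itself cannot be
    tightened without re-reading the density).
    """
    m = policy.max_mismatches
    while len(hits) > policy.max_hits and m > 0:
        m -= 1
        hits = [h for h in hits if h.n_mismatches <= m]
    if len(hits) > policy.max_hits:
        notes.append(f"{region}: truncated to top {policy.max_hits} hits")
        hits = hits[: policy.max_hits]
    elif m < policy.max_mismatches:
        notes.append(f"{region}: strictened to m={m}")
    return hits


def identify_protein(
    fingerprints: Sequence[Fingerprint],
    policy: SearchPolicy,
    dbs: Mapping[str, ProteomeDB],
    scheme: ResidueClassScheme = DEFAULT_SCHEME,
) -> IdentificationReport:
    """Run the search + refine loop per region and cross-verify the results.

    Every fingerprint (one per confidently traced backbone region of the same
    chain) is searched over the database chain in escalation order; within a
    database the relaxation ladder is walked until hits appear, and hit lists
    above the ceiling are strictened/truncated.  The per-region hit lists are
    then checked against each other for a consensus candidate.
    """
    if not fingerprints:
        raise ValidationError("at least one fingerprint is required")
    chains = {fp.chain_label for fp in fingerprints}
    if len(chains) > 1:
        raise ValidationError(f"fingerprints span multiple chains: {sorted(chains)}")
    chain_labels = list(policy.database_chain) or list(dbs)
    if not chain_labels:
        raise ValidationError("no databases to search")
    for label in chain_labels:
        if label not in dbs:
            raise ValidationError(f"database {label!r} not provided")

    region_hits: dict[str, list[MatchHit]] = {}
    searched: list[str] = []
    notes: list[str] = []
    for idx, fp in enumerate(fingerprints):
        region = fp.region_id or f"region{idx}"
        hits: list[MatchHit] = []
        for db_label in chain_labels:
            db = dbs[db_label]
            if db_label not in searched:
                searched.append(db_label)
            for trial_fp, m, note in _relaxation_ladder(fp, policy, scheme):
                pattern = compile_pattern(trial_fp, scheme)
                hits = search_pattern(pattern, db, policy, max_mismatches=m)
                if hits:
                    if note:
                        notes.append(f"{region}: {note}")
                    break
            if hits:
                hits = _stricten_or_truncate(hits, policy, notes, region)
                break
            notes.append(f"{region}: no hits in {db_label or db.name!r}")
        region_hits[region] = hits

    consensus, status, note = cross_verify(region_hits)
    if note:
        notes.append(note)
    return IdentificationReport(
        region_hits=region_hits,
        consensus_candidate=consensus,
        status=status,
        databases_searched=searched,
        notes=notes,
    )
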