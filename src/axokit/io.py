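"""File formats and run configuration.

Sequence databases are exchanged as FASTA, fingerprints as small JSON files,
particle coordinates as CSV or STAR tables, run configurations as YAML, and
hit lists as TSV.  Coordinates are stored and exchanged in nm throughout —
note that STAR files in other toolchains conventionally carry pixels or
Angstroms; converting to nm is the caller's responsibility.

The STAR dialect is a single data block with a loop of the RELION coordinate
tags (_rlnCoordinateX/Y/Z) and, when orientations are present, the angle
tags (_rlnAngleRot/_rlnAngleTilt/_rlnAnglePsi).  Unknown tags are preserved
on read and re-emitted unchanged.  All writers are deterministic: identical
in-memory objects produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .errors import ConfigError, ParseError, ValidationError
from .fingerprint import (
    CLASS_LABELS,
    Fingerprint,
    FingerprintPosition,
    MatchHit,
    ProteomeDB,
)

logger = logging.getLogger("axokit")


def setup_logging(verbose: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.INFO
    logging.basicConfig(level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s")


# --------------------------------------------------------------------------
# FASTA
# --------------------------------------------------------------------------

def read_fasta(path, name: str | None = None) -> ProteomeDB:
    """Read a FASTA protein database.

    Record ids are truncated at the first whitespace; lowercase is folded to
    uppercase; duplicate ids are an error.  Non-canonical letters (X, B, Z,
    U, *) are retained in the sequences but excluded from the background
    composition.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ParseError(
                    f"{path}:{lineno}: sequence data before the first '>' header"
                )
            break
        else:
            raise ParseError(f"{path}: empty FASTA file")

    records: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in records:
            raise ParseError(f"{path}: duplicate sequence id {record.id!r}")
        records[record.id] = str(record.seq).upper()
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return ProteomeDB(records=records, name=name or path.stem)


def write_fasta(db: ProteomeDB, path, wrap: int = 60) -> None:
    """Write a database as FASTA in insertion order; wrap=0 disables wrapping."""
    path = Path(path)
    with open(path, "w") as fh:
        for seq_id, seq in db.records.items():
            fh.write(f">{seq_id}\n")
            if wrap and wrap > 0:
                for i in range(0, len(seq), wrap):
                    fh.write(seq[i : i + wrap] + "\n")
            else:
                fh.write(seq + "\n")


# --------------------------------------------------------------------------
# Fingerprint JSON
# --------------------------------------------------------------------------

_LETTER_TO_CLASS = {"L": "LARGE", "M": "MIDDLE", "S": "SMALL", "G": "GLY"}
_CLASS_TO_LETTER = {v: k for k, v in _LETTER_TO_CLASS.items()}


def _decode_position(code: str) -> frozenset[str]:
    if code == "X":
        return frozenset(CLASS_LABELS)
    labels = set()
    for ch in code:
        if ch not in _LETTER_TO_CLASS:
            raise ParseError(f"unknown class letter {ch!r} in position code {code!r}")
        labels.add(_LETTER_TO_CLASS[ch])
    if not labels:
        raise ParseError("empty position code")
    return frozenset(labels)


def _encode_position(pos: FingerprintPosition) -> str:
    if pos.is_wildcard:
        return "X"
    return "".join(
        _CLASS_TO_LETTER[label] for label in CLASS_LABELS if label in pos.allowed_classes
    )


def read_fingerprint(path) -> Fingerprint:
    """Read a fingerprint JSON file.

    Schema: ``{"region_id": str, "chain_label": str, "positions": [code...],
    "confident": [bool...]}`` where each code is a string over {L,M,S,G}
    (multi-letter for class unions) or "X" for a wildcard.
    """
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    try:
        codes = data["positions"]
    except KeyError:
        raise ParseError(f"{path}: missing 'positions'") from None
    confident = data.get("confident", [True] * len(codes))
    if len(confident) != len(codes):
        raise ParseError(f"{path}: 'confident' mask length != number of positions")
    positions = tuple(
        FingerprintPosition(_decode_position(code), confident=bool(conf))
        for code, conf in zip(codes, confident)
    )
    return Fingerprint(
        positions=positions,
        region_id=data.get("region_id", path.stem),
        chain_label=data.get("chain_label", ""),
    )


def write_fingerprint(fp: Fingerprint, path) -> None:
    data = {
        "region_id": fp.region_id,
        "chain_label": fp.chain_label,
        "positions": [_encode_position(p) for p in fp.positions],
        "confident": [bool(p.confident) for p in fp.positions],
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


# --------------------------------------------------------------------------
# Hit lists
# --------------------------------------------------------------------------

HIT_COLUMNS = ("seq_id", "start", "end", "n_mismatches", "e_value", "matched_subsequence")


def write_hits(hits: Sequence[MatchHit], path) -> None:
    """Write a hit list as TSV with the documented header."""
    with open(path, "w") as fh:
        fh.write("\t".join(HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.seq_id}\t{h.start}\t{h.end}\t{h.n_mismatches}"
                f"\t{h.e_value:.6g}\t{h.matched_subsequence}\n"
            )


# --------------------------------------------------------------------------
# Particle tables (CSV / STAR)
# --------------------------------------------------------------------------

#: RELION tag <-> canonical column mapping.
_STAR_TAGS = {
    "_rlnCoordinateX": "x",
    "_rlnCoordinateY": "y",
    "_rlnCoordinateZ": "z",
    "_rlnAngleRot": "rot",
    "_rlnAngleTilt": "tilt",
    "_rlnAnglePsi": "psi",
}
_COLUMN_TAGS = {v: k for k, v in _STAR_TAGS.items()}
_COORD_COLUMNS = ("x", "y", "z")
_ANGLE_COLUMNS = ("tilt", "psi", "rot")


@dataclass
class ParticleTable:
    """Particle coordinates (nm) with optional ZYZ Euler angles (deg).

    ``data`` holds columns x, y, z and optionally tilt, psi, rot plus any
    extra columns (e.g. a source label or foreign STAR tags, which survive a
    round trip unchanged).
    """

    data: pd.DataFrame
    dialect: str = "CSV"
    rot_determined: bool = True
    extra_tag_order: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        missing = [c for c in _COORD_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"particle table missing coordinate column(s) {missing}")
        present = [c for c in _ANGLE_COLUMNS if c in self.data.columns]
        if present and len(present) != 3:
            raise ValidationError(
                "angle columns must be all present or all absent, "
                f"found only {present}"
            )

    @property
    def has_angles(self) -> bool:
        return all(c in self.data.columns for c in _ANGLE_COLUMNS)

    def __len__(self) -> int:
        return len(self.data)


def particles_to_table(particles, label: str | None = None) -> ParticleTable:
    """Build a ParticleTable from geometry.ResampledParticle objects."""
    rows = {
        "x": [p.position[0] for p in particles],
        "y": [p.position[1] for p in particles],
        "z": [p.position[2] for p in particles],
        "tilt": [p.tilt for p in particles],
        "psi": [p.psi for p in particles],
        "rot": [p.rot for p in particles],
    }
    df = pd.DataFrame(rows)
    if label is not None:
        df["label"] = label
    rot_det = all(getattr(p, "rot_determined", True) for p in particles)
    return ParticleTable(data=df, rot_determined=rot_det)


def _read_star(path: Path) -> tuple[list[str], pd.DataFrame]:
    """Minimal STAR loop_ reader: first data block, whitespace-split rows."""
    tags: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                if in_loop and rows and not line:
                    break  # blank line ends the loop body
                continue
            if line.startswith("data_"):
                if rows:
                    break  # a second data block ends the first
                continue
            if line == "loop_":
                in_loop = True
                continue
            if line.startswith("_"):
                if not in_loop:
                    continue  # key-value pairs outside loops are ignored
                tags.append(line.split()[0])
                continue
            if in_loop:
                fields = line.split()
                if len(fields) != len(tags):
                    raise ParseError(
                        f"{path}:{lineno}: expected {len(tags)} fields, got {len(fields)}"
                    )
                rows.append(fields)
    if not tags or not rows:
        raise ParseError(f"{path}: no loop_ data found")
    return tags, pd.DataFrame(rows, columns=tags)


def read_particles(path, dialect: str | None = None) -> ParticleTable:
    """Read a particle table from CSV or STAR (inferred from the extension)."""
    path = Path(path)
    if dialect is None:
        dialect = "STAR" if path.suffix.lower() == ".star" else "CSV"

    if dialect == "CSV":
        df = pd.read_csv(path)
        missing = [c for c in _COORD_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"{path}: missing coordinate column(s) {missing}")
        return ParticleTable(data=df, dialect="CSV")

    tags, raw = _read_star(path)
    missing_tags = [t for t in ("_rlnCoordinateX", "_rlnCoordinateY", "_rlnCoordinateZ") if t not in tags]
    if missing_tags:
        raise ParseError(f"{path}: missing coordinate tag(s) {missing_tags}")
    df = pd.DataFrame()
    extras: list[str] = []
    for tag in tags:
        if tag in _STAR_TAGS:
            df[_STAR_TAGS[tag]] = pd.to_numeric(raw[tag])
        else:
            df[tag] = raw[tag]  # foreign tag preserved verbatim
            extras.append(tag)
    return ParticleTable(data=df, dialect="STAR", extra_tag_order=tuple(extras))


def write_particles(table: ParticleTable, path, dialect: str | None = None) -> None:
    """Write a particle table as CSV or STAR."""
    path = Path(path)
    if dialect is None:
        dialect = "STAR" if path.suffix.lower() == ".star" else "CSV"

    if dialect == "CSV":
        table.data.to_csv(path, index=False, float_format="%.9g")
        return

    ordered: list[tuple[str, str]] = []  # (tag, column)
    for col in _COORD_COLUMNS:
        ordered.append((_COLUMN_TAGS[col], col))
    if table.has_angles:
        for col in ("rot", "tilt", "psi"):
            ordered.append((_COLUMN_TAGS[col], col))
    for col in table.data.columns:
        if col in _COORD_COLUMNS or col in _ANGLE_COLUMNS:
            continue
        tag = col if col.startswith("_") else f"_axokit{col.capitalize()}"
        ordered.append((tag, col))

    with open(path, "w") as fh:
        fh.write("# written by axokit; coordinates in nm\n")
        if table.has_angles and not table.rot_determined:
            fh.write("# _rlnAngleRot is undetermined from the filament tangent; stored as 0\n")
        fh.write("\ndata_particles\n\nloop_\n")
        for i, (tag, _) in enumerate(ordered, start=1):
            fh.write(f"{tag} #{i}\n")
        for _, row in table.data.iterrows():
            fields = []
            for _, col in ordered:
                value = row[col]
                if isinstance(value, (int, float, np.integer, np.floating)):
                    fields.append(f"{value:.9g}")
                else:
                    fields.append(str(value))
            fh.write(" ".join(fields) + "\n")


def read_track_csv(path) -> np.ndarray:
    """Read x,y,z coordinates (nm) from a CSV track file."""
    df = pd.read_csv(path)
    missing = [c for c in _COORD_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing coordinate column(s) {missing}")
    return df[list(_COORD_COLUMNS)].to_numpy(dtype=float)


# --------------------------------------------------------------------------
# Paired-repeat tables and profiles
# --------------------------------------------------------------------------

PAIR_COLUMNS = ("index", "arc_c1", "angle_c1", "arc_c2", "angle_c2")


def read_pairs_csv(path):
    """Read a paired-repeat CSV into a PairedRepeatSeries."""
    from .motion import PairedRepeatSeries

    df = pd.read_csv(path)
    missing = [c for c in PAIR_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    return PairedRepeatSeries(
        index=df["index"].to_numpy(),
        arc_c1=df["arc_c1"].to_numpy(float),
        angle_c1=df["angle_c1"].to_numpy(float),
        arc_c2=df["arc_c2"].to_numpy(float),
        angle_c2=df["angle_c2"].to_numpy(float),
    )


def write_pairs_csv(series, path) -> None:
    df = pd.DataFrame(
        {
            "index": series.index,
            "arc_c1": series.arc_c1,
            "angle_c1": series.angle_c1,
            "arc_c2": series.arc_c2,
            "angle_c2": series.angle_c2,
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")


def write_profile_tsv(profile, path) -> None:
    """Write a sliding/twist profile as TSV."""
    with open(path, "w") as fh:
        fh.write("pair_index\tsliding_nm\ttwist_deg\n")
        for i, (s, t) in enumerate(zip(profile.sliding, profile.twist)):
            fh.write(f"{i}\t{s:.9g}\t{t:.9g}\n")


def write_mode_summary(summary, path) -> None:
    """Write a ModeSummary as JSON."""
    data = {
        "modes": [float(m) for m in summary.modes],
        "separations": [float(s) for s in summary.separations],
        "bandwidth": float(summary.bandwidth),
        "tail_fraction": None if summary.tail_fraction is None else float(summary.tail_fraction),
        "tail_threshold": None if summary.tail_threshold is None else float(summary.tail_threshold),
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


# --------------------------------------------------------------------------
# Run configuration
# --------------------------------------------------------------------------

_CONFIG_SCHEMA = {
    "databases": None,  # required: list of {label, path}
    "fingerprints": None,  # required: list of fingerprint JSON paths
    "policy": {
        "max_mismatches": 0,
        "max_hits": 20,
        "composition_model": "EMPIRICAL",
        "database_chain": None,  # default: database order as listed
        "relax_budget": 2,
    },
    "seed": 0,
}


def load_config(path) -> dict:
    """Load and validate a YAML identification-run configuration.

    Unknown keys are rejected (naming the offending key) and defaults are
    filled in for everything optional.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: configuration must be a mapping")

    unknown = set(raw) - set(_CONFIG_SCHEMA)
    if unknown:
        raise ConfigError(f"{path}: unknown configuration key {sorted(unknown)[0]!r}")

    for required in ("databases", "fingerprints"):
        if required not in raw or not raw[required]:
            raise ConfigError(f"{path}: missing required key {required!r}")

    databases = []
    for entry in raw["databases"]:
        if not isinstance(entry, dict) or "path" not in entry:
            raise ConfigError(f"{path}: each database entry needs a 'path'")
        bad = set(entry) - {"label", "path"}
        if bad:
            raise ConfigError(f"{path}: unknown database key {sorted(bad)[0]!r}")
        databases.append(
            {"label": entry.get("label", Path(entry["path"]).stem), "path": entry["path"]}
        )

    policy_raw = raw.get("policy", {}) or {}
    schema_policy = _CONFIG_SCHEMA["policy"]
    unknown = set(policy_raw) - set(schema_policy)
    if unknown:
        raise ConfigError(f"{path}: unknown policy key {sorted(unknown)[0]!r}")
    policy = {k: policy_raw.get(k, v) for k, v in schema_policy.items()}
    if policy["database_chain"] is None:
        policy["database_chain"] = [d["label"] for d in databases]

    config = {
        "databases": databases,
        "fingerprints": list(raw["fingerprints"]),
        "policy": policy,
        "seed": int(raw.get("seed", 0)),
    }
    logger.info(
        "config loaded: hash=%s seed=%d",
        config_hash(config),
        config["seed"],
    )
    return config


def config_hash(config: dict) -> str:
    """Short deterministic hash of a resolved configuration."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]
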