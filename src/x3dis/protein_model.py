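"""Domain types and I/O for proteins, annotation tracks and disorder labels.

A protein is modelled as its primary sequence plus up to four per-residue
annotation tracks:

``aa``
    the amino-acid identity itself, one-hot over the 20 standard letters;
``pssm``
    a position-specific scoring matrix from an iterative profile search,
    stored raw as integer log-odds and scaled to (0, 1) for featurization;
``ss3``
    predicted 3-state secondary structure (helix H, strand E, coil C);
``sa``
    predicted 2-state solvent accessibility (buried B vs. exposed E at a
    25% exposure cut).

Disorder labels are per-residue ``O``/``D`` strings.  When derived from
crystallographic missing-residue masks, only maximal missing runs of length
at least four become disordered regions; shorter gaps stay ordered.

Residue positions are 1-based in all I/O and reports, 0-based internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PSSM_ALPHABET = AA_ALPHABET + "-"  # 20 amino acids + gap
SS3_ALPHABET = "HEC"
SA_ALPHABET = "BE"  # buried, exposed

TRACK_ALPHABETS = {
    "aa": AA_ALPHABET,
    "pssm": PSSM_ALPHABET,
    "ss3": SS3_ALPHABET,
    "sa": SA_ALPHABET,
}

#: Minimum length of a missing-residue run that qualifies as disordered
#: ("longer than three residues").
MIN_DISORDER_RUN = 4

DATASET_SCHEMA_VERSION = 1


class ProteinModelError(ValueError):
    """Raised on malformed sequences, tracks or files."""


@dataclass(frozen=True)
class AnnotationTrack:
    """A per-residue probability table p(i, l) over a fixed label set.

    Categorical tracks (aa, ss3, sa) are one-hot: each row has exactly one
    1.  The pssm track holds scaled log-odds in [0, 1] with no row-sum
    constraint.  Label order is fixed by the canonical alphabets above;
    feature layouts and argmax tie-breaks depend on it.
    """

    name: str
    probs: np.ndarray  # shape (n, |labels|)

    def __post_init__(self) -> None:
        if self.name not in TRACK_ALPHABETS:
            raise ProteinModelError(f"unknown track name {self.name!r}")
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.ndim != 2 or probs.shape[1] != len(self.labels):
            raise ProteinModelError(
                f"track {self.name!r}: expected shape (n, {len(self.labels)}), "
                f"got {probs.shape}"
            )
        if not np.isfinite(probs).all():
            raise ProteinModelError(f"track {self.name!r}: non-finite values")
        if probs.min() < 0.0 or probs.max() > 1.0:
            raise ProteinModelError(f"track {self.name!r}: values outside [0, 1]")

    @property
    def labels(self) -> str:
        return TRACK_ALPHABETS[self.name]

    @property
    def n(self) -> int:
        return self.probs.shape[0]

    def argmax_labels(self) -> np.ndarray:
        """Per-residue label index with the highest probability.

        Ties break toward the earliest label in canonical order (np.argmax
        returns the first maximum).
        """
        return np.argmax(self.probs, axis=1)


@dataclass(frozen=True)
class DisorderLabels:
    """Per-residue O/D labels; D positions tile into maximal runs >= 4."""

    labels: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - {"O", "D"}
        if bad:
            raise ProteinModelError(f"disorder labels contain {sorted(bad)}")
        for start, end in self.regions:
            if end - start + 1 < MIN_DISORDER_RUN:
                raise ProteinModelError(
                    f"disordered region [{start}, {end}] shorter than "
                    f"{MIN_DISORDER_RUN} residues"
                )

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def regions(self) -> list[tuple[int, int]]:
        """Maximal D-runs as 1-based inclusive (start, end) intervals."""
        out: list[tuple[int, int]] = []
        start = None
        for i, c in enumerate(self.labels):
            if c == "D" and start is None:
                start = i
            elif c == "O" and start is not None:
                out.append((start + 1, i))
                start = None
        if start is not None:
            out.append((start + 1, len(self.labels)))
        return out

    def as_mask(self) -> np.ndarray:
        return np.frombuffer(self.labels.encode(), dtype="S1") == b"D"


def one_hot_track(name: str, letters: str) -> AnnotationTrack:
    """One-hot encode a label string into an AnnotationTrack.

    For the aa track the letter 'X' (unknown residue) yields an all-zero
    row, exempted from the one-hot invariant.
    """
    alphabet = TRACK_ALPHABETS[name]
    probs = np.zeros((len(letters), len(alphabet)))
    for i, c in enumerate(letters):
        if name == "aa" and c == "X":
            continue
        j = alphabet.find(c)
        if j < 0:
            raise ProteinModelError(
                f"illegal character {c!r} for track {name!r} at position {i + 1}"
            )
        probs[i, j] = 1.0
    return AnnotationTrack(name, probs)


@dataclass
class ProteinRecord:
    """One protein: id, sequence, annotation tracks, optional disorder labels."""

    id: str
    sequence: str
    tracks: dict[str, AnnotationTrack] = field(default_factory=dict)
    disorder: DisorderLabels | None = None
    pssm_raw: np.ndarray | None = None  # (n, 20) integer log-odds, pre-scaling

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ProteinModelError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - set(AA_ALPHABET + "X")
        if bad:
            pos = min(i for i, c in enumerate(self.sequence) if c in bad)
            raise ProteinModelError(
                f"protein {self.id!r}: illegal sequence character "
                f"{self.sequence[pos]!r} at position {pos + 1}"
            )
        if "aa" not in self.tracks:
            self.tracks["aa"] = one_hot_track("aa", self.sequence)
        for name, track in self.tracks.items():
            if track.n != self.n:
                raise ProteinModelError(
                    f"protein {self.id!r}: track {name!r} has {track.n} rows, "
                    f"expected {self.n}"
                )
        if self.disorder is not None and self.disorder.n != self.n:
            raise ProteinModelError(
                f"protein {self.id!r}: disorder labels length {self.disorder.n} "
                f"!= {self.n}"
            )
        if self.pssm_raw is not None:
            self.pssm_raw = np.asarray(self.pssm_raw)
            if self.pssm_raw.shape != (self.n, 20):
                raise ProteinModelError(
                    f"protein {self.id!r}: raw pssm shape {self.pssm_raw.shape} "
                    f"!= ({self.n}, 20)"
                )

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def has_unknown_residues(self) -> bool:
        return "X" in self.sequence

    def attach_pssm(self, raw: np.ndarray) -> None:
        """Attach a raw integer PSSM; the scaled track is derived from it."""
        raw = np.asarray(raw)
        if raw.shape != (self.n, 20):
            raise ProteinModelError(
                f"protein {self.id!r}: pssm has {raw.shape[0]} rows, expected {self.n}"
            )
        self.pssm_raw = raw
        self.tracks["pssm"] = scale_pssm(raw)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords.

    The record id is the first whitespace-delimited header token; sequences
    are upper-cased and the aa one-hot track is attached automatically.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if entry.id in seen:
            raise ProteinModelError(f"duplicate FASTA id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(id=entry.id, sequence=str(entry.seq).upper()))
    if not records:
        raise ProteinModelError(f"no FASTA records in {path}")
    return records


def read_pssm_ascii(
    path: str | Path, n: int | None = None, sequence: str | None = None
) -> np.ndarray:
    """Parse a PSI-BLAST ASCII profile into an (n, 20) integer log-odds table.

    Rows are lines starting with a position index and a residue letter
    followed by at least 20 integer columns; only the first 20 (the log-odds
    block) are kept.  When `n` or `sequence` is given, row count and residue
    letters are cross-checked.
    """
    rows: list[list[int]] = []
    letters: list[str] = []
    expected_pos = 1
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        parts = line.split()
        if len(parts) < 22 or not parts[0].isdigit():
            continue  # header / footer lines
        if int(parts[0]) != expected_pos:
            raise ProteinModelError(
                f"{path}:{lineno}: position {parts[0]} out of order "
                f"(expected {expected_pos})"
            )
        try:
            values = [int(v) for v in parts[2:22]]
        except ValueError as exc:
            raise ProteinModelError(f"{path}:{lineno}: unparseable row") from exc
        rows.append(values)
        letters.append(parts[1])
        expected_pos += 1
    if not rows:
        raise ProteinModelError(f"{path}: no profile rows found")
    if n is not None and len(rows) != n:
        raise ProteinModelError(f"{path}: {len(rows)} profile rows, expected {n}")
    if sequence is not None:
        for i, (c, s) in enumerate(zip(letters, sequence)):
            if c != s and s != "X":
                raise ProteinModelError(
                    f"{path}: residue letter {c!r} at position {i + 1} does not "
                    f"match sequence letter {s!r}"
                )
    return np.array(rows, dtype=int)


def scale_pssm(raw: np.ndarray, squash=None) -> AnnotationTrack:
    """Scale raw integer log-odds to (0, 1) and append the gap column.

    The default squashing function is the logistic 1/(1+e^-x), the canonical
    [0, 1] mapping for raw profile log-odds; an alternative callable may be
    supplied.  The 21st (gap) column is constant 0 so it never wins argmax.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.isfinite(raw).all():
        raise ProteinModelError("raw pssm contains non-finite values")
    if squash is None:
        scaled = 1.0 / (1.0 + np.exp(-raw))
    else:
        scaled = np.asarray(squash(raw), dtype=float)
    probs = np.hstack([scaled, np.zeros((raw.shape[0], 1))])
    return AnnotationTrack("pssm", probs)


_SA_DIALECTS = {
    "BE": str.maketrans("BE", "BE"),
    "be": str.maketrans("be", "BE"),
    "-+": str.maketrans("-+", "BE"),
}


def parse_label_string(
    s: str, name: str, sa_dialect: str = "BE"
) -> AnnotationTrack | DisorderLabels:
    """Parse a per-residue label string into a one-hot track or disorder labels.

    `name` is one of ss3, sa, disorder.  Solvent-accessibility strings may
    use the 'BE', 'be' or '-+' dialect (buried first); the canonical
    internal alphabet is B/E.
    """
    if name == "disorder":
        return DisorderLabels(s)
    if name == "sa":
        if sa_dialect not in _SA_DIALECTS:
            raise ProteinModelError(f"unknown sa dialect {sa_dialect!r}")
        s = s.translate(_SA_DIALECTS[sa_dialect])
    if name not in ("ss3", "sa"):
        raise ProteinModelError(f"cannot parse label string for track {name!r}")
    return one_hot_track(name, s)


def label_disorder_from_missing(mask: Sequence[bool] | np.ndarray) -> DisorderLabels:
    """Derive O/D labels from a missing-coordinates mask.

    Maximal runs of missing residues longer than three (length >= 4) are
    labelled D; all other residues, including shorter missing runs, are O.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = np.full(mask.shape, "O", dtype="U1")
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= MIN_DISORDER_RUN:
                labels[i:j] = "D"
            i = j
        else:
            i += 1
    return DisorderLabels("".join(labels))


def _categorical_string(track: AnnotationTrack) -> str:
    idx = track.argmax_labels()
    return "".join(track.labels[j] for j in idx)


def write_dataset(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records as JSON-lines, one self-describing protein per line."""
    with open(path, "w") as fh:
        for rec in records:
            obj = {
                "schema_version": DATASET_SCHEMA_VERSION,
                "id": rec.id,
                "sequence": rec.sequence,
                "pssm_raw": rec.pssm_raw.tolist() if rec.pssm_raw is not None else None,
                "pssm_scaled": rec.pssm_raw is not None,
                "ss3": _categorical_string(rec.tracks["ss3"]) if "ss3" in rec.tracks else None,
                "sa": _categorical_string(rec.tracks["sa"]) if "sa" in rec.tracks else None,
                "disorder": rec.disorder.labels if rec.disorder is not None else None,
            }
            fh.write(json.dumps(obj) + "\n")


def read_dataset(path: str | Path) -> list[ProteinRecord]:
    """Read a JSON-lines dataset written by :func:`write_dataset`."""
    records: list[ProteinRecord] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
        except json.JSONDecodeError as exc:
            raise ProteinModelError(f"{path}:{lineno}: truncated or invalid line") from exc
        version = obj.get("schema_version")
        if version != DATASET_SCHEMA_VERSION:
            raise ProteinModelError(
                f"{path}:{lineno}: schema version {version} not supported "
                f"(expected {DATASET_SCHEMA_VERSION})"
            )
        rec = ProteinRecord(id=obj["id"], sequence=obj["sequence"])
        if obj.get("pssm_raw") is not None:
            rec.attach_pssm(np.array(obj["pssm_raw"], dtype=int))
        if obj.get("ss3") is not None:
            rec.tracks["ss3"] = one_hot_track("ss3", obj["ss3"])
        if obj.get("sa") is not None:
            rec.tracks["sa"] = one_hot_track("sa", obj["sa"])
        if obj.get("disorder") is not None:
            rec.disorder = DisorderLabels(obj["disorder"])
        # re-validate lengths now that all tracks are attached
        rec.__post_init__()
        records.append(rec)
    return records
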