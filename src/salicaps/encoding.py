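"""Sequence and profile encoding.

Proteins enter the network as fixed-size ``max_len x 20`` real matrices.  Two
encodings are supported: a one-hot encoding of the raw sequence, and a
normalized position-specific scoring matrix (PSSM) produced by an iterative
profile search (PSI-BLAST family of tools).  Raw PSSM scores are mapped into
(0, 1) with an elementwise logistic transform; the exact normalization used by
profile-generation pipelines is tool-specific, so the transform is pluggable.

Sequences longer than ``max_len`` are truncated by keeping the first
``max_len/2`` and last ``max_len/2`` residues, preserving the N- and
C-terminal regions that carry sorting signals; shorter sequences are
zero-padded at the end.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from Bio import SeqIO

#: Canonical amino-acid column order (the BLAST PSSM dialect).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class FastaError(ValueError):
    """Raised for malformed or empty FASTA input."""


class PssmError(ValueError):
    """Raised for malformed PSSM files or sequence/profile mismatches."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence.

    The sequence is stored upper-cased; letters outside the 20-residue
    alphabet (B, J, O, U, X, Z, ...) are kept and treated as unknowns by the
    one-hot encoder.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.id}: sequence must be nonempty")
        object.__setattr__(self, "sequence", self.sequence.upper())

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProfileMatrix:
    """An L x 20 profile with entries in [0, 1].

    ``source`` records whether the rows came from a normalized PSSM or from
    one-hot encoding.  Columns follow :data:`AMINO_ACIDS`.
    """

    values: np.ndarray
    source: str = "pssm"
    column_order: str = field(default=AMINO_ACIDS)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 2 or values.shape[1] != 20:
            raise ValueError(f"profile must be L x 20, got {values.shape}")
        if not np.all(np.isfinite(values)):
            raise ValueError("profile contains non-finite entries")
        if values.min() < 0.0 or values.max() > 1.0:
            raise ValueError("profile entries must lie in [0, 1]")
        if self.source not in ("pssm", "one_hot"):
            raise ValueError(f"unknown profile source {self.source!r}")
        if self.source == "one_hot":
            sums = values.sum(axis=1)
            if not np.all(np.isclose(sums, 0.0) | np.isclose(sums, 1.0)):
                raise ValueError("one-hot rows must sum to 0 or 1")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EncodedInput:
    """A fixed-size network input produced by :func:`pad_or_truncate`."""

    values: np.ndarray
    true_length: int
    truncated: bool

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    Record ids are the header tokens up to the first whitespace; sequences are
    upper-cased.  Duplicate ids and empty files are rejected.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        first = handle.read(1)
        if first == "":
            raise FastaError(f"{path}: empty FASTA file")
        if first != ">":
            raise FastaError(f"{path}: line 1: expected '>' header")
        handle.seek(0)
        for entry in SeqIO.parse(handle, "fasta"):
            if entry.id in seen:
                raise FastaError(f"{path}: duplicate record id {entry.id!r}")
            seen.add(entry.id)
            seq = str(entry.seq)
            if not seq:
                raise FastaError(f"{path}: record {entry.id!r} has an empty sequence")
            records.append(ProteinRecord(id=entry.id, sequence=seq))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def parse_pssm(
    path: str | Path, sequence: str | None = None
) -> np.ndarray:
    """Parse the first 20-column score block of a BLAST ASCII PSSM.

    Returns the raw (unnormalized) L x 20 score matrix with columns reordered
    to :data:`AMINO_ACIDS` if the file lists them in a different order.  When
    ``sequence`` is given, the row count must match its length.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    header_idx = None
    file_alphabet: list[str] = []
    for i, line in enumerate(lines):
        tokens = line.split()
        if len(tokens) >= 20 and all(
            len(t) == 1 and t in AMINO_ACIDS for t in tokens[:20]
        ):
            header_idx = i
            file_alphabet = tokens[:20]
            break
    if header_idx is None:
        raise PssmError(f"{path}: no 20-letter amino-acid column header found")
    if len(set(file_alphabet)) != 20:
        raise PssmError(f"{path}: column header repeats amino-acid letters")

    row_re = re.compile(r"^\s*(\d+)\s+([A-Za-z*])\s+(.*)$")
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            if rows:
                break  # end of the first block
            continue
        m = row_re.match(line)
        if m is None:
            if rows:
                break  # trailing statistics section
            raise PssmError(f"{path}: line {lineno}: unparseable PSSM row")
        fields = m.group(3).split()
        if len(fields) < 20:
            raise PssmError(
                f"{path}: line {lineno}: expected 20 score columns, "
                f"found {len(fields)}"
            )
        try:
            rows.append([float(v) for v in fields[:20]])
        except ValueError as exc:
            raise PssmError(f"{path}: line {lineno}: non-numeric score") from exc

    if not rows:
        raise PssmError(f"{path}: no score rows found")
    raw = np.asarray(rows, dtype=np.float64)

    # reorder the file's columns to the canonical alphabet
    order = [file_alphabet.index(aa) for aa in AMINO_ACIDS]
    raw = raw[:, order]

    if sequence is not None and raw.shape[0] != len(sequence):
        raise PssmError(
            f"{path}: {raw.shape[0]} PSSM rows but sequence has "
            f"{len(sequence)} residues"
        )
    return raw


def logistic(x: np.ndarray) -> np.ndarray:
    """Elementwise logistic 1/(1+exp(-x)); numerically safe for large |x|."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def normalize_profile(
    raw: np.ndarray,
    transform: Callable[[np.ndarray], np.ndarray] = logistic,
) -> ProfileMatrix:
    """Map raw PSSM scores into [0, 1] with an elementwise transform.

    The default logistic transform is monotone and bounded in (0, 1), so score
    order within each column is preserved.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw profile contains non-finite entries")
    return ProfileMatrix(values=transform(raw), source="pssm")


def one_hot(record: ProteinRecord) -> ProfileMatrix:
    """One-hot encode a sequence; unknown residues become all-zero rows."""
    values = np.zeros((len(record), 20), dtype=np.float64)
    for i, aa in enumerate(record.sequence):
        j = _AA_INDEX.get(aa)
        if j is not None:
            values[i, j] = 1.0
    return ProfileMatrix(values=values, source="one_hot")


def pad_or_truncate(profile: ProfileMatrix, max_len: int = 1000) -> EncodedInput:
    """Fit a profile to exactly ``max_len`` rows.

    Shorter profiles keep all rows and are zero-padded at the end.  Longer
    profiles keep the first ``max_len/2`` and last ``max_len/2`` rows so that
    N- and C-terminal sorting signals survive truncation.
    """
    if max_len < 2 or max_len % 2 != 0:
        raise ValueError("max_len must be even and >= 2")
    values = profile.values
    length = values.shape[0]
    if length > max_len:
        half = max_len // 2
        out = np.concatenate([values[:half], values[-half:]], axis=0)
        return EncodedInput(values=out, true_length=max_len, truncated=True)
    out = np.zeros((max_len, 20), dtype=np.float64)
    out[:length] = values
    return EncodedInput(values=out, true_length=length, truncated=False)


def encode_records(
    records: Sequence[ProteinRecord],
    profiles: dict[str, ProfileMatrix] | None = None,
    max_len: int = 1000,
) -> np.ndarray:
    """Stack encoded inputs for many records into an (N, max_len, 20) array.

    Records with an entry in ``profiles`` use it; the rest fall back to
    one-hot encoding.
    """
    encoded = []
    for rec in records:
        prof = profiles.get(rec.id) if profiles else None
        if prof is None:
            prof = one_hot(rec)
        encoded.append(pad_or_truncate(prof, max_len=max_len).values)
    return np.stack(encoded, axis=0)


def save_encoded(path: str | Path, ids: Sequence[str], values: np.ndarray) -> None:
    """Persist encoded tensors keyed by protein id (NumPy .npz container)."""
    np.savez_compressed(path, ids=np.asarray(list(ids)), values=values)


def load_encoded(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Load a container written by :func:`save_encoded`."""
    with np.load(path, allow_pickle=False) as data:
        return [str(x) for x in data["ids"]], data["values"]
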