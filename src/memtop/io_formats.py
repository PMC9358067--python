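"""On-disk formats and core domain types.

Sequences come in as FASTA, per-residue feature matrices live in an HDF5
container keyed by protein id (one float32 dataset per protein), and topology
annotations/predictions use a FASTA-like 3-line block format::

    >P12345
    MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ
    SSSSSSSSSSSSSSSSSSSSSoooooooooooo

Label alphabet: ``B``/``b`` transmembrane beta strand (in->out / out->in),
``H``/``h`` transmembrane helix, ``S`` signal peptide, ``i``/``o``
non-membrane inside/outside.  Intervals are 0-based half-open internally;
any human-readable table uses 1-based inclusive coordinates.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
from Bio import SeqIO

#: fixed class order used by every score/probability matrix in the package
CLASS_ORDER = ("B", "H", "S", "i", "o")
CLASS_INDEX = {c: k for k, c in enumerate(CLASS_ORDER)}

LABEL_ALPHABET = frozenset("BbHhSio")
_TM_CHARS = frozenset("BbHh")
_CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: ambiguous / rare residue codes collapsed to X (features exist for any token)
_AA_REMAP = {"U": "X", "B": "X", "Z": "X", "O": "X"}

MIN_SEGMENT_LEN = 5


class LabelGrammarWarning(UserWarning):
    """Annotation violates a soft topology-grammar rule (logged, not fatal)."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with a unique accession."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Segment:
    """A membrane-crossing or signal-peptide segment, 0-based half-open.

    ``direction`` is ``"in_out"`` / ``"out_in"`` for TM segments and ``None``
    for signal peptides.
    """

    kind: str  # "TMB" | "TMH" | "SP"
    start: int
    end: int
    direction: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("TMB", "TMH", "SP"):
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.kind == "SP" and self.direction is not None:
            raise ValueError("signal peptides carry no direction")
        if self.kind != "SP" and self.direction not in ("in_out", "out_in"):
            raise ValueError(f"TM segment needs a direction, got {self.direction!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class LabelSequence:
    """A validated per-residue topology string over {B,b,H,h,S,i,o}."""

    labels: str
    warnings: tuple[str, ...] = field(default=(), compare=False)

    def __len__(self) -> int:
        return len(self.labels)

    def __str__(self) -> str:
        return self.labels


def _runs(s: str) -> list[tuple[str, int, int]]:
    """Maximal runs of identical characters as (char, start, end)."""
    out: list[tuple[str, int, int]] = []
    start = 0
    for k in range(1, len(s) + 1):
        if k == len(s) or s[k] != s[start]:
            out.append((s[start], start, k))
            start = k
    return out


def parse_labels(s: str, *, name: str = "") -> LabelSequence:
    """Validate a topology string and collect soft-grammar warnings.

    Hard errors: characters outside the alphabet, and signal-peptide (S)
    characters anywhere but one contiguous run starting at the first residue.
    Soft violations found in hand-curated annotations -- TM/SP runs shorter
    than 5 residues, flanking sides that do not alternate across a TM segment,
    or a direct i<->o contact -- are recorded as warnings on the returned
    object (and emitted as :class:`LabelGrammarWarning`).
    """
    where = f" in {name}" if name else ""
    for pos, ch in enumerate(s):
        if ch not in LABEL_ALPHABET:
            raise ValueError(f"illegal label character {ch!r} at position {pos}{where}")
    first_s = s.find("S")
    if first_s > 0:
        raise ValueError(
            f"signal peptide must start at the N-terminus; found S at position {first_s}{where}"
        )
    runs = _runs(s)
    if sum(1 for c, *_ in runs if c == "S") > 1:
        # leading run plus a later one: the later one cannot start at 0
        later = next(start for c, start, _ in runs[1:] if c == "S")
        raise ValueError(
            f"signal peptide must start at the N-terminus; found S at position {later}{where}"
        )

    notes: list[str] = []
    for ch, start, end in runs:
        if ch in _TM_CHARS or ch == "S":
            if end - start < MIN_SEGMENT_LEN:
                notes.append(
                    f"{ch}-run [{start},{end}) shorter than {MIN_SEGMENT_LEN} residues"
                )
    # orientation bookkeeping: side before a TM run must match its direction
    # character and the side after must be the opposite
    side_of = {"B": ("i", "o"), "H": ("i", "o"), "b": ("o", "i"), "h": ("o", "i")}
    prev_side: str | None = None
    for ch, start, end in runs:
        if ch in ("i", "o"):
            if prev_side is not None and prev_side != ch:
                notes.append(f"side flips {prev_side}->{ch} at {start} without a TM segment")
            prev_side = ch
        elif ch == "S":
            prev_side = "o"  # translocated N-terminus
        else:
            before, after = side_of[ch]
            if prev_side is not None and prev_side != before:
                notes.append(
                    f"{ch}-run at [{start},{end}) entered from side {prev_side!r}, expected {before!r}"
                )
            prev_side = after
    for note in notes:
        _warnings.warn(note + where, LabelGrammarWarning, stacklevel=2)
    return LabelSequence(s, tuple(notes))


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein records; header token up to first whitespace is the id.

    Sequences are uppercased and the ambiguous residue codes U/B/Z/O are
    mapped to X.  Duplicate ids raise.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        pid = rec.id
        if pid in seen:
            raise ValueError(f"duplicate id {pid!r} in {path}")
        seen.add(pid)
        seq = str(rec.seq).upper()
        seq = "".join(_AA_REMAP.get(c, c) for c in seq)
        records.append(ProteinRecord(pid, seq))
    return records


def write_fasta(path: str | Path, records: Iterable[ProteinRecord], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for k in range(0, rec.length, width):
                fh.write(rec.sequence[k : k + width] + "\n")


def read_feature_container(
    path: str | Path,
    ids: Sequence[str],
    sequences: Mapping[str, str] | None = None,
) -> dict[str, np.ndarray]:
    """Load L x D float matrices for the requested ids from an HDF5 container.

    Validates finiteness and, when ``sequences`` is given, that row counts
    match the paired sequence lengths.
    """
    out: dict[str, np.ndarray] = {}
    with h5py.File(path, "r") as fh:
        for pid in ids:
            if pid not in fh:
                raise KeyError(f"{pid!r} not found in {path}")
            mat = np.asarray(fh[pid], dtype=np.float64)
            if mat.ndim != 2:
                raise ValueError(f"{pid!r}: expected a 2-D matrix, got shape {mat.shape}")
            bad = ~np.isfinite(mat)
            if bad.any():
                row = int(np.argwhere(bad)[0, 0])
                raise ValueError(f"{pid!r}: non-finite value at row {row}")
            if sequences is not None and pid in sequences:
                L = len(sequences[pid])
                if mat.shape[0] != L:
                    raise ValueError(
                        f"{pid!r}: matrix has {mat.shape[0]} rows but sequence length is {L}"
                    )
            out[pid] = mat
    return out


def write_feature_container(path: str | Path, matrices: Mapping[str, np.ndarray]) -> None:
    """Write one float32 dataset per protein id."""
    with h5py.File(path, "w") as fh:
        for pid, mat in matrices.items():
            fh.create_dataset(pid, data=np.asarray(mat, dtype=np.float32))


def read_labels(path: str | Path) -> dict[str, LabelSequence]:
    """Read topology annotations: blocks of ``>id`` followed by a label line.

    Accepts both the 2-line annotation form and the 3-line prediction form
    (id, amino-acid sequence, labels); the last non-header line of each block
    is taken as the label string.
    """
    blocks: dict[str, LabelSequence] = {}
    current: str | None = None
    lines: list[str] = []

    def _flush() -> None:
        if current is None:
            return
        if not lines:
            raise ValueError(f"no label line for {current!r} in {path}")
        if current in blocks:
            raise ValueError(f"duplicate id {current!r} in {path}")
        blocks[current] = parse_labels(lines[-1], name=current)

    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                _flush()
                current = line[1:].split()[0]
                lines = []
            else:
                lines.append(line)
        _flush()
    return blocks


def write_labels(path: str | Path, labels: Mapping[str, LabelSequence | str]) -> None:
    with open(path, "w") as fh:
        for pid, lab in labels.items():
            fh.write(f">{pid}\n{lab}\n")


def write_predictions(
    path: str | Path,
    records: Sequence[tuple[ProteinRecord, LabelSequence, np.ndarray | None]],
    with_probabilities: bool = False,
) -> None:
    """Write 3-line prediction blocks; optionally a per-residue probability TSV.

    The main file holds ``>id`` / sequence / label-string blocks.  With
    ``with_probabilities`` a sibling file ``<path>.probs.tsv`` is written with
    columns id, position (1-based), residue, label and the five class
    probabilities in the order B, H, S, i, o.
    """
    path = Path(path)
    for rec, lab, _ in records:
        if len(lab) != rec.length:
            raise ValueError(
                f"{rec.id!r}: label length {len(lab)} != sequence length {rec.length}"
            )
    with open(path, "w") as fh:
        for rec, lab, _ in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n{lab}\n")
    if with_probabilities:
        with open(path.with_name(path.name + ".probs.tsv"), "w") as fh:
            fh.write("id\tpos\tresidue\tlabel\t" + "\t".join(f"p_{c}" for c in CLASS_ORDER) + "\n")
            for rec, lab, probs in records:
                if probs is None:
                    raise ValueError(f"{rec.id!r}: probabilities requested but not provided")
                if probs.shape != (rec.length, len(CLASS_ORDER)):
                    raise ValueError(f"{rec.id!r}: probability matrix shape {probs.shape}")
                for t in range(rec.length):
                    row = "\t".join(f"{p:.6f}" for p in probs[t])
                    fh.write(f"{rec.id}\t{t + 1}\t{rec.sequence[t]}\t{lab.labels[t]}\t{row}\n")


def read_predictions(path: str | Path) -> dict[str, tuple[str, LabelSequence]]:
    """Read 3-line prediction blocks back as id -> (sequence, labels)."""
    out: dict[str, tuple[str, LabelSequence]] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    k = 0
    while k < len(lines):
        if not lines[k].startswith(">"):
            raise ValueError(f"expected header at line {k + 1} of {path}")
        pid = lines[k][1:].split()[0]
        try:
            seq, lab = lines[k + 1], lines[k + 2]
        except IndexError:
            raise ValueError(f"truncated block for {pid!r} in {path}") from None
        if pid in out:
            raise ValueError(f"duplicate id {pid!r} in {path}")
        out[pid] = (seq, parse_labels(lab, name=pid))
        k += 3
    return out


def length_filter(
    records: Sequence[ProteinRecord],
    min_len: int = 50,
    max_len: int = 15000,
) -> list[ProteinRecord]:
    """Keep records with min_len <= L <= max_len (both bounds inclusive).

    Very short sequences are typically sequencing fragments; extremely long
    ones are disproportionately expensive downstream.
    """
    kept = [r for r in records if min_len <= r.length <= max_len]
    n_short = sum(1 for r in records if r.length < min_len)
    n_long = sum(1 for r in records if r.length > max_len)
    if n_short or n_long:
        import logging

        logging.getLogger(__name__).info(
            "length_filter removed %d short (<%d) and %d long (>%d) of %d records",
            n_short, min_len, n_long, max_len, len(records),
        )
    return kept
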