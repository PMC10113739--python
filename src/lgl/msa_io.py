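"""Alignment I/O, preprocessing filters and one-hot encoding.

Reads aligned FASTA or Stockholm, normalizes the alphabet ('.' gaps to '-',
lowercase to uppercase, ambiguity codes B/Z/X/J/* to gap with a logged
count), applies the family-curation filters (contiguous-gap removal for
training alignments, nonsense-truncation removal for mutant libraries) and
converts alignments to the (n, L, 23) one-hot tensor every model consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.Align import MultipleSeqAlignment

from .alphabet import ALPHABET, AMBIGUOUS, GAP, Alphabet

logger = logging.getLogger(__name__)


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, empty input)."""


@dataclass
class Alignment:
    """An aligned protein family over the canonical 23-letter alphabet.

    Attributes
    ----------
    ids : list of str
        Unique sequence identifiers, input order preserved.
    seqs : list of str
        Equal-length aligned sequences.
    labels : dict, optional
        Annotation strings keyed by sequence id (used for label transfer).
    """

    ids: list[str]
    seqs: list[str]
    labels: Optional[dict[str, str]] = None
    alphabet: Alphabet = field(default_factory=lambda: ALPHABET, repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise AlignmentError("ids and seqs length mismatch")
        if len(set(self.ids)) != len(self.ids):
            dupes = {i for i in self.ids if self.ids.count(i) > 1}
            raise AlignmentError(f"duplicate sequence ids: {sorted(dupes)[:5]}")
        if self.seqs:
            L = len(self.seqs[0])
            for sid, s in zip(self.ids, self.seqs):
                if len(s) != L:
                    raise AlignmentError(
                        f"sequence {sid!r} has length {len(s)}, expected {L}"
                    )
            bad = set("".join(self.seqs)) - set(self.alphabet.symbols)
            if bad:
                raise AlignmentError(f"characters outside alphabet: {sorted(bad)}")

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def L(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.seqs))

    def subset(self, keep: list[int]) -> "Alignment":
        """New Alignment restricted to the given row indices (order kept)."""
        ids = [self.ids[i] for i in keep]
        labels = None
        if self.labels is not None:
            labels = {i: self.labels[i] for i in ids if i in self.labels}
        return Alignment(ids, [self.seqs[i] for i in keep], labels, self.alphabet)

    def indices(self) -> np.ndarray:
        """(n, L) integer-encoded matrix."""
        arr = np.frombuffer("".join(self.seqs).encode("ascii"), dtype=np.uint8)
        arr = arr.reshape(self.n, self.L)
        lut = np.full(128, -1, dtype=np.int64)
        for c, i in self.alphabet.index.items():
            lut[ord(c)] = i
        return lut[arr]


def _normalize(seq: str) -> tuple[str, int]:
    """Uppercase, '.'->'-', ambiguity codes to gap. Returns (seq, n_mapped)."""
    s = seq.upper().replace(".", GAP)
    mapped = sum(1 for c in s if c in AMBIGUOUS or c not in ALPHABET.index)
    if mapped:
        s = "".join(GAP if c not in ALPHABET.index else c for c in s)
    return s, mapped


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA or Stockholm file.

    Gap '.' characters become '-', lowercase is uppercased, and characters
    outside the 23-letter alphabet are mapped to gap with a logged count.

    Raises
    ------
    AlignmentError
        If sequences have unequal lengths (names the offending id) or the
        file contains no records.
    """
    path = Path(path)
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported format {format!r}")
    records = list(SeqIO.parse(str(path), format))
    if not records:
        raise AlignmentError(f"no sequences found in {path}")
    ids, seqs = [], []
    n_mapped = 0
    L = None
    for rec in records:
        s, mapped = _normalize(str(rec.seq))
        n_mapped += mapped
        if L is None:
            L = len(s)
        elif len(s) != L:
            raise AlignmentError(
                f"sequence {rec.id!r} has length {len(s)}, expected {L}"
            )
        ids.append(rec.id)
        seqs.append(s)
    if n_mapped:
        logger.warning(
            "%s: %d non-alphabet characters mapped to gap", path.name, n_mapped
        )
    return Alignment(ids, seqs)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    """Write FASTA (wrapped at 60 columns) or Stockholm 1.0."""
    path = Path(path)
    records = [
        SeqRecord(Seq(s), id=i, description="") for i, s in zip(aln.ids, aln.seqs)
    ]
    if format == "fasta":
        with open(path, "w") as fh:
            for rec in records:
                fh.write(f">{rec.id}\n")
                s = str(rec.seq)
                for k in range(0, len(s), 60):
                    fh.write(s[k : k + 60] + "\n")
    elif format == "stockholm":
        AlignIO.write(MultipleSeqAlignment(records), str(path), "stockholm")
    else:
        raise ValueError(f"unsupported format {format!r}")


def read_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV (id <TAB> label) -> dict."""
    labels: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sid, _, lab = line.partition("\t")
            labels[sid] = lab
    return labels


def write_labels(labels: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, lab in labels.items():
            fh.write(f"{sid}\t{lab}\n")


def _longest_gap_run(seq: str) -> int:
    run = best = 0
    for c in seq:
        run = run + 1 if c == GAP else 0
        best = max(best, run)
    return best


def filter_contiguous_gaps(aln: Alignment, threshold: float = 0.20) -> Alignment:
    """Drop sequences whose longest gap run covers >= `threshold` of L.

    The boundary is inclusive: a run of exactly ``threshold * L`` columns
    removes the sequence.  Survivor order is preserved; the result may be
    empty.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    L = aln.L
    keep = [
        k for k, s in enumerate(aln.seqs) if _longest_gap_run(s) / L < threshold
    ]
    dropped = aln.n - len(keep)
    if dropped:
        logger.info("filter_contiguous_gaps removed %d/%d sequences", dropped, aln.n)
    return aln.subset(keep)


def _truncation_length(seq: str, ref: str) -> int:
    """Length of the terminal run where `seq` is gapped but `ref` is not.

    Columns where the reference itself is gapped neither extend nor break
    the run (they are alignment gaps, not missing protein).
    """
    run = 0
    for c, r in zip(reversed(seq), reversed(ref)):
        if r == GAP:
            continue
        if c == GAP:
            run += 1
        else:
            break
    return run


def filter_nonsense_mutants(
    lib: Alignment, ref: str, threshold: float = 0.20
) -> Alignment:
    """Drop mutants truncated (premature termination) over `threshold` of L.

    A nonsense mutation shows up in an alignment as a terminal run of gaps
    relative to the reference protein; mutants whose truncation is strictly
    greater than ``threshold * L`` are discarded.
    """
    if len(ref) != lib.L:
        raise AlignmentError(
            f"reference length {len(ref)} does not match alignment L={lib.L}"
        )
    cut = threshold * lib.L
    keep = [k for k, s in enumerate(lib.seqs) if _truncation_length(s, ref) <= cut]
    dropped = lib.n - len(keep)
    if dropped:
        logger.info("filter_nonsense_mutants removed %d/%d mutants", dropped, lib.n)
    return lib.subset(keep)


def one_hot_encode(aln: Alignment, alphabet: Alphabet | None = None) -> np.ndarray:
    """(n, L, 23) one-hot tensor; exactly one 1 per (sequence, position)."""
    alphabet = alphabet or aln.alphabet
    idx = aln.indices()
    if (idx < 0).any():
        raise ValueError("alignment contains characters outside the alphabet")
    out = np.zeros((aln.n, aln.L, len(alphabet)), dtype=np.float64)
    n_idx = np.arange(aln.n)[:, None]
    l_idx = np.arange(aln.L)[None, :]
    out[n_idx, l_idx, idx] = 1.0
    return out


def one_hot_decode(
    onehot: np.ndarray, ids: list[str] | None = None, alphabet: Alphabet | None = None
) -> Alignment:
    """Inverse of :func:`one_hot_encode` via per-position argmax."""
    alphabet = alphabet or ALPHABET
    idx = onehot.argmax(axis=-1)
    seqs = [alphabet.decode(row) for row in idx]
    if ids is None:
        ids = [f"seq{k}" for k in range(len(seqs))]
    return Alignment(list(ids), seqs, alphabet=alphabet)
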