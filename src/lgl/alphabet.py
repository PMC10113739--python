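"""The 23-letter sequence alphabet shared by every model in the package.

The alphabet covers the 20 canonical amino acids, selenocysteine (U),
pyrrolysine (O) and the alignment gap character ``-``.  The ordering is
frozen (gap last, index 22) so that one-hot encodings, Potts parameter
tensors and decoder output columns always agree.
"""

from __future__ import annotations

from dataclasses import dataclass, field


SYMBOLS = "ACDEFGHIKLMNPQRSTVWYUO-"
GAP = "-"
Q = 23

# Ambiguity codes found in real family alignments; mapped to gap on read.
AMBIGUOUS = frozenset("BZXJ*")


@dataclass(frozen=True)
class Alphabet:
    """Ordered symbol set with a bijective symbol->index map.

    Attributes
    ----------
    symbols : str
        The 23 characters in canonical order, gap last.
    index : dict
        Inverse map ``symbol -> 0..22``.
    """

    symbols: str = SYMBOLS
    index: dict = field(default_factory=lambda: {c: i for i, c in enumerate(SYMBOLS)})

    def __post_init__(self) -> None:
        if len(self.symbols) != len(self.index):
            raise ValueError("alphabet symbols must be unique")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.index

    @property
    def gap_index(self) -> int:
        return self.index[GAP]

    def encode(self, seq: str) -> list[int]:
        """Map a sequence string to integer indices."""
        try:
            return [self.index[c] for c in seq]
        except KeyError as exc:  # pragma: no cover - guarded upstream
            raise ValueError(f"symbol {exc.args[0]!r} not in alphabet") from exc

    def decode(self, indices) -> str:
        """Map integer indices back to a sequence string."""
        return "".join(self.symbols[i] for i in indices)


#: Module-level singleton used by default everywhere.
ALPHABET = Alphabet()
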