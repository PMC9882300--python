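"""Genome container and basic sequence utilities.

Sequences are stored 5'->3' in the DNA alphabet (T, not U). Coordinates are
0-based, half-open everywhere inside the package; conversion to 1-based
inclusive happens only in the GFF3 reader/writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """A set of named chromosome sequences.

    Parameters
    ----------
    chroms
        Mapping of chromosome name to its forward-strand sequence.
    """

    chroms: dict[str, str] = field(default_factory=dict)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.chroms.items()}

    def __len__(self) -> int:
        return len(self.chroms)

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Return the sequence of ``[start, end)`` on ``strand``.

        For the minus strand the returned string reads 5'->3' on that strand,
        i.e. it is the reverse complement of the forward-strand slice.
        """
        if chrom not in self.chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (0 <= start <= end <= len(self.chroms[chrom])):
            raise ValueError(
                f"interval [{start},{end}) out of bounds for {chrom} "
                f"(length {len(self.chroms[chrom])})"
            )
        seq = self.chroms[chrom][start:end]
        return seq if strand == "+" else revcomp(seq)
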