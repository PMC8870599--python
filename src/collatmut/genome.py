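"""Reference sequence access.

Wraps either an indexed FASTA file (via pyfaidx) or an in-memory dict of
chromosome sequences behind one 1-based, fully-closed coordinate interface.
Soft-masked (lowercase) bases are uppercased on access.
"""

from __future__ import annotations

from typing import Iterable, Mapping


class Genome:
    """Random-access reference sequence with 1-based closed coordinates."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {str(c): str(s).upper() for c, s in sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    @classmethod
    def from_dict(cls, sequences: Mapping[str, str]) -> "Genome":
        return cls(sequences)

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self._seqs[chrom])

    def base(self, chrom: str, pos: int) -> str:
        """Base at 1-based position ``pos``."""
        seq = self._seqs[chrom]
        if not 1 <= pos <= len(seq):
            raise IndexError(f"position {pos} outside {chrom} (1..{len(seq)})")
        return seq[pos - 1]

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Sequence from ``start`` to ``end`` inclusive (1-based)."""
        seq = self._seqs[chrom]
        if start < 1 or end > len(seq) or start > end:
            raise IndexError(f"range {start}..{end} outside {chrom}")
        return seq[start - 1 : end]

    def sequence(self, chrom: str) -> str:
        return self._seqs[chrom]

    def eligible_regions(self, min_n_run: int = 10) -> list[tuple[str, int, int]]:
        """Chromosome spans minus runs of >= ``min_n_run`` N bases.

        Returns 1-based closed intervals usable as a resampling universe for
        the expected close-mutation-ratio null.
        """
        regions: list[tuple[str, int, int]] = []
        for chrom, seq in self._seqs.items():
            start = 1
            i = 0
            n = len(seq)
            while i < n:
                if seq[i] == "N":
                    j = i
                    while j < n and seq[j] == "N":
                        j += 1
                    if j - i >= min_n_run:
                        if i >= start:
                            if i - start + 1 > 0 and start <= i:
                                regions.append((chrom, start, i))
                        start = j + 1
                    i = j
                else:
                    i += 1
            if start <= n:
                regions.append((chrom, start, n))
        return regions

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seqs.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)
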