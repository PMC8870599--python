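"""Core record types shared across the package.

A mutation catalogue is a flat list of :class:`MutationRecord` objects, one
per somatic variant call. Coordinates are 1-based and fully closed
(VCF-style): ``pos`` is the position of the reference base for a
substitution, of the first deleted base for a deletion, and of the base
immediately left of the inserted sequence for an insertion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

VALID_BASES = frozenset("ACGT")

#: maximum indel length considered a "short indel"
MAX_INDEL_LEN = 20


def infer_kind(ref: str, alt: str) -> str:
    """Classify a ref/alt allele pair as SBS, INS or DEL."""
    if len(ref) == 1 and len(alt) == 1:
        if ref == alt:
            raise ValueError(f"ref and alt are identical ({ref!r})")
        return "SBS"
    if len(ref) > len(alt):
        return "DEL"
    if len(alt) > len(ref):
        return "INS"
    return "MNV"


@dataclass
class MutationRecord:
    """One somatic variant (SBS or short indel) with optional QC metrics."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    metrics: dict = field(default_factory=dict)
    kind: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if not self.kind:
            self.kind = infer_kind(self.ref, self.alt)

    @property
    def indel_len(self) -> int:
        """Length of the inserted/deleted sequence; 0 for substitutions."""
        return abs(len(self.ref) - len(self.alt))

    @property
    def is_long_indel(self) -> bool:
        return self.kind in ("INS", "DEL") and self.indel_len > MAX_INDEL_LEN

    def sort_key(self):
        return (self.sample_id, self.chrom, self.pos)

    def metric(self, name: str) -> Optional[float]:
        return self.metrics.get(name)


def sort_records(records: list[MutationRecord]) -> list[MutationRecord]:
    return sorted(records, key=MutationRecord.sort_key)


def group_by_sample(records) -> dict[str, list[MutationRecord]]:
    out: dict[str, list[MutationRecord]] = {}
    for r in records:
        out.setdefault(r.sample_id, []).append(r)
    for recs in out.values():
        recs.sort(key=MutationRecord.sort_key)
    return out


def group_by_sample_chrom(records) -> dict[tuple[str, str], list[MutationRecord]]:
    out: dict[tuple[str, str], list[MutationRecord]] = {}
    for r in records:
        out.setdefault((r.sample_id, r.chrom), []).append(r)
    for recs in out.values():
        recs.sort(key=lambda r: r.pos)
    return out
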