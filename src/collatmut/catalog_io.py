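"""Mutation catalogue I/O, trinucleotide contexts and 96-channel spectra.

The native catalogue format is a TSV with header columns
``sample  chrom  pos  ref  alt`` plus any number of optional numeric metric
columns (``mean_mapq``, ``coverage_fluct``, ...). A VCF reader is provided
for interoperability.

Substitution contexts are pyrimidine-normalised: when the reference base is
a purine, the whole up-ref-alt-down quadruple is reverse-complemented (with
the flanks swapped) so that every SBS maps onto one of the 96 canonical
channels C>A/C>G/C>T/T>A/T>C/T>G x 16 flank combinations, flanks sorted
alphabetically.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .genome import Genome, complement
from .records import MAX_INDEL_LEN, MutationRecord, sort_records

log = logging.getLogger(__name__)

PYR_SUBTYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = ("A", "C", "G", "T")

#: Canonical 96-channel labels, e.g. ``A[C>A]A``; substitution-major order,
#: then 5' flank, then 3' flank, alphabetical.
CHANNELS_96 = tuple(
    f"{up}[{sub}]{down}" for sub in PYR_SUBTYPES for up in BASES for down in BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass
class TripletContext:
    """Pyrimidine-normalised +/-1 bp context of a single base substitution."""

    up: str
    ref: str
    alt: str
    down: str
    strand_flipped: bool
    usable: bool = True

    @property
    def pyr_class(self) -> str:
        return f"{self.up}[{self.ref}>{self.alt}]{self.down}"

    @property
    def change(self) -> str:
        return f"{self.ref}>{self.alt}"


def triplet_context(genome: Genome, chrom: str, pos: int, ref: str, alt: str) -> TripletContext:
    """Annotate an SBS with its pyrimidine-normalised trinucleotide context.

    Raises ``ValueError`` if the genome base at ``pos`` disagrees with
    ``ref``. A non-ACGT base in either flank marks the context unusable.
    """
    ref = ref.upper()
    alt = alt.upper()
    gbase = genome.base(chrom, pos)
    if gbase != ref:
        raise ValueError(
            f"reference mismatch at {chrom}:{pos}: genome has {gbase}, record has {ref}"
        )
    if pos < 2 or pos > genome.length(chrom) - 1:
        return TripletContext("N", ref, alt, "N", strand_flipped=False, usable=False)
    up = genome.base(chrom, pos - 1)
    down = genome.base(chrom, pos + 1)
    flipped = ref in ("A", "G")
    if flipped:
        up, down = complement(down), complement(up)
        ref, alt = complement(ref), complement(alt)
    usable = up in BASES and down in BASES
    return TripletContext(up, ref, alt, down, strand_flipped=flipped, usable=usable)


def match_pattern(ctx: TripletContext, pattern: str) -> bool:
    """Test a pyrimidine-normalised context against an IUPAC triplet pattern.

    Patterns look like ``N[C>A]Y``: central ref must be C or T, flanks are
    IUPAC codes. Matching is strand-symmetric because contexts are already
    pyrimidine-normalised.
    """
    up_p, ref_p, alt_p, down_p = parse_pattern(pattern)
    if not ctx.usable:
        return False
    return (
        ctx.ref == ref_p
        and ctx.alt == alt_p
        and ctx.up in IUPAC[up_p]
        and ctx.down in IUPAC[down_p]
    )


def parse_pattern(pattern: str) -> tuple[str, str, str, str]:
    """Validate and split an IUPAC triplet-class pattern like ``N[C>A]Y``."""
    import re

    p = pattern.strip().upper()
    m = re.fullmatch(r"([A-Z])\[([CT])>([ACGT])\]([A-Z])", p)
    if not m:
        raise ValueError(f"invalid triplet pattern {pattern!r} (expected e.g. 'N[C>A]Y')")
    up_p, ref_p, alt_p, down_p = m.groups()
    if up_p not in IUPAC or down_p not in IUPAC:
        raise ValueError(f"invalid IUPAC flank in pattern {pattern!r}")
    if ref_p == alt_p:
        raise ValueError(f"pattern {pattern!r} has identical ref and alt")
    return up_p, ref_p, alt_p, down_p


# ---------------------------------------------------------------------------
# catalogue I/O

_REQUIRED_COLS = ("sample", "chrom", "pos", "ref", "alt")


def read_catalog(path, dialect: str = "tsv") -> list[MutationRecord]:
    """Read a mutation catalogue (native TSV or VCF) into records.

    Records are returned sorted by (sample, chrom, pos). Indels longer than
    20 bp trigger a warning and are flagged (``metrics['long_indel']=1``);
    downstream mixed-pair analysis excludes them.
    """
    if dialect == "tsv":
        records = _read_tsv(path)
    elif dialect == "vcf":
        records = _read_vcf(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for r in records:
        if r.is_long_indel:
            warnings.warn(
                f"indel longer than {MAX_INDEL_LEN} bp at {r.chrom}:{r.pos} "
                f"({r.sample_id}); flagged and excluded from mixed-pair analysis"
            )
            r.metrics["long_indel"] = 1.0
    return sort_records(records)


def _read_tsv(path) -> list[MutationRecord]:
    records = []
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line:
            return []
        header = header_line.rstrip("\n").split("\t")
        missing = [c for c in _REQUIRED_COLS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
        idx = {c: header.index(c) for c in header}
        metric_cols = [c for c in header if c not in _REQUIRED_COLS]
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ValueError(f"{path} line {lineno}: expected {len(header)} fields, got {len(fields)}")
            try:
                metrics = {}
                for c in metric_cols:
                    v = fields[idx[c]]
                    if v not in ("", "NA", "nan"):
                        metrics[c] = float(v)
                rec = MutationRecord(
                    sample_id=fields[idx["sample"]],
                    chrom=fields[idx["chrom"]],
                    pos=int(fields[idx["pos"]]),
                    ref=fields[idx["ref"]],
                    alt=fields[idx["alt"]],
                    metrics=metrics,
                )
            except (ValueError, IndexError) as e:
                raise ValueError(f"{path} line {lineno}: malformed row ({e})") from e
            records.append(rec)
    return records


def _read_vcf(path) -> list[MutationRecord]:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        import os

        stem = os.path.splitext(os.path.basename(str(path)))[0]
        for i, v in enumerate(vcf, start=1):
            if v.alts is None:
                raise ValueError(f"{path} record {i}: missing ALT")
            for alt in v.alts:
                carriers: list[str]
                if samples:
                    carriers = [
                        s for s in samples
                        if v.samples[s].get("GT") and any(a not in (0, None) for a in v.samples[s]["GT"])
                    ]
                    if not carriers:
                        carriers = samples
                else:
                    carriers = [stem]
                for s in carriers:
                    records.append(
                        MutationRecord(sample_id=s, chrom=v.chrom, pos=v.pos, ref=v.ref, alt=alt)
                    )
    return records


def write_catalog(records: Iterable[MutationRecord], path) -> None:
    """Write records to the native TSV format (round-trips with read_catalog)."""
    records = list(records)
    metric_cols = sorted({k for r in records for k in r.metrics})
    with open(path, "w") as fh:
        fh.write("\t".join(_REQUIRED_COLS + tuple(metric_cols)) + "\n")
        for r in sort_records(records):
            row = [r.sample_id, r.chrom, str(r.pos), r.ref, r.alt]
            for c in metric_cols:
                v = r.metrics.get(c)
                row.append("" if v is None else repr(float(v)))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# spectra


def build_spectrum(records: Iterable[MutationRecord], genome: Genome) -> pd.DataFrame:
    """Tally SBS records into a samples x 96 spectrum matrix.

    Rows are samples, columns the canonical 96 channels. Records whose
    context is unusable (non-ACGT flank or chromosome edge) are counted and
    logged but do not enter the matrix, so each row sums to the number of
    context-annotatable SBSs for that sample.
    """
    counts: dict[str, np.ndarray] = {}
    n_unusable = 0
    for r in records:
        if r.kind != "SBS":
            raise ValueError(f"build_spectrum expects SBS records, got {r.kind} at {r.chrom}:{r.pos}")
        row = counts.setdefault(r.sample_id, np.zeros(96, dtype=np.int64))
        ctx = triplet_context(genome, r.chrom, r.pos, r.ref, r.alt)
        if not ctx.usable:
            n_unusable += 1
            continue
        row[_CHANNEL_INDEX[ctx.pyr_class]] += 1
    if n_unusable:
        log.info("build_spectrum: %d records with unusable context excluded", n_unusable)
    df = pd.DataFrame(
        counts.values(), index=list(counts.keys()), columns=list(CHANNELS_96), dtype=np.int64
    )
    df.index.name = "sample"
    df.attrs["n_unusable"] = n_unusable
    return df


def write_spectrum(spectrum: pd.DataFrame, path) -> None:
    """Write a spectrum matrix as channels x samples TSV."""
    spectrum.T.to_csv(path, sep="\t", index_label="channel")


def read_spectrum(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0).T
    df.index.name = "sample"
    return df
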