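"""Solitary collateral mutations and their contribution to mutation burden.

Collateral mutations also arise next to *correctly* bypassed (and hence
invisible) lesions. Around solitary, non-primary substitutions this leaves
a directional footprint: an excess of potential lesion motifs (CC
dinucleotides 5' of the mutation, GG motifs 3' of it, for cisplatin-type
GG adducts). The excess over the window-wide background converts, via the
per-erroneous-bypass collateral rate measured from close pairs, into an
estimate of the number of invisible lesions and the share of the
non-primary burden produced by collateral mutagenesis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .classify import classify_primary, get_scheme
from .genome import Genome
from .records import MutationRecord, group_by_sample_chrom

@dataclass
class MotifProfile:
    """Per-offset motif counts around a set of mutation sites.

    Offsets are signed nearest-base distances: a motif at offset d < 0
    lies on the 5' side with its closest base |d| bp upstream of the
    mutation (genome positions pos+d-1, pos+d); at d > 0 it lies 3' with
    its closest base d bp downstream (positions pos+d, pos+d+1). Motifs
    overlapping the mutated base itself have no offset and are excluded.
    This indexing is exactly symmetric under reverse complement (CC<->GG,
    d -> -d).
    """

    counts: pd.DataFrame  # index: offset (signed nearest-base distance), columns: motifs
    n_sites: int
    window: int
    n_skipped_offsets: int = 0

    def frequencies(self) -> pd.DataFrame:
        return self.counts / self.n_sites

    def smoothed(self, frac: float = 0.1) -> pd.DataFrame:
        """Lowess-smoothed per-offset frequencies (cosmetic output only)."""
        from statsmodels.nonparametric.smoothers_lowess import lowess

        freq = self.frequencies()
        out = {}
        for motif in freq.columns:
            y = freq[motif].to_numpy(dtype=float)
            x = freq.index.to_numpy(dtype=float)
            ok = ~np.isnan(y)
            sm = lowess(y[ok], x[ok], frac=frac, return_sorted=False)
            col = np.full_like(y, np.nan)
            col[ok] = sm
            out[motif] = col
        return pd.DataFrame(out, index=freq.index)


@dataclass
class BurdenEstimate:
    observed_directional: Optional[int] = None
    expected_directional: Optional[float] = None
    excess: Optional[float] = None
    excess_per_genome: Optional[float] = None
    fisher_p: Optional[float] = None
    invisible_lesions: Optional[float] = None
    pct_correct_bypass: Optional[float] = None
    pct_burden_contribution: Optional[float] = None


def select_solitary_nonprimary(
    records: Iterable[MutationRecord],
    scheme,
    genome: Genome,
    min_dist: int = 100,
) -> list[MutationRecord]:
    """Solitary non-primary SBSs: no scheme pattern match and no other
    mutation (SBS or indel) within ``min_dist`` bp in the same sample."""
    scheme = get_scheme(scheme)
    out: list[MutationRecord] = []
    for (_, _), recs in group_by_sample_chrom(records).items():
        for i, r in enumerate(recs):
            if r.kind != "SBS":
                continue
            if i > 0 and r.pos - recs[i - 1].pos <= min_dist:
                continue
            if i < len(recs) - 1 and recs[i + 1].pos - r.pos <= min_dist:
                continue
            if classify_primary(r, scheme, genome).label == "primary":
                continue
            out.append(r)
    return out


def motif_positional_profile(
    sites: Iterable[MutationRecord],
    genome: Genome,
    motifs: Sequence[str] = ("CC", "GG"),
    window: int = 300,
) -> MotifProfile:
    """Count motif occurrences at each offset around mutation sites.

    Offsets are signed nearest-base distances (see :class:`MotifProfile`):
    d < 0 counts the dinucleotide at genome positions (pos+d-1, pos+d),
    d > 0 the one at (pos+d, pos+d+1); d runs over -window..-1, 1..window.
    Sites whose window crosses a chromosome end contribute only their
    in-range offsets (skips logged in ``n_skipped_offsets``).
    """
    sites = list(sites)
    offsets = [o for o in range(-window, window + 1) if o != 0]
    counts = {m: np.zeros(len(offsets), dtype=np.int64) for m in motifs}
    n_skipped = 0
    for r in sites:
        clen = genome.length(r.chrom)
        lo = max(1, r.pos - window - 1)
        hi = min(clen, r.pos + window + 1)
        seq = genome.slice(r.chrom, lo, hi)
        for k, o in enumerate(offsets):
            start = r.pos + o - 1 if o < 0 else r.pos + o
            if start < lo or start + 1 > hi:
                n_skipped += 1
                continue
            dinuc = seq[start - lo : start - lo + 2]
            for m in motifs:
                if dinuc == m:
                    counts[m][k] += 1
    df = pd.DataFrame(counts, index=pd.Index(offsets, name="offset"))
    return MotifProfile(counts=df, n_sites=len(sites), window=window, n_skipped_offsets=n_skipped)


def strand_swap_profile(profile: MotifProfile) -> MotifProfile:
    """Swap CC<->GG and negate offsets (reverse-complement symmetry).

    The signed nearest-base-distance index maps onto itself under this
    transform, so :func:`directional_excess` is exactly invariant.
    """
    df = profile.counts.copy()
    if set(df.columns) >= {"CC", "GG"}:
        df = df.rename(columns={"CC": "GG", "GG": "CC"})
    df.index = -df.index
    df = df.sort_index()
    df.index.name = "offset"
    return MotifProfile(df[list(profile.counts.columns)], profile.n_sites, profile.window, profile.n_skipped_offsets)


def directional_excess(
    profile: MotifProfile,
    k: int = 10,
    background: Optional[float] = None,
    n_genomes: int = 1,
) -> BurdenEstimate:
    """Directional motif excess within ``k`` bp of solitary mutations.

    Observed = CC dinucleotides at offsets -k..-1 plus GG motifs at
    offsets +1..+k (offsets overlapping the mutation excluded). Expected =
    background per-position motif frequency x k positions x n_sites x 2
    motif classes, where the background defaults to the median per-offset
    frequency over the full +/-window computed separately per motif and
    averaged. Significance by Fisher's exact test of observed vs
    round(expected) out of the possible site-offset slots.
    """
    if k > profile.window:
        raise ValueError(f"k={k} exceeds profile window {profile.window}")
    counts = profile.counts
    cc = counts["CC"]
    gg = counts["GG"]
    observed = int(
        cc.loc[[o for o in range(-k, 0) if o in cc.index]].sum()
        + gg.loc[[o for o in range(1, k + 1) if o in gg.index]].sum()
    )
    if background is None:
        freq = profile.frequencies()
        background = float((freq["CC"].median() + freq["GG"].median()) / 2.0)
    expected = background * k * profile.n_sites * 2
    excess = observed - expected
    total_possible = 2 * k * profile.n_sites
    exp_r = round(expected)
    table = [
        [observed, max(total_possible - observed, 0)],
        [exp_r, max(total_possible - exp_r, 0)],
    ]
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return BurdenEstimate(
        observed_directional=observed,
        expected_directional=float(expected),
        excess=float(excess),
        excess_per_genome=float(excess) / n_genomes,
        fisher_p=fisher_p,
    )


def burden_arithmetic(
    pairs_per_genome: float,
    primaries_per_genome: float,
    excess_per_genome: float,
    nonprimary_per_genome: float,
) -> BurdenEstimate:
    """Invisible-lesion and burden-contribution arithmetic.

    The per-erroneous-bypass collateral rate is pairs/primaries per genome;
    dividing the solitary-collateral excess by it gives the number of
    correctly bypassed ("invisible") lesions. The percent of lesions
    bypassed correctly is invisible/(invisible+primaries); the collateral
    share of the non-primary burden is (pairs+excess)/non-primary.
    """
    for name, v in (
        ("pairs_per_genome", pairs_per_genome),
        ("primaries_per_genome", primaries_per_genome),
        ("nonprimary_per_genome", nonprimary_per_genome),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0")
    rate = pairs_per_genome / primaries_per_genome
    invisible = excess_per_genome / rate
    pct_correct = 100.0 * invisible / (invisible + primaries_per_genome)
    pct_burden = 100.0 * (pairs_per_genome + excess_per_genome) / nonprimary_per_genome
    return BurdenEstimate(
        excess_per_genome=excess_per_genome,
        invisible_lesions=invisible,
        pct_correct_bypass=pct_correct,
        pct_burden_contribution=pct_burden,
    )
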