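"""Primary vs collateral classification of close mutation pairs.

A *primary* mutation arises directly opposite a DNA lesion and is
recognised by treatment-specific triplet classes (e.g. ``N[C>A]Y`` for
cisplatin adducts at GG/AG motifs). The accompanying *collateral* mutation
is made by the translesion polymerase on undamaged template downstream of
the lesion: 5' of the primary in upper-strand coordinates when the lesion
sits on the upper strand, 3' when it sits on the lower strand.

Schemes map observed upper-strand allele changes to the lesion strand: for
cisplatin, an observed G>T (or A>T) means the damaged purine is on the
upper strand, while the complementary C>A (or T>A) reading places it on the
lower strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .catalog_io import TripletContext, match_pattern, parse_pattern, triplet_context
from .genome import Genome
from .pairs import MutationPair
from .records import MutationRecord


@dataclass
class PrimaryScheme:
    """Treatment-specific definition of lesion-coupled primary mutations."""

    name: str
    patterns: list[str]
    upper_lesion_alleles: frozenset[str]

    def __post_init__(self):
        if not self.patterns:
            raise ValueError("scheme needs at least one pattern")
        for p in self.patterns:
            parse_pattern(p)  # validate at configuration load
        self.upper_lesion_alleles = frozenset(self.upper_lesion_alleles)


#: Built-in schemes. Cisplatin forms intrastrand crosslinks at GG/AG; UVC
#: forms pyrimidine dimers. Patterns are in pyrimidine-normalised space;
#: upper_lesion_alleles list the observed upper-strand ref>alt changes that
#: place the lesion on the upper strand.
BUILTIN_SCHEMES: dict[str, PrimaryScheme] = {
    s.name: s
    for s in (
        PrimaryScheme(
            "cisplatin_dt40",
            ["N[C>A]Y", "N[T>A]C", "C[T>A]N"],
            frozenset({"G>T", "A>T"}),
        ),
        PrimaryScheme(
            "uvc_dt40",
            ["Y[C>T]N", "Y[T>A]N"],
            frozenset({"C>T", "T>A"}),
        ),
        PrimaryScheme(
            "cisplatin_human_closepair",
            ["N[C>A]C"],
            frozenset({"G>T"}),
        ),
        PrimaryScheme(
            "cisplatin_human_burden",
            ["N[C>A]C", "C[C>T]N", "C[T>A]N"],
            frozenset({"G>T", "G>A", "A>T"}),
        ),
    )
}


def load_schemes(path) -> dict[str, PrimaryScheme]:
    """Load user-defined schemes from a YAML file.

    Expected layout::

        schemes:
          - name: my_treatment
            patterns: ["N[C>A]Y"]
            upper_lesion_alleles: ["G>T"]
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for block in doc.get("schemes", []):
        s = PrimaryScheme(
            name=block["name"],
            patterns=list(block["patterns"]),
            upper_lesion_alleles=frozenset(block["upper_lesion_alleles"]),
        )
        out[s.name] = s
    return out


def get_scheme(name_or_scheme) -> PrimaryScheme:
    if isinstance(name_or_scheme, PrimaryScheme):
        return name_or_scheme
    try:
        return BUILTIN_SCHEMES[name_or_scheme]
    except KeyError:
        raise KeyError(
            f"unknown scheme {name_or_scheme!r}; built-ins: {sorted(BUILTIN_SCHEMES)}"
        ) from None


@dataclass
class Classification:
    label: str  # "primary" | "non_primary"
    lesion_strand: Optional[str]  # "upper" | "lower" | None
    context: Optional[TripletContext]
    unusable_context: bool = False


def classify_primary(
    record: MutationRecord, scheme, genome: Genome
) -> Classification:
    """Label one SBS as primary (lesion-coupled) or non-primary.

    Primary iff any scheme pattern matches the pyrimidine-normalised
    context; the lesion strand follows from whether the observed
    upper-strand change is in the scheme's upper-strand allele set.
    Unusable contexts (N flank, chromosome edge) are labelled non-primary
    with a flag.
    """
    scheme = get_scheme(scheme)
    if record.kind != "SBS":
        return Classification("non_primary", None, None, unusable_context=True)
    ctx = triplet_context(genome, record.chrom, record.pos, record.ref, record.alt)
    if not ctx.usable:
        return Classification("non_primary", None, ctx, unusable_context=True)
    if any(match_pattern(ctx, p) for p in scheme.patterns):
        observed = f"{record.ref}>{record.alt}"
        strand = "upper" if observed in scheme.upper_lesion_alleles else "lower"
        return Classification("primary", strand, ctx)
    return Classification("non_primary", None, ctx)


@dataclass
class PairCategory:
    pair: MutationPair
    first_label: str
    second_label: str
    category: str  # proper | both_primary | both_non_primary
    orientation_consistent: Optional[bool]
    primary_is_first: Optional[bool] = None
    lesion_strand: Optional[str] = None


def categorize_pair(pair: MutationPair, scheme, genome: Genome) -> PairCategory:
    """Categorise a close pair and, when proper, its orientation.

    A *proper* pair has one primary and one non-primary member. Its
    orientation is consistent with downstream collateral mutagenesis when
    an upper-strand lesion has its primary as the 3' member (collateral
    5'), or a lower-strand lesion has its primary as the 5' member.
    """
    scheme = get_scheme(scheme)
    c1 = classify_primary(pair.first, scheme, genome)
    c2 = classify_primary(pair.second, scheme, genome)
    labels = (c1.label, c2.label)
    if labels == ("primary", "primary"):
        category = "both_primary"
    elif "primary" in labels:
        category = "proper"
    else:
        category = "both_non_primary"
    consistent = None
    primary_is_first = None
    strand = None
    if category == "proper":
        primary_is_first = c1.label == "primary"
        strand = (c1 if primary_is_first else c2).lesion_strand
        if strand == "upper":
            consistent = not primary_is_first  # primary should be the 3' member
        else:
            consistent = primary_is_first
    return PairCategory(pair, c1.label, c2.label, category, consistent, primary_is_first, strand)


def categorize_pairs(pairs: Iterable[MutationPair], scheme, genome: Genome) -> list[PairCategory]:
    return [categorize_pair(p, scheme, genome) for p in pairs]


# ---------------------------------------------------------------------------
# orientation asymmetry


def orientation_asymmetry(pairs: Iterable[MutationPair], scheme, genome: Genome) -> dict:
    """Association of primary allele classes with position inside pairs.

    Counts how often each primary allele class occurs as the 5' vs the 3'
    member over all primary mutations in pairs. Reports a two-sided
    Fisher's exact test on the 2x2 collapse (upper-lesion vs lower-lesion
    classes x position) and a chi-square test on the full class x position
    table. Both-primary pairs contribute both members; pairs whose two
    primaries imply conflicting lesion strands are skipped for the 2x2
    statistics.
    """
    scheme = get_scheme(scheme)
    pairs = list(pairs)
    if not pairs:
        raise ValueError("orientation_asymmetry needs at least one pair")
    import pandas as pd

    rows = []
    for p in pairs:
        for member, position in ((p.first, "5prime"), (p.second, "3prime")):
            c = classify_primary(member, scheme, genome)
            if c.label == "primary":
                rows.append(
                    {
                        "change": f"{member.ref}>{member.alt}",
                        "lesion_strand": c.lesion_strand,
                        "position": position,
                    }
                )
    if not rows:
        raise ValueError("no primary mutations among the supplied pairs")
    df = pd.DataFrame(rows)
    full = pd.crosstab(df["change"], df["position"]).reindex(columns=["5prime", "3prime"], fill_value=0)
    collapse = pd.crosstab(df["lesion_strand"], df["position"]).reindex(
        index=["upper", "lower"], columns=["5prime", "3prime"], fill_value=0
    )
    table = collapse.to_numpy()
    if table.sum() and table.shape == (2, 2):
        fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    else:
        fisher_p = float("nan")
    full_arr = full.to_numpy()
    chi2_p = float("nan")
    if full_arr.shape[0] >= 2 and full_arr.sum(axis=0).all() and full_arr.sum(axis=1).all():
        chi2_p = float(stats.chi2_contingency(full_arr)[1])
    return {
        "full_table": full,
        "collapse_2x2": collapse,
        "fisher_p": fisher_p,
        "full_table_chi2_p": chi2_p,
    }


# ---------------------------------------------------------------------------
# slippage


def _collateral_neighbor(cat: PairCategory, genome: Genome) -> Optional[str]:
    """Base adjacent to the collateral on the side facing the primary."""
    p = cat.pair
    if cat.primary_is_first:
        collateral, side = p.second, -1  # primary is 5' -> neighbour at pos-1
    else:
        collateral, side = p.first, +1
    npos = collateral.pos + side
    if npos < 1 or npos > genome.length(collateral.chrom):
        return None
    base = genome.base(collateral.chrom, npos)
    return base if base in "ACGT" else None


def slippage_analysis(proper_pairs: Iterable[PairCategory], genome: Genome) -> dict:
    """Test whether collateral variants copy the lesion-side neighbour base.

    For each proper pair the collateral's immediate neighbour on the side
    facing the primary mutation (upper-strand coordinates) is compared with
    the collateral's variant allele. Random base misinsertion would copy
    the neighbour one time in three, so (n_copy, n_noncopy) is compared
    with the 1:2 expectation at equal total by a two-sided Fisher's exact
    test.
    """
    n_copy = n_noncopy = n_excluded = 0
    for cat in proper_pairs:
        if cat.category != "proper":
            continue
        base = _collateral_neighbor(cat, genome)
        if base is None:
            n_excluded += 1
            continue
        collateral = cat.pair.second if cat.primary_is_first else cat.pair.first
        if collateral.alt == base:
            n_copy += 1
        else:
            n_noncopy += 1
    n = n_copy + n_noncopy
    if n == 0:
        return {
            "n_copy": 0,
            "n_noncopy": 0,
            "copy_fraction": None,
            "fisher_p": None,
            "n_excluded": n_excluded,
        }
    exp_copy = round(n / 3)
    table = [[n_copy, n_noncopy], [exp_copy, n - exp_copy]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return {
        "n_copy": n_copy,
        "n_noncopy": n_noncopy,
        "copy_fraction": n_copy / n,
        "fisher_p": p,
        "n_excluded": n_excluded,
    }


# ---------------------------------------------------------------------------
# simulated collateral null (neighbour-base distribution)


def simulate_collateral_null(
    solitary_primaries: Iterable[MutationRecord],
    distance_distribution: Iterable[int],
    scheme,
    genome: Genome,
    set_size: int,
    n_runs: int = 100,
    seed: int = 0,
) -> dict:
    """Neighbour-base distribution for virtual collaterals around primaries.

    Each run samples ``set_size`` solitary primary mutations with
    replacement, places a virtual collateral at an empirically sampled
    distance on the lesion-appropriate side (5' of upper-strand lesions,
    3' of lower-strand lesions) and records the virtual collateral's
    neighbour base facing the primary. Returns per-base mean and SD of the
    frequencies across runs.
    """
    scheme = get_scheme(scheme)
    primaries = [r for r in solitary_primaries]
    distances = np.asarray(list(distance_distribution), dtype=np.int64)
    if distances.size == 0:
        raise ValueError("empirical distance distribution is empty")
    if not primaries:
        raise ValueError("no solitary primaries supplied")
    strands = []
    for r in primaries:
        c = classify_primary(r, scheme, genome)
        strands.append(c.lesion_strand if c.label == "primary" else None)
    usable = [(r, s) for r, s in zip(primaries, strands) if s is not None]
    if not usable:
        raise ValueError("no classifiable primaries supplied")
    rng = np.random.default_rng(seed)
    freq = np.zeros((n_runs, 4))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for run in range(n_runs):
        counts = np.zeros(4)
        total = 0
        for _ in range(set_size):
            r, strand = usable[rng.integers(len(usable))]
            d = int(distances[rng.integers(distances.size)])
            if strand == "upper":
                cpos = r.pos - d  # collateral 5' of the lesion
                npos = cpos + 1  # neighbour toward the primary
            else:
                cpos = r.pos + d
                npos = cpos - 1
            if npos < 1 or npos > genome.length(r.chrom):
                continue
            base = genome.base(r.chrom, npos)
            if base in base_idx:
                counts[base_idx[base]] += 1
                total += 1
        if total:
            freq[run] = counts / total
    return {
        "bases": "ACGT",
        "mean": freq.mean(axis=0),
        "sd": freq.std(axis=0, ddof=1) if n_runs > 1 else np.zeros(4),
        "per_run": freq,
    }


def attribution_purity(treated_avg: float, mock_avg: float) -> float:
    """Fraction of primary-labelled mutations attributable to the treatment.

    ``1 - mock_avg / treated_avg`` where both are average per-genome counts
    of primary-class mutations in treated vs mock clones.
    """
    if treated_avg <= 0:
        raise ValueError("treated average must be positive")
    if mock_avg < 0:
        raise ValueError("mock average must be non-negative")
    return 1.0 - mock_avg / treated_avg
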