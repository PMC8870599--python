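"""Forward simulation of translesion-synthesis collateral mutagenesis.

The generator plants lesions at dinucleotide motifs (GG/AG for a
cisplatin-like treatment) on either strand of a random genome. Each lesion
is bypassed: with probability ``p_primary_error`` the bypass is mutagenic
and leaves a primary mutation in a treatment-typical triplet class;
independently, with probability ``p_collateral`` the translesion
polymerase also misinserts on undamaged template, leaving a collateral
substitution 2-100 bp away on the replication-downstream side (5' of
upper-strand lesions, 3' of lower-strand ones; flipped with
``p_upstream_switch``). With probability ``p_slip`` the collateral variant
copies its neighbour base on the lesion-facing side (polymerase slippage).
Collaterals next to error-free bypasses become solitary collateral
mutations beside an invisible lesion. Independent background SBSs and
short indels are sprinkled uniformly, and every record carries the QC
metrics the post-filters expect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .genome import Genome
from .records import MutationRecord

log = logging.getLogger(__name__)

BASES = "ACGT"


def truncated_geometric(p: float = 0.2, lo: int = 2, hi: int = 100) -> np.ndarray:
    """Probability vector over distances lo..hi with geometric decay.

    The default (p=0.2) puts ~87% of its mass at <= 10 bp, matching the
    heavy short-range concentration of observed collateral distances.
    """
    k = np.arange(lo, hi + 1)
    w = (1 - p) ** (k - lo)
    return w / w.sum()


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic collateral-mutagenesis model."""

    genome_length: int = 5_000_000
    gc_content: float = 0.45
    n_clones: int = 20
    n_lesions_per_clone: int = 200
    lesion_motifs: tuple[str, ...] = ("GG", "AG")
    p_lesion_upper: float = 0.5
    p_primary_error: float = 0.3
    p_collateral: float = 0.05
    distance_lo: int = 2
    distance_hi: int = 100
    distance_geom_p: float = 0.2
    distance_probs: Optional[np.ndarray] = None  # explicit distribution over lo..hi
    p_slip: float = 0.5
    p_upstream_switch: float = 0.2
    background_rate: float = 2e-5
    indel_rate: float = 2e-6
    seed: int = 0
    chrom: str = "chr1"

    def distance_distribution(self) -> np.ndarray:
        if self.distance_probs is not None:
            probs = np.asarray(self.distance_probs, dtype=float)
            if probs.size != self.distance_hi - self.distance_lo + 1:
                raise ValueError("distance_probs must cover lo..hi")
            return probs / probs.sum()
        return truncated_geometric(self.distance_geom_p, self.distance_lo, self.distance_hi)


@dataclass
class SimulationResult:
    records: list[MutationRecord]
    truth: pd.DataFrame
    genome: Genome
    per_clone: pd.DataFrame
    config: SyntheticConfig


def generate_genome(length: int, gc: float, seed: int, chrom: str = "chr1") -> Genome:
    """Random i.i.d. genome at the requested GC content."""
    if length < 1000:
        raise ValueError("genome length must be >= 1 kb")
    if not 0 <= gc <= 1:
        raise ValueError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    seq = "".join(np.array(list(BASES))[rng.choice(4, size=length, p=probs)])
    return Genome({chrom: seq})


def _motif_sites(seq: str, motifs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """1-based start positions of upper- and lower-strand motif instances.

    A motif on the lower strand appears on the upper strand as its reverse
    complement; the returned start is the upper-strand start of that
    reverse complement.
    """
    from .genome import revcomp

    upper, lower = [], []
    for m in motifs:
        rc = revcomp(m)
        i = seq.find(m)
        while i != -1:
            upper.append(i + 1)
            i = seq.find(m, i + 1)
        i = seq.find(rc)
        while i != -1:
            lower.append(i + 1)
            i = seq.find(rc, i + 1)
    return np.array(sorted(upper)), np.array(sorted(lower))


_DEFAULT_METRICS = {
    "mean_mapq": 60.0,
    "coverage_fluct": 0.0,
    "support_other_samples": 0.0,
    "reads_with_both_variants": 5.0,
    "ref_reads": 15.0,
    "alt_reads": 15.0,
}


def _qc_metrics(rng) -> dict:
    m = dict(_DEFAULT_METRICS)
    m["mean_mapq"] = float(60 - rng.integers(0, 10))
    m["ref_reads"] = float(rng.integers(10, 25))
    m["alt_reads"] = float(rng.integers(10, 25))
    return m


def simulate_clones(config: SyntheticConfig, genome: Optional[Genome] = None) -> SimulationResult:
    """Simulate mutation catalogues with full ground truth.

    Returns the catalogue records (sorted), a per-mutation truth table
    whose labels partition the catalogue (primary / collateral_paired /
    collateral_solitary / background / background_indel), the genome and a
    per-clone summary.
    """
    rng = np.random.default_rng(config.seed)
    if genome is None:
        genome = generate_genome(
            config.genome_length, config.gc_content, int(rng.integers(2**31 - 1)), config.chrom
        )
    chrom = genome.chroms[0]
    seq = genome.sequence(chrom)
    upper_sites, lower_sites = _motif_sites(seq, config.lesion_motifs)
    if len(upper_sites) < config.n_lesions_per_clone or len(lower_sites) < config.n_lesions_per_clone:
        raise ValueError(
            f"not enough {'/'.join(config.lesion_motifs)} motif sites "
            f"({len(upper_sites)}+{len(lower_sites)}) for {config.n_lesions_per_clone} lesions; "
            "use a longer genome"
        )
    distances = np.arange(config.distance_lo, config.distance_hi + 1)
    dist_probs = config.distance_distribution()

    records: list[MutationRecord] = []
    truth_rows: list[dict] = []
    clone_rows: list[dict] = []

    for ci in range(config.n_clones):
        sample = f"clone{ci:02d}"
        used: set[int] = set()
        n_primary = n_cpaired = n_csolo = n_slip = n_canonical = n_coll = 0

        def place(pos: int) -> bool:
            if pos in used or pos < 1 or pos > len(seq) or seq[pos - 1] == "N":
                return False
            used.add(pos)
            return True

        def emit(pos, ref, alt, label, **extra):
            records.append(
                MutationRecord(sample, chrom, pos, ref, alt, metrics=_qc_metrics(rng))
            )
            truth_rows.append(
                {"sample": sample, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                 "label": label, **extra}
            )

        # lesions
        for _ in range(config.n_lesions_per_clone):
            on_upper = rng.random() < config.p_lesion_upper
            sites = upper_sites if on_upper else lower_sites
            start = int(sites[rng.integers(len(sites))])
            motif = seq[start - 1 : start + 1]
            # choose the damaged base whose miscoding yields a scheme-matching
            # primary; anchor = upper-strand position of that base
            if on_upper:
                if motif[0] == "A" and rng.random() < 0.5:
                    anchor, ref, alt = start, "A", "T"  # C[T>A]N after normalisation
                else:
                    anchor, ref, alt = start + 1, motif[1], "T"  # G>T, N[C>A]Y
            else:
                # lower-strand motif: upper strand shows the complement
                if seq[start] == "T" and rng.random() < 0.5:
                    anchor, ref, alt = start + 1, "T", "A"
                else:
                    anchor, ref, alt = start, seq[start - 1], "A"  # C>A
            if (on_upper and ref not in ("G", "A")) or (not on_upper and ref not in ("C", "T")):
                continue  # motif truncated by N or edge; skip lesion
            has_primary = rng.random() < config.p_primary_error
            has_collateral = rng.random() < config.p_collateral
            strand = "upper" if on_upper else "lower"
            if has_primary:
                if not place(anchor):
                    continue
                emit(anchor, ref, alt, "primary", lesion_pos=anchor, lesion_strand=strand)
                n_primary += 1
            if has_collateral:
                placed = False
                # slip and orientation are drawn once; only the distance is
                # resampled on placement failure, so the realised copy
                # fraction and orientation consistency match p_slip and
                # 1 - p_upstream_switch exactly
                slip = rng.random() < config.p_slip
                downstream = rng.random() >= config.p_upstream_switch
                for _try in range(100):
                    d = int(rng.choice(distances, p=dist_probs))
                    # canonical: collateral 5' of upper-strand lesions, 3' of lower
                    if (strand == "upper") == downstream:
                        cpos = anchor - d
                        nb_pos = cpos + 1  # neighbour facing the lesion
                    else:
                        cpos = anchor + d
                        nb_pos = cpos - 1
                    if cpos < 2 or cpos > len(seq) - 1 or cpos in used:
                        continue
                    cref = seq[cpos - 1]
                    nb = seq[nb_pos - 1]
                    if cref not in BASES or nb not in BASES:
                        continue
                    if slip:
                        if nb == cref:
                            continue  # slippage invisible here; resample distance
                        calt = nb
                    else:
                        choices = [b for b in BASES if b not in (cref, nb)]
                        calt = choices[rng.integers(len(choices))]
                    if not place(cpos):
                        continue
                    label = "collateral_paired" if has_primary else "collateral_solitary"
                    emit(cpos, cref, calt, label, lesion_pos=anchor, lesion_strand=strand,
                         distance=d, slipped=slip, canonical_side=downstream)
                    n_coll += 1
                    n_slip += int(slip)
                    n_canonical += int(downstream)
                    if has_primary:
                        n_cpaired += 1
                    else:
                        n_csolo += 1
                    placed = True
                    break
                if not placed:
                    log.debug("collateral placement failed after 100 tries (%s)", sample)

        # background SBSs
        n_bg = rng.poisson(config.background_rate * len(seq))
        for _ in range(n_bg):
            for _try in range(100):
                pos = int(rng.integers(1, len(seq) + 1))
                ref = seq[pos - 1]
                if ref not in BASES or not place(pos):
                    continue
                alt = BASES[rng.integers(4)]
                while alt == ref:
                    alt = BASES[rng.integers(4)]
                emit(pos, ref, alt, "background")
                break

        # background short indels
        n_ind = rng.poisson(config.indel_rate * len(seq))
        for _ in range(n_ind):
            for _try in range(100):
                pos = int(rng.integers(2, len(seq) - 4))
                if seq[pos - 1] not in BASES or not place(pos):
                    continue
                ln = int(rng.integers(1, 4))
                if rng.random() < 0.5 and all(b in BASES for b in seq[pos - 1 : pos + ln]):
                    ref = seq[pos - 1 : pos + ln]  # deletion of ln bases after pos
                    alt = ref[0]
                else:
                    ins = "".join(BASES[rng.integers(4)] for _ in range(ln))
                    ref = seq[pos - 1]
                    alt = ref + ins
                emit(pos, ref, alt, "background_indel")
                break

        clone_rows.append(
            {
                "sample": sample,
                "n_primary": n_primary,
                "n_collateral_paired": n_cpaired,
                "n_collateral_solitary": n_csolo,
                "n_background": int(n_bg),
                "n_indels": int(n_ind),
                "true_copy_fraction": (n_slip / n_coll) if n_coll else np.nan,
                "true_orientation_consistency": (n_canonical / n_coll) if n_coll else np.nan,
            }
        )

    truth = pd.DataFrame(truth_rows)
    per_clone = pd.DataFrame(clone_rows).set_index("sample")
    cmr_truth = _true_cmr_per_clone(truth)
    per_clone = per_clone.join(cmr_truth)
    records.sort(key=MutationRecord.sort_key)
    return SimulationResult(records, truth, genome, per_clone, config)


def _true_cmr_per_clone(truth: pd.DataFrame) -> pd.DataFrame:
    """Realised close-mutation accounting of the generated catalogues.

    Mirrors the analysis definition: distance-1 runs collapse into double
    substitutions and drop out; remaining SBSs are close when another one
    lies within 100 bp. Returns per-clone n_close / n_after_merge / ratio.
    """
    rows = {}
    if truth.empty:
        return pd.DataFrame(columns=["true_n_close", "true_n_total", "true_cmr"])
    sbs = truth[~truth["label"].str.contains("indel")]
    for sample, sub in sbs.groupby("sample"):
        pos = np.sort(sub["pos"].to_numpy())
        if pos.size >= 2:
            d = np.diff(pos)
            adj = np.zeros(pos.size, dtype=bool)
            adj[:-1] |= d == 1
            adj[1:] |= d == 1
            pos = pos[~adj]
        close = np.zeros(pos.size, dtype=bool)
        if pos.size >= 2:
            d = np.diff(pos)
            hit = d <= 100
            close[:-1] |= hit
            close[1:] |= hit
        rows[sample] = {
            "true_n_close": int(close.sum()),
            "true_n_total": int(pos.size),
            "true_cmr": float(close.sum() / pos.size) if pos.size else np.nan,
        }
    return pd.DataFrame(rows).T


def recovery_report(result: SimulationResult, scheme="cisplatin_dt40") -> pd.DataFrame:
    """True vs pipeline-estimated parameters with 95% binomial CIs."""
    from statsmodels.stats.proportion import proportion_confint

    from .classify import categorize_pairs, slippage_analysis
    from .pairs import close_mutation_ratio, extract_pairs, find_clusters, merge_dbs

    recs = [r for r in result.records if r.kind == "SBS"]
    merged, _ = merge_dbs(recs)
    stats_cmr = close_mutation_ratio(merged)
    cats = categorize_pairs(stats_cmr["pairs"], scheme, result.genome)
    proper = [c for c in cats if c.category == "proper"]
    slip = slippage_analysis(proper, result.genome)
    n_consistent = sum(1 for c in proper if c.orientation_consistent)

    rows = []

    def add(param, true, k, n):
        est = k / n if n else np.nan
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson") if n else (np.nan, np.nan)
        rows.append(
            {"parameter": param, "true": true, "estimate": est,
             "ci_low": lo, "ci_high": hi, "n": n,
             "covered": bool(lo <= true <= hi) if n else False}
        )

    pooled_true_cmr = float(
        result.per_clone["true_n_close"].sum() / result.per_clone["true_n_total"].sum()
    )
    add("cmr", pooled_true_cmr, stats_cmr["n_close"], stats_cmr["n_total"])
    n_slip_total = slip["n_copy"] + slip["n_noncopy"]
    add("p_slip", result.config.p_slip, slip["n_copy"], n_slip_total)
    add(
        "orientation_consistency",
        1 - result.config.p_upstream_switch,
        n_consistent,
        len(proper),
    )
    return pd.DataFrame(rows).set_index("parameter")
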