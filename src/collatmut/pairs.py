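"""Close mutation pairs, clusters and the close mutation ratio (CMR).

Close mutations are same-sample substitutions on one chromosome within a
distance threshold (default 100 bp, inclusive). Directly adjacent events
(distance 1) are first collapsed into double/multi-nucleotide substitutions
and removed from all pair statistics, since those arise in a single
mutagenic step. Clusters are built by single-linkage chaining; size-2
clusters are the close pairs, larger clusters are reported separately and
omitted from pair-level analyses while their members still count as close
mutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .records import MutationRecord, group_by_sample_chrom, sort_records

DEFAULT_MAX_DIST = 100


@dataclass
class MutationCluster:
    """Chained group of >= 2 same-sample, same-chromosome mutations."""

    sample_id: str
    chrom: str
    members: list[MutationRecord]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def span(self) -> tuple[int, int]:
        return self.members[0].pos, self.members[-1].pos


@dataclass
class MutationPair:
    """A size-2 cluster; ``first`` is the 5' member (smaller position)."""

    first: MutationRecord
    second: MutationRecord

    @property
    def distance(self) -> int:
        return self.second.pos - self.first.pos

    @property
    def sample_id(self) -> str:
        return self.first.sample_id

    @property
    def chrom(self) -> str:
        return self.first.chrom


@dataclass
class NullConfig:
    """Configuration of the random-position expected-CMR null."""

    n_sims: int = 100
    seed: int = 0
    eligible_regions: Sequence[tuple[str, int, int]] = ()
    strand_correction: float = 2.0
    max_dist: int = DEFAULT_MAX_DIST


# ---------------------------------------------------------------------------
# distances and rainfall


def nearest_neighbor_distances(records: Iterable[MutationRecord]):
    """Per-record distances to the nearest 5' and 3' same-sample mutations.

    Returns a list of ``(record, dist5, dist3)`` with ``None`` on a side
    with no neighbour on the same chromosome. Drives 1D and 2D rainfall
    exports.
    """
    out = []
    for (_, _), recs in group_by_sample_chrom(records).items():
        for i, r in enumerate(recs):
            d5 = r.pos - recs[i - 1].pos if i > 0 else None
            d3 = recs[i + 1].pos - r.pos if i < len(recs) - 1 else None
            out.append((r, d5, d3))
    return out


def rainfall_table(records: Iterable[MutationRecord]):
    """Rainfall export: one row per record with 5'/3' neighbour distances."""
    import pandas as pd

    rows = [
        {
            "sample": r.sample_id,
            "chrom": r.chrom,
            "pos": r.pos,
            "ref": r.ref,
            "alt": r.alt,
            "dist5": d5,
            "dist3": d3,
        }
        for r, d5, d3 in nearest_neighbor_distances(records)
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# DBS merging


def merge_dbs(records: Iterable[MutationRecord]) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Collapse runs of directly adjacent SBSs into multi-nucleotide events.

    Returns ``(sbs_remaining, dbs_events)``: runs of >= 2 adjacent SBSs in
    one sample become a single flagged event (kind ``DBS``) whose ref/alt
    are the concatenated alleles; these are excluded from all close-pair
    statistics. Non-SBS records pass through untouched in the first list.
    """
    kept: list[MutationRecord] = []
    dbs: list[MutationRecord] = []
    for (sample, chrom), recs in group_by_sample_chrom(records).items():
        sbs = [r for r in recs if r.kind == "SBS"]
        kept.extend(r for r in recs if r.kind != "SBS")
        i = 0
        while i < len(sbs):
            j = i
            while j + 1 < len(sbs) and sbs[j + 1].pos == sbs[j].pos + 1:
                j += 1
            if j > i:
                run = sbs[i : j + 1]
                dbs.append(
                    MutationRecord(
                        sample_id=sample,
                        chrom=chrom,
                        pos=run[0].pos,
                        ref="".join(r.ref for r in run),
                        alt="".join(r.alt for r in run),
                        kind="DBS",
                        metrics={"n_bases": float(len(run))},
                    )
                )
            else:
                kept.append(sbs[i])
            i = j + 1
    return sort_records(kept), sort_records(dbs)


# ---------------------------------------------------------------------------
# clusters, pairs, CMR


def find_clusters(
    records: Iterable[MutationRecord], max_dist: int = DEFAULT_MAX_DIST
) -> list[MutationCluster]:
    """Single-linkage chaining of same-sample mutations within ``max_dist``.

    Input should already be DBS-merged. Consecutive mutations at most
    ``max_dist`` bp apart join the same cluster; singletons are dropped.
    """
    clusters: list[MutationCluster] = []
    for (sample, chrom), recs in group_by_sample_chrom(records).items():
        current = [recs[0]] if recs else []
        for r in recs[1:]:
            if r.pos - current[-1].pos <= max_dist:
                current.append(r)
            else:
                if len(current) >= 2:
                    clusters.append(MutationCluster(sample, chrom, current))
                current = [r]
        if len(current) >= 2:
            clusters.append(MutationCluster(sample, chrom, current))
    return clusters


def extract_pairs(
    clusters: Iterable[MutationCluster],
) -> tuple[list[MutationPair], list[MutationCluster]]:
    """Split clusters into close pairs (size 2) and omitted larger clusters."""
    pairs: list[MutationPair] = []
    omitted: list[MutationCluster] = []
    for c in clusters:
        if c.size == 2:
            pairs.append(MutationPair(c.members[0], c.members[1]))
        else:
            omitted.append(c)
    return pairs, omitted


def close_mutation_ratio(
    records: Iterable[MutationRecord], max_dist: int = DEFAULT_MAX_DIST
) -> dict:
    """Close mutation ratio: fraction of SBSs that belong to a close cluster.

    Expects DBS-merged records (pool clones of one group for a group-level
    CMR). Returns ``n_close``, ``n_total``, ``cmr`` (None when there are no
    mutations), plus pair/omitted-cluster accounting.
    """
    records = [r for r in records if r.kind == "SBS"]
    clusters = find_clusters(records, max_dist=max_dist)
    pairs, omitted = extract_pairs(clusters)
    n_close = sum(c.size for c in clusters)
    n_total = len(records)
    return {
        "n_close": n_close,
        "n_total": n_total,
        "cmr": (n_close / n_total) if n_total else None,
        "n_pairs": len(pairs),
        "omitted_clusters": omitted,
        "pairs": pairs,
    }


# ---------------------------------------------------------------------------
# expected CMR null


def _n_close_positions(positions: np.ndarray, max_dist: int) -> int:
    """Number of positions with another position within ``max_dist``."""
    if positions.size < 2:
        return 0
    pos = np.sort(positions)
    d = np.diff(pos)
    close = np.zeros(pos.size, dtype=bool)
    hit = d <= max_dist
    close[:-1] |= hit
    close[1:] |= hit
    return int(close.sum())


def expected_cmr(n_mut: int, null_cfg: NullConfig) -> dict:
    """Expected CMR from uniformly resampled genomic positions.

    Each simulation draws ``n_mut`` positions uniformly from the eligible
    regions, computes the fraction with another draw within ``max_dist``
    and divides by ``strand_correction`` (default 2) to count only
    same-strand coincidences. Returns mean, SD and the per-simulation
    values.
    """
    regions = list(null_cfg.eligible_regions)
    if not regions:
        raise ValueError("expected_cmr requires non-empty eligible regions")
    lengths = np.array([end - start + 1 for _, start, end in regions], dtype=np.int64)
    total = int(lengths.sum())
    if n_mut > total:
        raise ValueError(f"n_mut={n_mut} exceeds eligible region capacity {total}")
    if null_cfg.strand_correction <= 0:
        raise ValueError("strand_correction must be > 0")
    rng = np.random.default_rng(null_cfg.seed)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    values = np.empty(null_cfg.n_sims)
    for s in range(null_cfg.n_sims):
        flat = rng.integers(0, total, size=n_mut)
        # positions on different chromosomes must not pair: bucket per chrom
        region_idx = np.searchsorted(offsets, flat, side="right") - 1
        pos_by_chrom: dict[str, list[int]] = {}
        for f, ri in zip(flat, region_idx):
            chrom, start, _ = regions[ri]
            pos_by_chrom.setdefault(chrom, []).append(start + int(f - offsets[ri]))
        n_close = 0
        for ps in pos_by_chrom.values():
            n_close += _n_close_positions(np.array(ps, dtype=np.int64), null_cfg.max_dist)
        values[s] = (n_close / n_mut) / null_cfg.strand_correction
    return {"mean": float(values.mean()), "sd": float(values.std(ddof=1)) if null_cfg.n_sims > 1 else 0.0, "values": values}


# ---------------------------------------------------------------------------
# mixed SBS-indel pairs


def mixed_pairs(
    sbs_records: Iterable[MutationRecord],
    indel_records: Iterable[MutationRecord],
    max_dist: int = DEFAULT_MAX_DIST,
) -> dict:
    """Close pairs where exactly one member is a 1-20 bp indel.

    Applies the same distance threshold and cluster-omission rules as SBS
    pairs over the merged catalogue. Indels flagged as long (>20 bp) are
    excluded. The ratio mirrors CMR: mixed-close members over the combined
    SBS+indel total.
    """
    sbs = [r for r in sbs_records if r.kind == "SBS"]
    indels = [
        r
        for r in indel_records
        if r.kind in ("INS", "DEL") and not r.is_long_indel and not r.metrics.get("long_indel")
    ]
    merged = sort_records(sbs + indels)
    clusters = find_clusters(merged, max_dist=max_dist)
    pairs, omitted = extract_pairs(clusters)
    mixed = [
        p
        for p in pairs
        if (p.first.kind == "SBS") != (p.second.kind == "SBS")
    ]
    n_total = len(sbs) + len(indels)
    n_mixed_members = 2 * len(mixed)
    return {
        "pairs": mixed,
        "n_mixed_members": n_mixed_members,
        "n_total": n_total,
        "ratio": (n_mixed_members / n_total) if n_total else None,
        "omitted_clusters": omitted,
    }


# ---------------------------------------------------------------------------
# post-filters


class MissingMetricError(KeyError):
    pass


def _require(record: MutationRecord, name: str, mode: str) -> float:
    v = record.metrics.get(name)
    if v is None:
        raise MissingMetricError(f"metric column {name!r} required for postfilter mode {mode!r}")
    return v


def postfilter(
    records: Iterable[MutationRecord], mode: str = "default", alpha: float = 0.05
) -> tuple[list[MutationRecord], list[tuple[MutationRecord, str]]]:
    """Metric-based removal of likely artefactual calls.

    ``default`` mode drops records with mean mapping quality < 40 or with
    the coverage-fluctuation flag set (strong coverage change on both sides
    of a 200 bp window, precomputed upstream). ``melanoma`` mode instead
    requires mean mapping quality > 41, fewer than 2 supporting reads in
    any other sample, at least 3 reads carrying both variants of a
    candidate pair, and a non-significant allele-frequency difference
    between candidate pair members (Fisher's exact test on ref/alt read
    counts). Returns (kept, rejection log of (record, rule)). Idempotent.
    """
    records = sort_records(records)
    rejected: dict[int, str] = {}
    if mode == "default":
        for i, r in enumerate(records):
            if _require(r, "mean_mapq", mode) < 40:
                rejected[i] = "mean_mapq<40"
            elif r.metrics.get("coverage_fluct") is not None and r.metrics["coverage_fluct"] >= 1:
                rejected[i] = "coverage_fluctuation"
    elif mode == "melanoma":
        for i, r in enumerate(records):
            if _require(r, "mean_mapq", mode) <= 41:
                rejected[i] = "mean_mapq<=41"
            elif _require(r, "support_other_samples", mode) >= 2:
                rejected[i] = "support_other_samples>=2"
            elif _require(r, "reads_with_both_variants", mode) < 3:
                rejected[i] = "reads_with_both_variants<3"
        # allele-frequency consistency of candidate close pairs
        for i in range(len(records) - 1):
            a, b = records[i], records[i + 1]
            if i in rejected or (i + 1) in rejected:
                continue
            if a.sample_id != b.sample_id or a.chrom != b.chrom:
                continue
            if b.pos - a.pos > DEFAULT_MAX_DIST:
                continue
            if all(
                m in r.metrics for r in (a, b) for m in ("ref_reads", "alt_reads")
            ):
                table = [
                    [int(a.metrics["ref_reads"]), int(a.metrics["alt_reads"])],
                    [int(b.metrics["ref_reads"]), int(b.metrics["alt_reads"])],
                ]
                p = stats.fisher_exact(table, alternative="two-sided")[1]
                if p <= alpha:
                    rejected[i] = "allele_frequency_fisher"
                    rejected[i + 1] = "allele_frequency_fisher"
    else:
        raise ValueError(f"unknown postfilter mode {mode!r}")
    kept = [r for i, r in enumerate(records) if i not in rejected]
    log = [(records[i], rule) for i, rule in sorted(rejected.items())]
    return kept, log


# ---------------------------------------------------------------------------
# proportion test


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided two-sample proportion z-test (pooled variance).

    Equivalent to the chi-square test without continuity correction on the
    2x2 table (z^2 = chi^2). Returns the p-value; identical proportions
    give p = 1 exactly.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both sample sizes must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    p1, p2 = k1 / n1, k2 / n2
    if p1 == p2:
        return 1.0
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 1.0
    z = (p1 - p2) / se
    return float(2 * stats.norm.sf(abs(z)))
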