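"""Pair/solitary-split mutational-signature extraction and refitting.

Spectra (samples x 96 trinucleotide channels) are factorised by
non-negative matrix factorisation into signature profiles (96 x k, columns
summing to one) and exposures (k x samples, in mutation counts). To expose
a collateral-mutation-specific component, catalogues are first split:
solitary mutations stay one row per sample, while mutations in close pairs
are pooled per genotype-treatment group and treated as extra samples.

Rank selection follows the consensus-clustering approach: the cophenetic
correlation of the restart-consensus matrix together with the residual sum
of squares, choosing the largest rank before the first substantial
cophenetic drop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF as _SkNMF

from .catalog_io import CHANNELS_96, build_spectrum
from .genome import Genome
from .pairs import DEFAULT_MAX_DIST, find_clusters, merge_dbs
from .records import MutationRecord, group_by_sample


@dataclass
class SignatureModel:
    """Result of one NMF decomposition."""

    signatures: pd.DataFrame  # 96 x k, columns sum to 1
    exposures: pd.DataFrame  # k x samples, mutation counts
    rank: int
    rss: float
    n_starts: int
    seed: int

    def reconstruct(self) -> pd.DataFrame:
        """Reconstructed spectra, samples x 96."""
        return (self.signatures @ self.exposures).T


@dataclass
class SplitCatalog:
    """Solitary per-sample spectra plus pooled per-group pair spectra."""

    solitary: pd.DataFrame  # samples x 96
    pairs: pd.DataFrame  # groups x 96 (index "pairs:<group>")
    group_of_sample: dict[str, str]

    @property
    def combined(self) -> pd.DataFrame:
        return pd.concat([self.solitary, self.pairs])


def split_catalog(
    records: Iterable[MutationRecord],
    group_table: Mapping[str, str],
    genome: Genome,
    max_dist: int = DEFAULT_MAX_DIST,
) -> SplitCatalog:
    """Split catalogues into solitary and close-pair mutation spectra.

    Close-pair membership is decided per sample after DBS merging; paired
    (clustered) mutations are pooled across the samples of each group into
    one spectrum row per group. Row totals conserve the per-group count of
    annotatable SBSs.
    """
    by_sample = group_by_sample(records)
    missing = [s for s in by_sample if s not in group_table]
    if missing:
        raise KeyError(f"samples without a group assignment: {missing}")
    solitary_rows: list[MutationRecord] = []
    pair_rows: list[MutationRecord] = []
    for sample, recs in by_sample.items():
        sbs, _ = merge_dbs(recs)
        sbs = [r for r in sbs if r.kind == "SBS"]
        clustered = set()
        for c in find_clusters(sbs, max_dist=max_dist):
            for m in c.members:
                clustered.add(id(m))
        for r in sbs:
            (pair_rows if id(r) in clustered else solitary_rows).append(r)
    solitary = build_spectrum(solitary_rows, genome) if solitary_rows else pd.DataFrame(
        columns=list(CHANNELS_96), dtype=np.int64
    )
    solitary = solitary.reindex(sorted(by_sample), fill_value=0)
    solitary.index.name = "sample"
    groups = sorted(set(group_table[s] for s in by_sample))
    pair_mat = pd.DataFrame(
        0, index=[f"pairs:{g}" for g in groups], columns=list(CHANNELS_96), dtype=np.int64
    )
    if pair_rows:
        per_sample = build_spectrum(pair_rows, genome)
        for sample in per_sample.index:
            pair_mat.loc[f"pairs:{group_table[sample]}"] += per_sample.loc[sample]
    return SplitCatalog(solitary=solitary, pairs=pair_mat, group_of_sample=dict(group_table))


# ---------------------------------------------------------------------------
# NMF


def _single_nmf(X: np.ndarray, rank: int, seed: int):
    model = _SkNMF(
        n_components=rank,
        init="random",
        solver="mu",
        beta_loss="frobenius",
        tol=1e-6,
        max_iter=5000,
        random_state=seed,
    )
    W = model.fit_transform(X)  # samples x k
    H = model.components_  # k x 96
    rss = float(((X - W @ H) ** 2).sum())
    return W, H, rss


def nmf_decompose(
    spectra: pd.DataFrame, rank: int, n_starts: int = 50, seed: int = 0
) -> SignatureModel:
    """Frobenius NMF of a spectrum matrix, best of ``n_starts`` restarts.

    Signature columns are normalised to sum to one with exposures rescaled
    compensatingly, so exposures stay in mutation counts.
    """
    X = np.asarray(spectra, dtype=float)
    if X.min() < 0:
        raise ValueError("spectra must be nonnegative")
    if not X.any():
        raise ValueError("cannot factorise an all-zero matrix")
    if rank >= min(X.shape) and min(X.shape) > 1:
        raise ValueError(f"rank {rank} must be < min(dim) = {min(X.shape)}")
    rng = np.random.default_rng(seed)
    start_seeds = rng.integers(0, 2**31 - 1, size=n_starts)
    best = None
    for s in start_seeds:
        W, H, rss = _single_nmf(X, rank, int(s))
        if best is None or rss < best[2]:
            best = (W, H, rss)
    W, H, rss = best
    scale = H.sum(axis=1)  # per-component mass
    scale[scale == 0] = 1.0
    signatures = (H / scale[:, None]).T  # 96 x k, columns sum to 1
    exposures = W * scale[None, :]  # samples x k
    sig_df = pd.DataFrame(
        signatures, index=spectra.columns, columns=[f"S{i+1}" for i in range(rank)]
    )
    exp_df = pd.DataFrame(
        exposures.T, index=sig_df.columns, columns=spectra.index
    )
    return SignatureModel(sig_df, exp_df, rank, rss, n_starts, seed)


def _connectivity(W: np.ndarray) -> np.ndarray:
    assign = W.argmax(axis=1)
    return (assign[:, None] == assign[None, :]).astype(float)


def select_rank(
    spectra: pd.DataFrame,
    rank_range: Sequence[int],
    n_starts: int = 50,
    seed: int = 0,
    drop_threshold: float = 0.1,
    rss_improvement: float = 0.2,
) -> dict:
    """Per-rank cophenetic coefficient and RSS, with a recommendation.

    The cophenetic coefficient is computed Brunet-style from the consensus
    of sample connectivity matrices over restarts. Recommendation: the
    largest rank before the first cophenetic drop larger than
    ``drop_threshold``; when the consensus stays stable across the whole
    range (as happens with well-mixed exposures), the strongest elbow of
    the RSS curve (largest second difference of log RSS), which separates
    genuine components from the roughly geometric noise-absorption
    improvements beyond the true rank. Supply a range that brackets the
    candidate ranks; override by eye where the heuristic disagrees with
    the diagnostics.
    """
    X = np.asarray(spectra, dtype=float)
    n_samples = X.shape[0]
    rows = []
    rng = np.random.default_rng(seed)
    for rank in rank_range:
        start_seeds = rng.integers(0, 2**31 - 1, size=n_starts)
        consensus = np.zeros((n_samples, n_samples))
        best_rss = np.inf
        for s in start_seeds:
            W, H, rss = _single_nmf(X, rank, int(s))
            consensus += _connectivity(W)
            best_rss = min(best_rss, rss)
        consensus /= n_starts
        if rank == 1 or np.allclose(consensus, consensus[0, 0]):
            coph = 1.0
        else:
            dist = squareform(1.0 - consensus, checks=False)
            if not dist.any():
                coph = 1.0
            else:
                Z = linkage(dist, method="average")
                coph = float(cophenet(Z, dist)[0])
                if np.isnan(coph):
                    coph = 1.0
        rows.append({"rank": rank, "cophenetic": coph, "rss": best_rss})
    diag = pd.DataFrame(rows).set_index("rank")
    ranks = list(diag.index)
    recommended = None
    for i in range(len(ranks) - 1):
        if diag["cophenetic"].iloc[i] - diag["cophenetic"].iloc[i + 1] > drop_threshold:
            recommended = ranks[i]
            break
    if recommended is None:
        rss = np.maximum(diag["rss"].to_numpy(), 1e-300)
        if len(ranks) >= 3:
            dlog = -np.diff(np.log(rss))  # improvement entering each next rank
            elbow = np.diff(-dlog)  # second difference of log RSS
            recommended = ranks[int(np.argmax(elbow)) + 1]
        elif len(ranks) == 2:
            improved = (rss[0] - rss[1]) / rss[0] >= rss_improvement
            recommended = ranks[1] if improved else ranks[0]
        else:
            recommended = ranks[0]
    return {"diagnostics": diag, "recommended_rank": int(recommended)}


def cosine(profile_a, profile_b) -> float:
    """Cosine similarity of two nonnegative spectra/signatures."""
    a = np.asarray(profile_a, dtype=float).ravel()
    b = np.asarray(profile_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("profiles must have the same length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def refit_exposures(spectrum, fixed_signatures: pd.DataFrame) -> pd.Series:
    """Nonnegative least-squares exposures of a spectrum to fixed signatures.

    ``fixed_signatures`` is 96 x k with column-normalised profiles;
    exposures come back in mutation counts.
    """
    A = np.asarray(fixed_signatures, dtype=float)
    y = np.asarray(spectrum, dtype=float).ravel()
    coef, _ = nnls(A, y)
    return pd.Series(coef, index=fixed_signatures.columns)


def refit_exposures_matrix(spectra: pd.DataFrame, fixed_signatures: pd.DataFrame) -> pd.DataFrame:
    """Refit every row of a spectrum matrix; returns k x samples."""
    out = {s: refit_exposures(spectra.loc[s], fixed_signatures) for s in spectra.index}
    return pd.DataFrame(out)


def relative_rmsd(observed, reconstructed) -> float:
    """Per-sample reconstruction diagnostic.

    Root of the mean over channels of squared differences between the
    reconstructed and observed spectrum, normalised by the sample's total
    mutation count.
    """
    obs = np.asarray(observed, dtype=float).ravel()
    rec = np.asarray(reconstructed, dtype=float).ravel()
    if obs.shape != rec.shape:
        raise ValueError("matched dimensions required")
    total = obs.sum()
    if total == 0:
        raise ValueError("relative RMSD undefined for an empty spectrum")
    return float(np.sqrt(np.mean((obs - rec) ** 2)) / total)
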