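"""Macroevolutionary bioregionalization from clade × region species counts.

Pipeline: Hellinger-transform the clade rows (down-weighting species-rich
clades), compute Morisita-Horn dissimilarities between the 13 regional
assemblages, embed the dissimilarity matrix with classical metric MDS, and
run seeded K-means over candidate k, choosing k by the elbow (second
difference of the within-cluster sum of squares).  Clades are then assigned
to the cluster holding >60% of their species, otherwise labelled "mixed".

A config flag allows the Morisita-Horn step to run on raw counts instead of
the Hellinger-transformed matrix; both readings of the composition are
runnable (the transformed composition is the default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .trees import REGIONS

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceMatrix",
    "RegionClustering",
    "CladeAssignment",
    "hellinger_rows",
    "morisita_horn",
    "classical_mds",
    "embed_and_cluster",
    "elbow_choose_k",
    "assign_clades",
    "cluster_regions",
]


@dataclass(frozen=True)
class AbundanceMatrix:
    """Clade × region species counts (non-negative integers)."""

    counts: pd.DataFrame  # index = clade ids, columns = region names

    def __post_init__(self):
        df = self.counts
        if df.ndim != 2 or df.shape[1] < 2:
            raise ValueError("need a clade x region table")
        arr = df.to_numpy()
        if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
            raise ValueError("entries must be non-negative integers")

    @classmethod
    def from_csv(cls, path) -> "AbundanceMatrix":
        df = pd.read_csv(path, index_col=0)
        missing = set(REGIONS) - set(df.columns)
        if missing:
            raise ValueError(f"missing region columns: {sorted(missing)}")
        return cls(counts=df[list(REGIONS)])

    @property
    def regions(self) -> list[str]:
        return list(self.counts.columns)


def hellinger_rows(m: AbundanceMatrix | pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform per clade row: y_ij = sqrt(x_ij / sum_j x_ij).

    All-zero rows are dropped with a warning (no relative abundance exists).
    """
    df = m.counts if isinstance(m, AbundanceMatrix) else m
    totals = df.sum(axis=1)
    zero = totals == 0
    if zero.any():
        logger.warning("dropping %d all-zero clade rows", int(zero.sum()))
        df = df.loc[~zero]
        totals = totals[~zero]
    return np.sqrt(df.div(totals, axis=0))


def morisita_horn(m: pd.DataFrame | AbundanceMatrix) -> pd.DataFrame:
    """Morisita-Horn dissimilarity between the columns (regions).

    d(a, b) = 1 - 2 Σ a_i b_i / [(Σa_i²/A² + Σb_i²/B²) · A · B] with
    A = Σ a_i, B = Σ b_i.  Symmetric, zero diagonal, values in [0, 1].
    All-zero columns give undefined pairs: flagged NaN, to be excluded from
    clustering by the caller.
    """
    df = m.counts if isinstance(m, AbundanceMatrix) else m
    X = df.to_numpy(dtype=float)
    sums = X.sum(axis=0)
    simple = X.T @ X  # cross products between columns
    sq = (X**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        da = sq / sums**2
        denom = (da[:, None] + da[None, :]) * (sums[:, None] * sums[None, :])
        d = 1.0 - 2.0 * simple / denom
    d[~np.isfinite(d)] = np.nan
    np.fill_diagonal(d, 0.0)
    bad = sums == 0
    d[bad, :] = np.nan
    d[:, bad] = np.nan
    # numerical guard: clip the defined entries into [0, 1]
    mask = np.isfinite(d)
    d[mask] = np.clip(d[mask], 0.0, 1.0)
    return pd.DataFrame(d, index=df.columns, columns=df.columns)


def classical_mds(d: pd.DataFrame, var_explained: float = 0.95) -> np.ndarray:
    """Classical (Torgerson) metric MDS of a dissimilarity matrix.

    Keeps the leading positive-eigenvalue axes covering ``var_explained`` of
    the positive variance.
    """
    D = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-12
    vals_p, vecs_p = vals[pos], vecs[:, pos]
    cum = np.cumsum(vals_p) / vals_p.sum()
    keep = int(np.searchsorted(cum, var_explained) + 1)
    return vecs_p[:, :keep] * np.sqrt(vals_p[:keep])


@dataclass
class RegionClustering:
    k: int
    assignment: dict[str, int]
    wss_by_k: dict[int, float]
    chosen_k: int | None
    seed: int
    n_init: int
    coords: np.ndarray = field(repr=False, default=None)
    regions: list[str] = field(default_factory=list)

    def cluster_of(self, region: str) -> int:
        return self.assignment[region]


def embed_and_cluster(
    d: pd.DataFrame,
    k: int,
    n_init: int = 100,
    seed: int = 0,
    wss_k_max: int | None = None,
) -> RegionClustering:
    """MDS-embed a region dissimilarity matrix and K-means it at ``k``.

    Regions with undefined (NaN) dissimilarities are excluded with a warning.
    ``wss_by_k`` carries the within-cluster sum of squares for k = 1..k_max
    so the elbow can be taken afterwards.  Deterministic for a fixed seed.
    """
    names = list(d.index)
    D = d.to_numpy(dtype=float)
    offdiag = np.isnan(D) | np.eye(len(names), dtype=bool)
    defined = ~np.all(offdiag, axis=1)
    dropped = [n for n, ok in zip(names, defined) if not ok]
    if dropped:
        logger.warning("excluding regions with undefined dissimilarity: %s", dropped)
        names = [n for n, ok in zip(names, defined) if ok]
        D = D[np.ix_(defined, defined)]
    if np.any(np.isnan(D)):
        raise ValueError("dissimilarity has NaN entries among retained regions")
    n = len(names)
    if not (1 <= k <= n):
        raise ValueError(f"k must be in [1, {n}]")
    coords = classical_mds(pd.DataFrame(D, index=names, columns=names))
    k_max = wss_k_max or n
    wss_by_k: dict[int, float] = {}
    labels_at_k: dict[int, np.ndarray] = {}
    for kk in range(1, min(k_max, n) + 1):
        km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed)
        labels_at_k[kk] = km.fit_predict(coords)
        wss_by_k[kk] = float(km.inertia_)
    return RegionClustering(
        k=k,
        assignment={name: int(c) for name, c in zip(names, labels_at_k[k])},
        wss_by_k=wss_by_k,
        chosen_k=None,
        seed=seed,
        n_init=n_init,
        coords=coords,
        regions=names,
    )


def elbow_choose_k(wss_by_k: dict[int, float]) -> int:
    """Elbow rule: the interior k maximizing the discrete second difference
    WSS(k-1) - 2 WSS(k) + WSS(k+1); ties go to the smallest k."""
    ks = sorted(wss_by_k)
    if len(ks) < 3:
        raise ValueError("need WSS for at least 3 consecutive k")
    best_k, best_c = None, -np.inf
    for i in range(1, len(ks) - 1):
        c = wss_by_k[ks[i - 1]] - 2 * wss_by_k[ks[i]] + wss_by_k[ks[i + 1]]
        if c > best_c + 1e-12:
            best_k, best_c = ks[i], c
    return int(best_k)


@dataclass
class CladeAssignment:
    cluster: dict[str, object]  # clade -> cluster id (int) or "mixed"
    fraction_in_cluster: dict[str, float]


def assign_clades(
    m: AbundanceMatrix,
    clustering: RegionClustering,
    threshold: float = 0.6,
) -> CladeAssignment:
    """Assign each clade to the cluster holding strictly more than
    ``threshold`` of its species; otherwise "mixed".  Ties in the dominant
    fraction are conservative ("mixed"); zero-count clades are excluded."""
    df = m.counts[clustering.regions]
    labels = np.array([clustering.assignment[r] for r in clustering.regions])
    out: dict[str, object] = {}
    frac: dict[str, float] = {}
    for clade, row in df.iterrows():
        total = row.sum()
        if total == 0:
            logger.warning("clade %s has zero total count; excluded", clade)
            continue
        by_cluster = {}
        for c in np.unique(labels):
            by_cluster[int(c)] = row.to_numpy()[labels == c].sum() / total
        top = max(by_cluster.values())
        winners = [c for c, f in by_cluster.items() if f == top]
        frac[clade] = float(top)
        if len(winners) == 1 and top > threshold:
            out[clade] = winners[0]
        else:
            out[clade] = "mixed"
    return CladeAssignment(cluster=out, fraction_in_cluster=frac)


def cluster_regions(
    m: AbundanceMatrix,
    n_init: int = 100,
    seed: int = 0,
    k: int | None = None,
    hellinger_first: bool = True,
    k_max: int | None = None,
) -> RegionClustering:
    """Full bioregionalization: transform, dissimilarity, embed, K-means,
    elbow.  If ``k`` is given the elbow is skipped (still reported)."""
    table = hellinger_rows(m) if hellinger_first else m.counts
    d = morisita_horn(table)
    n = d.shape[0]
    probe = embed_and_cluster(d, k=min(2, n), n_init=n_init, seed=seed,
                              wss_k_max=k_max or max(n - 1, 3))
    chosen = k if k is not None else elbow_choose_k(probe.wss_by_k)
    result = embed_and_cluster(d, k=chosen, n_init=n_init, seed=seed,
                               wss_k_max=k_max or max(n - 1, 3))
    result.chosen_k = chosen
    return result
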