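"""Statistical recoupling of variables (SRV).

Segments the ppm axis into clusters of consecutive, highly correlated
spectral features and aggregates neighbouring clusters into superclusters.
A run of features is a cluster when every adjacent feature pair correlates
at r >= corr_threshold (Pearson, across samples) and the run spans at
least min_cluster_size features (default 10).  Neighbouring clusters whose
mean-intensity profiles correlate at the same threshold share a
supercluster, aggregated greedily left-to-right up to
max_clusters_per_supercluster (default 3) members.

The original procedure includes a manual curation pass; here sub-minimum
runs are kept as unassigned features and exported for review instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectra import SpectrumSet


@dataclass(frozen=True)
class SRVParams:
    corr_threshold: float = 0.9
    min_cluster_size: int = 10
    max_clusters_per_supercluster: int = 3
    correlation_kind: str = "pearson"

    def __post_init__(self) -> None:
        if not (0.0 < self.corr_threshold <= 1.0):
            raise ValueError("corr_threshold must be in (0, 1]")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.max_clusters_per_supercluster < 1:
            raise ValueError("max_clusters_per_supercluster must be >= 1")
        if self.correlation_kind != "pearson":
            raise ValueError("only Pearson correlation is supported")


@dataclass(frozen=True)
class Cluster:
    cluster_id: int
    start: int            # feature index, inclusive
    end: int              # feature index, inclusive
    supercluster_id: int
    sentinel_feature: int | None = None

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def members(self) -> range:
        return range(self.start, self.end + 1)


@dataclass
class ClusterMap:
    clusters: list[Cluster]
    unassigned_features: list[int]
    n_features: int

    def __post_init__(self) -> None:
        covered = set(self.unassigned_features)
        prev_end = -1
        for c in sorted(self.clusters, key=lambda c: c.start):
            if c.start <= prev_end:
                raise ValueError("overlapping clusters")
            prev_end = c.end
            covered.update(c.members())
        if covered != set(range(self.n_features)):
            raise ValueError("every feature must be clustered or unassigned")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def cluster_of(self, feature: int) -> int | None:
        for c in self.clusters:
            if c.start <= feature <= c.end:
                return c.cluster_id
        return None

    def to_frame(self, ppm: np.ndarray | None = None) -> pd.DataFrame:
        rows = []
        for c in self.clusters:
            row = {
                "cluster_id": c.cluster_id,
                "start_index": c.start,
                "end_index": c.end,
                "n_features": c.size,
                "supercluster_id": c.supercluster_id,
                "sentinel_feature": c.sentinel_feature,
            }
            if ppm is not None:
                row["ppm_start"] = ppm[c.start]
                row["ppm_end"] = ppm[c.end]
            rows.append(row)
        return pd.DataFrame(rows)

    def to_tsv(self, path, ppm: np.ndarray | None = None) -> None:
        self.to_frame(ppm).to_csv(path, sep="\t", index=False)


def _adjacent_correlations(x: np.ndarray) -> np.ndarray:
    """Pearson r between consecutive feature columns; NaN where constant."""
    xc = x - x.mean(axis=0)
    ss = np.einsum("ij,ij->j", xc, xc)
    num = np.einsum("ij,ij->j", xc[:, :-1], xc[:, 1:])
    denom = np.sqrt(ss[:-1] * ss[1:])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    r[denom == 0] = np.nan
    return r


def srv_cluster(spectra: SpectrumSet, params: SRVParams = SRVParams()) -> ClusterMap:
    """Segment the feature axis into SRV clusters.

    Constant features are pre-flagged unassigned and break runs.
    """
    x = spectra.intensities
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples to estimate correlations")
    m = x.shape[1]
    constant = x.std(axis=0) == 0
    if constant.all():
        raise ValueError("all features are constant")
    r = _adjacent_correlations(x)
    # link j—j+1 holds when both features vary and r >= threshold
    link = np.zeros(m - 1, dtype=bool)
    with np.errstate(invalid="ignore"):
        link = (~constant[:-1]) & (~constant[1:]) & (np.nan_to_num(r, nan=-2.0) >= params.corr_threshold)

    clusters: list[Cluster] = []
    unassigned: list[int] = []
    cid = 0
    start = 0
    for j in range(m):
        run_ends = j == m - 1 or not link[j]
        if run_ends:
            size = j - start + 1
            if size >= params.min_cluster_size and not constant[start]:
                clusters.append(Cluster(cid, start, j, supercluster_id=cid))
                cid += 1
            else:
                unassigned.extend(range(start, j + 1))
            start = j + 1
    return ClusterMap(clusters, unassigned, m)


def merge_superclusters(
    cmap: ClusterMap, spectra: SpectrumSet, params: SRVParams = SRVParams()
) -> ClusterMap:
    """Aggregate neighbouring clusters into superclusters.

    Adjacent clusters (in ppm order) whose mean-intensity profiles
    correlate at >= corr_threshold join the same supercluster, greedily
    left-to-right, never exceeding max_clusters_per_supercluster members.
    """
    if not cmap.clusters:
        return cmap
    x = spectra.intensities
    order = sorted(cmap.clusters, key=lambda c: c.start)
    profiles = np.column_stack([
        x[:, c.start:c.end + 1].mean(axis=1) for c in order])
    new: list[Cluster] = []
    group_id = order[0].cluster_id
    group_size = 1
    new.append(replace(order[0], supercluster_id=group_id))
    for k in range(1, len(order)):
        a, b = profiles[:, k - 1], profiles[:, k]
        denom = a.std() * b.std()
        r = float(np.corrcoef(a, b)[0, 1]) if denom > 0 else 0.0
        if r >= params.corr_threshold and group_size < params.max_clusters_per_supercluster:
            group_size += 1
        else:
            group_id = order[k].cluster_id
            group_size = 1
        new.append(replace(order[k], supercluster_id=group_id))
    return ClusterMap(new, cmap.unassigned_features, cmap.n_features)
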