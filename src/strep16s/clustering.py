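"""Greedy centroid clustering of 16S sequences across identity thresholds.

Implements vsearch-style greedy clustering: records are processed in a
deterministic order (decreasing length, ties by id) and each record
joins the first existing centroid it matches at or above the threshold,
otherwise founding a new cluster.  A sweep applies the rule over a grid
of thresholds (by default 98.0-100.0% in 0.1% steps); at 100% the
clusters are the zero-radius OTUs (zOTUs).

Because the default identity ignores terminal gap columns, two
non-identical strings (e.g. one a truncation of the other) can still
cluster together at 100% - the reason a strictly non-redundant sequence
set can yield fewer zOTUs than distinct strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import DEFAULT_IDENTITY, IdentityCache, IdentityDefinition
from .records import SequenceRecord

_EPS = 1e-9


@dataclass
class Cluster:
    threshold: float                 # percent identity
    centroid_id: str
    member_ids: list[str] = field(default_factory=list)
    taxid_set: set[int] = field(default_factory=set)
    n_unclassified: int = 0

    @property
    def size(self) -> int:
        return len(self.member_ids)


def default_thresholds() -> list[float]:
    """The standard sweep grid: 98.0, 98.1, ..., 100.0 (inclusive)."""
    return [round(98.0 + 0.1 * i, 1) for i in range(21)]


def cluster_order(records: list[SequenceRecord]) -> list[SequenceRecord]:
    return sorted(records, key=lambda r: (-r.length, r.id))


def greedy_cluster(
    records: list[SequenceRecord],
    threshold: float,
    identity_def: IdentityDefinition = DEFAULT_IDENTITY,
    cache: IdentityCache | None = None,
) -> list[Cluster]:
    """First-fit greedy clustering at one percent-identity threshold.

    ``records`` are assumed dereplicated.  Every record lands in exactly
    one cluster; centroids are scanned in founding order.
    """
    cache = cache if cache is not None else IdentityCache(identity_def)
    clusters: list[Cluster] = []
    centroids: list[SequenceRecord] = []
    frac = threshold / 100.0
    for rec in cluster_order(records):
        placed = False
        for cl, cen in zip(clusters, centroids):
            ident = cache.identity(rec.id, rec.seq, cen.id, cen.seq)
            if ident >= frac - _EPS:
                cl.member_ids.append(rec.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(threshold=threshold, centroid_id=rec.id, member_ids=[rec.id]))
            centroids.append(rec)
    return clusters


@dataclass
class SweepResult:
    clusters_by_threshold: dict[float, list[Cluster]]

    def counts(self) -> dict[float, int]:
        return {t: len(cl) for t, cl in self.clusters_by_threshold.items()}


def run_sweep(
    records: list[SequenceRecord],
    thresholds: list[float] | None = None,
    identity_def: IdentityDefinition = DEFAULT_IDENTITY,
) -> SweepResult:
    """Greedy clustering at every threshold, sharing one identity cache."""
    grid = thresholds if thresholds is not None else default_thresholds()
    cache = IdentityCache(identity_def)
    return SweepResult(
        {t: greedy_cluster(records, t, identity_def, cache) for t in grid}
    )


def propagate_taxids(
    clusters: list[Cluster],
    taxids: dict[str, int | None],
    member_map: dict[str, list[SequenceRecord]] | None = None,
) -> None:
    """Fill each cluster's taxid_set / unclassified count in place.

    ``taxids`` maps record id -> species-level taxID (None when the
    record is unclassified or unresolvable).  ``member_map`` carries the
    dereplication classes so labels of removed duplicates are credited
    to their retained representative.
    """
    for cl in clusters:
        cl.taxid_set = set()
        cl.n_unclassified = 0
        for member_id in cl.member_ids:
            ids = [member_id]
            if member_map and member_id in member_map:
                ids = [m.id for m in member_map[member_id]]
            for rid in ids:
                t = taxids.get(rid)
                if t is None:
                    cl.n_unclassified += 1
                else:
                    cl.taxid_set.add(int(t))


def composition_stats(clusters: list[Cluster]) -> tuple[pd.DataFrame, dict]:
    """Per-cluster taxonomic composition and a summary.

    Requires taxIDs already propagated (see :func:`propagate_taxids`).
    """
    rows = [
        {
            "threshold": cl.threshold,
            "centroid_id": cl.centroid_id,
            "n_members": cl.size,
            "n_distinct_taxids": len(cl.taxid_set),
            "only_unclassified": not cl.taxid_set and cl.n_unclassified > 0,
            "has_any_unclassified": cl.n_unclassified > 0,
        }
        for cl in clusters
    ]
    per_cluster = pd.DataFrame(rows)
    summary = {
        "n_clusters": len(clusters),
        "n_multi_taxid": int(sum(len(cl.taxid_set) >= 2 for cl in clusters)),
        "n_with_any_unclassified": int(sum(cl.n_unclassified > 0 for cl in clusters)),
        "n_only_unclassified": int(
            sum(not cl.taxid_set and cl.n_unclassified > 0 for cl in clusters)
        ),
    }
    return per_cluster, summary


def taxid_ecdf(clusters: list[Cluster]) -> pd.DataFrame:
    """ECDF of per-cluster distinct taxID counts (one threshold's clusters)."""
    counts = np.sort([len(cl.taxid_set) for cl in clusters])
    if counts.size == 0:
        return pd.DataFrame(columns=["n_taxids", "cumulative_fraction"])
    values, idx = np.unique(counts, return_index=True)
    cum = [(idx[i + 1] if i + 1 < len(idx) else counts.size) / counts.size for i in range(len(values))]
    return pd.DataFrame({"n_taxids": values, "cumulative_fraction": cum})


def ecdf_value(ecdf: pd.DataFrame, k: float) -> float:
    """F(k): fraction of clusters with n_taxids <= k."""
    mask = ecdf["n_taxids"] <= k
    if not mask.any():
        return 0.0
    return float(ecdf.loc[mask, "cumulative_fraction"].iloc[-1])
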