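"""Randomized test of cluster occupancy for a tagged cell population.

Given per-cell cluster labels and a boolean mask for one tag of interest,
the test asks, cluster by cluster, whether tagged cells occupy the cluster
more (enrichment) or less (depletion) than random draws of the same number
of cells from the pooled population. Each draw takes ``n`` cells (the
tagged-population size) without replacement from all ``n + s`` cells and
records per-cluster occupancy fractions; the observed fraction's tail rank
among the draws gives the p-value, with +1 smoothing on both tails so a
finite resample never reports exactly zero.

One tag per invocation; to test several tags, run the test once per tag,
as in per-sample engraftment analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OccupancyResult",
    "ClusterOccupancyTest",
    "occupancy_pvalues",
    "significant_clusters",
]


@dataclass
class OccupancyResult:
    """Per-cluster observed fractions and two-sided tail p-values."""

    clusters: np.ndarray
    observed_fraction: np.ndarray
    p_enrich: np.ndarray
    p_deplete: np.ndarray
    n_tagged: int
    n_untagged: int
    n_draws: int
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster": self.clusters,
                "observed_fraction": self.observed_fraction,
                "p_enrich": self.p_enrich,
                "p_deplete": self.p_deplete,
            }
        )

    def calls(self, alpha: float = 0.05) -> pd.DataFrame:
        return significant_clusters(self, alpha=alpha)

    def summary(self) -> str:
        df = self.calls()
        lines = [
            "Cluster occupancy permutation test",
            "==================================",
            f"tagged cells (n):    {self.n_tagged}",
            f"untagged cells (s):  {self.n_untagged}",
            f"draws:               {self.n_draws} (seed={self.seed})",
            df.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)


class ClusterOccupancyTest:
    """Model object for the occupancy test.

    Parameters
    ----------
    cluster_labels
        Per-cell cluster identifiers.
    tag_mask
        Per-cell boolean; True for cells carrying the tag of interest.
    exclude_clusters
        Cluster ids removed before pooling (e.g. a cluster known a priori to
        be composed of the tagged population itself, which would otherwise
        dominate the null).
    """

    def __init__(
        self,
        cluster_labels: Sequence,
        tag_mask: Sequence[bool],
        exclude_clusters: Sequence = (),
    ):
        clusters = np.asarray(cluster_labels)
        mask = np.asarray(tag_mask, dtype=bool)
        if clusters.shape != mask.shape:
            raise ValueError("cluster_labels and tag_mask must have equal length")
        excluded = set(exclude_clusters)
        keep = ~np.isin(clusters, list(excluded)) if excluded else np.ones(len(clusters), bool)
        dropped = set(np.unique(clusters).tolist()) - set(np.unique(clusters[keep]).tolist())
        if dropped - excluded:
            warnings.warn(f"clusters emptied by exclusion: {sorted(dropped - excluded)}")
        self.clusters = clusters[keep]
        self.tag_mask = mask[keep]
        self.n_tagged = int(self.tag_mask.sum())
        self.n_untagged = int((~self.tag_mask).sum())
        if self.n_tagged < 1:
            raise ValueError("no tagged cells after exclusion")

    def fit(self, n_draws: int = 10_000, seed: Optional[int] = None,
            alpha: float = 0.05) -> OccupancyResult:
        if n_draws < 1:
            raise ValueError("n_draws must be >= 1")
        min_p = 1.0 / (1 + n_draws)
        if min_p >= alpha:
            warnings.warn(
                f"n_draws={n_draws} cannot resolve p-values below alpha={alpha} "
                f"(smoothed minimum is {min_p:.3g})"
            )
        rng = np.random.default_rng(seed)
        cluster_ids, cluster_codes = np.unique(self.clusters, return_inverse=True)
        n_clusters = len(cluster_ids)
        n, total = self.n_tagged, self.n_tagged + self.n_untagged

        observed_counts = np.bincount(
            cluster_codes[self.tag_mask], minlength=n_clusters
        )
        # each draw: n cells without replacement from the pooled population
        draw_counts = np.empty((n_draws, n_clusters), dtype=np.int64)
        chunk = max(1, int(2_000_000 // max(total, 1)))
        row = 0
        while row < n_draws:
            m = min(chunk, n_draws - row)
            picks = rng.permuted(
                np.broadcast_to(np.arange(total), (m, total)).copy(), axis=1
            )[:, :n]
            picked_codes = cluster_codes[picks]
            for c in range(n_clusters):
                draw_counts[row : row + m, c] = (picked_codes == c).sum(axis=1)
            row += m

        # integer-count comparisons: exact, no floating-point tie ambiguity
        ge = (draw_counts >= observed_counts).sum(axis=0)
        le = (draw_counts <= observed_counts).sum(axis=0)
        return OccupancyResult(
            clusters=cluster_ids,
            observed_fraction=observed_counts / n,
            p_enrich=(1 + ge) / (1 + n_draws),
            p_deplete=(1 + le) / (1 + n_draws),
            n_tagged=n,
            n_untagged=self.n_untagged,
            n_draws=n_draws,
            seed=seed,
        )


def occupancy_pvalues(
    cluster_labels: Sequence,
    tag_mask: Sequence[bool],
    exclude_clusters: Sequence = (),
    n_draws: int = 10_000,
    seed: Optional[int] = None,
) -> OccupancyResult:
    """Functional wrapper around :class:`ClusterOccupancyTest`."""
    return ClusterOccupancyTest(cluster_labels, tag_mask, exclude_clusters).fit(
        n_draws=n_draws, seed=seed
    )


def significant_clusters(result: OccupancyResult, alpha: float = 0.05) -> pd.DataFrame:
    """Call each cluster enriched, depleted, or ns at level ``alpha``.

    If both tails are below alpha (possible only in degenerate tiny
    instances), the smaller p wins and the row is flagged.
    """
    calls = []
    flags = []
    for pe, pd_ in zip(result.p_enrich, result.p_deplete):
        both = pe < alpha and pd_ < alpha
        if pe < alpha and (not both or pe <= pd_):
            calls.append("enriched")
        elif pd_ < alpha:
            calls.append("depleted")
        else:
            calls.append("ns")
        flags.append(both)
    df = result.to_frame()
    df["call"] = calls
    df["both_tails_flag"] = flags
    return df
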