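"""Sphere-clustering collapse of sequencing-error barcode variants.

Greedy, abundance-ranked collapse in the style of Starcode's sphere
algorithm: sequences are scanned from most to least abundant, and a sequence
either becomes a new centroid or — if it lies within ``max_dist`` of an
already-declared centroid — is absorbed by the earliest-declared such
centroid. Only centroids absorb; there is no transitive chaining through
absorbed sequences, so the centroid set is a maximal independent set at
distance > ``max_dist``.

The default radius is 1 for 8-nt tags: a length-scaled radius of 2 would
risk merging distinct predefined sample indexes that differ at only two
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import edlib
import numpy as np
import scipy.sparse as sp

from .matrix import TagCountMatrix

__all__ = ["CollapseMap", "collapse", "apply_collapse", "sequence_distance"]


def sequence_distance(a: str, b: str, metric: str = "levenshtein", k: int = -1) -> int:
    """Distance between two barcode sequences.

    ``levenshtein`` uses edlib's banded alignment (``k >= 0`` caps the search;
    beyond-cap distances return a value > k). ``hamming`` requires equal
    lengths and counts substitutions only.
    """
    if metric == "levenshtein":
        d = edlib.align(a, b, task="distance", k=k)["editDistance"]
        return d if d >= 0 else (k + 1 if k >= 0 else -1)
    if metric == "hamming":
        if len(a) != len(b):
            raise ValueError(
                f"hamming distance requires equal lengths ({a!r} vs {b!r})"
            )
        return sum(x != y for x, y in zip(a, b))
    raise ValueError(f"unknown metric {metric!r}")


@dataclass
class CollapseMap:
    """Total mapping from raw tag sequence to its centroid."""

    mapping: dict[str, str]
    centroids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for c in self.centroids:
            if self.mapping.get(c) != c:
                raise ValueError(f"centroid {c!r} does not map to itself")

    def __getitem__(self, tag: str) -> str:
        return self.mapping[tag]

    def __len__(self) -> int:
        return len(self.mapping)

    def to_pairs(self) -> list[tuple[str, str]]:
        return sorted(self.mapping.items())


def collapse(
    tag_totals: Mapping[str, int],
    max_dist: int = 1,
    metric: str = "levenshtein",
) -> CollapseMap:
    """Sphere-cluster tags onto abundant centroids.

    Tags are sorted by total count descending with lexicographic ascending
    tie-break (deterministic, seed-free), then scanned in order. Absorption
    ties (within ``max_dist`` of several centroids) go to the
    earliest-declared — i.e. most abundant — centroid.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if metric == "hamming":
        lengths = {len(t) for t in tag_totals}
        if len(lengths) > 1:
            raise ValueError("hamming metric requires equal-length tags")
    order = sorted(tag_totals, key=lambda t: (-tag_totals[t], t))
    if max_dist == 0:
        return CollapseMap({t: t for t in order}, list(order))
    centroids: list[str] = []
    mapping: dict[str, str] = {}
    for seq in order:
        assigned = None
        for cent in centroids:
            if sequence_distance(seq, cent, metric, k=max_dist) <= max_dist:
                assigned = cent
                break
        if assigned is None:
            centroids.append(seq)
            mapping[seq] = seq
        else:
            mapping[seq] = assigned
    return CollapseMap(mapping, centroids)


def apply_collapse(matrix: TagCountMatrix, cmap: CollapseMap) -> TagCountMatrix:
    """Merge matrix columns that share a centroid; counts are conserved exactly."""
    missing = [t for t in matrix.tag_seqs if t not in cmap.mapping]
    if missing:
        raise KeyError(f"tags missing from collapse map: {missing[:10]}")
    kept = [c for c in cmap.centroids if any(cmap.mapping[t] == c for t in matrix.tag_seqs)]
    col_of = {c: j for j, c in enumerate(kept)}
    # indicator matrix S (old tags x kept centroids): counts @ S sums columns
    rows = np.arange(matrix.n_tags)
    cols = np.array([col_of[cmap.mapping[t]] for t in matrix.tag_seqs], dtype=np.int64)
    sel = sp.csr_matrix(
        (np.ones(matrix.n_tags, dtype=np.int64), (rows, cols)),
        shape=(matrix.n_tags, len(kept)),
    )
    merged = (matrix.counts @ sel).tocsr()
    return TagCountMatrix(matrix.cell_ids.copy(), np.asarray(kept, dtype=object), merged)
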