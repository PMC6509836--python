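"""Dynamic-binarization demultiplexing of CellTag Index counts.

The classifier assigns each cell of a pooled experiment back to its sample
of origin from its CellTag UMI counts. The procedure:

1. select the sample index tags (either a stated list or the most prevalent
   ``top_k``),
2. log-normalize the selected counts per cell,
3. for each tag, fit a density to its normalized expression across all
   cells, repeatedly draw samples from it, and score every cell by the
   proportion ``P_ij`` of draws at or above the cell's value (a small
   proportion means the cell sits in the upper tail of that tag's
   distribution — a significant signal),
4. classify each cell from its row of the proportion matrix: the tag with
   the overall minimum wins; other tags whose proportion lies within
   ``delta`` of the minimum indicate a multiplet; rows whose minimum is not
   small enough are non-determined,
5. optionally reconcile the multiplet count against the droplet-loading
   expectation of the 10x platform (the "multiplet checkpoint").

``CellTagDemux`` wraps these steps as a model object whose ``fit`` returns a
``DemuxResults`` carrying the proportion matrix, the per-cell labels and a
summary table; the individual steps remain importable functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .matrix import TagCountMatrix

__all__ = [
    "NormalizedTagMatrix",
    "TagDensity",
    "ProportionMatrix",
    "Classification",
    "select_tags",
    "log_normalize",
    "compute_proportions",
    "classify",
    "expected_multiplet_percent",
    "multiplet_checkpoint",
    "agreement_kappa",
    "CellTagDemux",
    "DemuxResults",
]

SINGLET = "Singlet"
MULTIPLET = "Multiplet"
NON_DETERMINED = "NonDetermined"

#: Baseline pairwise-difference cutoff separating singlets from multiplets,
#: learned by the original benchmarking against orthogonal species calls.
DEFAULT_DELTA = 0.238
#: Cells whose minimum proportion is at or above this are non-determined
#: (symmetric reuse of the learned cutoff: 1 - 0.238).
DEFAULT_ND_THRESHOLD = 1 - DEFAULT_DELTA


# ---------------------------------------------------------------------------
# step 1-2: tag selection and normalization
# ---------------------------------------------------------------------------

def select_tags(
    matrix: TagCountMatrix,
    expected_tags: Optional[Sequence[str]] = None,
    top_k: Optional[int] = None,
) -> TagCountMatrix:
    """Restrict the matrix to the sample index tags.

    Exactly one of ``expected_tags`` (keep those columns, in the given
    order) or ``top_k`` (keep the k tags detected in the most cells, ties
    broken by total count then lexicographically) must be supplied.
    """
    if (expected_tags is None) == (top_k is None):
        raise ValueError("supply exactly one of expected_tags or top_k")
    if expected_tags is not None:
        index = {t: j for j, t in enumerate(matrix.tag_seqs)}
        missing = [t for t in expected_tags if t not in index]
        if missing:
            raise KeyError(f"expected tags absent from matrix: {missing}")
        cols = [index[t] for t in expected_tags]
    else:
        if top_k < 1:
            raise ValueError("top_k must be >= 1")
        n_pos = np.asarray((matrix.counts > 0).sum(axis=0)).ravel()
        totals = np.asarray(matrix.counts.sum(axis=0)).ravel()
        ranked = sorted(
            range(matrix.n_tags),
            key=lambda j: (-n_pos[j], -totals[j], matrix.tag_seqs[j]),
        )
        cols = sorted(ranked[: min(top_k, matrix.n_tags)])
    return TagCountMatrix(
        matrix.cell_ids.copy(), matrix.tag_seqs[cols].copy(), matrix.counts[:, cols]
    )


@dataclass
class NormalizedTagMatrix:
    """Log-normalized expression C of the selected tags.

    ``zero_flag`` marks cells with no counts on any selected tag; they carry
    all-zero rows and are classified non-determined regardless of thresholds.
    """

    values: np.ndarray
    cell_ids: np.ndarray
    tag_seqs: np.ndarray
    zero_flag: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_tags(self) -> int:
        return self.values.shape[1]


def log_normalize(matrix: TagCountMatrix, scale: float = 10.0) -> NormalizedTagMatrix:
    """Per-cell proportion log transform: C_ij = ln(1 + scale * x_ij / total_i).

    ``total_i`` sums over the selected tags only, so C depends on a cell's
    tag *composition*, not its sequencing depth: multiplying a cell's counts
    by a constant leaves its row unchanged. Zero-total cells get all-zero
    rows and are flagged.
    """
    x = matrix.dense().astype(float)
    totals = x.sum(axis=1)
    zero_flag = totals == 0
    safe = np.where(zero_flag, 1.0, totals)
    values = np.log1p(scale * x / safe[:, None])
    values[zero_flag] = 0.0
    return NormalizedTagMatrix(
        values=values,
        cell_ids=matrix.cell_ids.copy(),
        tag_seqs=matrix.tag_seqs.copy(),
        zero_flag=zero_flag,
    )


# ---------------------------------------------------------------------------
# step 3: per-tag density and the sampled proportion matrix
# ---------------------------------------------------------------------------

class TagDensity:
    """Gaussian kernel density over one tag's normalized expression.

    Scott's rule bandwidth ``h = sd * n^(-1/5)`` over all cells, zeros
    included. Sampling draws a kernel center uniformly from the data and
    adds N(0, h^2) noise; negative draws are clamped to 0 (normalized
    expression is non-negative). A column with zero variance degenerates to
    a point mass at its value.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            raise ValueError("cannot fit a density to an empty column")
        self.centers = values
        sd = values.std(ddof=1) if values.size > 1 else 0.0
        self.bandwidth = float(sd) * values.size ** (-1 / 5)
        self.point_mass = self.bandwidth == 0.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        draws = rng.choice(self.centers, size=size, replace=True)
        if not self.point_mass:
            draws = draws + rng.normal(0.0, self.bandwidth, size=size)
        return np.maximum(draws, 0.0)

    def survival(self, x: np.ndarray) -> np.ndarray:
        """Closed-form P(draw >= x) of the clamped kernel mixture."""
        from scipy.stats import norm

        x = np.asarray(x, dtype=float)
        if self.point_mass:
            return (x <= self.centers[0]).astype(float)
        sf = norm.sf((x[..., None] - self.centers) / self.bandwidth).mean(axis=-1)
        return np.where(x <= 0, 1.0, sf)


@dataclass
class ProportionMatrix:
    """Sampled proportions P_ij in [0, 1], averaged over n_iter rounds."""

    P: np.ndarray
    cell_ids: np.ndarray
    tag_seqs: np.ndarray
    zero_flag: np.ndarray
    n_samples: int = 1000
    n_iter: int = 50
    seed: Optional[int] = None

    @property
    def n_cells(self) -> int:
        return self.P.shape[0]

    @property
    def n_tags(self) -> int:
        return self.P.shape[1]


def compute_proportions(
    norm: NormalizedTagMatrix,
    n_samples: int = 1000,
    n_iter: int = 50,
    seed: Optional[int] = None,
) -> ProportionMatrix:
    """Dynamic binarization: score every (cell, tag) against the tag's density.

    For each tag ``j`` a density is fitted on its column; per iteration,
    ``n_samples`` draws S are taken and ``P_ij = |{s in S : s >= C_ij}| /
    n_samples``; the final matrix averages ``n_iter`` independent
    iterations. Small P_ij = the cell is in the tag's upper expression tail.
    """
    if n_samples < 1 or n_iter < 1:
        raise ValueError("n_samples and n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    P = np.zeros_like(norm.values)
    for j in range(norm.n_tags):
        col = norm.values[:, j]
        density = TagDensity(col)
        acc = np.zeros(norm.n_cells)
        for _ in range(n_iter):
            draws = np.sort(density.sample(rng, n_samples))
            # s >= C  <=>  n_samples - (number of draws strictly below C)
            below = np.searchsorted(draws, col, side="left")
            acc += (n_samples - below) / n_samples
        P[:, j] = acc / n_iter
    return ProportionMatrix(
        P=P,
        cell_ids=norm.cell_ids.copy(),
        tag_seqs=norm.tag_seqs.copy(),
        zero_flag=norm.zero_flag.copy(),
        n_samples=n_samples,
        n_iter=n_iter,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# step 4-5: classification and the multiplet checkpoint
# ---------------------------------------------------------------------------

@dataclass
class Classification:
    """Per-cell sample-of-origin labels.

    ``category`` is one of Singlet/Multiplet/NonDetermined per cell; ``tags``
    holds the assigned tag (singlets) or the tied tag set (multiplets);
    ``min_p`` and ``gap`` (second-smallest minus smallest proportion) are the
    classifier's evidence, kept for the checkpoint and for reporting.
    """

    cell_ids: np.ndarray
    category: np.ndarray
    tags: list[tuple[str, ...]]
    min_p: np.ndarray
    gap: np.ndarray
    tag_seqs: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        if not (len(self.category) == len(self.tags) == len(self.min_p) == len(self.gap) == n):
            raise ValueError("classification fields must have equal length")

    def summary(self) -> dict[str, int]:
        cats, counts = np.unique(self.category, return_counts=True)
        out = {SINGLET: 0, MULTIPLET: 0, NON_DETERMINED: 0}
        out.update(dict(zip(cats.tolist(), counts.tolist())))
        return out

    def labels(self) -> np.ndarray:
        """Flat per-cell labels: the tag sequence, 'Multiplet', or 'NonDetermined'."""
        out = np.empty(len(self.cell_ids), dtype=object)
        for i, cat in enumerate(self.category):
            out[i] = self.tags[i][0] if cat == SINGLET else cat
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "label": self.labels(),
                "tags": [";".join(t) for t in self.tags],
                "min_p": self.min_p,
                "gap": self.gap,
            }
        )


def classify(
    P: ProportionMatrix,
    delta: float = DEFAULT_DELTA,
    nd_threshold: float = DEFAULT_ND_THRESHOLD,
) -> Classification:
    """Label each cell from its proportion row.

    Let ``m`` be the row minimum. Zero-flagged cells and cells with
    ``m >= nd_threshold`` are NonDetermined. Otherwise the tag set
    ``T = {j : P_ij - m <= delta}`` decides: one tag is a singlet, two or
    more (including exact ties for the minimum) a multiplet.
    """
    if not (0.0 <= delta <= 1.0) or not (0.0 <= nd_threshold <= 1.0):
        raise ValueError("delta and nd_threshold must be in [0, 1]")
    if P.n_tags == 0:
        raise ValueError("cannot classify with an empty tag set")
    order = np.sort(P.P, axis=1)
    m = order[:, 0]
    second = order[:, 1] if P.n_tags > 1 else np.ones_like(m)
    gap = second - m
    category = np.empty(P.n_cells, dtype=object)
    tags: list[tuple[str, ...]] = []
    for i in range(P.n_cells):
        if P.zero_flag[i] or m[i] >= nd_threshold:
            category[i] = NON_DETERMINED
            tags.append(())
            continue
        members = np.flatnonzero(P.P[i] - m[i] <= delta)
        if len(members) == 1:
            category[i] = SINGLET
        else:
            category[i] = MULTIPLET
        tags.append(tuple(P.tag_seqs[members]))
    return Classification(
        cell_ids=P.cell_ids.copy(),
        category=category,
        tags=tags,
        min_p=m,
        gap=gap,
        tag_seqs=P.tag_seqs.copy(),
    )


def expected_multiplet_percent(n_cells: int) -> float:
    """Expected multiplet percentage from the 10x droplet-loading calibration.

    Linear in the number of cells recovered:
    ``% = 0.0007589 * n_cells + 0.0527214``.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    return 0.0007589 * n_cells + 0.0527214


def multiplet_checkpoint(
    cls: Classification, P: ProportionMatrix, n_cells: int
) -> Classification:
    """Reconcile called multiplets with the droplet-loading expectation.

    If the number of called multiplets M exceeds 1.5x the expected count E,
    only the most multiplet-like calls — those with the smallest gap between
    the two smallest proportions — are retained (1.5 * E of them, i.e. the
    ``(1.5 * E) / M`` quantile of the gap ranking, ties broken by cell id);
    the rest are reclassified to their minimum tag as singlets.
    """
    expected = round(expected_multiplet_percent(n_cells) / 100.0 * n_cells)
    is_mult = cls.category == MULTIPLET
    m_count = int(is_mult.sum())
    allowance = 1.5 * expected
    if m_count <= allowance:
        return cls
    keep_n = int(round(allowance))
    mult_idx = np.flatnonzero(is_mult)
    ranked = sorted(mult_idx, key=lambda i: (cls.gap[i], cls.cell_ids[i]))
    demote = ranked[keep_n:]
    category = cls.category.copy()
    tags = list(cls.tags)
    for i in demote:
        j = int(np.argmin(P.P[i]))
        category[i] = SINGLET
        tags[i] = (str(P.tag_seqs[j]),)
    return Classification(
        cell_ids=cls.cell_ids.copy(),
        category=category,
        tags=tags,
        min_p=cls.min_p.copy(),
        gap=cls.gap.copy(),
        tag_seqs=cls.tag_seqs.copy() if cls.tag_seqs is not None else None,
    )


def agreement_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Cohen's kappa between two label vectors over a shared category set.

    Returns 1.0 for complete agreement (including the degenerate case where
    chance agreement p_e = 1 and the kappa ratio is 0/0).
    """
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if len(a) != len(b):
        raise ValueError(f"label vectors differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("label vectors are empty")
    if np.all(a == b):
        return 1.0
    return float(cohen_kappa_score(a, b))


# ---------------------------------------------------------------------------
# model / results wrappers
# ---------------------------------------------------------------------------

class CellTagDemux:
    """Demultiplexing model over a (collapsed) cell x tag count matrix.

    Parameters
    ----------
    matrix
        UMI count matrix, typically after barcode collapse.
    expected_tags, top_k
        Sample index tag selection; exactly one must be given (``top_k``
        defaults to all tags if both are omitted).
    scale
        Log-normalization scale factor.
    delta
        Singlet/multiplet pairwise-difference cutoff.
    nd_threshold
        Non-determined cutoff on the row-minimum proportion.
    n_samples, n_iter
        Draws per density per iteration, and number of iterations averaged.
    """

    def __init__(
        self,
        matrix: TagCountMatrix,
        expected_tags: Optional[Sequence[str]] = None,
        top_k: Optional[int] = None,
        scale: float = 10.0,
        delta: float = DEFAULT_DELTA,
        nd_threshold: float = DEFAULT_ND_THRESHOLD,
        n_samples: int = 1000,
        n_iter: int = 50,
    ):
        if expected_tags is None and top_k is None:
            top_k = matrix.n_tags
        self.matrix = matrix
        self.expected_tags = expected_tags
        self.top_k = top_k
        self.scale = scale
        self.delta = delta
        self.nd_threshold = nd_threshold
        self.n_samples = n_samples
        self.n_iter = n_iter

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CellTagDemux":
        return cls(TagCountMatrix.from_dataframe(df), **kwargs)

    def fit(self, seed: Optional[int] = None, checkpoint: bool = True) -> "DemuxResults":
        selected = select_tags(self.matrix, self.expected_tags, self.top_k)
        norm = log_normalize(selected, scale=self.scale)
        P = compute_proportions(
            norm, n_samples=self.n_samples, n_iter=self.n_iter, seed=seed
        )
        cls_before = classify(P, delta=self.delta, nd_threshold=self.nd_threshold)
        checkpoint_applied = False
        result_cls = cls_before
        if checkpoint:
            result_cls = multiplet_checkpoint(cls_before, P, n_cells=self.matrix.n_cells)
            checkpoint_applied = result_cls is not cls_before
        return DemuxResults(
            model=self,
            normalized=norm,
            proportions=P,
            classification=result_cls,
            pre_checkpoint=cls_before,
            checkpoint_applied=checkpoint_applied,
            seed=seed,
        )


@dataclass
class DemuxResults:
    """Fitted demultiplexing results.

    Carries the normalized matrix, the sampled proportion matrix, the final
    per-cell classification (after the multiplet checkpoint, when applied)
    and the pre-checkpoint classification for comparison.
    """

    model: CellTagDemux
    normalized: NormalizedTagMatrix
    proportions: ProportionMatrix
    classification: Classification
    pre_checkpoint: Classification
    checkpoint_applied: bool
    seed: Optional[int]

    def to_frame(self) -> pd.DataFrame:
        return self.classification.to_frame()

    def summary_dict(self) -> dict:
        counts = self.classification.summary()
        singlet_tags: dict[str, int] = {}
        for cat, tags in zip(self.classification.category, self.classification.tags):
            if cat == SINGLET:
                singlet_tags[tags[0]] = singlet_tags.get(tags[0], 0) + 1
        n = len(self.classification.cell_ids)
        classified = counts[SINGLET] + counts[MULTIPLET]
        return {
            "n_cells": n,
            "counts": counts,
            "singlets_per_tag": dict(sorted(singlet_tags.items())),
            "percent_classified": round(100.0 * classified / n, 1) if n else float("nan"),
            "expected_multiplet_percent": expected_multiplet_percent(n),
            "checkpoint_applied": self.checkpoint_applied,
            "seed": self.seed,
        }

    def summary(self) -> str:
        info = self.summary_dict()
        counts = info["counts"]
        lines = [
            "CellTag demultiplexing results",
            "==============================",
            f"cells:                  {info['n_cells']}",
            f"tags:                   {', '.join(self.proportions.tag_seqs)}",
            f"singlets:               {counts[SINGLET]}",
            f"multiplets:             {counts[MULTIPLET]}",
            f"non-determined:         {counts[NON_DETERMINED]}",
            f"percent classified:     {info['percent_classified']:.1f}%",
            f"expected multiplet %:   {info['expected_multiplet_percent']:.4f}%",
            f"multiplet checkpoint:   {'applied' if self.checkpoint_applied else 'not triggered'}",
            f"delta / nd threshold:   {self.model.delta} / {self.model.nd_threshold}",
            f"sampling:               {self.proportions.n_samples} draws x "
            f"{self.proportions.n_iter} iterations (seed={self.seed})",
            "singlets per tag:",
        ]
        for tag, c in info["singlets_per_tag"].items():
            lines.append(f"  {tag}: {c}")
        return "\n".join(lines)
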