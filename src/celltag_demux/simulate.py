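"""Synthetic CellTag datasets with known ground truth.

The generator emulates the tag-count structure of a pooled multiplexing
experiment: each sample's cells express their own index tag at high UMI
counts (overdispersed, as is typical for lentiviral expression), every cell
picks up low ambient counts of the other tags, a stated fraction of
droplets are doublets (two cells, distinct tags), and a stated fraction of
cells received no virus and carry ambient counts only. A read-level layer
wraps each UMI in the flanking motif with per-base substitution errors in
the tag region, so extraction and collapse can be exercised end to end.

Only the tag-count structure is simulated — no transcriptomes, no
cell-type biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .demux import MULTIPLET, NON_DETERMINED, SINGLET, Classification, agreement_kappa
from .extraction import ReadRecord
from .matrix import TagCountMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_count_matrix",
    "simulate_reads",
    "assign_clusters",
    "evaluate",
]

UNTAGGED = "Untagged"

#: Two-sample default emulating a two-tag species-mixing design: equal pools,
#: strong own-tag expression, low ambient cross-tag counts, a 5% doublet
#: fraction and a 10% untransduced fraction.
DEFAULT_SAMPLES = (("TGCTATAT", 5000), ("GTTGGCTA", 5000))

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the reference study conditions."""

    samples: tuple[tuple[str, int], ...] = DEFAULT_SAMPLES
    mu_signal: float = 20.0          # mean own-tag UMIs per transduced cell
    dispersion: float = 2.0          # negative-binomial size parameter
    lambda_bg: float = 0.2           # Poisson mean of ambient counts per off-tag
    doublet_rate: float = 0.05
    untagged_rate: float = 0.10
    seed: Optional[int] = None
    # read-level extras
    flank5: str = "GGTTAACTCGAG"     # synthetic constant flanks (construct stand-ins)
    flank3: str = "GAATTCTAGCAA"
    error_rate: float = 0.01         # per-base substitution rate in the tag region
    reads_per_umi: int = 1
    umi_length: int = 12

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("at least one sample required")
        tags = [t for t, _ in self.samples]
        if len(set(tags)) != len(tags):
            raise ValueError("tag sequences must be unique")
        if len({len(t) for t in tags}) != 1:
            raise ValueError("tag sequences must have equal length")
        for rate in (self.doublet_rate, self.untagged_rate, self.error_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.doublet_rate + self.untagged_rate > 1.0:
            raise ValueError("doublet_rate + untagged_rate must be <= 1")
        if not self.mu_signal > self.lambda_bg >= 0.0:
            raise ValueError("require mu_signal > lambda_bg >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.reads_per_umi < 1:
            raise ValueError("reads_per_umi must be >= 1")

    @property
    def tags(self) -> list[str]:
        return [t for t, _ in self.samples]

    @property
    def n_cells(self) -> int:
        return sum(n for _, n in self.samples)


@dataclass
class SimTruth:
    """Ground-truth origin per simulated cell."""

    cell_ids: np.ndarray
    category: np.ndarray                       # Singlet / Multiplet / Untagged
    tags: list[tuple[str, ...]]                # () for untagged
    clusters: Optional[np.ndarray] = None

    def labels(self) -> np.ndarray:
        """Singlet tag, 'Multiplet', or 'Untagged' per cell."""
        out = np.empty(len(self.cell_ids), dtype=object)
        for i, cat in enumerate(self.category):
            out[i] = self.tags[i][0] if cat == SINGLET else cat
        return out

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "category": self.category,
                "tags": [";".join(t) for t in self.tags],
            }
        )
        if self.clusters is not None:
            df["cluster"] = self.clusters
        return df


def _truncated_nb(rng: np.random.Generator, mu: float, size_param: float, n: int) -> np.ndarray:
    """Negative binomial (mean mu, size r) truncated to >= 1 by resampling."""
    p = size_param / (size_param + mu)
    out = rng.negative_binomial(size_param, p, size=n)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.negative_binomial(size_param, p, size=int(zero.sum()))


def simulate_count_matrix(
    config: SimConfig = SimConfig(), seed: Optional[int] = None
) -> tuple[TagCountMatrix, SimTruth]:
    """Draw a cell x tag UMI count matrix plus its ground truth.

    Singlets draw own-tag counts ~ NegBinom(mu_signal, dispersion) truncated
    to >= 1 ("transduced" means at least one tag transcript) and ambient
    off-tag counts ~ Poisson(lambda_bg). Doublets are sums of two
    independent singlet profiles with distinct tags (same-tag doublets are
    invisible to any tag-based caller and are not generated). Untagged cells
    draw ambient counts only.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    tags = config.tags
    n_tags = len(tags)
    n = config.n_cells
    weights = np.array([c for _, c in config.samples], dtype=float)
    weights /= weights.sum()

    u = rng.random(n)
    is_doublet = u < config.doublet_rate
    is_untagged = (~is_doublet) & (u < config.doublet_rate + config.untagged_rate)
    if n_tags < 2:
        is_doublet[:] = False
    counts = rng.poisson(config.lambda_bg, size=(n, n_tags))

    category = np.empty(n, dtype=object)
    tag_sets: list[tuple[str, ...]] = [()] * n
    singlet_idx = np.flatnonzero(~is_doublet & ~is_untagged)
    own = rng.choice(n_tags, size=len(singlet_idx), p=weights)
    own_counts = _truncated_nb(rng, config.mu_signal, config.dispersion, len(singlet_idx))
    counts[singlet_idx, own] += own_counts
    for i, j in zip(singlet_idx, own):
        category[i] = SINGLET
        tag_sets[i] = (tags[j],)

    doublet_idx = np.flatnonzero(is_doublet)
    for i in doublet_idx:
        # two distinct tags, probability proportional to pool sizes
        j1 = rng.choice(n_tags, p=weights)
        rest = np.delete(np.arange(n_tags), j1)
        w = weights[rest] / weights[rest].sum()
        j2 = rng.choice(rest, p=w)
        counts[i, j1] += _truncated_nb(rng, config.mu_signal, config.dispersion, 1)[0]
        counts[i, j2] += _truncated_nb(rng, config.mu_signal, config.dispersion, 1)[0]
        # the second cell of the doublet contributes its own ambient load
        counts[i] += rng.poisson(config.lambda_bg, size=n_tags)
        category[i] = MULTIPLET
        pair = tuple(sorted((tags[j1], tags[j2])))
        tag_sets[i] = pair

    untagged_idx = np.flatnonzero(is_untagged)
    category[untagged_idx] = UNTAGGED

    width = len(str(n))
    cell_ids = np.asarray([f"cell{str(i).zfill(width)}" for i in range(n)], dtype=object)
    matrix = TagCountMatrix(
        cell_ids, np.asarray(tags, dtype=object), sp.csr_matrix(counts)
    )
    truth = SimTruth(cell_ids=cell_ids.copy(), category=category, tags=tag_sets)
    return matrix, truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0.0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for i in hits:
        out[i] = rng.choice(_BASES[_BASES != out[i]])
    return "".join(out)


def simulate_reads(
    config: SimConfig, matrix: TagCountMatrix, seed: Optional[int] = None
) -> Iterator[ReadRecord]:
    """Emit reads for every UMI of a simulated count matrix.

    Each (cell, tag) UMI yields ``reads_per_umi`` reads whose sequence embeds
    ``flank5 + tag + flank3`` in random context. Substitution errors at
    ``error_rate`` hit the tag region only — the flanks stay exact, so the
    read-level layer isolates collapse behavior from extraction losses.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(None if seed is None else seed + 1)
    coo = matrix.counts.tocoo()
    for i, j, c in zip(coo.row, coo.col, coo.data):
        cell = matrix.cell_ids[i]
        tag = matrix.tag_seqs[j]
        for _ in range(int(c)):
            umi = _random_seq(rng, config.umi_length)
            for _ in range(config.reads_per_umi):
                observed = _mutate(rng, tag, config.error_rate)
                sequence = (
                    _random_seq(rng, 6)
                    + config.flank5
                    + observed
                    + config.flank3
                    + _random_seq(rng, 6)
                )
                yield ReadRecord(cell_barcode=cell, umi=umi, sequence=sequence)


def assign_clusters(
    truth: SimTruth,
    n_clusters: int,
    enrichment: Optional[dict[str, Sequence[float]]] = None,
    seed: Optional[int] = None,
) -> SimTruth:
    """Assign each cell a cluster id, optionally enriched by truth label.

    ``enrichment`` maps a truth label (as returned by ``truth.labels()``) to
    unnormalized per-cluster weights; unlisted labels get uniform weights.
    Enables power checks of the occupancy test against a known signal.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    rng = np.random.default_rng(seed)
    labels = truth.labels()
    clusters = np.empty(len(labels), dtype=np.int64)
    uniform = np.ones(n_clusters) / n_clusters
    for i, lab in enumerate(labels):
        w = np.asarray((enrichment or {}).get(lab, uniform), dtype=float)
        if len(w) != n_clusters or (w < 0).any() or w.sum() == 0:
            raise ValueError(f"invalid enrichment weights for label {lab!r}")
        clusters[i] = rng.choice(n_clusters, p=w / w.sum())
    return SimTruth(
        cell_ids=truth.cell_ids.copy(),
        category=truth.category.copy(),
        tags=list(truth.tags),
        clusters=clusters,
    )


def evaluate(cls: Classification, truth: SimTruth) -> dict:
    """Score a classification against simulation ground truth.

    Singlet accuracy is over true singlets not called NonDetermined;
    multiplet recall/precision over true/called multiplets; kappa is
    computed on the {tag..., Multiplet} label space restricted to cells that
    are determined by the classifier and tagged in truth (mirroring how
    non-determined cells are dropped before benchmarking agreement).
    Empty denominators report None with their count.
    """
    if len(cls.cell_ids) != len(truth.cell_ids) or not np.array_equal(
        np.sort(cls.cell_ids), np.sort(truth.cell_ids)
    ):
        raise ValueError("classification and truth cover different cell sets")
    order = {c: i for i, c in enumerate(cls.cell_ids)}
    t_idx = np.asarray([order[c] for c in truth.cell_ids])

    pred_cat = cls.category[t_idx]
    pred_labels = cls.labels()[t_idx]
    true_cat = truth.category
    true_labels = truth.labels()

    true_singlet = true_cat == SINGLET
    determined = pred_cat != NON_DETERMINED
    sing_det = true_singlet & determined
    n_sing_det = int(sing_det.sum())
    singlet_accuracy = (
        float((pred_labels[sing_det] == true_labels[sing_det]).mean())
        if n_sing_det
        else None
    )
    # weaker notion: the true tag appears in the assigned tag set (a singlet
    # called as a {true, other} multiplet still recovers its tag)
    pred_tags = [cls.tags[i] for i in t_idx]
    singlet_tag_recovery = (
        float(
            np.mean(
                [truth.tags[i][0] in pred_tags[i] for i in np.flatnonzero(sing_det)]
            )
        )
        if n_sing_det
        else None
    )

    true_mult = true_cat == MULTIPLET
    pred_mult = pred_cat == MULTIPLET
    multiplet_recall = float(pred_mult[true_mult].mean()) if true_mult.any() else None
    multiplet_precision = float(true_mult[pred_mult].mean()) if pred_mult.any() else None

    kappa_mask = determined & (true_cat != UNTAGGED)
    n_kappa = int(kappa_mask.sum())
    kappa = (
        agreement_kappa(true_labels[kappa_mask], pred_labels[kappa_mask])
        if n_kappa
        else None
    )

    confusion = pd.crosstab(
        pd.Series(true_labels, name="truth"),
        pd.Series(pred_labels, name="predicted"),
        dropna=False,
    )
    return {
        "singlet_accuracy": singlet_accuracy,
        "singlet_tag_recovery": singlet_tag_recovery,
        "n_true_singlets_determined": n_sing_det,
        "multiplet_recall": multiplet_recall,
        "multiplet_precision": multiplet_precision,
        "non_determined_rate": float((~determined).mean()),
        "kappa": kappa,
        "n_kappa_cells": n_kappa,
        "confusion": confusion,
    }
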