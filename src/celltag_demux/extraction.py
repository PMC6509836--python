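"""CellTag extraction from tagged reads and UMI-deduplicated counting.

Each read that carries a CellTag contains the 8-nt variable barcode inside a
fixed flanking motif (the constant sequence on either side of the variable
region in the GFP 3' UTR construct). Extraction finds the first motif
occurrence on the read as given — no reverse-complement search and no fuzzy
flank matching; sequencing-error tolerance lives in the collapse stage, which
acts on the variable region where errors matter for barcode identity.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

import numpy as np
import scipy.sparse as sp

from .matrix import TagCountMatrix

__all__ = [
    "ReadRecord",
    "MotifConfig",
    "ExtractionStats",
    "extract_tags",
    "count_matrix",
    "read_records_from_csv",
    "read_records_from_bam",
]

_VALID_FLANK = re.compile(r"^[ACGT]*$")


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced read with its droplet barcode and UMI."""

    cell_barcode: str
    umi: str
    sequence: str


@dataclass(frozen=True)
class MotifConfig:
    """Constant flanks around the variable CellTag region.

    The flanking sequences are construct-specific and therefore a required
    input with no default: extracting with the wrong motif silently yields an
    empty matrix, so explicitness is safer than a baked-in constant.
    """

    flank5: str
    flank3: str
    tag_length: int = 8

    def __post_init__(self) -> None:
        if self.tag_length < 1:
            raise ValueError("tag_length must be >= 1")
        for name, flank in (("flank5", self.flank5), ("flank3", self.flank3)):
            if not _VALID_FLANK.match(flank):
                raise ValueError(f"{name} must be over A/C/G/T, got {flank!r}")
        if not self.flank5 and not self.flank3:
            raise ValueError("at least one flank must be non-empty")

    def pattern(self) -> re.Pattern[str]:
        # N allowed inside the window so an ambiguous tag consumes the
        # read's single extraction attempt instead of matching further right
        return re.compile(
            re.escape(self.flank5)
            + "([ACGTN]{%d})" % self.tag_length
            + re.escape(self.flank3)
        )


@dataclass
class ExtractionStats:
    """Per-run bookkeeping emitted alongside the triple stream."""

    n_reads: int = 0
    n_matched: int = 0
    n_no_motif: int = 0
    n_ambiguous_tag: int = 0
    n_malformed: int = 0
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict[str, int]:
        return {
            "n_reads": self.n_reads,
            "n_matched": self.n_matched,
            "n_no_motif": self.n_no_motif,
            "n_ambiguous_tag": self.n_ambiguous_tag,
            "n_malformed": self.n_malformed,
        }


def extract_tags(
    reads: Iterable[ReadRecord],
    motif: MotifConfig,
    stats: Optional[ExtractionStats] = None,
) -> Iterator[tuple[str, str, str]]:
    """Yield ``(cell_barcode, umi, tag_seq)`` for reads matching the motif.

    The first left-to-right motif occurrence is used; reads without a match,
    and tags containing N, are skipped. Records missing a barcode or UMI are
    skipped with a warning counted in ``stats``.
    """
    pattern = motif.pattern()
    for read in reads:
        if stats is not None:
            stats.n_reads += 1
        if not read.cell_barcode or not read.umi:
            if stats is not None:
                stats.n_malformed += 1
                if len(stats.warnings) < 100:
                    stats.warnings.append(
                        f"malformed record (missing barcode/UMI): {read!r}"
                    )
            continue
        m = pattern.search(read.sequence)
        if m is None:
            if stats is not None:
                stats.n_no_motif += 1
            continue
        tag = m.group(1)
        if "N" in tag:
            if stats is not None:
                stats.n_ambiguous_tag += 1
            continue
        if stats is not None:
            stats.n_matched += 1
        yield read.cell_barcode, read.umi, tag


def count_matrix(
    triples: Iterable[tuple[str, str, str]],
    cell_whitelist: Optional[set[str]] = None,
) -> TagCountMatrix:
    """Build a UMI-deduplicated cell x tag count matrix from extracted triples.

    Identical ``(cell, umi, tag)`` triples are counted once; deduplication is
    exact-match (UMI error correction is out of scope — tag counts are small
    and the downstream classifier is robust to +/-1 UMI). Cells outside the
    whitelist, if one is given, are dropped. Row and column order is
    lexicographic for determinism.
    """
    seen: set[tuple[str, str, str]] = set()
    pair_counts: dict[tuple[str, str], int] = {}
    for triple in triples:
        cell, umi, tag = triple
        if cell_whitelist is not None and cell not in cell_whitelist:
            continue
        if triple in seen:
            continue
        seen.add(triple)
        key = (cell, tag)
        pair_counts[key] = pair_counts.get(key, 0) + 1

    cells = sorted({c for c, _ in pair_counts})
    tags = sorted({t for _, t in pair_counts})
    cell_index = {c: i for i, c in enumerate(cells)}
    tag_index = {t: j for j, t in enumerate(tags)}
    rows = np.fromiter((cell_index[c] for c, _ in pair_counts), dtype=np.int64, count=len(pair_counts))
    cols = np.fromiter((tag_index[t] for _, t in pair_counts), dtype=np.int64, count=len(pair_counts))
    vals = np.fromiter(pair_counts.values(), dtype=np.int64, count=len(pair_counts))
    counts = sp.csr_matrix((vals, (rows, cols)), shape=(len(cells), len(tags)))
    return TagCountMatrix(
        np.asarray(cells, dtype=object), np.asarray(tags, dtype=object), counts
    )


def read_records_from_csv(path: str) -> Iterator[ReadRecord]:
    """Stream read records from a headered CSV/TSV.

    Required columns: ``cell_barcode``, ``umi``, ``sequence``. The delimiter
    is sniffed from the header line (comma or tab).
    """
    with open(path, newline="") as fh:
        header = fh.readline()
        delim = "\t" if header.count("\t") >= header.count(",") else ","
        names = [c.strip() for c in header.rstrip("\n").split(delim)]
        required = {"cell_barcode", "umi", "sequence"}
        if not required.issubset(names):
            raise ValueError(
                f"{path}: expected columns {sorted(required)}, found {names}"
            )
        reader = csv.DictReader(fh, fieldnames=names, delimiter=delim)
        for row in reader:
            yield ReadRecord(
                cell_barcode=row["cell_barcode"] or "",
                umi=row["umi"] or "",
                sequence=row["sequence"] or "",
            )


def read_records_from_bam(
    path: str, cell_tag: str = "CB", umi_tag: str = "UB"
) -> Iterator[ReadRecord]:
    """Stream read records from a BAM, taking barcodes from alignment tags.

    Requires pysam (optional dependency). Records lacking either tag are
    yielded with empty fields so extraction counts them as malformed.
    """
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "BAM input requires pysam; install the 'bam' extra"
        ) from exc
    with pysam.AlignmentFile(path, check_sq=False) as bam:
        for aln in bam.fetch(until_eof=True):
            cb = aln.get_tag(cell_tag) if aln.has_tag(cell_tag) else ""
            ub = aln.get_tag(umi_tag) if aln.has_tag(umi_tag) else ""
            yield ReadRecord(str(cb), str(ub), aln.query_sequence or "")
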