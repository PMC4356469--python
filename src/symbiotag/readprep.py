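"""Quality filtering and demultiplexing of barcoded single-end amplicon reads.

Reads carry an inline sample barcode followed by the amplification primer and
the biological insert.  Processing order is: demultiplex (exact barcode match,
no mismatch allowed), trim barcode + primer, then apply the length and
expected-error filters to the trimmed insert.  Filter thresholds therefore
describe the biologically informative sequence.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Forward amplification primer located immediately after the sample barcode.
FORWARD_PRIMER = "AAGGTAGCCGTACGAGA"

#: Default inclusive filter thresholds (applied to the trimmed insert).
DEFAULT_MIN_LEN = 250
DEFAULT_MAX_EE = 0.5


@dataclasses.dataclass
class TaggedRead:
    """A single sequencing read.

    ``quals`` are Phred scores, one per base.  ``observed_barcode`` is empty
    until the read has been demultiplexed; demultiplexing removes the barcode
    (and primer) from ``bases``.
    """

    id: str
    bases: str
    quals: np.ndarray
    observed_barcode: str = ""

    def __post_init__(self) -> None:
        self.quals = np.asarray(self.quals, dtype=np.int16)
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if len(self.quals) and (self.quals.min() < 0 or self.quals.max() > 60):
            raise ValueError(f"read {self.id!r}: Phred scores outside [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)


@dataclasses.dataclass(frozen=True)
class SampleSpec:
    """One single-cell library: barcode plus host/termite annotation."""

    sample_id: str
    barcode: str
    host_species: str
    termite_species: str


def validate_sheet(samples: Sequence[SampleSpec]) -> int:
    """Check barcode uniqueness and equal length; return the barcode length."""
    if not samples:
        raise ValueError("empty sample sheet")
    barcodes = [s.barcode for s in samples]
    if len(set(barcodes)) != len(barcodes):
        dupes = sorted({b for b in barcodes if barcodes.count(b) > 1})
        raise ValueError(f"duplicate barcodes in sample sheet: {dupes}")
    lengths = {len(b) for b in barcodes}
    if len(lengths) != 1:
        raise ValueError(f"barcodes of unequal length: {sorted(lengths)}")
    return lengths.pop()


def expected_error(quals: Sequence[int] | np.ndarray) -> float:
    """Expected number of errors implied by Phred scores: sum of 10^(-Q/10)."""
    q = np.asarray(quals, dtype=float)
    if q.size == 0:
        return 0.0
    return float(np.sum(10.0 ** (-q / 10.0)))


def quality_filter(
    reads: Iterable[TaggedRead],
    min_len: int = DEFAULT_MIN_LEN,
    max_ee: float = DEFAULT_MAX_EE,
    *,
    stats: dict | None = None,
) -> list[TaggedRead]:
    """Keep reads with length >= ``min_len`` and expected error <= ``max_ee``.

    Both thresholds are inclusive.  Input order is preserved.  Per-reason
    rejection counts are logged and, if ``stats`` is given, accumulated into
    it under ``input``/``passed``/``failed_length``/``failed_ee``.
    """
    kept: list[TaggedRead] = []
    n_in = n_len = n_ee = 0
    for read in reads:
        n_in += 1
        if len(read) < min_len:
            n_len += 1
            continue
        if expected_error(read.quals) > max_ee:
            n_ee += 1
            continue
        kept.append(read)
    logger.info(
        "quality_filter: %d in, %d passed, %d failed length<%d, %d failed EE>%g",
        n_in, len(kept), n_len, min_len, n_ee, max_ee,
    )
    if stats is not None:
        stats["input"] = stats.get("input", 0) + n_in
        stats["passed"] = stats.get("passed", 0) + len(kept)
        stats["failed_length"] = stats.get("failed_length", 0) + n_len
        stats["failed_ee"] = stats.get("failed_ee", 0) + n_ee
    return kept


def demultiplex(
    reads: Iterable[TaggedRead],
    samples: Sequence[SampleSpec],
    primer: str = FORWARD_PRIMER,
) -> tuple[dict[str, list[TaggedRead]], list[TaggedRead]]:
    """Assign reads to samples by exact positional barcode match.

    A read belongs to sample ``s`` iff its first L bases equal ``s.barcode``
    exactly (no mismatch allowed).  The primer must then follow with zero
    mismatches; reads failing either check go to the unassigned bin.
    Assigned reads are returned with barcode and primer removed.  Every input
    read lands in exactly one bin.
    """
    bc_len = validate_sheet(samples)
    lookup: Mapping[str, str] = {s.barcode: s.sample_id for s in samples}
    bins: dict[str, list[TaggedRead]] = {s.sample_id: [] for s in samples}
    unassigned: list[TaggedRead] = []
    trim = bc_len + len(primer)
    for read in reads:
        barcode = read.bases[:bc_len]
        sample_id = lookup.get(barcode)
        if sample_id is None or read.bases[bc_len:trim] != primer:
            unassigned.append(read)
            continue
        bins[sample_id].append(
            TaggedRead(
                id=read.id,
                bases=read.bases[trim:],
                quals=read.quals[trim:],
                observed_barcode=barcode,
            )
        )
    n_assigned = sum(len(v) for v in bins.values())
    logger.info(
        "demultiplex: %d assigned to %d samples, %d unassigned",
        n_assigned, len(samples), len(unassigned),
    )
    return bins, unassigned
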