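"""Libraries x phylotypes abundance table and major-phylotype calls.

Each single-cell library is expected to be dominated by exactly one symbiont
phylotype; the "major" phylotype of a library is the argmax of its counts.
Relative abundances per row are the heatmap-ready export.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import pandas as pd

from .clustering import Phylotype
from .readprep import SampleSpec

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class AbundanceTable:
    """Counts of reads per (library, phylotype) with sample annotation.

    Rows are ordered by (termite species, host species, sample id); columns
    by run-total phylotype abundance, descending.
    """

    counts: pd.DataFrame
    samples: list[SampleSpec]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def phylotype_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def relative(self) -> pd.DataFrame:
        """Per-row relative abundances; all-zero rows stay at zero."""
        sums = self.counts.sum(axis=1)
        return self.counts.div(sums.where(sums > 0, other=1), axis=0)

    def host_map(self) -> dict[str, str]:
        return {s.sample_id: s.host_species for s in self.samples}

    def termite_map(self) -> dict[str, str]:
        return {s.sample_id: s.termite_species for s in self.samples}


def tabulate(
    phylotypes: Sequence[Phylotype], samples: Sequence[SampleSpec]
) -> AbundanceTable:
    """Build the libraries x phylotypes count matrix.

    Samples with zero surviving reads are retained as all-zero rows (with a
    warning); an empty phylotype list yields a table with zero columns.
    """
    ordered = sorted(
        samples, key=lambda s: (s.termite_species, s.host_species, s.sample_id)
    )
    index = [s.sample_id for s in ordered]
    columns = [p.phylotype_id for p in phylotypes]
    counts = pd.DataFrame(0, index=index, columns=columns, dtype=int)
    for p in phylotypes:
        for sample_id, n in p.counts.items():
            if sample_id not in counts.index:
                raise KeyError(
                    f"phylotype {p.phylotype_id} has reads for unknown "
                    f"sample {sample_id!r}"
                )
            counts.loc[sample_id, p.phylotype_id] = n
    empty = counts.index[counts.sum(axis=1) == 0]
    for sample_id in empty:
        logger.warning("sample %s has no surviving reads (all-zero row)", sample_id)
    return AbundanceTable(counts=counts, samples=list(ordered))


def table_from_truth(truth: pd.DataFrame, samples: Sequence[SampleSpec]) -> AbundanceTable:
    """Abundance table implied by a simulation truth table.

    Counts reads by (observed library, origin phylotype), i.e. what a perfect
    clusterer would recover; used for estimator studies that do not need the
    sequence-level pipeline.
    """
    pivot = truth.pivot_table(
        index="observed_library",
        columns="origin_phylotype",
        values="read_id",
        aggfunc="count",
        fill_value=0,
    )
    ordered = sorted(
        samples, key=lambda s: (s.termite_species, s.host_species, s.sample_id)
    )
    index = [s.sample_id for s in ordered]
    counts = pivot.reindex(index=index, fill_value=0).fillna(0).astype(int)
    counts = counts[sorted(counts.columns, key=lambda c: (-counts[c].sum(), c))]
    counts.index.name = None
    counts.columns.name = None
    return AbundanceTable(counts=counts, samples=list(ordered))


def major_phylotype(table: AbundanceTable, sample_id: str) -> str:
    """The argmax-count phylotype of one library.

    Ties are broken by larger run-total abundance, then by phylotype id.
    Raises on an all-zero row.
    """
    row = table.counts.loc[sample_id]
    if row.sum() == 0:
        raise ValueError(f"no reads for sample {sample_id!r}")
    totals = table.counts.sum(axis=0)
    return sorted(row.index, key=lambda p: (-row[p], -totals[p], p))[0]


def majors(table: AbundanceTable) -> dict[str, str]:
    """Major phylotype for every library with at least one read."""
    out: dict[str, str] = {}
    for sample_id in table.sample_ids:
        if table.counts.loc[sample_id].sum() > 0:
            out[sample_id] = major_phylotype(table, sample_id)
    return out


def check_major_fraction(
    table: AbundanceTable, min_major_frac: float = 0.5
) -> list[str]:
    """Warn (and return) libraries whose major phylotype is below a fraction."""
    flagged: list[str] = []
    rel = table.relative
    for sample_id, major in majors(table).items():
        if rel.loc[sample_id, major] < min_major_frac:
            logger.warning(
                "sample %s: major phylotype %s at %.1f%% < %.0f%%",
                sample_id, major, 100 * rel.loc[sample_id, major],
                100 * min_major_frac,
            )
            flagged.append(sample_id)
    return flagged
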