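"""Tag-switching (mistagging) artifact analysis.

When the amplicon is longer than the read, only one sample tag per read is
observable and mistagged reads cannot be recognised directly.  This module
implements the indirect evidence chain:

* per-library counts of reads belonging to *other* libraries' major
  phylotypes (foreign reads), and the regression of foreign counts on
  own-major counts — a strong linear correlation indicates that minor
  phylotypes are carried over from abundant source libraries rather than
  being genuine community members;
* a run-level mistagged-read fraction: a read in library *s* counts as
  mistagged iff its phylotype differs from the major phylotype of *s* and is
  the major phylotype of at least one other library (a stricter cross-termite
  variant requires all home libraries of that phylotype to belong to the
  other termite species);
* a clone-library purity check: Sanger clones of the pre-run amplicon pool
  compared against the major pyrotag phylotype.
"""

from __future__ import annotations

import dataclasses
import json
from collections.abc import Mapping, Sequence

import pandas as pd
from scipy import stats

from .community import AbundanceTable, majors as _majors


@dataclasses.dataclass
class MistagReport:
    """Per-library foreign-read counts, correlation, and run-level fractions."""

    per_sample: pd.DataFrame
    slope: float
    intercept: float
    pearson_r: float
    mistag_fraction: float
    mistag_fraction_cross_termite: float
    total_reads: int

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "pearson_r": self.pearson_r,
            "mistag_fraction": self.mistag_fraction,
            "mistag_fraction_cross_termite": self.mistag_fraction_cross_termite,
            "total_reads": self.total_reads,
            "per_sample": self.per_sample.reset_index()
            .rename(columns={"index": "sample_id"})
            .to_dict(orient="records"),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def foreign_counts(
    table: AbundanceTable,
    majors: Mapping[str, str],
    host_map: Mapping[str, str],
) -> pd.DataFrame:
    """Own-major and foreign counts per library.

    For each library *s* with major phylotype P: ``o`` is the count of P in
    *s* itself; ``f`` is the summed count of P across all libraries whose
    host species differs from that of *s*.
    """
    counts = table.counts
    rows = {}
    for s, major in majors.items():
        o = int(counts.loc[s, major])
        f = int(
            sum(
                counts.loc[t, major]
                for t in counts.index
                if host_map[t] != host_map[s]
            )
        )
        rows[s] = {"major": major, "o": o, "f": f}
    return pd.DataFrame.from_dict(rows, orient="index")


def mistag_correlation(
    pairs: Sequence[tuple[float, float]],
) -> tuple[float, float, float]:
    """OLS of foreign counts on own-major counts plus Pearson r.

    Requires at least three (o, f) pairs and variance in o.
    """
    if len(pairs) < 3:
        raise ValueError("mistag_correlation requires >= 3 (o, f) pairs")
    o = [p[0] for p in pairs]
    f = [p[1] for p in pairs]
    if len(set(o)) == 1:
        raise ValueError("zero variance in own-major counts")
    res = stats.linregress(o, f)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def run_mistag_fraction(
    table: AbundanceTable,
    majors: Mapping[str, str],
    termite_map: Mapping[str, str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Run-level mistagged-read fraction and per-sample breakdown.

    Default rule: a read in library *s* is mistagged iff its phylotype is not
    major(s) but is the major of at least one other library.  The returned
    frame also carries ``mistagged_cross_termite`` (phylotypes whose home
    libraries all lie in the other termite species) when ``termite_map`` is
    given; libraries sharing a major are blind spots of both rules by
    construction.
    """
    counts = table.counts
    homes: dict[str, set[str]] = {}
    for s, p in majors.items():
        homes.setdefault(p, set()).add(s)
    rows = {}
    for s in counts.index:
        total = int(counts.loc[s].sum())
        own_major = majors.get(s)
        mis = mis_ct = 0
        for p in counts.columns:
            n = int(counts.loc[s, p])
            if n == 0 or p == own_major or p not in homes:
                continue
            if homes[p] - {s}:
                mis += n
                if termite_map is not None and all(
                    termite_map[t] != termite_map[s] for t in homes[p] - {s}
                ):
                    mis_ct += n
        rows[s] = {
            "total": total,
            "mistagged": mis,
            "mistagged_cross_termite": mis_ct,
        }
    per_sample = pd.DataFrame.from_dict(rows, orient="index")
    grand = int(per_sample["total"].sum())
    fraction = per_sample["mistagged"].sum() / grand if grand else 0.0
    return float(fraction), per_sample


def purity_check(
    clone_seqs: Sequence[str] | Sequence[tuple[str, str]],
    representative: str,
) -> tuple[int, int]:
    """Count clones identical to the representative over the shorter length.

    Clones are full-length amplicons while the pyrotag representative is a 5'
    prefix, so each comparison is over the shorter of the two sequences.
    Returns ``(n_identical, n_total)``; an empty clone set gives ``(0, 0)``.
    """
    if not representative:
        raise ValueError("purity_check requires a non-empty representative")
    n_identical = n_total = 0
    for clone in clone_seqs:
        seq = clone[1] if isinstance(clone, tuple) else clone
        n_total += 1
        L = min(len(seq), len(representative))
        if L and seq[:L] == representative[:L]:
            n_identical += 1
    return n_identical, n_total


def mistag_report(table: AbundanceTable) -> MistagReport:
    """Full artifact analysis on one abundance table."""
    maj = _majors(table)
    host_map = table.host_map()
    termite_map = table.termite_map()
    fc = foreign_counts(table, maj, host_map)
    slope, intercept, r = mistag_correlation(list(zip(fc["o"], fc["f"])))
    fraction, per_sample = run_mistag_fraction(table, maj, termite_map)
    grand = int(per_sample["total"].sum())
    fraction_ct = per_sample["mistagged_cross_termite"].sum() / grand if grand else 0.0
    per_sample = per_sample.join(fc[["major", "o", "f"]])
    return MistagReport(
        per_sample=per_sample,
        slope=slope,
        intercept=intercept,
        pearson_r=r,
        mistag_fraction=float(fraction),
        mistag_fraction_cross_termite=float(fraction_ct),
        total_reads=grand,
    )


def switch_visibility(
    truth: pd.DataFrame, majors: Mapping[str, str]
) -> dict[str, float]:
    """Measure the estimator's blind spot against the simulation truth table.

    A switched read is invisible to the shared-phylotype rule when its origin
    and observed libraries call the same major phylotype.  Returns the
    switched count, the invisible (same-major) fraction among switched reads,
    and the truth-level switched fraction of the whole run.
    """
    switched = truth[truth["switched"]]
    n_switched = len(switched)
    if n_switched == 0:
        same_major = 0.0
    else:
        same = sum(
            majors.get(row.origin_library) == majors.get(row.observed_library)
            for row in switched.itertuples()
        )
        same_major = same / n_switched
    return {
        "n_switched": float(n_switched),
        "same_major_fraction": same_major,
        "true_switched_fraction": n_switched / len(truth) if len(truth) else 0.0,
    }
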