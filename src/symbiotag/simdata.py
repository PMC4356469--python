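"""Synthetic multiplexed pyrotag runs with a controlled tag-switching process.

The generator emulates a single 454-style sequencing run of barcoded ITS
amplicons from single-cell endosymbiont libraries:

* a phylogenetically structured reference set (one ancestor per host species
  derived from a common root, host-specific phylotypes derived from each
  ancestor), rejected and re-drawn until all cross-phylotype identities are
  below the clustering threshold minus a safety margin;
* one true phylotype per library (each host cell carries a homogeneous
  symbiont population);
* reads built as barcode + forward primer + 5' prefix of the ITS sequence,
  truncated to a drawn read length that never reaches the far end of the
  ~600 bp amplicon, so only the forward tag is ever observable;
* per-base substitution errors drawn from the read's own quality string
  (declining Q38 -> Q25 profile; error probability at each base is
  10^(-Q/10)), which couples expected-error filtering to the error model;
* tag switching: with probability ``tag_switch_prob`` a read's observed
  barcode is replaced by one drawn uniformly from the other n-1 libraries,
  so a switched read is always observed in a foreign library and the
  expected switched fraction equals ``tag_switch_prob`` exactly.

A truth table records origin and observed library for every read.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd

from .clustering import pairwise_identity
from .readprep import FORWARD_PRIMER, SampleSpec, TaggedRead

_BASE_BYTES = np.frombuffer(b"ACGT", np.uint8)

#: Mean per-base substitution rate implied by the nominal Q38->Q25 quality
#: profile; ``per_base_error_rate`` rescales the profile relative to this.
PROFILE_NOMINAL_RATE = 1.0e-3


class SimulationGeometryError(RuntimeError):
    """Raised when separable references cannot be drawn (settings too tight)."""


@dataclasses.dataclass(frozen=True)
class HostSpec:
    host_species: str
    termite_species: str
    n_phylotypes: int
    n_libraries: int


@dataclasses.dataclass
class SimConfig:
    """Parameters of one synthetic multiplexed run."""

    seed: int = 1
    hosts: tuple[HostSpec, ...] = ()
    between_host_divergence: float = 0.10
    within_host_divergence: float = 0.02
    its_length: int = 565
    library_depth_range: tuple[int, int] = (300, 3000)
    per_base_error_rate: float = 1.0e-3
    tag_switch_prob: float = 0.15
    read_length_mean: float = 350.0
    read_length_sd: float = 25.0
    read_length_bounds: tuple[int, int] = (200, 400)
    barcode_length: int = 8
    separability_margin: float = 0.003
    separability_window: int = 250

    def __post_init__(self) -> None:
        if not self.hosts:
            raise ValueError("SimConfig requires at least one host")
        if not (0.0 <= self.tag_switch_prob < 1.0):
            raise ValueError("tag_switch_prob must be in [0, 1)")
        if not (0.0 <= self.per_base_error_rate < 1.0):
            raise ValueError("per_base_error_rate must be in [0, 1)")
        for h in self.hosts:
            if h.n_phylotypes < 1 or h.n_libraries < h.n_phylotypes:
                raise ValueError(
                    f"host {h.host_species!r}: needs n_phylotypes >= 1 and "
                    "n_libraries >= n_phylotypes (every phylotype must be "
                    "carried by at least one library)"
                )
        lo, hi = self.library_depth_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid library_depth_range")
        lo, hi = self.read_length_bounds
        if lo <= self.barcode_length + len(FORWARD_PRIMER) or hi < lo:
            raise ValueError("read_length_bounds too short for barcode + primer")
        if hi > self.barcode_length + len(FORWARD_PRIMER) + self.its_length:
            raise ValueError("read length may exceed the amplicon")

    @property
    def n_libraries(self) -> int:
        return sum(h.n_libraries for h in self.hosts)

    @property
    def n_phylotypes(self) -> int:
        return sum(h.n_phylotypes for h in self.hosts)


def paper_mimic_config(seed: int = 1, **overrides) -> SimConfig:
    """The packaged study scenario: 45 libraries, 5 hosts, 17 phylotypes.

    Nine single-cell libraries per host species; *T. agilis* (from
    *R. santonensis*) carries two closely related phylotypes, while the four
    *Zootermopsis nevadensis* hosts are more diverse (3 + 3 + 5 + 4).
    """
    hosts = (
        HostSpec("Trichonympha agilis", "Reticulitermes santonensis", 2, 9),
        HostSpec("Trichonympha sphaerica", "Zootermopsis nevadensis", 3, 9),
        HostSpec("Trichonympha collaris", "Zootermopsis nevadensis", 3, 9),
        HostSpec("Trichonympha postcylindrica", "Zootermopsis nevadensis", 5, 9),
        HostSpec("Trichonympha campanula", "Zootermopsis nevadensis", 4, 9),
    )
    return SimConfig(seed=seed, hosts=hosts, **overrides)


@dataclasses.dataclass(frozen=True)
class Reference:
    phylotype: str
    host_species: str
    termite_species: str
    sequence: str


@dataclasses.dataclass
class RunResult:
    """Everything one synthetic run produces, truth included."""

    config: SimConfig
    references: list[Reference]
    reads: list[TaggedRead]
    samples: list[SampleSpec]
    truth: pd.DataFrame
    assignments: dict[str, Reference]


def _host_abbrev(host_species: str) -> str:
    genus, _, epithet = host_species.partition(" ")
    return (genus[:1] + epithet[:4]).capitalize()


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate`` to a different base."""
    out = seq.copy()
    mask = rng.random(seq.size) < rate
    n = int(mask.sum())
    if n:
        out[mask] = (out[mask] + rng.integers(1, 4, n)) % 4
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode()


def _separable(a: str, b: str, limit: float, window: int) -> bool:
    """True if both the full-length and first-``window`` identities are < limit."""
    for x, y in ((a, b), (a[:window], b[:window])):
        arr_x = np.frombuffer(x.encode(), np.uint8)
        arr_y = np.frombuffer(y.encode(), np.uint8)
        # Hamming screen: alignment identity can only exceed 1 - d/L, so a
        # clearly divergent pair needs no alignment; borderline pairs get the
        # exact global-alignment identity.
        d = int(np.count_nonzero(arr_x != arr_y))
        if 1.0 - d / len(x) < limit - 0.005:
            continue
        if pairwise_identity(x, y) >= limit:
            return False
    return True


def generate_references(
    config: SimConfig, max_attempts: int = 200
) -> list[Reference]:
    """Draw host-structured reference phylotypes separable at 99% identity.

    Host ancestors derive from a common root and phylotypes from their host
    ancestor; each divergence parameter is the expected *pairwise* divergence
    between sister sequences, so each branch mutates at half that rate.
    Candidate phylotypes are re-drawn until every cross-phylotype identity
    (full length and over the first ``separability_window`` bases) is below
    0.99 - margin; deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    limit = 0.99 - config.separability_margin
    window = config.separability_window
    root = rng.integers(0, 4, config.its_length).astype(np.uint8)
    references: list[Reference] = []
    accepted: list[str] = []
    for host in config.hosts:
        ancestor = _mutate(root, config.between_host_divergence / 2.0, rng)
        abbrev = _host_abbrev(host.host_species)
        for k in range(host.n_phylotypes):
            for _ in range(max_attempts):
                cand = _codes_to_str(
                    _mutate(ancestor, config.within_host_divergence / 2.0, rng)
                )
                if all(_separable(cand, prev, limit, window) for prev in accepted):
                    break
            else:
                raise SimulationGeometryError(
                    f"could not draw a separable phylotype for "
                    f"{host.host_species!r} after {max_attempts} attempts; "
                    "divergence settings too tight for the requested counts"
                )
            accepted.append(cand)
            references.append(
                Reference(
                    phylotype=f"{abbrev}-{k + 1}",
                    host_species=host.host_species,
                    termite_species=host.termite_species,
                    sequence=cand,
                )
            )
    return references


def _draw_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    barcodes: list[str] = []
    seen: set[str] = set()
    while len(barcodes) < n:
        bc = _codes_to_str(rng.integers(0, 4, length).astype(np.uint8))
        if bc not in seen:
            seen.add(bc)
            barcodes.append(bc)
    return barcodes


def _quality_and_errors(
    length: int, rate: float, rng: np.random.Generator,
    profile_cache: dict[int, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a declining quality string and the error mask implied by it.

    The nominal profile declines linearly Q38 at 5' to Q25 at 3' with per-base
    jitter (sd 2); ``rate`` rescales the implied error probabilities relative
    to the nominal profile mean.  The returned qualities encode exactly the
    substitution probabilities used, so expected-error filtering sees the
    true error process.
    """
    base = profile_cache.get(length)
    if base is None:
        base = np.linspace(38.0, 25.0, length)
        profile_cache[length] = base
    q = base + rng.normal(0.0, 2.0, length)
    if rate == 0.0:
        q = np.clip(np.rint(q), 2, 41).astype(np.int16)
        return q, np.zeros(length, dtype=bool)
    if rate != PROFILE_NOMINAL_RATE:
        p = 10.0 ** (-q / 10.0) * (rate / PROFILE_NOMINAL_RATE)
        with np.errstate(divide="ignore"):
            q = -10.0 * np.log10(p)
    q = np.clip(np.rint(q), 2, 41).astype(np.int16)
    p = 10.0 ** (-q / 10.0)
    errors = rng.random(length) < p
    return q, errors


def generate_run(config: SimConfig, references: Sequence[Reference]) -> RunResult:
    """Simulate one multiplexed run: reads, sample sheet, and truth table."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    by_host: dict[str, list[Reference]] = {}
    for ref in references:
        by_host.setdefault(ref.host_species, []).append(ref)
    for host in config.hosts:
        if len(by_host.get(host.host_species, [])) != host.n_phylotypes:
            raise ValueError(
                f"references do not match config for host {host.host_species!r}"
            )

    barcodes = _draw_barcodes(config.n_libraries, config.barcode_length, rng)
    samples: list[SampleSpec] = []
    assignments: dict[str, Reference] = {}
    lib_refs: list[Reference] = []
    i = 0
    for host in config.hosts:
        abbrev = _host_abbrev(host.host_species)
        phylos = by_host[host.host_species]
        for j in range(host.n_libraries):
            sid = f"{abbrev}-{j + 1:02d}"
            samples.append(
                SampleSpec(sid, barcodes[i], host.host_species, host.termite_species)
            )
            # round-robin: every phylotype of a host is carried by >= 1 library
            assignments[sid] = phylos[j % len(phylos)]
            lib_refs.append(phylos[j % len(phylos)])
            i += 1

    n_libs = len(samples)
    primer = FORWARD_PRIMER
    prefix_len = config.barcode_length + len(primer)
    ref_codes = {
        r.phylotype: np.searchsorted(
            _BASE_BYTES, np.frombuffer(r.sequence.encode(), np.uint8),
            sorter=np.argsort(_BASE_BYTES),
        ).astype(np.uint8)
        for r in references
    }
    # argsort(_BASE_BYTES) is identity (ACGT is ascending); map via frombuffer
    bc_codes = [
        np.searchsorted(_BASE_BYTES, np.frombuffer(bc.encode(), np.uint8)).astype(np.uint8)
        for bc in barcodes
    ]
    primer_codes = np.searchsorted(
        _BASE_BYTES, np.frombuffer(primer.encode(), np.uint8)
    ).astype(np.uint8)

    lo_d, hi_d = config.library_depth_range
    lo_l, hi_l = config.read_length_bounds
    profile_cache: dict[int, np.ndarray] = {}
    reads: list[TaggedRead] = []
    truth_rows: list[tuple[str, str, str, str, bool]] = []
    counter = 0
    for lib_idx, sample in enumerate(samples):
        ref = lib_refs[lib_idx]
        its = ref_codes[ref.phylotype]
        depth = int(rng.integers(lo_d, hi_d + 1))
        lengths = np.clip(
            np.rint(rng.normal(config.read_length_mean, config.read_length_sd, depth)),
            lo_l, hi_l,
        ).astype(int)
        switched = rng.random(depth) < config.tag_switch_prob
        targets = rng.integers(0, n_libs - 1, depth)
        targets = targets + (targets >= lib_idx)  # uniform over the other n-1
        for r in range(depth):
            length = int(lengths[r])
            obs_idx = int(targets[r]) if switched[r] else lib_idx
            template = np.concatenate(
                (bc_codes[obs_idx], primer_codes, its[: length - prefix_len])
            )
            quals, err = _quality_and_errors(
                length, config.per_base_error_rate, rng, profile_cache
            )
            n_err = int(err.sum())
            if n_err:
                template = template.copy()
                template[err] = (template[err] + rng.integers(1, 4, n_err)) % 4
            read_id = f"read{counter:06d}"
            counter += 1
            reads.append(
                TaggedRead(id=read_id, bases=_codes_to_str(template), quals=quals)
            )
            truth_rows.append(
                (
                    read_id,
                    sample.sample_id,
                    samples[obs_idx].sample_id,
                    ref.phylotype,
                    bool(switched[r]),
                )
            )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id", "origin_library", "observed_library",
            "origin_phylotype", "switched",
        ],
    )
    assert (
        (truth["origin_library"] != truth["observed_library"]) == truth["switched"]
    ).all()
    return RunResult(
        config=config,
        references=list(references),
        reads=reads,
        samples=samples,
        truth=truth,
        assignments=assignments,
    )


def generate_switching_truth(
    config: SimConfig,
    depths: Sequence[int] | None = None,
) -> tuple[list[SampleSpec], pd.DataFrame, dict[str, str]]:
    """Draw library depths and the tag-switching process without read bases.

    Produces the same kind of truth table as :func:`generate_run` (with
    synthetic phylotype names derived from the host abbreviations) but skips
    sequence construction entirely.  Useful for estimator studies over many
    seeds where only the (origin, observed, phylotype) bookkeeping matters.
    ``depths`` overrides the per-library depth draw, e.g. to impose a
    deliberately skewed run.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    barcodes = _draw_barcodes(config.n_libraries, config.barcode_length, rng)
    samples: list[SampleSpec] = []
    phylo_names: list[str] = []
    assignments: dict[str, str] = {}
    i = 0
    for host in config.hosts:
        abbrev = _host_abbrev(host.host_species)
        for j in range(host.n_libraries):
            sid = f"{abbrev}-{j + 1:02d}"
            samples.append(
                SampleSpec(sid, barcodes[i], host.host_species, host.termite_species)
            )
            assignments[sid] = f"{abbrev}-{j % host.n_phylotypes + 1}"
            phylo_names.append(assignments[sid])
            i += 1
    n_libs = len(samples)
    if depths is not None and len(depths) != n_libs:
        raise ValueError(f"depths must have one entry per library ({n_libs})")
    lo_d, hi_d = config.library_depth_range
    sample_ids = np.array([s.sample_id for s in samples])
    phylo_arr = np.array(phylo_names)
    frames = []
    for lib_idx in range(n_libs):
        depth = int(depths[lib_idx]) if depths is not None else int(
            rng.integers(lo_d, hi_d + 1)
        )
        switched = rng.random(depth) < config.tag_switch_prob
        targets = rng.integers(0, n_libs - 1, depth)
        targets = targets + (targets >= lib_idx)
        obs = np.where(switched, targets, lib_idx)
        frames.append(
            pd.DataFrame(
                {
                    "origin_library": np.repeat(sample_ids[lib_idx], depth),
                    "observed_library": sample_ids[obs],
                    "origin_phylotype": np.repeat(phylo_arr[lib_idx], depth),
                    "switched": switched,
                }
            )
        )
    truth = pd.concat(frames, ignore_index=True)
    truth.insert(0, "read_id", truth.index.astype(str))
    return samples, truth, assignments


def generate_clone_library(
    library_id: str,
    assignments: Mapping[str, Reference],
    n_clones: int,
) -> list[tuple[str, str]]:
    """Simulate Sanger sequencing of a library's pre-run amplicon pool.

    Returns ``n_clones`` full-length, error-free copies of the library's true
    phylotype sequence as ``(clone_id, sequence)`` pairs.  The pool is drawn
    before emulsion PCR/pyrosequencing, so no tag switching and no per-base
    read errors apply.
    """
    if library_id not in assignments:
        raise ValueError(f"unknown library id {library_id!r}")
    if n_clones < 0:
        raise ValueError("n_clones must be non-negative")
    seq = assignments[library_id].sequence
    return [(f"{library_id}_clone{i + 1:02d}", seq) for i in range(n_clones)]
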