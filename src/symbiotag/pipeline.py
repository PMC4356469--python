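"""End-to-end orchestration: simulate -> demux -> filter -> cluster ->
tabulate -> mistag analysis -> host-specificity tree.

All randomness flows from the single seed in the simulation config; rerunning
the same config reproduces byte-identical outputs.  ``run_pipeline`` works
entirely in memory; ``run_all`` additionally writes every artifact plus a
manifest with per-stage record counts and checksums.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Any

import yaml

from . import __version__, clustering, community, io, mistag, phylocheck, readprep
from .simdata import (
    HostSpec,
    RunResult,
    SimConfig,
    generate_references,
    generate_run,
    paper_mimic_config,
)

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclasses.dataclass
class PipelineResult:
    """All in-memory artifacts of one end-to-end run."""

    config: SimConfig
    run: RunResult
    demux_bins: dict[str, list[readprep.TaggedRead]]
    unassigned: list[readprep.TaggedRead]
    filtered: dict[str, list[readprep.TaggedRead]]
    qc_stats: dict
    phylotypes: list[clustering.Phylotype]
    table: community.AbundanceTable
    majors: dict[str, str]
    report: mistag.MistagReport
    tree: phylocheck.Node | None
    newick: str | None


def load_config(source: str | Path | dict) -> tuple[SimConfig, dict]:
    """Build a SimConfig (plus per-stage options) from YAML or a dict.

    Schema: top-level ``seed`` and optional ``scenario: paper-mimic``;
    ``simulate`` holds SimConfig field overrides (``hosts`` as a list of
    [host_species, termite_species, n_phylotypes, n_libraries]); ``filter``
    and ``cluster`` hold stage options.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw: dict = yaml.safe_load(fh) or {}
    else:
        raw = dict(source)
    seed = int(raw.get("seed", 1))
    sim: dict[str, Any] = dict(raw.get("simulate", {}) or {})
    if "hosts" in sim:
        sim["hosts"] = tuple(HostSpec(*h) for h in sim["hosts"])
    for key in ("library_depth_range", "read_length_bounds"):
        if key in sim:
            sim[key] = tuple(sim[key])
    scenario = raw.get("scenario")
    try:
        if scenario in (None, "custom"):
            config = SimConfig(seed=seed, **sim)
        elif scenario == "paper-mimic":
            config = paper_mimic_config(seed=seed, **sim)
        else:
            raise ValueError(f"unknown scenario {scenario!r}")
    except (TypeError, ValueError) as exc:
        raise PipelineError("config", str(exc)) from exc
    stages = {
        "filter": dict(raw.get("filter", {}) or {}),
        "cluster": dict(raw.get("cluster", {}) or {}),
    }
    return config, stages


def process_run(
    run: RunResult,
    min_len: int = readprep.DEFAULT_MIN_LEN,
    max_ee: float = readprep.DEFAULT_MAX_EE,
    threshold: float = clustering.DEFAULT_THRESHOLD,
    build_tree: bool = True,
) -> PipelineResult:
    """Run the analysis stages on an existing (simulated or loaded) run."""
    try:
        bins, unassigned = readprep.demultiplex(run.reads, run.samples)
    except ValueError as exc:
        raise PipelineError("demux", str(exc)) from exc
    qc_stats: dict = {"unassigned": len(unassigned), "per_sample": {}}
    filtered: dict[str, list[readprep.TaggedRead]] = {}
    fstats: dict = {}
    for sample_id, reads in bins.items():
        kept = readprep.quality_filter(reads, min_len=min_len, max_ee=max_ee, stats=fstats)
        filtered[sample_id] = kept
        qc_stats["per_sample"][sample_id] = {
            "assigned": len(reads),
            "passed": len(kept),
        }
    qc_stats.update(fstats)

    uniques = clustering.dereplicate(filtered)
    phylotypes = clustering.greedy_cluster(uniques, threshold=threshold)
    table = community.tabulate(phylotypes, run.samples)
    majors = community.majors(table)
    report = mistag.mistag_report(table)

    tree = newick = None
    if build_tree and len(phylotypes) >= 2:
        reps = {p.phylotype_id: p.representative for p in phylotypes}
        dm = phylocheck.distance_matrix(reps)
        tree = phylocheck.upgma(dm)
        newick = phylocheck.to_newick(tree)

    return PipelineResult(
        config=run.config,
        run=run,
        demux_bins=bins,
        unassigned=unassigned,
        filtered=filtered,
        qc_stats=qc_stats,
        phylotypes=phylotypes,
        table=table,
        majors=majors,
        report=report,
        tree=tree,
        newick=newick,
    )


def run_pipeline(
    config: SimConfig,
    min_len: int = readprep.DEFAULT_MIN_LEN,
    max_ee: float = readprep.DEFAULT_MAX_EE,
    threshold: float = clustering.DEFAULT_THRESHOLD,
    build_tree: bool = True,
) -> PipelineResult:
    """Simulate a run under ``config`` and analyse it, all in memory."""
    references = generate_references(config)
    run = generate_run(config, references)
    return process_run(
        run, min_len=min_len, max_ee=max_ee, threshold=threshold,
        build_tree=build_tree,
    )


def run_all(config_source: str | Path | dict, outdir: str | Path) -> PipelineResult:
    """Execute every stage and write all artifacts plus a RunManifest."""
    config, stages = load_config(config_source)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    result = run_pipeline(
        config,
        min_len=int(stages["filter"].get("min_len", readprep.DEFAULT_MIN_LEN)),
        max_ee=float(stages["filter"].get("max_ee", readprep.DEFAULT_MAX_EE)),
        threshold=float(stages["cluster"].get("threshold", clustering.DEFAULT_THRESHOLD)),
    )
    run = result.run

    io.write_fastq(run.reads, out / "run.fastq")
    io.write_sample_sheet(run.samples, out / "samples.tsv")
    run.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    io.write_fasta(
        [(f"{r.phylotype} host={r.host_species.replace(' ', '_')}", r.sequence)
         for r in run.references],
        out / "references.fasta",
    )
    with open(out / "config.yaml", "w") as fh:
        cfg = dataclasses.asdict(config)
        cfg["hosts"] = [list(dataclasses.astuple(h)) for h in config.hosts]
        yaml.safe_dump(cfg, fh, sort_keys=True)

    persample_dir = out / "per_sample"
    persample_dir.mkdir(exist_ok=True)
    for sample_id, reads in result.filtered.items():
        io.write_fastq(reads, persample_dir / f"{sample_id}.fastq")
    with open(out / "qc.json", "w") as fh:
        json.dump(result.qc_stats, fh, indent=2, sort_keys=True)

    io.write_fasta(io.phylotype_fasta_records(result.phylotypes), out / "phylotypes.fasta")
    membership = [
        (p.phylotype_id, m.bases, m.abundance)
        for p in result.phylotypes
        for m in p.members
    ]
    with open(out / "membership.tsv", "w") as fh:
        fh.write("phylotype_id\tsequence\tabundance\n")
        for pid, seq, ab in membership:
            fh.write(f"{pid}\t{seq}\t{ab}\n")

    io.write_tsv(result.table.counts, out / "counts.tsv")
    io.write_tsv(result.table.relative, out / "relabund.tsv")
    with open(out / "majors.tsv", "w") as fh:
        fh.write("sample_id\tmajor_phylotype\n")
        for sample_id in result.table.sample_ids:
            fh.write(f"{sample_id}\t{result.majors.get(sample_id, 'NA')}\n")

    report_dict = result.report.to_dict()
    report_dict["truth_check"] = mistag.switch_visibility(run.truth, result.majors)
    with open(out / "mistag.json", "w") as fh:
        json.dump(report_dict, fh, indent=2, sort_keys=True)
    io.write_tsv(result.report.per_sample, out / "mistag_per_sample.tsv")

    if result.newick is not None:
        (out / "tree.nwk").write_text(result.newick + "\n")

    n_assigned = sum(len(v) for v in result.demux_bins.values())
    n_filtered = sum(len(v) for v in result.filtered.values())
    manifest = {
        "tool": "symbiotag",
        "version": __version__,
        "seed": config.seed,
        "counts": {
            "simulated_reads": len(run.reads),
            "demux_assigned": n_assigned,
            "demux_unassigned": len(result.unassigned),
            "filter_passed": n_filtered,
            "unique_sequences": sum(len(p.members) for p in result.phylotypes),
            "phylotypes": len(result.phylotypes),
            "table_reads": int(result.table.counts.values.sum()),
        },
        "checksums": {
            p.name: io.sha256(p)
            for p in sorted(out.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    assert manifest["counts"]["demux_assigned"] + manifest["counts"]["demux_unassigned"] \
        == manifest["counts"]["simulated_reads"]
    assert manifest["counts"]["table_reads"] == manifest["counts"]["filter_passed"]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run_all complete: %s", json.dumps(manifest["counts"]))
    return result
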