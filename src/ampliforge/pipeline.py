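"""End-to-end pipeline orchestration and the cross-talk screen.

``run_pipeline`` drives the fixed stage order — read prep, OTU inference,
taxonomy, rarefaction, diversity/ordination/hypothesis tests, co-occurrence
network — and writes a plain-text results directory.  One seed in the config
governs every stochastic step (rarefaction, classifier bootstraps, NMDS
starts, permutation tests), so reruns with the same config produce identical
tabular outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .diversity import (
    ALPHA_INDICES,
    BETA_MEASURES,
    alpha_diversity,
    amova,
    beta_distance,
    homova,
    nmds,
    pcoa,
    upgma_tree,
)
from .io_formats import (
    read_mapping,
    read_oligos,
    write_fasta,
    write_gexf,
    write_newick,
    write_shared_table,
    SequenceRecord,
)
from .network import NetworkParams, build_network, correlate_pairs, filter_network_otus
from .otu_inference import (
    ClusterParams,
    OtuTable,
    build_otu_table,
    cluster_otus,
    dereplicate,
    rarefy_table,
    remove_singletons,
)
from .read_prep import FilterParams, MergeParams, pool_samples
from .taxonomy import RANKS, classify, read_reference_db

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "crosstalk_report"]


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters; flag names mirror the CLI."""

    analysis_name: str
    mapping: str
    oligos: str
    reference_fasta: str | None = None
    reference_taxonomy: str | None = None
    seqformat: str = "fastq"
    seqtype: str = "paired"
    marker_gene: str = "16S"  # accepted and logged; no branching logic
    similarity_cutoff: float = 0.97
    min_overlap_len: int = 100
    max_diffs: int = 8
    pdiffs: int = 2
    maxee: float = 1.0
    trunclen: int = 250
    rarefy_depth: int | None = None  # None -> smallest sample total
    network: NetworkParams = field(default_factory=NetworkParams)
    n_boot: int = 100
    conf_cutoff: float = 0.80
    n_permutations: int = 999
    seed: int = 1


@dataclass
class PipelineResult:
    outdir: Path
    stats: object
    otu_table: OtuTable
    rarefied_table: OtuTable
    taxonomy: dict[str, object]
    distance_matrices: dict[str, object]
    tests: dict[str, object]


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, header)) + "\n")
        for row in rows:
            fh.write("\t".join(map(str, row)) + "\n")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run the full pipeline and populate ``outdir``; see module docstring."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    log_lines.append(f"ampliforge {__version__}")
    log_lines.append(f"config_hash {cfg_hash}")
    for k, v in sorted(cfg_dict.items()):
        log_lines.append(f"param {k} = {v}")

    rng = np.random.default_rng(config.seed)
    seeds = {
        name: int(rng.integers(2**31))
        for name in ("rarefy", "taxonomy", "nmds", "amova", "homova")
    }

    for label, path in (("-map", config.mapping), ("-oligos", config.oligos)):
        if not Path(path).exists():
            raise FileNotFoundError(f"{label}: file not found: {path}")

    # --- stage 1-2: read prep ------------------------------------------------
    entries = read_mapping(config.mapping)
    primers = read_oligos(config.oligos)
    merge_params = MergeParams(config.min_overlap_len, config.max_diffs)
    filter_params = FilterParams(config.trunclen, config.maxee, config.pdiffs)
    reads, stats = pool_samples(
        entries, primers, merge_params, filter_params, seqformat=config.seqformat
    )
    reasons = sorted({r for per in stats.discarded.values() for r in per})
    _write_tsv(
        outdir / "prep_stats.tsv",
        ["sample", "input", "passed", *reasons],
        [
            [
                s,
                stats.input[s],
                stats.passed[s],
                *[stats.discarded.get(s, {}).get(r, 0) for r in reasons],
            ]
            for s in stats.input
        ],
    )
    for s in stats.input:
        total = stats.passed[s] + sum(stats.discarded.get(s, {}).values())
        assert total == stats.input[s], "read accounting does not reconcile"
        log_lines.append(f"sample {s}: {stats.input[s]} in, {stats.passed[s]} passed")
    if not reads:
        raise RuntimeError("no reads survived quality control")

    # --- stage 3: OTU inference ---------------------------------------------
    cluster_params = ClusterParams(similarity_cutoff=config.similarity_cutoff)
    uniques = dereplicate(reads)
    retained = remove_singletons(uniques, cluster_params.min_size)
    otus = cluster_otus(retained, cluster_params)
    if not otus:
        raise RuntimeError("no OTUs formed")
    table = build_otu_table(reads, otus, cluster_params)
    log_lines.append(
        f"otu_inference: {len(uniques)} uniques, {len(retained)} non-singleton, "
        f"{len(otus)} OTUs, {int(table.counts.sum())} reads mapped"
    )
    write_fasta(
        [SequenceRecord(id=o.otu_id, bases=o.centroid) for o in table.otus],
        outdir / "otus.fasta",
    )
    write_shared_table(table, outdir / "otu_table.shared")

    depth = config.rarefy_depth or int(table.counts.sum(axis=1).min())
    log_lines.append(f"rarefaction depth = {depth}")
    rarefied = rarefy_table(table, depth, seed=seeds["rarefy"])
    write_shared_table(rarefied, outdir / "otu_table.rarefied.shared")

    # --- taxonomy ------------------------------------------------------------
    taxonomy: dict[str, object] = {}
    if config.reference_fasta and config.reference_taxonomy:
        db = read_reference_db(config.reference_fasta, config.reference_taxonomy)
        tax_rng = np.random.default_rng(seeds["taxonomy"])
        rows = []
        for otu in table.otus:
            assignment = classify(
                otu.centroid,
                db,
                n_boot=config.n_boot,
                conf_cutoff=config.conf_cutoff,
                seed=int(tax_rng.integers(2**31)),
            )
            taxonomy[otu.otu_id] = assignment
            rows.append([otu.otu_id, otu.size, assignment.lineage_string()])
        _write_tsv(outdir / "taxonomy.tsv", ["otu", "size", "taxonomy"], rows)

    # --- stage 4: diversity --------------------------------------------------
    for name, tbl in (("raw", table), ("rarefied", rarefied)):
        _write_tsv(
            outdir / f"alpha_diversity.{name}.tsv",
            ["sample", *ALPHA_INDICES],
            [
                [s, *[f"{alpha_diversity(tbl.counts[i], ix):.6f}" for ix in ALPHA_INDICES]]
                for i, s in enumerate(tbl.samples)
            ],
        )

    groups = {e.sample_name: e.treatment for e in entries}
    dms: dict[str, object] = {}
    tests: dict[str, object] = {}
    test_rows = []
    for measure in BETA_MEASURES:
        dm = beta_distance(rarefied, measure)
        dms[measure] = dm
        _write_tsv(
            outdir / f"distance.{measure}.tsv",
            ["sample", *dm.labels],
            [[lab, *[f"{v:.6f}" for v in dm.d[i]]] for i, lab in enumerate(dm.labels)],
        )
        write_newick(upgma_tree(dm), outdir / f"upgma.{measure}.nwk")
        if len(dm.labels) >= 3:
            ord_res = pcoa(dm)
            _write_tsv(
                outdir / f"pcoa.{measure}.tsv",
                ["sample", *[f"axis{k+1}" for k in range(ord_res.coordinates.shape[1])]],
                [
                    [lab, *[f"{v:.6f}" for v in ord_res.coordinates[i]]]
                    for i, lab in enumerate(ord_res.labels)
                ],
            )
        if len(dm.labels) >= 4:
            nmds_res = nmds(dm, seed=seeds["nmds"])
            _write_tsv(
                outdir / f"nmds.{measure}.tsv",
                ["sample", "axis1", "axis2"],
                [
                    [lab, *[f"{v:.6f}" for v in nmds_res.coordinates[i]]]
                    for i, lab in enumerate(nmds_res.labels)
                ],
            )
            log_lines.append(f"nmds {measure}: stress = {nmds_res.stress:.4f}")
        group_sizes = {}
        for lab in dm.labels:
            group_sizes[groups[lab]] = group_sizes.get(groups[lab], 0) + 1
        if len(group_sizes) >= 2 and min(group_sizes.values()) >= 2:
            am = amova(dm, groups, config.n_permutations, seed=seeds["amova"])
            hm = homova(dm, groups, config.n_permutations, seed=seeds["homova"])
            tests[f"amova_{measure}"] = am
            tests[f"homova_{measure}"] = hm
            test_rows.append(["amova", measure, f"{am.statistic:.6f}", f"{am.p_value:.6f}"])
            test_rows.append(["homova", measure, f"{hm.statistic:.6f}", f"{hm.p_value:.6f}"])
    if test_rows:
        _write_tsv(outdir / "hypothesis_tests.tsv", ["test", "measure", "statistic", "p"], test_rows)

    # --- network -------------------------------------------------------------
    net_params = config.network
    filtered = filter_network_otus(table, net_params)
    if len(table.samples) >= 4 and len(filtered.otus) >= 2:
        pairs = correlate_pairs(filtered, net_params.method)
        tax_strings = {
            oid: taxonomy[oid].lineage_string() if oid in taxonomy else "unclassified"
            for oid in filtered.otu_ids
        }
        graph = build_network(filtered, pairs, tax_strings, net_params)
        write_gexf(graph, outdir / "cooccurrence.gexf")
        _write_tsv(
            outdir / "cooccurrence_edges.tsv",
            ["otu_i", "otu_j", "r", "p"],
            [
                [filtered.otu_ids[i], filtered.otu_ids[j], f"{r:.6f}", f"{p:.6g}"]
                for i, j, r, p in pairs
            ],
        )
        log_lines.append(
            f"network: {graph.number_of_nodes()} nodes, {graph.number_of_edges()} edges"
        )

    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    return PipelineResult(
        outdir=outdir,
        stats=stats,
        otu_table=table,
        rarefied_table=rarefied,
        taxonomy=taxonomy,
        distance_matrices=dms,
        tests=tests,
    )


def crosstalk_report(
    table: OtuTable,
    major_frac: float = 0.01,
    trace_frac: float = 0.001,
    min_trace_reads: int = 1,
) -> list[dict]:
    """Screen an OTU table for candidate cross-talk (index hopping).

    For every OTU, samples where it is *major* (relative abundance above
    ``major_frac``) and samples where it is *trace* (present with at least
    ``min_trace_reads`` reads but below ``trace_frac``) are listed; each
    (OTU, trace sample) pair with at least one major sample elsewhere is
    flagged as consistent with cross-talk.  Raising ``min_trace_reads`` or
    lowering ``trace_frac`` can only reduce the number of flags.
    """
    if not (0.0 < trace_frac < major_frac):
        raise ValueError("need 0 < trace_frac < major_frac")
    rel = table.relative_abundances()
    flags: list[dict] = []
    for j, oid in enumerate(table.otu_ids):
        col_rel = rel[:, j]
        col_counts = table.counts[:, j]
        major = [table.samples[i] for i in np.flatnonzero(col_rel > major_frac)]
        trace = [
            table.samples[i]
            for i in np.flatnonzero(
                (col_counts >= min_trace_reads) & (col_rel < trace_frac)
            )
        ]
        if not major:
            continue
        for t in trace:
            flags.append(
                {
                    "otu": oid,
                    "trace_sample": t,
                    "major_samples": major,
                    "trace_fraction": float(col_rel[table.samples.index(t)]),
                }
            )
    return flags


def write_crosstalk_report(flags: Sequence[dict], path: str | Path) -> None:
    _write_tsv(
        Path(path),
        ["otu", "trace_sample", "trace_fraction", "major_samples"],
        [
            [
                f["otu"],
                f["trace_sample"],
                f"{f['trace_fraction']:.6g}",
                ",".join(f["major_samples"]),
            ]
            for f in flags
        ],
    )
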