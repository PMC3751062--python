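"""End-to-end orchestration: simulate (or load) reads, assemble across k,
select/filter/merge, extract ORFs, search, cluster, annotate, measure
completeness, partition host vs symbiont, and quantify expression.

Every stage threshold carries its published default: 150 bp contig and ORF
length floors, annotation E-value 2e-30 (relaxed tier 2e-10), inflation
r = 2.5, completeness coverage 0.80, symbiont cutoff 1e-80, top-3 k
selection.  A run is fully determined by its configuration and seed; all
intermediates are written to the output directory and a machine-readable
run report is produced.
"""

from __future__ import annotations

import copy
import json
import logging
import time
from pathlib import Path
from typing import Mapping

import yaml

from . import assembly, clustering, homology, orffinder, partition, quantify, simulate
from .seqio import SeqRecord, read_fasta, read_fastq, write_fasta, write_fastq

__all__ = ["DEFAULT_CONFIG", "load_config", "run_pipeline", "PipelineError"]

logger = logging.getLogger("holotx")

DEFAULT_CONFIG: dict = {
    "simulate": {
        "n_families": 12,
        "paralogs_per_family": 2,
        "n_host": 36,
        "n_symbiont": 8,
        "n_pairs": 4000,
        "length_range": [100, 180],
        "host_divergence": 0.05,
        "symbiont_pool_divergence": 0.50,
        "error_rate": 0.005,
        "read_len": 75,
        "insert_mean": 200,
        "insert_sd": 30,
        "expression_sigma": 1.0,
    },
    "inputs": {                      # used instead of "simulate" on real data
        "reads1": None,
        "reads2": None,
        "reference_proteome": None,
        "reference_annotation": None,
        "symbiont_db": None,
    },
    "assembly": {
        "k_values": [29, 33, 37, 41, 45],
        "min_kmer_count": 2,
        "top_n": 3,
        "min_contig_len": 150,
        "merge_min_overlap": 40,
        "merge_min_identity": 0.90,
    },
    "orf": {"min_nt": 150},
    "annotation": {
        "evalue_max": 2e-30,
        "evalue_relaxed": 2e-10,
        "completeness_min_cov": 0.80,
    },
    "clustering": {
        "inflation": 2.5,
        "prune": 1e-5,
        "max_iter": 200,
        "tol": 1e-8,
        "weight_cap": 200.0,
    },
    "partition": {
        "cutoff": 1e-80,
        "calibrate": False,
        "average": "geometric",
    },
    "quantify": {"seed_len": 31, "max_mismatch": 2},
    "confirm_translated": True,
}


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def load_config(path) -> dict:
    """Load a YAML configuration, filling unset keys from the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    for section, values in user.items():
        if isinstance(values, Mapping) and isinstance(cfg.get(section), Mapping):
            cfg[section].update(values)
        else:
            cfg[section] = values
    return cfg


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(config: dict | None = None, seed: int = 0,
                 out_dir="holotx_run") -> dict:
    """Run all stages; returns the run report (also written as JSON).

    With a ``simulate`` block the inputs are generated with the given seed;
    otherwise the ``inputs`` block names the read pair, reference proteome,
    reference annotation table and symbiont transcriptome.  Identical
    config + seed give identical outputs (report timing excepted).
    """
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if config:
        for section, values in config.items():
            if isinstance(values, Mapping) and isinstance(cfg.get(section), Mapping):
                cfg[section].update(values)
            else:
                cfg[section] = values
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    report: dict = {"seed": seed, "parameters": cfg, "stages": {}}
    stages = report["stages"]

    # ---- inputs -----------------------------------------------------------
    truth = None
    if cfg.get("simulate"):
        _stage("simulate")
        sim = dict(cfg["simulate"])
        sim["length_range"] = tuple(sim["length_range"])
        truth, m1, m2 = simulate.simulate_holobiont(seed=seed, **sim)
        simulate.write_truth_tables(truth, out / "truth")
        write_fastq(m1, out / "reads_1.fastq")
        write_fastq(m2, out / "reads_2.fastq")
        reference_proteome = truth.reference_proteome
        annotation = simulate.simulate_annotation(
            reference_proteome, truth.family_of, seed=seed)
        annotation.to_csv(out / "truth" / "reference_annotation.tsv",
                          sep="\t", index=False)
        symbiont_db = truth.symbiont_pool
        reads = m1 + m2
    else:
        _stage("load inputs")
        inp = cfg["inputs"]
        try:
            m1 = read_fastq(inp["reads1"])
            m2 = read_fastq(inp["reads2"])
            reference_proteome = read_fasta(inp["reference_proteome"])
            annotation = clustering.read_annotation(inp["reference_annotation"])
            symbiont_db = read_fasta(inp["symbiont_db"])
        except Exception as exc:
            raise PipelineError("load inputs", str(exc)) from exc
        reads = m1 + m2
    stages["reads"] = {"n_pairs": len(m1), "n_reads": len(reads)}

    # ---- assembly ---------------------------------------------------------
    _stage("assemble")
    acfg = cfg["assembly"]
    try:
        assemblies = assembly.assemble_multik(reads, acfg["k_values"],
                                              acfg["min_kmer_count"])
    except ValueError as exc:
        raise PipelineError("assemble", str(exc)) from exc
    per_k = {}
    with open(out / "nstats.tsv", "w") as fh:
        fh.write("assembly\tn_contigs\ttotal_bp\t" +
                 "\t".join(f"N{x}" for x in range(10, 100, 10)) +
                 "\tmedian\tmean\n")
        for k in sorted(assemblies):
            contigs = assemblies[k]
            write_fasta([SeqRecord(c.id, c.seq) for c in contigs],
                        out / f"assembly_k{k}.fasta")
            if contigs:
                st = assembly.compute_nstats(contigs)
                per_k[k] = {"n_contigs": st.n_contigs, "n50": st.n50,
                            "median": st.median_length}
                fh.write(f"k{k}\t{st.n_contigs}\t{st.total_length}\t" +
                         "\t".join(str(st.nx[x]) for x in range(10, 100, 10)) +
                         f"\t{st.median_length:g}\t{st.mean_length:.2f}\n")
            else:
                per_k[k] = {"n_contigs": 0, "n50": 0, "median": 0}
    stages["assembly_per_k"] = per_k

    _stage("select/filter")
    try:
        pool = assembly.select_and_filter(assemblies, acfg["top_n"],
                                          acfg["min_contig_len"])
    except ValueError as exc:
        raise PipelineError("select/filter", str(exc)) from exc
    write_fasta([SeqRecord(c.id, c.seq) for c in pool], out / "combined.fasta")
    stages["selected_pool"] = {"n_contigs": len(pool)}

    _stage("merge")
    merged = assembly.merge_assemblies(pool, acfg["merge_min_overlap"],
                                       acfg["merge_min_identity"])
    write_fasta([SeqRecord(c.id, c.seq) for c in merged], out / "merged.fasta")
    mstats = assembly.compute_nstats(merged) if merged else None
    stages["merged"] = {"n_contigs": len(merged),
                        "n50": mstats.n50 if mstats else 0}

    # ---- ORFs -------------------------------------------------------------
    _stage("orfs")
    orfs = []
    for c in merged:
        orfs.extend(orffinder.find_orfs(SeqRecord(c.id, c.seq),
                                        cfg["orf"]["min_nt"]))
    orffinder.orf_table(orfs).to_csv(out / "orfs.tsv", sep="\t", index=False)
    peptides = orffinder.orf_peptides(orfs)
    write_fasta(peptides, out / "orfs.faa")
    stages["orfs"] = {"n_orfs": len(orfs)}

    # ---- homology search --------------------------------------------------
    _stage("search")
    anncfg = cfg["annotation"]
    if not reference_proteome:
        raise PipelineError("search", "reference proteome is empty")
    hits = homology.search(peptides, reference_proteome,
                           homology.PROTEIN_SCHEME,
                           evalue_max=anncfg["evalue_max"])
    homology.write_hits(hits, out / "hits.tsv")
    annotated_orf_ids = sorted(set(hits["qseqid"])) if not hits.empty else []
    stages["search"] = {"n_hits": int(len(hits)),
                        "n_annotated_orfs": len(annotated_orf_ids)}

    # ---- clustering -------------------------------------------------------
    _stage("cluster")
    ccfg = cfg["clustering"]
    if not hits.empty:
        graph = homology.build_precluster_graph(hits, ccfg["weight_cap"])
        homology.write_graph_abc(graph, out / "precluster.abc")
        mres = clustering.mcl(graph, ccfg["inflation"], ccfg["prune"],
                              ccfg["max_iter"], ccfg["tol"])
        clusters = clustering.make_isoform_clusters(
            mres, [p.id for p in reference_proteome])
    else:
        clusters = []
    _stage("annotate")
    if clusters:
        clusters, tally = clustering.transfer_annotation(clusters, annotation,
                                                         hits)
        tally.to_csv(out / "annotation_tally.tsv", sep="\t", index=False)
        clustering.write_clusters(clusters, out / "clusters.tsv")
        with open(out / "annotated_clusters.tsv", "w") as fh:
            fh.write("cluster_id\tgene_name\tn_orfs\tn_refs\tgo\tkog\tinterpro\n")
            for cl in clusters:
                fh.write(f"{cl.cluster_id}\t{cl.gene_name}\t"
                         f"{len(cl.member_orf_ids)}\t{len(cl.member_reference_ids)}\t"
                         f"{';'.join(cl.go_terms)}\t{';'.join(cl.kog_terms)}\t"
                         f"{';'.join(cl.interpro_terms)}\n")
    n_annotated_clusters = sum(1 for cl in clusters if cl.gene_name)
    stages["clusters"] = {"n_clusters": len(clusters),
                          "n_annotated_clusters": n_annotated_clusters}

    # ---- completeness -----------------------------------------------------
    _stage("completeness")
    ref_lengths = {p.id: len(p.seq) for p in reference_proteome}
    pct = homology.completeness(hits, ref_lengths,
                                anncfg["completeness_min_cov"],
                                anncfg["evalue_max"])
    stages["completeness"] = {"percent": pct}

    # ---- partition --------------------------------------------------------
    _stage("partition")
    orf_by_id = {o.orf_id: o for o in orfs}
    regions = orffinder.orf_cdna_export([orf_by_id[i] for i in annotated_orf_ids])
    write_fasta(regions, out / "annotated_cdna.fasta")
    pcfg = cfg["partition"]
    cutoff = pcfg["cutoff"]
    if pcfg.get("calibrate") and truth is not None:
        host_side = simulate.reference_cds(truth.reference_proteome, seed)
        try:
            cutoff = partition.calibrate_threshold(host_side, symbiont_db,
                                                   method=pcfg["average"])
        except ValueError:
            logger.warning("calibration found no cross-hits; using configured "
                           "cutoff %.3g", cutoff)
    if regions:
        presult, non_symbiont = partition.classify_origin(
            regions, symbiont_db, cutoff=cutoff, total_contigs=len(merged))
        partition.write_partition(presult, out / "partition.tsv")
        write_fasta(non_symbiont, out / "non_symbiont.fasta")
        stages["partition"] = {
            "threshold": cutoff,
            "n_symbiont": presult.n_symbiont,
            "n_host": presult.n_host,
            "pct_of_annotated": presult.fraction_symbiont_of_annotated,
            "pct_of_total_contigs": presult.fraction_symbiont_of_total_contigs,
        }
    else:
        presult, non_symbiont = None, []
        stages["partition"] = {"threshold": cutoff, "n_symbiont": 0,
                               "n_host": 0, "pct_of_annotated": 0.0,
                               "pct_of_total_contigs": 0.0}

    # ---- translated confirmation ------------------------------------------
    if cfg.get("confirm_translated") and non_symbiont:
        _stage("confirm translated")
        expected = {row.qseqid: row.sseqid
                    for row in homology.best_hits(hits).itertuples(index=False)}
        agreement = partition.confirm_translated_annotation(
            non_symbiont, reference_proteome, expected,
            evalue_max=anncfg["evalue_max"])
        stages["translated_confirmation"] = {"agreement": agreement}

    # ---- quantify ---------------------------------------------------------
    _stage("quantify")
    qcfg = cfg["quantify"]
    if regions:
        mapping = quantify.map_reads(reads, regions, qcfg["seed_len"],
                                     qcfg["max_mismatch"])
        records = quantify.expression_table(mapping, regions)
        quantify.write_expression(records, out / "expression.tsv")
        summary = quantify.expression_summary(records)
        stages["quantify"] = {"n_mapped": mapping.n_mapped,
                              "n_ambiguous": mapping.n_ambiguous,
                              "n_unmapped": mapping.n_unmapped,
                              "summary": summary}
    else:
        stages["quantify"] = {"n_mapped": 0, "n_ambiguous": 0,
                              "n_unmapped": len(reads), "summary": {}}

    report_path = out / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    logger.info("pipeline finished in %.1f s; report at %s",
                time.time() - t0, report_path)
    return report
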