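"""End-to-end orchestration: simulate -> collapse -> annotate -> de ->
intersect -> targets -> network -> enrich, driven by one YAML-style config.

Each stage writes plain-text outputs into the run directory and appends an
entry (parameters, output digests, wall time) to ``manifest.json``. Stage
outputs are byte-identical across reruns with the same config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Callable, Mapping

import pandas as pd
import yaml

from . import __version__
from .cross_species import (
    apply_ortholog_map,
    mirna_identity_map,
    shared_de_features,
    venn_partition,
)
from .diffexpr import CountMatrix, call_de_replicated, call_de_unreplicated
from .mirna_annotation import MiRNACatalog, aggregate_mirna_counts, conserved_tags, partition_conserved
from .network import (
    anchored_subnetwork,
    export_graph,
    hypergeom_enrichment,
    integrate_regulatory_edges,
    set_node_fold_changes,
    top_core,
)
from .smallrna_io import collapse_tags, process_reads, read_sequences, TagTable
from .synthetic_data import ANCHOR_SPECIES, SPECIES, SimConfig, simulate_reads, simulate_study
from .target_prediction import inverse_expression_filter, predict_targets

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "collapse",
    "annotate",
    "de",
    "intersect",
    "targets",
    "network",
    "enrich",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage. Partial outputs remain."""


def demo_config(seed: int = 42) -> dict[str, Any]:
    """Small self-contained configuration exercising every stage."""
    return {
        "rng_seed": seed,
        "species": {
            "zebrafish": {"role": "anchor_replicated", "n_ctrl": 3, "n_case": 3},
            "bichir": {"role": "unreplicated", "n_ctrl": 1, "n_case": 1},
            "axolotl": {"role": "unreplicated", "n_ctrl": 1, "n_case": 1},
        },
        "simulate": {
            "n_shared_mirnas": 30,
            "n_pairwise": 4,
            "n_unique_per_species": 4,
            "n_genes": 120,
            "n_anchor_genes": 8,
            "frac_planted_up": 0.15,
            "frac_planted_down": 0.12,
            "effect_log2fc": 2.0,
            "dispersion": 0.1,
            "lib_sizes": 20000,
            "isomir_rate": 0.05,
            "trf_rate": 0.01,
            "rrf_rate": 0.01,
            "utr_len": 240,
            "sites_per_target": 1,
            "n_target_genes": 12,
            "n_interactions": 300,
        },
        "collapse": {"min_len": 20, "max_len": 25, "q_threshold": 20,
                     "min_overlap": 5, "max_mismatch": 1},
        "de": {"alpha": 0.05, "fc_threshold": 0.58},
        "intersect": {"unreplicated_rule": "sign_only"},
        "targets": {"min_score": 0.0, "allow_bulge": True},
        "network": {"top_fraction": 0.02},
    }


def validate_config(config: Mapping[str, Any]) -> list[str]:
    """Cross-field validation; returns error strings naming key paths."""
    errors: list[str] = []
    species = config.get("species")
    if not isinstance(species, Mapping) or not species:
        errors.append("species: must map species names to role blocks")
        return errors
    anchors = [sp for sp, blk in species.items() if blk.get("role") == "anchor_replicated"]
    if len(anchors) != 1:
        errors.append(
            f"species: exactly one anchor_replicated species required, found {len(anchors)}"
        )
    for sp, blk in species.items():
        role = blk.get("role")
        if role not in ("anchor_replicated", "unreplicated"):
            errors.append(f"species.{sp}.role: unknown role {role!r}")
        n_ctrl, n_case = blk.get("n_ctrl", 1), blk.get("n_case", 1)
        if role == "anchor_replicated" and min(n_ctrl, n_case) < 2:
            errors.append(f"species.{sp}: anchor_replicated needs >=2 replicates per group")
        if role == "unreplicated" and (n_ctrl, n_case) != (1, 1):
            errors.append(f"species.{sp}: unreplicated needs exactly 1 replicate per group")
    de = config.get("de", {})
    if de.get("fc_threshold", 0.58) < 0:
        errors.append("de.fc_threshold: must be >= 0")
    if not 0 < de.get("alpha", 0.05) < 1:
        errors.append("de.alpha: must lie in (0, 1)")
    net = config.get("network", {})
    if not 0 < net.get("top_fraction", 0.02) < 1:
        errors.append("network.top_fraction: must lie in (0, 1)")
    sim = config.get("simulate", {})
    try:
        _sim_config(config)
    except (ValueError, TypeError) as exc:
        errors.append(f"simulate: {exc}")
    rule = config.get("intersect", {}).get("unreplicated_rule", "sign_only")
    if rule not in ("sign_only", "threshold"):
        errors.append(f"intersect.unreplicated_rule: unknown rule {rule!r}")
    if sim.get("sites_per_target", 1) < 1:
        errors.append("simulate.sites_per_target: must be >= 1")
    return errors


def _sim_config(config: Mapping[str, Any]) -> SimConfig:
    sim = dict(config.get("simulate", {}))
    design = {
        sp: (blk.get("n_ctrl", 1), blk.get("n_case", 1))
        for sp, blk in config.get("species", {}).items()
    }
    cfg = SimConfig(rng_seed=int(config.get("rng_seed", 0)),
                    replicate_design=design, **sim)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_fasta(path: Path, records: Mapping[str, str]) -> None:
    with open(path, "w") as handle:
        for name in records:
            handle.write(f">{name}\n{records[name]}\n")


def run_all(
    config: Mapping[str, Any],
    outdir: str | Path,
    seed: int | None = None,
) -> Path:
    """Run every stage in dependency order; returns the run directory.

    The manifest lists, per stage, the parameters used and the sha256 of
    each output, so any stage can be reproduced by the matching CLI
    subcommand. A stage failure raises :class:`PipelineError` naming the
    stage; outputs of completed stages are retained.
    """
    config = dict(config)
    if seed is not None:
        config["rng_seed"] = int(seed)
    errors = validate_config(config)
    if errors:
        raise PipelineError("invalid configuration: " + "; ".join(errors))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "rng_seed": config.get("rng_seed", 0),
        "config": config,
        "stages": [],
    }
    state: dict[str, Any] = {}

    def stage(name: str, fn: Callable[[], dict[str, Path]], params: Mapping[str, Any]) -> None:
        t0 = time.perf_counter()
        logger.info("stage %s: starting", name)
        try:
            outputs = fn()
        except Exception as exc:
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        entry = {
            "stage": name,
            "params": dict(params),
            "outputs": {k: str(p.relative_to(outdir)) for k, p in outputs.items()},
            "digests": {k: _sha256(p) for k, p in outputs.items()},
            "wall_seconds": round(time.perf_counter() - t0, 3),
        }
        manifest["stages"].append(entry)
        logger.info("stage %s: done in %.2fs", name, entry["wall_seconds"])

    sim_cfg = _sim_config(config)
    anchor = next(
        sp for sp, blk in config["species"].items() if blk["role"] == "anchor_replicated"
    )

    # -- simulate ----------------------------------------------------------
    def do_simulate() -> dict[str, Path]:
        study = simulate_study(sim_cfg)
        state["study"] = study
        outputs: dict[str, Path] = {}
        simdir = outdir / "simulate"
        simdir.mkdir(exist_ok=True)
        for sp, catalog in study.catalogs.items():
            p = simdir / f"catalog_{sp}.fasta"
            catalog.to_fasta(p)
            outputs[f"catalog_{sp}"] = p
        _write_fasta(simdir / "trna_ref.fasta", study.trna_ref)
        _write_fasta(simdir / "rrna_ref.fasta", study.rrna_ref)
        outputs["trna_ref"] = simdir / "trna_ref.fasta"
        outputs["rrna_ref"] = simdir / "rrna_ref.fasta"
        _write_fasta(simdir / "utrs.fasta", study.utrs)
        outputs["utrs"] = simdir / "utrs.fasta"
        for sp, cm in study.gene_counts.items():
            p = simdir / f"gene_counts_{sp}.tsv"
            cm.counts.to_csv(p, sep="\t")
            outputs[f"gene_counts_{sp}"] = p
        study.interactions.to_csv(simdir / "interactions.tsv", sep="\t", index=False)
        outputs["interactions"] = simdir / "interactions.tsv"
        anchors_path = simdir / "anchor_genes.txt"
        anchors_path.write_text("".join(f"{g}\n" for g in sorted(study.truth.anchor_genes)))
        outputs["anchor_genes"] = anchors_path
        rows = [
            {"species": sp, "transcript": t, "gene": g}
            for sp, m in study.truth.ortholog_map.items()
            for t, g in sorted(m.items())
        ]
        pd.DataFrame(rows).to_csv(simdir / "orthologs.tsv", sep="\t", index=False)
        outputs["orthologs"] = simdir / "orthologs.tsv"
        with open(simdir / "categories.tsv", "w") as handle:
            handle.write("category\tgene\n")
            for cat in sorted(study.categories):
                for gene in sorted(study.categories[cat]):
                    handle.write(f"{cat}\t{gene}\n")
        outputs["categories"] = simdir / "categories.tsv"
        study.truth.to_json(simdir / "truth.json")
        outputs["truth"] = simdir / "truth.json"
        # raw small-RNA reads from the miRNA tag counts
        readdir = simdir / "reads"
        name_to_seq = study.truth.mirna_sequences
        fastqs: dict[str, Path] = {}
        for sp, cm in study.mirna_counts.items():
            tag_counts = {
                sample: {
                    name_to_seq[name]: int(cm.counts.at[name, sample])
                    for name in cm.counts.index
                }
                for sample in cm.counts.columns
            }
            fastqs.update(
                simulate_reads(tag_counts, sim_cfg, study.trna_ref, study.rrna_ref, readdir)
            )
        state["fastqs"] = fastqs
        state["sample_species"] = {
            sample: sp
            for sp, cm in study.mirna_counts.items()
            for sample in cm.counts.columns
        }
        for sample, p in fastqs.items():
            outputs[f"reads_{sample}"] = p
        return outputs

    stage("simulate", do_simulate, {"rng_seed": sim_cfg.rng_seed})

    # -- collapse ----------------------------------------------------------
    col = config.get("collapse", {})

    def do_collapse() -> dict[str, Path]:
        study = state["study"]
        bounds = (col.get("min_len", 20), col.get("max_len", 25))
        tagdir = outdir / "collapse"
        tagdir.mkdir(exist_ok=True)
        outputs = {}
        state["tag_tables"] = {}
        for sp in study.mirna_counts:
            samples = list(study.mirna_counts[sp].counts.columns)
            per_sample = {
                sample: process_reads(
                    read_sequences(state["fastqs"][sample], "fastq"),
                    sim_cfg.adapter,
                    col.get("min_overlap", 5),
                    col.get("max_mismatch", 1),
                    col.get("q_threshold", 20),
                )
                for sample in samples
            }
            table = collapse_tags(per_sample, bounds)
            p = tagdir / f"tags_{sp}.tsv"
            table.to_tsv(p)
            outputs[f"tags_{sp}"] = p
            state["tag_tables"][sp] = table
        return outputs

    stage("collapse", do_collapse, col)

    # -- annotate ----------------------------------------------------------
    def do_annotate() -> dict[str, Path]:
        study = state["study"]
        anndir = outdir / "annotate"
        anndir.mkdir(exist_ok=True)
        outputs = {}
        state["mirna_count_matrices"] = {}
        for sp, table in state["tag_tables"].items():
            agg = aggregate_mirna_counts(table, study.catalogs[sp])
            p = anndir / f"mirna_counts_{sp}.tsv"
            agg.to_csv(p, sep="\t")
            outputs[f"mirna_counts_{sp}"] = p
            design = config["species"][sp]
            groups = {
                s: ("ctrl" if "_ctrl_" in s else "case") for s in agg.columns
            }
            state["mirna_count_matrices"][sp] = CountMatrix(agg, groups)
        conserved = conserved_tags(list(state["tag_tables"].values()))
        combined = [e for sp in sorted(study.catalogs) for e in study.catalogs[sp]]
        partition = partition_conserved(
            conserved, combined, study.trna_ref, study.rrna_ref
        )
        rows = [
            {"tag": tag, "cls": cls, "seed_variant": int(tag in partition["seed_sub"])}
            for cls in ("mirna", "trf", "rrf", "unknown")
            for tag in sorted(partition[cls])
        ]
        p = anndir / "conserved_partition.tsv"
        pd.DataFrame(rows, columns=["tag", "cls", "seed_variant"]).to_csv(
            p, sep="\t", index=False
        )
        outputs["conserved_partition"] = p
        return outputs

    stage("annotate", do_annotate, {})

    # -- de ----------------------------------------------------------------
    de_cfg = config.get("de", {})

    def do_de() -> dict[str, Path]:
        dedir = outdir / "de"
        dedir.mkdir(exist_ok=True)
        outputs = {}
        state["mirna_de"] = {}
        state["gene_de"] = {}
        for label, matrices in (
            ("mirna", state["mirna_count_matrices"]),
            ("gene", {sp: cm for sp, cm in state["study"].gene_counts.items()}),
        ):
            for sp, cm in matrices.items():
                if config["species"][sp]["role"] == "anchor_replicated":
                    table = call_de_replicated(cm, alpha=de_cfg.get("alpha", 0.05))
                else:
                    table = call_de_unreplicated(
                        cm, fc_threshold=de_cfg.get("fc_threshold", 0.58)
                    )
                p = dedir / f"de_{label}_{sp}.tsv"
                table.to_csv(p, sep="\t")
                outputs[f"de_{label}_{sp}"] = p
                state[f"{label}_de"][sp] = table
        return outputs

    stage("de", do_de, de_cfg)

    # -- intersect ---------------------------------------------------------
    int_cfg = config.get("intersect", {})

    def do_intersect() -> dict[str, Path]:
        study = state["study"]
        intdir = outdir / "intersect"
        intdir.mkdir(exist_ok=True)
        outputs = {}
        rule = int_cfg.get("unreplicated_rule", "sign_only")
        rules = {
            sp: ("significant" if sp == anchor else rule)
            for sp in config["species"]
        }
        # key miRNA DE tables by mature-sequence identity groups
        identity = mirna_identity_map(study.catalogs, anchor=anchor)
        rep_name = {}
        for _, row in identity.iterrows():
            for sp in row["species"]:
                name_in_sp = next(
                    e.name for e in study.catalogs[sp] if e.mature == row["mature"]
                )
                rep_name[(sp, name_in_sp)] = row["name"]
        mirna_tables = {}
        for sp, table in state["mirna_de"].items():
            renamed = table.copy()
            renamed.index = [rep_name.get((sp, n), n) for n in table.index]
            mirna_tables[sp] = renamed
        mirna_parts = shared_de_features(
            mirna_tables, anchor, rules,
            alpha=de_cfg.get("alpha", 0.05),
            fc_threshold=de_cfg.get("fc_threshold", 0.58),
        )
        for name, df in mirna_parts.items():
            p = intdir / f"mirna_shared_{name.replace('+', '_')}.tsv"
            df.to_csv(p, sep="\t", index=False)
            outputs[f"mirna_shared_{name}"] = p
        state["mirna_parts"] = mirna_parts
        # genes: re-key unreplicated species into the anchor namespace
        gene_tables = {anchor: state["gene_de"][anchor]}
        for sp in config["species"]:
            if sp == anchor:
                continue
            omap = pd.DataFrame(
                [
                    {"gene_a": g, "gene_b": t}
                    for t, g in study.truth.ortholog_map[sp].items()
                ]
            )
            gene_tables[sp] = apply_ortholog_map(state["gene_de"][sp], omap)
        gene_parts = shared_de_features(
            gene_tables, anchor, rules,
            alpha=de_cfg.get("alpha", 0.05),
            fc_threshold=de_cfg.get("fc_threshold", 0.58),
        )
        for name, df in gene_parts.items():
            p = intdir / f"gene_shared_{name.replace('+', '_')}.tsv"
            df.to_csv(p, sep="\t", index=False)
            outputs[f"gene_shared_{name}"] = p
        state["gene_parts"] = gene_parts
        venn = venn_partition(
            *(study.catalogs[sp].mature_sequences for sp in SPECIES)
        )
        p = intdir / "mirna_catalog_venn.json"
        p.write_text(json.dumps(venn, indent=1, sort_keys=True))
        outputs["mirna_catalog_venn"] = p
        return outputs

    stage("intersect", do_intersect, int_cfg)

    # -- targets -----------------------------------------------------------
    tgt_cfg = config.get("targets", {})

    def do_targets() -> dict[str, Path]:
        study = state["study"]
        tdir = outdir / "targets"
        tdir.mkdir(exist_ok=True)
        shared = state["mirna_parts"]["all"]
        shared_names = set(shared["feature"])
        catalog = [
            e for e in study.catalogs[anchor] if e.name in shared_names
        ]
        sites = predict_targets(
            catalog,
            study.utrs,
            min_score=tgt_cfg.get("min_score", 0.0),
            allow_bulge=tgt_cfg.get("allow_bulge", True),
        )
        sites.to_csv(tdir / "sites.tsv", sep="\t", index=False)
        mirna_verdicts = dict(zip(shared["feature"], shared["verdict"]))
        gene_shared = state["gene_parts"]["all"]
        gene_verdicts = dict(zip(gene_shared["feature"], gene_shared["verdict"]))
        pairs = inverse_expression_filter(sites, mirna_verdicts, gene_verdicts)
        pairs.to_csv(tdir / "regulatory_pairs.tsv", sep="\t", index=False)
        state["pairs"] = pairs
        return {"sites": tdir / "sites.tsv", "pairs": tdir / "regulatory_pairs.tsv"}

    stage("targets", do_targets, tgt_cfg)

    # -- network -----------------------------------------------------------
    net_cfg = config.get("network", {})

    def do_network() -> dict[str, Path]:
        study = state["study"]
        ndir = outdir / "network"
        ndir.mkdir(exist_ok=True)
        anchors = sorted(study.truth.anchor_genes)
        gene_shared = state["gene_parts"]["all"]
        candidates = set(gene_shared["feature"])
        net = anchored_subnetwork(study.interactions, anchors, candidates)
        lfc = dict(
            zip(gene_shared["feature"], gene_shared[f"log2fc_{anchor}"])
        )
        set_node_fold_changes(net, lfc)
        core = top_core(net, net_cfg.get("top_fraction", 0.02))
        full = integrate_regulatory_edges(
            net,
            state["pairs"],
            mirna_log2fc=dict(
                zip(
                    state["mirna_parts"]["all"]["feature"],
                    state["mirna_parts"]["all"][f"log2fc_{anchor}"],
                )
            ),
        )
        export_graph(full, ndir / "network.tsv", "edge-tsv")
        export_graph(full, ndir / "network.graphml", "graphml")
        export_graph(core, ndir / "core.tsv", "edge-tsv")
        state["network"] = full
        return {
            "network_tsv": ndir / "network.tsv",
            "network_graphml": ndir / "network.graphml",
            "core_tsv": ndir / "core.tsv",
        }

    stage("network", do_network, net_cfg)

    # -- enrich ------------------------------------------------------------
    def do_enrich() -> dict[str, Path]:
        study = state["study"]
        edir = outdir / "enrich"
        edir.mkdir(exist_ok=True)
        gene_shared = state["gene_parts"]["all"]
        query = set(gene_shared["feature"])
        universe = set(study.genes)
        result = hypergeom_enrichment(query, study.categories, universe)
        p = edir / "enrichment.tsv"
        result.to_csv(p, sep="\t", index=False)
        return {"enrichment": p}

    stage("enrich", do_enrich, {})

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return outdir


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as handle:
        return yaml.safe_load(handle)
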