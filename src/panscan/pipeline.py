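"""End-to-end orchestration: simulate (or load), scan, classify, report.

Stage order: simulate? -> domain scan -> family assignment -> architecture
clustering -> collinear blocks -> duplication typing -> copy-number matrix
-> splice-variant typing -> homoeolog bias -> expression atlas -> report.
The report bundle carries per-stage record counts, truth-versus-call
confusion tables whenever planted truth is available, and every parameter
value used, so a run is reproducible from its own output.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .core_io import GenomeID, ProteinRecord
from .domain_architecture import (
    Architecture,
    build_architecture,
    classify_family,
    cluster_architectures,
    scan_protein,
)
from .duplication_synteny import (
    HomologPair,
    build_cnv_matrix,
    classify_duplications,
    find_collinear_blocks,
    write_blocks,
)
from .homoeolog_expression import (
    classify_heb_table,
    compare_pair_expression,
    summarize_atlas,
)
from .protein_properties import compute_properties
from .splice_variants import classify_transcripts
from .synthetic_data import SimConfig, SyntheticDataset, simulate

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("panscan")


@dataclass
class RunConfig:
    """Parameters of one pipeline run (synthetic mode)."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str | Path = "panscan_out"
    min_anchors: int = 5
    max_gap: int = 25
    proximal_window: int = 10
    wgd_envelope: bool = False
    score_floor: float = 100.0
    expression_threshold: float = 0.5
    require_both_expressed: bool = False
    predominance_factor: float = 2.0
    write_figures: bool = False


@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    architectures: pd.DataFrame
    families: pd.DataFrame
    properties: pd.DataFrame
    clusters: dict[str, object]
    blocks: dict[str, list]
    duplication_calls: pd.DataFrame
    cnv: pd.DataFrame
    as_calls: pd.DataFrame
    heb_calls: pd.DataFrame
    atlas: pd.DataFrame
    pair_reports: pd.DataFrame
    report: dict


def _confusion(truth: pd.Series, called: pd.Series) -> dict:
    table = pd.crosstab(truth, called)
    agree = (truth.to_numpy() == called.to_numpy()).mean() if len(truth) else 0.0
    return {
        "agreement": float(agree),
        "n": int(len(truth)),
        "table": {str(k): {str(c): int(v) for c, v in row.items()}
                  for k, row in table.iterrows()},
    }


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages on a synthetic dataset and write the bundle."""
    out = Path(config.out_dir)
    for sub in ("tables", "logs", "truth") + (("figures",) if config.write_figures else ()):
        (out / sub).mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "logs" / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("panscan %s; seed=%d", __version__, config.sim.seed)

    try:
        dataset = simulate(config.sim)
        dataset.write(out)
        gs = dataset.genome_set
        counts: dict[str, int] = {}

        # --- domain scan -------------------------------------------------
        arch_rows = []
        arch_of: dict[str, Architecture] = {}
        for prot in gs.proteins:
            arch = build_architecture(scan_protein(prot), len(prot))
            arch_of[prot.protein_id] = arch
            arch_rows.append(
                {
                    "protein_id": prot.protein_id,
                    "signature": arch.signature,
                    "kinase_state": arch.kinase_state,
                    "ef_count": arch.ef_count,
                    "ca_count": arch.ca_count,
                    "lobes": ",".join(arch.lobes),
                }
            )
        architectures = pd.DataFrame(arch_rows)
        counts["scan"] = len(architectures)

        # --- family assignment -------------------------------------------
        fam_rows = []
        for prot in gs.proteins:
            label, score, warns = classify_family(
                prot, gs.seeds, arch_of[prot.protein_id],
                score_floor=config.score_floor,
            )
            fam_rows.append(
                {"protein_id": prot.protein_id, "family": label,
                 "score": score, "warnings": ";".join(warns)}
            )
        families = pd.DataFrame(fam_rows)
        counts["family"] = len(families)

        # --- molecular properties ----------------------------------------
        prop_rows = []
        for prot in gs.proteins:
            rec = compute_properties(prot.protein_id, prot.sequence)
            prop_rows.append(
                {
                    "protein_id": rec.protein_id,
                    "length": rec.length,
                    "mw_kDa": round(rec.mw_kda, 1),
                    "pi": round(rec.pi, 2),
                    "myr": rec.myristoylation,
                    "palm_sites": ",".join(map(str, rec.palmitoylation)),
                    "localization": rec.localization,
                }
            )
        properties = pd.DataFrame(prop_rows)
        counts["properties"] = len(properties)

        # --- architecture clustering per ortholog group --------------------
        gene_info = gs.genes.set_index("gene_id")
        clusters = {}
        cluster_rows = []
        fam_mask = gs.genes["family"] != "none"
        for grp, sub in gs.genes[fam_mask].groupby("ortholog_group"):
            members = [
                (gid, arch_of[gid]) for gid in sub["gene_id"] if gid in arch_of
            ]
            cl = cluster_architectures(members, group=grp)
            clusters[grp] = cl
            cluster_rows.append(
                {
                    "ortholog_group": grp,
                    "representative": cl.representative.signature
                    if cl.representative else "",
                    "support": cl.representative_support,
                    "n_variants": len(cl.variants),
                    "n_solo": len(cl.solo_excluded),
                    "all_solo": cl.all_solo,
                }
            )
        counts["cluster"] = len(clusters)

        # --- collinear blocks & duplication typing ------------------------
        ranks = gs.ranks()
        genome_labels = [
            s.genome.label for s in config.sim.genomes
        ]
        blocks: dict[str, list] = {}
        dup_frames = []
        for label in genome_labels:
            intra = gs.homology[
                (gs.homology["scope"] == "intra")
                & (gs.homology["genome"] == label)
            ]
            outg = gs.homology[
                (gs.homology["scope"] == "outgroup")
                & (gs.homology["genome"] == label)
            ]
            intra_pairs = [
                HomologPair(r.gene_a, r.gene_b, r.score) for r in intra.itertuples()
            ]
            outg_pairs = [
                HomologPair(r.gene_a, r.gene_b, r.score) for r in outg.itertuples()
            ]
            intra_blocks = find_collinear_blocks(
                intra_pairs, ranks, config.min_anchors, config.max_gap
            )
            outg_blocks = find_collinear_blocks(
                outg_pairs, ranks, config.min_anchors, config.max_gap
            )
            blocks[label] = intra_blocks
            fam_genes = list(
                gs.genes[(gs.genes["genome"] == label) & fam_mask]["gene_id"]
            )
            fam_set = set(fam_genes)
            fam_pairs = [
                p for p in intra_pairs
                if p.gene_a in fam_set and p.gene_b in fam_set
            ]
            calls = classify_duplications(
                fam_pairs, intra_blocks, ranks, outg_blocks, fam_genes,
                proximal_window=config.proximal_window,
                wgd_envelope=config.wgd_envelope,
            )
            dup_frames.append(
                pd.DataFrame(
                    [
                        {"genome": label, "gene_id": c.gene_id, "mode": c.mode,
                         "partner": c.partner, "evidence": c.evidence}
                        for c in calls
                    ]
                )
            )
        duplication_calls = pd.concat(dup_frames, ignore_index=True)
        counts["blocks"] = sum(len(b) for b in blocks.values())
        counts["duplication"] = len(duplication_calls)

        # --- copy-number matrix -------------------------------------------
        cnv = build_cnv_matrix(gs.genes)
        counts["cnv_groups"] = len(cnv)

        # --- splice-variant typing ----------------------------------------
        references = {}
        for tx in dataset.transcripts:
            gid = tx.gene_id
            if gid not in references:
                references[gid] = arch_of[gid]
        as_calls_list = classify_transcripts(
            dataset.transcripts, dataset.variant_proteins, references
        )
        as_calls = pd.DataFrame(
            [
                {"transcript_id": c.transcript_id, "gene_id": c.gene_id,
                 "type": c.type, "variant_signature": c.variant_arch.signature,
                 "reference_signature": c.reference_arch.signature}
                for c in as_calls_list
            ]
        )
        counts["as"] = len(as_calls)

        # --- homoeolog expression bias -------------------------------------
        if dataset.heb_species and len(dataset.heb_pairs):
            heb_calls = classify_heb_table(
                dataset.expression[dataset.heb_species],
                dataset.heb_pairs,
                threshold=config.expression_threshold,
                require_both=config.require_both_expressed,
            )
        else:
            heb_calls = pd.DataFrame(
                columns=["pair_id", "tissue", "gene_a", "gene_b",
                         "p_a", "p_b", "category"]
            )
        counts["heb"] = len(heb_calls)

        # --- atlas + duplicate-pair expression ------------------------------
        atlas_frames = []
        pair_rows = []
        for species, matrix in sorted(dataset.expression.items()):
            if species == dataset.heb_species:
                continue
            for s in summarize_atlas(
                matrix, predominance_factor=config.predominance_factor,
                threshold=config.expression_threshold,
            ):
                atlas_frames.append(
                    {
                        "species": species,
                        "gene_id": s.gene_id,
                        "dominant_tissue": s.dominant_tissue,
                        "predominance_ratio": round(s.predominance_ratio, 3),
                        "predominant": s.predominant,
                        "expressed_anywhere": s.expressed_anywhere,
                        **{f"mean_{t}": round(v, 3)
                           for t, v in s.tissue_means.items()},
                    }
                )
            genes_here = set(matrix.values.index)
            for r in gs.duplication_truth.itertuples():
                if r.gene in genes_here and r.partner in genes_here:
                    rep = compare_pair_expression(
                        r.gene, r.partner, matrix,
                        silent_threshold=config.expression_threshold,
                    )
                    pair_rows.append(
                        {
                            "species": species, "gene_a": rep.gene_a,
                            "gene_b": rep.gene_b, "call": rep.call,
                            "concordance": rep.concordance,
                        }
                    )
        atlas = pd.DataFrame(atlas_frames)
        pair_reports = pd.DataFrame(pair_rows)
        counts["atlas"] = len(atlas)

        # --- confusion tables versus planted truth ---------------------------
        confusion = {}
        if len(dataset.as_truth):
            merged = dataset.as_truth.merge(as_calls, on="transcript_id")
            confusion["as"] = _confusion(merged["type_x"], merged["type_y"])
        if len(dataset.heb_truth):
            merged = dataset.heb_truth.merge(
                heb_calls, on=["pair_id", "tissue"]
            )
            confusion["heb"] = _confusion(
                merged["category_x"], merged["category_y"]
            )
        if len(gs.duplication_truth):
            truth = gs.duplication_truth.rename(columns={"gene": "gene_id"})
            merged = truth.merge(
                duplication_calls, on=["genome", "gene_id"], how="left"
            )
            confusion["duplication"] = _confusion(
                merged["mode_x"], merged["mode_y"].fillna("SINGLETON")
            )

        # --- write bundle -----------------------------------------------------
        tables = out / "tables"
        architectures.to_csv(tables / "architectures.tsv", sep="\t", index=False)
        families.to_csv(tables / "families.tsv", sep="\t", index=False)
        properties.to_csv(tables / "properties.tsv", sep="\t", index=False)
        pd.DataFrame(cluster_rows).to_csv(
            tables / "architecture_clusters.tsv", sep="\t", index=False
        )
        duplication_calls.to_csv(
            tables / "duplication_calls.tsv", sep="\t", index=False
        )
        cnv.to_csv(tables / "cnv_matrix.tsv", sep="\t")
        as_calls.to_csv(tables / "as_calls.tsv", sep="\t", index=False)
        heb_calls.to_csv(tables / "heb_calls.tsv", sep="\t", index=False)
        atlas.to_csv(tables / "atlas.tsv", sep="\t", index=False)
        pair_reports.to_csv(tables / "pair_expression.tsv", sep="\t", index=False)
        for label, bl in blocks.items():
            write_blocks(bl, str(tables / f"blocks_{label}.collinearity"))
        if config.write_figures and len(heb_calls):
            from .homoeolog_expression import heb_heatmap

            heb_heatmap(heb_calls, str(out / "figures" / "heb.png"))

        report = {
            "version": __version__,
            "seed": config.sim.seed,
            "parameters": {
                "min_anchors": config.min_anchors,
                "max_gap": config.max_gap,
                "proximal_window": config.proximal_window,
                "wgd_envelope": config.wgd_envelope,
                "score_floor": config.score_floor,
                "expression_threshold": config.expression_threshold,
                "require_both_expressed": config.require_both_expressed,
                "predominance_factor": config.predominance_factor,
                "p_dom": config.sim.p_dom,
                "expression_noise_sd": config.sim.expression_noise_sd,
                "wgd_block_anchor_count": config.sim.wgd_block_anchor_count,
            },
            "counts": counts,
            "confusion": confusion,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info("pipeline complete: %s", counts)
        return PipelineResult(
            dataset=dataset,
            architectures=architectures,
            families=families,
            properties=properties,
            clusters=clusters,
            blocks=blocks,
            duplication_calls=duplication_calls,
            cnv=cnv,
            as_calls=as_calls,
            heb_calls=heb_calls,
            atlas=atlas,
            pair_reports=pair_reports,
            report=report,
        )
    except Exception:
        logger.exception("pipeline stage failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
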