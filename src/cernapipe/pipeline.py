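"""End-to-end orchestration of the checkpoint-to-ceRNA analysis.

Stage order mirrors the study design: (1) survival screening of the
candidate checkpoints, (2) clinical-feature association, (3) checkpoint
high/low differential expression of mRNAs and lncRNAs, (4) enrichment
(over-representation, GSEA, per-sample set scores + differential
pathways), (5) immune-infiltration correlation filtering for the CD4+ and
CD8+ branches, (6) ceRNA network assembly per branch, (7) degree ranking
and key-gene intersection, (8) validation correlations in independent
cohorts.

Every intermediate table is written to the output directory, a JSON
manifest records thresholds, seed, package versions, per-stage status and
filter funnel counts, and reruns with the same seed and config are
byte-identical.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cerna, diffexpr, enrichment, io, simulate, stats, survival
from .errors import CernaPipeError
from .simulate import CHECKPOINT_GENES, Bundle

logger = logging.getLogger(__name__)

CLINICAL_FEATURES = ("gender", "stage", "location")


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, with the study defaults."""

    seed: int = 0
    checkpoint_genes: tuple = CHECKPOINT_GENES
    checkpoint_override: str | None = None   # skip data-driven selection
    screen_alpha: float = 0.05
    cut_q_low: float = 0.1
    cut_q_high: float = 0.9
    cut_n_perm: int = 0                      # permutation p for optimal cutpoints
    de_alpha: float = 0.05
    de_lfc: float = 2.0
    ora_p_cut: float = 0.5
    ora_min_count: int = 2
    gsea_weight: float = 1.0
    gsea_n_perm: int = 200
    pathway_alpha: float = 0.05
    pathway_lfc: float = 0.263
    rho_cut: float = 0.4
    coexpr_r_cut: float = 0.7
    coexpr_alpha: float = 0.05
    lnc_mir_score_cut: float = 0.9
    mir_mrna_min_sources: int = 5
    top_k: int = 10
    validation_alpha: float = 0.05

    def thresholds(self) -> dict:
        d = asdict(self)
        d.pop("checkpoint_genes", None)
        return d


class PipelineStageError(CernaPipeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(bundle: Bundle, config: PipelineConfig, outdir) -> dict:
    """Run all stages on an in-memory bundle, writing artifacts to ``outdir``.

    Returns a dict of in-memory results keyed by stage name; raises
    :class:`PipelineStageError` naming the failing stage (already-written
    artifacts are left in place).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("cernapipe")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "seed": config.seed,
        "thresholds": config.thresholds(),
        "versions": _versions(),
        "stages": {},
        "counts": {},
    }
    results: dict = {}
    expr = bundle.expression
    stage = "screen"
    try:
        # ---- 1. prognostic screening ----------------------------------
        genes = [g for g in config.checkpoint_genes if g in expr.genes]
        med = survival.screen_checkpoints(
            expr.values, bundle.survival, genes, method="median",
            alpha=config.screen_alpha,
        )
        opt = survival.screen_checkpoints(
            expr.values, bundle.survival, genes, method="optimal",
            alpha=config.screen_alpha, q_low=config.cut_q_low,
            q_high=config.cut_q_high, n_perm=config.cut_n_perm, seed=config.seed,
        )
        merged = med.merge(
            opt, on=["gene", "endpoint"], suffixes=("_median", "_optimal")
        )
        merged["concordant"] = (
            merged["significant_median"] == merged["significant_optimal"]
        )
        io.write_table(med, outdir / "screen_median.tsv")
        io.write_table(opt, outdir / "screen_optimal.tsv")
        io.write_table(merged, outdir / "screen_concordance.tsv")
        results["screen"] = {"median": med, "optimal": opt, "merged": merged}
        manifest["stages"][stage] = "completed"

        # data-driven checkpoint selection: smallest median-split OS p
        if config.checkpoint_override:
            checkpoint = config.checkpoint_override
        else:
            os_rows = med[(med["endpoint"] == "OS") & (med["status"] == "ok")]
            checkpoint = os_rows.sort_values(["p", "gene"]).iloc[0]["gene"]
        manifest["selected_checkpoint"] = str(checkpoint)
        results["checkpoint"] = str(checkpoint)

        # ---- 2. clinical association ----------------------------------
        stage = "assoc"
        clin = bundle.clinical.set_index("sample_id")
        rows = []
        for gene in genes:
            values = expr.values.loc[gene, clin.index].to_numpy(dtype=float)
            for feat in CLINICAL_FEATURES:
                if feat not in clin.columns:
                    continue
                try:
                    res = stats.associate_feature(values, clin[feat].to_numpy())
                    rows.append(
                        {"gene": gene, "feature": feat, "method": res.method,
                         "statistic": res.statistic, "p": res.p_value,
                         "n": res.details.get("n")}
                    )
                except CernaPipeError as exc:
                    logger.warning("assoc %s/%s skipped: %s", gene, feat, exc)
        assoc = pd.DataFrame(rows)
        if len(assoc):
            assoc["adj_p"] = stats.bh_adjust(assoc["p"].to_numpy())
        io.write_table(assoc, outdir / "clinical_association.tsv")
        results["assoc"] = assoc
        manifest["stages"][stage] = "completed"

        # ---- 3. differential expression -------------------------------
        stage = "de"
        high = survival.split_by_median(
            expr.values.loc[checkpoint].to_numpy(dtype=float)
        )
        mrna, lnc = diffexpr.partition_biotype(expr)
        de_mrna = diffexpr.de_table(
            mrna.values, high, alpha=config.de_alpha, lfc=config.de_lfc
        )
        up_m, down_m = diffexpr.select_de(de_mrna, config.de_alpha, config.de_lfc)
        if lnc.values.shape[0] == 0:
            logger.warning("no lncRNAs in the matrix; lncRNA DE skipped")
            de_lnc = pd.DataFrame(
                columns=["logFC", "s2", "df", "stdev_unscaled", "s2_post",
                         "t_mod", "p", "adj_p", "direction"]
            )
            up_l, down_l = [], []
        else:
            de_lnc = diffexpr.de_table(
                lnc.values, high, alpha=config.de_alpha, lfc=config.de_lfc
            )
            up_l, down_l = diffexpr.select_de(de_lnc, config.de_alpha, config.de_lfc)
        io.write_table(de_mrna.reset_index(names="gene_id"), outdir / "de_mrna.tsv")
        io.write_table(de_lnc.reset_index(names="gene_id"), outdir / "de_lncrna.tsv")
        results["de"] = {
            "mrna": de_mrna, "lnc": de_lnc,
            "up_mrna": up_m, "down_mrna": down_m,
            "up_lnc": up_l, "down_lnc": down_l,
            "high_mask": high,
        }
        manifest["counts"].update(
            de_mrna_up=len(up_m), de_mrna_down=len(down_m),
            de_lnc_up=len(up_l), de_lnc_down=len(down_l),
        )
        manifest["stages"][stage] = "completed"

        # ---- 4. enrichment --------------------------------------------
        stage = "enrichment"
        universe = list(mrna.genes)
        ora_tab = enrichment.ora(
            up_m + down_m, universe, bundle.gene_sets,
            p_cut=config.ora_p_cut, min_count=config.ora_min_count,
        )
        io.write_table(ora_tab, outdir / "ora.tsv")
        gsea_tab = enrichment.gsea_collection(
            de_mrna["logFC"], bundle.gene_sets, weight=config.gsea_weight,
            n_perm=config.gsea_n_perm, seed=config.seed,
        )
        io.write_table(gsea_tab, outdir / "gsea.tsv")
        scores = enrichment.gsva_scores(mrna.values, bundle.gene_sets)
        io.write_table(scores.reset_index(names="set_name"), outdir / "gsva_scores.tsv")
        diff_path = enrichment.differential_pathways(
            scores, high, alpha=config.pathway_alpha, lfc=config.pathway_lfc
        )
        io.write_table(
            diff_path.reset_index(names="set_name"), outdir / "differential_pathways.tsv"
        )
        results["enrichment"] = {
            "ora": ora_tab, "gsea": gsea_tab, "gsva": scores, "pathways": diff_path,
        }
        manifest["stages"][stage] = "completed"

        # ---- 5.-7. immune filtering + ceRNA per branch ----------------
        de_mrna_expr = mrna.values.loc[up_m + down_m]
        de_lnc_expr = lnc.values.loc[up_l + down_l]
        lnc_mir = cerna.filter_lnc_mir(bundle.predictions, config.lnc_mir_score_cut)
        mir_mrna = cerna.consensus_mir_mrna(
            bundle.predictions, config.mir_mrna_min_sources
        )
        io.write_table(lnc_mir, outdir / "lnc_mir_pairs.tsv")
        io.write_table(mir_mrna, outdir / "mir_mrna_pairs.tsv")
        branches = {}
        for branch, cell_type in (("cd4", "CD4_T"), ("cd8", "CD8_T")):
            stage = f"immune_{branch}"
            fm = cerna.immune_filter(
                de_mrna_expr, bundle.infiltration, cell_type, config.rho_cut
            )
            fl = cerna.immune_filter(
                de_lnc_expr, bundle.infiltration, cell_type, config.rho_cut
            )
            io.write_table(fm, outdir / f"immune_mrna_{branch}.tsv")
            io.write_table(fl, outdir / f"immune_lnc_{branch}.tsv")
            manifest["stages"][stage] = "completed"

            stage = f"cerna_{branch}"
            keep_m = fm.loc[fm["kept"], "gene"].tolist()
            keep_l = fl.loc[fl["kept"], "gene"].tolist()
            coexpr = cerna.coexpression_pairs(
                de_lnc_expr.loc[keep_l], de_mrna_expr.loc[keep_m],
                r_cut=config.coexpr_r_cut, alpha=config.coexpr_alpha,
            )
            net = cerna.assemble_cerna(coexpr, lnc_mir, mir_mrna)
            audit = cerna.audit_network(
                net, coexpr, lnc_mir, mir_mrna,
                r_cut=config.coexpr_r_cut, alpha=config.coexpr_alpha,
                score_cut=config.lnc_mir_score_cut,
                min_sources=config.mir_mrna_min_sources,
            )
            if audit:
                raise CernaPipeError(f"network audit failed: {audit[:3]}")
            ranks = cerna.degree_rank(net)
            top_mrna = cerna.degree_rank(net, k=config.top_k, node_class="mRNA")
            io.write_table(
                coexpr[coexpr["kept"]], outdir / f"coexpression_{branch}.tsv"
            )
            io.write_table(
                pd.DataFrame(net.triads, columns=["lncRNA", "miRNA", "mRNA"]),
                outdir / f"triads_{branch}.tsv",
            )
            for fmt in ("tsv", "sif", "graphml"):
                io.write_network(net, outdir / f"network_{branch}.{fmt}", fmt)
            io.write_table(ranks, outdir / f"degree_{branch}.tsv")
            branches[branch] = {
                "immune_mrna": fm, "immune_lnc": fl, "coexpr": coexpr,
                "network": net, "ranks": ranks, "top_mrna": top_mrna,
            }
            manifest["counts"][f"immune_mrna_{branch}"] = len(keep_m)
            manifest["counts"][f"immune_lnc_{branch}"] = len(keep_l)
            manifest["counts"][f"coexpr_pairs_{branch}"] = int(coexpr["kept"].sum()) if len(coexpr) else 0
            manifest["counts"][f"triads_{branch}"] = len(net.triads)
            manifest["stages"][stage] = "completed"
        results["branches"] = branches

        # ---- 8. key genes + validation --------------------------------
        stage = "key_genes"
        key_genes = cerna.intersect_top_genes(
            branches["cd4"]["top_mrna"], branches["cd8"]["top_mrna"]
        )
        io.write_table(pd.DataFrame({"gene": key_genes}), outdir / "key_genes.tsv")
        validation = cerna.validate_key_genes(
            key_genes, checkpoint, bundle.validation_cohorts,
            alpha=config.validation_alpha,
        )
        io.write_table(validation, outdir / "validation.tsv")
        results["key_genes"] = key_genes
        results["validation"] = validation
        manifest["counts"]["key_genes"] = len(key_genes)
        manifest["stages"][stage] = "completed"
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        io.write_json(manifest, outdir / "manifest.json")
        root.removeHandler(handler)
        handler.close()
        if isinstance(exc, PipelineStageError):
            raise
        raise PipelineStageError(stage, exc) from exc

    io.write_json(manifest, outdir / "manifest.json")
    results["manifest"] = manifest
    root.removeHandler(handler)
    handler.close()
    return results


def write_bundle(bundle: Bundle, outdir) -> None:
    """Persist a synthetic bundle as the pipeline's TSV/GMT/JSON inputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_expression(
        bundle.expression, outdir / "expression.tsv", outdir / "biotype.tsv"
    )
    io.write_table(bundle.survival, outdir / "survival.tsv")
    io.write_table(bundle.clinical, outdir / "clinical.tsv")
    io.write_table(bundle.infiltration.reset_index(), outdir / "infiltration.tsv")
    io.write_predictions(
        bundle.predictions, outdir / "lnc_mir.tsv", outdir / "mir_mrna.tsv"
    )
    io.write_gmt(bundle.gene_sets, outdir / "gene_sets.gmt")
    for name, expr in bundle.validation_cohorts.items():
        df = expr.copy()
        df.index.name = "gene_id"
        io.write_table(df, outdir / f"validation_{name}.tsv", index=True)
    io.write_json(bundle.truth.to_dict(), outdir / "truth.json")
    io.write_json(asdict(bundle.config), outdir / "sim_config.json")


def load_bundle(indir) -> Bundle:
    """Re-load a bundle previously written by :func:`write_bundle`."""
    indir = Path(indir)
    cfg = simulate.SimConfig(**io.read_json(indir / "sim_config.json"))
    truth_d = io.read_json(indir / "truth.json")
    truth_d["triads_cd4"] = [tuple(t) for t in truth_d["triads_cd4"]]
    truth_d["triads_cd8"] = [tuple(t) for t in truth_d["triads_cd8"]]
    truth = simulate.TruthRecord(**truth_d)
    validation = {}
    for path in sorted(indir.glob("validation_*.tsv")):
        name = path.stem.replace("validation_", "")
        validation[name] = pd.read_csv(path, sep="\t", index_col=0)
    return Bundle(
        expression=io.read_expression(indir / "expression.tsv", indir / "biotype.tsv"),
        survival=io.read_survival(indir / "survival.tsv"),
        clinical=pd.read_csv(indir / "clinical.tsv", sep="\t"),
        infiltration=io.read_infiltration(indir / "infiltration.tsv"),
        predictions=io.read_predictions(indir / "lnc_mir.tsv", indir / "mir_mrna.tsv"),
        gene_sets=io.read_gmt(indir / "gene_sets.gmt"),
        validation_cohorts=validation,
        truth=truth,
        config=cfg,
    )


def _versions() -> dict:
    import networkx
    import scipy

    from . import __version__

    return {
        "cernapipe": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "networkx": networkx.__version__,
    }
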