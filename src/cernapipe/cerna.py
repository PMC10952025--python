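"""Immune-infiltration correlation filtering and ceRNA network construction.

The competing-endogenous-RNA model: an lncRNA and an mRNA that (i) are
positively co-expressed (Pearson r > 0.7, BH-adjusted p < 0.05 over the full
tested grid), (ii) are both predicted targets of the same miRNA — the
lncRNA–miRNA interaction with prediction score > 0.9 and the miRNA–mRNA
interaction supported by at least ``min_sources`` of six prediction
databases — form a (lncRNA, miRNA, mRNA) triad.  The network is the union
of triad edges; node importance is unweighted degree (distinct neighbors),
and genes ranking in the top-k of both the CD4+ and CD8+ networks are the
key genes.

Upstream of the network, only differentially expressed genes whose Spearman
correlation with the relevant immune-cell infiltration abundance exceeds
0.4 in absolute value ("immune-related" genes) enter the co-expression
universe.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .stats import bh_adjust, pairwise_pearson, pearson_test, spearman_test

logger = logging.getLogger(__name__)

CELL_TYPES = ("B_cell", "CD4_T", "CD8_T", "neutrophil", "macrophage", "dendritic")
PREDICTION_SOURCES = ("miRWalk", "Targetscan", "Microt4", "PITA", "RNA22", "miRanda")


def validate_infiltration(table: pd.DataFrame) -> pd.DataFrame:
    """Samples x cell-type abundance table; all six columns required."""
    missing = [c for c in CELL_TYPES if c not in table.columns]
    if missing:
        raise InvalidInputError(f"infiltration table missing cell types {missing}")
    vals = table[list(CELL_TYPES)].to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise InvalidInputError("infiltration abundances must be finite")
    if (vals < 0).any():
        raise InvalidInputError("infiltration abundances must be non-negative")
    return table


@dataclass
class PredictionDB:
    """Tabular interaction predictions.

    ``lnc_mir``: columns lncRNA, miRNA, score (in [0, 1]).
    ``mir_mrna``: columns miRNA, mRNA plus one 0/1 column per source in
    :data:`PREDICTION_SOURCES`.
    """

    lnc_mir: pd.DataFrame
    mir_mrna: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("lncRNA", "miRNA", "score"):
            if col not in self.lnc_mir.columns:
                raise InvalidInputError(f"lnc_mir table missing column {col!r}")
        if len(self.lnc_mir) and not self.lnc_mir["score"].between(0, 1).all():
            raise InvalidInputError("lnc_mir scores must lie in [0, 1]")
        for col in ("miRNA", "mRNA", *PREDICTION_SOURCES):
            if col not in self.mir_mrna.columns:
                raise InvalidInputError(f"mir_mrna table missing column {col!r}")
        self.lnc_mir = self.lnc_mir.drop_duplicates(subset=["lncRNA", "miRNA"])
        self.mir_mrna = self.mir_mrna.drop_duplicates(subset=["miRNA", "mRNA"])


def immune_filter(
    de_expr: pd.DataFrame,
    infiltration: pd.DataFrame,
    cell_type: str,
    rho_cut: float = 0.4,
) -> pd.DataFrame:
    """Spearman filter of DE genes against one infiltration abundance.

    Keeps genes with |rho| strictly greater than ``rho_cut``.  The
    correlation-test p is reported for reference but plays no role in the
    keep rule.  ``de_expr`` must already be restricted to the DE genes.
    """
    if cell_type not in CELL_TYPES:
        raise InvalidInputError(f"unknown cell type {cell_type!r}")
    if cell_type not in infiltration.columns:
        raise InvalidInputError(f"infiltration table lacks {cell_type!r}")
    shared = [s for s in de_expr.columns if s in infiltration.index]
    if len(shared) < 10:
        raise InvalidInputError(f"only {len(shared)} shared samples (need >=10)")
    abundance = infiltration.loc[shared, cell_type].to_numpy(dtype=float)
    rows = []
    for gene in de_expr.index:
        res = spearman_test(de_expr.loc[gene, shared].to_numpy(dtype=float), abundance)
        rows.append(
            {
                "gene": gene,
                "cell_type": cell_type,
                "rho": res.coefficient,
                "p": res.p_value,
                "kept": abs(res.coefficient) > rho_cut,
            }
        )
    out = pd.DataFrame(rows, columns=["gene", "cell_type", "rho", "p", "kept"])
    logger.info(
        "immune_filter[%s]: %d of %d genes pass |rho| > %g",
        cell_type, int(out["kept"].sum()), len(out), rho_cut,
    )
    return out


def coexpression_pairs(
    lnc_values: pd.DataFrame,
    mrna_values: pd.DataFrame,
    r_cut: float = 0.7,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Positively co-expressed lncRNA–mRNA pairs.

    All lncRNA x mRNA Pearson correlations are tested; BH adjustment is
    applied over the full grid; pairs with r strictly above ``r_cut``
    (positive only) and adjusted p below ``alpha`` are kept.
    """
    shared = [s for s in lnc_values.columns if s in mrna_values.columns]
    if len(shared) < 10:
        raise InvalidInputError(f"only {len(shared)} shared samples (need >=10)")
    if lnc_values.empty or mrna_values.empty:
        return pd.DataFrame(columns=["lncRNA", "mRNA", "r", "p", "adj_p", "kept"])
    r, p = pairwise_pearson(
        lnc_values[shared].to_numpy(dtype=float),
        mrna_values[shared].to_numpy(dtype=float),
    )
    adj = bh_adjust(p.ravel()).reshape(p.shape)
    lnc_ids = np.repeat(lnc_values.index.to_numpy(), mrna_values.shape[0])
    mrna_ids = np.tile(mrna_values.index.to_numpy(), lnc_values.shape[0])
    out = pd.DataFrame(
        {
            "lncRNA": lnc_ids,
            "mRNA": mrna_ids,
            "r": r.ravel(),
            "p": p.ravel(),
            "adj_p": adj.ravel(),
        }
    )
    out["kept"] = (out["r"] > r_cut) & (out["adj_p"] < alpha)
    logger.info(
        "coexpression: %d of %d lncRNA x mRNA pairs pass r > %g & adj_p < %g",
        int(out["kept"].sum()), len(out), r_cut, alpha,
    )
    return out


def filter_lnc_mir(db: PredictionDB, score_cut: float = 0.9) -> pd.DataFrame:
    """lncRNA–miRNA pairs with prediction score strictly above ``score_cut``."""
    out = db.lnc_mir[db.lnc_mir["score"] > score_cut].reset_index(drop=True)
    logger.info("filter_lnc_mir: %d of %d pairs pass score > %g",
                len(out), len(db.lnc_mir), score_cut)
    return out


def consensus_mir_mrna(db: PredictionDB, min_sources: int = 5) -> pd.DataFrame:
    """miRNA–mRNA pairs supported by at least ``min_sources`` databases."""
    counts = db.mir_mrna[list(PREDICTION_SOURCES)].astype(int).sum(axis=1)
    out = db.mir_mrna.assign(db_count=counts)
    out = out[out["db_count"] >= min_sources].reset_index(drop=True)
    logger.info("consensus_mir_mrna: %d of %d pairs in >=%d sources",
                len(out), len(db.mir_mrna), min_sources)
    return out


@dataclass
class CeRNANetwork:
    """Tripartite lncRNA–miRNA–mRNA network assembled from triads."""

    graph: nx.Graph
    triads: list[tuple[str, str, str]] = field(default_factory=list)

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def nodes_of_type(self, node_class: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("node_type") == node_class]

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def assemble_cerna(
    coexpr_pairs: pd.DataFrame,
    lnc_mir_pairs: pd.DataFrame,
    mir_mrna_pairs: pd.DataFrame,
) -> CeRNANetwork:
    """Build the network from the three filtered relation tables.

    A triad (L, m, M) is included iff (L, M) is a kept co-expression pair,
    (L, m) a kept lncRNA–miRNA prediction and (m, M) a kept consensus
    miRNA–mRNA prediction.  Edges are deduplicated; every edge carries its
    provenance (r/adj_p, score, or db_count) and type.
    """
    coexpr = coexpr_pairs[coexpr_pairs["kept"]] if "kept" in coexpr_pairs.columns else coexpr_pairs
    coexpr_set = {
        (row.lncRNA, row.mRNA): (row.r, row.adj_p) for row in coexpr.itertuples()
    }
    lnc_by_mir: dict[str, dict[str, float]] = {}
    for row in lnc_mir_pairs.itertuples():
        lnc_by_mir.setdefault(row.miRNA, {})[row.lncRNA] = row.score
    mrna_by_mir: dict[str, dict[str, int]] = {}
    for row in mir_mrna_pairs.itertuples():
        mrna_by_mir.setdefault(row.miRNA, {})[row.mRNA] = int(row.db_count)

    g = nx.Graph()
    triads = []
    for mir in sorted(set(lnc_by_mir) & set(mrna_by_mir)):
        for (lnc, score), (mrna, db_count) in itertools.product(
            sorted(lnc_by_mir[mir].items()), sorted(mrna_by_mir[mir].items())
        ):
            if (lnc, mrna) not in coexpr_set:
                continue
            r, adj_p = coexpr_set[(lnc, mrna)]
            triads.append((lnc, mir, mrna))
            g.add_node(lnc, node_type="lncRNA")
            g.add_node(mir, node_type="miRNA")
            g.add_node(mrna, node_type="mRNA")
            g.add_edge(lnc, mir, edge_type="lnc_mir", score=float(score))
            g.add_edge(mir, mrna, edge_type="mir_mrna", db_count=int(db_count))
            g.add_edge(lnc, mrna, edge_type="lnc_mrna_coexpr", r=float(r), adj_p=float(adj_p))
    if not triads:
        logger.warning("assemble_cerna: empty network")
    return CeRNANetwork(graph=g, triads=sorted(set(triads)))


def audit_network(
    network: CeRNANetwork,
    coexpr_pairs: pd.DataFrame,
    lnc_mir_pairs: pd.DataFrame,
    mir_mrna_pairs: pd.DataFrame,
    r_cut: float = 0.7,
    alpha: float = 0.05,
    score_cut: float = 0.9,
    min_sources: int = 5,
) -> list[str]:
    """Re-verify every emitted triad against the three threshold rules.

    Returns a list of human-readable violations (empty = clean audit).
    """
    violations = []
    coexpr = coexpr_pairs.set_index(["lncRNA", "mRNA"])
    lm = lnc_mir_pairs.set_index(["lncRNA", "miRNA"])
    mm = mir_mrna_pairs.set_index(["miRNA", "mRNA"])
    for lnc, mir, mrna in network.triads:
        try:
            row = coexpr.loc[(lnc, mrna)]
            if not (row["r"] > r_cut and row["adj_p"] < alpha):
                violations.append(f"coexpr thresholds fail for ({lnc}, {mrna})")
        except KeyError:
            violations.append(f"missing co-expression record ({lnc}, {mrna})")
        try:
            if not lm.loc[(lnc, mir), "score"] > score_cut:
                violations.append(f"lnc-mir score fails for ({lnc}, {mir})")
        except KeyError:
            violations.append(f"missing lnc-mir record ({lnc}, {mir})")
        try:
            if not mm.loc[(mir, mrna), "db_count"] >= min_sources:
                violations.append(f"mir-mrna consensus fails for ({mir}, {mrna})")
        except KeyError:
            violations.append(f"missing mir-mrna record ({mir}, {mrna})")
    return violations


def degree_rank(
    network: CeRNANetwork, k: int | None = None, node_class: str | None = None
) -> pd.DataFrame:
    """Nodes sorted by unweighted degree (descending), ties lexicographic.

    Optionally restricted to one node class; degree is always counted over
    the full network (all edge types, distinct neighbors).
    """
    nodes = (
        network.nodes_of_type(node_class) if node_class else list(network.graph.nodes)
    )
    rows = sorted(
        ((n, network.graph.degree(n)) for n in nodes), key=lambda t: (-t[1], t[0])
    )
    if k is not None:
        rows = rows[:k]
    out = pd.DataFrame(rows, columns=["node", "degree"])
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def intersect_top_genes(top_cd4: pd.DataFrame, top_cd8: pd.DataFrame) -> list[str]:
    """Key genes: intersection of the two top-k mRNA lists.

    Ordered by the worse (maximal) of the two ranks, ties lexicographic.
    """
    r4 = dict(zip(top_cd4["node"], top_cd4["rank"]))
    r8 = dict(zip(top_cd8["node"], top_cd8["rank"]))
    common = set(r4) & set(r8)
    return sorted(common, key=lambda g: (max(r4[g], r8[g]), g))


def validate_key_genes(
    key_genes,
    checkpoint_gene: str,
    cohorts: dict[str, pd.DataFrame],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation of each key gene with the checkpoint per cohort.

    Genes (or the checkpoint) missing from a cohort are recorded with
    status 'missing' rather than raising.
    """
    rows = []
    for cohort_name, expr in cohorts.items():
        has_cp = checkpoint_gene in expr.index
        for gene in key_genes:
            row = {"cohort": cohort_name, "gene": gene, "checkpoint": checkpoint_gene}
            if not has_cp or gene not in expr.index:
                row.update(status="missing", r=np.nan, p=np.nan, significant=False)
            else:
                res = pearson_test(
                    expr.loc[gene].to_numpy(dtype=float),
                    expr.loc[checkpoint_gene].to_numpy(dtype=float),
                )
                row.update(
                    status="ok",
                    r=res.coefficient,
                    p=res.p_value,
                    n=res.n,
                    significant=bool(res.p_value < alpha),
                )
            rows.append(row)
    return pd.DataFrame(rows)
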