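"""Gene-set enrichment: over-representation, running-sum GSEA, per-sample
set-variation scores, and differential-pathway calling.

Three complementary views of the same question (which pathways separate the
checkpoint-high from the checkpoint-low samples) are provided:

* ``ora`` — hypergeometric over-representation of a discrete DE gene list;
* ``gsea`` — weighted Kolmogorov–Smirnov running-sum statistic over the full
  logFC-ranked list, with a gene-permutation null;
* ``gsva_scores`` — a per-sample, rank-based KS max-deviation score per set
  (a deterministic variant of gene-set variation analysis without kernel
  density smoothing), feeding the same moderated-t machinery used for genes.

The default ORA keep-rule is ``p < 0.5`` and overlap count strictly greater
than 2, both configurable; see the methods note for the discussion of that
permissive default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diffexpr import de_table
from .errors import InvalidInputError, UndefinedSetError
from .stats import bh_adjust, hypergeom_enrich

logger = logging.getLogger(__name__)

GeneSetCollection = dict[str, list[str]]


@dataclass(frozen=True)
class EnrichmentRecord:
    set_name: str
    overlap_count: int
    p: float
    adj_p: float | None = None
    es: float | None = None
    nes: float | None = None


def ora(
    gene_list,
    universe,
    collection: GeneSetCollection,
    p_cut: float = 0.5,
    min_count: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_list`` in each set.

    Sets are intersected with the universe first.  A set is flagged ``kept``
    when p < p_cut and overlap strictly exceeds ``min_count``.  BH-adjusted
    p-values are reported alongside but are not part of the keep rule.
    """
    universe = set(universe)
    if not universe:
        raise InvalidInputError("empty universe")
    genes = set(gene_list) & universe
    outside = set(gene_list) - universe
    if outside:
        logger.info("ora: %d query genes outside universe ignored", len(outside))
    rows = []
    for name, members in collection.items():
        members_in = set(members) & universe
        if not members_in:
            continue
        k = len(genes & members_in)
        res = hypergeom_enrich(k, len(genes), len(members_in), len(universe))
        rows.append(
            {"set_name": name, "overlap_count": k, "set_size": len(members_in), "p": res.p_value}
        )
    out = pd.DataFrame(rows, columns=["set_name", "overlap_count", "set_size", "p"])
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
        out["kept"] = (out["p"] < p_cut) & (out["overlap_count"] > min_count)
        out = out.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
    else:
        out["adj_p"] = []
        out["kept"] = []
    return out


def _running_es(order_scores: np.ndarray, hit: np.ndarray, weight: float) -> float:
    """Signed maximal deviation of the GSEA running sum.

    ``order_scores`` are the ranking scores already sorted (descending);
    ``hit`` marks set members in that order.
    """
    n = hit.size
    nh = int(hit.sum())
    if nh == 0 or nh == n:
        raise UndefinedSetError("gene set empty or equal to the whole ranked list")
    w = np.abs(order_scores) ** weight
    w_hit = np.where(hit, w, 0.0)
    denom = w_hit.sum()
    if denom == 0.0:
        # all member scores are exactly zero: fall back to unweighted hits
        w_hit = hit.astype(float)
        denom = float(nh)
    steps = w_hit / denom - (~hit) / float(n - nh)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea(
    ranked_scores: pd.Series,
    gene_set,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> EnrichmentRecord:
    """Running-sum enrichment of one gene set in a score-ranked gene list.

    Genes are sorted by score (descending).  Hits advance the running sum by
    |score|^weight (normalized to total 1 over hits); misses retreat by
    1/(N - Nh).  ES is the signed maximal deviation; the null redistributes
    the set labels over genes (gene permutation).  p = (b + 1)/(n_perm + 1)
    counting permutations with same-sign ES at least as extreme; NES divides
    ES by the mean |permuted ES| of the same sign.
    """
    scores = ranked_scores.astype(float).sort_values(ascending=False, kind="stable")
    present = [g for g in set(gene_set) if g in scores.index]
    if not present:
        raise UndefinedSetError("gene set does not intersect the ranked list")
    dropped = len(set(gene_set)) - len(present)
    if dropped:
        logger.info("gsea: %d set members missing from ranked list", dropped)
    hit = scores.index.isin(present)
    vals = scores.to_numpy()
    es = _running_es(vals, hit, weight)
    rng = np.random.default_rng(seed)
    nh = int(hit.sum())
    perm_es = np.empty(n_perm)
    base = np.zeros(vals.size, dtype=bool)
    for i in range(n_perm):
        idx = rng.choice(vals.size, size=nh, replace=False)
        ph = base.copy()
        ph[idx] = True
        perm_es[i] = _running_es(vals, ph, weight)
    same_sign = perm_es * np.sign(es) > 0
    b = int(np.sum(same_sign & (np.abs(perm_es) >= abs(es) - 1e-12)))
    p = (b + 1) / (n_perm + 1)
    mean_same = float(np.abs(perm_es[same_sign]).mean()) if same_sign.any() else np.nan
    nes = es / mean_same if mean_same and not np.isnan(mean_same) else np.nan
    return EnrichmentRecord(
        set_name="", overlap_count=len(present), p=p, es=es, nes=float(nes)
    )


def gsea_collection(
    ranked_scores: pd.Series,
    collection: GeneSetCollection,
    weight: float = 1.0,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """GSEA over every set in a collection, with BH across sets."""
    rows = []
    for i, (name, members) in enumerate(sorted(collection.items())):
        try:
            rec = gsea(
                ranked_scores,
                members,
                weight=weight,
                n_perm=n_perm,
                seed=None if seed is None else seed + i,
            )
        except UndefinedSetError as exc:
            logger.warning("gsea: skipping %s (%s)", name, exc)
            continue
        rows.append(
            {"set_name": name, "overlap_count": rec.overlap_count, "es": rec.es, "nes": rec.nes, "p": rec.p}
        )
    out = pd.DataFrame(rows, columns=["set_name", "overlap_count", "es", "nes", "p"])
    if len(out):
        out["adj_p"] = bh_adjust(out["p"].to_numpy())
    else:
        out["adj_p"] = []
    return out


def gsva_scores(values: pd.DataFrame, collection: GeneSetCollection) -> pd.DataFrame:
    """Per-sample gene-set scores: rank-based KS max deviation.

    For each sample, genes are replaced by within-sample ranks (mid-ranks
    for ties, larger expression = larger rank).  For each set, walking genes
    from the highest to the lowest rank, the weighted in-set ECDF (weights =
    rank) is compared with the uniform out-of-set ECDF; the score is the
    signed maximal deviation.  Scores are invariant to any strictly
    increasing within-sample transform of expression.
    """
    if values.shape[1] < 2:
        raise InvalidInputError("gsva needs >=2 samples")
    x = values.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    ranks = pd.DataFrame(x).rank(axis=0, method="average").to_numpy()
    order = np.argsort(-ranks, axis=0, kind="stable")  # descending rank, per sample
    sets = {}
    for name, members in sorted(collection.items()):
        idx = values.index.get_indexer([m for m in members if m in values.index])
        idx = np.unique(idx[idx >= 0])
        if idx.size < 2:
            logger.warning("gsva: skipping %s (<2 genes present)", name)
            continue
        sets[name] = idx
    scores = np.zeros((len(sets), n_samples))
    for j in range(n_samples):
        ord_j = order[:, j]
        rank_sorted = ranks[ord_j, j]
        for i, (name, idx) in enumerate(sets.items()):
            hit = np.zeros(n_genes, dtype=bool)
            hit[idx] = True
            hit_sorted = hit[ord_j]
            w = np.where(hit_sorted, rank_sorted, 0.0)
            denom = w.sum()
            steps = w / denom - (~hit_sorted) / float(n_genes - idx.size)
            running = np.cumsum(steps)
            scores[i, j] = running[np.argmax(np.abs(running))]
    return pd.DataFrame(scores, index=list(sets), columns=values.columns)


def differential_pathways(
    score_matrix: pd.DataFrame,
    high_mask,
    alpha: float = 0.05,
    lfc: float = 0.263,
) -> pd.DataFrame:
    """Moderated-t differential pathway calling on a set x sample score matrix.

    Identical machinery to gene-level DE with the score-scale effect
    threshold (default 0.263, i.e. 1.2-fold on the log2 scale).
    """
    return de_table(score_matrix, high_mask, alpha=alpha, lfc=lfc)
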