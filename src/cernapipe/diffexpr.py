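"""Moderated-t differential expression between checkpoint high/low groups.

Expression is assumed to be on a log2 scale (e.g. log2(TPM + 0.001)), so a
difference of group means is directly a log2 fold change.  Per-gene residual
variances from the two-group linear model are shrunk toward a common prior
with an empirical-Bayes scheme: the prior degrees of freedom d0 and prior
variance s0^2 are estimated by closed-form moment matching on the log
residual variances (the scaled-F / log-variance moments route), the
posterior variance is

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g),

and the moderated t uses d0 + d_g degrees of freedom.  Gene selection then
applies the strict thresholds adj_p < alpha and |log2 FC| > lfc.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats as sps

from .errors import DegenerateDataError, InsufficientDataError, InvalidInputError

logger = logging.getLogger(__name__)

# Annotation categories defining the mRNA / lncRNA partition; anything else
# (pseudogenes, TEC, ...) is excluded from both lists.
MRNA_BIOTYPES = frozenset({"protein_coding"})
LNCRNA_BIOTYPES = frozenset(
    {
        "non_coding",
        "lincRNA",
        "antisense",
        "sense_intronic",
        "sense_overlapping",
        "processed_transcript",
        "3prime_overlapping_ncRNA",
    }
)
_CANONICAL = {b.lower().replace(" ", "_").replace("'", ""): b for b in MRNA_BIOTYPES | LNCRNA_BIOTYPES}
_CANONICAL["3_prime_overlapping_ncrna"] = "3prime_overlapping_ncRNA"


def canonical_biotype(label: str) -> str:
    """Normalize a biotype label ('protein coding' -> 'protein_coding', ...)."""
    key = str(label).strip().lower().replace(" ", "_").replace("'", "")
    return _CANONICAL.get(key, str(label).strip())


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression with optional biotype labels."""

    values: pd.DataFrame
    biotype: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise InvalidInputError(f"duplicate gene id {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise InvalidInputError(f"duplicate sample id {dup!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise InvalidInputError("expression values must be finite")
        if self.biotype is not None:
            self.biotype = self.biotype.reindex(self.values.index)

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.values.index]
        bt = self.biotype.loc[keep] if self.biotype is not None else None
        return ExpressionMatrix(self.values.loc[keep], bt)


def collapse_probes(probe_matrix: pd.DataFrame, probe_to_gene: pd.Series) -> pd.DataFrame:
    """Collapse probe-level rows to genes by averaging probes per gene.

    Probes missing from the map are dropped (count logged).
    """
    if len(probe_to_gene) == 0:
        raise InvalidInputError("empty probe-to-gene mapping")
    mapped = probe_matrix.index.intersection(probe_to_gene.index)
    n_dropped = probe_matrix.shape[0] - len(mapped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    sub = probe_matrix.loc[mapped]
    genes = probe_to_gene.loc[mapped]
    collapsed = sub.groupby(genes.to_numpy()).mean()
    collapsed.index.name = probe_matrix.index.name
    return collapsed


def partition_biotype(matrix: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Split into (mRNA, lncRNA) matrices; other biotypes are excluded."""
    if matrix.biotype is None:
        raise InvalidInputError("biotype annotation required for partition")
    canon = matrix.biotype.map(canonical_biotype)
    mrna = matrix.genes[canon.isin(MRNA_BIOTYPES)]
    lnc = matrix.genes[canon.isin(LNCRNA_BIOTYPES)]
    return matrix.subset_genes(mrna), matrix.subset_genes(lnc)


def fit_group_model(values: pd.DataFrame, high_mask) -> pd.DataFrame:
    """Per-gene two-group model: logFC = mean(high) - mean(low).

    Returns a frame with columns logFC, s2 (pooled residual variance),
    df (n - 2) and the per-gene unscaled standard error sqrt(1/n1 + 1/n2).
    """
    high = np.asarray(high_mask, dtype=bool)
    if high.size != values.shape[1]:
        raise InvalidInputError("group labels must align with samples")
    n1, n2 = int(high.sum()), int((~high).sum())
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("both groups need >=2 samples")
    x = values.to_numpy(dtype=float)
    mh = x[:, high].mean(axis=1)
    ml = x[:, ~high].mean(axis=1)
    rss = ((x[:, high] - mh[:, None]) ** 2).sum(axis=1) + (
        (x[:, ~high] - ml[:, None]) ** 2
    ).sum(axis=1)
    df = n1 + n2 - 2
    return pd.DataFrame(
        {
            "logFC": mh - ml,
            "s2": rss / df,
            "df": float(df),
            "stdev_unscaled": math.sqrt(1.0 / n1 + 1.0 / n2),
        },
        index=values.index,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(special.polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from log residual variances.

    With s2_g ~ s0^2 * F(df, d0), z_g = log(s2_g) has
    E z = log(s0^2) + digamma(df/2) - log(df/2) - digamma(d0/2) + log(d0/2)
    Var z = trigamma(df/2) + trigamma(d0/2).
    """
    z = np.log(np.maximum(s2, 1e-300))
    e = z - float(special.digamma(df / 2)) + math.log(df / 2)
    n = z.size
    if n < 2:
        raise InsufficientDataError("need >=10 genes for hyperparameter estimation")
    mean_e = float(e.mean())
    var_e = float(((e - mean_e) ** 2).sum() / (n - 1))
    excess = var_e - float(special.polygamma(1, df / 2))
    if excess <= 0:
        d0 = math.inf
        s0_sq = math.exp(mean_e)
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = math.exp(
            mean_e + float(special.digamma(d0 / 2)) - math.log(d0 / 2)
        )
    return d0, s0_sq


def ebayes_moderate(fit: pd.DataFrame) -> pd.DataFrame:
    """Empirical-Bayes variance shrinkage and moderated-t p-values.

    Input is the output of :func:`fit_group_model`.  Adds columns s2_post,
    t_mod and p; attaches the hyperparameters via ``frame.attrs``.
    """
    if fit.shape[0] < 10:
        raise InsufficientDataError("need >=10 genes for stable shrinkage")
    s2 = fit["s2"].to_numpy(dtype=float)
    df = float(fit["df"].iloc[0])
    if np.all(s2 == 0.0):
        raise DegenerateDataError("all residual variances are zero")
    d0, s0_sq = estimate_prior(s2, df)
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = math.inf
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_post) * fit["stdev_unscaled"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        t = fit["logFC"].to_numpy(dtype=float) / se
    if math.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    out = fit.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t
    out["p"] = np.minimum(p, 1.0)
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0_sq
    return out


def de_table(
    values: pd.DataFrame,
    high_mask,
    alpha: float = 0.05,
    lfc: float = 2.0,
) -> pd.DataFrame:
    """Full moderated-t DE analysis with BH adjustment and direction calls.

    ``direction`` is 'up' iff adj_p < alpha and logFC > lfc (strict), 'down'
    for the mirrored condition, 'ns' otherwise.
    """
    from .stats import bh_adjust

    fit = ebayes_moderate(fit_group_model(values, high_mask))
    fit["adj_p"] = bh_adjust(fit["p"].to_numpy())
    logfc = fit["logFC"]
    up = (fit["adj_p"] < alpha) & (logfc > lfc)
    down = (fit["adj_p"] < alpha) & (logfc < -lfc)
    fit["direction"] = np.where(up, "up", np.where(down, "down", "ns"))
    return fit


def select_de(results: pd.DataFrame, alpha: float = 0.05, lfc: float = 2.0):
    """(up, down) gene-id lists at strict thresholds adj_p < alpha, |logFC| > lfc."""
    up = results.index[(results["adj_p"] < alpha) & (results["logFC"] > lfc)]
    down = results.index[(results["adj_p"] < alpha) & (results["logFC"] < -lfc)]
    return list(up), list(down)
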