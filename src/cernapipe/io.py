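"""Readers and writers for the pipeline's tabular formats.

Everything is plain text: TSV for matrices and tables ('.' decimal, ``NA``
for missing, floats at 6 significant digits for bit-stable reruns), GMT for
gene sets, SIF/GraphML/TSV for networks, JSON for the truth record and the
run manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .cerna import CELL_TYPES, PREDICTION_SOURCES, CeRNANetwork, PredictionDB, validate_infiltration
from .diffexpr import ExpressionMatrix
from .errors import FormatError
from .survival import validate_survival

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.6g"


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT, na_rep="NA",
              lineterminator="\n")


def read_expression(path, biotype_path=None) -> ExpressionMatrix:
    """Gene x sample TSV (header row of sample ids, first column gene ids)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # malformed header / ragged rows
        raise FormatError(f"{path}: cannot parse expression TSV ({exc})") from exc
    if df.columns.size == 0 or df.index.name is None:
        raise FormatError(f"{path}: missing header row")
    try:  # a numeric corner label means the first line was data, not a header
        float(str(df.index.name))
    except ValueError:
        pass
    else:
        raise FormatError(f"{path}: missing header row")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    non_numeric = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric):
        col = non_numeric[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        gene = bad.index[0] if len(bad) else "?"
        raise FormatError(f"{path}: non-numeric value at gene {gene!r}, sample {col!r}")
    biotype = None
    if biotype_path is not None:
        bt = pd.read_csv(biotype_path, sep="\t")
        if bt.shape[1] < 2:
            raise FormatError(f"{biotype_path}: expected two columns (gene, biotype)")
        biotype = bt.set_index(bt.columns[0])[bt.columns[1]]
    return ExpressionMatrix(df.astype(float), biotype)


def write_expression(matrix: ExpressionMatrix, path, biotype_path=None) -> None:
    df = matrix.values.copy()
    df.index.name = df.index.name or "gene_id"
    write_table(df, path, index=True)
    if biotype_path is not None and matrix.biotype is not None:
        bt = matrix.biotype.rename("biotype").reset_index()
        bt.columns = ["gene_id", "biotype"]
        write_table(bt, biotype_path)


def read_survival(path) -> pd.DataFrame:
    return validate_survival(pd.read_csv(path, sep="\t"))


def read_infiltration(path) -> pd.DataFrame:
    return validate_infiltration(pd.read_csv(path, sep="\t", index_col=0))


def read_predictions(lnc_mir_path, mir_mrna_path) -> PredictionDB:
    lm = pd.read_csv(lnc_mir_path, sep="\t")
    mm = pd.read_csv(mir_mrna_path, sep="\t")
    return PredictionDB(lm, mm)


def write_predictions(db: PredictionDB, lnc_mir_path, mir_mrna_path) -> None:
    write_table(db.lnc_mir, lnc_mir_path)
    write_table(db.mir_mrna[["miRNA", "mRNA", *PREDICTION_SOURCES]], mir_mrna_path)


def read_gmt(path) -> dict[str, list[str]]:
    """GMT gene sets: name <tab> description <tab> member...

    Duplicate members within a set are removed (logged); lines with fewer
    than three fields raise a format error naming the line.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name, _desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.info("read_gmt: %s has %d duplicate members",
                            name, len(members) - len(unique))
            sets[name] = unique
    return sets


def write_gmt(collection: dict[str, list[str]], path, descriptions=None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in collection.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def _edge_table(network: CeRNANetwork) -> pd.DataFrame:
    rows = []
    for u, v, data in sorted(network.graph.edges(data=True)):
        rows.append(
            {
                "source": u,
                "target": v,
                "edge_type": data.get("edge_type", "NA"),
                "score": data.get("score"),
                "r": data.get("r"),
                "adj_p": data.get("adj_p"),
                "db_count": data.get("db_count"),
                "source_type": network.graph.nodes[u].get("node_type"),
                "target_type": network.graph.nodes[v].get("node_type"),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["source", "target", "edge_type", "score", "r", "adj_p",
                 "db_count", "source_type", "target_type"],
    )


def write_network(network: CeRNANetwork, path, fmt: str = "tsv") -> None:
    """Export the network as edge-list TSV, SIF, or GraphML."""
    path = Path(path)
    if fmt == "tsv":
        write_table(_edge_table(network), path)
    elif fmt == "sif":
        with open(path, "w") as fh:
            for u, v, data in sorted(network.graph.edges(data=True)):
                label = data.get("edge_type", "related")
                if label == "lnc_mrna_coexpr":
                    label = "coexpr"
                fh.write(f"{u}\t{label}\t{v}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        degrees = dict(network.graph.degree())
        for n, data in network.graph.nodes(data=True):
            g.add_node(n, node_type=data.get("node_type", "NA"), degree=degrees[n])
        for u, v, data in network.graph.edges(data=True):
            attrs = {k: v2 for k, v2 in data.items() if v2 is not None}
            g.add_edge(u, v, **attrs)
        nx.write_graphml(g, path)
    else:
        raise FormatError(f"unknown network format {fmt!r}")


def read_network_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_network_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def read_id_mapping(path) -> pd.Series:
    """Two-column TSV mapping old gene ids (e.g. Ensembl) to symbols."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (old_id, new_id)")
    return df.set_index(df.columns[0])[df.columns[1]]


def rename_genes(matrix: ExpressionMatrix, mapping: pd.Series | None) -> ExpressionMatrix:
    """Apply an id-to-symbol mapping; ids without an entry pass through.

    With ``mapping=None`` the matrix is returned unchanged.  Ids mapping to
    the same symbol are collapsed by averaging, consistent with probe
    collapsing.
    """
    if mapping is None:
        return matrix
    new_ids = matrix.values.index.to_series().map(
        lambda g: mapping.get(g, g)
    )
    collapsed = matrix.values.groupby(new_ids.to_numpy()).mean()
    biotype = None
    if matrix.biotype is not None:
        biotype = matrix.biotype.groupby(new_ids.to_numpy()).first()
    return ExpressionMatrix(collapsed, biotype)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
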