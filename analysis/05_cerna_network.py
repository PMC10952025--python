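"""Immune filtering, ceRNA network construction and key-gene validation.

DE genes are filtered by |Spearman rho| > 0.4 against CD4+ and CD8+ T-cell
infiltration abundance; per branch, co-expressed (r > 0.7, adj_p < 0.05)
lncRNA-mRNA pairs sharing a predicted miRNA (lncRNA-miRNA score > 0.9;
miRNA-mRNA in >= 5 of 6 databases) form triads.  mRNAs ranking top-10 by
unweighted degree in both networks are the key genes, validated by Pearson
correlation with the checkpoint in two independent cohorts.
"""

import argparse
from pathlib import Path

import pandas as pd

from cernapipe import cerna, io
from cernapipe.pipeline import load_bundle

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=RESULTS / "data")
    ap.add_argument("--screening", type=Path, default=RESULTS / "screening")
    ap.add_argument("--de", type=Path, default=RESULTS / "de")
    ap.add_argument("--out", type=Path, default=RESULTS / "cerna")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    bundle = load_bundle(args.data)
    checkpoint = (args.screening / "selected_checkpoint.txt").read_text().strip()
    de_mrna = pd.read_csv(args.de / "de_mrna.tsv", sep="\t", index_col="gene_id")
    de_lnc = pd.read_csv(args.de / "de_lncrna.tsv", sep="\t", index_col="gene_id")
    mrna_expr = bundle.expression.values.loc[de_mrna.index[de_mrna["direction"] != "ns"]]
    lnc_expr = bundle.expression.values.loc[de_lnc.index[de_lnc["direction"] != "ns"]]

    lnc_mir = cerna.filter_lnc_mir(bundle.predictions)
    mir_mrna = cerna.consensus_mir_mrna(bundle.predictions)
    tops = {}
    for branch, cell in (("cd4", "CD4_T"), ("cd8", "CD8_T")):
        fm = cerna.immune_filter(mrna_expr, bundle.infiltration, cell)
        fl = cerna.immune_filter(lnc_expr, bundle.infiltration, cell)
        coexpr = cerna.coexpression_pairs(
            lnc_expr.loc[fl.loc[fl["kept"], "gene"]],
            mrna_expr.loc[fm.loc[fm["kept"], "gene"]],
        )
        net = cerna.assemble_cerna(coexpr, lnc_mir, mir_mrna)
        violations = cerna.audit_network(net, coexpr, lnc_mir, mir_mrna)
        assert not violations, violations
        for fmt in ("tsv", "sif", "graphml"):
            io.write_network(net, args.out / f"network_{branch}.{fmt}", fmt)
        io.write_table(cerna.degree_rank(net), args.out / f"degree_{branch}.tsv")
        tops[branch] = cerna.degree_rank(net, k=10, node_class="mRNA")
        n_l = len(net.nodes_of_type("lncRNA"))
        n_m = len(net.nodes_of_type("miRNA"))
        n_g = len(net.nodes_of_type("mRNA"))
        print(f"{branch.upper()} network: {len(net.triads)} triads, "
              f"{n_l} lncRNAs / {n_m} miRNAs / {n_g} mRNAs (audit clean)")

    key_genes = cerna.intersect_top_genes(tops["cd4"], tops["cd8"])
    io.write_table(pd.DataFrame({"gene": key_genes}), args.out / "key_genes.tsv")
    validation = cerna.validate_key_genes(
        key_genes, checkpoint, bundle.validation_cohorts
    )
    io.write_table(validation, args.out / "validation.tsv")
    print(f"key genes (top-10 by degree in both networks): {', '.join(key_genes)}")
    ok = validation[validation["status"] == "ok"]
    print(f"validation: {int(ok['significant'].sum())} of {len(ok)} "
          f"(gene, cohort) correlations with {checkpoint} significant; "
          f"mean r = {ok['r'].mean():.3f}")


if __name__ == "__main__":
    main()
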