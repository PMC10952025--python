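"""Enrichment of the checkpoint-stratified differential expression signal.

Three views over the same gene-set collection: over-representation of the
DE mRNA list, running-sum GSEA over the full logFC-ranked list, and
per-sample set-variation scores tested for differential pathways between
the checkpoint high/low groups (adj_p < 0.05, |score shift| > 0.263).
"""

import argparse
from pathlib import Path

import pandas as pd

from cernapipe import diffexpr, enrichment, io, survival
from cernapipe.pipeline import load_bundle

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=RESULTS / "data")
    ap.add_argument("--screening", type=Path, default=RESULTS / "screening")
    ap.add_argument("--de", type=Path, default=RESULTS / "de")
    ap.add_argument("--out", type=Path, default=RESULTS / "enrichment")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    bundle = load_bundle(args.data)
    checkpoint = (args.screening / "selected_checkpoint.txt").read_text().strip()
    de_mrna = pd.read_csv(args.de / "de_mrna.tsv", sep="\t", index_col="gene_id")
    de_list = de_mrna.index[de_mrna["direction"] != "ns"].tolist()
    mrna, _ = diffexpr.partition_biotype(bundle.expression)

    ora_tab = enrichment.ora(de_list, list(mrna.genes), bundle.gene_sets)
    io.write_table(ora_tab, args.out / "ora.tsv")
    print(f"ORA: {int(ora_tab['kept'].sum())} sets kept "
          f"(best: {ora_tab.iloc[0]['set_name']}, p = {ora_tab.iloc[0]['p']:.2e})")

    gsea_tab = enrichment.gsea_collection(
        de_mrna["logFC"], bundle.gene_sets, n_perm=200, seed=args.seed
    )
    io.write_table(gsea_tab, args.out / "gsea.tsv")
    top = gsea_tab.sort_values("p").iloc[0]
    print(f"GSEA: top set {top['set_name']} (ES = {top['es']:.3f}, p = {top['p']:.3f})")

    scores = enrichment.gsva_scores(mrna.values, bundle.gene_sets)
    high = survival.split_by_median(
        bundle.expression.values.loc[checkpoint].to_numpy(dtype=float)
    )
    paths = enrichment.differential_pathways(scores, high)
    io.write_table(scores.reset_index(names="set_name"), args.out / "gsva_scores.tsv")
    io.write_table(paths.reset_index(names="set_name"), args.out / "differential_pathways.tsv")
    n_up = int((paths["direction"] == "up").sum())
    n_down = int((paths["direction"] == "down").sum())
    print(f"differential pathways: {n_up} up, {n_down} down "
          f"(of {len(paths)} scored sets)")


if __name__ == "__main__":
    main()
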