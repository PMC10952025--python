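"""Prognostic screening of the 14 candidate immune checkpoints.

Each checkpoint is dichotomized at its median and at the maximally selected
(optimal) cutpoint; high/low survival is compared with the log-rank test
for both OS and PFS.  Clinical-feature associations (Welch t / Welch ANOVA)
are computed alongside.  The checkpoint with the smallest median-split OS
p-value is carried forward by the later steps.
"""

import argparse
from pathlib import Path

import pandas as pd

from cernapipe import CHECKPOINT_GENES, io, stats, survival
from cernapipe.pipeline import CLINICAL_FEATURES, load_bundle

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=RESULTS / "data")
    ap.add_argument("--out", type=Path, default=RESULTS / "screening")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    bundle = load_bundle(args.data)
    expr = bundle.expression.values
    med = survival.screen_checkpoints(expr, bundle.survival, CHECKPOINT_GENES, "median")
    opt = survival.screen_checkpoints(expr, bundle.survival, CHECKPOINT_GENES, "optimal")
    io.write_table(med, args.out / "screen_median.tsv")
    io.write_table(opt, args.out / "screen_optimal.tsv")

    clin = bundle.clinical.set_index("sample_id")
    rows = []
    for gene in CHECKPOINT_GENES:
        values = expr.loc[gene, clin.index].to_numpy(dtype=float)
        for feat in CLINICAL_FEATURES:
            res = stats.associate_feature(values, clin[feat].to_numpy())
            rows.append({"gene": gene, "feature": feat, "method": res.method,
                         "p": res.p_value})
    assoc = pd.DataFrame(rows)
    assoc["adj_p"] = stats.bh_adjust(assoc["p"].to_numpy())
    io.write_table(assoc, args.out / "clinical_association.tsv")

    os_med = med[(med["endpoint"] == "OS") & (med["status"] == "ok")]
    selected = os_med.sort_values(["p", "gene"]).iloc[0]
    (args.out / "selected_checkpoint.txt").write_text(selected["gene"] + "\n")
    n_sig = int(os_med["significant"].sum())
    print(f"median-split OS screen: {n_sig} of {len(os_med)} checkpoints at p < 0.05")
    print(f"selected checkpoint: {selected['gene']} "
          f"(p = {selected['p']:.2e}, direction: {selected['direction']})")
    print(f"clinical features with p < 0.05 for {selected['gene']}: "
          f"{assoc[(assoc['gene'] == selected['gene']) & (assoc['p'] < 0.05)]['feature'].tolist()}")


if __name__ == "__main__":
    main()
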