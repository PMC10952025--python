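"""Differential expression between checkpoint-high and -low samples.

Samples are split at the selected checkpoint's median expression; mRNAs and
lncRNAs are tested separately with the moderated-t model and called at the
strict thresholds adj_p < 0.05 and |log2 FC| > 2.
"""

import argparse
from pathlib import Path

from cernapipe import diffexpr, io, survival
from cernapipe.pipeline import load_bundle

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=RESULTS / "data")
    ap.add_argument("--screening", type=Path, default=RESULTS / "screening")
    ap.add_argument("--out", type=Path, default=RESULTS / "de")
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    bundle = load_bundle(args.data)
    checkpoint = (args.screening / "selected_checkpoint.txt").read_text().strip()
    high = survival.split_by_median(
        bundle.expression.values.loc[checkpoint].to_numpy(dtype=float)
    )
    mrna, lnc = diffexpr.partition_biotype(bundle.expression)
    for label, matrix in (("mrna", mrna), ("lncrna", lnc)):
        table = diffexpr.de_table(matrix.values, high)
        up, down = diffexpr.select_de(table)
        io.write_table(table.reset_index(names="gene_id"), args.out / f"de_{label}.tsv")
        print(f"{label}: {len(up)} up-regulated, {len(down)} down-regulated "
              f"(of {matrix.values.shape[0]} tested; {checkpoint} high vs low)")


if __name__ == "__main__":
    main()
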