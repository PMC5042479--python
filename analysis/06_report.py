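#!/usr/bin/env python
"""Stage 6: assemble the plain-text analysis report.

Pulls together the outputs of stages 1-5 into results/report.txt.
"""

from collections import defaultdict
from pathlib import Path

import pandas as pd

from isopipe.feature_counting import flatten_annotation
from isopipe.gene_model import enumerate_isoforms
from isopipe.io import atomic_write, read_gtf, read_region_table
from isopipe.report import build_report, model_summary_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    by_gene = defaultdict(list)
    for tx in read_gtf(RESULTS / "gene" / "annotation.gtf"):
        by_gene[tx.gene_id].append(tx)
    model_summary = model_summary_frame(
        [flatten_annotation(txs) for txs in by_gene.values()]
    )

    table = read_region_table(RESULTS / "gene" / "regions.tsv")
    enumeration = {
        "major isoforms": len(enumerate_isoforms(table, majors_only=True)),
        "full combinatorial space": len(enumerate_isoforms(table.unconstrained())),
    }

    gene_table = pd.read_csv(RESULTS / "diffusage" / "genes.tsv", sep="\t")
    threshold_table = pd.read_csv(RESULTS / "diffusage" / "thresholds.tsv", sep="\t")
    roi_tables = {
        name: pd.read_csv(RESULTS / "longreads" / f"{name}.tsv", sep="\t")
        for name in ("summary", "per_isoform", "tiers")
    }

    text = build_report(
        model_summary=model_summary, gene_table=gene_table,
        threshold_table=threshold_table, enumeration=enumeration,
        roi_tables=roi_tables,
    )
    with atomic_write(RESULTS / "report.txt") as out:
        out.write(text)
    print(f"report written to {RESULTS / 'report.txt'}")
    print()
    print(text)


if __name__ == "__main__":
    main()
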