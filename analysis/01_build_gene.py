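#!/usr/bin/env python
"""Stage 1: build the toy gene and write its reference files.

Outputs (results/gene/): genome.fa, regions.tsv, annotation.gtf, primers.tsv,
manifest.json.
"""

from pathlib import Path

from isopipe.differential_usage import write_manifest
from isopipe.simulate import ToyGeneConfig, make_toy_gene

SEED = 1
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    outdir = RESULTS / "gene"
    gene = make_toy_gene(ToyGeneConfig(seed=SEED))
    paths = gene.write(outdir)
    write_manifest(
        outdir / "manifest.json", SEED, (),
        extra={"stage": "01_build_gene", "files": sorted(paths)},
    )
    print(f"toy gene (seed {SEED}) written to {outdir}")
    print(f"  contig: {gene.config.contig} ({len(gene.genome[gene.config.contig]):,} nt)")
    print(f"  exons: {len(gene.exons)}, reference ORF: {gene.reference_orf_aa} aa, "
          f"domains: {len(gene.domains)}")
    print(f"  regions: {len(gene.region_table.regions)}, "
          f"sub-variants: {len(gene.region_table.subvariants)}")


if __name__ == "__main__":
    main()
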