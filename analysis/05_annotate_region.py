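"""Gene content of the called candidate regions.

Intersects each region from results/regions/regions.tsv with the synthetic
gene models (>= 1 bp overlap), tabulates SNPs per gene, and flags how many
genes would survive a transposon/hypothetical-protein exclusion list.
"""

from pathlib import Path

import pandas as pd

from bulkscan.annotation import genes_in_region, variants_per_gene

REGIONS = Path("results/regions/regions.tsv")
GFF = Path("results/sim/genes.gff3")
SITES = Path("results/scan/snp_index.tsv")
OUT = Path("results/annotation")
EXCLUDE = ("retrotransposon protein", "hypothetical protein")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    regions = pd.read_csv(REGIONS, sep="\t")
    sites = pd.read_csv(SITES, sep="\t")
    if regions.empty:
        print("no regions to annotate")
        return
    reports = []
    for r in regions.itertuples(index=False):
        genes = genes_in_region(GFF, r.chrom, int(r.start), int(r.end))
        shortlisted = genes_in_region(
            GFF, r.chrom, int(r.start), int(r.end), exclude_descriptions=EXCLUDE
        )
        region_sites = sites[
            (sites["chrom"] == r.chrom)
            & (sites["pos"] >= r.start)
            & (sites["pos"] <= r.end)
        ]
        counts = variants_per_gene(region_sites, genes)
        counts.insert(0, "region", f"{r.chrom}:{r.start}-{r.end}")
        reports.append(counts)
        print(f"{r.chrom}:{r.start:,}-{r.end:,} ({r.size_mb:.3f} Mb): "
              f"{len(genes)} genes, {len(shortlisted)} after exclusions, "
              f"{len(region_sites)} SNPs in the interval")
    pd.concat(reports, ignore_index=True).to_csv(
        OUT / "region_genes.tsv", sep="\t", index=False
    )
    print(f"wrote {OUT/'region_genes.tsv'}")


if __name__ == "__main__":
    main()
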