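"""Generate the synthetic bulked-segregant study used by the downstream steps.

Design: 365 F2 plants from a tolerant x sensitive cross, one major
spikelet-fertility QTL (additive effect 0.18) at 4.0 Mb of the
chromosome-8 analog, reduced genome (3 chromosomes x 10 Mb, 20 SNPs/Mb),
bulks of the 50 most extreme plants per tail sequenced at ~57x.

Writes VCF, phenotype TSV, bulk membership, GFF3 gene models and the truth
file under results/sim/.
"""

from pathlib import Path

from bulkscan.experiments import scaled_config
from bulkscan.simulate import simulate_dataset

OUT = Path("results/sim")
SEED = 1


def main() -> None:
    config = scaled_config(seed=SEED, with_qtl=True)
    paths = simulate_dataset(config, OUT)
    chrom, pos, a, d = config.qtl[0]
    print(f"simulated {config.n_f2} F2 plants over {len(config.chrom_lengths)} chromosomes")
    print(f"planted QTL: {chrom}:{pos:,} (a={a}, d={d}) on the fertility proportion scale")
    for key, path in paths.items():
        print(f"  {key:11s} -> {path}")


if __name__ == "__main__":
    main()
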