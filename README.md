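# bulkscan

Bulked-segregant QTL-seq analysis for mapping quantitative trait loci from
pooled sequencing of phenotypic extremes — built around the rice
heat-tolerance design: spikelet-fertility phenotyping of an F2:3
population, tolerant/sensitive DNA bulks of 50 plants, SNP-index and
Δ(SNP-index) genome scans with 500 kb / 5 kb sliding windows, a
resampling-based 99.9% confidence threshold, candidate-region calling with
the 0.7/0.3 pool-index criteria, gene annotation of the mapped interval,
and 2^−ΔΔCt qPCR comparisons of candidate genes.

At an effective SNP (parents opposite homozygotes) the SNP-index of a pool
is the fraction of reads carrying the tolerant-parent (HHZ) allele, and

    Δ(SNP-index) = index(T-pool) − index(S-pool)

which is 0 in expectation at unlinked loci and approaches 1 where the
tolerant allele was driven to fixation in the tolerant bulk. Windowed Δ is
tested against a Monte-Carlo null that redraws bulks of 50 F2 genotypes and
resamples reads at the observed depths.

Because the statistics only reveal their behaviour under known truth, the
package ships a first-class simulator: F2 meiosis with Haldane crossovers
(250 kb/cM), family-mean fertility phenotypes calibrated to the study's
population moments (mean 0.50, SD 0.1847 on the proportion scale), tail
bulks, and pooled reads with sequencing error, emitted as standard
VCF/GFF3/TSV with a ground-truth file. See `docs/methods.md` for the models
and their assumptions.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (a reduced genome: 3 chromosomes × 10 Mb, one planted fertility QTL of
additive effect 0.18 at chr8:4,000,000):

```sh
python analysis/01_simulate.py
python analysis/02_phenotypes_and_bulks.py
python analysis/03_genome_scan.py
python analysis/04_call_regions.py
python analysis/05_annotate_region.py
python analysis/06_qpcr.py
```

Selected output (seed 1):

```
n = 365 plants; fertility mean 0.5097 (proportion), SD 0.1813, CV 35.57%
sensitive bulk (50 plants): 5.50-29.50%
tolerant  bulk (50 plants): 71.50-100.00%
...
read 601 records, kept 601 effective SNPs
largest window Δ(SNP-index) = 0.780 at chr8:3,685,001-4,185,000 (index T 0.895, S 0.116)
...
2 candidate region(s):
  chr8:1-8,070,000  size 8.070 Mb, peak Δ 0.780 at 3,935,000, index T 0.827 / S 0.203
```

The population moments match the calibration target, the bulks separate
cleanly, and the scan finds the planted QTL: the peak window sits 65 kb
from the true position and the called region contains it. The region
itself is wide — with a single strong QTL the pool-index plateau extends
megabases under 250 kb/cM linkage (see the limitations section of
`docs/methods.md`). `analysis/06_qpcr.py` then recovers the ~4× induction
of the two simulated candidate genes with ** significance at every
timepoint, and `analysis/07_calibration_experiments.py` repeats the scan
over 20 seeds with and without the QTL (recovery 20/20; no false region in
20/20 null runs).

The same stages are available as a CLI (`bulkscan simulate | phenotype |
scan | regions | annotate | qpcr | run`), with `bulkscan run --config
config.yaml` executing any subset of stages and writing a manifest with
config snapshot, input checksums, seed and per-stage runtimes.

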