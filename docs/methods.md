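# Methods

`bulkscan` implements the analysis chain of a bulked-segregant (QTL-seq)
mapping experiment for heat tolerance at the rice flowering stage, together
with a synthetic-data generator that reproduces the statistical structure of
such an experiment so that every stage can be validated against known truth.
This note records the models, the defaults and why they were chosen, the
numerical decisions, and what the synthetic experiments can and cannot show.

## Study design being modelled

An F2 population of 365 plants derives from a cross between a heat-tolerant
parent (HHZ) and a heat-sensitive parent (9311). Each F2 plant is phenotyped
for spikelet fertility after heat stress at anthesis — operationally, as an
F2:3 family: a small number of selfed progeny are scored and averaged. The
50 most tolerant and 50 most sensitive plants form two DNA bulks, each
sequenced as a pool (~57x) alongside the two parents (~36x). At a SNP where
the parents carry opposite homozygous alleles, the *SNP-index* of a pool is
the fraction of its reads carrying the HHZ allele, and

    Δ(SNP-index) = index(T-pool) − index(S-pool).

Unlinked loci have expectation 0.5 per pool and Δ = 0; a locus where
tolerance alleles were enriched by the phenotypic selection pushes the
T-pool toward 1 and the S-pool toward 0. Per-site indices are averaged in
500 kb windows advanced in 5 kb steps, and windows are tested against a
resampling null at the 99.9% confidence level. Significant windows with
T-pool index ≥ 0.7 and S-pool index ≤ 0.3 merge into candidate regions,
which are then intersected with gene models. Candidate genes are compared
between genotypes by qPCR with the 2^−ΔΔCt method.

## Synthetic-data generator

**Meiosis.** Each F2 plant is the union of two independent F1 gametes per
chromosome. Crossovers fall as a Poisson process (Haldane model, no
interference) with a physical-to-genetic scale of 250 kb/cM, the genome-wide
average for rice; `bp_per_cm` is configurable and `inf` disables
recombination entirely. Interference is immaterial at the 500 kb window
scale, so the simplest standard map function is used.

**Markers.** Informative SNP positions are drawn uniformly per chromosome at
`snp_density` (default 20/Mb); QTL positions are always included as markers.
Parents are fixed opposite homozygotes at every marker, which is what the
"effective SNP" filter selects for in real data.

**Phenotype.** The genetic value of a locus with additive effect `a` and
dominance `d` is `a·(dosage−1) + d·[dosage==1]` on the fertility proportion
scale. Family-mean phenotyping is mimicked by averaging the genetic value
over `f3_family_size` (default 12) selfed progeny of each F2 plant — progeny
of a heterozygote re-segregate 1:2:1 — before adding a family-level residual
`Normal(0, resid_sd)` to the baseline (default 0.50) and clamping to [0, 1].
The DNA pools, in contrast, sample the *F2* genotype, matching how bulks are
built from F2 leaf tissue while phenotypes come from F2:3 families.

With the default single QTL of `a = 0.18`, `resid_sd = 0.131` makes the
total phenotype SD ≈ 0.1847 (the calibration target on the proportion
scale): the additive locus contributes variance a²/2 between families plus
a²/(4·m) within heterozygous families, and
sqrt(0.1847² − 0.0162 − 0.0007) ≈ 0.131. Measured over 20 seeds, the
realised SD falls in [0.16, 0.20].

**Grain counts.** Each plant's panicle carries 200 grains;
`filled ~ Binomial(200, fertility)` split 9:1 into fully and partially
filled. These two knobs are invented (only the fertility ratio is
constrained by the design) and exist so the phenotype file has the same
columns a field experiment produces (N_FG, N_PG, N_EG).

**Pooled reads.** At each marker the true pool frequency is
`f = Σ dosages / (2·bulk_size)` over the pooled plants (equimolar pooling
assumed); site depth is `Poisson(mean_depth)` and HHZ-supporting reads are
`Binomial(depth, f(1−ε) + (1−f)ε)` with a single symmetric per-read miscall
probability ε (default 0.001). REF/ALT orientation in the emitted VCF is
randomised per site so that downstream code must orient by the parent
genotype, never by REF status. No read-level artifacts (indels, mapping
error, duplicates) are simulated.

**Determinism.** All randomness flows from one root seed through named
`SeedSequence` substreams (markers, meiosis per chromosome, phenotype,
reads, genes), so datasets are byte-identical across runs and stages can be
re-run independently.

## Filtering and orientation

The source experiment reports counts of "high-quality" and "effective"
SNPs without stating cutoffs, so the filter is explicit and logged instead
of guessed: parents genotyped and opposite homozygotes, parent depth ≥ 6,
pool depth within [8, 3× mean]. Each removed site is attributed to the
first rule it fails, so per-rule counts plus kept sites always equal the
input count, and filtering is idempotent. Absolute counts of retained SNPs
are therefore pipeline-specific and are not treated as reproduction
targets.

## Windows

Windows are anchored at bp 1 and advance by the step; terminal windows are
truncated at the chromosome end and kept with their true span. Every SNP
contributes to each window covering it (interior SNPs to exactly
ceil(window/step) windows). Window means are computed with prefix sums over
position-sorted sites and are exactly equal (not approximately) to a
brute-force rescan, which the tests assert on randomised instances. The
window Δ is the mean of per-SNP Δ values; with identical SNP sets per pool
this equals the difference of per-pool window means. Windows with fewer
than `min_snps = 3` SNPs are flagged: they are written to output but carry
no threshold and cannot contribute to regions, which guards against
single-SNP spikes.

## Resampling null and thresholds

Each null replicate draws two bulk HHZ frequencies
`f ~ Binomial(2·bulk_size, 1/2) / (2·bulk_size)` — the exact distribution of
an F2 bulk's allele frequency at an unlinked locus — and then reads
`Binomial(depth, f)` per pool, returning |Δ|. Thresholds are upper sample
quantiles (method `higher`, conservative at the tail) at 95/99/99.9%.

Window-level thresholds condition on the window's observed median pool
depths and its SNP count. Crucially, the bulk-frequency pair is drawn *once
per replicate* and shared across the window's sites, while read noise is
drawn independently per site: SNPs within 500 kb ride on essentially the
same chromosomes of the same 100 plants, so averaging across a window
cancels read noise but not genotype noise. Treating the sites as
independent (available as `linkage="independent"` for comparison) would
shrink the null spread by roughly sqrt(n_snps) and inflate the
false-positive rate by two orders of magnitude. With the shared-genotype
null, the measured window exceedance rate on no-QTL simulations is ~0.0006
at the 99.9% level — slightly conservative, as expected when intra-window
linkage is modelled as complete.

Thresholds are cached by (median depth T, median depth S, n_snps) with a
seed substream derived from the key, so identical windows get identical
thresholds regardless of evaluation order. The default of 1,000 replicates
honours the stated resampling protocol, but the 99.9% quantile of 1,000
draws is order-statistic noisy; the tool warns and supports large `n_reps`
for production use. A pool-label permutation null is not offered as the
default because with only two pools it cannot resolve the 99.9% tail.

## Region calling

A window is significant when its mean Δ exceeds its 99.9% threshold and the
pool-index criteria hold (T ≥ 0.7, S ≤ 0.3; both toggleable, applied at
window level). Significant windows on a chromosome merge while the gap
between consecutive windows is at most `gap_max` (default twice the step).
Regions report their span, size in Mb (`(end − start)/10^6`, matching how
the mapped interval's 0.965 Mb is computed from its endpoints), the peak
window's Δ and midpoint, and mean pool indices. Merging is idempotent and
independent of input row order.

## qPCR

ΔCt = Ct(target) − Ct(reference) within a condition, ΔΔCt subtracts the
calibrator condition's mean ΔCt, fold change is 2^−ΔΔCt; a plate-wide Ct
offset cancels exactly. The calibrator is an explicit (sample, timepoint)
pair — by default the sensitive genotype at the first timepoint — because
the baseline choice materially changes fold values and should never be
implicit. Replicate reference-gene wells are matched to target wells by
replicate id, giving per-replicate fold changes for the genotype contrast;
a pooled mode averages ΔCt first. The contrast is a two-sided two-sample
Student's t-test (equal variance by default, matching the convention of the
era's analyses; Welch by flag), starred * below 0.05 and ** below 0.01.
Primer-efficiency correction is out of scope.

## Calibration experiments and their problem sizes

Both standing experiments use a reduced genome (3 chromosomes × 10 Mb,
20 SNPs/Mb) with the full design (365 F2, bulks of 50, 57× pools), a size
chosen so a 20-seed batch finishes in about a minute per experiment on one
CPU while every stage still operates far from small-sample corner cases.

* **Recovery** (planted QTL, a = 0.18 at 4.0 Mb of the chromosome-8
  analog): across 20 seeds, a called region overlaps the true position on
  the correct chromosome in 20/20 runs.
* **Type-I** (no QTL): mean fraction of windows exceeding their 99.9%
  threshold ≈ 0.0006; with the 0.7/0.3 criteria no region is called in any
  of 20 seeds.
* **Estimator property**: the mean pooled SNP-index over ≥ 10,000 unlinked
  sites is statistically indistinguishable from (1−2ε)·0.5 + ε (= 0.5; the
  symmetric miscall term cancels at f = 0.5), with the standard error taken
  over independent chromosomes because sites within a chromosome share the
  pooled genotype.

## Known limitations

* **Localisation, not just detection, is limited by linkage.** A single
  additive QTL of a = 0.18 with total phenotype SD 0.1847 yields a very
  strong selection response: the bulk allele frequency at the QTL reaches
  ~0.88/0.12. At 250 kb/cM the expected pool indices then stay beyond the
  0.7/0.3 cutoffs for more than ±6 Mb (the marker shift decays as e^−2m),
  so the called region spans most of a 10 Mb chromosome and its *midpoint*
  lands ~1 Mb from the truth, even though the region always contains the
  QTL and the *peak window* localises to ~0.1 Mb (median over seeds). A
  sub-Mb mapped interval, as reported for real data, implies a locally much
  weaker selection response than a single-QTL model with these parameters
  produces — consistent with polygenic background absorbing part of the
  phenotypic variance. The generator deliberately models only the
  configured QTL list; users wanting narrow regions in simulation should
  plant weaker effects or add background loci to the list.
* The simulator emits SNPs only (no indels), one error rate, no mapping or
  duplication artifacts, and assumes exactly equimolar plant contributions
  to each pool; real pools violate all of these mildly.
* Window thresholds model intra-window linkage as complete, which is
  slightly conservative for windows spanning more than ~1 cM.
* Passing the synthetic experiments demonstrates the statistics are
  implemented and calibrated as specified, not that any particular real
  dataset will reproduce a published interval — the upstream read
  processing (alignment, variant calling) is consumed, never reimplemented.
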