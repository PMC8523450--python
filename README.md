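# mitoqc

QC, artifact filtering, threshold variant calling and sensitivity analysis
for whole-mitochondrial-genome amplicon panel sequencing.

Forensic mtDNA typing by massively parallel sequencing on short-amplicon
panels faces a characteristic set of nuisances: short low-MAPQ
micro-amplicon reads that dominate amplification negatives, recurrent
low-level noise at NUMT-associated positions, homopolymer miscalls,
strand-biased regions, and stochastic template sampling when input DNA is in
the picogram range.  `mitoqc` packages the analytical workflow a laboratory
uses to validate such an assay, so each step is reusable, testable and
scriptable:

* **coordinates** — the circular rCRS axis, its +80 nt linearization
  (`rCRS + 80`), 1-based inclusive intervals, amplicon panels (BED I/O).
* **read_filter** — two-cluster analysis of read length × MAPQ (exact
  2-means on small inputs, seeded k-means otherwise), length-cutoff
  derivation, the validated 80 bp filter, per-amplicon artifact hotspots.
* **pileup / caller** — strand-resolved pileups and a threshold cascade
  with the validated parameters (coverage ≥ 20 reads; 96% confirmation;
  10% point heteroplasmy, reported as IUPAC codes such as `7861Y`; 20%
  insertion; 30% deletion; 5%-of-amplicon-median low-coverage marking),
  EMPOP-style haplotype profiles, VCF/BED output.
* **varfreq** — per-position haplotype purity (VarFreq), its cumulative
  distribution on the 0–99 grid, a cross-sample recurrent-noisy-position
  blacklist (a 26-position annotated table ships with the package), and an
  envelope test that classifies a run as stable or stochastic against a
  band of known-good replicates.
* **sensitivity** — the copy-number equation (0.1 ng gDNA ≈ 2,900 mtDNA
  copies), scoring of called profiles against a known truth across a
  13-step dilution ladder, PHP recovery curves, and haplotype concordance
  with forensic conventions (control-region restriction, PHP leniency).
* **simulate** — a seeded generator producing aligned reads (SAM or
  in-memory) with template-count-driven stochasticity, template-level
  heteroplasmy, jackpot PCR noise, micro-amplicon artifacts, NUMT-like
  recurrent noise, homopolymer and strand-bias errors — plus ground truth
  for every injected feature.

The model at the core of the sensitivity analysis: a sample at input mass
*m* pg contributes *N* ~ Poisson(29 · *m*) mtDNA templates; each amplicon
captures templates by binomial thinning, heteroplasmic alleles ride on
templates (not reads), and library normalization keeps sequencing depth
near-constant while templates dwindle — so low-input failure modes are
allele dropout, jackpot amplification of early PCR errors, and amplicon
dropout, exactly the behaviors the dilution series probes.

## Worked example

```python
import mitoqc as m
from mitoqc.sensitivity import score_replicate
from mitoqc.varfreq import load_noisy_position_annotation, coverage_summary

cfg = m.make_config(seed=42, input_pg=100.0, sample="demo")
res = m.run_simulated_sample(cfg)          # simulate -> filter -> call -> QC

rep = res.filter_report
print(f"reads: {rep.total_mapped}  removed <80 bp: {rep.removed} ({rep.pct_short_display}%)")
cov = coverage_summary(res.pileup, cfg.panel, n_reads=rep.kept)
print(f"mean base coverage: {cov.mean_base_coverage:.0f}x  uniformity: {cov.uniformity_pct:.2f}%")
blacklist = set(load_noisy_position_annotation().position)
score = score_replicate(res.profile, res.truth, exclude_positions=blacklist)
print(f"covered: {score.pct_mtDNA_covered:.1f}%  FP: {score.false_positive_calls}  FN: {score.false_negative_calls}")
print(f"PHP 7861 observed: {score.php_detected[7861]:.1f}% (truth 17.0%)")
```

prints

```
reads: 160044  removed <80 bp: 4426 (2.8%)
mean base coverage: 1399x  uniformity: 100.00%
covered: 100.0%  FP: 0  FN: 0
PHP 7861 observed: 18.2% (truth 17.0%)
```

A 100 pg sample yields ~160k mapped reads of which 2.8% are short
micro-amplicon artifacts; after the 80 bp filter the caller recovers the
entire genome with no false calls outside the known-noisy blacklist, and the
17% heteroplasmy at position 7861 is detected at 18.2% (template sampling at
~2,900 copies plus read noise).  Dropping `input_pg` to 0.075 (≈ 2 templates)
produces missed heteroplasmies, false positives and coverage gaps — the
stochastic regime the dilution series maps out.

A thin CLI mirrors the library (`mitoqc simulate | filter-reads | call |
varfreq | runqc | sensitivity | concord`); run `mitoqc --help`.

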