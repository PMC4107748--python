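# ddcnv

Absolute copy-number-variant (CNV) quantification from droplet digital
PCR (ddPCR), with an extreme-phenotype association pipeline for blood
pressure.

Real-time qPCR measures copy number only relatively, which has made CNV
association studies unreliable. ddPCR partitions each reaction into ~10⁴
droplets and counts which ones amplify, so the template concentration —
and from it the *absolute* integer copy number per diploid genome — falls
out of Poisson partition statistics. `ddcnv` implements that measurement
chain and the downstream genetics for a two-tail ("power of extremes")
blood-pressure design: quantify λ per channel, call integer copy number
against a reference assay, select extreme systolic-BP groups, and test
whether deletion/gain carriers are enriched in the hypertensive tail.

## The model

With k positive droplets of n, the mean template occupancy per droplet is

    λ̂ = −ln(1 − k/n)        (95% CI: delta method; exact binomial near the boundary)

and copy number per diploid genome is normalised by the two-copy
reference locus (RNaseP):

    ĈN = 2·λ̂_target / λ̂_reference.

A sample is genotyped when the 95% CI of ĈN contains exactly one integer
in {1, 2, 3}; unresolved samples are repeated and, if still unresolved or
discordant, excluded. Association uses logistic regression of
extreme-group membership on carrier status (adjusted for age, BMI, sex)
and within-group Wilcoxon rank-sum tests of BP by genotype.

## Worked example

Run the built-in end-to-end pipeline — simulate an extreme cohort
(96 high / 92 low, deletion prevalence 12.6% vs 2.2%), genotype every
subject by simulated duplex ddPCR, and test the association:

```
$ ddcnv run --seed 7 --out-dir demo
$ cat demo/summary.txt
ddcnv pipeline report (seed 7)
assay: Hs01327571

droplets/well 13599.2 +/- 81.3 (SEM); genotyped 188/188 (excluded 0.0%); repeated fraction 0.537, concordance 0.822

genotype counts (per group):
  high: CN1: 7 (7.3%), CN2: 89 (92.7%)
  low: CN1: 4 (4.3%), CN2: 88 (95.7%)

logistic (high vs low ~ carrier + age+bmi+sex): OR 1.51 [0.14, 15.77], P = 0.7329
Wilcoxon high_sbp: diff -1.81 mmHg, P = 0.757 (n = 7 vs 89)
...
tests run (unadjusted): 5
```

Reading it: each well carried ~13,600 droplets (SEM over 188+ wells);
every sample resolved to an integer genotype, so nothing was excluded;
this particular draw put 7 deletion carriers in the high group and 4 in
the low group, an odds ratio of 1.5 whose wide CI straddles 1 — a
reminder that at ~190 subjects a single cohort draw frequently misses a
true prevalence difference of 12.6% vs 2.2%. The intermediate artifacts
(`wells.csv`, `estimates.tsv`, `calls.tsv`, `report.json`) are all
written alongside, and the same seed reproduces them byte-for-byte.

The stages are also available piecewise (`ddcnv simulate droplets`,
`quantify`, `call`, `design`, `associate`) and as library functions:

```python
>>> from ddcnv import estimate_lambda, cn_ratio, call_integer
>>> t = estimate_lambda(2780, 14000)   # target channel
>>> r = estimate_lambda(5070, 14000)   # reference channel
>>> cn, ci = cn_ratio(t, r)
>>> call_integer(cn, ci).integer_call
1
```

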