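# corrlink

Fast pairwise recombination-fraction estimation for biparental selfing
populations (F2, F3, ..., F_t), with EM reference estimators,
Haldane linkage-map construction, a mechanistic F_t population simulator,
and a genomic-mating workflow built on GBLUP progeny prediction.

## Who this is for

Plant and animal geneticists building genetic maps from biparental crosses
with inbred founders (F2 or later selfing generations), and breeders who
want to go one step past genomic selection: predicting the genomic value of
*crosses* between selected parents and choosing the best mate allocation.

## The core idea

Code genotypes at each biallelic locus as the allele count
`X ∈ {0, 1, 2}` of one parental allele. In an F_t population derived by
selfing from a coupling-phase F1 (`AB/ab`), with no segregation distortion
and no crossover interference, the Pearson correlation between the codes of
two loci satisfies

    r = 1 − 2θ            for every generation t ≥ 2,

where θ is the recombination fraction. So

    θ̂ = (1 − r̂)/2,       s_θ̂ = (1 − r̂²) / (2 √(n − 3)),

one correlation instead of an iterative likelihood maximization per marker
pair. Negative correlations (possible under distortion or sampling noise)
are clamped to r = 0, giving θ̂ = 0.5. For reference and for diagnosis the
package also implements:

* **EM, codominant model** (`estimate_em_codominant`) — the classical EM
  for fully informative markers; only the double heterozygote mixes
  recombinant classes, and the M-step is recombinant-gamete counting.
* **EM, dominant model** (`estimate_em_dominant`) — the four-phenotype-class
  formulation iterating on π = (1 − θ)², for dominant markers.
* **Backcross counting** (`estimate_bc_direct`) — direct recombinant ratio.

Standard errors for both EM estimators come from the Louis observed
information (expected complete-data information minus the posterior variance
of the complete-data score); see `docs/methods.md` for the closed forms.

Adjacent-pair estimates are converted to map distances with the Haldane
function `d = −50·ln(1 − 2θ)` cM and assembled into per-chromosome linkage
maps. A chi-square diagnostic against the F_t segregation ratios
(1:2:1 at F2) flags the distorted marker pairs where the correlation
estimator is unreliable.

The `mating` module closes the loop from maps to breeding decisions:
two-variance-component REML (additive + dominance marker kinships), BLUP
prediction of individual EBVs, marker-effect back-solving, progeny
prediction per cross by Mendelian expectation or by simulated meiosis
(Poisson crossovers, no interference), and exhaustive search over all
`d!/(v!)^s` assignments of d dams to s sires.

## Worked example

The package ships the joint genotype counts of two adjacent marker-bin
pairs from a 191-plant rice F2 population (`corrlink.examples`). The
chromosome 1 pair segregates cleanly; the chromosome 4 pair is strongly
distorted:

```python
from corrlink import examples, estimate_pcorr, estimate_em_codominant, \
    estimate_em_dominant, collapse_to_phenotypes, segregation_chisq

for name, table in [("chr1", examples.rice_pair_chr1()),
                    ("chr4", examples.rice_pair_chr4())]:
    p = estimate_pcorr(table)
    c = estimate_em_codominant(table)
    d = estimate_em_dominant(collapse_to_phenotypes(table))
    x2 = segregation_chisq(table.m.sum(axis=1), generation=2)
    print(f"{name}: pcorr {p.theta:.5f}±{p.se:.5f}  "
          f"emcd {c.theta:.5f}±{c.se:.5f}  emd {d.theta:.5f}±{d.se:.5f}  "
          f"X2={x2.statistic:.4f}")
```

prints

```
chr1: pcorr 0.02557±0.00363  emcd 0.02387±0.00792  emd 0.02192±0.01093  X2=1.2199
chr4: pcorr 0.05645±0.00777  emcd 0.03473±0.00957  emd 0.03323±0.01486  X2=25.6073
```

On chromosome 1 the three estimators agree closely and the correlation
method has the smallest standard error. On chromosome 4 the segregation
chi-square (25.61 on 2 df, p ≈ 3e-6) reveals strong distortion, and the
correlation estimate (0.056) drifts away from the likelihood-based ones
(≈ 0.034) — exactly the failure mode the diagnostic is there to catch.

The same comparison is available from the shell:

```bash
corrlink pair chr1_counts.tsv            # 3x3 integer table, rows X_A = 0,1,2
corrlink map --genotypes g.tsv --map m.tsv --method pcorr --out map.tsv
corrlink sim-study --thetas 0:0.5:0.05 --n 200 --reps 100 --out study.tsv
corrlink mate --n 500 --sim-reps 1000 --seed 1 --outdir design/
```

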