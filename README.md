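# bincfdr

Binary conditional false discovery rates for GWAS: leverage a **binary**
auxiliary covariate (overlap with transcription-factor footprints, chromatin
states, coding/non-coding status, …) alongside GWAS p-values to gain power
while keeping the FDR controlled.

## Who this is for

Statistical geneticists with a per-SNP table of association p-values and one
or more binary functional annotations. Classical conditional-FDR (cFDR)
methods require a continuous covariate; `bincfdr` implements the two-stratum
extension, which turns each (p, q) pair into a **v-value** — uniform on
(0, 1] under the null, small where the annotation is enriched for signal —
that can be fed to any standard multiple-testing procedure such as
Benjamini–Hochberg (BH). Applying the transform iteratively leverages several
annotations in turn.

## The method

For SNP i with p-value `p_i ∈ (0, 1]` and covariate `q_i ∈ {0, 1}`, consider
rejection regions that are unions of two half-lines,

    L(p0, p1) = (P ≤ p0, Q = 0) ∪ (P ≤ p1, Q = 1).

The two thresholds are matched so that the estimated density ratio
`f(p, q) / f0(p, q)` is equal at `(p0, 0)` and `(p1, 1)`; the coordinate of
the observed stratum is pinned at `p_i` and the other is solved from

    p · Pr(Q = q | H0) / ( F_q(p) · Pr(Q = q) ),

where `F_q` is the stratum's CDF of p. The v-value is the null mass of the
region,

    v_i = p0 · (1 − q0) + p1 · q0,        q0 = Pr(Q = 1 | H0).

Estimation details (see `docs/methods.md`): per-stratum CDFs are
continuity-corrected empirical CDFs concavified by their least concave
majorant (the Grenander estimate under the standard assumption that the
p-value density is nonincreasing), which makes the ratio monotone in p and
its inversion a stable closed form; `q0` is the covariate rate among SNPs
with p > 1/2 (a null-dominated region); and everything is fit with
leave-one-group-out folds (chromosome or LD block) so rejection rules are
never applied to the data that built them.

The package also ships the simulation study used to validate these claims:
block-LD GWAS summary statistics (AR(1) within-block correlation, 2–4 causal
variants per block with log-OR ~ N(0, 0.2²), 5000 cases / 5000 controls) and
three covariate scenarios — A: irrelevant q ~ Bern(0.05); B: q ~ Bern(0.4)
on "functional" SNPs (causal ± 10 kb) and Bern(0.05) elsewhere; C: as B with
rate 0.8, the misuse case of repeatedly leveraging one functional mark.

## Worked example

Simulate a scenario-B study (9600 SNPs, 24 LD blocks, three covariate
columns) and leverage the three annotations iteratively:

```bash
bincfdr simulate --scenario B --seed 7 --iterations 3 --out study.tsv
bincfdr run --input study.tsv --q-cols q_iter1,q_iter2,q_iter3 --out cfdr.tsv
```

The log reports each iteration's discovery count at BH-FDR < 0.05:

```
INFO bincfdr.core: binary_cfdr iteration 1: m=9600, groups=24, 787 SNPs with fdr<0.05
INFO bincfdr.core: binary_cfdr iteration 2: m=9600, groups=24, 891 SNPs with fdr<0.05
INFO bincfdr.core: binary_cfdr iteration 3: m=9600, groups=24, 1062 SNPs with fdr<0.05
```

At the stringent genome-wide threshold (FDR ≤ 5×10⁻⁶) the raw p-values give
276 significant SNPs; iterations 1–3 give 279, 285 and 300 — power grows as
informative annotations are layered in. `cfdr.tsv` carries the input columns
plus `v_iterK` / `fdr_iterK` per iteration:

```
  snp        p  q  v_iter1  fdr_iter1  v_iter3  fdr_iter3
snp_0 0.911114  1 0.212692   0.658023 0.060779   0.288563
snp_1 0.346479  1 0.073563   0.396861 0.001550   0.018392
snp_2 0.132231  0 0.208800   0.654283 0.034393   0.198420
```

SNPs in the annotated stratum (q = 1, enriched for signal in scenario B)
have their evidence strengthened; unannotated SNPs are nudged the other way.

The same machinery is available as a library (`bincfdr.binary_cfdr`,
`bincfdr.iterate_cfdr`, `bincfdr.run_scenario`, …), and
`bincfdr annotate --input study.tsv --bed marks.bed --out annotated.tsv`
builds a binary covariate from a BED track (1-based SNP positions against
0-based half-open intervals).

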