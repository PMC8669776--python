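# fdrkit

False discovery rate **estimation** and FDR/FWER **control** from raw
p-values — as a Python library and a command-line tool.

In large-scale testing (genomics, imaging, proteomics) the same adjustment
machinery produces two quantities that are routinely confused, and some
software even reports one labeled as the other:

- the **adjusted p-value** `p~_i` — the smallest threshold γ at which feature
  *i* would be *selected* by a control procedure.  For Benjamini–Hochberg
  (step-up): `p~_(i) = min_{j≥i} p_(j)·m/j`.  Monotone in rank by
  construction.
- the **per-feature FDR estimate** `FDR_i` — the propensity for that specific
  finding to be a false discovery.  For BH: `FDR_i = p_i·m/rank(p_i)·π0`,
  with **no** step smoothing, so it need not be monotone.

A feature can be selected by the control procedure at level γ while its own
estimated FDR exceeds γ; both numbers matter and answer different questions.
`fdrkit` computes both, keeps them distinct, and surrounds them with the
supporting machinery:

- six methods: BH, BY (harmonic `c(m) = Σ 1/j` dependence correction),
  Bonferroni, Sidak, Holm, Hochberg — each giving an FDR estimate, an
  adjusted p-value, and a raw step-up/step-down rejection search;
- null-proportion (π0) estimators: fixed value, **Last Histogram Height**
  (`π̂0 = H_B·B/m`, with Scott's-rule binning), Storey's λ-tuned estimator
  with spline smoothing, and Pounds (`min(1, 2·p̄)`);
- a univariate Gaussian **lower bound** on the FDR,
  `(1 + exp(z²/2)·π1/π0)⁻¹`, usable even for a single test;
- the two-group mixture model `F = π0·F0 + π1·F1` on the Z scale with
  region-wise empirical-Bayes FDR `π0·F0(Z)/F(Z)`;
- a seeded two-group simulator with bias/MSE grids for the π0 estimators and
  empirical-FDR/power checks of the control procedures;
- diagnostic plots (p-values/FDRs by rank or Z-value; π0 histograms with the
  last-bin-height line and density overlays).

## Worked example

Five features with raw p-values 0.005, 0.049, 0.050, 0.051, 0.700, two-sided:

```sh
printf "0.005\n0.049\n0.050\n0.051\n0.700\n" > tbl1.txt
fdrkit compute --input tbl1.txt --method BH --threshold 0.05 --lower-bound
```

prints (summary on stderr, table on stdout):

```
method=BH m=5 pi0=1 rejected=1
feature,raw_p,adjusted_p,fdr,lower_bound_fdr,reject
1,0.005,0.025,0.025,0.019082451054697976,Reject.H0
2,0.049,0.06375,0.1225,0.1259033306258998,FTR.H0
3,0.05,0.06375,0.08333333333333333,0.12778024966946022,FTR.H0
4,0.051,0.06375,0.06375,0.1296410028386706,FTR.H0
5,0.7,0.7,0.7,0.481449535748192,FTR.H0
```

Reading the table: at γ = 0.05 only feature 1 is selected
(`adjusted_p = 0.025 ≤ 0.05`).  The adjusted p-values rise monotonically
(0.025, 0.064, 0.064, 0.064, 0.700) but the FDR estimates do not
(0.025, 0.122, 0.083, 0.064, 0.700): feature 2's finding has an estimated
12% propensity to be a false discovery even though its raw p-value is below
0.05.  At γ = 0.07 the step-up search would select features 1–4, yet only
features 1 and 4 have estimated FDRs below 0.07 — selection by a control
procedure is not the same statement as a small per-feature FDR.  The last
column is the Gaussian lower bound: feature 4's FDR cannot be below 0.13
under any prior with odds 1, flagging its BH estimate (0.064) as optimistic.

The same computation in Python:

```python
import fdrkit as fk

res = fk.p_fdr([0.005, 0.049, 0.050, 0.051, 0.700],
               method="BH", threshold=0.05, include_lower_bound=True)
print(res.fdrs)        # [0.025  0.1225 0.0833 0.0637 0.7   ]
print(res.n_rejected)  # 1
```

Null-proportion estimation and simulation benchmarks:

```sh
fdrkit pi0 --method set.pi0 --set-pi0 0.8     # prints 0.8
fdrkit pi0 --method last.hist --input p.txt   # Last Histogram Height
fdrkit simulate --m 100 --pi0-true 0.8 --reps 200 --seed 1 --out-prefix sim
```

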