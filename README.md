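# FLARE — fragmentomics for long-read nanopore cfDNA

FLARE (Fragmentation and Long-read Analysis of Regulatory Epigenetics) is
an integrated analysis toolkit for cell-free DNA (cfDNA) sequenced on
long-read nanopore platforms, where each read spans a whole cfDNA molecule
and carries native 5mC calls in its MM/ML tags.  It is aimed at liquid-
biopsy researchers who want fragment-level tumor signal from shallow
plasma sequencing:

- **Filtering** — primary, mapped reads with mapq ≥ 20 and a fragment-
  length cut, with per-reason drop accounting.
- **Fragment sizes** — length QC (mean/median/N50) and stratification into
  short (< 150 bp), intermediate (150–300 bp) and long (> 300 bp) classes.
- **5' end motifs** — strand-aware extraction of the 4-mer at each
  fragment's 5' terminus into a samples × 256 frequency matrix, decomposed
  by non-negative matrix factorization (multiplicative updates, best of
  100 random restarts, consensus/cophenetic stability) into latent
  fragmentation profiles W·H.
- **Copy number & tumor fraction** — binned coverage, GC correction,
  panel-of-normals log2 ratios, and a 4-state HMM (c ∈ {0,1,2,3}) with
  emission means μ_c(n, φ) = log2((2n + (1−n)c)/(2n + (1−n)φ)) fitted by
  MAP-EM from normal-fraction restarts {0.95, 0.99, 0.995, 0.999}; the
  restart with the highest log-likelihood is reported and the tumor
  fraction is 1 − n̂.  The same fit is re-run per size class.
- **Methylation tumor fraction** — per-read beta-binomial class
  likelihoods over a marker panel, maximized as a tumor/normal mixture
  θ·L_t + (1−θ)·L_n on a θ grid with informativeness weighting
  (λ = 0.5).
- **Statistics** — exact Wilcoxon signed-rank / rank-sum tests and
  Spearman correlation with Fisher-z CIs, used by the cohort report.
- **Simulator** — synthetic cohorts (reference, SAM with MM/ML, marker
  BED, panel of normals, truth JSON) with planted fragment-length
  mixtures, end-motif profiles, CNV profiles and methylation levels, so
  every stage is testable against known truth.

See `docs/methods.md` for the models, parameter defaults and limitations.

## Worked example

Recover a planted tumor fraction from binned log2 ratios (3,000 bins,
gains on 20% and losses on 10% of the genome, noise σ = 0.15, true
tf = 0.30):

```python
import numpy as np
from flare import cnvtf

rng = np.random.default_rng(7)
states = np.full(3000, 2)
states[600:900] = 3; states[1200:1500] = 3; states[2100:2400] = 1
log2r = cnvtf.expected_log_ratio(states, 0.7, 2.0) + rng.normal(0, 0.15, 3000)
sol = cnvtf.fit_cnv_hmm(log2r)
print(f"tumor_fraction={sol.tumor_fraction:.3f} ploidy={sol.phi_hat:.2f} "
      f"accuracy={np.mean(sol.states == states):.3f} segments={len(sol.segments)}")
```

```
tumor_fraction=0.301 ploidy=2.03 accuracy=0.991 segments=7
```

The estimated tumor fraction (0.301) recovers the planted 0.30, the
ploidy stays at the diploid baseline, and 99.1% of bins get the correct
copy state across 7 segments.  The independent methylation route, on
10,000 simulated marker reads at θ = 0.2 with tumor Beta(8,2) vs normal
Beta(2,8) markers:

```python
from flare import methtf
est = methtf.estimate_tumor_fraction(reads, markers, lam=0.5)
print(f"theta_hat={est.theta_hat:.4f} n_reads={est.n_reads_used}")
```

```
theta_hat=0.2015 n_reads=10000
```

A full cohort — simulate 6 subjects × 2 timepoints, then run every stage
and write a consolidated report (`report.json`, `report.md`, motif matrix,
W/H, per-sample CNV tables, methylation tumor fractions):

```
flare simulate --seed 3 --subjects 6 --out-dir cohort/
flare run --config run.json      # {"input_dir": "cohort", "out_dir": "out"}
```

Subcommands `flare filter / fraglen / motif / nmf / cnv / methtf / stats`
expose the individual stages.

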