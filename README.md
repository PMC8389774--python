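# entroconv

Binding-entropy estimators for end-state free-energy calculations —
and the diagnostics that tell you whether to believe them.

## The problem

MM/PBSA- and MM/GBSA-style methods estimate protein–ligand binding free
energies by post-processing MD snapshots. The entropic term is the hard
part. Two cheap estimators compute it directly from the per-snapshot
interaction energies ΔE_IE = ΔE_el + ΔE_vdW already produced by the
free-energy pipeline:

* **interaction entropy (IE)** — the mean-centered exponential average

  −TΔS_IE = RT · ln ⟨ exp[(ΔE_IE − ⟨ΔE_IE⟩)/RT] ⟩

* **second-order cumulant (C2)** — the variance approximation

  −TΔS_C2 = σ_IE² / (2RT)

  where σ_IE is the standard deviation of ΔE_IE over all snapshots.

For Gaussian energy fluctuations the two coincide in the infinite-sample
limit. At finite N, however, the exponential average is dominated by
rare, favorable fluctuations at |ΔE| ≈ σ²/RT — for σ_IE = 15 kJ/mol at
300 K that is ~90 kJ/mol out in the tail, where the Gaussian density is
~4×10⁻¹⁰. IE therefore systematically underestimates the entropy and
creeps upward as sampling grows, with no visible sign of failure. C2
converges far faster but inflates quadratically with σ_IE.

`entroconv` implements both estimators (plus a cutoff-truncated IE),
quantifies exactly how many snapshots each needs as a function of σ_IE,
and provides the block-averaging, autocorrelation, extrapolation and
Gaussianity diagnostics needed to judge a real energy series.

## Who it is for

Anyone computing MM/GBSA-style binding entropies from per-frame energy
tables who needs to know: is my σ_IE small enough for IE at all, how
many frames do I need, is my estimate converged, and how much is serial
correlation in dense sampling costing me?

## Worked example

A synthetic i.i.d. Gaussian energy stream with σ_IE = 20 kJ/mol —
inside the regime where the exponential average can no longer be
converged at practical sample sizes:

```python
from entroconv import (StreamSpec, generate, ie_entropy, c2_entropy,
                       analytic_c2, GaussianSpec, convergence_curve,
                       verdict_tier)

series = generate(StreamSpec(kind="gaussian", sigma=20.0, n=100_000, seed=7))
ie, c2 = ie_entropy(series), c2_entropy(series)
print("sigma_IE =", round(c2.sigma_hat, 2))
print("-TdS_IE  =", round(ie.minus_T_delta_S, 2))
print("-TdS_C2  =", round(c2.minus_T_delta_S, 2))
print("analytic =", round(analytic_c2(GaussianSpec(20.0)), 2))
for n, est, se, nb in convergence_curve(series, [100, 1000, 10000], "IE").points:
    print(f"N={n:>6}  IE={est:7.2f} +- {se:.2f}  ({nb} batches)")
print("verdict tier:", verdict_tier(c2.sigma_hat))
```

prints

```
sigma_IE = 19.97
-TdS_IE  = 54.71
-TdS_C2  = 79.91
analytic = 80.18
N=   100  IE=  38.94 +- 0.24  (1000 batches)
N=  1000  IE=  47.97 +- 0.57  (100 batches)
N= 10000  IE=  53.44 +- 0.79  (10 batches)
verdict tier: 2
```

C2 recovers the analytic value σ²/(2RT) = 80.2 kJ/mol almost exactly,
while IE sits ~25 kJ/mol low even at N = 100,000 — and the
block-averaged IE climbing steadily with block size (38.9 → 48.0 →
53.4 kJ/mol) is precisely the signature of an unconverged exponential
average. Verdict tier 2 means: σ_IE is in the 15–25 kJ/mol band where
IE should not be used and only C2 is meaningful.

The same analysis runs from the shell on real per-frame tables:

```sh
entroconv estimate --input energies.tsv --estimator both --block-sizes 100,1000
entroconv minN --sigma 9 --estimator ie --seed 1
entroconv report --config report.yaml --out report.json
```

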