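# adnorm — adaptive normalization for IP vs Mock enrichment experiments

Immunoprecipitation (IP) and affinity-purification experiments identify the
RNAs (or DNA fragments) bound by a protein of interest by comparing
enrichment in a specific IP against a non-specific **Mock** control.  On the
log scale each replicate carries an unknown additive normalization constant
(labeling, scanning, and library-depth effects), and the statistical job is
to estimate the difference `c_IP − c_Mock` before any gene-level test.
Median or quantile normalization silently assumes that most genes are *not*
enriched; for proteins that bind hundreds to thousands of targets that
assumption is wrong, and it caps the number of targets that can ever be
detected.

`adnorm` implements an adaptive, background-anchored alternative for
analysts of RIP-chip / RIP-seq / ChIP-style two-condition enrichment data.
The model is

```
IP_i   = Mock_i + T_i + Z_i + c_IP      (per gene i, per replicate)
T_i    >= 0                             (true binding signal)
Z_i    ~  mean-zero noise
```

Because `T` is non-negative, the genes with the **largest Mock − IP
difference** are the ones least enriched by the IP — the most trustworthy
background.  The package:

- ranks the per-gene differences between a Mock reference and each
  replicate, and estimates the replicate's constant from the top-`k`
  background set `S_k` (median alignment by default);
- chooses `k` automatically per replicate, at the rank where the descending
  difference curve first becomes piecewise linear (sliding 500-rank linear
  windows at R² ≥ 0.995);
- runs every Mock replicate through the *identical* machinery against its
  leave-one-out Mock average, so the order-statistic selection bias enters
  IP and Mock constants equally and cancels in the IP-vs-Mock comparison;
- calls enriched genes with a moderated t-statistic and a conservative
  permutation FDR (plus a Welch + Benjamini–Hochberg cross-check);
- ships seeded simulators for the idealized IP experiment, all-background
  nulls, and Mock-vs-Mock false-target splits, and a preprocessor that turns
  per-bin sequencing counts into a log2 matrix.

## Worked example

```python
import adnorm as ad

# an idealized experiment: 6,000 genes, 10% true targets shifted by +3,
# 3 IP + 3 Mock replicates, each with a hidden Uniform(-2, 2) offset
ds = ad.simulate_ip_experiment(ad.SimulationSpec(seed=7))

result = ad.normalize_experiment(ds.matrix, ad.Config())
print(result.summary()[["replicate", "condition", "constant", "k"]])

vals = result.normalized.values
enrich = vals[ds.matrix.ip_ids].mean(axis=1) - vals[ds.matrix.mock_ids].mean(axis=1)
bg = ds.truth == "background"
print(f"background mean {enrich[bg].mean():+.3f}   target mean {enrich[~bg].mean():+.3f}")

called = ad.permutation_fdr(result.normalized, fdr_threshold=0.05, seed=7)
print(f"{called.n_called} genes called enriched")
```

prints (exactly, for seed 7):

```
  replicate condition  constant            k
0       ip1        IP  0.507274  794;647;785
1       ip2        IP  1.032836  530;500;804
2       ip3        IP  2.722293  655;500;500
3     mock1      Mock  2.090488          641
4     mock2      Mock  2.012163          718
5     mock3      Mock  2.218994          527
background mean -0.095   target mean +2.867
321 genes called enriched
```

Each IP constant undoes that replicate's hidden offset: adding the true
offsets (1.406, 1.022, −0.653 for this seed) to the constants gives 1.91,
2.06, 2.07 — nearly equal across replicates, as the model requires (the
common level is shared with the Mock constants and cancels in the
comparison).  Relative to the normalized Mock center, background genes sit
at ≈ 0 and targets at ≈ +3 (this seed draws −0.10 and +2.87; across
thousands of seeds the averages are −0.05 and 2.95), and the one-sided
permutation test recovers half of the 600 true targets at a 5% FDR while a
Mock-vs-Mock sham split calls none.  Under median normalization of the same
draw the target mean falls visibly short of +3 — the failure mode this
method exists to avoid.

The same pipeline is available from the shell:

```bash
adnorm simulate --preset targets --seed 7 --out sim.tsv \
    --conditions-out cond.tsv --truth truth.tsv
adnorm normalize --matrix sim.tsv --conditions cond.tsv --out norm.tsv --report report.tsv
adnorm select-k  --matrix sim.tsv --conditions cond.tsv --replicate ip1 \
    --plot rank.png --out k.tsv
adnorm test      --matrix norm.tsv --conditions cond.tsv --fdr 0.05 --seed 1 --out targets.tsv
adnorm bin-counts --ip ip_counts.tsv --mock mock_counts.tsv --out logmat.tsv
```

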