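# latvar

Statistical analysis of hemispheric lateralisation and interindividual
variability in bilateral white matter tract metrics.

Diffusion tractography yields paired left/right measurements of language
pathways — the three arcuate fasciculus segments (AFl, AFa, AFp), the
inferior fronto-occipital fasciculus (IFOF), uncinate fasciculus (UF),
inferior longitudinal fasciculus (ILF) and frontal aslant tract (FAT) —
for three metrics per tract: HMOA (hindrance-modulated orientational
anisotropy), streamline count (TC), and voxel count (VC).  `latvar` answers
three questions about such a cohort:

1. **Is each tract lateralised on average?**  Per participant and tract ×
   metric the lateralisation index is

   LI = (value_R − value_L) / (value_R + value_L) ∈ [−1, 1],

   negative = leftward.  Population-level evidence for a nonzero mean LI is
   a Bayes factor comparing a Gaussian model with free mean μ (Cauchy(0,
   0.707) prior truncated to [−1, 1]) against the μ = 0 model, both with a
   half-Student-t(3, 2.5) prior on the dispersion.  Marginal likelihoods
   are computed by deterministic tensor quadrature (no MCMC), so results
   are exactly reproducible; BF10 > 1 favours lateralisation, BF10 < 1
   favours bilaterality.

2. **Is one hemisphere more variable across individuals?**  The variability
   index contrasts robust dispersion between hemispheres:

   VI = (MAD_R − MAD_L) / (MAD_R + MAD_L),

   with MAD the raw median absolute deviation across participants.
   Significance comes from a paired hemisphere-swap permutation test (each
   participant's L/R values swapped with probability ½; two-sided on |VI|),
   Bonferroni-corrected over the 24-test family (7 tracts × 3 metrics + 3
   hemisphere-averaged comparisons; α = 0.0021).

3. **Do lateralisation profiles form discrete phenotypes or a continuum?**
   The participants × 21 LI matrix is embedded in 2-D with UMAP
   (n_neighbors = 15, min_dist = 0.1, Euclidean) and clustering tendency is
   quantified on the original 21-D space via the Hopkins statistic and the
   best k-means silhouette.

A fully controllable synthetic cohort generator (Gaussian copula over
lognormal / logit-normal marginals with calibrated target LI, MAD ratio,
interhemispheric correlation and reconstruction-failure rates) makes every
stage testable without any imaging data.

## Worked example

```python
import latvar

cfg = latvar.reference_scenario()           # 164 participants, realistic regime
table = latvar.generate_cohort(cfg)         # long-format bilateral cohort
li = latvar.assemble_li_matrix(table)       # participants x 21 LI features

res = latvar.bayes_one_sample_li(li[("FAT", "TC")].dropna().to_numpy())
print(f"FAT TC: mean {res.post_mean:.3f} (SD {res.post_sd:.3f}), "
      f"BF10 = {res.bf10:.3g}")

left, right = latvar.paired_values(table, "ILF", "TC")
import numpy as np
vi = latvar.permutation_test_vi(np.column_stack([left, right]),
                                n_perm=100_000, seed=0)
print(f"ILF TC: VI {vi.observation.vi:.2f}, p = {vi.p_value:.5g}")
```

prints (seed 0 scenario):

```
FAT TC: mean -0.576 (SD 0.017), BF10 = 2.76e+68
ILF TC: VI -0.27, p = 5e-05
```

i.e. the frontal aslant streamline count is strongly left-lateralised
(posterior mean LI ≈ −0.58, extreme evidence), and the inferior
longitudinal fasciculus streamline count is more dispersed in the left
hemisphere (VI ≈ −0.27, five of 100 000 hemisphere-swap permutations as
extreme, far below the corrected α = 0.0021).

The same pipeline runs from the shell:

```bash
latvar simulate --seed 0 --out cohort.tsv
latvar report --in cohort.tsv --seed 0 --n-perm 10000 --out report/
```

which writes `li.tsv`, `bayes.tsv`, `vi_results.tsv`, `embedding.tsv`,
`clusterability.json` and a reproducibility manifest.

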