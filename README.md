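# diffconn

Differential co-expression connectivity analysis for small paired
transcriptome studies, with the moderated statistics and exact clinical
tests such studies need.

The motivating setting is a nine-patient trial of autologous
nonmyeloablative hematopoietic stem cell transplantation (AHST) in newly
diagnosed type 1 diabetes: each patient's peripheral blood mononuclear
cells are profiled before treatment and six months after, six patients
become insulin free (IF) and three remain insulin dependent (ID), and the
question is which transcriptional events distinguish the two responses.
At that depth nothing standard works off the shelf — gene-wise variances
are hopeless at n = 3–6, co-expression networks are built from three
profiles, and group comparisons need exact small-sample tests — so the
package provides the complete pipeline:

* **Moderated paired differential expression** (`diffconn.rvm`) — the
  random variance model: gene-wise precisions share a Gamma(a, b) prior
  fitted by maximum marginal likelihood (s²·a·b ~ F(m, 2a)), each gene's
  variance is replaced by its posterior mean
  s̃² = (m·s² + 2/b)/(m + 2a), and the paired t statistic gains m + 2a
  degrees of freedom.  Benjamini–Hochberg FDR across genes; direction
  classes (Up / Down / Other) across the two patient groups.
* **Pathway over-representation** (`diffconn.enrichment`) — one-sided
  Fisher exact (hypergeometric tail) and chi-square with continuity
  correction against a GMT collection, FDR-ranked, top-N reporting.
* **Differential connectivity** (`diffconn.network`) — per condition,
  the unsigned connectivity K_i = Σ_j≠i |r_ij| of the Pearson network
  over a combined differentially-expressed gene set, normalized by the
  network maximum (k_i = K_i / max K).  The rewiring statistic is
  **DiffK = k(post) − k(pre)**; its significance comes from a pre/post
  label-swap permutation null (enumerated exactly when the patient count
  allows), and a gene is a *hub* when |DiffK| > 0.2 and p < 0.05.
  Includes the 6→3 similarity-based sample merging (average-linkage
  pairing on 1 − r), sector classification of the (DiffK, p) plane, and
  node/edge exports for graph viewers.
* **Exact clinical statistics** (`diffconn.clinical`) — tie-aware exact
  two-sided Mann–Whitney U by complete enumeration of group assignments,
  paired t, group summaries, natural-log GADA handling, trapezoidal AUC.
* **A synthetic study generator** (`diffconn.simulate`) — paired two-group
  studies with inverse-gamma gene variances, planted differential
  expression, and planted co-expression modules whose wiring changes
  between timepoints with a known DiffK sign, so every stage has a
  ground-truth recovery test.  A packaged nine-patient clinical table
  makes the published clinical statistics reproducible as printed.

## Worked example

```python
from diffconn import load_table1
from diffconn.clinical import group_compare, insulin_independence_rate, summarize_group
from diffconn.simulate import hub_recovery_spec, simulate_expression
from diffconn.network import hub_table

t1 = load_table1()
r = group_compare(t1, "insulin_12mo")
print(f"12-month insulin dose, IF vs ID: U={r.U:g}, exact two-sided p={r.p:.3f}")
mean, sd, n = summarize_group(t1, "duration")
print(f"diagnosis-to-transplant delay: {mean:.1f} +/- {sd:.1f} months (n={n})")
count, total, pct = insulin_independence_rate(t1)
print(f"insulin independent at 12 months: {count}/{total} ({pct:.0f}%)")

study, truth = simulate_expression(hub_recovery_spec(seed=1))
tab = hub_table(study, study.gene_ids, "IF", n_perm=499, seed=1)
hubs = tab[tab["hub"]]
planted = set(truth.expected_hubs)
print(f"hub genes called: {len(hubs)} (planted module: 15, recovered: {len(planted & set(hubs.index))})")
print(hubs[["k_pre", "k_post", "diffk", "p", "sector"]].head(3).round(3))
```

prints

```
12-month insulin dose, IF vs ID: U=0, exact two-sided p=0.012
diagnosis-to-transplant delay: 2.0 +/- 0.9 months (n=9)
insulin independent at 12 months: 6/9 (67%)
hub genes called: 18 (planted module: 15, recovered: 15)
        k_pre  k_post  diffk      p  sector
G00060  0.961   0.149 -0.812  0.031       3
G00100  0.961   0.150 -0.811  0.031       3
G00114  0.962   0.147 -0.815  0.031       3
```

The six zero 12-month insulin doses against three positive ones admit a
single equally-extreme assignment among C(9,3) = 84, hence p = 0.012 —
the exact tie-aware two-sided value (doubling a one-sided tail would give
0.024).  In the synthetic study, the fifteen genes of a module that
decouples from the co-expression core after treatment lose most of their
normalized connectivity (DiffK ≈ −0.8) and land in sector 3 of the
(DiffK, p) plane: they are hubs whose network role the treatment removed.

A `diffconn` command-line tool exposes the same stages
(`simulate`, `de`, `enrich`, `network`, `clinical`); see `diffconn --help`.

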