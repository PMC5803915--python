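# ratconnectome

Structural and functional brain-network analysis for rodent MRI cohorts:
connectome construction from tractography streamlines and regional BOLD
time series, graph-theory characterization, and two-group statistics with
behavioural correlation screening. A synthetic cohort generator with
planted, recoverable effects makes the whole pipeline testable without any
imaging data.

The package targets studies that compare a transgenic disease model (e.g.
a TgF344-AD Alzheimer's rat line) against wild-type controls: each animal
contributes a diffusion-MRI tractogram, a resting-state fMRI session and
behavioural outcomes (operant training sessions, delayed nonmatch-to-sample
trial counts and accuracy), and the question is whether brain-network
organization differs between groups and tracks cognition.

## The models

**Structural connectome.** Brain regions from an atlas parcellation are
nodes; two regions *I*, *J* are connected if at least one streamline joins
them. Three edge weightings:

- *binary* — 1 if any streamline connects the pair;
- *FA-weighted* — mean fractional anisotropy over the connecting
  streamlines;
- *fiber-density-weighted* —

  FD(I, J) = 1/(V_I · V_J) · Σ_{s ∈ S_IJ} 1/l(s),

  where S_IJ is the set of connecting streamlines, l(s) the streamline
  length (mm) and V_I, V_J the region volumes (mm³).

**Functional connectome.** Regional BOLD series (grey-matter regions only)
are detrended, band-passed (0.01–0.1 Hz), residualised against motion and
WM/CSF nuisance signals, and z-scored. The edge weight is the partial
correlation of each pair conditioned on all other regions — from the
inverse sample correlation matrix P as −P_ij/√(P_ii P_jj) — mapped through
Fisher's z (arctanh). Negative partial correlations are excluded; the
binary variant marks strictly positive edges.

**Graph metrics.** Degree, strength, global efficiency (mean inverse
shortest-path length, edge length 1/w), nodal efficiency (efficiency of
the neighbour subgraph), and clustering coefficient (binary triangle
fraction / Onnela weighted form). Global summaries average the nodal
values.

**Statistics.** Per metric: a Kruskal–Wallis rank test and a Gaussian GLM
`metric ~ group + age` (age at scan is confounded with group in this
design, because the disease model needs longer behavioural training).
Regional p-values are Benjamini–Hochberg FDR-corrected per metric family.
Metrics are screened against behavioural outcomes with Spearman
correlation; |r| > 0.7 is flagged.

## Worked example

```python
import numpy as np
from ratconnectome import (CohortConfig, generate_cohort,
                           build_structural_connectome, summarize,
                           kruskal_wallis)

cfg = CohortConfig(seed=7, n_per_group=9, n_regions_structural=30,
                   n_regions_functional=20, modalities=("structural",))
cohort = generate_cohort(cfg)   # 9 control + 9 transgenic animals

eff = {"control": [], "transgenic": []}
for subj in cohort.subjects:
    conn = build_structural_connectome(
        cohort.streamlines[subj.subject_id], cohort.region_table, "fa_weighted")
    _, glob = summarize(conn)
    eff[subj.group].append(glob.global_efficiency)

h, p = kruskal_wallis(eff["control"], eff["transgenic"])
print(f"FA-w global efficiency: control {np.mean(eff['control']):.4f}, "
      f"transgenic {np.mean(eff['transgenic']):.4f}")
print(f"Kruskal-Wallis H = {h:.3f}, p = {p:.4f}")
```

Output:

```
FA-w global efficiency: control 0.2934, transgenic 0.2500
Kruskal-Wallis H = 12.789, p = 0.0003
```

The generator plants a 15% FA reduction in the transgenic group by
default, so FA-weighted integration is lower in transgenic animals and the
rank test detects it. The same analysis runs end to end from files via the
CLI:

```bash
ratconnectome simulate --out cohort/ --seed 7
ratconnectome run --config pipeline.yaml      # paths + options, see docs
ratconnectome report runs/my_run
```

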