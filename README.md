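# mirtraj

Directional statistics for microRNA expression trajectories after kidney
ischemia-reperfusion injury (IRI).

## The problem

Renal IRI — tissue damage caused by a temporary loss and restoration of
blood flow — alters the expression of microRNAs (miRs) in the kidney. If
those alterations move in a *consistent direction* over the course of
injury, miR expression can serve as a biomarker of renal damage. `mirtraj`
asks exactly that question of a miR microarray time course: does the
post-injury trajectory of expression change point somewhere, or does it
wander like noise?

The package is aimed at analysts working with small, densely sampled bulk
expression time courses (one pooled sample per strain × treatment × day)
who want a defensible significance statement about trajectory
directionality, not just a 3-D plot.

## The method

Given raw intensities $x_{ij}$ (miR $i$, sample $j$) the pipeline:

1. **Filters and normalizes.** Intensities below 200 are below reliable
   detection, so each value is floored at 200; miRs whose mean raw
   intensity stays under 200 are dropped; each retained miR is expressed as
   $w_{ij} = \ln\!\big(\max(x_{ij},200)/\max(x_{i,\mathrm{naive}},200)\big)$,
   the natural-log ratio to the strain's untreated (naive, day-0) kidney.
2. **Projects by PCA.** The time-point vectors $w_j \in \mathbb{R}^m$ are
   decomposed by PCA; the first $k=3$ components typically carry most of
   the variance, so each series becomes a trajectory
   $x_1,\dots,x_n \in \mathbb{R}^3$. A full-dimension mode skips the
   projection and works on $S^{m-1}$ directly.
3. **Maps change to the sphere.** From a chosen center point (day 0 for
   sham arms, day 1 for the wild-type injured arm) each later time point
   defines a unit direction $d_i = (x_i - c)/\lVert x_i - c\rVert$ on
   $S^{d-1}$.
4. **Measures spread.** Two centers are fitted to the direction set: the
   minimal enclosing spherical cap (center $\hat c$ minimizing the maximum
   angle, radius $\hat r$) and the spherical standard deviation (center
   minimizing the root-mean-square angle, SD = that RMS). All angles are in
   degrees.
5. **Assigns P-values by Monte Carlo.** Under the null the trajectory is a
   random walk whose displacements are independent unit vectors uniform on
   the sphere. 10,000 such walks give a null distribution of cap radii; the
   P-value of an observed radius is the fraction of null radii that are
   equal or smaller. Two groups are compared by the **discrimination** —
   angular separation of their SD centers divided by the larger SD — and by
   **proximity** of a test group's center to a fixed reference center, each
   with its own Monte-Carlo null.
6. **Digital knockout.** Setting a chosen miR set's normalized values to 0
   before PCA quantifies that set's contribution to the observed geometry.

A synthetic-data module generates full experiments (571 miRs, wild-type and
two immunodeficient strains, sham/IRI arms) with a known injected injury
direction, so every stage of the pipeline is testable without any download,
including power, type-I error and parameter-recovery studies.

## Worked example

```python
from mirtraj import (SimulationConfig, generate_experiment,
                     AnalysisPlan, GroupSpec, run_analysis)

matrix, sheet, truth = generate_experiment(SimulationConfig(), rng=0)
plan = AnalysisPlan(
    groups=(GroupSpec("C57BL/6", "sham"), GroupSpec("C57BL/6", "IRI")),
    n_reps=10000, seed=0,
)
report = run_analysis(matrix, sheet, plan)
```

which prints (via the summary loop in the module docs):

```
retained miRs: 127 / 571
variance explained: PC1-3 82.4%, PC1-9 98.9%
C57BL/6/sham: 7 directions, cap radius 29.5 deg, spherical SD 21.5 deg, P = 0.2016
C57BL/6/IRI: 6 directions, cap radius 8.4 deg, spherical SD 6.0 deg, P = 0.0001
separation 90.6 deg, discrimination 4.22, P = 0.1148
```

Reading: the mean-intensity filter keeps 127 of 571 simulated miRs; three
principal components carry 82% of the variance. The sham trajectory's seven
directions need a 29.5° cap — a fifth of random walks do as well, so sham
surgery defines no direction ($P = 0.20$). The injured arm's six directions
fit in an 8.4° cap, which almost no random walk achieves ($P = 10^{-4}$):
injury drives expression in a well-defined direction, 90.6° away from the
sham response.

The same analysis runs from the shell:

```bash
mirtraj simulate --seed 0 --out sim/
mirtraj analyze --matrix sim/expression.tsv --samples sim/samples.tsv \
    --plan plan.yaml --reps 10000 --seed 0 --out report.json
```

with `plan.yaml` naming the groups as in the Python plan. `--knockout
mirs.txt` runs a paired digital-knockout comparison, `--subset mirs.txt`
restricts the analysis to a miR subset, and `--full-dim` works on all
retained miRs instead of three PCs.

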