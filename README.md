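# lineagevar

Lineage-resolved statistics of stress-induced phenotypic variability in
bacterial micro-colonies, together with the stochastic positive-feedback
lineage simulator that generates the data they run on.

When a clonal *E. coli* micro-colony meets a sub-inhibitory dose of an
aminoglycoside, genetically identical sister cells diverge: some keep
growing, others induce their heat-shock (RpoH/ibpAB) reporter, arrest and
die — and both the divergence and its timing run in families.  This
package implements the tree statistics used to dissect that behaviour from
time-lapse tracking data:

* **SLCV / IDCV** — the *sub-lineage* coefficient of variation
  `SLCV = √(Σᵢ nᵢ(x̄ᵢ − x̄)²/(N_s − 1)) / x̄` (cells at time *t* grouped by
  their ancestor alive at time *s*) against the *individual*
  `IDCV = sd(x)/x̄`.  SLCV rising above IDCV flags lineage differentiation;
  with *s = t* the two are identical by construction.
* **Pre-disposition node tests** — Welch T-tests between the descendant
  groups of sister cells that divided *before* induction, a 500-fold
  progeny-reassignment null per node, the combinatorial probability
  `C(n,k)·pᵏ` of a tree with *k* significant nodes, and an exact binomial
  test for the direction bias (does the brighter sister found the more
  stressed sub-lineage?).
* **Lineage-switch randomization** — same-generation subtree swaps of
  post-induction cells that preserve IDCV exactly while scrambling
  sub-lineage membership.
* **Epigenetic memory** — the lineage autocorrelation function
  AF(*g*) = corr(ancestor phenotype at *s*, descendant phenotype *g*
  colony generations later), its fitted exponential half-life, and the
  linear birth–dilution prediction `ln2 / (ln2/T_d + d − b)`.
* **Fate calls** — a two-component Gaussian-mixture threshold on the
  bimodal growth-rate distribution, death as prolonged growth arrest, and
  death-commitment times from maximal all-dead subtrees.
* **The simulator** — drug uptake with damage-dependent membrane
  permeability (the positive feedback), growth inhibition by damage,
  binomial molecule partitioning with asymmetric damage segregation,
  growth-arrest death, and an optional passive co-reporter that reads out
  the permeability mechanism.  Unstressed defaults give a one-generation
  expression memory; the calibrated `stressed` preset reproduces the
  stressed phenomenology.  See `docs/methods.md`.

## Worked example

```python
import math, warnings
from lineagevar import (get_params, simulate_tree, first_time_at_size,
                        slcv, idcv, lineage_af, fit_halflife,
                        classify_fate, tree_probability)
from lineagevar.lineage import PhenotypeProvider

tree = simulate_tree(get_params("stressed"), seed=1)
print(f"colony: {tree.n_cells} cells, induction at {tree.induction_time:.0f} min")

t_end = float(tree.frame_times()[-1])
prov = PhenotypeProvider(tree, "fluorescence")
s = first_time_at_size(tree, 8)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    sl = slcv(tree, s, t_end, provider=prov)
    vals = [v for v in prov.values_at(t_end).values() if math.isfinite(v)]
    print(f"SLCV = {sl:.2f} vs IDCV = {idcv(vals):.2f} at t = {t_end:.0f} min")

calls = classify_fate(tree, t_end)
print(f"growth-rate threshold {calls[0].threshold:.4f} min^-1; "
      f"{sum(c.fate == 'dead' for c in calls)}/{len(calls)} cells called dead")

g_ind = tree.colony_stage_generation(tree.induction_time)
s_af = next(t for t in tree.frame_times()
            if t >= tree.induction_time
            and tree.colony_stage_generation(t) >= g_ind + 4)
af = lineage_af(tree, s_af, provider=prov)
print(f"stressed memory half-life: {fit_halflife(af):.1f} generations")
print(f"chance probability of 12/15 significant nodes: "
      f"{tree_probability(15, 12, 0.02):.2g}")
```

prints

```
colony: 1213 cells, induction at 74 min
SLCV = 0.84 vs IDCV = 0.67 at t = 254 min
growth-rate threshold 0.0235 min^-1; 35/607 cells called dead
stressed memory half-life: 4.3 generations
chance probability of 12/15 significant nodes: 1.9e-18
```

The sub-lineage CV exceeds the individual CV (differentiation among the
8-cell-stage families), the growth-rate mixture separates a dead
sub-population, expression memory measured from a late post-induction
start stretches over several generations (versus one generation without
stress), and a tree with 12 of 15 pre-induction nodes significant is
essentially impossible under the ~2% per-node false-positive rate.

## Command line

```
lineagevar simulate --preset stressed --seed 1 --n-trees 4 --out runs/stressed
lineagevar variation --input runs/stressed/tree_001.tsv ... --out runs/var
lineagevar memory    --input runs/stressed/tree_001.tsv --start-size 16 --out runs/mem
lineagevar predisposition --input runs/stressed/tree_001.tsv --seed 1 --out runs/pre
lineagevar randomize --input runs/stressed/tree_001.tsv --seed 1 --out runs/rand
```

Outputs are tidy TSVs plus a `run_log.yaml`; identical seeds give
byte-identical data files.

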