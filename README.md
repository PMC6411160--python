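# emspart

Community-assembly inference for multi-year site-by-species survey
data: **Elements of Metacommunity Structure** (EMS) pattern analysis
with null models, and **variation partitioning** of community
composition into environmental, spatial and temporal fractions by
partial redundancy analysis — together with a ground-truthed synthetic
metacommunity generator that makes every stage verifiable without
field data.

The package is written for community ecologists working with repeated
point-count or plot surveys (the motivating system is a farmland bird
metacommunity: 260 stations surveyed twice a year over five years,
with land-use composition measured in buffers of 200–1400 m around
each station), but every stage operates on plain site-by-species
tables and applies to any metacommunity survey of similar shape.

## The two analyses

**EMS pattern analysis.** The incidence matrix is ordinated by
correspondence analysis (reciprocal averaging) and three indices are
computed on the ordered matrix:

- *Coherence*: the number of embedded absences **Abs** (gaps strictly
  inside a species' range along the site ordering). Fewer gaps than
  expected under the null means species respond to a shared latent
  gradient; more gaps indicate a checkerboard of mutual exclusions.
- *Species turnover*: the number of replacements **Re**, counted over
  every pair of sites and pair of species on the range-filled matrix.
  Fewer replacements than expected indicates nestedness.
- *Boundary clumping*: Morisita's index **M** of the dispersion of
  range boundaries over sites, with a chi-square test. M > 1 means
  groups of species share range limits (Clementsian), M ≈ 1
  individualistic ranges (Gleasonian), M < 1 evenly spaced ranges.

Coherence and turnover are judged against a Monte-Carlo null in which
every site keeps its observed richness while species are drawn without
replacement with probability proportional to their occurrence
frequency (200 iterations by default); each null replicate is
re-ordinated before the indices are recomputed. The decision tree over
the three tests yields the structure label (checkerboard / random /
nested / Clementsian / Gleasonian / evenly spaced, with `quasi_`
variants when turnover evidence is sub-threshold).

**Variation partitioning.** Abundances are Hellinger-transformed
(y′ᵢⱼ = √(yᵢⱼ/yᵢ₊)) and regressed on three predictor blocks by
multivariate least squares (RDA): environment **E** (per-grain
land-use means and coefficients of variation), space **S** (the nine
monomials x, y, x², y², xy, x³, y³, x²y, xy² of a third-degree trend
surface of centred coordinates, or classic PCNM eigenvectors), and
time **T** (centred year/session dummies). Each block is reduced by
forward selection with the double stopping rule (candidate permutation
p ≤ α and the adjusted-R² cap of the full model). Explained variance
uses Ezekiel's adjustment, R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1),
and the seven-model inclusion–exclusion system yields the pure and
shared fractions (they sum to 1 exactly; negative fractions are
reported as computed). Per-variable contributions are marginal
partial-RDA F-ratios, reported as shares Fᵢ/ΣF.

**Deconstruction.** Species are clustered (complete-linkage on axis-1
ordination scores, cut at k = 3: open-land / intermediate / woodland)
and sites are binned by tree-cover fraction in a 200 m buffer
(0–35 / 35–70 / 70–100%); both analyses are re-run inside every class
and at every grain.

## Worked example

```python
from emspart import *

cfg = SyntheticConfig(n_sites=120, n_species=30,
                      structure="clementsian", seed=11)
ds = simulate_dataset(cfg)                      # coords, env, surveys, truth
inc = to_incidence(pool_surveys(ds.surveys))    # station x species incidence
ords = correspondence_analysis(inc, n_axes=2, anchor=inc.richness())
res = ems_analysis(inc, axis=1, spec=NullModelSpec(iterations=200, seed=11))

rcfg = RunConfig(grains=(200, 1400), null_iterations=200,
                 n_perm=199, deconstruction=False, seed=11)
rep = run_full_analysis(ds, rcfg)

print(f"axis 1 inertia: {100*ords.inertia_fraction[0]:.1f}%")
print(f"structure: {res.label}")
print(f"coherence: Abs={res.Abs} (null {res.MA:.0f} +/- {res.SA:.0f}), "
      f"z={res.z_coherence:.1f}, p={res.Apr:.2g}")
print(f"turnover:  Re={res.Re} (null {res.MR:.0f} +/- {res.SR:.0f}), "
      f"z={res.z_turnover:.1f}, p={res.Rpr:.2g}")
print(f"clumping:  M={res.M:.2f}, p={res.Mpr:.2g}")
for u in rep["varpart"]["global"]:
    f = u["fractions"]
    print(f"grain {u['grain']:>4} m: explained {100*u['total_explained']:.1f}% "
          f"(pure env {100*f['pure_env']:.1f}%, pure space "
          f"{100*f['pure_space']:.1f}%, pure time {100*f['pure_time']:.1f}%)")
```

prints:

```
axis 1 inertia: 46.6%
structure: clementsian
coherence: Abs=51 (null 2145 +/- 34), z=-61.0, p=0
turnover:  Re=461257 (null 18571 +/- 4702), z=94.1, p=0
clumping:  M=16.00, p=0
grain  200 m: explained 34.0% (pure env 24.0%, pure space 2.7%, pure time 0.0%)
grain 1400 m: explained 28.6% (pure env 18.7%, pure space 5.0%, pure time -0.0%)
```

Reading this: the simulated community is strongly coherent (far fewer
embedded absences than the null, z = −61), with high positive turnover
and strongly clumped range boundaries — a Clementsian gradient, which
is exactly what the generator planted. The partition attributes most
explained compositional variance to the environment block, with the
environmental contribution shrinking as the measurement grain coarsens
from 200 m to 1400 m.

The same chain is available from the shell:

```bash
emspart simulate --structure clementsian --n-sites 260 --n-species 40 --seed 1 --out sim/
emspart ems sim/surveys.csv --iterations 200 --seed 1
emspart pipeline --structure clementsian --grains 200,800,1400 --seed 1 --out run/
```

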