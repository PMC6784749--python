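# crtplan

Sample-size planning for cluster-randomized trials (CRTs) with
incidence-rate outcomes, aimed at hospital epidemiology and antimicrobial
stewardship: trials that randomize ICUs, wards or whole hospitals and count
rare events — MRSA bacteremia, catheter-associated UTIs, central-line
bloodstream infections, *C. difficile* infections, MRSA/VRE acquisition —
against person-time denominators.

Because patients within a unit are correlated, the number of *clusters*
drives power. `crtplan` covers the full design loop:

1. **Estimate** the between-cluster coefficient of variation (CV) of true
   daily rates from a per-cluster count table, using the excess-variance
   moment method (observed variance of cluster rates minus the expected
   Poisson sampling floor, truncated at zero), with a cluster-bootstrap
   standard error.
2. **Size** a two-arm parallel CRT with the Hayes–Bennett incidence
   formula: for control/experimental daily rates λ₁, λ₂, person-time
   y = m·t per cluster and CV k,

       c = 1 + (z₁₋α/2 + z_power)² · [ (λ₁+λ₂)/y + k²(λ₁²+λ₂²) ] / (λ₁−λ₂)²

   with algebraic inversion to power and sensitivity grids over effect
   size, CV and power.
3. **Validate** computed sizes by Monte-Carlo simulation on synthetic
   gamma–Poisson hospital data (cluster-summary t test), and check
   estimator recovery on data with known truth.

Packaged parameter sets for six outcomes (2016 US Hospital Compare
facility data and the BUGG ICU study baseline) let you reproduce published
cluster requirements or use realistic rates and CVs as starting points for
your own design.

## Worked example

```python
from crtplan import clusters_required, load_paper_fixture

spec = load_paper_fixture("cdi").design_spec(effect_size=0.30)
res = clusters_required(spec)
print(res.clusters_unrounded, res.total_clusters, res.n_intervention, res.n_control)
```

prints

```
31.465956139606035 31 16 15
```

Reading: to detect a 30% reduction in the daily *C. difficile* infection
rate (control rate 0.000616 per patient-day, mean cluster size 124.2
patient-days/day, CV 0.44, α = 0.05 two-sided, power 0.80, 1-year
follow-up), the formula value is c ≈ 31.5; under the reporting convention
this is 31 clusters total, 16 intervention / 15 control. The raw
Hayes–Bennett reading of c is per arm — see `docs/methods.md` for the two
conventions and `examples/04_validate_power.py`, which confirms by
simulation that 32 clusters per arm deliver ≈ 0.83 empirical power.

More narrative walkthroughs live in `examples/` (one script per
capability: sizing, CV estimation, sensitivity grids, power validation,
reproduction of published totals). A thin CLI mirrors the library:

```bash
crtplan size --rate-control 0.000616 --effect 0.30 --cluster-size 124.2 \
             --followup-days 365 --cv 0.44
crtplan grid --outcome mrsa_bacteremia
crtplan reproduce
```

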