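# evtsar

Nested species–area relationships (SARs) through extreme value theory.

## The problem

Counting species in circles of increasing area around a fixed focal point
produces the *nested* SAR. On log–log axes it is triphasic: counts rise
steeply at small areas (Phase I), follow a shallow power law `S ∝ A^z` at
intermediate areas (Phase II), and steepen again towards slope 1 at the
largest areas (Phase III). `evtsar` models this curve with order statistics:
a species enters the SAR at the area of the circle through its *nearest*
individual, so each species' contribution is governed by the distribution of
the minimum of its individual-to-focal-point distances.

For a species whose `n` individuals have distance cdf `F(r)`, the minimum
distance has cdf

    L(r) = 1 − (1 − F(r))^n,            A = πr²,

and the expected SAR is the equally weighted mixture over the `S_T` species
of the community,

    S_M(A) = (1/S_T) Σ_i L_i(A).

When individuals cluster around a range centre as an isotropic bivariate
normal with scale `σ_p`, `F` is a Rice distribution with location `υ_p` (the
centre's distance to the focal point); `υ_p = 0` reduces it to a Rayleigh
law. For large `n`, `L` approaches a generalised extreme value (GEV)
distribution for minima with location `μ`, scale `σ` and shape `ξ`: ranges
covering the focal point (`υ_p/σ_p < 2`) give Weibull-type minima
(`ξ ≈ −0.5`) and drive Phase I; far ranges (`υ_p/σ_p > 4`) give Gumbel-like
minima (`ξ ≲ 0`) and drive Phase III; the band in between produces the
Phase II power law. For range centres distributed uniformly over a region of
area `A_T`, the species counts at the phase transitions have the closed form

    S_P = S_T · π (k σ_p)² / A_T,       k = 2 (I–II), k = 4 (II–III),

with a general double-integral version for arbitrary centre densities and
range-width laws. The same machinery applies to empirical occurrence tables
(`species, x, y` in an equidistant projection): random focal points, the
nearest record per species, rank-based mean/median SARs, and empirical
transition counts from per-species "centres of gravity" and distance spreads.

## Worked example

```python
import numpy as np
import evtsar as e

# a community of 5000 species, unit range scale, centres uniform in a disc
cfg = e.CommunityConfig(n_species=5000, n_individuals=1000,
                        sigma_kernel=1.0, region_radius=20.0, seed=1)
community = e.generate_community(cfg)

# one realised SAR: per-species minimum distance of 1000 individuals
curve = e.simulate_sar_realisation(community, n=1000, seed=2)

# predicted transition counts for uniform centres
pred = e.predict_transitions(sigma_p=1.0, A_T=np.pi * 20.0**2, S_T=5000)
print(pred.count_I_II, pred.count_II_III)        # 50 200

# log-log slopes of the three phases
f1, f2, f3 = e.phase_slopes(curve, pred.count_I_II, pred.count_II_III)
print(round(f1.slope, 2), round(f2.slope, 2), round(f3.slope, 2))
# 0.69 0.27 0.65
```

The transition counts say that after about 50 species the curve leaves the
steep near-focal regime and after about 200 it enters the far-range regime.
The fitted slopes show the triphasic signature: the intermediate window is a
shallow power law (`z ≈ 0.3`, here 0.27) while both outer windows are
steeper; Phase III's slope keeps rising towards 1 on larger regions (at this
small region radius the curve saturates before getting there).

A command-line surface wraps the same operations
(`evtsar simulate | fit-gev | sar | mixture | transitions | empirical |
fixture`); every run writes CSV outputs plus a JSON manifest with the seed
and configuration, so outputs can be regenerated from the manifest alone.

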