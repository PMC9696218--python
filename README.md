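# dnabuckle

Predict and fit the persistence length of double-stranded DNA from an
Euler-buckling model of an end-constrained fragment.

## The problem

The persistence length l_p of dsDNA (~50 nm at standard conditions) is never
measured directly: it is extracted from raw observables through a model, and
different experimental techniques — bulk scattering and birefringence,
optical tweezers, tethered-particle motion, microscopy of adsorbed molecules
— report systematically different values under identical ionic conditions.
A large part of that divergence comes from the *mechanical constraints* the
technique imposes on the molecule's ends.

`dnabuckle` implements a quantitative model of this effect.  A bent fragment
of length l_cb, isolated from a longer chain, is treated as an axially
loaded elastic column.  The compressive load is the sum of two statistical
forces:

- the electrostatic support reaction of the charged backbone in Manning's
  counterion-condensation form,

      F_ele = (k_B T / Z² l_B) [ (2Zξ − 1) κb e^(−κb) / (1 − e^(−κb))
                                 − 1 − ln(1 − e^(−κb)) ],

  with Bjerrum length l_B, Debye screening κ = 1/λ_D, charge spacing b and
  condensation parameter ξ = l_B/b;

- a thermal-fluctuation reaction F_tf = √(EA k_B T / l_cb), with the stretch
  modulus eliminated through the wormlike-chain identity EI = k_B T l_p.

Setting F_ele + F_tf equal to the Euler critical load π²EI/(μ l_cb)² of the
column — where μ is the *effective length factor* encoding the end
constraints (hinge-hinge 1.0, clamp-hinge ≈ 0.7, clamp-clamp 0.5) — and
solving for l_p gives an explicit three-term map (f = F_ele/k_B T):

    l_p = (1/π⁴R²) [ 2μ⁴l_cb³                                (TODC)
                     + 2μ³l_cb^{5/2} √(μ²l_cb + π²R²f)       (TWDE)
                     + π²μ²R²l_cb² f ]                       (TSDE)

a superposition of a constraint-only term, a weakly environment-dependent
square-root coupling term, and a strongly environment-dependent linear term.
Fitting (μ, l_cb) to measured l_p-vs-salt curves identifies the effective
end constraint of each experimental technique.

## What the package provides

- `media_forces` — constants, dielectric law ε_r(T), Bjerrum/Debye lengths,
  both force laws.
- `buckling` — effective length factors, including μ from rotational/lateral
  end-spring stiffnesses via the column characteristic equation.
- `persistence_map` — the bidirectional l_p ↔ l_cb map, its TODC/TWDE/TSDE
  decomposition, and uncertainty bands from the spread of μ.
- `fitting` — bounded multi-start least-squares fitting of (μ, l_cb) to
  (c, l_p) datasets, r², and per-class aggregation.
- `temperature` — the empirical cyclization law l_p(T), its inversion to a
  linear l_cb(T), and gradient transfer across constraint classes.
- `wlc_ensemble` — wormlike-chain end-to-end statistics: estimate l_p from
  conformation ensembles, and a seeded discrete-WLC sampler.
- `fixtures`, `synthetic`, `io`, `cli` — reference fitted-parameter tables,
  synthetic dataset generation, plain-text file formats, and the
  `dnabuckle` command-line tool.

## Worked example

Class-mean parameters for DNA suspended in bulk solution are μ = 1.021,
l_cb = 5.95 nm; for the fix-bead constraint (optical tweezers / tethered
particle) μ = 0.718, l_cb = 8.43 nm.  At 0.1 M monovalent salt, 298 K:

```python
>>> from dnabuckle import BucklingModel, EndConstraint, Medium, \
...     persistence_from_buckling, decompose
>>> med = Medium(c=0.1, Z=1, T=298.0)
>>> sus = BucklingModel(EndConstraint(1.021), 5.95e-9)
>>> round(persistence_from_buckling(sus, med) * 1e9, 2)
68.1
>>> d = decompose(sus, med)
>>> [round(x * 1e9, 1) for x in (d.todc, d.twde, d.tsde)]
[4.7, 20.6, 42.8]
```

The suspended-class prediction is 68.1 nm, inside the 40–80 nm band the bulk
experiments report at this salt, and the strongly environment-dependent term
(42.8 nm) dominates.  The fix-bead class gives 62.74 nm — stronger end
constraints (smaller μ) make the apparent persistence length smaller at
every salt concentration.  The same numbers from the shell:

    $ dnabuckle predict --mu 1.021 --lcb-nm 5.95 --n-points 5
    concentration_M lp_nm     lp_low_nm  lp_high_nm
    0.001           86.1569   86.1569    86.1569
    0.00795271      78.5893   78.5893    78.5893
    0.0632456       70.1818   70.1818    70.1818
    0.502973        59.5994   59.5994    59.5994
    4               43.8067   43.8067    43.8067

    $ dnabuckle stats --constraint-class fix_bead
    constraint_class = fix_bead
    n = 5
    mu_mean = 0.718
    mu_sd = 0.075
    lcb_mean_nm = 8.43
    lcb_sd_nm = 1.25

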