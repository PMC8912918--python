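# poremap

Where — and how fast — do electric-field-driven pores form in plasma
membranes with realistic, heterogeneous lipid composition?

Coarse-grained molecular dynamics studies of membrane electroporation show
that pores do not nucleate uniformly: they colocalize with nanodomains
enriched in polyunsaturated (PU) lipids and avoid regions rich in
cholesterol, gangliosides, and fully saturated lipids, while the poration
*kinetics* depends on membrane composition and on the polarity of the
applied field. `poremap` implements the full desk-scale analysis chain
behind that kind of study, for people analysing coarse-grained membrane
trajectories (or testing such analyses without access to large MD data):

1. **Pore localization** — a two-stage search for the first persistent
   transmembrane water column: a coarse scan over a 10 × 10 partition of the
   membrane plane (strictly more than 12 midplane water beads flags a fully
   formed pore), then a frame-by-frame backtrack with a persistence check,
   reporting the poration time and the pore's box-relative coordinates.
2. **Local membrane features** — 21 per-location features (area per lipid
   from periodic Voronoi tessellation, thickness, mean curvature, headgroup
   dipole cosine, headgroup charge, tail order
   P2 = (3 ⟨cos θ⟩² − 1)/2, and 15 lipid-group densities) read out
   through a truncated Gaussian kernel
   V(x_p) = Σᵢ Vᵢ wᵢ / Σᵢ wᵢ with wᵢ = exp(−|xᵢ−x_p|²/2r²), r = 1.5 nm.
3. **Feature ranking** — the signed symmetrized Kullback–Leibler distance
   ±½∫[p log(p/q) + q log(q/p)]dx between kernel-density estimates of each
   feature in porated vs non-porated locations.
4. **Poration-site classification** — SMOTE-balanced random forest / SVM /
   multilayer perceptron with leakage-controlled split schemes, feature
   importances, a four-feature (PU, GM, CHOL, FS) reduced model, and the
   >90%-of-frames per-location porated call.
5. **Poration kinetics** — a Bayesian piecewise-exponential proportional
   hazards model λᵢ(t) = λ₀(t)·exp(βᵢ) with 1.5-ns baseline intervals,
   MCMC posterior, 94% credible intervals, posterior predictive checks, the
   rate-law interpretation (βᵢ − βⱼ ≈ −(δᵢ − δⱼ)/kT for comparable
   prefactors), and the E²-proportional Maxwell-stress response fits.
6. **Synthetic membranes** — a generator producing two-leaflet bilayers with
   spatially correlated, leaflet-asymmetric composition over the standard
   lipid groups, disorder-coupled tail chains, water slabs, plantable pores,
   and first-poration event tables drawn exactly from a piecewise hazard —
   so every stage above is testable end-to-end.

## Worked example

```python
import numpy as np
import poremap
from poremap.events import events_to_frame
from poremap import porefind, survival

# 1. a synthetic average-plasma-membrane patch with PU-rich nanodomains
cfg = poremap.SyntheticConfig(n_lipids_per_leaflet=1500, box_xy=30.0, seed=0)
fields = poremap.gen_composition_fields(cfg)

# 2. first-poration times from a two-regime hazard, pores placed by PU density
hazard = poremap.HazardSpec(
    interval_endpoints=[0.0, 3.0, 15.0], baseline_rates=[0.0, 0.25],
    betas={"APM-dep": 0.0, "APM-hyp": 1.1}, censor_time=20.0)
events = events_to_frame(poremap.sample_poration_dataset(
    hazard, 60, pu_field=fields.pu_field(smooth_nm=1.5), coupling=3.0, seed=0))
print(events.groupby("system")["t_ns"].describe()[["count", "mean"]].round(2))

# 3. re-detect a planted pore with the two-stage water-column search
traj = poremap.gen_trajectory(cfg, 32, fields=fields, seed=0)
planted = poremap.plant_pore(traj, (10.4, 4.6), n_waters=15, start_frame=20)
found = porefind.locate_first_pore(planted)
print(f"pore at t = {found.t_ns:.1f} ns, "
      f"({found.x_rel*30:.2f}, {found.y_rel*30:.2f}) nm")

# 4. Bayesian piecewise-hazard fit and the hyperpolarized/depolarized ratio
spec = survival.HazardModelSpec(width=1.5, systems=["APM-dep", "APM-hyp"])
post = survival.fit_hazard(events, spec, seed=0)
rr = survival.rate_ratio(post, "APM-hyp", "APM-dep")
print(f"rate ratio hyp/dep: {rr['median']:.2f} "
      f"(94% CI {rr['interval'][0]:.2f}-{rr['interval'][1]:.2f}), "
      f"R-hat {post.rhat['max']:.3f}")
```

prints

```
         count  mean
system
APM-dep   60.0  6.92
APM-hyp   60.0  4.47
pore at t = 2.0 ns, (10.47, 4.60) nm
rate ratio hyp/dep: 2.54 (94% CI 1.72-3.68), R-hat 1.007
```

The depolarized system porates with mean first-poration time 6.9 ns versus
4.5 ns under hyperpolarization; the planted 15-water column is re-detected
at its onset frame (2.0 ns) within 0.1 nm of where it was planted; and the
posterior rate ratio brackets the generating value exp(1.1) ≈ 3.0 inside its
94% credible interval.

The same stages are available from the shell:

```sh
poremap run-all --seed 1 --out results/
poremap classify --features results/features.csv \
    --scheme pairwise-membranes --four-features --out ml.json
poremap survival --events results/events.csv --width 1.5 --out results/
```

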