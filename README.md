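# lobulesim

Agent-based simulation of toxin-induced liver fibrosis on a 2-D lobule
lattice.

Repeated injury by a metabolically activated hepatotoxin (CCl₄) kills
hepatocytes around the central vein; Kupffer cells that phagocytose the
dead cells polarise M1 → M2, secreting first TNF-α and then TGF-β; TNF-α
transforms hepatic stellate cells (HSC) into myofibroblasts; and
myofibroblasts and portal fibroblasts lay down collagen wherever TGF-β
exceeds a threshold and free space exists. Collagen deposits are tagged
by their cellular origin, so pericentral (myofibroblast-derived) and
periportal (portal-fibroblast-derived) scarring can be followed
separately. The package is for systems-biology work on fibrosis
dynamics: exploring how dosing schedules and resident-cell ratios shape
the onset and progression of scarring.

## Model

* **Lattice.** A `height × width` grid (default 101 × 101) with a 3 × 3
  central-vein block and four 3 × 3 portal tracts at the lobule
  vertices. Hepatocytes, dead cells, collagen and vascular structures
  occupy space exclusively (one per site); Kupffer cells, HSCs,
  myofibroblasts and portal fibroblasts share sites freely. Zonation
  weight `w(d) = exp(−d/λ)` (distance *d* to the nearest vein site)
  makes pericentral hepatocytes more susceptible to the toxin.
* **Mediators.** Four concentration fields — CCl₄, HMGB1, TNF-α, TGF-β —
  each diffusing by the discrete share-with-8-neighbours scheme (a site
  keeps `1−p` of its value and sends `p/8` to each Moore neighbour) and
  decaying first-order per step.
* **Rules per step.** Toxin injection → hepatocyte death checks
  (necrosis by `w·CCl₄ > θ_ccl4`, else apoptosis by `TNF-α > θ_tnf`) →
  HMGB1 release by necrotic cells only → Kupffer
  move/phagocytose/activate/secrete → HSC → myofibroblast activation →
  collagen secretion → hepatocyte proliferation into blank sites →
  ageing/culling → field diffusion and decay.

All rates and thresholds live in one calibration table
(`lobulesim.calibration`) and every parameter can be overridden through
`default_config(...)` or a YAML config.

## Worked example

```python
import lobulesim as ls
from lobulesim import metrics

run = ls.run(ls.default_config(seed=1))          # 120 steps, toxin every 10
tc = run.timecourse

print("TNF-alpha peak step:", metrics.peak_step(tc["tnfa_total"]))
print("pericentral collagen onset:", metrics.onset_step(tc["collagen_mfb"]))
print("portal collagen onset:", metrics.onset_step(tc["collagen_pf"]))
print("collagen at step 120:", int(tc["collagen_total"].iloc[-1]))
```

prints (seed 1):

```
TNF-alpha peak step: 17
pericentral collagen onset: 22
portal collagen onset: 37
collagen at step 120: 93
```

The TNF-α peak marks the inflammatory burst that follows the second and
third injections (ensemble means sit near step 25; individual seeds
resolve to one of the two injection bursts); collagen of myofibroblast
origin appears pericentrally shortly after, and portal-fibroblast
collagen follows once TGF-β reaches the portal tracts (ensemble mean
near step 40). With the dose set to zero every one of these quantities
stays at zero — fibrosis in the model is strictly injury-driven.

### Command line

```bash
lobulesim simulate --seed 1 --out out/run1 --snapshots 0,40,100
lobulesim exp intervals --seeds 1,2,3,4,5 --out out/intervals
lobulesim exp injections --seeds 1,2,3,4,5 --out out/inj
lobulesim exp kc-sweep --out out/kc
lobulesim exp hsc-sweep --out out/hsc
```

`simulate` writes the per-step time-course CSV, PNG snapshots
(hepatocytes brown, dead cells grey, myofibroblast collagen blue, portal
collagen green) and a JSON manifest that reproduces the run exactly;
the `exp` subcommands run the packaged sensitivity studies (injection
interval, injection count, initial Kupffer ratio, initial stellate
ratio).

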