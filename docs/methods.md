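# Methods

## Model overview

`lobulesim` simulates toxin-induced fibrosis in a two-dimensional section
of a liver lobule as a stochastic agent-based model on a square lattice.
Two layers coexist:

* an **occupancy layer** of space-occupying agents — hepatocytes, dead
  cells (necrotic or apoptotic), collagen deposits (tagged myofibroblast-
  or portal-fibroblast-derived), and the vascular structures (central
  vein, portal tracts, optional septa) — at most one per site;
* a **free layer** of non-occupying cells — Kupffer cells, hepatic
  stellate cells (HSC), myofibroblasts and portal fibroblasts — any
  number of which may share a site with each other and with the
  occupancy layer.

Four diffusible mediators (CCl₄, HMGB1, TNF-α, TGF-β) live on matching
concentration lattices. Diffusion is the discrete share-with-neighbours
scheme: per step each site keeps `1 − p` of its value and sends `p/8` to
each of its eight Moore-neighbour slots; slots falling outside the
lattice are lost (absorbing boundary, so total mass is non-increasing;
a periodic-boundary mode used in tests conserves mass exactly). Decay is
first-order. Both operations are synchronous and linear, and are checked
in the test suite against a naive double-loop implementation.

### Rule order within one step

1. toxin injection, if scheduled: one dose distributed over the lattice
   proportionally to the zonation weight and normalised to the total
   dose;
2. hepatocyte death checks against the phase-start fields: necrosis if
   zonation-weighted CCl₄ exceeds `theta_ccl4` (the toxin acts through
   its metabolically activated form, concentrated pericentrally),
   otherwise apoptosis if TNF-α exceeds `theta_tnf_death`; the toxin
   test takes precedence;
3. HMGB1 release by necrotic dead cells only — apoptotic cells release
   none, making HMGB1 a damage signal specific to toxic injury;
4. Kupffer replenishment at the portal tracts, then every Kupffer cell
   (random order): one undirected Moore move; phagocytosis of a
   co-located dead cell (freeing the site, and activating a quiescent
   cell to M1); quiescent cells also activate when local HMGB1 exceeds
   `theta_hmgb1`; M1 cells secrete TNF-α and switch to M2 after
   `tau_m1m2` steps; M2 cells secrete TGF-β;
5. each HSC transforms in place into a myofibroblast when local TNF-α
   exceeds `theta_tnf_hsc` (a deliberate model simplification treating
   TNF-α as the single activating signal);
6. each myofibroblast/portal fibroblast (random order) places one
   origin-tagged collagen deposit in the nearest vacant site (own site,
   else random vacant orthogonal, else diagonal neighbour) when local
   TGF-β exceeds `theta_tgf`; a myofibroblast dies after
   `max_collagen_per_mfb` deposits; portal fibroblasts persist;
7. hepatocytes adjacent to blank sites divide into a uniformly chosen
   vacant neighbour (random order), unless the parent is within its
   replication cooldown or the neighbourhood holds at least
   `collagen_rich_threshold` collagen deposits — scar suppresses
   regeneration;
8. ageing and lifespan culling (space-occupiers leave blanks; collagen
   is permanent — no regression/healing is modelled);
9. diffusion then decay of all four fields.

Within each phase, threshold decisions read a snapshot of the field taken
at the start of that phase, so outcomes do not depend on agent scan
order; the scan order itself is reshuffled from the run RNG every step.
A run is a pure function of (config, seed): identical inputs give
bit-identical time courses.

## Geometry and initial state

Default lattice 101 × 101 with a 3 × 3 central-vein block in the middle
and four 3 × 3 portal tracts at the vertices of a compact lobule unit,
inset 42 % from the lattice edges (≈ 11 cells from the vein). The inset
is a deliberate choice: all transport in the model (3 × 3 diffusion
stencil, one-cell Kupffer moves) propagates at most ~1–2 cells per step,
so portal-side events on the canonical fibrosis timeline require portal
structures within a few tens of cells of the injury focus. Placing the
tracts at the far corners of the grid (available via `portal_inset=0`)
puts them beyond the reach of any signal within the simulated horizon.
The area beyond the portal ring represents surrounding parenchyma.

The occupancy layer starts confluent (hepatocytes on every
non-structural site). Kupffer cells and HSCs are scattered uniformly at
15 % and 5 % of all lattice sites — the textbook resident-cell ratios —
and one portal fibroblast sits on each portal site and each of its
neighbours. Hepatocytes have a 200-step lifespan with uniformly
randomised initial ages, giving stationary background turnover (~0.5 %
of cells per step); this turnover supplies the sparse vacancies that
portal collagen later occupies. Zonation weight is `exp(−d/λ)` with
λ = width/4.

## Calibrated timeline (defaults)

The dose (4000 units per injection, every 10 steps to step 120) and the
toxin kinetics (share 0.30, decay 0.10/step) are set so that the
zonation-weighted toxin crosses the necrosis threshold only through
accumulation: nothing dies after the first injection, a small
pericentral ring (~30 cells) dies after the second, a roughly
twice-larger region after the third and subsequent ones. The necrosis
threshold 1.60 sits 0.5 % above the deterministic ceiling of the
18-step-interval schedule, which therefore never produces any death or
collagen, while the 14-step schedule crosses late and weakly — endpoint
collagen decreases monotonically in the injection interval.

Kupffer cells activated by the bursts drive a total-TNF-α peak near step
25 (ensemble mean; individual seeds resolve to the second- or
third-injection burst, and occasional seeds peak later when a late
activation flare outweighs the early bursts — the peak step is an argmax
of a noisy series and is the least stable of the reported statistics).
M2 conversion after 7 steps hands the signal to TGF-β, whose slow field
(decay 0.03) reaches the portal tracts around step 40. Myofibroblast
collagen thus starts pericentrally near step 22–25 and portal-fibroblast
collagen near step 40. Scarring feeds back: any adjacent deposit blocks
hepatocyte replication (`collagen_rich_threshold=1`), so the pericentral
kill zone progressively stops refilling and the dead-cell bursts shrink
after the initial peak.

With only two injections, every dead cell is phagocytosed or cleared (12
step dead-cell lifespan) by about step 21 and inflammation never becomes
self-sustaining; with three, the large step-20 burst produces the
characteristic dead-cell surge at step 21 and measurably more collagen
by step 100.

## Parameters

All defaults live in `lobulesim/calibration.py` (arbitrary concentration
units; time in steps). The ones that matter most:

| parameter | default | meaning |
|---|---|---|
| `dose`, `interval` | 4000, 10 | toxin mass per injection, steps between |
| `theta_ccl4` | 1.60 | necrosis threshold on zonation-weighted toxin |
| `theta_tnf_death` | 2.20 | apoptosis threshold (above typical peak fields: toxic, not inflammatory, death dominates the default run) |
| `theta_tnf_hsc` | 0.15 | stellate activation threshold |
| `theta_tgf` | 0.70 | collagen-secretion threshold |
| `theta_hmgb1` | 12.0 | Kupffer activation by the DAMP depot; reached only under deficient clearance (e.g. very low Kupffer ratios) |
| `tau_m1m2` | 7 | M1 residence time |
| `max_collagen_per_mfb` | 8 | deposits before a myofibroblast dies |
| `replication_cooldown` | 15 | steps between hepatocyte divisions |
| `dead_cell_lifespan` | 12 | steps before an uncleared dead cell resolves |
| `hepatocyte_lifespan` | 200 | background turnover time |

## What the simulations do and do not show

The generator-free design means every experiment is synthetic: the model
emulates the *logic* of toxic liver injury — pericentral zonation,
DAMP-gated macrophage activation, M1/M2 cytokine sequence, origin-tagged
collagen — with all quantities in arbitrary units and one step an
unspecified interval of real time. It does not emulate vascular flow,
cholestatic injury, fibrosis regression, bone-marrow-derived
myofibroblasts, or receptor-level kinetics, and the textbook ratios and
calibrated thresholds stand in for biology that is not quantitatively
known. Passing tests therefore demonstrate internal consistency of the
rule set and reproducibility of the calibrated timeline, not predictions
about tissue.

Known limitations found during calibration, documented as model
behaviour:

* The first Kupffer activation necessarily follows the first dead cell
  by only a step or two (15 % Kupffer density makes early phagocytosis
  almost certain), so activated cells appear in the ensemble around step
  11, immediately after the second injection's necrosis ring.
* The step of maximal total TNF-α has high seed-to-seed variance (see
  above); ensemble means over ≥ 10 seeds are reported for it.
* Endpoint blank area is nearly flat in the initial Kupffer ratio:
  faster phagocytosis frees sites earlier but also lets them refill
  earlier. The robust low-Kupffer phenotypes are persistent dead cells
  and delayed collagen onset.
* Portal-fibroblast collagen is vacancy-limited rather than TGF-limited,
  so its dependence on the initial HSC ratio is weak (slightly
  decreasing, via competition for space).

## Numerical choices

Fields are float64; diffusion uses a 3 × 3 convolution
(`scipy.signal.convolve2d`), clipped at zero against rounding noise.
Ties in vacant-site choices are broken uniformly at random; ties in
`peak_step` resolve to the earliest step. `onset_step` uses a strict
`> fraction × final` comparison and is undefined (None) for
all-zero series; `dominant_period` is the median gap between
`scipy.signal.find_peaks` maxima above 10 % of the series maximum.
Agents are culled when `age >= lifespan`, after ageing, so an agent with
lifespan L created at step 0 is last present at step L−1. The RNG is
NumPy's PCG64; one generator per run drives placement, movement,
scheduling shuffles and tie-breaks.
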