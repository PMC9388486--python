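"""Default calibration of the fibrosis simulator.

The rule set of the model is qualitative (thresholds, secretion, transport
and decay rates); the defaults below are the package's reference
calibration, chosen so the default run (101 x 101 field, one central vein,
four portal tracts at the lobule vertices, toxin injected every 10 steps up
to step 120, Kupffer/stellate ratios 15%/5% of lattice sites) reproduces
the canonical timeline of toxin-induced pericentral fibrosis:

* The toxin is deposited zonation-weighted and decays slowly enough that
  repeated 10-step dosing accumulates: the first injection kills nothing,
  the second kills a small pericentral ring (~steps 10-12), the third a
  much larger one (~steps 20-22).  An 18-step interval never reaches the
  necrosis threshold, so that schedule produces no fibrosis at all.
* Kupffer cells activated by phagocytosing the necrotic bursts stay M1 for
  tau_m1m2 = 7 steps, so the M1 pools of the second and third bursts
  stack and total TNF-alpha peaks around step 25, declining
  afterwards as pericentral scarring (below) shrinks later bursts.
* Activated stellate cells become myofibroblasts near the vein; each
  produces a few collagen deposits and dies.  Any adjacent deposit blocks
  hepatocyte replication, so scar accumulates where cells keep dying,
  which is the negative feedback that caps the dead-cell bursts.
* TGF-beta from M2 Kupffer cells spreads outward; it crosses the
  collagen-secretion threshold at the portal tracts around step 40, when
  portal-fibroblast collagen begins to occupy the sparse vacancies left
  by hepatocyte turnover.
* Dead cells persist at most 12 steps, so with only two injections every
  dead cell is phagocytosed or cleared by about step 20 and no
  self-sustaining inflammation develops.

All quantities are in arbitrary concentration units and steps.
"""

DEFAULT_CALIBRATION: dict = {
    # Geometry
    "height": 101,
    "width": 101,
    "vein_block": 3,            # central vein: vein_block x vein_block at centre
    "portal_block": 3,          # one portal tract block per lobule vertex
    "portal_inset": 0.42,       # fractional inset of tract centres from the edges
    "zonation_lambda": None,    # None -> width / 4
    # Initial cell ratios, as fractions of all lattice sites
    "hepatocyte_ratio": 0.60,
    "kupffer_ratio": 0.15,
    "hsc_ratio": 0.05,
    "myofibroblast_ratio": 0.0,
    "portal_fibroblast_density": 1.0,   # fibroblasts per eligible portal site
    # Injection schedule
    "interval": 10,
    "first_step": 0,
    "last_step": 120,
    "dose": 4000.0,             # total toxin mass per injection
    # Field transport (share fraction per step, first-order decay per step)
    "ccl4_share": 0.30,
    "ccl4_decay": 0.10,
    "hmgb1_share": 0.30,
    "hmgb1_decay": 0.03,        # slow: a local memory of repeated necrosis
    "tnfa_share": 0.55,
    "tnfa_decay": 0.30,         # fast: total TNF tracks the current M1 pool
    "tgfb_share": 0.60,
    "tgfb_decay": 0.03,         # slow: reaches the portal tracts
    # Secretion per agent per step
    "hmgb1_secretion": 1.0,     # per necrotic dead cell
    "tnf_secretion": 1.0,       # per M1 Kupffer cell
    "tgf_secretion": 8.0,       # per M2 Kupffer cell
    # Thresholds
    "theta_ccl4": 1.60,         # on zonation-weighted toxin; necrosis
    "theta_tnf_death": 2.20,    # hepatocyte apoptosis
    "theta_tnf_hsc": 0.15,      # stellate-cell activation
    "theta_tgf": 0.70,          # collagen secretion
    "theta_hmgb1": 12.0,        # Kupffer activation by the DAMP depot
    # Kupffer kinetics
    "tau_m1m2": 7,             # steps in the M1 phenotype before switching
    "kc_replenish_rate": 0.25,  # new quiescent KC per portal tract per step
    # Hepatocyte turnover
    "replication_cooldown": 15,
    "collagen_rich_threshold": 1,
    # Fibroblasts
    "max_collagen_per_mfb": 8,
    # Lifespans in steps (None = not age-limited)
    "hepatocyte_lifespan": 200,
    "dead_cell_lifespan": 12,
    "kupffer_lifespan": None,
    "hsc_lifespan": None,
    "myofibroblast_lifespan": None,
    "portal_fibroblast_lifespan": None,
    # Run control
    "n_steps": 120,
    "seed": 0,
}
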