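# Methods

## Scope and assumptions

hydramol scores hydrogen-bond donors and acceptors atomistically and sums
an additive three-term hydration free energy (polar + apolar +
acceptor-interaction) on a single 3D conformation.  The model is
deliberately minimal: donors are simply hydrogens, acceptors are atoms
with at least one lone pair; bond directionality, solvent structure,
conformational ensembles, tautomer/protonation equilibria and
supramolecular effects are outside the model.  Higher-order charge
corrections (hybridisation dipole, quadrupole, constant offset) that
appear in the antecedent force-field formulation are intentionally absent
from the acceptor strength — the simplification is part of the model
definition, not an approximation made here.  Protonation states and
tautomers are taken exactly as given in the input.

## Charge backend

Strengths are linear in the corrected partial charges, so the charge model
is the scientific core of the pipeline.  The packaged backend is an
isotropic electronegativity-equilibration (EEQ) solver: Gaussian-smeared
atomic charges, per-element electronegativity, hardness and charge-width
parameters, a coordination-number-scaled electronegativity
(`chi_eff = chi − k_CN √CN` with an error-function covalent CN), and a
single constrained linear solve per molecule.  Charges are therefore
geometry-aware (symmetric atoms in a relaxed geometry receive equal
charges; conformation changes shift charges) and exactly invariant under
rigid motions.

The per-element electronegativities were fitted once, by weighted linear
least squares, to a small packaged set of Hirshfeld-style reference
charges for simple hydrides and methyl derivatives
(`data/synthetic_hirshfeld_reference.csv`).  That table is a synthetic
stand-in assembled from literature-consensus magnitudes, not the output of
any specific calculation, and is labelled as such; water is up-weighted
(×4) because the entire strength scale is anchored on water.  The residual
of the fit is ≈0.02 e.  Supported elements: H, B, C, N, O, F, Si, P, S,
Cl, Br, I; anything else raises a typed error rather than guessing.

Van der Waals radii follow a screened-electron power law
`r(q) = r0 ((Z − q)/Z)^(4/7)` around consensus neutral-atom radii — a
monotone, parameter-free charge dependence (cations contract, anions
expand).  This radius convention is this package's own; it sets the
absolute scale of the apolar surface term, so apolar energies should be
compared within one backend, not across implementations.

## Calibration constants and the published values

`calibrate_water` embeds water from SMILES `O` with a fixed seed,
minimises with MMFF94, and sets `D = 1/(qH + δqH)` (mean over the two
hydrogens) and `A = 1/(qO + δqO)`, which makes the water strengths exactly
1.0 — the closure is a round trip and holds for any backend.

The defaults shipped in `StrengthParams` are the published constants
D = 63.7, A = −4.4362, which were derived with a different,
non-redistributable charge implementation.  With this package's backend
the calibration yields A = −4.392 — within 1 % of the published acceptor
constant — but D = 12.10.  The donor discrepancy is structural, not a
charge-model artefact: for a symmetric neutral water (q_O = −2 q_H) the
shell equation gives

    qH + δqH = qH (1 − 2T + T²)        qO + δqO = qO (1 − T)

so D/A = −2(1 − T)/(1 − T)² ≈ −2.75 for T = 0.274 *independently of the
charge model*, while the published pair has D/A ≈ −14.4.  No charge
assignment can reproduce both published constants through the shell
equation as printed; the implementation behind the published donor value
evidently departs from that equation in an undocumented way.  hydramol
follows the printed equations and recommends calibrating D and A with
`calibrate_water` for whatever backend is in use; the published pair
remains available as the documented default for comparability of
downstream parameter values.

## Parameters

| name | default | role |
|---|---|---|
| D | 63.7 (published); 12.10 self-calibrated | donor scale, dimensionless |
| A | −4.4362 (published); −4.392 self-calibrated | acceptor scale, dimensionless |
| T | 0.274 | shell attenuation per bond, in (0, 1) |
| exp_d, exp_a | 0.50, 0.34 | multiplicity exponents for n_H, n_LP |
| g_d, g_a | 0.908, −16.131 | polar-term coefficients, kJ/mol |
| g_0, g_s | 1.884, 0.0467 | apolar constant (kJ/mol) and surface slope (kJ/mol/Å²) |
| g_r, g_π², g_π¹ | −3.643, −1.174, −1.602 | ring and π-orbital corrections, kJ/mol |
| g_i, F | 4.9996, 0.514 | interaction coefficient and 3-bond attenuation |

The eleven free-energy parameters were published as a fit against an
experimental hydration dataset that is not redistributed here; they are
shipped as inputs.  Because the published donor scale differs from the
self-calibrated one (above), users fitting to their own data should
recalibrate D/A first and then refit the free parameters.

## Perception conventions

* Lone pairs: `n_LP = (valence electrons − formal charge − total bond
  order)/2`, clamped at zero, with carbon and hydrogen fixed at 0 and one
  override — aromatic N/P with three σ neighbours (pyrrole-type) gets 0
  because its pair sits in the aromatic sextet.  This makes halogens
  (n_LP = 3), thioethers (2), pyridine-type nitrogens (1) and carbonyl
  oxygens (2) acceptors, matching the intended acceptor inventory.
* Hybridisation: aromatic atoms count as sp2; heavy atoms outside
  sp1/sp2/sp3 (hypervalent centres) are rejected with a typed error since
  the surface equation defines no hybridisation number for them.
* Shells: an atom contributes to δq once, at its shortest bond-count
  distance; hydrogens and heavy atoms both count; distance ≥ 4 never
  contributes.
* Ring count is SSSR; π counts are 2 per sp1 and 1 per sp2 heavy atom,
  heteroatoms included.
* Polar-term donors: hydrogen-bearing *non-carbon* heavy atoms by default,
  each entering with the arithmetic mean of its hydrogens' strengths;
  both choices are open in the formulation, so `donor_scope="all-h"` and
  `donor_aggregation="max"` are provided to compare the readings.
* Interaction pairs are counted from both origins (ordered sum), exactly
  as the equation is written; any symmetrisation is absorbed in g_i.
* r² is reported as the squared Pearson correlation (and the
  1 − SS_res/SS_tot variant alongside, since either convention can be
  meant by "coefficient of determination" on a scatter).

## Fitting

`HydrationModel.fit` minimises the mean absolute error with a seeded
(1+1) evolution strategy: Gaussian proposals around the incumbent,
acceptance only on strict improvement, multiplicative step-size adaptation
(×1.25 on success, ×0.985 on failure, clamped to [1e-4, 1]), sign-
preserving decade bounds around each starting value, and an early stop
after `patience` (default 300) consecutive non-improving trials.  Ties
keep the first-seen incumbent.  Geometry and charges do not depend on the
free parameters, so molecules are featurised once and each trial is a
cheap dot-product re-scoring; the trial log records every evaluation and
the whole search is reproducible from its seed.

## Synthetic data

`generate_synthetic_dataset` enumerates small organics from a seeded
fragment grammar (alkanes, alcohols, amines, ethers, thio- and halogen
derivatives, simple aromatics and heteroaromatics — all MMFF94-
parameterised by construction) and labels them with the model's own
prediction plus Gaussian noise.  It emulates the size and functional-group
diversity of a small hydration benchmark, not its experimental error
structure or its conformational complexity; recovery tests on it
demonstrate that the fitting machinery is correct and deterministic, not
that the model generalises to real measurements.  The packaged property
checks run the interaction-term brute-force oracle on 100 generated
molecules and parameter recovery (g_d, g_a from a perturbed start, 5 %
tolerance, final MAE < 0.1 kJ/mol) on 50 noise-free molecules — sizes
chosen to exercise every code path while keeping the default suite quick.

## Degenerate inputs and numerics

Zero-variance inputs to correlations raise a typed error (and are
isolated per feature in SAR tables); molecules whose embedding or MMFF94
parameterisation fails are excluded from batches with a logged reason,
never silently; an atom with more heavy neighbours than its hybridisation
allows raises a valence error; acceptor strength on a lone-pair-free atom
is an argument error, so the `n_LP^exp_a` factor never sees n_LP = 0.
Strengths are kept unrounded internally; file outputs round to 2 decimals.
Energies are exact sums of their three terms by construction.

## Known limitations

* Absolute hydration energies inherit the published free parameters,
  whose donor/acceptor scale is tied to the original charge backend;
  expect systematic offsets on polar compounds until refitted.
* The radius convention (and hence the apolar scale) is package-specific.
* Formally charged atoms follow the lone-pair rule but are unvalidated;
  intramolecular hydrogen bonds are only crudely captured by the
  interaction term, and strongly interacting neighbouring groups (e.g.
  ortho donor/acceptor pairs) are the known worst case of this model
  family.
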