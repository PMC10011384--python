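# hydramol

Atomistic hydrogen-bond donor/acceptor strengths and hydration free
energies for small organic molecules.

Hydrogen bonding drives target affinity, solubility and oral availability,
so medicinal and computational chemists routinely need a *fast* estimate of
how strongly each polar atom of a candidate molecule hydrogen-bonds, and of
the molecule's free energy of hydration ΔG_hydr — fast enough for
interactive design, library screening and machine-learning featurisation,
where quantum-chemical solvation calculations are far too slow.  hydramol
computes both from a single 3D conformation in milliseconds per molecule.

## The model

Partial charges `q` and charge-dependent van der Waals radii come from a
geometry-aware electronegativity-equilibration (EEQ) charge model.  Each
hydrogen is scored as a donor and each lone-pair atom as an acceptor:

    sd = D (qH + δqH)          sa = A (qa + δqa)

    δq = T Σ_α q  +  T² Σ_β q  +  T³ Σ_γ q

where α, β, γ are the atoms one, two and three bonds away and T = 0.274 is
the bond reduction factor.  D and A are calibrated on an MMFF94-minimised
water molecule so that its hydrogens and oxygen score exactly 1.0: a
strength above 1 means "hydrogen-bonds more strongly than water".

The hydration free energy is a sum of three contributions (kJ/mol):

    ΔG_hydr = ΔG^p + ΔG^a + ΔG^i

    ΔG^p = g_d Σ_donors sd_i n_H^exp_d  +  g_a Σ_acceptors sa_i n_LP^exp_a
    ΔG^a = g_0 + g_s N_s + g_r N_r + g_π² N_π² + g_π¹ N_π¹
    ΔG^i = g_i Σ_j a_j ( Σ_{k∈n(j)} a_k + Σ_{l∈nn(j)} a_l + F Σ_{m∈nnn(j)} a_m ),
           a_p = sa_p n_LP^exp_a

with the topological surface `N_s^i = 4π r_vdW² (1 − n_l/(h+1))` summed over
heavy atoms (h = 1, 2, 3 for sp1/sp2/sp3), ring count N_r (SSSR) and
π-orbital counts, and an empirical penalty for acceptor pairs within three
bonds.  The eleven free parameters ship with published defaults and can be
refitted to any (molecule, ΔG) dataset by MAE minimisation with early
stopping; D, A, T stay fixed during fitting.

## Worked example

```python
import hydramol as hm

D, A = hm.calibrate_water()                  # D = 12.0991, A = -4.3920
params = hm.ParameterSet(strength=hm.StrengthParams(D=D, A=A))

rec = hm.prepare_record(hm.from_smiles("CCO", "ethanol"))
res = hm.total_hydration(rec, params)
ss  = res.strengths
```

This prints, for a few familiar molecules:

```
   water: polar  -19.13  apolar   3.68  interaction  0.00  total  -15.46 kJ/mol
 ethanol: polar  -20.29  apolar   5.89  interaction  0.00  total  -14.40 kJ/mol
  hexane: polar    0.00  apolar   9.40  interaction  0.00  total    9.40 kJ/mol
 benzene: polar    0.00  apolar  -7.10  interaction  0.00  total   -7.10 kJ/mol
```

Polar molecules hydrate favourably through their donor/acceptor strengths
(ethanol's hydroxyl hydrogen scores sd = 0.67, its oxygen sa = 1.02 —
slightly *better* than water's oxygen), hexane's positive ΔG is pure
surface term, and benzene picks up its negative value from the ring and
π-orbital corrections.  `hm.HydrationModel(records, dg_exp).fit()` refits
the free parameters to experimental data and returns a results object with
`summary()`, the full trial log and predictions.

The same functionality is exposed on the command line:

```bash
hydramol calibrate
hydramol predict   --input mols.smi --output predictions.csv
hydramol strengths --input mols.smi --output strengths.csv
hydramol depict    --input mols.smi --output svg/ --mode donor
hydramol fit       --dataset dg.csv --output fit.json
hydramol sar       --series cdk2 --output sar.csv
```

Donor depictions shade each hydrogen white→red with intensity monotone in
strength (acceptors white→blue) and annotate the 2-decimal values, which
supports reading structure–activity trends directly off the rendering.
Per-atom strengths of two published inhibitor series and their activity
tables are packaged (`hydramol.datasets.load_fixture`), and
`hydramol sar` reproduces the published correlation analysis from them.

External benchmark datasets of experimental ΔG_hydr are not redistributed
here; to use one, curate it to a CSV with columns `id, smiles,
dg_exp_kj_mol` (keep only kJ/mol or kcal/mol entries, converting kcal→kJ
with ×4.184, and drop compounds present in your fitting set), then run
`hydramol validate --dataset your.csv --output metrics.json`.

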