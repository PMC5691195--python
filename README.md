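# knotcost

**How much free energy does it cost a protein to tie itself in a knot?**

Some proteins fold into native states threaded by a trefoil (3₁) knot.
Whether such knots can simply form by chance in the denatured chain — or
must be paid for along the folding pathway — hinges on one number: the
free-energy cost ΔG_U of spontaneous trefoil formation in the unfolded
state. This package computes that number two independent ways, for
researchers in single-molecule biophysics and protein folding:

1. **Experimentally**, from optical-tweezers pulling data on a
   120-residue two-domain construct that is trapped, molecule by
   molecule, in either a knotted or an unknotted native form. A
   thermodynamic cycle connects the two unfolding free energies
   (from Crooks-fluctuation-theorem work analysis and from the
   coexistence force F₁/₂) with the native-state knotting free energy
   ΔG_N:

       ΔG_U = ΔG_unfold(knotted) − ΔG_unfold(unknotted) − ΔG_N

2. **Theoretically**, from Monte Carlo ensembles of excluded-volume
   freely-jointed chains (N Kuhn segments of length 2P = 1.4 nm,
   hard-cylinder diameter D). The equilibrium trefoil fraction p gives
   the entropic knotting cost ΔG_S = −RT ln[p/(1−p)], detected per
   conformation by the Alexander polynomial |Δ(−1)|, |Δ(−2)| after
   polygon closure and topology-preserving simplification.

The agreement of the two routes — and the diameter D at which they
match — is the scientific payoff. A synthetic-data generator emulates
the pulling experiment (two non-interconverting molecule classes,
bimodal force distributions, CFT-consistent work samples) so the whole
analysis chain is testable against known ground truth.

## Worked example

```python
from knotcost import (ChainParams, knotting_probability, delta_g_native,
                      knotting_cost_cycle)

# entropic knotting cost of the 120-residue chain (32 Kuhn segments)
est = knotting_probability(
    ChainParams(n_segments=32, kuhn_length=1.4, diameter=0.49),
    120_000, seed=7)
print(f"p = {est.p_knot:.2e}, dG_S = {est.delta_g_s:.2f} "
      f"+- {est.delta_g_s_err:.2f} kcal/mol")

# the experimental cycle: class stabilities and native populations
dg_n = delta_g_native(6, 26)          # 6 unknotted vs 26 knotted molecules
cyc = knotting_cost_cycle(12.25, 5.8, dg_n)
print(f"dG_N = {dg_n:.2f}, dG_U = {cyc.dg_unfolded_knotting:.2f} kcal/mol")
```

prints

```
p = 5.00e-05, dG_S = 5.87 +- 0.26 kcal/mol
dG_N = 0.87, dG_U = 5.58 kcal/mol
```

— the Monte Carlo entropic cost for the 32-segment chain at the
effective diameter 0.49 nm (5.9 kcal/mol from 6 trefoils in 120,000
ring conformations) agrees with the experimentally derived cycle value
(~5.6–5.8 kcal/mol, depending on the stability route), which is the
central result.

The `analysis/` scripts run the full narrative on synthetic data:

* `01_simulate_experiment.py` — generate pulling traces, force pairs
  and work samples with ground truth;
* `02_classify_molecules.py` — biphasic clustering of (F_R, F_U) pairs
  into the two molecule classes (molecule-vote accuracy 1.00 on the
  default dataset);
* `03_contour_and_work.py` — rip detection (recall 0.998), per-class
  contour lengths (36.8 vs 39.9 nm) and rip works;
* `04_free_energy_cycle.py` — CFT and F₁/₂ stabilities (12.20/12.34
  knotted, 6.21/5.59 unknotted), ΔG_N = 0.87, and ΔG_U = 5.1–5.9
  kcal/mol by route;
* `05_knot_monte_carlo.py` — ΔG_S at N = 32, the diameter scan with
  interpolation (D/2P = 0.346 → D = 0.49 nm at ΔG_U = 5.8), and the
  chain-length scan;
* `06_kinetics.py` — Bell-model round trip and the refolding-force
  signature of the knot (a ~4 nm reduction of |Δx≠|).

Outputs land in `results/` as TSV/JSON. `docs/methods.md` documents the
models, samplers, tolerances and known limitations.

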