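"""Force-dependent kinetics: rate extraction and the refolding Δx shift.

Simulates Bell-model rupture forces under the 100 nm/s ramp, transforms
the force histogram back into rates, refits the model (closing the
loop), and shows that shrinking the unfolded-to-transition-state
distance Δx≠ of the refolding branch by ~4 nm — the knotted protein's
signature, with part of the denatured chain sequestered in the knot —
broadens and shifts the refolding force distribution exactly as the
two classes differ.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from knotcost import (KineticModel, LoadingProtocol, fit_kinetic_model,
                      rates_from_force_histogram, simulate_rupture_forces)
from knotcost.io import write_table

ROOT = Path(__file__).resolve().parents[1] / "results" / "kinetics"
SEED = 5


def main() -> None:
    protocol = LoadingProtocol()  # 100 nm/s, 0.1 pN/nm, 2-30 pN
    truth = KineticModel(k0=0.01, dx_ddagger=2.0)
    forces = simulate_rupture_forces(truth, protocol, 5000, seed=SEED)
    table = rates_from_force_histogram(forces, protocol)
    write_table(table, ROOT / "unfold_rates.tsv")
    fit, errs = fit_kinetic_model(table, "bell")
    print("unfolding round trip (simulate -> histogram -> fit):")
    print(f"  truth  k0 = {truth.k0}, Δx‡ = {truth.dx_ddagger} nm")
    print(f"  fitted k0 = {fit.k0:.4f} ± ln-err {errs['ln_k0']:.2f}, "
          f"Δx‡ = {fit.dx_ddagger:.2f} ± {errs['dx_ddagger']:.2f} nm")

    # refolding: negative-Δx convention on the falling ramp
    rows = []
    print("\nrefolding force distributions:")
    for name, dx in (("unknotted-like", -8.0), ("knotted-like", -4.0)):
        model = KineticModel(k0=1e4, dx_ddagger=dx)
        fr = simulate_rupture_forces(model, protocol, 5000, seed=SEED + 1,
                                     direction="fold")
        rows.append({"class": name, "dx_refold_nm": dx,
                     "mean_pN": fr.mean(), "sd_pN": fr.std(ddof=1)})
        print(f"  Δx≠ = {dx:5.1f} nm -> F_R = {fr.mean():.1f} "
              f"± {fr.std(ddof=1):.1f} pN")
    write_table(pd.DataFrame(rows), ROOT / "refold_shift.tsv")
    print("shrinking |Δx≠| by 4 nm raises and broadens the refolding "
          "forces, as seen for the knotted class")


if __name__ == "__main__":
    main()
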