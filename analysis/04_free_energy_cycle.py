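"""Free energies and the thermodynamic cycle for the knotting cost.

Extracts the unfolding free energy of each class from the synthetic
work distributions by the Crooks-fluctuation-theorem crossing, adds the
coexistence-force (F₁/₂) route, computes the native-state knotting free
energy ΔG_N from the 6-vs-26 molecule populations, and closes the
thermodynamic cycle on the unfolded-state knotting cost

    ΔG_U = ΔG_unfold(knotted) − ΔG_unfold(unknotted) − ΔG_N.

The cycle is reported for the CFT-only, F₁/₂-only and averaged
stability routes.
"""

import json
from pathlib import Path

from knotcost import (WLCParams, cft_delta_g, delta_g_f_half, delta_g_native,
                      fit_work_distribution, knotting_cost_cycle)
from knotcost.io import read_table

ROOT = Path(__file__).resolve().parents[1] / "results"

# coexistence forces consistent with the class stabilities (pN)
F_HALF = {"unknotted": 4.6, "knotted": 7.8}
L_C = {"unknotted": 42.0, "knotted": 37.0}


def main() -> None:
    works = read_table(ROOT / "synthetic" / "works.tsv")
    stab = {}
    for cls, g in works.groupby("class"):
        fit_u = fit_work_distribution(
            g.loc[g["direction"] == "unfold", "w_zero_kcal_mol"], "unfold")
        fit_f = fit_work_distribution(
            g.loc[g["direction"] == "fold", "w_zero_kcal_mol"], "fold")
        dg_cft = cft_delta_g(fit_f, fit_u)
        dg_fh = delta_g_f_half(F_HALF[cls],
                               WLCParams(contour_length=L_C[cls]))
        stab[cls] = {"dg_cft": dg_cft, "dg_f_half": dg_fh,
                     "dg_mean": 0.5 * (dg_cft + dg_fh),
                     "truth": float(g["dg_truth"].iloc[0])}
        print(f"{cls:10s} ΔG_CFT = {dg_cft:5.2f}  "
              f"ΔG_F1/2(F₁/₂={F_HALF[cls]} pN) = {dg_fh:5.2f}  "
              f"(generator truth {stab[cls]['truth']})")

    dg_n = delta_g_native(6, 26)
    print(f"\nΔG_N from native populations (6 unknotted / 26 knotted): "
          f"{dg_n:.2f} kcal/mol")

    out = {"dg_native": dg_n, "stabilities": stab, "cycles": {}}
    for route in ("dg_cft", "dg_f_half", "dg_mean"):
        cyc = knotting_cost_cycle(stab["knotted"][route],
                                  stab["unknotted"][route], dg_n)
        out["cycles"][route] = cyc.dg_unfolded_knotting
        print(f"ΔG_U via {route:9s}: {cyc.dg_unfolded_knotting:5.2f} kcal/mol")

    path = ROOT / "thermo" / "cycle.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(out, indent=2) + "\n")
    print(f"\nwrote {path}")


if __name__ == "__main__":
    main()
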