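"""Random-chain Monte Carlo: the entropic cost of a trefoil knot.

Estimates the equilibrium trefoil fraction of excluded-volume chains
(32 Kuhn segments of 1.4 nm, effective diameter 0.49 nm, matching the
120-residue construct) in the closed-polygon ensemble, converts it to
ΔG_S = −RT ln(p/(1−p)), scans ΔG_S over the relative diameter D/2P and
interpolates the linear fit at the experimental ΔG_U = 5.8 kcal/mol to
recover the effective diameter, and scans chain length at D = 0.49 nm.
Sample counts here are moderate (a few minutes); scripts/acceptance.py
runs the full-scale versions.
"""

import sys
from pathlib import Path

from knotcost import (ChainParams, generate_ensemble, knotting_probability,
                      interpolate_effective_diameter, radius_of_gyration,
                      scan_chain_length, scan_diameter)
from knotcost.io import write_manifest, write_table

ROOT = Path(__file__).resolve().parents[1] / "results" / "knotting"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7


def main() -> None:
    params = ChainParams(n_segments=32, kuhn_length=1.4, diameter=0.49)
    est = knotting_probability(params, 120_000, seed=SEED)
    print(f"N=32, D=0.49 nm (ring ensemble): "
          f"{est.n_knot['trefoil']} trefoils in {est.n_total:,} samples, "
          f"p = {est.p_knot:.2e}")
    print(f"  ΔG_S = {est.delta_g_s:.2f} ± {est.delta_g_s_err:.2f} kcal/mol")

    rg, sem = radius_of_gyration(generate_ensemble(params, 5000,
                                                   rng=SEED + 1))
    print(f"open-chain mean Rg = {rg:.2f} ± {sem:.2f} nm")

    dscan = scan_diameter([0.10, 0.20, 0.30, 0.40], 32,
                          [30_000, 60_000, 120_000, 250_000], seed=SEED + 2)
    write_table(dscan.table, ROOT / "diameter_scan.tsv")
    x, (lo, hi) = interpolate_effective_diameter(dscan, 5.8)
    print(f"\nΔG_S(D/2P) fit: slope {dscan.slope:.2f}, "
          f"intercept {dscan.intercept:.2f}")
    print(f"interpolation at ΔG_U = 5.8 kcal/mol: D/2P = {x:.3f} "
          f"(95% CI {lo:.3f}–{hi:.3f}) → D = {1.4 * x:.2f} nm")

    lscan = scan_chain_length([20, 32, 50, 100], 0.49,
                              [60_000, 60_000, 40_000, 20_000],
                              seed=SEED + 3)
    write_table(lscan.table, ROOT / "length_scan.tsv")
    print("\nΔG_S versus chain length at D = 0.49 nm:")
    print(lscan.table[["N", "n", "n_trefoil", "dG_S", "dG_S_err"]]
          .round(2).to_string(index=False))
    write_manifest(ROOT / "manifest.json", seed=SEED,
                   script=Path(__file__).name)


if __name__ == "__main__":
    main()
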