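"""Generate the synthetic optical-tweezers dataset.

Emulates constant-speed (100 nm/s) pulling of a two-class molecule
population — 6 unknotted and 26 knotted molecules that never
interconvert — plus labeled (F_R, F_U) force pairs drawn from the pooled
bimodal force-distribution fits, and CFT-consistent work samples for
both classes.  Everything is written with its ground truth under
results/synthetic/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from knotcost import (ExperimentSpec, gen_cft_work_samples, gen_force_pairs,
                      gen_pulling_dataset)
from knotcost.io import write_manifest, write_table

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 11


def main() -> None:
    spec = ExperimentSpec(n_molecules=(6, 26), cycles_per_molecule=20,
                          seed=SEED)
    traces, truth = gen_pulling_dataset(spec)
    write_table(traces, OUT / "traces.tsv")
    write_table(truth, OUT / "rip_truth.tsv")
    print(f"pulling cycles: {truth.shape[0] // 2} "
          f"({truth['molecule_id'].nunique()} molecules, "
          f"{len(traces):,} trace points)")

    pairs = gen_force_pairs(537, seed=SEED + 1)
    write_table(pairs, OUT / "force_pairs.tsv")
    print(f"force pairs: {len(pairs)} "
          f"(unfold mean {pairs['f_unfold'].mean():.1f} pN)")

    rng = np.random.default_rng(SEED + 2)
    works = []
    for name, dg, wdis in (("unknotted", 6.2, 1.5), ("knotted", 12.2, 2.0)):
        s = gen_cft_work_samples(dg, wdis, 500, seed=rng)
        works.append(pd.DataFrame({
            "class": name,
            "w_zero_kcal_mol": np.concatenate([s.unfold, s.fold_flipped]),
            "direction": ["unfold"] * len(s.unfold)
                         + ["fold"] * len(s.fold_flipped),
            "dg_truth": dg, "w_dis": wdis,
        }))
    write_table(pd.concat(works, ignore_index=True), OUT / "works.tsv")
    print("work samples: 500/side/class at dG truths 6.2 and 12.2 kcal/mol")
    write_manifest(OUT / "manifest.json", seed=SEED, spec=spec,
                   script=Path(__file__).name)


if __name__ == "__main__":
    main()
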