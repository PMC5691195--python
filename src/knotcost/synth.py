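"""Synthetic single-molecule data with known ground truth.

The generators emulate the two-state optical-tweezers experiment on the
knotted/unknotted two-class molecule population: constant-speed pulling
cycles with one unfolding rip per pull and one refolding rip per relax,
class-specific force distributions and contour lengths, CFT-consistent
work samples, labeled (F_R, F_U) pairs for clustering, and canonical
knot polygons for the topology code.  Every generator is deterministic
given its seed, and every dataset is accompanied by its ground truth.

Default class parameters are the experiment's printed values: the
low-force (unknotted) class unfolds at 8.2 ± 2.7 pN and refolds at
4.7 ± 0.5 pN with contour length 40.2 nm; the high-force (knotted)
class at 14.7 ± 3.9 / 7.3 ± 1.0 pN with 36.9 nm; molecules keep their
class for all cycles (the two forms do not interconvert).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import rt_kcal
from .kinetics import KineticModel, LoadingProtocol, simulate_rupture_forces
from .wlc import WLCParams, wlc_extension

__all__ = [
    "MoleculeClassSpec", "ExperimentSpec", "CftWorkSamples",
    "default_classes", "gen_pulling_dataset", "gen_cft_work_samples",
    "gen_force_pairs", "canonical_knot_polygons",
]


@dataclass(frozen=True)
class MoleculeClassSpec:
    """Ground-truth description of one molecule class."""

    name: str                      # "knotted" | "unknotted"
    l_c: float                     # unfolded contour length, nm
    unfold_force_mean: float       # pN
    unfold_force_sd: float
    refold_force_mean: float
    refold_force_sd: float
    dg_truth: float                # unfolding free energy, kcal/mol
    kinetic_unfold: KineticModel | None = None
    kinetic_refold: KineticModel | None = None

    def __post_init__(self) -> None:
        if min(self.l_c, self.unfold_force_mean, self.unfold_force_sd,
               self.refold_force_mean, self.refold_force_sd) <= 0:
            raise ValueError("class parameters must be positive")


@dataclass(frozen=True)
class ExperimentSpec:
    """Layout of one synthetic pulling experiment."""

    n_molecules: tuple = (6, 26)       # per class, same order as classes
    cycles_per_molecule: int = 20
    pulling_speed: float = 100.0       # nm/s
    noise_sd: float = 0.15             # force noise, pN
    sample_rate: float = 1000.0        # Hz
    trap_stiffness: float = 0.1        # pN/nm
    force_window: tuple = (2.0, 30.0)  # pN
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_molecules) < 1 or self.cycles_per_molecule < 1:
            raise ValueError("counts must be >= 1")


def default_classes() -> list[MoleculeClassSpec]:
    """The two-class population with the experiment's fitted parameters."""
    return [
        MoleculeClassSpec(name="unknotted", l_c=40.2,
                          unfold_force_mean=8.2, unfold_force_sd=2.7,
                          refold_force_mean=4.7, refold_force_sd=0.5,
                          dg_truth=6.2),
        MoleculeClassSpec(name="knotted", l_c=36.9,
                          unfold_force_mean=14.7, unfold_force_sd=3.9,
                          refold_force_mean=7.3, refold_force_sd=1.0,
                          dg_truth=12.2),
    ]


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = np.empty(size)
    need = np.arange(size)
    while need.size:
        draw = rng.normal(mean, sd, size=need.size)
        ok = (draw > lo) & (draw < hi)
        out[need[ok]] = draw[ok]
        need = need[~ok]
    return out


def _transition_force(rng, cls: MoleculeClassSpec, direction: str,
                      spec: ExperimentSpec) -> float:
    """Class transition force: first-passage draw when a kinetic model is
    attached, otherwise a window-truncated Gaussian at the printed
    mean/SD."""
    model = (cls.kinetic_unfold if direction == "unfold"
             else cls.kinetic_refold)
    if model is not None:
        protocol = LoadingProtocol(
            pulling_speed=spec.pulling_speed,
            effective_stiffness=spec.trap_stiffness,
            force_window=spec.force_window)
        return float(simulate_rupture_forces(
            model, protocol, 1, rng,
            direction="unfold" if direction == "unfold" else "fold")[0])
    mean = (cls.unfold_force_mean if direction == "unfold"
            else cls.refold_force_mean)
    sd = (cls.unfold_force_sd if direction == "unfold"
          else cls.refold_force_sd)
    return float(_truncated_normal(rng, mean, sd,
                                   spec.force_window[0],
                                   spec.force_window[1], 1)[0])


def gen_pulling_dataset(spec: ExperimentSpec | None = None,
                        classes: list[MoleculeClassSpec] | None = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic pulling cycles with per-rip ground truth.

    Each cycle consists of a pull ramp (force rising through the window
    at the effective loading rate) and a relax ramp; at the drawn
    transition force the molecular extension jumps by the WLC extension
    of the unfolded chain at that force and the measured force jumps by
    the corresponding trap response.  Gaussian force noise is added on
    top.  Molecules never change class between cycles.

    Returns (traces, truth): ``traces`` has columns time_s,
    extension_nm, force_pN, ramp_id, direction, molecule_id, cycle;
    ``truth`` one row per rip with the noiseless transition force and
    extension change.
    """
    spec = spec or ExperimentSpec()
    classes = classes or default_classes()
    if len(spec.n_molecules) != len(classes):
        raise ValueError("n_molecules must match the number of classes")
    rng = np.random.default_rng(spec.seed)
    r_load = spec.pulling_speed * spec.trap_stiffness  # pN/s
    f_lo, f_hi = spec.force_window
    dt = 1.0 / spec.sample_rate
    n_pts = int(np.ceil((f_hi - f_lo) / r_load / dt))
    t_ramp = np.arange(n_pts) * dt
    f_ramp = f_lo + r_load * t_ramp

    traces, truth = [], []
    ramp_counter = 0
    mol_counter = 0
    for cls, n_mol in zip(classes, spec.n_molecules):
        wlc = WLCParams(contour_length=cls.l_c)
        for _ in range(n_mol):
            mol_id = f"mol{mol_counter:03d}"
            mol_counter += 1
            for cyc in range(spec.cycles_per_molecule):
                for direction in ("pull", "relax"):
                    is_pull = direction == "pull"
                    f_clean = f_ramp if is_pull else f_ramp[::-1].copy()
                    x = np.zeros_like(f_clean)
                    f_tr = _transition_force(
                        rng, cls, "unfold" if is_pull else "fold", spec)
                    dx = wlc_extension(f_tr, wlc)
                    if is_pull:
                        idx = np.searchsorted(f_clean, f_tr)
                        unfolded = np.arange(len(f_clean)) >= idx
                    else:
                        # the refolding force is measured on the unfolded
                        # branch, which sits one trap response below the
                        # clean ramp
                        thr = f_tr + spec.trap_stiffness * dx
                        idx = len(f_clean) - np.searchsorted(
                            f_clean[::-1], thr)
                        unfolded = np.arange(len(f_clean)) < idx
                    x[unfolded] += dx
                    # the extension jump appears in the measured force as
                    # the trap's response: a drop on unfolding, a rise on
                    # refolding
                    f_obs = (f_clean
                             - spec.trap_stiffness * dx * unfolded
                             + rng.normal(0.0, spec.noise_sd,
                                          size=f_clean.size))
                    traces.append(pd.DataFrame({
                        "time_s": t_ramp,
                        "extension_nm": x,
                        "force_pN": f_obs,
                        "ramp_id": ramp_counter,
                        "direction": direction,
                        "molecule_id": mol_id,
                        "cycle": cyc,
                    }))
                    truth.append({
                        "ramp_id": ramp_counter,
                        "molecule_id": mol_id,
                        "cycle": cyc,
                        "class": cls.name,
                        "direction": "unfold" if is_pull else "fold",
                        "force_pN": f_tr,
                        "delta_x_nm": dx,
                        "l_c_true": cls.l_c,
                    })
                    ramp_counter += 1
    return (pd.concat(traces, ignore_index=True),
            pd.DataFrame(truth))


@dataclass(frozen=True)
class CftWorkSamples:
    """Work samples on the unfolding-work axis with their ground truth."""

    unfold: np.ndarray        # forward works, kcal/mol
    fold_flipped: np.ndarray  # reverse works, sign-flipped, kcal/mol
    dg_truth: float
    w_dis: float
    sigma: float


def gen_cft_work_samples(dg: float, w_dis: float, n: int, seed=None,
                         temperature: float = 298.15) -> CftWorkSamples:
    """Gaussian work pairs exactly consistent with the Crooks relation.

    Forward (unfolding) works are N(dg + w_dis, σ²) and sign-flipped
    reverse works N(dg − w_dis, σ²) with σ² = 2·RT·w_dis — the unique
    Gaussian pair with symmetric dissipation satisfying
    P_F(W)/P_R(W) = exp[(W − ΔG)/RT], so the densities cross exactly at
    ΔG.  ``w_dis = 0`` degenerates both distributions to the point dg.
    """
    if w_dis < 0:
        raise ValueError("dissipated work must be >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sigma = float(np.sqrt(2.0 * rt_kcal(temperature) * w_dis))
    return CftWorkSamples(
        unfold=rng.normal(dg + w_dis, sigma, size=n),
        fold_flipped=rng.normal(dg - w_dis, sigma, size=n),
        dg_truth=float(dg), w_dis=float(w_dis), sigma=sigma)


def gen_force_pairs(n_per_class: int = 500, seed=None, *,
                    refold_means=(4.7, 7.3), refold_sds=(0.5, 1.0),
                    unfold_means=(10.0, 16.5), unfold_sds=(3.0, 2.5),
                    labels=("unknotted", "knotted"),
                    force_window=(2.0, 30.0),
                    rips_per_molecule: int = 10) -> pd.DataFrame:
    """Labeled (F_R, F_U) pairs from the experiment's bimodal fits.

    Defaults are the printed two-component fit parameters of the pooled
    refolding (μ = 4.7, 7.3; σ = 0.5, 1.0 pN) and unfolding
    (μ = 10, 16.5; σ = 3, 2.5 pN) force distributions.  Forces are
    truncated to the instrument's measurable window (2–30 pN by
    default): rips outside it are never recorded by the experiment.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    lo, hi = force_window
    frames = []
    mol = 0
    for c, lab in enumerate(labels):
        fr = _truncated_normal(rng, refold_means[c], refold_sds[c],
                               lo, hi, n_per_class)
        fu = _truncated_normal(rng, unfold_means[c], unfold_sds[c],
                               lo, hi, n_per_class)
        mol_ids = [f"mol{mol + i // rips_per_molecule:03d}"
                   for i in range(n_per_class)]
        mol += int(np.ceil(n_per_class / rips_per_molecule))
        frames.append(pd.DataFrame({
            "f_refold": fr, "f_unfold": fu,
            "molecule_id": mol_ids, "label": lab,
        }))
    return pd.concat(frames, ignore_index=True)


def canonical_knot_polygons() -> dict:
    """Exact-coordinate closed polygons with known knot classes.

    Returns name -> (vertices, expected_label, expected_det_t_minus1):
    a planar unknot, the (2,3) torus trefoil and the figure-eight knot,
    with enough vertices that the polygonal curve preserves the smooth
    knot type.
    """
    t60 = np.linspace(0.0, 2.0 * np.pi, 60, endpoint=False)
    trefoil = np.column_stack([
        (2.0 + np.cos(3.0 * t60)) * np.cos(2.0 * t60),
        (2.0 + np.cos(3.0 * t60)) * np.sin(2.0 * t60),
        np.sin(3.0 * t60),
    ])
    t80 = np.linspace(0.0, 2.0 * np.pi, 80, endpoint=False)
    figure_eight = np.column_stack([
        (2.0 + np.cos(2.0 * t80)) * np.cos(3.0 * t80),
        (2.0 + np.cos(2.0 * t80)) * np.sin(3.0 * t80),
        np.sin(4.0 * t80),
    ])
    square = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                       [1.0, 1.0, 0.0], [0.0, 1.0, 0.0]])
    return {
        "unknot": (square, "unknot", 1),
        "trefoil": (trefoil, "trefoil", 3),
        "figure_eight": (figure_eight, "other", 5),
    }
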