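"""Material-state classification of aging condensates from probe trajectories.

Simulates probe-bead ensembles in three media — a near-Fickian viscous liquid,
a Maxwell fluid, and an arrested elastic solid — then runs the full
microrheology chain: ensemble MSD, diffusive exponent alpha, GSER moduli,
and the storage/loss crossover.
"""

import numpy as np

from condensage import (
    GserParams,
    MotionModel,
    SimulationConfig,
    classify_timecourse,
    compute_msd,
    find_crossover,
    fit_powerlaw,
    gser_moduli,
    simulate_trajectories,
)

MEDIA = [
    ("fresh (h0-like)", MotionModel(kind="subdiffusive", alpha_true=0.8054, K=0.5)),
    ("mid-aged (h4-like)", MotionModel(kind="jeffreys", D_free=0.05, plateau=0.02,
                                       tau_relax=0.005)),
    ("aged (h8-like)", MotionModel(kind="subdiffusive", alpha_true=0.02, K=0.005)),
]

states = []
for name, model in MEDIA:
    cfg = SimulationConfig(seed=1, n_particles=300, n_frames=200, dt=0.02)
    traj = simulate_trajectories(cfg, model)
    msd = compute_msd(traj, max_lag_fraction=0.25)
    fit = fit_powerlaw(msd, window=(msd.lag[0], msd.lag[0] * 10))
    moduli = gser_moduli(msd, fit, GserParams())
    state = find_crossover(moduli)
    states.append(state)
    extra = f", tau_c = {state.tau_c:.3f} s" if state.tau_c else ""
    print(f"{name:20s} alpha = {fit.alpha:6.3f}  state = {state.state}{extra}")

summary = classify_timecourse(states)
print(f"\nstate sequence {summary['sequence']} "
      f"consistent with viscous -> maxwell -> elastic aging: {summary['consistent']}")
print("alpha near 1 means Fickian diffusion (liquid); near 0, an arrested network.")
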