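"""Independent oracles shared by the unit and acceptance suites."""

import numpy as np

from senspread import minimal as mm
from senspread import spatial as sp
from senspread.params import derive_compound_params


def bernoulli_chain_first_event_cdf(
    pop_positions, emitter_pos, p, t_grid, dt=0.01, n_reps=2000, seed=0
):
    """Fine-timestep first-induction-time CDF for a static single emitter.

    Independent of the event-driven path: each normal cell is a Bernoulli
    chain with per-step success 1 - exp(-rate * dt); the replicate's first
    event is the minimum geometric waiting time across cells.
    """
    d = derive_compound_params(p)
    r = np.hypot(*(np.asarray(pop_positions) - np.asarray(emitter_pos)).T)
    lam = p.NE * mm.per_cell_binding_probability(r, d, p.rcell)
    rates = np.atleast_1d(sp.poisson_induction_rate(lam, p.ND))
    rng = np.random.default_rng(seed)
    n_steps = int(t_grid[-1] / dt)
    p_step = 1.0 - np.exp(-rates * dt)
    first_steps = np.full(n_reps, n_steps + 1)
    for ps in p_step:
        if ps <= 0:
            continue
        draws = rng.geometric(ps, size=n_reps)
        first_steps = np.minimum(first_steps, draws)
    first_t = first_steps * dt
    return np.array([(first_t <= t).mean() for t in t_grid])
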