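"""Numba kernels for exact stochastic simulation (direct-method SSA).

One kernel serves the plain five-reaction system and its ATP-coupled
extension.  ``energy_mode`` selects how the ATP fraction A evolves:

* 0 — no energy coupling (Wee1/Cdc25 multipliers pinned to 1; the plain
  reaction table exactly),
* 1 — A held fixed at ``atp_frac0``,
* 2 — stoichiometric depletion: each firing of channel k converts
  ``atp_cost[k]`` ATP to ADP out of a conserved pool,
* 3 — scheduled: A(t) follows a piecewise-constant schedule.

Hill functions are evaluated on concentrations (counts/omega) so EC50s keep
their nM meaning at any droplet volume.  The A = 1/2 reference point is
special-cased to multiplier exactly 1 so the energy model reduces
bit-exactly to the plain table there.
"""

import numpy as np
from numba import njit

# params vector layout (float64[14]):
KSY, A_DEG, B_DEG, N_DEG, E_DEG, A_W, B_W, N_W, E_W, A_C, B_C, N_C, E_C, R = range(14)

STATUS_OK = 0
STATUS_MAX_EVENTS = 1


@njit(cache=True)
def _hill_up(x, a, b, n, ec50):
    q = (x / ec50) ** n
    return a + b * q / (q + 1.0)


@njit(cache=True)
def _hill_down(x, a, b, n, ec50):
    q = (x / ec50) ** n
    return a + b / (q + 1.0)


@njit(cache=True)
def _wee1_multiplier(A, w0):
    # steady-state active-Wee1 fraction relative to its A=1/2 reference
    if A == 0.5:
        return 1.0
    return (1.0 - A) / (A * (1.0 - 2.0 * w0) + w0)


@njit(cache=True)
def _cdc25_multiplier(A, c0):
    if A == 0.5:
        return 1.0
    return A / ((1.0 - c0) + (2.0 * c0 - 1.0) * A)


@njit(cache=True)
def ssa_kernel(
    params,
    omega,
    n_a0,
    n_i0,
    t_end,
    record_dt,
    seed,
    energy_mode,
    atp_frac0,
    pool,
    atp_cost,
    sched_t,
    sched_a,
    max_events,
):
    """Direct-method SSA; zero-order-hold recording on a uniform grid.

    Returns (times, n_a, n_i, counts, atp, status): counts is the cumulative
    per-channel firing count at each record time; atp is the ATP fraction
    series (1.0 where energy_mode == 0).
    """
    np.random.seed(seed)
    n_rec = int(np.floor(t_end / record_dt)) + 1
    times = np.empty(n_rec)
    rec_a = np.empty(n_rec, dtype=np.int64)
    rec_i = np.empty(n_rec, dtype=np.int64)
    rec_atp = np.empty(n_rec)
    counts = np.zeros((n_rec, 5), dtype=np.int64)
    fired = np.zeros(5, dtype=np.int64)

    sqrt_r = np.sqrt(params[R])
    rho1 = params[KSY] * omega

    n_a = n_a0
    n_i = n_i0
    if energy_mode == 2:
        n_atp = np.int64(np.rint(atp_frac0 * pool))
    else:
        n_atp = np.int64(0)
    t = 0.0
    rec = 0
    sched_i = 0
    n_events = np.int64(0)
    status = STATUS_OK
    rho = np.empty(5)

    while True:
        # current ATP fraction
        if energy_mode == 0:
            A = 0.5  # multipliers pinned to 1 below
        elif energy_mode == 1:
            A = atp_frac0
        elif energy_mode == 2:
            A = n_atp / pool
        else:
            while sched_i + 1 < len(sched_t) and sched_t[sched_i + 1] <= t:
                sched_i += 1
            A = sched_a[sched_i]

        conc = n_a / omega
        kdeg = _hill_up(conc, params[A_DEG], params[B_DEG], params[N_DEG], params[E_DEG])
        hw = _hill_down(conc, params[A_W], params[B_W], params[N_W], params[E_W])
        hc = _hill_up(conc, params[A_C], params[B_C], params[N_C], params[E_C])
        if energy_mode == 0:
            m2 = 1.0
            m3 = 1.0
        else:
            w0 = hw / (params[A_W] + params[B_W])
            c0 = hc / (params[A_C] + params[B_C])
            m2 = _wee1_multiplier(A, w0)
            m3 = _cdc25_multiplier(A, c0)
        rho[0] = rho1
        rho[1] = sqrt_r * hw * m2 * n_a
        rho[2] = (hc / sqrt_r) * m3 * n_i
        rho[3] = kdeg * n_a
        rho[4] = kdeg * n_i
        if energy_mode == 2:
            # no phosphotransfer without ATP
            for k in range(5):
                if atp_cost[k] > 0 and n_atp < atp_cost[k]:
                    rho[k] = 0.0

        total = rho[0] + rho[1] + rho[2] + rho[3] + rho[4]
        if total <= 0.0:
            tau = np.inf
        else:
            u = np.random.random()
            while u <= 0.0:
                u = np.random.random()
            tau = -np.log(u) / total
        t_next = t + tau

        # record grid points passed before this event fires
        while rec < n_rec and rec * record_dt <= t_next:
            times[rec] = rec * record_dt
            rec_a[rec] = n_a
            rec_i[rec] = n_i
            rec_atp[rec] = A if energy_mode != 0 else 1.0
            for k in range(5):
                counts[rec, k] = fired[k]
            rec += 1
        if rec >= n_rec or t_next > t_end or not np.isfinite(t_next):
            break

        # choose channel
        u2 = np.random.random() * total
        acc = 0.0
        ch = 4
        for k in range(5):
            acc += rho[k]
            if u2 < acc:
                ch = k
                break
        if ch == 0:
            n_a += 1
        elif ch == 1:
            n_a -= 1
            n_i += 1
        elif ch == 2:
            n_a += 1
            n_i -= 1
        elif ch == 3:
            n_a -= 1
        else:
            n_i -= 1
        fired[ch] += 1
        if energy_mode == 2:
            n_atp -= atp_cost[ch]
        t = t_next
        n_events += 1
        if n_events >= max_events:
            status = STATUS_MAX_EVENTS
            break

    # fill any remaining grid points by holding the final state
    while rec < n_rec:
        times[rec] = rec * record_dt
        rec_a[rec] = n_a
        rec_i[rec] = n_i
        rec_atp[rec] = (n_atp / pool) if energy_mode == 2 else (1.0 if energy_mode == 0 else rec_atp[max(rec - 1, 0)])
        for k in range(5):
            counts[rec, k] = fired[k]
        rec += 1

    return times, rec_a, rec_i, counts, rec_atp, status
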