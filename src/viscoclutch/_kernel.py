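"""JIT-compiled inner loop of the clutch simulation.

Mirrors the pure-python reference ``engine.step_ensemble`` sub-step for
sub-step, including the order of random draws, but runs the whole
trajectory in one compiled call.  Numba's np.random (MT19937) is seeded
per call, so a given seed always reproduces the same trajectory.
"""

import numpy as np
from numba import njit

__all__ = ["run_clutch_kernel"]


@njit(cache=True)
def run_clutch_kernel(
    seed,
    n_steps,
    dt,
    record_every,
    n_init,
    n_max,
    k_on,
    k_off0_eff,  # genotype factor already folded in
    f_bond,
    k_clutch,
    f_unfold,
    k_vin,
    d_recruit,
    stall_force,
    v_unloaded,
    k1,
    k2,
    eta,
    bond_mode,  # 0 = slip, 1 = catch-slip
    f_catch,
    catch_share,
):
    np.random.seed(seed)

    bound = np.zeros(n_max, dtype=np.bool_)
    x_c = np.zeros(n_max, dtype=np.float64)
    unfolded = np.zeros(n_max, dtype=np.bool_)
    vinc = np.zeros(n_max, dtype=np.bool_)

    x_sub = 0.0
    f_m = 0.0
    n_rec = n_init
    v = v_unloaded

    # exact exponential Maxwell-arm update coefficients
    if k1 > 0.0:
        tau = eta / k1
        a = np.exp(-dt / tau)
        b = k1 * (tau / dt) * (1.0 - a)
    else:
        a = 1.0
        b = 0.0

    p_on = 1.0 - np.exp(-k_on * dt)
    p_vin = 1.0 - np.exp(-k_vin * dt)

    n_out = n_steps // record_every
    out_t = np.empty(n_out, dtype=np.float64)
    out_f = np.empty(n_out, dtype=np.float64)
    out_frac = np.empty(n_out, dtype=np.float64)
    out_dens = np.empty(n_out, dtype=np.float64)
    out_v = np.empty(n_out, dtype=np.float64)

    i_out = 0
    for step in range(n_steps):
        # (1) binding: fresh bonds engage at zero extension
        for i in range(n_rec):
            if not bound[i]:
                if np.random.random() < p_on:
                    bound[i] = True
                    x_c[i] = x_sub
                    unfolded[i] = False
                    vinc[i] = False

        # (2) actin advances bound clutches
        adv = v * dt
        nb = 0
        s = 0.0
        for i in range(n_rec):
            if bound[i]:
                x_c[i] += adv
                s += x_c[i]
                nb += 1

        # (3) substrate deformation balancing the summed clutch load
        x_old = x_sub
        x_sub = (k_clutch * s + b * x_old - a * f_m) / (k2 + b + nb * k_clutch)
        f_m = a * f_m + b * (x_sub - x_old)

        # (4)-(7) unbinding, talin unfolding, vinculin, recruitment
        for i in range(n_rec):
            if not bound[i]:
                continue
            f = k_clutch * (x_c[i] - x_sub)
            if f < 0.0:
                f = 0.0
            if bond_mode == 0:
                koff = k_off0_eff * np.exp(f / f_bond)
            else:
                koff = k_off0_eff * (
                    catch_share * np.exp(-f / f_catch)
                    + (1.0 - catch_share) * np.exp(f / f_bond)
                )
            if np.random.random() < 1.0 - np.exp(-koff * dt):
                bound[i] = False
                unfolded[i] = False
                vinc[i] = False
                x_c[i] = 0.0
                continue
            if f >= f_unfold:
                unfolded[i] = True
            if unfolded[i] and not vinc[i]:
                if np.random.random() < p_vin:
                    vinc[i] = True
                    n_rec = min(n_max, n_rec + d_recruit)

        # (7b) instantaneous elastic re-balance after unbinding events
        # (dashpot frozen: recoil acts through k2 and the Maxwell spring)
        nbr = 0
        sr = 0.0
        for i in range(n_rec):
            if bound[i]:
                sr += x_c[i]
                nbr += 1
        x_new = (k_clutch * sr + k1 * x_sub - f_m) / (k2 + k1 + nbr * k_clutch)
        f_m = f_m + k1 * (x_new - x_sub)
        x_sub = x_new

        # (8) retrograde flow from the substrate load
        f_sub = k2 * x_sub + f_m
        if f_sub < 0.0:
            f_sub = 0.0
        load = 1.0 - f_sub / stall_force
        if load < 0.0:
            load = 0.0
        v = v_unloaded * load

        if (step + 1) % record_every == 0:
            out_t[i_out] = (step + 1) * dt
            out_f[i_out] = f_sub
            nb2 = 0
            for i in range(n_rec):
                if bound[i]:
                    nb2 += 1
            out_frac[i_out] = nb2 / n_rec
            out_dens[i_out] = n_rec
            out_v[i_out] = v
            i_out += 1

    return out_t, out_f, out_frac, out_dens, out_v
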