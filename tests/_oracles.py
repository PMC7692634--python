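"""Independent oracles used only by the tests.

These deliberately avoid the package's solution paths: the species
oracle is a nested 2-D bisection over (p_free, l_free) instead of the
analytic free-ligand elimination + Brent solve, and the titration oracle
is the closed-form 1:1 Wiseman quadratic.
"""

import math


def species_2d_bisection(p_tot, l_tot, kd1, kd2, iters=80):
    """Brute-force solve of the two coupled equilibria.

    Outer bisection on p_free in [0, p_tot] against the receptor mass
    balance; for each candidate p_free, inner bisection on l_free in
    [0, l_tot] against the ligand mass balance.  Returns
    (p_free, l_free, pl, p2l).
    """
    if l_tot == 0.0:
        return p_tot, 0.0, 0.0, 0.0
    if p_tot == 0.0:
        return 0.0, l_tot, 0.0, 0.0

    def inner_l(p):
        lo, hi = 0.0, l_tot
        for _ in range(iters):
            l = 0.5 * (lo + hi)
            pl = p * l / kd1
            p2l = pl * p / kd2
            if l + pl + p2l < l_tot:
                lo = l
            else:
                hi = l
        return 0.5 * (lo + hi)

    def outer_resid(p):
        l = inner_l(p)
        pl = p * l / kd1
        p2l = pl * p / kd2
        return p + pl + 2.0 * p2l - p_tot

    lo, hi = 0.0, p_tot
    for _ in range(iters):
        p = 0.5 * (lo + hi)
        if outer_resid(p) < 0.0:
            lo = p
        else:
            hi = p
    p = 0.5 * (lo + hi)
    l = inner_l(p)
    pl = p * l / kd1
    p2l = pl * p / kd2
    return p, l, pl, p2l


def single_site_quadratic(p_tot, l_tot, kd):
    """Closed-form 1:1 complex concentration."""
    b = p_tot + l_tot + kd
    pl = (b - math.sqrt(b * b - 4.0 * p_tot * l_tot)) / 2.0
    return pl


def wiseman_heats(protocol, kd, dh):
    """Independent single-site titration heats (µcal) under the same
    overflow-dilution convention: closed-form quadratic per injection."""
    v0 = protocol.cell_volume
    p_tot, l_tot = protocol.cell_conc, 0.0
    pl_pre = 0.0
    heats = []
    for v in protocol.injection_volumes:
        d = 1.0 - v / v0
        p_tot *= d
        l_tot = l_tot * d + protocol.syringe_conc * (v / v0)
        pl = single_site_quadratic(p_tot, l_tot, kd)
        heats.append(v0 * dh * (pl - pl_pre * d) * 1e6)
        pl_pre = pl
    return heats


def total_heat_with_losses(protocol, kd1, kd2, dh1, dh2, iters=80):
    """Independent cumulative-heat oracle.

    Tracks the perfusion loss term: the heat content carried out of the
    cell by displaced liquid.  Sum of injection heats must equal
    V0*[dH1*(PL_f + P2L_f) + dH2*P2L_f] plus the accumulated loss.
    """
    v0 = protocol.cell_volume
    p_tot, l_tot = protocol.cell_conc, 0.0
    pl_pre, p2l_pre = 0.0, 0.0
    loss_pl = 0.0
    loss_p2l = 0.0
    for v in protocol.injection_volumes:
        d = 1.0 - v / v0
        loss_pl += pl_pre * (v / v0)
        loss_p2l += p2l_pre * (v / v0)
        p_tot *= d
        l_tot = l_tot * d + protocol.syringe_conc * (v / v0)
        _, _, pl_pre, p2l_pre = species_2d_bisection(p_tot, l_tot, kd1, kd2, iters=iters)
    pl_eff = pl_pre + loss_pl
    p2l_eff = p2l_pre + loss_p2l
    return v0 * (dh1 * (pl_eff + p2l_eff) + dh2 * p2l_eff) * 1e6
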