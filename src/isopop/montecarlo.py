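"""Stochastic validation of the stationary labeling solver.

Samples precursor labeling patterns by direct simulation of the generative
rules — each oxaloacetate molecule traces back through a geometric number
of TCA turns to an anaplerotic entry, picking up fresh acetyl-CoA / CO2
carbons and succinate scrambling along the way — without any reference to
the linear fixed-point solution.  Agreement between sampled frequencies
and :func:`isopop.model.solve_precursor_arrays` (within sampling error)
validates the solver.

The turnover history is truncated where its residual probability falls
below ``history_tol``; draws exceeding the cap are forced to anaplerotic
entry, which biases pattern probabilities by at most ``history_tol``.
"""

from __future__ import annotations

import math
from typing import Dict

import numpy as np

from .model import AIR, HEAVY, LIGHT, PopulationState, _code, _pattern_tuples


def _build_tables():
    oaa = _pattern_tuples(4)
    fwd = np.zeros((81, 2), dtype=np.int64)       # [oaa_code, ac_label] -> akg code
    rev = np.zeros((81, 3, 2), dtype=np.int64)    # [oaa_code, co2_label, scramble]
    for o_idx, o in enumerate(oaa):
        for lab in (LIGHT, HEAVY):
            fwd[o_idx, lab] = _code((o[3], o[2], o[1], lab, lab))
        for lab in (LIGHT, HEAVY, AIR):
            for scr, succ in enumerate((o, o[::-1])):
                rev[o_idx, lab, scr] = _code((lab,) + succ)
    akg = _pattern_tuples(5)
    turn = np.zeros((243, 2), dtype=np.int64)     # [akg_code, scramble] -> oaa code
    for a_idx, a in enumerate(akg):
        for scr, succ in enumerate((a[1:], a[1:][::-1])):
            turn[a_idx, scr] = _code(succ)
    return fwd, rev, turn


_FWD, _REV, _TURN = _build_tables()


def sample_precursor_patterns(
    state: PopulationState,
    n_draws: int = 1_000_000,
    seed: int = 0,
    history_tol: float = 1e-8,
) -> Dict[str, np.ndarray]:
    """Empirical pattern frequencies of every precursor from ``n_draws``
    independent simulated molecules.

    Requires ``ap > 0`` (with no anaplerotic entry the turnover history
    never terminates).
    """
    u = state.usage12c
    ap, rev, ppp, co2 = state.biochem.as_tuple()
    if ap <= 0.0:
        raise ValueError("Monte-Carlo sampling requires ap > 0")
    h = 1.0 - u
    rng = np.random.default_rng(seed)

    def unit_labels(n):
        return np.where(rng.random(n) < h, HEAVY, LIGHT).astype(np.int64)

    def co2_labels(n):
        r = rng.random(n)
        p_air = co2
        p_heavy = (1.0 - co2) * h
        return np.where(r < p_air, AIR, np.where(r < p_air + p_heavy, HEAVY, LIGHT)).astype(np.int64)

    # --- single-unit precursors ------------------------------------------
    triose_lab = unit_labels(n_draws)
    triose = triose_lab * 13  # code of (x, x, x) in base 3
    accoa = unit_labels(n_draws) * 4  # code of (x, x)
    co2_pool = co2_labels(n_draws)

    e4p_single = unit_labels(n_draws)
    u1, u2 = unit_labels(n_draws), unit_labels(n_draws)
    oxidative = rng.random(n_draws) < ppp
    # (a,a,b,b) code = a*36 + b*4 ; single unit = a*40
    e4p = np.where(oxidative, e4p_single * 40, u1 * 36 + u2 * 4)

    # --- oxaloacetate: geometric TCA-turn history ------------------------
    k_max = max(1, math.ceil(math.log(history_tol) / math.log1p(-ap))) if ap < 1.0 else 0
    turns = rng.geometric(ap, size=n_draws) - 1
    turns = np.minimum(turns, k_max)

    ana_unit = unit_labels(n_draws)
    oaa = ana_unit * 39 + co2_labels(n_draws)  # (t,t,t,c) code = t*(27+9+3) + c

    remaining = turns.copy()
    while True:
        active = np.flatnonzero(remaining > 0)
        if active.size == 0:
            break
        n = active.size
        use_rev = rng.random(n) < rev
        scr_turn = (rng.random(n) < 0.5).astype(np.int64)
        akg_codes = np.empty(n, dtype=np.int64)
        idx_fwd = ~use_rev
        if idx_fwd.any():
            ac = unit_labels(int(idx_fwd.sum()))
            akg_codes[idx_fwd] = _FWD[oaa[active[idx_fwd]], ac]
        if use_rev.any():
            m = int(use_rev.sum())
            cl = co2_labels(m)
            scr_rev = (rng.random(m) < 0.5).astype(np.int64)
            akg_codes[use_rev] = _REV[oaa[active[use_rev]], cl, scr_rev]
        oaa[active] = _TURN[akg_codes, scr_turn]
        remaining[active] -= 1

    # --- alpha-ketoglutarate: one more synthesis arc from OAA ------------
    n = n_draws
    use_rev = rng.random(n) < rev
    akg = np.empty(n, dtype=np.int64)
    idx_fwd = ~use_rev
    if idx_fwd.any():
        ac = unit_labels(int(idx_fwd.sum()))
        akg[idx_fwd] = _FWD[oaa[idx_fwd], ac]
    if use_rev.any():
        m = int(use_rev.sum())
        cl = co2_labels(m)
        scr_rev = (rng.random(m) < 0.5).astype(np.int64)
        akg[use_rev] = _REV[oaa[use_rev], cl, scr_rev]

    return {
        "triose": np.bincount(triose, minlength=27) / n_draws,
        "acetyl_coa": np.bincount(accoa, minlength=9) / n_draws,
        "co2": np.bincount(co2_pool, minlength=3) / n_draws,
        "e4p": np.bincount(e4p, minlength=81) / n_draws,
        "oxaloacetate": np.bincount(oaa, minlength=81) / n_draws,
        "alpha_ketoglutarate": np.bincount(akg, minlength=243) / n_draws,
    }


def max_z_score(
    state: PopulationState,
    n_draws: int = 1_000_000,
    seed: int = 0,
) -> float:
    """Largest |frequency - probability| / SE over all precursor patterns.

    SE is the binomial standard error of each pattern's sampled frequency
    (floored at one count to keep rare patterns meaningful).
    """
    from .model import solve_precursor_arrays

    freqs = sample_precursor_patterns(state, n_draws=n_draws, seed=seed)
    probs = solve_precursor_arrays(state)
    worst = 0.0
    for name, p in probs.items():
        f = freqs[name]
        se = np.sqrt(np.clip(p * (1 - p), 0, None) / n_draws)
        se = np.maximum(se, 1.0 / n_draws)
        worst = max(worst, float(np.max(np.abs(f - p) / se)))
    return worst
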