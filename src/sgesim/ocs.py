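"""Optimum-contribution selection under a rate-of-inbreeding constraint.

Dams receive fixed, equal contributions (each selected dam is mated once);
sire contributions are optimized to maximize the average EBV of the next
generation subject to a cap on the group coancestry of the parents,

    x' A x / 2 <= C_t,      C_t = 1 - (1 - dF)^t,

with ``x`` the combined genome-fraction vector of sires and dams and A the
pedigree relationship matrix among the candidates.  The continuous problem
is solved in closed form per active set: for a fixed Lagrange multiplier on
the coancestry constraint the stationarity conditions are linear, the
constraint becomes a quadratic in the inverse multiplier, and sires driven
negative are removed iteratively.  The continuous solution is then rounded
to integer mating counts by largest remainder, re-solving at a slightly
tighter cap if rounding breaks the constraint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

__all__ = ["OCSResult", "preselect", "optimize_contributions", "allocate_matings"]


@dataclass
class OCSResult:
    """Selected sire contributions and solver diagnostics for one round."""

    sire_matings: np.ndarray  # integer counts per candidate sire
    contributions: np.ndarray  # continuous sire genome fractions (sum 1/2)
    constraint_value: float  # achieved x'Ax/2 with the integer counts
    constraint_bound: float
    merit: float  # c' EBV at the continuous solution
    status: str  # "optimal" | "unconstrained" | "infeasible"


def preselect(
    ids: np.ndarray,
    ebv: np.ndarray,
    sex: np.ndarray,
    n_males: int,
    n_females: int,
) -> tuple[np.ndarray, np.ndarray]:
    """EBV truncation pre-selection ahead of the OCS optimization.

    Returns the ids of the top ``n_males`` males and ``n_females`` females
    by EBV.  Ties are broken by id, so the result is deterministic.
    """
    ids = np.asarray(ids)
    ebv = np.asarray(ebv, dtype=float)
    sex = np.asarray(sex)
    out = []
    for s, k in ((0, n_males), (1, n_females)):
        mask = sex == s
        if mask.sum() < k:
            raise ValueError(
                f"requested {k} of sex {s} but only {int(mask.sum())} candidates"
            )
        cand_ids = ids[mask]
        cand_ebv = ebv[mask]
        order = np.lexsort((cand_ids, -cand_ebv))
        out.append(cand_ids[order[:k]])
    return out[0], out[1]


def _continuous_solution(
    ebv: np.ndarray,
    a_ss: np.ndarray,
    a_sd_d: np.ndarray,
    dam_term: float,
    constraint: float,
) -> tuple[np.ndarray, str]:
    """Merit-maximal sire contributions at the coancestry cap.

    Returns the contribution vector (summing to 1/2) and a status tag.
    """
    ns = ebv.size

    def coancestry(c: np.ndarray) -> float:
        return 0.5 * (c @ a_ss @ c) + c @ a_sd_d + 0.5 * dam_term

    # Unconstrained optimum: all matings to the single top sire.
    top = int(np.lexsort((np.arange(ns), -ebv))[0])
    vertex = np.zeros(ns)
    vertex[top] = 0.5
    if coancestry(vertex) <= constraint + 1e-12:
        return vertex, "unconstrained"

    active = np.arange(ns)
    for _ in range(4 * ns + 4):
        g = ebv[active]
        asb = a_ss[np.ix_(active, active)]
        rhs_d = a_sd_d[active]
        cf = sla.cho_factor(asb)
        p = sla.cho_solve(cf, g)
        q = sla.cho_solve(cf, np.ones(active.size))
        r = sla.cho_solve(cf, rhs_d)
        alpha = p.sum() / q.sum()
        beta = (0.5 + r.sum()) / q.sum()
        a_vec = p - alpha * q  # 1'a = 0
        b_vec = beta * q - r  # 1'b = 1/2; b is the min-coancestry point
        # coancestry(a t + b) = k2 t^2 + k1 t + k0 with t = 1/lambda >= 0
        k2 = 0.5 * (a_vec @ asb @ a_vec)
        k1 = a_vec @ asb @ b_vec + a_vec @ rhs_d
        k0 = 0.5 * (b_vec @ asb @ b_vec) + b_vec @ rhs_d + 0.5 * dam_term
        if k0 >= constraint - 1e-14:
            # even the minimum-coancestry solution violates the cap
            c_min = np.zeros(ns)
            c_min[active] = np.clip(b_vec, 0.0, None)
            if c_min.sum() > 0:
                c_min *= 0.5 / c_min.sum()
            return c_min, "infeasible"
        if k2 <= 0:
            t = 0.0
        else:
            disc = k1 * k1 - 4.0 * k2 * (k0 - constraint)
            t = (-k1 + np.sqrt(max(disc, 0.0))) / (2.0 * k2)
            t = max(t, 0.0)
        c_act = a_vec * t + b_vec
        if np.any(c_act < -1e-12):
            active = active[c_act > -1e-12]
            if active.size == 1:
                c_opt = np.zeros(ns)
                c_opt[active] = 0.5
                return c_opt, "optimal"
            continue
        # KKT check for excluded sires: re-admit any whose reduced gradient
        # is positive (a sire dropped early may belong in the optimum)
        lam = 1.0 / t if t > 0 else np.inf
        mu = np.mean(g - lam * (asb @ c_act + rhs_d)) if np.isfinite(lam) else None
        excluded = np.setdiff1d(np.arange(ns), active)
        if excluded.size and np.isfinite(lam):
            grad = (
                ebv[excluded]
                - lam * (a_ss[np.ix_(excluded, active)] @ c_act + a_sd_d[excluded])
                - mu
            )
            worst = np.argmax(grad)
            if grad[worst] > 1e-10:
                active = np.sort(np.append(active, excluded[worst]))
                continue
        c_opt = np.zeros(ns)
        c_opt[active] = np.clip(c_act, 0.0, None)
        s = c_opt.sum()
        if s > 0:
            c_opt *= 0.5 / s
        return c_opt, "optimal"
    # cycling safeguard: return the best feasible point found
    c_opt = np.zeros(ns)
    c_opt[active] = np.clip(c_act, 0.0, None)
    s = c_opt.sum()
    if s > 0:
        c_opt *= 0.5 / s
    return c_opt, "optimal"


def optimize_contributions(
    ebv: np.ndarray,
    a_candidates: np.ndarray,
    n_sires: int,
    constraint: float,
    n_matings: int,
    jitter: float = 1e-10,
) -> OCSResult:
    """Optimize sire contributions with dams fixed at equal contributions.

    ``a_candidates`` is the relationship matrix over the shortlist with the
    ``n_sires`` candidate sires first and the selected dams after; ``ebv``
    aligns with the sires.  ``constraint`` is the group-coancestry cap
    ``C_t``; the achieved integer-mating coancestry never exceeds it except
    in the flagged infeasible case.
    """
    ebv = np.asarray(ebv, dtype=float)
    ns = n_sires
    nd = a_candidates.shape[0] - ns
    if ebv.size != ns or nd <= 0:
        raise ValueError("EBV must align with the sire block of A")
    a_ss = a_candidates[:ns, :ns] + jitter * np.eye(ns)
    a_sd = a_candidates[:ns, ns:]
    a_dd = a_candidates[ns:, ns:]
    d = np.full(nd, 0.5 / nd)  # fixed equal dam contributions
    a_sd_d = a_sd @ d
    dam_term = d @ a_dd @ d

    def coancestry(c: np.ndarray) -> float:
        return 0.5 * (c @ a_ss @ c) + c @ a_sd_d + 0.5 * dam_term

    c_opt, status = _continuous_solution(ebv, a_ss, a_sd_d, dam_term, constraint)
    matings = _largest_remainder(c_opt, n_matings)
    if status != "infeasible":
        cap = constraint
        c_round = c_opt
        for _ in range(20):
            x = matings / (2.0 * n_matings)
            if coancestry(x) <= constraint + 1e-8:
                break
            cap *= 0.998  # rounding overshoot: re-tighten and re-round
            c_round, st = _continuous_solution(ebv, a_ss, a_sd_d, dam_term, cap)
            if st == "infeasible":
                break
            matings = _largest_remainder(c_round, n_matings)
    x = matings / (2.0 * n_matings)
    return OCSResult(
        sire_matings=matings,
        contributions=c_opt,
        constraint_value=float(coancestry(x)),
        constraint_bound=float(constraint),
        merit=float(c_opt @ ebv),
        status=status,
    )


def _largest_remainder(contributions: np.ndarray, n_matings: int) -> np.ndarray:
    """Integer mating counts proportional to contributions (sum preserved)."""
    raw = contributions * 2.0 * n_matings
    base = np.floor(raw + 1e-12).astype(int)
    short = n_matings - base.sum()
    if short > 0:
        frac = raw - base
        order = np.lexsort((np.arange(raw.size), -frac))
        base[order[:short]] += 1
    elif short < 0:
        order = np.lexsort((np.arange(raw.size), -base))
        for i in order[: -short]:
            base[i] -= 1
    return base


def allocate_matings(
    sire_ids: np.ndarray,
    sire_matings: np.ndarray,
    dam_ids: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Random pairing of dams to sires given integer mating counts.

    Each dam appears exactly once; each sire appears as often as its mating
    count.  The pairing is a seeded random permutation, so reruns with the
    same generator state reproduce the list exactly.
    """
    sire_ids = np.asarray(sire_ids)
    sire_matings = np.asarray(sire_matings)
    dam_ids = np.asarray(dam_ids)
    if sire_matings.sum() != dam_ids.size:
        raise ValueError("sire matings must sum to the number of dams")
    slots = np.repeat(sire_ids, sire_matings)
    dams = rng.permutation(dam_ids)
    return [(int(s), int(d)) for s, d in zip(slots, dams)]
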