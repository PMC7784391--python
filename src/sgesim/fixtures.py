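"""Deterministic micro-instances for exercising every stage in isolation.

Each fixture is generated programmatically from a frozen seed (no stored
data); regenerating with the same seed is bit-identical.  Expected outputs,
where the fixture carries any, come from independent closed-form oracles
(direct inversion, ANOVA estimators), not from the code paths under test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sgesim.grouping import assign_random
from sgesim.traits import VarianceComponents, simulate_phenotypes

__all__ = ["Fixture", "make_fixture", "list_fixtures"]


@dataclass
class Fixture:
    name: str
    inputs: dict
    expected: dict = field(default_factory=dict)
    tolerance: float = 1e-10


def _trio_pedigree(seed: int) -> Fixture:
    """Two unrelated founders and their offspring.

    The relationship matrix and its inverse are textbook: parent-offspring
    relationship 1/2, inverse diagonal (1.5, 1.5, 2) with off-diagonals
    (0.5, -1).
    """
    sire = np.array([-1, -1, 0])
    dam = np.array([-1, -1, 1])
    a = np.array([[1.0, 0.0, 0.5], [0.0, 1.0, 0.5], [0.5, 0.5, 1.0]])
    a_inv = np.linalg.inv(a)  # independent oracle: direct dense inversion
    return Fixture(
        name="trio_pedigree",
        inputs={"sire": sire, "dam": dam},
        expected={"A": a, "A_inv": a_inv},
    )


def _two_pens_model1(seed: int) -> Fixture:
    """24 animals in 2 pens of 12 and 4 litters of 6, with phenotype
    components retained for the decomposition audit."""
    rng = np.random.default_rng(seed)
    n = 24
    u_d = rng.normal(0, 1, n)
    u_s = rng.normal(0, 0.1, n)
    litter = np.repeat(np.arange(4), 6)
    pens = assign_random(np.arange(n), 12, rng)
    vc = VarianceComponents.sgm(sigma2_s=0.01, r_ds=0.0)
    ph = simulate_phenotypes(u_d, u_s, pens.pen_of, litter, vc, rng, 12)
    return Fixture(
        name="two_pens_model1",
        inputs={"u_d": u_d, "u_s": u_s, "pens": pens, "litter": litter,
                "vc": vc, "phenotypes": ph},
    )


def _ocs_grid40(seed: int) -> Fixture:
    """40 candidate sires and 40 dams with a pedigree-derived relationship
    matrix and random EBV; the merit oracle is a fine Lagrangian grid search
    run by the consuming test."""
    rng = np.random.default_rng(seed)
    n_parents = 20
    sires_p = rng.integers(0, n_parents // 2, size=80)
    dams_p = rng.integers(n_parents // 2, n_parents, size=80)
    sire = np.concatenate([np.full(n_parents, -1), sires_p])
    dam = np.concatenate([np.full(n_parents, -1), dams_p])
    from sgesim.relationships import build_A

    a = build_A(sire, dam)
    cand = np.arange(n_parents, n_parents + 80)
    a_cand = a[np.ix_(cand, cand)]
    ebv = rng.normal(0, 1, 40)
    return Fixture(
        name="ocs_grid40",
        inputs={"ebv": ebv, "A": a_cand, "n_sires": 40,
                "constraint": 0.08, "n_matings": 40},
        tolerance=1e-6,
    )


def _balanced_oneway(seed: int) -> Fixture:
    """Balanced one-way layout (pens only): y = mu + pen + e.

    The expected REML estimates are the closed-form ANOVA values
    ``s2_e = MSW`` and ``s2_pen = (MSB - MSW) / n`` — REML and ANOVA
    coincide in balanced designs.
    """
    rng = np.random.default_rng(seed)
    n_pens, n_per = 40, 8
    pen_eff = rng.normal(0, np.sqrt(0.5), n_pens)
    y = (2.0 + np.repeat(pen_eff, n_per) + rng.normal(0, 1.0, n_pens * n_per))
    pen = np.repeat(np.arange(n_pens), n_per)
    groups = y.reshape(n_pens, n_per)
    msw = float(np.sum((groups - groups.mean(1, keepdims=True)) ** 2)
                / (n_pens * (n_per - 1)))
    msb = float(n_per * np.sum((groups.mean(1) - y.mean()) ** 2) / (n_pens - 1))
    return Fixture(
        name="balanced_oneway",
        inputs={"y": y, "pen": pen, "n_per": n_per},
        expected={"var_pen": (msb - msw) / n_per, "var_residual": msw},
        tolerance=1e-5,
    )


_REGISTRY = {
    "trio_pedigree": _trio_pedigree,
    "two_pens_model1": _two_pens_model1,
    "ocs_grid40": _ocs_grid40,
    "balanced_oneway": _balanced_oneway,
}


def list_fixtures() -> list[str]:
    return sorted(_REGISTRY)


def make_fixture(name: str, seed: int = 0) -> Fixture:
    if name not in _REGISTRY:
        raise KeyError(f"unknown fixture {name!r}; have {list_fixtures()}")
    return _REGISTRY[name](seed)
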