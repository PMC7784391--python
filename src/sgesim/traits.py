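"""Variance components and phenotype simulation for the social animal model.

A phenotype is the animal's own direct genetic effect, plus the sum of the
social genetic effects of its pen mates, plus random pen, litter and
residual terms:

    y_i = u_D(i) + sum_{j in pen(i), j != i} u_S(j) + c_pen + c_litter + e_i

Group size is constant, so a separate social *environmental* effect would be
completely confounded with the pen effect and is not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["VarianceComponents", "simulate_phenotypes"]

SGM = "sgm"
CGM = "cgm"


@dataclass(frozen=True)
class VarianceComponents:
    """(Co)variance parameter set for the social (SGM) or classical (CGM) model.

    For SGM the genetic part is the 2x2 matrix of the direct variance,
    direct-social covariance and social variance.  For CGM the same slots
    hold the primed single-genetic-effect analogues and the social terms are
    absent (zero).
    """

    model: str
    var_dge: float
    var_sge: float = 0.0
    cov_dge_sge: float = 0.0
    var_pen: float = 0.25
    var_litter: float = 0.25
    var_residual: float = 2.5

    def __post_init__(self) -> None:
        if self.model not in (SGM, CGM):
            raise ValueError(f"unknown model tag {self.model!r}")
        if self.model == CGM and (self.var_sge != 0.0 or self.cov_dge_sge != 0.0):
            raise ValueError("CGM has no social genetic terms")
        for name in ("var_dge", "var_sge", "var_pen", "var_litter", "var_residual"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        bound = np.sqrt(self.var_dge * self.var_sge)
        if abs(self.cov_dge_sge) > bound + 1e-12:
            raise ValueError("genetic covariance exceeds Cauchy-Schwarz bound")

    @classmethod
    def sgm(
        cls,
        sigma2_s: float,
        r_ds: float,
        sigma2_d: float = 1.0,
        var_pen: float = 0.25,
        var_litter: float = 0.25,
        var_residual: float = 2.5,
    ) -> "VarianceComponents":
        """SGM components from the social variance and the DGE-SGE correlation."""
        return cls(
            model=SGM,
            var_dge=sigma2_d,
            var_sge=sigma2_s,
            cov_dge_sge=r_ds * np.sqrt(sigma2_d * sigma2_s),
            var_pen=var_pen,
            var_litter=var_litter,
            var_residual=var_residual,
        )

    def genetic_matrix(self) -> np.ndarray:
        """2x2 genetic covariance matrix (SGM) or 1x1 (CGM)."""
        if self.model == CGM:
            return np.array([[self.var_dge]])
        return np.array(
            [
                [self.var_dge, self.cov_dge_sge],
                [self.cov_dge_sge, self.var_sge],
            ]
        )

    def correlation(self) -> float:
        b = np.sqrt(self.var_dge * self.var_sge)
        return 0.0 if b == 0 else self.cov_dge_sge / b


def simulate_phenotypes(
    u_d: np.ndarray,
    u_s: np.ndarray,
    pen: np.ndarray,
    litter: np.ndarray,
    vc: VarianceComponents,
    rng: np.random.Generator,
    group_size: int,
    generation: int = 0,
    ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate phenotypes for one cohort under the social model.

    Returns one record per animal with the phenotype ``y`` and every
    component retained (``dge``, ``social``, ``pen_effect``,
    ``litter_effect``, ``residual``) so their sum reproduces ``y``
    bit-exactly.  Pen and litter effects are drawn once per level; the
    residual once per animal; all mutually independent.
    """
    if vc.model != SGM:
        raise ValueError("phenotypes are simulated under the social model")
    u_d = np.asarray(u_d, dtype=float)
    u_s = np.asarray(u_s, dtype=float)
    pen = np.asarray(pen)
    litter = np.asarray(litter)
    n = u_d.size
    if not (u_s.size == pen.size == litter.size == n):
        raise ValueError("per-animal arrays must align")
    pen_codes, pen_idx = np.unique(pen, return_inverse=True)
    counts = np.bincount(pen_idx)
    if np.any(counts != group_size):
        raise ValueError(
            f"every pen must have exactly {group_size} members; "
            f"got sizes {sorted(set(counts.tolist()))}"
        )
    # social sum: pen total minus the animal's own SGE (self never contributes)
    pen_sum = np.bincount(pen_idx, weights=u_s)
    social = pen_sum[pen_idx] - u_s

    lit_codes, lit_idx = np.unique(litter, return_inverse=True)
    pen_eff = rng.normal(0.0, np.sqrt(vc.var_pen), size=pen_codes.size)
    lit_eff = rng.normal(0.0, np.sqrt(vc.var_litter), size=lit_codes.size)
    resid = rng.normal(0.0, np.sqrt(vc.var_residual), size=n)

    df = pd.DataFrame(
        {
            "id": np.arange(n) if ids is None else np.asarray(ids),
            "generation": generation,
            "pen": pen,
            "litter": litter,
            "dge": u_d,
            "social": social,
            "pen_effect": pen_eff[pen_idx],
            "litter_effect": lit_eff[lit_idx],
            "residual": resid,
        }
    )
    df["y"] = (
        df["dge"]
        + df["social"]
        + df["pen_effect"]
        + df["litter_effect"]
        + df["residual"]
    )
    return df
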