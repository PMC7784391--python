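"""Reported statistics: response, inbreeding rates, accuracy, bias,
bootstrap design comparison and the closed-form analytic panel.

The analytic quantities are exact consequences of the trait model:

* total heritable variation  sigma2_TBV = s2_D + 2(n-1) s_DS + (n-1)^2 s2_S,
* the classical-model equivalents when the social model is the truth,
  s2_D' = s2_D - 2 s_DS + s2_S   and   s2_pen' = s2_pen + 2 s_DS + (n-2) s2_S,
* the SGE share of phenotypic variance for unrelated pen mates,
  (n-1)^2 s2_S / (s2_D + (n-1) s2_S + s2_pen + s2_litter + s2_e),
* expected within-pen additive relationships from pair-type probabilities
  under the nucleus mating design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sgesim.mixed_models import SCHEME_SGM_TBV
from sgesim.traits import VarianceComponents

__all__ = [
    "MetricsReport",
    "response_to_selection",
    "delta_f",
    "accuracy_and_bias",
    "bootstrap_group_comparison",
    "analytic_tbv_variance",
    "analytic_cgm_equivalents",
    "analytic_sge_phenotypic_ratio",
    "expected_group_relationship",
    "summarize_replicates",
]


def response_to_selection(mean_y_by_generation: dict[int, float]) -> float:
    """Per-generation response: (mean y at final generation - at 3) / span."""
    gens = sorted(g for g in mean_y_by_generation if g >= 3)
    if len(gens) < 2:
        raise ValueError("need phenotype means for generation 3 and a later one")
    t0, t1 = gens[0], gens[-1]
    if t0 != 3:
        raise ValueError("response is anchored at generation 3")
    return (mean_y_by_generation[t1] - mean_y_by_generation[t0]) / (t1 - t0)


def delta_f(
    mean_f_by_generation: dict[int, float],
    generations: list[int] | None = None,
) -> float:
    """Rate of inbreeding in percent per generation.

    Ordinary least squares of ``ln(1 - mean F_t)`` on ``t`` over the chosen
    generations; the rate is ``(1 - exp(slope)) * 100``.
    """
    if generations is None:
        generations = sorted(g for g in mean_f_by_generation if g >= 3)
    if len(generations) < 2:
        raise ValueError("need at least two generations")
    t = np.array(generations, dtype=float)
    z = np.log1p(-np.array([mean_f_by_generation[g] for g in generations]))
    slope = np.polyfit(t, z, 1)[0]
    return float((1.0 - np.exp(slope)) * 100.0)


def _slope(true: np.ndarray, pred: np.ndarray) -> float:
    """OLS regression coefficient of true on predicted (with intercept)."""
    v = np.var(pred, ddof=1)
    if v == 0:
        return np.nan
    return float(np.cov(true, pred)[0, 1] / v)


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def accuracy_and_bias(
    u_tbv: np.ndarray,
    u_d: np.ndarray,
    u_s: np.ndarray,
    ebv: np.ndarray,
    u_d_hat: np.ndarray,
    u_s_hat: np.ndarray | None,
    scheme: str,
) -> dict[str, float]:
    """Accuracies (correlations) and biases (slopes of true on predicted).

    The selection-criterion accuracy (GESC) is the correlation of the
    scheme EBV with the true total breeding value; direct accuracy compares
    predicted and true DGE; social accuracy is reported for the TBV scheme
    only, where SGE enter selection.
    """
    out = {
        "acc_gesc": _corr(ebv, u_tbv),
        "bias_gesc": _slope(u_tbv, ebv),
        "acc_dge": _corr(u_d_hat, u_d),
        "bias_dge": _slope(u_d, u_d_hat),
    }
    if scheme == SCHEME_SGM_TBV and u_s_hat is not None:
        out["acc_sge"] = _corr(u_s_hat, u_s)
        out["bias_sge"] = _slope(u_s, u_s_hat)
    else:
        out["acc_sge"] = np.nan
        out["bias_sge"] = np.nan
    return out


def bootstrap_group_comparison(
    rs_fam_a,
    rs_ran_a,
    rs_fam_g,
    rs_ran_g,
    n_rounds: int = 5000,
    sample_size: int | None = None,
    seed: int | np.random.Generator = 0,
) -> dict[str, float]:
    """Bootstrap comparison of the family/random response ratio for A vs G.

    Per round, each cell is resampled with replacement (sample size defaults
    to the cell's replicate count), cell means are formed, and
    ``delta = (fam_A / ran_A) - (fam_G / ran_G)`` is recorded.  Reports the
    mean of the two ratios over rounds and the percentage of rounds with
    ``delta > 0``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cells = [np.asarray(c, dtype=float) for c in (rs_fam_a, rs_ran_a, rs_fam_g, rs_ran_g)]
    ratios_a = np.empty(n_rounds)
    ratios_g = np.empty(n_rounds)
    for b in range(n_rounds):
        means = [
            np.mean(rng.choice(c, size=sample_size or c.size, replace=True))
            for c in cells
        ]
        ratios_a[b] = means[0] / means[1]
        ratios_g[b] = means[2] / means[3]
    delta = ratios_a - ratios_g
    return {
        "d_a_mean": float(ratios_a.mean()),
        "d_g_mean": float(ratios_g.mean()),
        "pct_positive": float(np.mean(delta > 0) * 100.0),
    }


# ---------------------------------------------------------------------------
# analytic panel


def analytic_tbv_variance(
    sigma2_d: float, sigma2_s: float, r_ds: float, n: int
) -> float:
    """Total heritable variation of a group-housed trait."""
    cov = r_ds * np.sqrt(sigma2_d * sigma2_s)
    return float(sigma2_d + 2 * (n - 1) * cov + (n - 1) ** 2 * sigma2_s)


def analytic_cgm_equivalents(vc: VarianceComponents, n: int) -> tuple[float, float]:
    """Classical-model genetic and pen variances implied by a social truth."""
    s2d = vc.var_dge - 2 * vc.cov_dge_sge + vc.var_sge
    s2p = vc.var_pen + 2 * vc.cov_dge_sge + (n - 2) * vc.var_sge
    return float(s2d), float(s2p)


def analytic_sge_phenotypic_ratio(vc: VarianceComponents, n: int) -> float:
    """Share of phenotypic variance due to SGE, unrelated pen mates."""
    s2p = (
        vc.var_dge
        + (n - 1) * vc.var_sge
        + vc.var_pen
        + vc.var_litter
        + vc.var_residual
    )
    return float((n - 1) ** 2 * vc.var_sge / s2p)


def expected_group_relationship(
    design: str,
    n_sires: int,
    n_dams: int,
    litter_size: int = 6,
    pen_size: int = 12,
    method: str = "analytic",
    n_pens: int = 10000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Expected mean pairwise additive relationship within a pen.

    Parents are unrelated and non-inbred, each sire serves
    ``n_dams / n_sires`` dams, each dam has one litter of ``litter_size``,
    so full sibs are related by 0.5 and paternal half sibs by 0.25.
    ``analytic`` evaluates the pair-type expectation; ``mc`` draws pens
    from a simulated offspring population and averages realized pairs.
    """
    dps = n_dams // n_sires
    if design == "random":
        if method == "analytic":
            n_off = n_dams * litter_size
            p_fs = (litter_size - 1) / (n_off - 1)
            p_hs = litter_size * (dps - 1) / (n_off - 1)
            return float(0.5 * p_fs + 0.25 * p_hs)
    elif design == "four_families":
        if method == "analytic":
            k = pen_size // 4
            fs_pairs = 4 * k * (k - 1) / 2
            total_pairs = pen_size * (pen_size - 1) / 2
            cross = total_pairs - fs_pairs
            p_same_sire = (dps - 1) / (n_dams - 1)
            return float((fs_pairs * 0.5 + cross * 0.25 * p_same_sire) / total_pairs)
    else:
        raise ValueError(f"unknown design {design!r}")

    if method != "mc":
        raise ValueError("method must be 'analytic' or 'mc'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dam_ids = np.arange(n_dams)
    sire_of_dam = dam_ids // dps
    total = 0.0
    count = 0
    if design == "random":
        off_dam = np.repeat(dam_ids, litter_size)
        n_off = off_dam.size
        for _ in range(n_pens):
            pick = rng.choice(n_off, size=pen_size, replace=False)
            dams = off_dam[pick]
            sires = sire_of_dam[dams]
            same_dam = dams[:, None] == dams[None, :]
            same_sire = sires[:, None] == sires[None, :]
            rel = 0.25 * same_sire + 0.25 * same_dam
            iu = np.triu_indices(pen_size, 1)
            total += rel[iu].sum()
            count += iu[0].size
    else:
        k = pen_size // 4
        for _ in range(n_pens):
            litters = rng.choice(n_dams, size=4, replace=False)
            dams = np.repeat(litters, k)
            sires = sire_of_dam[dams]
            same_dam = dams[:, None] == dams[None, :]
            same_sire = sires[:, None] == sires[None, :]
            rel = 0.25 * same_sire + 0.25 * same_dam
            iu = np.triu_indices(pen_size, 1)
            total += rel[iu].sum()
            count += iu[0].size
    return float(total / count)


# ---------------------------------------------------------------------------
# replicate aggregation


@dataclass
class MetricsReport:
    """Per-replicate statistics and their aggregates for one scenario."""

    replicates: pd.DataFrame
    summary: dict[str, float]
    analytic: dict[str, float]
    config: object | None = None

    def to_csv(self, path) -> None:
        self.replicates.to_csv(path, index=False)


def summarize_replicates(reps: list) -> MetricsReport:
    """Aggregate a scenario's replicate set into a metrics report."""
    rows = []
    for rep in reps:
        cfg = rep.config
        my = rep.mean_phenotype_by_generation()
        row = {"replicate": rep.replicate}
        try:
            row["rs"] = response_to_selection(my)
        except ValueError:
            row["rs"] = np.nan
        ft = rep.mean_true_inbreeding_by_generation()
        fp = rep.mean_pedigree_inbreeding_by_generation()
        gens = sorted(g for g in ft if g >= 3)
        if len(gens) >= 2:
            row["delta_f_true_pct"] = delta_f(ft, gens)
            row["delta_f_ped_pct"] = delta_f(fp, gens)
        if 4 in rep.ebv_by_generation:
            pop = rep.population
            idx = pop.cohort(4)
            df = rep.ebv_by_generation[4].data.set_index("animal").loc[idx]
            ab = accuracy_and_bias(
                pop.u_tbv[idx], pop.u_d[idx], pop.u_s[idx],
                df["ebv"].to_numpy(), df["u_d"].to_numpy(),
                df["u_s"].to_numpy() if not df["u_s"].isna().all() else None,
                cfg.scheme,
            )
            row.update(ab)
        if rep.reml_result is not None and rep.reml_result.vc is not None:
            for k, v in rep.reml_result.theta.items():
                row[f"reml_{k}"] = v
            row["reml_converged"] = rep.reml_result.converged
        rows.append(row)
    df = pd.DataFrame(rows)
    summary: dict[str, float] = {}
    for col in df.columns:
        if col == "replicate" or df[col].dtype == object:
            continue
        vals = df[col].astype(float).dropna()
        if len(vals):
            summary[f"{col}_mean"] = float(vals.mean())
            summary[f"{col}_se"] = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan

    analytic = {}
    if reps:
        cfg = reps[0].config
        n = cfg.scale.pen_size
        vc = cfg.true_vc
        analytic["sigma2_tbv"] = analytic_tbv_variance(
            cfg.sigma2_d, cfg.sigma2_s, cfg.r_ds, n
        )
        s2d, s2p = analytic_cgm_equivalents(vc, n)
        analytic["sigma2_dge_cgm"] = s2d
        analytic["sigma2_pen_cgm"] = s2p
        analytic["sge_phenotypic_ratio"] = analytic_sge_phenotypic_ratio(vc, n)
        analytic["expected_rel_random"] = expected_group_relationship(
            "random", cfg.scale.n_sires, cfg.scale.n_dams,
            cfg.scale.litter_size, n,
        )
        analytic["expected_rel_four_families"] = expected_group_relationship(
            "four_families", cfg.scale.n_sires, cfg.scale.n_dams,
            cfg.scale.litter_size, n,
        )
    return MetricsReport(
        replicates=df,
        summary=summary,
        analytic=analytic,
        config=reps[0].config if reps else None,
    )
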