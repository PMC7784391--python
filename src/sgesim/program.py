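"""The generation loop: simulate one replicate or a whole scenario.

A replicate runs a closed nucleus for ``n_generations`` discrete
generations.  Generation 1 is the founder parent cohort (unrelated,
non-inbred pedigree founders).  Their offspring form generation 2; parents
of generation 3 are drawn at random from generation 2.  From generation 3
onward each cohort is evaluated by BLUP (cumulative data from generation 2
up to the current one), candidates are pre-selected on EBV, sire
contributions are optimized under the pedigree coancestry constraint, and
matings are allocated at random given the optimized counts.  Variance
components are either the simulation truth or a single pedigree AI-REML
estimate obtained at generation 3 and reused afterwards.

Random streams are keyed by (master seed, replicate, purpose, generation).
With the common-random-numbers option the keys are identical across
scenarios, so trait, meiosis and grouping draws coincide until selection
decisions make the populations diverge; EBV-dependent steps use their own
streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sgesim.config import ScenarioConfig
from sgesim.genome import (
    HaplotypeSet,
    make_offspring,
    sample_raw_effects,
    scale_qtl_effects,
    simulate_founders,
    true_genetic_values,
)
from sgesim.grouping import assign_four_families, assign_random
from sgesim.mixed_models import EBVSet, build_mme, extract_ebv, solve_pcg
from sgesim.ocs import allocate_matings, optimize_contributions, preselect
from sgesim.relationships import build_A_inverse, build_G, extend_A
from sgesim.reml import REMLResult, choose_vc, fit_reml
from sgesim.traits import simulate_phenotypes, CGM

__all__ = ["PopulationState", "ReplicateResult", "run_replicate", "run_scenario"]

# stream purpose tags for seed derivation
_S_FOUNDER, _S_EFFECTS, _S_MEIOSIS, _S_TRAIT, _S_GROUP, _S_SELECT, _S_MATE, _S_REML = range(8)


@dataclass
class PopulationState:
    """Pedigree, genomes, true effects and phenotypes accumulated so far."""

    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray
    generation: np.ndarray
    litter: np.ndarray
    pen: np.ndarray
    u_d: np.ndarray
    u_s: np.ndarray
    u_tbv: np.ndarray
    f_true: np.ndarray
    a_matrix: np.ndarray
    phenotypes: pd.DataFrame
    haplotypes: HaplotypeSet | None = None
    marker_dosage: np.ndarray | None = None

    @property
    def n_animals(self) -> int:
        return self.sire.size

    def cohort(self, t: int) -> np.ndarray:
        return np.flatnonzero(self.generation == t)

    def pedigree_inbreeding(self) -> np.ndarray:
        return np.diag(self.a_matrix) - 1.0

    def to_table(self) -> pd.DataFrame:
        """Pedigree/phenotype table (one row per animal, NaN y if unrecorded)."""
        df = pd.DataFrame(
            {
                "id": np.arange(self.n_animals),
                "sire": self.sire,
                "dam": self.dam,
                "sex": self.sex,
                "generation": self.generation,
                "litter": self.litter,
                "pen": self.pen,
            }
        )
        y = self.phenotypes.set_index("animal")["y"] if len(self.phenotypes) else pd.Series(dtype=float)
        df["y"] = df["id"].map(y)
        return df


@dataclass
class ReplicateResult:
    """Everything one replicate produces."""

    config: ScenarioConfig
    replicate: int
    population: PopulationState
    ebv_by_generation: dict[int, EBVSet]
    reml_result: REMLResult | None
    generation_log: pd.DataFrame
    ocs_log: pd.DataFrame

    def mean_phenotype_by_generation(self) -> dict[int, float]:
        g = self.population.phenotypes.groupby("generation")["y"].mean()
        return {int(k): float(v) for k, v in g.items()}

    def mean_true_inbreeding_by_generation(self) -> dict[int, float]:
        out = {}
        for t in np.unique(self.population.generation):
            idx = self.population.cohort(int(t))
            out[int(t)] = float(np.mean(self.population.f_true[idx]))
        return out

    def mean_pedigree_inbreeding_by_generation(self) -> dict[int, float]:
        f = self.population.pedigree_inbreeding()
        out = {}
        for t in np.unique(self.population.generation):
            idx = self.population.cohort(int(t))
            out[int(t)] = float(np.mean(f[idx]))
        return out


def _stream(config: ScenarioConfig, replicate: int, purpose: int, t: int = 0,
            ebv_dependent: bool = False) -> np.random.Generator:
    """Deterministic, platform-stable random stream.

    Scheme-independent streams share keys across scenarios when common
    random numbers are requested; all other streams (and all streams when
    CRN is off) additionally key on the scenario cell.
    """
    key = [int(config.seed) & 0x7FFFFFFF, replicate, purpose, t]
    if ebv_dependent or not config.common_random_numbers:
        desc = f"{config.scheme}|{config.relationship}|{config.sigma2_s}|" \
               f"{config.r_ds}|{config.grouping}|{config.vc_mode}"
        key.append(zlib.crc32(desc.encode()) & 0x7FFFFFFF)
    return np.random.default_rng(np.random.SeedSequence(key))


def _constraint_bound(delta_f: float, t: int) -> float:
    """Group-coancestry cap at selection time t (founders are generation 1)."""
    return 1.0 - (1.0 - delta_f) ** t


def run_replicate(
    config: ScenarioConfig,
    replicate: int = 0,
    reml_cache: dict | None = None,
) -> ReplicateResult:
    """Run one replicate.

    ``reml_cache`` is an optional dict keyed by (replicate, model).  Under
    common random numbers, scenarios that differ only in scheme share
    identical data up to generation 3, so the generation-3 REML fit can be
    reused across paired runs; the caller is responsible for only sharing a
    cache between scenarios whose early generations coincide.
    """
    sc = config.scale
    spec = config.genome_spec()
    ns, nd = sc.n_sires, sc.n_dams
    n_found = ns + nd
    group = sc.pen_size
    lit = sc.litter_size

    rng_f = _stream(config, replicate, _S_FOUNDER)
    haplo = simulate_founders(spec, n_found, rng_f)
    target = config.true_vc.genetic_matrix()
    raw = sample_raw_effects(spec.n_qtl, target, _stream(config, replicate, _S_EFFECTS))
    effects = scale_qtl_effects(raw, haplo.dosage(spec.qtl_indices), target)

    # founder pedigree block: generation 1, unknown parents
    sire = np.full(n_found, -1, dtype=np.int64)
    dam = np.full(n_found, -1, dtype=np.int64)
    sex = np.concatenate([np.zeros(ns, dtype=np.int64), np.ones(nd, dtype=np.int64)])
    generation = np.ones(n_found, dtype=np.int64)
    litter = np.full(n_found, -1, dtype=np.int64)
    pen = np.full(n_found, -1, dtype=np.int64)
    u_d, u_s, u_tbv = true_genetic_values(haplo.dosage(spec.qtl_indices), effects, group)
    f_true = haplo.true_inbreeding()
    a = extend_A(np.zeros((0, 0)), sire, dam)
    base_freq = haplo.dosage().mean(axis=0) / 2.0

    phenotypes: list[pd.DataFrame] = []
    ebv_by_generation: dict[int, EBVSet] = {}
    reml_result: REMLResult | None = None
    gen_rows: list[dict] = []
    ocs_rows: list[dict] = []
    pen_offset = 0

    # next mating plan: arrays of pedigree indices, one entry per mating
    founder_dams = np.arange(ns, n_found)
    rng_sel = _stream(config, replicate, _S_SELECT, 1)
    dam_order = rng_sel.permutation(founder_dams)
    mating_sires = np.repeat(np.arange(ns), sc.dams_per_sire)
    mating_dams = dam_order

    for t in range(2, sc.n_generations + 1):
        # --- reproduce -------------------------------------------------
        off_sire = np.repeat(mating_sires, lit)
        off_dam = np.repeat(mating_dams, lit)
        rng_mei = _stream(config, replicate, _S_MEIOSIS, t)
        off_haplo = make_offspring(haplo, off_sire, off_dam, spec, rng_mei)
        n_off = off_sire.size
        off_sex = np.tile(
            np.concatenate([np.zeros(lit // 2, np.int64), np.ones(lit // 2, np.int64)]),
            mating_sires.size,
        )
        off_litter = off_dam.copy()  # one litter per dam per generation
        start = sire.size
        idx_off = np.arange(start, start + n_off)

        # --- pens ------------------------------------------------------
        rng_grp = _stream(config, replicate, _S_GROUP, t)
        if config.grouping == "random":
            pens = assign_random(idx_off, group, rng_grp)
        else:
            pens = assign_four_families(
                idx_off, off_litter, off_sex, rng_grp, litter_size=lit, pen_size=group
            )
        off_pen = pens.pen_of + pen_offset
        pen_offset += pens.n_pens

        # --- truth and phenotypes --------------------------------------
        od, os_, ot = true_genetic_values(off_haplo.dosage(spec.qtl_indices), effects, group)
        of = off_haplo.true_inbreeding()
        rng_tr = _stream(config, replicate, _S_TRAIT, t)
        ph = simulate_phenotypes(
            od, os_, off_pen, off_litter, config.true_vc, rng_tr, group,
            generation=t, ids=idx_off,
        )
        ph = ph.rename(columns={"id": "animal"})
        phenotypes.append(ph)

        # --- bookkeeping -----------------------------------------------
        sire = np.concatenate([sire, off_sire])
        dam = np.concatenate([dam, off_dam])
        sex = np.concatenate([sex, off_sex])
        generation = np.concatenate([generation, np.full(n_off, t, np.int64)])
        litter = np.concatenate([litter, off_litter])
        pen = np.concatenate([pen, off_pen])
        u_d = np.concatenate([u_d, od])
        u_s = np.concatenate([u_s, os_])
        u_tbv = np.concatenate([u_tbv, ot])
        f_true = np.concatenate([f_true, of])
        haplo = HaplotypeSet.concatenate([haplo, off_haplo])
        a = extend_A(a, sire, dam)

        records = pd.concat(phenotypes, ignore_index=True)
        f_ped = np.diag(a) - 1.0
        row = {
            "generation": t,
            "mean_y": float(ph["y"].mean()),
            "mean_f_true": float(np.mean(of)),
            "mean_f_ped": float(np.mean(f_ped[idx_off])),
        }

        # --- evaluate and select ---------------------------------------
        last = t == sc.n_generations
        if t >= 3 and (not last or config.evaluate_final):
            if t == 3 and config.vc_mode == "estimated":
                cache_key = (replicate, config.model)
                if reml_cache is not None and cache_key in reml_cache:
                    reml_result = reml_cache[cache_key]
                else:
                    rng_reml = _stream(config, replicate, _S_REML, t,
                                       ebv_dependent=True)
                    start_vc = _perturbed_start(config, rng_reml)
                    reml_result = fit_reml(
                        records, sire, dam, config.model, start_vc, group,
                        a_matrix=a,
                    )
                    if reml_cache is not None:
                        reml_cache[cache_key] = reml_result
                row["reml_converged"] = reml_result.converged
            vc_use = choose_vc(config.vc_mode, config.model, config.true_vc, reml_result)

            if config.relationship == "A":
                u_inv = build_A_inverse(sire, dam, inbreeding=f_ped)
            else:
                g = build_G(haplo.dosage(spec.marker_indices), base_freq[spec.marker_indices], a)
                u_inv = _dense_inverse(g)
            system = build_mme(records, vc_use, u_inv, sire.size, group)
            sol = solve_pcg(system)
            ebv = extract_ebv(sol, config.scheme, group)
            ebv_by_generation[t] = ebv
            row["solver_iterations"] = ebv.iterations
            row["solver_converged"] = ebv.converged

            if not last:
                mating_sires, mating_dams, audit = _select_parents(
                    config, t, idx_off, sex, ebv, a, replicate
                )
                ocs_rows.append(audit)
        elif t == 2:
            # random selection of generation-3 parents from generation 2
            rng_sel = _stream(config, replicate, _S_SELECT, t)
            males = idx_off[sex[idx_off] == 0]
            females = idx_off[sex[idx_off] == 1]
            sel_s = rng_sel.choice(males, size=ns, replace=False)
            sel_d = rng_sel.choice(females, size=nd, replace=False)
            mating_sires = np.repeat(sel_s, sc.dams_per_sire)
            mating_dams = rng_sel.permutation(sel_d)
        gen_rows.append(row)

    pop = PopulationState(
        sire=sire, dam=dam, sex=sex, generation=generation, litter=litter, pen=pen,
        u_d=u_d, u_s=u_s, u_tbv=u_tbv, f_true=f_true, a_matrix=a,
        phenotypes=pd.concat(phenotypes, ignore_index=True),
        haplotypes=haplo if config.keep_genomes else None,
        marker_dosage=haplo.dosage(spec.marker_indices) if config.keep_genomes else None,
    )
    return ReplicateResult(
        config=config,
        replicate=replicate,
        population=pop,
        ebv_by_generation=ebv_by_generation,
        reml_result=reml_result,
        generation_log=pd.DataFrame(gen_rows),
        ocs_log=pd.DataFrame(ocs_rows),
    )


def _perturbed_start(config: ScenarioConfig, rng: np.random.Generator):
    """REML starting values: truth times Uniform(0.5, 2) per component."""
    v = config.true_vc
    m = rng.uniform(0.5, 2.0, size=6)
    if config.model == CGM:
        from sgesim.traits import VarianceComponents

        return VarianceComponents(
            model=CGM,
            var_dge=v.var_dge * m[0],
            var_pen=v.var_pen * m[3],
            var_litter=v.var_litter * m[4],
            var_residual=v.var_residual * m[5],
        )
    from sgesim.traits import VarianceComponents

    var_d = v.var_dge * m[0]
    var_s = max(v.var_sge * m[2], 1e-6)
    # perturb the correlation, not the covariance, so the start stays inside
    # the parameter space whatever the variance draws were
    r = np.clip(v.correlation() * m[1], -0.9, 0.9)
    return VarianceComponents(
        model="sgm",
        var_dge=var_d,
        cov_dge_sge=r * np.sqrt(var_d * var_s),
        var_sge=var_s,
        var_pen=v.var_pen * m[3],
        var_litter=v.var_litter * m[4],
        var_residual=v.var_residual * m[5],
    )


def _dense_inverse(g: np.ndarray) -> np.ndarray:
    from scipy.linalg.lapack import dpotrf, dpotri

    c, info = dpotrf(g, lower=1)
    if info == 0:
        inv, info2 = dpotri(c, lower=1)
        if info2 == 0:
            return np.tril(inv) + np.tril(inv, -1).T
    return np.linalg.pinv(g)


def _select_parents(
    config: ScenarioConfig,
    t: int,
    candidates: np.ndarray,
    sex: np.ndarray,
    ebv: EBVSet,
    a: np.ndarray,
    replicate: int,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Pre-selection, contribution optimization and mating allocation."""
    sc = config.scale
    ebv_all = ebv.data.set_index("animal")["ebv"]
    cand_ebv = ebv_all.loc[candidates].to_numpy()
    males, females = preselect(
        candidates, cand_ebv, sex[candidates],
        sc.n_preselect_males, sc.n_preselect_females,
    )
    # dams: the best n_select_dams of the pre-selected females (fixed, equal use)
    dams = females[: sc.n_select_dams]
    shortlist = np.concatenate([males, dams])
    a_sub = a[np.ix_(shortlist, shortlist)]
    bound = _constraint_bound(config.delta_f, t)
    res = optimize_contributions(
        ebv_all.loc[males].to_numpy(), a_sub, males.size, bound, n_matings=sc.n_dams
    )
    rng_mate = _stream(config, replicate, _S_MATE, t, ebv_dependent=True)
    pairs = allocate_matings(males, res.sire_matings, dams, rng_mate)
    mating_sires = np.array([p[0] for p in pairs], dtype=np.int64)
    mating_dams = np.array([p[1] for p in pairs], dtype=np.int64)
    audit = {
        "generation": t,
        "bound": res.constraint_bound,
        "achieved": res.constraint_value,
        "status": res.status,
        "n_sires_used": int(np.sum(res.sire_matings > 0)),
        "merit": res.merit,
    }
    return mating_sires, mating_dams, audit


def run_scenario(config: ScenarioConfig, n_replicates: int | None = None):
    """Run the replicate set and aggregate the reported statistics."""
    from sgesim.metrics import summarize_replicates

    reps = []
    k = config.n_replicates if n_replicates is None else n_replicates
    for r in range(k):
        reps.append(run_replicate(config, r))
    return summarize_replicates(reps)
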