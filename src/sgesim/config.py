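"""Scenario configuration: one cell of the simulation factorial plus scale.

A scenario combines a breeding scheme (which model predicts the EBV and
which prediction is the selection criterion), the relationship source (A or
G), the trait's social variance and direct-social correlation, the pen
composition design, and whether BLUP uses true or generation-3-estimated
variance components.  The scale block holds the population and genome
sizes; its defaults are the full-scale design (30 sires x 600 dams x 6
offspring, pens of 12, 10 generations, 18 chromosomes / 30 Morgan, 54,218
markers, 2,000 QTL) and every entry is overridable for desk-scale runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from sgesim.genome import GenomeSpec
from sgesim.traits import VarianceComponents, SGM, CGM
from sgesim.mixed_models import SCHEME_MODEL

__all__ = ["ScaleBlock", "ScenarioConfig"]


@dataclass(frozen=True)
class ScaleBlock:
    """Population, genome and selection sizes for one program."""

    n_sires: int = 30
    n_dams: int = 600
    litter_size: int = 6
    pen_size: int = 12
    n_generations: int = 10
    n_preselect_males: int = 600
    n_preselect_females: int = 900
    n_select_dams: int = 600
    n_chromosomes: int = 18
    total_map_length: float = 30.0
    n_markers: int = 54218
    n_qtl: int = 2000

    def __post_init__(self) -> None:
        if self.litter_size % 2 != 0:
            raise ValueError("litters must split evenly into males and females")
        if (self.n_dams * self.litter_size) % self.pen_size != 0:
            raise ValueError("offspring per generation must fill whole pens")
        if self.n_dams % self.n_sires != 0:
            raise ValueError("each sire must receive a whole number of dams")
        if self.n_select_dams > self.n_preselect_females:
            raise ValueError("cannot select more dams than were pre-selected")
        per_sex = self.n_dams * self.litter_size // 2
        if self.n_preselect_males > per_sex or self.n_preselect_females > per_sex:
            raise ValueError("pre-selection exceeds candidates per sex")
        if self.n_generations < 3:
            raise ValueError("need at least three generations")

    @property
    def offspring_per_generation(self) -> int:
        return self.n_dams * self.litter_size

    @property
    def dams_per_sire(self) -> int:
        return self.n_dams // self.n_sires

    @classmethod
    def desk(
        cls,
        n_sires: int = 5,
        n_dams: int = 100,
        n_generations: int = 7,
        n_markers: int = 1000,
        n_qtl: int = 300,
        n_chromosomes: int = 18,
        total_map_length: float = 30.0,
        **kwargs,
    ) -> "ScaleBlock":
        """A reduced program preserving family sizes (dams per sire, litter
        and pen size), which is what the prediction accuracies depend on."""
        offspring = n_dams * 6
        return cls(
            n_sires=n_sires,
            n_dams=n_dams,
            n_generations=n_generations,
            n_preselect_males=offspring // 6,
            n_preselect_females=offspring // 4,
            n_select_dams=n_dams,
            n_chromosomes=n_chromosomes,
            total_map_length=total_map_length,
            n_markers=n_markers,
            n_qtl=n_qtl,
            **kwargs,
        )


@dataclass(frozen=True)
class ScenarioConfig:
    """One scenario cell plus replication and seeding."""

    scheme: str = "SGM_TBV"
    relationship: str = "A"
    sigma2_s: float = 0.01
    r_ds: float = 0.0
    grouping: str = "random"
    vc_mode: str = "estimated"
    n_replicates: int = 100
    seed: int = 0
    delta_f: float = 0.01
    scale: ScaleBlock = field(default_factory=ScaleBlock)
    common_random_numbers: bool = False
    evaluate_final: bool = True
    keep_genomes: bool = False
    sigma2_d: float = 1.0
    var_pen: float = 0.25
    var_litter: float = 0.25
    var_residual: float = 2.5

    def __post_init__(self) -> None:
        if self.scheme not in SCHEME_MODEL:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.relationship not in ("A", "G"):
            raise ValueError("relationship must be 'A' or 'G'")
        if self.grouping not in ("random", "four_families"):
            raise ValueError("grouping must be 'random' or 'four_families'")
        if self.vc_mode not in ("true", "estimated"):
            raise ValueError("vc_mode must be 'true' or 'estimated'")
        if self.model == CGM and self.vc_mode == "true":
            raise ValueError(
                "true variance components are not defined for the classical model"
            )
        if not 0.0 < self.delta_f < 1.0:
            raise ValueError("delta_f must lie in (0, 1)")

    @property
    def model(self) -> str:
        return SCHEME_MODEL[self.scheme]

    @property
    def true_vc(self) -> VarianceComponents:
        return VarianceComponents.sgm(
            sigma2_s=self.sigma2_s,
            r_ds=self.r_ds,
            sigma2_d=self.sigma2_d,
            var_pen=self.var_pen,
            var_litter=self.var_litter,
            var_residual=self.var_residual,
        )

    def genome_spec(self) -> GenomeSpec:
        """The (deterministic) genome map shared by all replicates."""
        return GenomeSpec.random(
            n_chromosomes=self.scale.n_chromosomes,
            total_length=self.scale.total_map_length,
            n_markers=self.scale.n_markers,
            n_qtl=self.scale.n_qtl,
            seed=np.random.SeedSequence([int(self.seed), 0xC0FFEE]),
        )

    def replace(self, **kwargs) -> "ScenarioConfig":
        return dataclasses.replace(self, **kwargs)

    # -- plain-text round trip -------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "scale" in d and isinstance(d["scale"], dict):
            d["scale"] = ScaleBlock(**d["scale"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
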