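"""Founder genomes, meiosis and QTL effects for direct and social traits.

The genome is a set of autosomes with biallelic loci placed on a genetic map
measured in Morgans.  Loci are either neutral markers (used for genomic
relationships) or QTL (which carry a pair of allelic effects: one on the
carrier's own phenotype, one on each pen mate's phenotype).  Founders are
generated in linkage equilibrium; descendants are produced by gene dropping
with Poisson-distributed crossovers (Haldane map, no interference).

Every haplotype also carries an integer founder-allele label per locus, which
is copied through meiosis unchanged.  Identity of the two labels at a locus
is identity by descent, the basis of the true inbreeding coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GenomeSpec",
    "HaplotypeSet",
    "QTLEffects",
    "simulate_founders",
    "meiosis",
    "make_offspring",
    "sample_raw_effects",
    "scale_qtl_effects",
    "true_genetic_values",
]


@dataclass(frozen=True)
class GenomeSpec:
    """Static description of the simulated genome.

    Parameters
    ----------
    chromosome_lengths:
        Genetic length of each autosome in Morgans.
    positions:
        Map position of every locus, in Morgans within its chromosome,
        concatenated over chromosomes and sorted within each chromosome.
    chromosome:
        Chromosome index (0-based) of every locus.
    is_qtl:
        Boolean mask marking QTL; the complement are neutral markers.
    freq_low, freq_high:
        Range of the uniform distribution from which founder allele
        frequencies are drawn, one frequency per locus.
    max_fixed_fraction:
        Upper bound on the fraction of loci the frequency sampler may fix
        (frequency 0 or 1); exceeding it signals a degenerate specification.
    """

    chromosome_lengths: np.ndarray
    positions: np.ndarray
    chromosome: np.ndarray
    is_qtl: np.ndarray
    freq_low: float = 0.05
    freq_high: float = 0.95
    max_fixed_fraction: float = 0.25

    def __post_init__(self) -> None:
        if len(self.chromosome_lengths) == 0 or np.any(self.chromosome_lengths <= 0):
            raise ValueError("chromosome lengths must be positive")
        if self.positions.shape != self.chromosome.shape or self.positions.shape != self.is_qtl.shape:
            raise ValueError("positions, chromosome and is_qtl must align")
        lens = self.chromosome_lengths[self.chromosome]
        if np.any(self.positions <= 0) or np.any(self.positions >= lens):
            raise ValueError("locus positions must lie strictly inside their chromosome")
        for c in range(len(self.chromosome_lengths)):
            p = self.positions[self.chromosome == c]
            if np.any(np.diff(p) < 0):
                raise ValueError("positions must be sorted within chromosomes")

    @property
    def n_loci(self) -> int:
        return int(self.positions.size)

    @property
    def n_qtl(self) -> int:
        return int(self.is_qtl.sum())

    @property
    def n_markers(self) -> int:
        return self.n_loci - self.n_qtl

    @property
    def qtl_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_qtl)

    @property
    def marker_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.is_qtl)

    def chromosome_slices(self) -> list[slice]:
        """Contiguous locus slice for each chromosome."""
        out = []
        start = 0
        for c in range(len(self.chromosome_lengths)):
            n = int(np.sum(self.chromosome == c))
            out.append(slice(start, start + n))
            start += n
        return out

    @classmethod
    def random(
        cls,
        n_chromosomes: int = 18,
        total_length: float = 30.0,
        n_markers: int = 54218,
        n_qtl: int = 2000,
        seed: int | np.random.SeedSequence = 0,
        **kwargs,
    ) -> "GenomeSpec":
        """Draw a genome with uniformly placed loci.

        Defaults are the full-scale design: 18 autosomes totalling 30 Morgan,
        54,218 markers and 2,000 QTL.  All four are overridable for
        desk-scale work.  Markers and QTL are disjoint by construction
        (continuous positions, distinct draws).
        """
        if n_chromosomes <= 0 or n_markers < 0 or n_qtl <= 0:
            raise ValueError("counts must be positive")
        rng = np.random.default_rng(seed)
        lengths = np.full(n_chromosomes, total_length / n_chromosomes)
        n_loci = n_markers + n_qtl
        # allocate loci to chromosomes proportionally to length
        chrom = rng.choice(n_chromosomes, size=n_loci, p=lengths / lengths.sum())
        pos = rng.uniform(0.0, lengths[chrom])
        eps = lengths[chrom] * 1e-9
        pos = np.clip(pos, eps, lengths[chrom] - eps)
        qtl = np.zeros(n_loci, dtype=bool)
        qtl[rng.choice(n_loci, size=n_qtl, replace=False)] = True
        order = np.lexsort((pos, chrom))
        return cls(
            chromosome_lengths=lengths,
            positions=pos[order],
            chromosome=chrom[order],
            is_qtl=qtl[order],
            **kwargs,
        )


@dataclass
class HaplotypeSet:
    """Phased genomes for a batch of animals.

    ``alleles`` has shape ``(n_animals, 2, n_loci)`` with biallelic codes
    0/1; ``labels`` has the same shape and holds the founder-allele label of
    each haplotype copy.  Labels are assigned once, in the founder
    generation, and are only ever copied afterwards.
    """

    alleles: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        if self.alleles.shape != self.labels.shape:
            raise ValueError("allele and label arrays must have identical shape")

    @property
    def n_animals(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[2]

    def dosage(self, loci: np.ndarray | None = None) -> np.ndarray:
        """Allele dosage (0/1/2) per animal, optionally at a locus subset."""
        a = self.alleles if loci is None else self.alleles[:, :, loci]
        return a.sum(axis=1, dtype=np.float64)

    def true_inbreeding(self) -> np.ndarray:
        """Fraction of loci at which the two founder labels are identical."""
        return np.mean(self.labels[:, 0, :] == self.labels[:, 1, :], axis=1)

    @classmethod
    def concatenate(cls, sets: list["HaplotypeSet"]) -> "HaplotypeSet":
        return cls(
            alleles=np.concatenate([s.alleles for s in sets], axis=0),
            labels=np.concatenate([s.labels for s in sets], axis=0),
        )


def simulate_founders(
    spec: GenomeSpec, n_founders: int, seed: int | np.random.Generator
) -> HaplotypeSet:
    """Sample founder haplotypes in linkage equilibrium.

    Allele frequencies are drawn once per locus from
    ``Uniform(freq_low, freq_high)``; haplotype alleles are then independent
    Bernoulli draws (no base-population LD).  Founder labels are globally
    unique: animal ``i`` carries labels ``2 i`` and ``2 i + 1``.
    """
    if n_founders < 2:
        raise ValueError("need at least two founders")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = rng.uniform(spec.freq_low, spec.freq_high, size=spec.n_loci)
    fixed = np.mean((freqs <= 0.0) | (freqs >= 1.0))
    if fixed > spec.max_fixed_fraction:
        raise ValueError(
            f"frequency sampler fixed {fixed:.0%} of loci "
            f"(cap {spec.max_fixed_fraction:.0%}); degenerate genome spec"
        )
    alleles = (
        rng.random(size=(n_founders, 2, spec.n_loci)) < freqs[None, None, :]
    ).astype(np.uint8)
    labels = np.broadcast_to(
        np.arange(2 * n_founders, dtype=np.int32).reshape(n_founders, 2, 1),
        alleles.shape,
    ).copy()
    return HaplotypeSet(alleles=alleles, labels=labels)


def meiosis(
    alleles: np.ndarray,
    labels: np.ndarray,
    spec: GenomeSpec,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Produce one gamete from a parent's two haplotypes.

    Per chromosome the crossover count is Poisson with mean equal to the map
    length in Morgans, crossover positions are uniform and interference-free
    (Haldane), and the starting haplotype is chosen with probability one
    half.  Chromosomes segregate independently.  Founder labels travel with
    the alleles.
    """
    n_loci = alleles.shape[1]
    out_a = np.empty(n_loci, dtype=alleles.dtype)
    out_l = np.empty(n_loci, dtype=labels.dtype)
    for c, sl in enumerate(spec.chromosome_slices()):
        length = spec.chromosome_lengths[c]
        start = rng.integers(0, 2)
        k = rng.poisson(length)
        if k == 0:
            out_a[sl] = alleles[start, sl]
            out_l[sl] = labels[start, sl]
            continue
        cx = np.sort(rng.uniform(0.0, length, size=k))
        # haplotype index at each locus: start parity flipped at each crossover
        flips = np.searchsorted(cx, spec.positions[sl])
        hap = (start + flips) % 2
        idx = np.arange(sl.start, sl.stop)
        out_a[sl] = alleles[hap, idx]
        out_l[sl] = labels[hap, idx]
    return out_a, out_l


def make_offspring(
    parents: HaplotypeSet,
    sire_idx: np.ndarray,
    dam_idx: np.ndarray,
    spec: GenomeSpec,
    rng: np.random.Generator,
) -> HaplotypeSet:
    """Gene-drop a cohort: one paternal and one maternal gamete per offspring.

    ``sire_idx``/``dam_idx`` index rows of ``parents`` and must have equal
    length (one entry per offspring).
    """
    sire_idx = np.asarray(sire_idx)
    dam_idx = np.asarray(dam_idx)
    if sire_idx.shape != dam_idx.shape:
        raise ValueError("sire and dam index arrays must align")
    n = sire_idx.size
    alleles = np.empty((n, 2, spec.n_loci), dtype=parents.alleles.dtype)
    labels = np.empty((n, 2, spec.n_loci), dtype=parents.labels.dtype)
    for i in range(n):
        alleles[i, 0], labels[i, 0] = meiosis(
            parents.alleles[sire_idx[i]], parents.labels[sire_idx[i]], spec, rng
        )
        alleles[i, 1], labels[i, 1] = meiosis(
            parents.alleles[dam_idx[i]], parents.labels[dam_idx[i]], spec, rng
        )
    return HaplotypeSet(alleles=alleles, labels=labels)


@dataclass(frozen=True)
class QTLEffects:
    """Per-QTL allelic effect pairs (direct, social) plus their target.

    ``effects`` has shape ``(n_qtl, 2)``: column 0 is the effect of one
    allele copy on the carrier's own phenotype, column 1 the effect on each
    pen mate's phenotype.  ``target`` is the 2x2 base-population genetic
    covariance matrix the effects were scaled to.  Effects are constant over
    generations; only allele frequencies drift.
    """

    effects: np.ndarray
    target: np.ndarray = field(default_factory=lambda: np.eye(2))

    @property
    def direct(self) -> np.ndarray:
        return self.effects[:, 0]

    @property
    def social(self) -> np.ndarray:
        return self.effects[:, 1]


def sample_raw_effects(
    n_qtl: int, target: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Draw raw (direct, social) effect pairs, bivariate normal at the target.

    The raw correlation matches the target's sign; the subsequent linear
    rescaling in :func:`scale_qtl_effects` makes the realized founder
    covariance exact.
    """
    target = np.asarray(target, dtype=float)
    # guard against exactly singular targets for the raw draw only
    draw_cov = target + 1e-12 * np.eye(2) * max(np.trace(target), 1.0)
    return rng.multivariate_normal(np.zeros(2), draw_cov, size=n_qtl)


def scale_qtl_effects(
    raw_effects: np.ndarray,
    founder_qtl_dosage: np.ndarray,
    target: np.ndarray,
) -> QTLEffects:
    """Rescale QTL effect pairs so the founder genetic covariance is exact.

    With founder dosage matrix ``D`` (animals x QTL) and effect matrix ``E``
    (QTL x 2), the genetic values are ``U = D E``.  A joint linear transform
    ``E <- E T'`` with ``T = chol(target) chol(realized)^-1`` maps the
    realized sample covariance of ``U`` onto the target exactly, so the base
    population starts at precisely the stated variances, not approximately.
    """
    target = np.asarray(target, dtype=float)
    u = founder_qtl_dosage @ raw_effects
    realized = np.cov(u, rowvar=False)
    if not np.all(np.isfinite(realized)):
        raise ValueError("non-finite realized covariance")
    try:
        l_real = np.linalg.cholesky(realized)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "realized genetic covariance of raw effects is singular; "
            "founder set unusable (all QTL fixed?)"
        ) from exc
    l_tgt = np.linalg.cholesky(target) if np.linalg.det(target) > 0 else None
    if l_tgt is None:
        # semi-definite target (e.g. |r|=1): use symmetric square roots
        wt, vt = np.linalg.eigh(target)
        l_tgt = vt @ np.diag(np.sqrt(np.clip(wt, 0, None))) @ vt.T
    t = l_tgt @ np.linalg.inv(l_real)
    return QTLEffects(effects=raw_effects @ t.T, target=target)


def true_genetic_values(
    qtl_dosage: np.ndarray, effects: QTLEffects, group_size: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """True DGE, SGE and total breeding value for a batch of animals.

    The total breeding value of an animal in a group of ``n`` is
    ``u_TBV = u_D + (n - 1) u_S``: its direct effect on itself plus its
    social effect on each of its ``n - 1`` pen mates.
    """
    u = qtl_dosage @ effects.effects
    u_d, u_s = u[:, 0], u[:, 1]
    return u_d, u_s, u_d + (group_size - 1) * u_s
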