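"""Synthetic inbred-line panels with block LD, family relatedness, additive
phenotypes, and GBS-style simulated missingness.

The generator emulates the structure of an elite inbred breeding panel:
founder lines carry haplotypes drawn from a Beta-shaped allele-frequency
spectrum; each family is a biparental cross advanced by several generations
of single-seed-descent selfing, with recombination simulated on unordered
markers via a hidden chromosome assignment and genetic position. Markers stay
unordered from the consumer's point of view — the hidden order exists only to
make co-inheritance (and hence LD) realistic.

Missingness is introduced per marker: a target missing fraction is drawn from
a level-specific distribution (a right-skewed Beta rescaled to the level's
cap, standing in for the empirical GBS per-marker distributions, which have a
long left tail and concentrate near the cap), and that many observed cells
are hidden uniformly at random.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import Coding, GenotypeMatrix, PhenotypeVector


class Level(str, enum.Enum):
    """Per-marker missingness cap: up to 20 / 50 / 70 % missing per marker."""

    NA20 = "NA20"
    NA50 = "NA50"
    NA70 = "NA70"

    @property
    def cap(self) -> float:
        return _LEVEL_PARAMS[self][0]


# cap, Beta shape a, Beta shape b. Shapes put the mode near the cap with a
# long left tail; means of cap * a/(a+b) reproduce realistic total-missingness
# regimes of roughly 12, 35 and 60.5 % for the three levels.
_LEVEL_PARAMS = {
    Level.NA20: (0.20, 2.0, 1.3),
    Level.NA50: (0.50, 2.33, 1.0),
    Level.NA70: (0.70, 3.2, 0.5),
}


@dataclass
class MissingnessSpec:
    """Distribution of per-marker target missing fractions.

    Either an empirical list of fractions (resampled with replacement) or a
    Beta(a, b) rescaled to [0, cap].
    """

    cap: float
    seed: int = 0
    fractions: Optional[np.ndarray] = None
    beta_a: float = 2.0
    beta_b: float = 1.3

    def __post_init__(self) -> None:
        if not 0.0 < self.cap <= 1.0:
            raise ValueError("cap must be in (0, 1]")
        if self.fractions is not None:
            self.fractions = np.asarray(self.fractions, dtype=float).ravel()
            if np.any(self.fractions > self.cap + 1e-12) or np.any(self.fractions < 0):
                raise ValueError("empirical fractions must lie in [0, cap]")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.fractions is not None:
            return rng.choice(self.fractions, size=n, replace=True)
        return self.cap * rng.beta(self.beta_a, self.beta_b, size=n)


def default_missingness_distribution(level: Level | str, seed: int = 0) -> MissingnessSpec:
    """Built-in parametric stand-in for empirical GBS missingness at a level."""
    cap, a, b = _LEVEL_PARAMS[Level(level)]
    return MissingnessSpec(cap=cap, seed=seed, beta_a=a, beta_b=b)


@dataclass
class MaskedDataset:
    """A complete truth matrix plus the same matrix with simulated holes."""

    truth: GenotypeMatrix
    observed: GenotypeMatrix
    simulated_mask: np.ndarray  # True where a cell was hidden by simulation
    spec: MissingnessSpec

    def __post_init__(self) -> None:
        if np.any(self.simulated_mask & self.truth.missing_mask):
            raise ValueError("simulated mask overlaps pre-existing missing cells")
        keep = ~self.observed.missing_mask
        if not np.array_equal(
            self.observed.values[keep], self.truth.values[keep]
        ):
            raise ValueError("observed values disagree with truth at unmasked cells")

    def unmask(self) -> np.ndarray:
        """Reconstruct the truth values from observed + mask (sanity helper)."""
        out = self.observed.values.copy()
        out[self.simulated_mask] = self.truth.values[self.simulated_mask]
        return out


@dataclass
class SimulatedPopulation:
    genotypes: GenotypeMatrix
    pedigree: pd.DataFrame  # individual_id, family, founder_a, founder_b
    sim_params: dict
    true_breeding_values: Optional[np.ndarray] = None
    phenotypes: Optional[PhenotypeVector] = None
    qtl_indices: Optional[np.ndarray] = None
    heritability: Optional[float] = None


def _draw_allele_freqs(n: int, maf_floor: float, rng: np.random.Generator) -> np.ndarray:
    """Allele-1 frequencies with MAF >= maf_floor, U-shaped Beta(0.5, 0.5)."""
    p = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        cand = rng.beta(0.5, 0.5, size=todo.size)
        ok = np.minimum(cand, 1 - cand) >= maf_floor
        p[todo[ok]] = cand[ok]
        todo = todo[~ok]
    return p


def _draw_founder_alleles(
    p: np.ndarray,
    chrom_order: list[np.ndarray],
    n_founders: int,
    founder_ld: float,
    founder_ld_flip: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Founder haplotypes with historic LD along each chromosome.

    With probability ``founder_ld`` a marker copies the previous marker's
    founder alleles (each founder's bit flipped with probability
    ``founder_ld_flip``), otherwise alleles are drawn fresh at that marker's
    frequency. This emulates the shared ancestry of elite founder pools, in
    which many markers tag the same haplotype block — the source of the
    near-perfect LD pairs that real DArT/GBS panels contain.
    """
    n_markers = p.size
    alleles = np.empty((n_founders, n_markers), dtype=np.int8)
    for order in chrom_order:
        prev = None
        for j in order:
            fresh = (rng.random(n_founders) < p[j]).astype(np.int8)
            if prev is None or rng.random() >= founder_ld:
                alleles[:, j] = fresh
            else:
                flips = rng.random(n_founders) < founder_ld_flip
                alleles[:, j] = np.where(flips, 1 - alleles[:, prev], alleles[:, prev])
            prev = j
    return alleles


def simulate_population(
    n_founders: int = 20,
    n_families: int = 20,
    lines_per_family: int = 10,
    n_markers: int = 500,
    n_chromosomes: int = 10,
    recomb_rate: float = 0.1,
    selfing_generations: int = 8,
    maf_floor: float = 0.05,
    founder_ld: float = 0.9,
    founder_ld_flip: float = 0.05,
    seed: int = 0,
) -> SimulatedPopulation:
    """Simulate a panel of inbred lines from biparental crosses.

    ``recomb_rate`` is the expected number of crossovers per chromosome per
    meiosis; 0 makes whole chromosomes co-inherit (complete within-family LD).
    ``founder_ld`` is the probability that a marker's founder alleles copy
    the previous marker's along the (hidden) chromosome order, emulating the
    historic LD / marker redundancy of elite founder pools; 0 draws every
    marker independently. Monomorphic markers have their founder alleles
    re-drawn. Deterministic under ``seed``.
    """
    for name, v in [
        ("n_founders", n_founders), ("n_families", n_families),
        ("lines_per_family", lines_per_family), ("n_markers", n_markers),
        ("n_chromosomes", n_chromosomes),
    ]:
        if v < 1:
            raise ValueError(f"{name} must be >= 1")
    if n_founders < 2:
        raise ValueError("need at least 2 founders for a cross")
    if not 0.0 <= maf_floor < 0.5:
        raise ValueError("maf_floor must be in [0, 0.5)")
    if recomb_rate < 0 or selfing_generations < 0:
        raise ValueError("recomb_rate and selfing_generations must be >= 0")
    if not 0.0 <= founder_ld < 1.0:
        raise ValueError("founder_ld must be in [0, 1)")

    rng = np.random.default_rng(seed)
    chrom = rng.integers(0, n_chromosomes, size=n_markers)
    pos = rng.uniform(0.0, 1.0, size=n_markers)
    chrom_markers = [np.flatnonzero(chrom == c) for c in range(n_chromosomes)]

    def gamete(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        """One meiotic product of a plant whose homologs carry founder ids."""
        g = np.empty(n_markers, dtype=np.int32)
        for idx in chrom_markers:
            if idx.size == 0:
                continue
            n_x = rng.poisson(recomb_rate)
            start = rng.integers(2)
            if n_x == 0:
                g[idx] = h1[idx] if start == 0 else h2[idx]
                continue
            points = np.sort(rng.uniform(0.0, 1.0, size=n_x))
            parity = (start + np.searchsorted(points, pos[idx])) % 2
            g[idx] = np.where(parity == 0, h1[idx], h2[idx])
        return g

    # ancestry: which founder's haplotype each homolog carries at each marker
    m_total = n_families * lines_per_family
    anc1 = np.empty((m_total, n_markers), dtype=np.int32)
    anc2 = np.empty((m_total, n_markers), dtype=np.int32)
    ped_rows = []
    row = 0
    for fam in range(n_families):
        fa, fb = rng.choice(n_founders, size=2, replace=False)
        for line in range(lines_per_family):
            h1 = np.full(n_markers, fa, dtype=np.int32)
            h2 = np.full(n_markers, fb, dtype=np.int32)
            for _ in range(selfing_generations):
                h1, h2 = gamete(h1, h2), gamete(h1, h2)
            anc1[row], anc2[row] = h1, h2
            ped_rows.append(
                (f"F{fam:02d}_L{line:02d}", fam, int(fa), int(fb))
            )
            row += 1

    cols = np.arange(n_markers)
    p = _draw_allele_freqs(n_markers, maf_floor, rng)
    chrom_order = [idx[np.argsort(pos[idx])] for idx in chrom_markers if idx.size]
    founder_alleles = _draw_founder_alleles(
        p, chrom_order, n_founders, founder_ld, founder_ld_flip, rng
    )

    def genotypes_for(js: np.ndarray) -> np.ndarray:
        a1 = founder_alleles[anc1[:, js], js]
        a2 = founder_alleles[anc2[:, js], js]
        return (a1 + a2 - 1).astype(float)  # -1 / 0 / 1

    values = genotypes_for(cols)
    for _ in range(100):
        mono = np.flatnonzero(np.all(values == values[0, :], axis=0))
        if mono.size == 0:
            break
        p[mono] = _draw_allele_freqs(mono.size, maf_floor, rng)
        founder_alleles[:, mono] = (
            rng.random((n_founders, mono.size)) < p[mono]
        ).astype(np.int8)
        values[:, mono] = genotypes_for(mono)
    else:
        raise RuntimeError(
            "could not make all markers polymorphic; the descent pattern may "
            "involve a single founder at some markers (increase family count)"
        )

    ped = pd.DataFrame(
        ped_rows, columns=["individual_id", "family", "founder_a", "founder_b"]
    )
    gm = GenotypeMatrix(
        values=values,
        individual_ids=ped["individual_id"].tolist(),
        marker_ids=[f"M{j:05d}" for j in range(n_markers)],
        coding=Coding.MINUS1_0_1,
    )
    params = dict(
        n_founders=n_founders, n_families=n_families,
        lines_per_family=lines_per_family, n_markers=n_markers,
        n_chromosomes=n_chromosomes, recomb_rate=recomb_rate,
        selfing_generations=selfing_generations, maf_floor=maf_floor,
        founder_ld=founder_ld, founder_ld_flip=founder_ld_flip, seed=seed,
    )
    return SimulatedPopulation(genotypes=gm, pedigree=ped, sim_params=params)


def simulate_phenotypes(
    pop: SimulatedPopulation, n_qtl: int = 40, h2: float = 0.5, seed: int = 0
) -> SimulatedPopulation:
    """Add an additive polygenic trait at heritability ``h2``.

    Standard-normal effects at ``n_qtl`` sampled markers define the true
    breeding values; i.i.d. Gaussian noise is scaled so that
    var(noise) = var(BV) * (1 - h2) / h2.
    """
    if n_qtl < 1:
        raise ValueError("n_qtl must be >= 1")
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must be in (0, 1)")
    gm = pop.genotypes
    if n_qtl > gm.n_markers:
        raise ValueError("n_qtl exceeds marker count")
    rng = np.random.default_rng(seed)
    qtl = np.sort(rng.choice(gm.n_markers, size=n_qtl, replace=False))
    effects = rng.standard_normal(n_qtl)
    bv = gm.values[:, qtl] @ effects
    var_bv = bv.var()
    if var_bv == 0:
        raise RuntimeError("true breeding values are constant; re-seed or add QTL")
    noise = rng.standard_normal(bv.size) * np.sqrt(var_bv * (1.0 - h2) / h2)
    ph = PhenotypeVector(
        values=bv + noise,
        individual_ids=gm.individual_ids,
        trait_name="sim_trait",
    )
    return replace(
        pop,
        true_breeding_values=bv,
        phenotypes=ph,
        qtl_indices=qtl,
        heritability=h2,
    )


def mask_missing(truth: GenotypeMatrix, spec: MissingnessSpec) -> MaskedDataset:
    """Hide observed cells at random, marker by marker.

    For each marker a target fraction is drawn from ``spec``; then
    round(fraction * n_observed) observed cells are hidden uniformly without
    replacement, never exceeding the cap and always leaving at least one
    observed call per marker. Reproducible under ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = truth.values.shape
    pre_missing = truth.missing_mask
    if np.any(pre_missing.sum(axis=0) == m):
        raise ValueError("truth has markers with no observed cells")
    fracs = spec.draw(n, rng)
    sim_mask = np.zeros((m, n), dtype=bool)
    cap_count = int(np.floor(spec.cap * m + 1e-9))
    for j in range(n):
        obs = np.flatnonzero(~pre_missing[:, j])
        n_hide = int(np.rint(fracs[j] * obs.size))
        n_hide = min(n_hide, cap_count, obs.size - 1)
        if n_hide <= 0:
            continue
        hide = rng.choice(obs, size=n_hide, replace=False)
        sim_mask[hide, j] = True
    observed_values = truth.values.copy()
    observed_values[sim_mask] = np.nan
    observed = replace(truth, values=observed_values)
    return MaskedDataset(
        truth=truth, observed=observed, simulated_mask=sim_mask, spec=spec
    )
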