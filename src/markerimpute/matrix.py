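"""Genotype and phenotype containers.

The central object is :class:`GenotypeMatrix`: an ``m x n`` matrix of
allele-dosage codes for ``m`` individuals (rows) by ``n`` biallelic markers
(columns), with missing calls stored as ``NaN``. Three codings are supported:

* ``MINUS1_1`` — fully inbred / dominant-marker data scored -1 / 1 (one allele
  observation per individual per marker);
* ``ZERO_1`` — the same two-state data scored 0 / 1;
* ``MINUS1_0_1`` — diploid dosage data with heterozygotes scored 0.

All downstream algorithms treat the codes as continuous values, so an imputed
matrix carries arbitrary reals and is flagged ``continuous=True``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np


class Coding(str, enum.Enum):
    """Allele-dosage coding scheme of a genotype matrix."""

    MINUS1_1 = "minus1_1"
    ZERO_1 = "zero_1"
    MINUS1_0_1 = "minus1_0_1"

    @property
    def allowed_values(self) -> tuple[float, ...]:
        return _ALLOWED[self]

    @property
    def midpoint(self) -> float:
        """Centre of the code range; sign-flipping a marker reflects about it."""
        return _MIDPOINT[self]

    @property
    def alleles_per_individual(self) -> int:
        """Allele observations contributed by one non-missing call (1 for the
        inbred two-state codings, 2 for diploid dosage)."""
        return 2 if self is Coding.MINUS1_0_1 else 1


_ALLOWED = {
    Coding.MINUS1_1: (-1.0, 1.0),
    Coding.ZERO_1: (0.0, 1.0),
    Coding.MINUS1_0_1: (-1.0, 0.0, 1.0),
}
_MIDPOINT = {Coding.MINUS1_1: 0.0, Coding.ZERO_1: 0.5, Coding.MINUS1_0_1: 0.0}


def _as_str_array(ids, name: str, n: int) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=object)
    if arr.shape != (n,):
        raise ValueError(f"{name}: expected {n} identifiers, got {arr.shape}")
    if len(set(arr)) != n:
        seen, dups = set(), []
        for x in arr:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"{name}: duplicate identifiers {dups[:5]}")
    return arr


@dataclass
class GenotypeMatrix:
    """m individuals (rows) x n markers (columns), NaN = missing call."""

    values: np.ndarray
    individual_ids: np.ndarray
    marker_ids: np.ndarray
    coding: Coding = Coding.MINUS1_1
    continuous: bool = False

    def __post_init__(self) -> None:
        self.values = np.array(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = self.values.shape
        self.coding = Coding(self.coding)
        self.individual_ids = _as_str_array(self.individual_ids, "individual_ids", m)
        self.marker_ids = _as_str_array(self.marker_ids, "marker_ids", n)
        if not self.continuous:
            obs = self.values[~np.isnan(self.values)]
            bad = obs[~np.isin(obs, self.coding.allowed_values)]
            if bad.size:
                raise ValueError(
                    f"genotype codes {sorted(set(bad))[:5]} are not valid under "
                    f"coding {self.coding.value} (allowed: {self.coding.allowed_values})"
                )

    # -- basic geometry -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    def copy(self) -> "GenotypeMatrix":
        return replace(
            self,
            values=self.values.copy(),
            individual_ids=self.individual_ids.copy(),
            marker_ids=self.marker_ids.copy(),
        )

    # -- summaries ------------------------------------------------------
    def missing_fraction(self) -> np.ndarray:
        """Per-marker fraction of missing calls."""
        return np.isnan(self.values).mean(axis=0)

    def minor_allele_frequency(self) -> np.ndarray:
        """Per-marker frequency of the rarer allele, from non-missing calls.

        Inbred two-state codings count one allele observation per individual;
        the heterozygote code of ``MINUS1_0_1`` contributes half a count to
        each allele. All-missing markers raise.
        """
        v = self.values
        nonmiss = (~np.isnan(v)).sum(axis=0)
        if np.any(nonmiss == 0):
            bad = self.marker_ids[nonmiss == 0]
            raise ValueError(f"all calls missing for marker(s) {list(bad[:5])}")
        if self.coding is Coding.ZERO_1:
            dose = v  # 0 or 1 allele observation of allele '1'
            per = 1
        elif self.coding is Coding.MINUS1_1:
            dose = (v + 1.0) / 2.0
            per = 1
        else:  # MINUS1_0_1: -1/0/1 -> 0/1/2 copies of allele '1'
            dose = v + 1.0
            per = 2
        p = np.nansum(dose, axis=0) / (per * nonmiss)
        return np.minimum(p, 1.0 - p)

    # -- transforms -----------------------------------------------------
    def recode(self, target: Coding) -> "GenotypeMatrix":
        """Re-express the codes under another coding scheme (mask preserved).

        The 0/1 <-> -1/1 map is affine (x -> 2x - 1); diploid-coded data can
        only move to a two-state coding when no heterozygote calls are present.
        Recoding is an involution: recoding back restores the original matrix.
        """
        target = Coding(target)
        if self.continuous:
            raise ValueError("cannot recode a continuous (imputed) matrix")
        if target is self.coding:
            return self.copy()
        v = self.values
        src = self.coding
        two_state = {Coding.MINUS1_1, Coding.ZERO_1}
        if src in two_state and target in two_state:
            out = 2.0 * v - 1.0 if src is Coding.ZERO_1 else (v + 1.0) / 2.0
        elif src is Coding.MINUS1_0_1:
            if np.any(v[~np.isnan(v)] == 0.0):
                raise ValueError(
                    "matrix contains heterozygote calls (code 0); cannot recode "
                    f"to two-state coding {target.value}"
                )
            out = v.copy() if target is Coding.MINUS1_1 else (v + 1.0) / 2.0
        else:  # two-state -> MINUS1_0_1: homozygotes only
            out = v.copy() if src is Coding.MINUS1_1 else 2.0 * v - 1.0
        return replace(self, values=out, coding=target)

    def filter_markers_by_missingness(self, max_frac: float) -> "GenotypeMatrix":
        """Keep markers whose missing fraction is <= ``max_frac`` (order kept)."""
        keep = np.flatnonzero(self.missing_fraction() <= max_frac + 1e-12)
        return self.select_markers(keep)

    def subsample_markers(self, n_keep: int, seed: int) -> "GenotypeMatrix":
        """Uniform random marker subset without replacement (seeded)."""
        if n_keep > self.n_markers:
            raise ValueError(f"n_keep={n_keep} exceeds marker count {self.n_markers}")
        rng = np.random.default_rng(seed)
        keep = rng.choice(self.n_markers, size=n_keep, replace=False)
        return self.select_markers(keep)

    def select_markers(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return replace(self, values=self.values[:, idx], marker_ids=self.marker_ids[idx])

    def select_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self, values=self.values[idx, :], individual_ids=self.individual_ids[idx]
        )


@dataclass
class PhenotypeVector:
    """Complete-case breeding-value estimates aligned to a GenotypeMatrix."""

    values: np.ndarray
    individual_ids: np.ndarray
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.individual_ids = _as_str_array(
            self.individual_ids, "individual_ids", self.values.size
        )
        if np.isnan(self.values).any():
            raise ValueError("phenotype vector contains missing values")

    def aligned_to(self, gm: GenotypeMatrix) -> np.ndarray:
        """Values reordered to match ``gm.individual_ids``."""
        lookup = {iid: i for i, iid in enumerate(self.individual_ids)}
        try:
            order = [lookup[iid] for iid in gm.individual_ids]
        except KeyError as e:  # pragma: no cover - defensive
            raise ValueError(f"phenotype missing for individual {e}") from e
        return self.values[np.asarray(order)]
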