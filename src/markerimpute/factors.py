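"""Factors affecting imputation accuracy.

* Pairwise LD as r^2 = D^2 / (p1 q1 p2 q2), with the two-locus haplotype
  frequency x11 estimated by EM when heterozygote calls make phase ambiguous
  (for fully inbred two-state data the haplotypes are directly observed and
  the EM reduces to counting).
* LD classification: a marker is in at least moderate LD when its highest
  pairwise r^2 with any other marker is >= 0.5 (default threshold).
* Binned accuracy tables behind the MAF / nonmissing-count / closest-relative
  distance / PEV factor curves.
* Per-individual prediction error variance (PEV) from the mixed-model
  equations, one marker at a time, with the genomic relationship matrix
  built from all other markers; low PEV indicates high genetic connectedness.
* Weir-Cockerham-style per-marker Fst for screening markers whose accuracy
  is driven by population subdivision.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import pdist, squareform

from .matrix import Coding, GenotypeMatrix


class LDClass(str, enum.Enum):
    LOW_LD = "LOW_LD"
    MODERATE_LD = "MODERATE_LD"


@dataclass
class LDSummary:
    max_r2_per_marker: np.ndarray  # NaN where undefined (monomorphic)
    class_per_marker: np.ndarray  # LDClass values
    threshold: float = 0.5

    @property
    def moderate_fraction(self) -> float:
        """Fraction of classifiable markers in at least moderate LD."""
        moderate = np.array(
            [c == LDClass.MODERATE_LD for c in self.class_per_marker]
        )
        defined = ~np.isnan(self.max_r2_per_marker)
        if defined.sum() == 0:
            return np.nan
        return float(np.mean(moderate[defined]))


@dataclass
class RelatednessSummary:
    min_distance_per_individual: np.ndarray
    pev_per_individual: Optional[np.ndarray] = None


def _dosage(values: np.ndarray, coding: Coding = Coding.MINUS1_0_1) -> np.ndarray:
    """Copies of the 'high' allele per call: 0/1/2 (inbred calls count double)."""
    v = np.asarray(values, dtype=float)
    if coding is Coding.ZERO_1:
        return 2.0 * v
    if coding is Coding.MINUS1_1:
        return v + 1.0  # -1/1 -> 0/2
    return v + 1.0  # -1/0/1 -> 0/1/2


def ld_r2_em(
    marker_j,
    marker_l,
    coding: Coding = Coding.MINUS1_0_1,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> float:
    """Squared LD correlation between two markers from unphased genotypes.

    Uses pairwise-complete individuals. Haplotype frequencies are estimated
    by the standard two-locus EM; only double heterozygotes carry phase
    ambiguity, so for inbred data the estimate is the direct haplotype count.
    Returns NaN when either marker is monomorphic in the pairwise-complete
    subset.
    """
    a = _dosage(marker_j, coding)
    b = _dosage(marker_l, coding)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    n = a.size
    if n == 0:
        return np.nan
    pA = a.sum() / (2 * n)
    pB = b.sum() / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        return np.nan

    # genotype pair counts; index = dosage (0,1,2)
    counts = np.zeros((3, 3))
    for ga in (0, 1, 2):
        for gb in (0, 1, 2):
            counts[ga, gb] = np.sum((a == ga) & (b == gb))

    # haplotype freqs (AB, Ab, aB, ab) where A/B are the 'high' alleles
    f = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    f = np.maximum(f, 1e-12)
    f /= f.sum()
    n_hap = 2.0 * n
    # haplotype contributions of each unambiguous genotype pair:
    # dosage ga contributes ga copies of A... enumerate directly
    for _ in range(max_iter):
        c = np.zeros(4)
        for ga in (0, 1, 2):
            for gb in (0, 1, 2):
                m = counts[ga, gb]
                if m == 0:
                    continue
                if ga == 1 and gb == 1:
                    # double heterozygote: AB/ab vs Ab/aB
                    cis = f[0] * f[3]
                    trans = f[1] * f[2]
                    tot = cis + trans
                    w = 0.5 if tot == 0 else cis / tot
                    c[0] += m * w
                    c[3] += m * w
                    c[1] += m * (1 - w)
                    c[2] += m * (1 - w)
                else:
                    # phase unambiguous: the two haplotypes are determined
                    for ha, hb in _split_haplotypes(ga, gb):
                        c[_hap_index(ha, hb)] += m
        f_new = c / n_hap
        f_new = np.maximum(f_new, 0.0)
        s = f_new.sum()
        if s > 0:
            f_new /= s
        if np.max(np.abs(f_new - f)) < tol:
            f = f_new
            break
        f = f_new
    x11 = f[0]
    D = x11 - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    r2 = (D * D) / denom
    return float(min(max(r2, 0.0), 1.0))


def _hap_index(ha: int, hb: int) -> int:
    return {(1, 1): 0, (1, 0): 1, (0, 1): 2, (0, 0): 3}[(ha, hb)]


def _split_haplotypes(nA: int, nB: int):
    """The two haplotypes of a genotype pair with known phase.

    Valid for all combinations except the double heterozygote (1, 1).
    """
    if nA == 1 and nB == 1:
        raise ValueError("double heterozygote has ambiguous phase")
    a_alleles = [1, 0] if nA == 1 else [nA // 2] * 2
    b_alleles = [1, 0] if nB == 1 else [nB // 2] * 2
    if nA == 1:
        # het at A, hom at B: A travels with one B copy, a with the other
        return [(1, b_alleles[0]), (0, b_alleles[1])]
    if nB == 1:
        return [(a_alleles[0], 1), (a_alleles[1], 0)]
    return [(a_alleles[0], b_alleles[0]), (a_alleles[1], b_alleles[1])]


def pairwise_r2(gm: GenotypeMatrix) -> np.ndarray:
    """All-pairs r^2 matrix (NaN on the diagonal and for undefined pairs).

    Fully inbred matrices (no heterozygote calls) use the closed-form
    count-based estimate, which coincides with the EM solution; matrices with
    heterozygotes fall back to the per-pair EM.
    """
    v = gm.values
    n = gm.n_markers
    has_het = (
        gm.coding is Coding.MINUS1_0_1 and np.any(v[~np.isnan(v)] == 0.0)
    )
    if not has_het:
        # pairwise-complete Pearson correlation of dosages, squared
        df = pd.DataFrame(v)
        r = df.corr(min_periods=1).to_numpy()
        r2 = r * r
        np.fill_diagonal(r2, np.nan)
        return r2
    out = np.full((n, n), np.nan)
    for j in range(n):
        for l in range(j + 1, n):
            val = ld_r2_em(v[:, j], v[:, l], coding=gm.coding)
            out[j, l] = out[l, j] = val
    return out


def ld_classify(gm: GenotypeMatrix, threshold: float = 0.5) -> LDSummary:
    """Classify each marker by its maximum pairwise r^2 with any other marker."""
    if gm.n_markers < 2:
        raise ValueError("need at least 2 markers")
    r2 = pairwise_r2(gm)
    with np.errstate(invalid="ignore"):
        max_r2 = np.nanmax(r2, axis=1)
    cls = np.empty(gm.n_markers, dtype=object)
    cls[:] = [
        LDClass.MODERATE_LD if v >= threshold else LDClass.LOW_LD for v in max_r2
    ]
    return LDSummary(max_r2_per_marker=max_r2, class_per_marker=cls, threshold=threshold)


def ld_ratio(ldsum: LDSummary, rm2bar: np.ndarray) -> float:
    """median(accuracy | low LD) / median(accuracy | moderate LD)."""
    rm2bar = np.asarray(rm2bar, dtype=float)
    is_low = np.array([c == LDClass.LOW_LD for c in ldsum.class_per_marker])
    low = rm2bar[is_low & ~np.isnan(rm2bar)]
    mod = rm2bar[~is_low & ~np.isnan(rm2bar)]
    if low.size == 0 or mod.size == 0:
        raise ValueError("one of the LD classes is empty")
    return float(np.median(low) / np.median(mod))


class Factor(str, enum.Enum):
    MAF = "MAF"
    N_NONMISSING = "N_NONMISSING"
    DISTANCE = "DISTANCE"
    PEV = "PEV"


def _default_binning(factor: Factor) -> Callable[[np.ndarray], np.ndarray]:
    if factor is Factor.MAF:
        return lambda v: np.round(v, 1)  # nearest tenth
    if factor is Factor.N_NONMISSING:
        return lambda v: 5.0 * np.round(np.asarray(v, float) / 5.0)  # nearest 5
    if factor is Factor.DISTANCE:
        return lambda v: np.round(v, 0)  # nearest whole number
    # PEV has no natural grain: decile bins on the observed values
    def deciles(v):
        v = np.asarray(v, float)
        edges = np.quantile(v, np.linspace(0, 1, 11))
        idx = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, 9)
        return idx.astype(float)

    return deciles


def bin_accuracy_by(
    factor: Factor | str,
    values,
    accuracies,
    binning: Optional[Callable] = None,
) -> pd.DataFrame:
    """Median accuracy per factor bin (empty bins omitted).

    Rounding rules: MAF to the nearest tenth, nonmissing count to the nearest
    multiple of 5, closest-relative distance to the nearest whole number,
    PEV to decile bins.
    """
    factor = Factor(factor)
    values = np.asarray(values, dtype=float).ravel()
    accuracies = np.asarray(accuracies, dtype=float).ravel()
    if values.size != accuracies.size:
        raise ValueError("values and accuracies differ in length")
    binning = binning or _default_binning(factor)
    keep = ~(np.isnan(values) | np.isnan(accuracies))
    bins = np.asarray(binning(values[keep]), dtype=float)
    df = pd.DataFrame({"bin": bins, "accuracy": accuracies[keep]})
    out = (
        df.groupby("bin")["accuracy"]
        .agg(median_accuracy="median", n="size")
        .reset_index()
        .sort_values("bin", ignore_index=True)
    )
    out.insert(0, "factor", factor.value)
    return out


def relatedness_summary(
    gm: GenotypeMatrix,
    variance_components: Optional[tuple[float, float]] = None,
    pev_mode: str = "auto",
) -> RelatednessSummary:
    """Closest-relative distance and overall PEV for every individual."""
    return RelatednessSummary(
        min_distance_per_individual=closest_relative_distance(gm),
        pev_per_individual=pev_per_individual(
            gm, mode=pev_mode, variance_components=variance_components
        ),
    )


def closest_relative_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Euclidean distance from each individual to its nearest other individual."""
    if gm.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if gm.missing_mask.any():
        raise ValueError("matrix has missing cells; impute or use the truth matrix")
    d = squareform(pdist(gm.values, metric="euclidean"))
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1)


# ---------------------------------------------------------------------------
# PEV from the mixed-model equations


def grm(values: np.ndarray) -> np.ndarray:
    """VanRaden-style genomic relationship matrix, mean diagonal scaled to 1."""
    Z = values - values.mean(axis=0, keepdims=True)
    K = Z @ Z.T
    scale = np.trace(K) / K.shape[0]
    if scale <= 0:
        raise ValueError("degenerate marker matrix (no variation)")
    return K / scale


def _reml_kinship(K: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """REML variance components (sigma2_g, sigma2_e) for y = 1*mu + g + e."""
    m = y.size
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(m)

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = 1.0 / (d + delta)
        xwx = float((xt * w * xt).sum())
        beta = float((xt * w * yt).sum()) / xwx
        r = yt - xt * beta
        s2 = float((r * r * w).sum()) / (m - 1)
        if s2 <= 0:
            return np.inf
        return 0.5 * (
            (m - 1) * np.log(s2) + np.log(d + delta).sum() + np.log(xwx) + (m - 1)
        )

    res = minimize_scalar(neg_restricted_ll, bounds=(-10.0, 10.0), method="bounded")
    delta = float(np.exp(res.x))
    w = 1.0 / (d + delta)
    xwx = float((xt * w * xt).sum())
    beta = float((xt * w * yt).sum()) / xwx
    r = yt - xt * beta
    sigma2_g = float((r * r * w).sum()) / (m - 1)
    sigma2_e = sigma2_g * delta
    return sigma2_g, sigma2_e


def pev_from_mme(
    K: np.ndarray, sigma2_g: float, sigma2_e: float, ridge: float = 1e-8
) -> np.ndarray:
    """Diagonal of the genetic block of the inverted MME coefficient matrix."""
    m = K.shape[0]
    Kinv = np.linalg.inv(K + ridge * np.eye(m))
    C = np.empty((m + 1, m + 1))
    C[0, 0] = m / sigma2_e
    C[0, 1:] = 1.0 / sigma2_e
    C[1:, 0] = 1.0 / sigma2_e
    C[1:, 1:] = np.eye(m) / sigma2_e + Kinv / sigma2_g
    Cinv = np.linalg.inv(C)
    return np.diag(Cinv)[1:].copy()


def pev_per_individual(
    gm: GenotypeMatrix,
    mode: str = "auto",
    variance_components: Optional[tuple[float, float]] = None,
    fast_threshold: int = 500,
) -> np.ndarray:
    """Overall PEV per individual, summed over single-marker mixed models.

    For each marker j the model y = 1*mu + g + e is fitted with y = column j
    and cov(g) proportional to the relationship matrix built from all markers
    except j; the marker's PEV vector is the diagonal of the genetic block of
    the inverted coefficient matrix, and the overall PEV is the sum across
    markers. ``mode='exact'`` re-estimates variance components by REML per
    marker; ``'fast'`` estimates them once from the phenotype-free average
    model and reuses them (the default above ``fast_threshold`` markers).
    ``variance_components`` fixes (sigma2_g, sigma2_e) for all markers.
    """
    if gm.missing_mask.any():
        raise ValueError("matrix has missing cells; impute or use the truth matrix")
    m, n = gm.values.shape
    if m < 3:
        raise ValueError("need at least 3 individuals")
    if mode == "auto":
        mode = "exact" if n <= fast_threshold else "fast"

    V = gm.values
    Z = V - V.mean(axis=0, keepdims=True)
    G_full = Z @ Z.T
    col_ss = (Z**2).sum(axis=0)

    shared: Optional[tuple[float, float]] = variance_components
    if shared is None and mode == "fast":
        sg, se = 0.0, 0.0
        K_all = G_full / max(np.trace(G_full) / m, 1e-300)
        pick = np.linspace(0, n - 1, num=min(n, 25), dtype=int)
        comps = [_reml_kinship(K_all, V[:, j]) for j in pick]
        sg = float(np.median([c[0] for c in comps]))
        se = float(np.median([c[1] for c in comps]))
        shared = (max(sg, 1e-8), max(se, 1e-8))

    total = np.zeros(m)
    used = 0
    for j in range(n):
        Kj_raw = G_full - np.outer(Z[:, j], Z[:, j])
        scale = (np.trace(G_full) - col_ss[j]) / m
        if scale <= 0:
            continue
        Kj = Kj_raw / scale
        if shared is not None:
            sg, se = shared
        else:
            try:
                sg, se = _reml_kinship(Kj, V[:, j])
            except Exception:
                continue
            sg, se = max(sg, 1e-8), max(se, 1e-8)
        total += pev_from_mme(Kj, sg, se)
        used += 1
    if used == 0:
        raise RuntimeError("no marker model could be fitted")
    return total * (n / used)


def fst_per_marker(gm: GenotypeMatrix, groups: Sequence) -> np.ndarray:
    """Per-marker Fst across groups (variance-components estimator).

    Treats each individual's call as allele observations (one for inbred
    two-state codings, two for diploid dosage) and contrasts among-group and
    within-group allele-frequency variance. Monomorphic markers are NaN.
    """
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least 2 groups")
    for g in labels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")
    dose = _dosage(gm.values, gm.coding) / 2.0  # per-allele freq contribution
    out = np.full(gm.n_markers, np.nan)
    for j in range(gm.n_markers):
        x = dose[:, j]
        ni, pi = [], []
        for g in labels:
            xg = x[groups == g]
            xg = xg[~np.isnan(xg)]
            if xg.size == 0:
                continue
            ni.append(xg.size)
            pi.append(xg.mean())
        if len(ni) < 2:
            continue
        ni = np.asarray(ni, float)
        pi = np.asarray(pi, float)
        ntot = ni.sum()
        pbar = (ni * pi).sum() / ntot
        if pbar in (0.0, 1.0):
            continue
        r = len(ni)
        nbar = ntot / r
        nc = (ntot - (ni**2).sum() / ntot) / (r - 1)
        msp = (ni * (pi - pbar) ** 2).sum() / (r - 1)
        msg = (ni * pi * (1 - pi)).sum() / (ntot - r)
        denom = msp + (nc - 1) * msg
        if denom <= 0:
            out[j] = 0.0
        else:
            out[j] = float((msp - msg) / denom)
    return out
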