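"""Population-genetic analysis of a small marker panel.

Covers the four computations the breed survey needs:

* binomial allele-frequency estimates with Wilson score confidence
  intervals (the score interval reproduces the printed bounds at extreme
  proportions, which Clopper-Pearson does not);
* expectation-maximisation (EM) haplotype phasing of unphased diploid
  genotypes, with most-probable diplotype assignment per dog;
* linkage-disequilibrium D and r^2 from a phased haplotype pool;
* haplotype frequencies from diplotype counts, and Mann-Whitney comparison
  of per-breed frequencies between breed groups (e.g. Sighthounds vs
  others).

Percent values intended for display are rounded half-up, matching the
convention of the published tables (17.5% -> 18%).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .variants import GenotypeCall, HaplotypeSet, Polymorphism

__all__ = [
    "FrequencyEstimate",
    "DiplotypeCounts",
    "LdResult",
    "PhasingResult",
    "round_half_up",
    "wilson_bounds",
    "wilson_ci",
    "allele_frequencies",
    "em_phase",
    "ld_r2",
    "ld_matrix",
    "haplotype_freqs_from_diplotypes",
    "breed_group_compare",
    "mann_whitney_u",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer with ties away from zero toward +inf."""
    return int(math.floor(x + 0.5))


# ---------------------------------------------------------------------------
# Allele frequencies

@dataclass(frozen=True)
class FrequencyEstimate:
    """Variant-allele frequency k/n with a Wilson score interval."""

    k: int
    n: int
    ci_low: float
    ci_high: float
    conf: float = 0.95

    @property
    def p_hat(self) -> float:
        return self.k / self.n


def wilson_bounds(k, n, conf: float = 0.95):
    """Vectorised Wilson score interval bounds, clipped to [0, 1]."""
    k_arr = np.asarray(k)
    n_arr = np.asarray(n)
    low, high = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    # exact endpoints at the degenerate proportions (guards float round-off)
    low = np.where(k_arr == 0, 0.0, np.clip(low, 0.0, 1.0))
    high = np.where(k_arr == n_arr, 1.0, np.clip(high, 0.0, 1.0))
    if np.ndim(k) == 0:
        return float(low), float(high)
    return low, high


def wilson_ci(k: int, n: int, conf: float = 0.95) -> FrequencyEstimate:
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    low, high = wilson_bounds(k, n, conf)
    return FrequencyEstimate(k=k, n=n, ci_low=float(low), ci_high=float(high), conf=conf)


def allele_frequencies(
    panel: Sequence[GenotypeCall],
    variants: Sequence[Polymorphism],
    conf: float = 0.95,
) -> dict[str, FrequencyEstimate]:
    """Per-site variant-allele frequency over a genotype panel.

    Missing alleles are excluded pairwise: the denominator at each site is
    the number of observed chromosomes there.
    """
    out: dict[str, FrequencyEstimate] = {}
    for v in variants:
        k = n = 0
        for call in panel:
            for allele in call.alleles[v.id]:
                code = v.allele_code(allele)
                if code is not None:
                    n += 1
                    k += code
        if n == 0:
            raise ValueError(f"site {v.id}: no observed chromosomes")
        out[v.id] = wilson_ci(k, n, conf)
    return out


# ---------------------------------------------------------------------------
# EM haplotype phasing

@dataclass
class PhasingResult:
    haplotypes: HaplotypeSet           # EM frequencies under population "em"
    diplotypes: dict[str, tuple[str, str]]  # dog_id -> (label_a, label_b), a <= b
    loglik_trace: list[float]
    converged: bool
    n_iter: int


def _compatible_pairs(codes: Sequence[tuple[int | None, int | None]]):
    """All unordered haplotype pairs compatible with one unphased genotype.

    Haplotypes are 0/1 tuples.  Heterozygous sites contribute a phase
    choice; missing sites are marginalised over both alleles on both
    chromosomes (uniform prior over site alleles).
    """
    per_site: list[list[tuple[int, int]]] = []
    for a, b in codes:
        if a is None and b is None:
            per_site.append([(0, 0), (0, 1), (1, 0), (1, 1)])
        elif a is None or b is None:
            known = a if a is not None else b
            per_site.append([(known, 0), (known, 1), (0, known), (1, known)])
        elif a == b:
            per_site.append([(a, a)])
        else:
            per_site.append([(0, 1), (1, 0)])
    pairs: set[tuple[tuple[int, ...], tuple[int, ...]]] = set()
    for combo in itertools.product(*per_site):
        h1 = tuple(c[0] for c in combo)
        h2 = tuple(c[1] for c in combo)
        pairs.add((h1, h2) if h1 <= h2 else (h2, h1))
    return sorted(pairs)


def em_phase(
    panel: Sequence[GenotypeCall],
    variants: Sequence[Polymorphism],
    tol: float = 1e-8,
    max_iter: int = 10_000,
    prune_threshold: float | None = None,
) -> PhasingResult:
    """Maximum-likelihood haplotype frequencies by EM, plus most-probable
    diplotype per dog.

    The model is the standard multinomial over unordered haplotype pairs
    with Hardy-Weinberg pairing: P(h_i, h_j) = (2 - delta_ij) f_i f_j.
    Initialisation is uniform over every haplotype compatible with at least
    one genotype (deterministic, no seed).  Iteration stops when the largest
    frequency change drops below ``tol``; hitting ``max_iter`` first sets
    ``converged=False`` on the result rather than raising.  Haplotypes with
    fitted frequency below ``prune_threshold`` (default 1/(4N) chromosomes)
    are pruned and the rest renormalised.
    """
    if not panel:
        raise ValueError("empty genotype panel")
    if prune_threshold is None:
        prune_threshold = 1.0 / (4 * len(panel))

    dog_codes = [call.codes(variants) for call in panel]
    # Collapse identical genotype vectors so EM cost scales with distinct
    # genotypes, not dogs.
    class_of: dict[tuple, int] = {}
    class_counts: list[int] = []
    class_pairs: list[list[tuple[tuple[int, ...], tuple[int, ...]]]] = []
    dog_class: list[int] = []
    for codes in dog_codes:
        key = tuple(tuple(sorted((a if a is not None else -1, b if b is not None else -1))) for a, b in codes)
        if key not in class_of:
            class_of[key] = len(class_counts)
            class_counts.append(0)
            class_pairs.append(_compatible_pairs(codes))
        idx = class_of[key]
        class_counts[idx] += 1
        dog_class.append(idx)

    universe = sorted({h for pairs in class_pairs for pair in pairs for h in pair})
    hap_index = {h: i for i, h in enumerate(universe)}
    H = len(universe)
    freqs = np.full(H, 1.0 / H)
    counts = np.asarray(class_counts, dtype=float)
    n_dogs = counts.sum()

    pair_idx = [
        np.array([[hap_index[a], hap_index[b]] for a, b in pairs], dtype=int)
        for pairs in class_pairs
    ]
    pair_coef = [
        np.array([1.0 if a == b else 2.0 for a, b in pairs]) for pairs in class_pairs
    ]

    def class_pair_probs(f: np.ndarray) -> list[np.ndarray]:
        return [
            coef * f[idx[:, 0]] * f[idx[:, 1]]
            for idx, coef in zip(pair_idx, pair_coef)
        ]

    loglik_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        probs = class_pair_probs(freqs)
        totals = np.array([p.sum() for p in probs])
        if np.any(totals <= 0):
            raise FloatingPointError("EM reached a zero-likelihood genotype class")
        loglik_trace.append(float(np.dot(counts, np.log(totals))))
        new = np.zeros(H)
        for idx, p, total, c in zip(pair_idx, probs, totals, counts):
            w = c * p / total
            np.add.at(new, idx[:, 0], w)
            np.add.at(new, idx[:, 1], w)
        new /= 2.0 * n_dogs
        delta = float(np.max(np.abs(new - freqs)))
        freqs = new
        if delta < tol:
            converged = True
            break

    keep = freqs >= prune_threshold
    kept = [universe[i] for i in np.flatnonzero(keep)]
    kept_freqs = freqs[keep]
    kept_freqs = kept_freqs / kept_freqs.sum()
    order = np.argsort(-kept_freqs, kind="stable")
    labels = [f"E{rank + 1}" for rank in range(len(kept))]
    label_of = {kept[int(i)]: labels[rank] for rank, i in enumerate(order)}
    freq_of = {label_of[kept[int(i)]]: float(kept_freqs[int(i)]) for i in np.flatnonzero(np.ones(len(kept), bool))}

    by_id = {v.id: v for v in variants}
    site_order = [v.id for v in variants]

    def hap_alleles(h: tuple[int, ...]) -> tuple[str, ...]:
        return tuple(
            by_id[s].var_allele if code else by_id[s].ref_allele
            for s, code in zip(site_order, h)
        )

    hapset = HaplotypeSet(
        site_order=site_order,
        haplotypes={label_of[h]: hap_alleles(h) for h in kept},
        frequencies={"em": freq_of},
    )

    # Most-probable diplotype per dog among surviving haplotypes; ties are
    # broken by lexicographic label pair.
    kept_set = set(kept)
    diplotypes: dict[str, tuple[str, str]] = {}
    f_by_hap = {h: freq_of[label_of[h]] for h in kept}
    for call, cls in zip(panel, dog_class):
        best: tuple[str, str] | None = None
        best_p = -1.0
        for a, b in class_pairs[cls]:
            if a not in kept_set or b not in kept_set:
                continue
            coef = 1.0 if a == b else 2.0
            p = coef * f_by_hap[a] * f_by_hap[b]
            lab = tuple(sorted((label_of[a], label_of[b])))
            if p > best_p + 1e-15 or (abs(p - best_p) <= 1e-15 and (best is None or lab < best)):
                best, best_p = lab, max(p, best_p)
        if best is None:
            raise FloatingPointError(f"dog {call.dog_id}: all compatible haplotypes were pruned")
        diplotypes[call.dog_id] = best

    return PhasingResult(
        haplotypes=hapset,
        diplotypes=diplotypes,
        loglik_trace=loglik_trace,
        converged=converged,
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Linkage disequilibrium

@dataclass(frozen=True)
class LdResult:
    site_i: str
    site_j: str
    D: float
    r2: float
    defined: bool

    @property
    def displayed_r2_percent(self) -> int | None:
        if not self.defined:
            return None
        return round_half_up(100.0 * self.r2)


def _pool_codes(
    hapset: HaplotypeSet,
    population: str,
    variants: Sequence[Polymorphism],
) -> tuple[np.ndarray, np.ndarray]:
    """Expand a counted haplotype pool into per-chromosome 0/1 code rows."""
    code_mat = hapset.allele_code_matrix(variants)
    rows = []
    weights = []
    for label, count in hapset.counts[population].items():
        if count < 0:
            raise ValueError(f"negative count for haplotype {label}")
        if count:
            rows.append(code_mat[label])
            weights.append(count)
    return np.asarray(rows, dtype=float), np.asarray(weights, dtype=float)


def ld_r2(
    hapset: HaplotypeSet,
    population: str,
    site_i: str,
    site_j: str,
    variants: Sequence[Polymorphism],
) -> LdResult:
    """Pairwise D and r^2 from a counted haplotype pool.

    ``r^2 = D^2 / (pA qA pB qB)`` with p the variant-allele frequency at each
    site; a monomorphic site yields an undefined-LD sentinel rather than an
    exception.
    """
    rows, weights = _pool_codes(hapset, population, variants)
    i = hapset.site_order.index(site_i)
    j = hapset.site_order.index(site_j)
    total = weights.sum()
    pa = float(np.dot(weights, rows[:, i]) / total)
    pb = float(np.dot(weights, rows[:, j]) / total)
    pab = float(np.dot(weights, rows[:, i] * rows[:, j]) / total)
    D = pab - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    if denom <= 0:
        return LdResult(site_i, site_j, D=D, r2=float("nan"), defined=False)
    r2 = D * D / denom
    return LdResult(site_i, site_j, D=D, r2=float(min(max(r2, 0.0), 1.0)), defined=True)


def ld_matrix(
    hapset: HaplotypeSet,
    population: str,
    variants: Sequence[Polymorphism],
) -> dict[tuple[str, str], LdResult]:
    out = {}
    for a, b in itertools.combinations(hapset.site_order, 2):
        out[(a, b)] = ld_r2(hapset, population, a, b, variants)
    return out


# ---------------------------------------------------------------------------
# Diplotype-count arithmetic

@dataclass
class DiplotypeCounts:
    """Number of dogs observed with each unordered haplotype pair."""

    population: str
    counts: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        norm: dict[tuple[str, str], int] = {}
        for pair, c in self.counts.items():
            if c < 0 or c != int(c):
                raise ValueError(f"{self.population}: count for {pair} must be a nonnegative integer")
            a, b = sorted(pair)
            norm[(a, b)] = norm.get((a, b), 0) + int(c)
        self.counts = norm

    @property
    def n_dogs(self) -> int:
        return sum(self.counts.values())


def haplotype_freqs_from_diplotypes(counts: DiplotypeCounts) -> dict[str, dict[str, float]]:
    """Haplotype frequencies from diplotype counts (homozygotes count twice).

    Returns ``{label: {"frequency": fraction, "percent": round-half-up int}}``;
    the fractions sum to 1 exactly.
    """
    if not counts.counts:
        raise ValueError("empty diplotype counts")
    chrom = 2 * counts.n_dogs
    tallies: dict[str, int] = {}
    for (a, b), c in counts.counts.items():
        tallies[a] = tallies.get(a, 0) + c
        tallies[b] = tallies.get(b, 0) + c
    return {
        label: {"frequency": k / chrom, "percent": round_half_up(100.0 * k / chrom)}
        for label, k in sorted(tallies.items())
    }


# ---------------------------------------------------------------------------
# Breed-group comparison

def mann_whitney_u(
    x: Sequence[float],
    y: Sequence[float],
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    The exact null distribution is used when both groups have at most
    ``exact_max_n`` observations; otherwise the normal approximation with
    tie correction (and continuity correction) is applied.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    method = "exact" if (x.size <= exact_max_n and y.size <= exact_max_n and
                         np.unique(np.concatenate([x, y])).size == x.size + y.size) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    u_statistic: float
    p_value: float
    n_a: int = 0
    n_b: int = 0


def breed_group_compare(
    freq_by_breed: Mapping[str, float],
    group_of: Mapping[str, str],
    group_a: str,
    group_b: str,
    exact_max_n: int = 8,
) -> GroupComparison:
    """Compare per-breed haplotype frequencies between two breed groups
    (mean +/- SE per group, two-sided Mann-Whitney U)."""
    a = [v for b, v in freq_by_breed.items() if group_of[b] == group_a]
    b = [v for br, v in freq_by_breed.items() if group_of[br] == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 breeds")
    u, p = mann_whitney_u(a, b, exact_max_n=exact_max_n)
    a_arr, b_arr = np.asarray(a), np.asarray(b)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        mean_a=float(a_arr.mean()),
        se_a=float(a_arr.std(ddof=1) / math.sqrt(a_arr.size)),
        mean_b=float(b_arr.mean()),
        se_b=float(b_arr.std(ddof=1) / math.sqrt(b_arr.size)),
        u_statistic=u,
        p_value=p,
        n_a=a_arr.size,
        n_b=b_arr.size,
    )
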