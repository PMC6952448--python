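import itertools

import numpy as np
import pytest

from cyp2b11kit import datasets
from cyp2b11kit.variants import GenotypeCall, Polymorphism

HAPS_2SITE = [(0, 0), (0, 1), (1, 0), (1, 1)]


@pytest.fixture(scope="session")
def variants():
    return datasets.load_variant_table()


@pytest.fixture(scope="session")
def hapset():
    return datasets.load_discovery_haplotypes()


@pytest.fixture(scope="session")
def diplotype_counts():
    return datasets.load_diplotype_counts()


@pytest.fixture(scope="session")
def two_snp_variants():
    return [
        Polymorphism(id="sA", genomic_pos=100, cdna_pos=10, ref_allele="G", var_allele="A", region="utr3"),
        Polymorphism(id="sB", genomic_pos=200, cdna_pos=20, ref_allele="C", var_allele="T", region="utr3"),
    ]


def make_two_snp_panel(genotype_class_counts, two_snp_variants):
    """Build a panel from {(g1, g2): n_dogs} with g in {0: ref/ref, 1: het, 2: var/var}."""
    panel = []
    i = 0
    for (g1, g2), n in genotype_class_counts.items():
        for _ in range(n):
            i += 1
            alleles = {}
            for v, g in zip(two_snp_variants, (g1, g2)):
                pair = {
                    0: (v.ref_allele, v.ref_allele),
                    1: (v.ref_allele, v.var_allele),
                    2: (v.var_allele, v.var_allele),
                }[g]
                alleles[v.id] = pair
            panel.append(GenotypeCall(dog_id=f"dog{i:03d}", alleles=alleles))
    return panel


def _genotype_of(g):
    # unordered allele pair for a genotype code 0/1/2
    return {0: (0, 0), 1: (0, 1), 2: (1, 1)}[g]


def _compat_matrix(g1, g2):
    """4x4 indicator: ordered haplotype pair (i, j) compatible with (g1, g2)."""
    M = np.zeros((4, 4))
    want1, want2 = _genotype_of(g1), _genotype_of(g2)
    for i, a in enumerate(HAPS_2SITE):
        for j, b in enumerate(HAPS_2SITE):
            if tuple(sorted((a[0], b[0]))) == want1 and tuple(sorted((a[1], b[1]))) == want2:
                M[i, j] = 1.0
    return M


def two_site_loglik(freqs, genotype_class_counts):
    """Multinomial log-likelihood of two-site genotype counts given the four
    haplotype frequencies (order: 00, 01, 10, 11).  Independent oracle for
    checking the EM fixed point."""
    f = np.asarray(freqs, dtype=float)
    ll = 0.0
    for (g1, g2), n in genotype_class_counts.items():
        p = f @ _compat_matrix(g1, g2) @ f
        if p <= 0:
            return -np.inf
        ll += n * np.log(p)
    return ll


def grid_search_two_site(genotype_class_counts, coarse=0.02, fine=0.001):
    """Brute-force maximiser of the two-site multinomial likelihood over the
    haplotype-frequency simplex: coarse grid over the whole simplex, then
    local refinement at the fine step.  Fully vectorised so the fine step
    can be small."""
    mats = {g: _compat_matrix(*g) for g in genotype_class_counts}
    counts = np.array([genotype_class_counts[g] for g in genotype_class_counts], dtype=float)

    def evaluate(F):
        # F: (N, 4) frequency vectors on the simplex
        ll = np.zeros(F.shape[0])
        for g, n in zip(mats, counts):
            p = np.einsum("ni,ij,nj->n", F, mats[g], F)
            with np.errstate(divide="ignore"):
                ll += n * np.log(p)
        return ll

    def candidates(lo, hi, step):
        axes = [np.arange(max(0.0, l), min(1.0, h) + step / 2, step) for l, h in zip(lo, hi)]
        g1, g2, g3 = np.meshgrid(*axes, indexing="ij")
        F = np.column_stack([g1.ravel(), g2.ravel(), g3.ravel()])
        f4 = 1.0 - F.sum(axis=1)
        keep = f4 >= -1e-12
        return np.column_stack([F[keep], np.clip(f4[keep], 0.0, None)])

    F = candidates((0, 0, 0), (1, 1, 1), coarse)
    best = F[np.argmax(evaluate(F))]
    F = candidates(best[:3] - 1.5 * coarse, best[:3] + 1.5 * coarse, fine)
    ll = evaluate(F)
    i = np.argmax(ll)
    return F[i], float(ll[i])
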