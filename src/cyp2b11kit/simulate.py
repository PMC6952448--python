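"""Synthetic-data generators for every pipeline input.

The generators reproduce the statistical structure the analyses assume, so
the whole pipeline is testable without the study's raw sequencing and
enzymology data:

* breed panels of unphased diploid genotypes drawn under Hardy-Weinberg
  from labelled haplotype pools with stated frequencies (within-breed
  inbreeding is deliberately not modelled);
* paired RNA/DNA allelic read depths, binomial in a variant-read fraction
  that combines a true expression ratio rho with a variant:reference
  mapping-efficiency bias b *shared between tissues* — exactly the
  assumption that makes DNA-ratio correction valid;
* liver activity panels in which microsomal activity is an
  abundance-weighted sum of isoform intrinsic rates, with lognormal
  multiplicative jitter on abundances (positive, right-skewed) and optional
  independent readout noise;
* 3'-UTR sequences with AATAAA motifs planted at stated positions and a
  rejection-sampled background that contains no accidental motif, in
  either the reference or the variant-applied sequence.

Reproducibility: one global integer seed; each generator derives an
independent stream from ``(seed, generator name)`` so modules can be
regenerated independently and bit-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .motifs import CANONICAL_POLYA, scan_motif
from .variants import GenotypeCall, HaplotypeSet, Polymorphism, apply_variants

__all__ = [
    "BreedSpec",
    "AseSimParams",
    "ActivitySimParams",
    "derive_rng",
    "gen_breed_panel",
    "gen_allelic_counts",
    "gen_activity_panel",
    "gen_utr_sequence",
]


def derive_rng(seed: int, name: str) -> np.random.Generator:
    """Independent, named random stream derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode()),))
    )


# ---------------------------------------------------------------------------
# Breed genotype panels

@dataclass
class BreedSpec:
    """A breed population to simulate: haplotype pool frequencies and size."""

    name: str
    group: str  # sighthound | other | mixed
    n_dogs: int
    haplotype_freqs: dict[str, float]

    def __post_init__(self) -> None:
        if self.group not in ("sighthound", "other", "mixed"):
            raise ValueError(f"{self.name}: unknown breed group {self.group!r}")
        if self.n_dogs < 1:
            raise ValueError(f"{self.name}: n_dogs must be >= 1")
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: haplotype frequencies sum to {total}, not 1")
        if any(f < 0 for f in self.haplotype_freqs.values()):
            raise ValueError(f"{self.name}: negative haplotype frequency")


def gen_breed_panel(
    specs: Sequence[BreedSpec],
    haplotype_defs: HaplotypeSet,
    variants: Sequence[Polymorphism],
    seed: int,
) -> tuple[list[GenotypeCall], pd.DataFrame]:
    """Simulate unphased genotype panels for one or more breeds.

    Each dog's two haplotypes are drawn i.i.d. from its breed's frequency
    vector (Hardy-Weinberg); unphased genotypes are derived per site with
    alleles sorted reference-first so no phase leaks.  Returns the panel
    and a truth table (dog_id, breed, group, hap_a, hap_b) for oracle
    checks.
    """
    for spec in specs:
        unknown = set(spec.haplotype_freqs) - set(haplotype_defs.haplotypes)
        if unknown:
            raise KeyError(f"{spec.name}: haplotype labels {sorted(unknown)} not defined")
    haplotype_defs.validate_against(variants)
    rng = derive_rng(seed, "breed_panel")
    by_id = {v.id: v for v in variants}
    site_order = haplotype_defs.site_order
    panel: list[GenotypeCall] = []
    truth_rows = []
    for spec in specs:
        labels = sorted(spec.haplotype_freqs)
        probs = np.array([spec.haplotype_freqs[l] for l in labels])
        draws = rng.choice(len(labels), size=(spec.n_dogs, 2), p=probs)
        for d in range(spec.n_dogs):
            la, lb = labels[draws[d, 0]], labels[draws[d, 1]]
            if lb < la:
                la, lb = lb, la
            dog_id = f"{spec.name}_{d + 1:04d}"
            alleles = {}
            for s, aa, ab in zip(
                site_order,
                haplotype_defs.haplotypes[la],
                haplotype_defs.haplotypes[lb],
            ):
                pair = sorted((aa, ab), key=lambda a: (by_id[s].allele_code(a), a))
                alleles[s] = (pair[0], pair[1])
            panel.append(GenotypeCall(dog_id=dog_id, alleles=alleles, breed=spec.name, group=spec.group))
            truth_rows.append(
                {"dog_id": dog_id, "breed": spec.name, "group": spec.group, "hap_a": la, "hap_b": lb}
            )
    return panel, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Allelic read depths

@dataclass
class AseSimParams:
    """Paired RNA/DNA depth simulation for one heterozygous site set.

    ``true_ratio`` (rho) is the variant:reference expression ratio;
    ``mapping_bias`` (b) is the variant:reference mapping-efficiency ratio
    shared between RNA and DNA of the same site.
    """

    true_ratio: float
    mapping_bias: float
    depth_rna: int
    depth_dna: int
    n_samples: int
    seed: int
    sites: tuple[tuple[str, int], ...] = (("site1", 1000),)  # (site_id, cdna_pos)

    def __post_init__(self) -> None:
        if self.true_ratio < 0:
            raise ValueError("true_ratio must be nonnegative")
        if self.mapping_bias <= 0:
            raise ValueError("mapping_bias must be positive")
        if self.depth_rna < 1 or self.depth_dna < 1:
            raise ValueError("depths must be >= 1")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def gen_allelic_counts(params: AseSimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate paired RNA and DNA per-site read-depth tables.

    DNA variant depth ~ Binomial(depth_dna, b/(1+b)); RNA variant depth
    ~ Binomial(depth_rna, rho*b/(1+rho*b)).  Separate individuals supply the
    DNA cohort, as in a design where genomic sequencing comes from other
    dogs of the same diplotype.
    """
    rng = derive_rng(params.seed, "allelic_counts")
    rho, b = params.true_ratio, params.mapping_bias
    p_dna = b / (1.0 + b)
    p_rna = (rho * b) / (1.0 + rho * b) if rho > 0 else 0.0
    rows_rna, rows_dna = [], []
    for site_id, cdna_pos in params.sites:
        var_rna = rng.binomial(params.depth_rna, p_rna, size=params.n_samples)
        var_dna = rng.binomial(params.depth_dna, p_dna, size=params.n_samples)
        for s in range(params.n_samples):
            rows_rna.append(
                {"sample_id": f"rna_{s + 1:03d}", "tissue": "RNA", "site_id": site_id,
                 "cdna_pos": cdna_pos, "ref_depth": params.depth_rna - int(var_rna[s]),
                 "var_depth": int(var_rna[s])}
            )
            rows_dna.append(
                {"sample_id": f"dna_{s + 1:03d}", "tissue": "DNA", "site_id": site_id,
                 "cdna_pos": cdna_pos, "ref_depth": params.depth_dna - int(var_dna[s]),
                 "var_depth": int(var_dna[s])}
            )
    return pd.DataFrame(rows_rna), pd.DataFrame(rows_dna)


# ---------------------------------------------------------------------------
# Liver activity panels

@dataclass
class ActivitySimParams:
    """Liver panel simulation: abundance-weighted isoform activities.

    ``noise_cv`` is the coefficient of variation of the lognormal
    multiplicative jitter applied to each liver's isoform abundances;
    ``readout_cv`` adds independent lognormal noise to the activity
    measurement itself.
    """

    abundances: dict[str, float]
    intrinsic_rates: dict[str, float]
    noise_cv: float
    n_livers: int
    seed: int
    readout_cv: float = 0.0

    def __post_init__(self) -> None:
        if set(self.abundances) != set(self.intrinsic_rates):
            raise ValueError("abundance and intrinsic-rate label sets must match")
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be nonnegative")
        if any(v < 0 for v in self.intrinsic_rates.values()):
            raise ValueError("intrinsic rates must be nonnegative")
        if self.noise_cv < 0 or self.readout_cv < 0:
            raise ValueError("noise CVs must be nonnegative")
        if self.n_livers < 1:
            raise ValueError("n_livers must be >= 1")


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal jitter with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def gen_activity_panel(params: ActivitySimParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-liver microsomal activities and isoform protein contents.

    Liver activity = sum_i abundance_i * jitter_i * intrinsic_i (times
    optional readout noise); per-liver protein content of each isoform is
    abundance_i * jitter_i, so protein and activity share the jitter that
    drives their correlation.
    """
    rng = derive_rng(params.seed, "activity_panel")
    labels = sorted(params.abundances)
    ab = np.array([params.abundances[l] for l in labels])
    intr = np.array([params.intrinsic_rates[l] for l in labels])
    jitter = _lognormal_unit_mean(rng, params.noise_cv, (params.n_livers, len(labels)))
    protein = ab[None, :] * jitter
    activity = (protein * intr[None, :]).sum(axis=1)
    activity = activity * _lognormal_unit_mean(rng, params.readout_cv, params.n_livers)
    liver_ids = [f"liver_{i + 1:03d}" for i in range(params.n_livers)]
    act_df = pd.DataFrame({"liver_id": liver_ids, "activity": activity})
    prot_df = pd.DataFrame(protein, columns=labels)
    prot_df.insert(0, "liver_id", liver_ids)
    return act_df, prot_df


# ---------------------------------------------------------------------------
# 3'-UTR sequences

class UtrGenerationError(RuntimeError):
    pass


def gen_utr_sequence(
    length: int,
    motif_positions: Sequence[int],
    variants: Sequence[Polymorphism],
    seed: int,
    motif: str = CANONICAL_POLYA,
    seq_start: int = 1,
    max_attempts: int = 1000,
) -> tuple[str, str]:
    """Generate a reference transcript segment and its variant-applied form.

    The motif is planted exactly at the stated 1-based positions (in the
    ``seq_start`` coordinate frame); reference alleles of the supplied
    markers are embedded at their positions.  The random background is
    rejection-sampled so that neither the reference nor the variant-applied
    sequence contains an accidental motif.  Motif windows may not overlap
    each other or a marker span.
    """
    if length < 1:
        raise ValueError("length must be positive")
    k = len(motif)
    spans = [(p, p + k - 1) for p in motif_positions]
    for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
        if a2 <= b1:
            raise UtrGenerationError("motif windows overlap")
    for v in variants:
        va, vb = v.cdna_pos, v.cdna_pos + len(v.ref_allele) - 1
        if va < seq_start or vb > seq_start + length - 1:
            raise UtrGenerationError(f"marker {v.id} outside the sequence")
        for a, b in spans:
            if va <= b and vb >= a:
                raise UtrGenerationError(f"marker {v.id} collides with a motif window")
    for p in motif_positions:
        if p < seq_start or p + k - 1 > seq_start + length - 1:
            raise UtrGenerationError(f"motif position {p} outside the sequence")

    rng = derive_rng(seed, "utr_sequence")
    bases = np.array(list("ACGT"))
    wanted = set(motif_positions)
    for _ in range(max_attempts):
        seq = list(rng.choice(bases, size=length))
        for v in variants:
            i = v.cdna_pos - seq_start
            seq[i : i + len(v.ref_allele)] = list(v.ref_allele)
        for p in motif_positions:
            i = p - seq_start
            seq[i : i + k] = list(motif)
        ref = "".join(seq)
        if {h.cdna_start for h in scan_motif(ref, motif, seq_start)} != wanted:
            continue
        alt, posmap = apply_variants(ref, variants, seq_start=seq_start)
        alt_hits_ref = {posmap.alt_to_ref(h.cdna_start) for h in scan_motif(alt, motif, seq_start)}
        if alt_hits_ref != wanted:
            continue
        return ref, alt
    raise UtrGenerationError(f"could not generate a motif-clean sequence in {max_attempts} attempts")
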