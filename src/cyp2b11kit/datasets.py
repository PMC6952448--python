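"""Bundled fixtures: the published marker panel, discovery haplotype pools,
and breed diplotype counts, shipped as package data so the desk-scale
replication analyses run offline."""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .popgen import DiplotypeCounts
from .variants import HaplotypeSet, Polymorphism, read_variant_table

__all__ = [
    "load_variant_table",
    "load_discovery_haplotypes",
    "load_diplotype_counts",
    "greyhound_breed_spec_freqs",
]


def _data_path(name: str):
    return resources.files("cyp2b11kit.data").joinpath(name)


def load_variant_table() -> list[Polymorphism]:
    """The 9-marker panel: enhancer SNP, exon-7 synonymous SNP, and seven
    3'-UTR markers between c.1913 and c.2536."""
    with resources.as_file(_data_path("variants_table.tsv")) as p:
        return read_variant_table(p)


def load_discovery_haplotypes() -> HaplotypeSet:
    """Six discovery haplotypes (H1-H6) with chromosome counts for the
    Greyhound (n=26 chromosomes) and 45-other-breed (n=90) pools."""
    df = pd.read_csv(_data_path("haplotypes_discovery.tsv"), sep="\t", dtype=str)
    site_order = [c for c in df.columns if c.startswith("#")]
    haplotypes = {
        row["label"]: tuple(row[s] for s in site_order) for _, row in df.iterrows()
    }
    counts = {
        "greyhound": {row["label"]: int(row["greyhound_count"]) for _, row in df.iterrows()},
        "other_breeds": {row["label"]: int(row["other_breeds_count"]) for _, row in df.iterrows()},
    }
    return HaplotypeSet(site_order=site_order, haplotypes=haplotypes, counts=counts)


def load_diplotype_counts() -> dict[str, DiplotypeCounts]:
    """Per-population diplotype counts from the breed genotyping survey."""
    df = pd.read_csv(_data_path("diplotype_counts.tsv"), sep="\t")
    out: dict[str, DiplotypeCounts] = {}
    pair_cols = [c for c in df.columns if "/" in c]
    for _, row in df.iterrows():
        counts = {tuple(c.split("/")): int(row[c]) for c in pair_cols}
        dc = DiplotypeCounts(population=row["population"], counts=counts)
        if dc.n_dogs != int(row["n_dogs"]):
            raise ValueError(f"{row['population']}: diplotype counts sum to {dc.n_dogs}, not {row['n_dogs']}")
        out[row["population"]] = dc
    return out


def greyhound_breed_spec_freqs() -> dict[str, float]:
    """Greyhound discovery-pool haplotype frequencies (8/26, 13/26, 5/26)."""
    hs = load_discovery_haplotypes()
    freqs = hs.freq_from_counts("greyhound")
    return {k: v for k, v in freqs.items() if v > 0}
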