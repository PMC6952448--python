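#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Writes to results/sim/: a 500-dog Greyhound genotype panel (with the true
diplotypes kept aside for oracle checks), paired RNA/DNA allelic read
depths for an H1/H2-like cohort, a 15-liver activity panel driven by a
single isoform, and a synthetic full-length transcript carrying the seven
3'-UTR markers with polyadenylation signals planted at c.1715 and c.2582.
"""

from pathlib import Path

from cyp2b11kit import datasets
from cyp2b11kit.ase import write_site_depths
from cyp2b11kit.phenotyping import DOG_LIVER_CYP_ABUNDANCE
from cyp2b11kit.simulate import (
    ActivitySimParams,
    AseSimParams,
    BreedSpec,
    gen_activity_panel,
    gen_allelic_counts,
    gen_breed_panel,
    gen_utr_sequence,
)
from cyp2b11kit.variants import write_fasta, write_genotypes

SEED = 20240901
OUT = Path(__file__).resolve().parents[1] / "results" / "sim"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    variants = datasets.load_variant_table()
    hapset = datasets.load_discovery_haplotypes()

    # Greyhound discovery-pool frequencies (8/26, 13/26, 5/26)
    spec = BreedSpec("Greyhound", "sighthound", 500, datasets.greyhound_breed_spec_freqs())
    panel, truth = gen_breed_panel([spec], hapset, variants, seed=SEED)
    write_genotypes(panel, variants, OUT / "greyhound_panel.tsv")
    truth.to_csv(OUT / "greyhound_diplotype_truth.tsv", sep="\t", index=False)
    print(f"wrote {len(panel)}-dog Greyhound panel over {len(variants)} markers")

    # H1/H2-like cohort: near-silenced variant allele (rho 0.1) with a
    # mapping bias of 0.8 against the variant, depth 500, six samples each
    ase = AseSimParams(
        true_ratio=0.1, mapping_bias=0.8, depth_rna=500, depth_dna=500,
        n_samples=6, seed=SEED,
        sites=(("#5", 2137), ("#6", 2166)),
    )
    rna, dna = gen_allelic_counts(ase)
    rna["breed"], rna["diplotype"] = "Greyhound", "H1/H2"
    dna["diplotype"] = "H1/H2"
    write_site_depths(rna, OUT / "ase_rna_depths.tsv")
    write_site_depths(dna, OUT / "ase_dna_depths.tsv")
    print(f"wrote paired RNA/DNA depths: {len(rna)} RNA rows, {len(dna)} DNA rows")

    # 15-liver panel, bupropion-hydroxylation-like: CYP2B11 is the only
    # active isoform; abundance jitter CV 0.3, readout CV 0.3
    intrinsic = {k: 0.0 for k in DOG_LIVER_CYP_ABUNDANCE}
    intrinsic["CYP2B11"] = 1.0
    act_params = ActivitySimParams(
        abundances=DOG_LIVER_CYP_ABUNDANCE, intrinsic_rates=intrinsic,
        noise_cv=0.3, n_livers=15, seed=SEED, readout_cv=0.3,
    )
    act, prot = gen_activity_panel(act_params)
    act.to_csv(OUT / "liver_activity.tsv", sep="\t", index=False)
    prot.to_csv(OUT / "liver_protein.tsv", sep="\t", index=False)
    print(f"wrote {len(act)}-liver activity and protein tables")

    utr3 = [v for v in variants if v.region == "utr3"]
    ref, alt = gen_utr_sequence(2625, [1715, 2582], utr3, seed=SEED)
    write_fasta({"transcript_ref_synthetic": ref, "transcript_var_synthetic": alt},
                OUT / "transcript_synthetic.fasta")
    print("wrote synthetic transcript pair (reference + all-variant)")


if __name__ == "__main__":
    main()
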