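#!/usr/bin/env python
"""Mapping-bias-corrected allelic imbalance and transcript 3'-end inference.

Reads the simulated H1/H2 cohort depths from results/sim/ and writes to
results/ase/.  Findings: the DNA-normalised estimator recovers the true
variant:reference expression ratio of 0.1 at both 3'-UTR sites despite a
mapping bias of 0.8 against the variant allele, both sites are flagged
imbalanced at the 0.3 threshold, and the combined imbalance + amplicon
evidence brackets the truncated H2 transcript end at (c.1913, c.2138),
the H3 end at (c.1952, c.2199), and leaves the H1 end at c.2625.
"""

import json
from pathlib import Path

import pandas as pd

from cyp2b11kit.ase import (
    RegionPresence,
    corrected_ratio_profile,
    detect_imbalance,
    infer_transcript_end,
    read_site_depths,
)
from cyp2b11kit import datasets

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results" / "ase"

REGIONS = {
    "H1": [RegionPresence("Region 1", 1773, 1872, "strong"),
           RegionPresence("Region 2", 1853, 2199, "strong"),
           RegionPresence("Region 3", 1853, 2312, "strong")],
    "H2": [RegionPresence("Region 1", 1773, 1872, "strong"),
           RegionPresence("Region 2", 1853, 2199, "weak"),
           RegionPresence("Region 3", 1853, 2312, "absent")],
    "H3": [RegionPresence("Region 1", 1773, 1872, "strong"),
           RegionPresence("Region 2", 1853, 2199, "weak"),
           RegionPresence("Region 3", 1853, 2312, "absent")],
}
REFERENCE_END = 2625


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    variants = datasets.load_variant_table()
    site_lengths = {v.id: len(v.ref_allele) for v in variants}

    rna = read_site_depths(SIM / "ase_rna_depths.tsv")
    dna = read_site_depths(SIM / "ase_dna_depths.tsv")
    prof = corrected_ratio_profile(rna, dna)
    prof = detect_imbalance(prof, threshold=0.3)
    prof.to_csv(OUT / "corrected_profile.tsv", sep="\t", index=False)
    print("corrected variant:reference ratios by site:")
    print(prof[["site_id", "cdna_pos", "raw_rna_ratio", "dna_ratio",
                "corrected_ratio", "imbalanced"]].to_string(index=False))

    # per-haplotype evidence patterns: the simulated H1/H2 profile supplies
    # the H2 sites; H3's single SNP (corrected ratio 0.7) and H1's balanced
    # profile are encoded directly
    h2_profile = pd.concat([
        pd.DataFrame([{"site_id": "#3", "cdna_pos": 1913, "corrected_ratio": 0.95}]),
        prof[["site_id", "cdna_pos", "corrected_ratio"]],
    ], ignore_index=True)
    h3_profile = pd.DataFrame([{"site_id": "#4", "cdna_pos": 1952, "corrected_ratio": 0.7}])
    h1_profile = pd.DataFrame(
        [{"site_id": s, "cdna_pos": p, "corrected_ratio": 1.0}
         for s, p in (("#5", 2137), ("#6", 2166))]
    )

    intervals = {}
    for hap, profile in (("H1", h1_profile), ("H2", h2_profile), ("H3", h3_profile)):
        res = infer_transcript_end(profile, REGIONS[hap], REFERENCE_END,
                                   site_lengths=site_lengths)
        intervals[hap] = {"low": res.low, "high": res.high, "consistent": res.consistent}
        print(f"{hap}: transcript 3' end in (c.{res.low}, c.{res.high})")
    (OUT / "transcript_end_intervals.json").write_text(json.dumps(intervals, indent=2))


if __name__ == "__main__":
    main()
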