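#!/usr/bin/env python
"""Hepatic-abundance extrapolation, correlation attribution, and
diplotype-phenotype association on the simulated liver panel.

Writes to results/phenotyping/.  Findings: with equal per-pmol rates the
CYP2B11:CYP3A12 contribution split follows their hepatic abundances
(79 vs 125 pmol/mg, fractions 0.39/0.61); on the simulated single-driver
panel CYP2B11 protein attains the top Spearman correlation with activity;
and a cohort in which carriers translate protein at 30% efficiency shows
a significantly lower protein/mRNA ratio by exact Mann-Whitney test.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from cyp2b11kit.phenotyping import (
    DOG_LIVER_CYP_ABUNDANCE,
    diplotype_association,
    extrapolate_to_microsomes,
    spearman_corr,
)

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "sim"
OUT = ROOT / "results" / "phenotyping"
SEED = 20240904


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # --- abundance extrapolation for a two-isoform split
    table = extrapolate_to_microsomes({"CYP2B11": 1.0, "CYP3A12": 1.0})
    table.to_csv(OUT / "extrapolation_two_isoform.tsv", sep="\t", index=False)
    fr = dict(zip(table["cyp"], table["fraction"]))
    print(f"equal specific rates: CYP2B11 fraction {fr['CYP2B11']:.3f}, "
          f"CYP3A12 fraction {fr['CYP3A12']:.3f}")

    # --- correlation attribution on the simulated panel
    act = pd.read_csv(SIM / "liver_activity.tsv", sep="\t")
    prot = pd.read_csv(SIM / "liver_protein.tsv", sep="\t")
    rows = []
    for cyp in DOG_LIVER_CYP_ABUNDANCE:
        rs = stats.spearmanr(prot[cyp], act["activity"]).statistic
        rows.append({"cyp": cyp, "spearman_rs": round(float(rs), 3)})
    corr = pd.DataFrame(rows).sort_values("spearman_rs", ascending=False)
    corr.to_csv(OUT / "protein_activity_correlation.tsv", sep="\t", index=False)
    print("top correlate with activity:", corr.iloc[0]["cyp"],
          f"(Rs = {corr.iloc[0]['spearman_rs']})")

    # exact permutation p-value for a small sub-panel of the driver
    rs, p = spearman_corr(prot["CYP2B11"][:8], act["activity"][:8])
    print(f"driver sub-panel (n=8): Rs = {rs:.2f}, exact p = {p:.4f}")

    # --- diplotype association: carriers translate at 30% efficiency
    rng = np.random.default_rng(SEED)
    rows = []
    for i in range(15):
        carrier = i >= 5
        mrna = rng.lognormal(0, 0.3)
        protein = mrna * (0.3 if carrier else 1.0) * rng.lognormal(0, 0.3)
        rows.append({"liver_id": f"L{i:02d}",
                     "diplotype": "H1/H2" if carrier else "H1/H1",
                     "protein": protein, "mrna": mrna,
                     "protein_mrna_ratio": protein / mrna})
    livers = pd.DataFrame(rows)
    assoc = diplotype_association(livers, ["protein", "mrna", "protein_mrna_ratio"])
    assoc.to_csv(OUT / "diplotype_association.tsv", sep="\t", index=False)
    row = assoc.set_index("phenotype").loc["protein_mrna_ratio"]
    print(f"protein/mRNA ratio: H1/H1 median {row['ref_median']:.2f} "
          f"(IQR {row['ref_q1']:.2f}-{row['ref_q3']:.2f}) vs carriers "
          f"{row['carrier_median']:.2f} (IQR {row['carrier_q1']:.2f}-"
          f"{row['carrier_q3']:.2f}), Mann-Whitney p = {row['p_value']:.4f}")


if __name__ == "__main__":
    main()
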