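"""Allele-specific expression from paired RNA/DNA read depths, and
transcript 3'-end interval inference.

The estimator follows the two-step normalisation used for heterozygous
liver samples: variant:reference read-depth ratios are computed per sample
at each transcript-internal marker, averaged within a (breed x diplotype)
group, and the group average is divided by the corresponding averaged DNA
allelic ratio from a genomic-sequencing cohort of the same diplotype.  The
DNA ratio captures mapping-efficiency differences between the variant and
reference alleles; because alignment bias acts identically on RNA and DNA
reads at a site, the division cancels it and leaves the true expression
ratio.

Transcript 3'-end inference combines two evidence channels:

* per-site corrected ratios: a balanced (expressed) heterozygous site shows
  the transcript extends at least to that site; an imbalanced site shows
  the variant transcript has ended before it;
* RT-PCR amplicon presence calls over fixed cDNA regions: a *strong* band
  means transcripts span the whole amplicon (lower bound at its 3' primer),
  a *weak* band means full-length amplicons are depleted (upper bound at
  its 3' primer), *absent* means the transcript ends before the 3' primer.

Multi-nucleotide markers bound the interval with their 3'-most reference
base: the dinucleotide marker starting at c.2137 therefore sets an upper
bound of c.2138.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SITE_DEPTH_COLUMNS",
    "RegionPresence",
    "EndInterval",
    "read_site_depths",
    "write_site_depths",
    "raw_allelic_ratio",
    "corrected_ratio_profile",
    "detect_imbalance",
    "infer_transcript_end",
]

SITE_DEPTH_COLUMNS = ["sample_id", "tissue", "site_id", "cdna_pos", "ref_depth", "var_depth"]


def read_site_depths(path: str | Path) -> pd.DataFrame:
    """Read a per-site read-depth TSV and validate the schema.

    Extra metadata columns (breed, diplotype, ...) are preserved.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SITE_DEPTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df[~df["tissue"].isin(["RNA", "DNA"])]
    if not bad.empty:
        raise ValueError(f"{path}: tissue must be RNA or DNA (first bad row {bad.index[0] + 2})")
    if (df[["ref_depth", "var_depth"]] < 0).any().any():
        raise ValueError(f"{path}: negative read depths")
    return df


def write_site_depths(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def raw_allelic_ratio(var_depth: float, ref_depth: float, pseudocount: float = 0.0) -> float:
    """Variant:reference depth ratio ``(var + pc) / (ref + pc)``.

    With the default pseudocount of 0 a zero reference depth yields ``inf``;
    sites below the inclusion depth are meant to be filtered out upstream.
    """
    if var_depth < 0 or ref_depth < 0:
        raise ValueError("read depths must be nonnegative")
    num = var_depth + pseudocount
    den = ref_depth + pseudocount
    return float(num / den) if den > 0 else float("inf")


def _mean_ratios(
    df: pd.DataFrame,
    group_cols: Sequence[str],
    min_depth: int,
    pseudocount: float,
) -> pd.DataFrame:
    kept = df[(df["ref_depth"] + df["var_depth"]) >= min_depth].copy()
    kept["ratio"] = (kept["var_depth"] + pseudocount) / (kept["ref_depth"] + pseudocount)
    keys = [*group_cols, "site_id", "cdna_pos"]
    return kept.groupby(keys, as_index=False)["ratio"].mean()


def corrected_ratio_profile(
    rna: pd.DataFrame,
    dna: pd.DataFrame,
    rna_groupby: Sequence[str] = ("breed", "diplotype"),
    dna_groupby: Sequence[str] = ("diplotype",),
    min_depth: int = 20,
    pseudocount: float = 0.0,
    per_sample: bool = False,
) -> pd.DataFrame:
    """Mapping-bias-corrected variant:reference expression ratios.

    Default order of operations: average raw RNA ratios within each RNA
    group, average DNA ratios within the DNA reference cohort, then divide
    elementwise per site.  Set ``per_sample=True`` to instead correct each
    RNA sample by the cohort DNA ratio before averaging (an alternative the
    default deliberately does not use).

    ``dna_groupby`` must be a subset of ``rna_groupby`` (plus site keys) so
    every RNA group can be joined to a DNA cohort; a DNA ratio of zero at a
    site flags that site uncorrectable (``corrected_ratio`` NaN,
    ``uncorrectable`` True).
    """
    rna_groupby = list(rna_groupby)
    dna_groupby = list(dna_groupby)
    if not set(dna_groupby) <= set(rna_groupby):
        raise ValueError("dna_groupby must be a subset of rna_groupby")
    dna_means = _mean_ratios(dna, dna_groupby, min_depth, pseudocount).rename(
        columns={"ratio": "dna_ratio"}
    )
    if per_sample:
        kept = rna[(rna["ref_depth"] + rna["var_depth"]) >= min_depth].copy()
        kept["raw"] = (kept["var_depth"] + pseudocount) / (kept["ref_depth"] + pseudocount)
        merged = kept.merge(dna_means, on=[*dna_groupby, "site_id", "cdna_pos"], how="left")
        merged["corr"] = merged["raw"] / merged["dna_ratio"]
        prof = merged.groupby([*rna_groupby, "site_id", "cdna_pos"], as_index=False).agg(
            raw_rna_ratio=("raw", "mean"),
            dna_ratio=("dna_ratio", "mean"),
            corrected_ratio=("corr", "mean"),
        )
    else:
        rna_means = _mean_ratios(rna, rna_groupby, min_depth, pseudocount).rename(
            columns={"ratio": "raw_rna_ratio"}
        )
        prof = rna_means.merge(dna_means, on=[*dna_groupby, "site_id", "cdna_pos"], how="left")
        prof["corrected_ratio"] = prof["raw_rna_ratio"] / prof["dna_ratio"]
    prof["uncorrectable"] = ~np.isfinite(prof["corrected_ratio"])
    prof.loc[prof["uncorrectable"], "corrected_ratio"] = np.nan
    return prof.sort_values([*rna_groupby, "cdna_pos"]).reset_index(drop=True)


def detect_imbalance(profile: pd.DataFrame, threshold: float = 0.3) -> pd.DataFrame:
    """Flag sites whose corrected ratio falls strictly below ``threshold``.

    The default of 0.3 separates near-silenced variant alleles (corrected
    ratios around 0.05-0.15) from the mildly reduced regime (around 0.7)
    that is not informative about transcript truncation.
    """
    if profile.empty:
        raise ValueError("empty ratio profile")
    out = profile.copy()
    out["imbalanced"] = out["corrected_ratio"] < threshold
    return out


@dataclass(frozen=True)
class RegionPresence:
    """RT-PCR amplicon presence call over a cDNA span (primer coordinates)."""

    label: str
    start: int
    end: int
    call: str  # strong | weak | absent

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.label}: start must precede end")
        if self.call not in ("strong", "weak", "absent"):
            raise ValueError(f"region {self.label}: call {self.call!r} not in strong/weak/absent")


@dataclass
class EndInterval:
    """Inferred location of the transcript 3' end, in cDNA coordinates."""

    low: int | None
    high: int | None
    consistent: bool
    problems: list[str] = field(default_factory=list)


def infer_transcript_end(
    profile: pd.DataFrame,
    regions: Sequence[RegionPresence],
    reference_end: int,
    threshold: float = 0.3,
    site_lengths: dict[str, int] | None = None,
) -> EndInterval:
    """Bracket the transcript 3' end from imbalance and amplicon evidence.

    Lower-bound candidates (transcript extends at least this far):
    expressed/balanced heterozygous sites (their cDNA position) and the 3'
    ends of regions with strong bands.  Upper-bound candidates (transcript
    has ended by here): the 3'-most reference base of the most-5'
    imbalanced site (``site_lengths`` maps site_id to reference-allele
    length for multi-nucleotide markers), and the 3' primer coordinates of
    weak and absent regions.  With no truncation evidence the interval
    collapses to ``(reference_end, reference_end)``.  Contradictory
    evidence (upper bound 5' of a lower bound) yields no interval and a
    problem report.
    """
    regions = sorted(regions, key=lambda r: (r.start, r.end))
    for r in regions:
        if r.end > reference_end:
            raise ValueError(f"region {r.label} extends past the reference 3' end")
    site_lengths = site_lengths or {}
    flagged = detect_imbalance(profile, threshold)

    lower: list[int] = []
    upper: list[int] = []
    for _, row in flagged.iterrows():
        if not np.isfinite(row["corrected_ratio"]):
            continue
        if row["imbalanced"]:
            upper.append(int(row["cdna_pos"]) + site_lengths.get(row["site_id"], 1) - 1)
        else:
            lower.append(int(row["cdna_pos"]))
    for r in regions:
        if r.call == "strong":
            lower.append(r.end)
        else:  # weak or absent: full-length amplicons depleted or gone
            upper.append(r.end)

    if not upper:
        return EndInterval(low=reference_end, high=reference_end, consistent=True)
    low = max(lower) if lower else None
    high = min(upper)
    if low is not None and high < low:
        return EndInterval(
            low=None,
            high=None,
            consistent=False,
            problems=[
                f"upper-bound evidence at c.{high} lies 5' of lower-bound evidence at c.{low}"
            ],
        )
    return EndInterval(low=low, high=high, consistent=True)
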