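"""Variant and genotype data model, coordinate conventions, and tabular IO.

Conventions
-----------
* Genomic positions are 1-based, inclusive, on the reference assembly, and
  always refer to the *first* nucleotide of a (possibly multi-nucleotide)
  marker.
* cDNA positions are transcript coordinates with the adenine of the start
  codon at +1; upstream positions are negative (e.g. the enhancer marker at
  c.-489).  There is no position 0.
* Multi-nucleotide substitutions (TG/CA) and insertions (TCA/TCCA) are kept
  as single biallelic markers; no normalisation to a minimal VCF
  representation is attempted, because the downstream haplotype and
  allelic-imbalance analyses treat each marker as one locus.
* Coordinate mapping between genomic and cDNA space is a table lookup over
  the loaded marker panel, not a general liftover.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "MISSING",
    "Polymorphism",
    "GenotypeCall",
    "HaplotypeSet",
    "CoordinateMap",
    "PositionMap",
    "VariantTableError",
    "GenotypeParseError",
    "read_variant_table",
    "write_variant_table",
    "read_genotypes",
    "write_genotypes",
    "read_genotypes_vcf",
    "read_fasta",
    "write_fasta",
    "apply_variants",
]

#: Sentinel for an unobserved allele in a genotype call.
MISSING = "."

_VALID_REGION_PREFIXES = ("enhancer", "exon_", "utr3")
_NUCLEOTIDES = frozenset("ACGT")


class VariantTableError(ValueError):
    """Raised when a variant definition table violates the schema."""


class GenotypeParseError(ValueError):
    """Raised when a genotype panel is inconsistent with its variant panel."""


def _check_allele(allele: str, what: str, row: object) -> None:
    if not allele or set(allele) - _NUCLEOTIDES:
        raise VariantTableError(f"row {row}: {what} allele {allele!r} is not a nonempty A/C/G/T string")


@dataclass(frozen=True)
class Polymorphism:
    """A single biallelic marker keyed by its first-nucleotide position.

    ``ref_allele``/``var_allele`` may differ in length (insertions); the
    marker still behaves as one biallelic locus.
    """

    id: str
    genomic_pos: int
    cdna_pos: int
    ref_allele: str
    var_allele: str
    region: str
    dbsnp_id: str | None = None

    def __post_init__(self) -> None:
        _check_allele(self.ref_allele, "reference", self.id)
        _check_allele(self.var_allele, "variant", self.id)
        if self.ref_allele == self.var_allele:
            raise VariantTableError(f"row {self.id}: reference and variant alleles are identical")
        if self.genomic_pos <= 0:
            raise VariantTableError(f"row {self.id}: genomic position must be positive")
        if self.cdna_pos == 0:
            raise VariantTableError(f"row {self.id}: cDNA position 0 does not exist (+1 is the start codon A)")
        if not self.region.startswith(_VALID_REGION_PREFIXES):
            raise VariantTableError(f"row {self.id}: unknown region {self.region!r}")

    @property
    def cdna_end(self) -> int:
        """cDNA position of the 3'-most reference base of the marker."""
        return self.cdna_pos + len(self.ref_allele) - 1

    def allele_code(self, allele: str) -> int | None:
        """0 for the reference allele, 1 for the variant, None for missing."""
        if allele == self.ref_allele:
            return 0
        if allele == self.var_allele:
            return 1
        if allele == MISSING:
            return None
        raise GenotypeParseError(
            f"allele {allele!r} at site {self.id} is neither {self.ref_allele!r} nor {self.var_allele!r}"
        )


@dataclass
class GenotypeCall:
    """Unphased diploid genotype of one dog over a marker panel.

    ``alleles`` maps site id to an unordered allele pair (strings equal to
    the site's ref or var allele, or :data:`MISSING`).
    """

    dog_id: str
    alleles: dict[str, tuple[str, str]]
    breed: str = ""
    group: str = ""

    def codes(self, variants: Sequence[Polymorphism]) -> list[tuple[int | None, int | None]]:
        """Per-site unordered allele codes (0=ref, 1=var, None=missing)."""
        out = []
        for v in variants:
            a1, a2 = self.alleles[v.id]
            out.append((v.allele_code(a1), v.allele_code(a2)))
        return out


@dataclass
class HaplotypeSet:
    """Labelled haplotypes over an ordered marker panel, with optional
    per-population counts and/or frequencies."""

    site_order: list[str]
    haplotypes: dict[str, tuple[str, ...]]
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    frequencies: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.site_order)
        for label, vec in self.haplotypes.items():
            if len(vec) != n:
                raise VariantTableError(
                    f"haplotype {label}: {len(vec)} alleles for {n} sites"
                )

    def validate_against(self, variants: Sequence[Polymorphism]) -> None:
        by_id = {v.id: v for v in variants}
        for label, vec in self.haplotypes.items():
            for site_id, allele in zip(self.site_order, vec):
                code = by_id[site_id].allele_code(allele)
                if code is None:
                    raise VariantTableError(f"haplotype {label}: missing allele at {site_id}")

    def freq_from_counts(self, population: str) -> dict[str, float]:
        cnt = self.counts[population]
        total = sum(cnt.values())
        return {label: c / total for label, c in cnt.items()}

    def allele_code_matrix(self, variants: Sequence[Polymorphism]) -> dict[str, tuple[int, ...]]:
        by_id = {v.id: v for v in variants}
        return {
            label: tuple(by_id[s].allele_code(a) for s, a in zip(self.site_order, vec))
            for label, vec in self.haplotypes.items()
        }


class CoordinateMap:
    """Bijective lookup between genomic and cDNA coordinates of a loaded
    marker panel.  No interpolation: only listed positions map."""

    def __init__(self, variants: Iterable[Polymorphism]):
        self._c2g: dict[int, int] = {}
        self._g2c: dict[int, int] = {}
        for v in variants:
            if v.cdna_pos in self._c2g or v.genomic_pos in self._g2c:
                raise VariantTableError(f"duplicate coordinate for site {v.id}")
            self._c2g[v.cdna_pos] = v.genomic_pos
            self._g2c[v.genomic_pos] = v.cdna_pos

    def cdna_to_genomic(self, cdna_pos: int) -> int:
        try:
            return self._c2g[cdna_pos]
        except KeyError:
            raise KeyError(f"cDNA position {cdna_pos} is not a listed marker position") from None

    def genomic_to_cdna(self, genomic_pos: int) -> int:
        try:
            return self._g2c[genomic_pos]
        except KeyError:
            raise KeyError(f"genomic position {genomic_pos} is not a listed marker position") from None


# ---------------------------------------------------------------------------
# Tabular IO

_VARIANT_COLUMNS = ["id", "genomic_pos", "cdna_pos", "ref_allele", "var_allele", "region", "dbsnp_id"]


def read_variant_table(path: str | Path) -> list[Polymorphism]:
    """Read a marker definition TSV into a validated, cDNA-ordered list.

    Raises :class:`VariantTableError` (naming the offending row) on malformed
    alleles, duplicate ids, or coordinates that are not strictly increasing
    in both systems.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        return []
    missing = [c for c in _VARIANT_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise VariantTableError(f"{path}: missing required columns {missing}")
    out: list[Polymorphism] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        if row["id"] in seen:
            raise VariantTableError(f"row {i + 2} ({row['id']}): duplicate marker id")
        seen.add(row["id"])
        dbsnp = row.get("dbsnp_id", ".")
        out.append(
            Polymorphism(
                id=row["id"],
                genomic_pos=int(row["genomic_pos"]),
                cdna_pos=int(row["cdna_pos"]),
                ref_allele=row["ref_allele"],
                var_allele=row["var_allele"],
                region=row["region"],
                dbsnp_id=None if dbsnp in (".", "", "-") else dbsnp,
            )
        )
    out.sort(key=lambda v: v.cdna_pos)
    for a, b in zip(out, out[1:]):
        if b.cdna_pos <= a.cdna_pos or b.genomic_pos <= a.genomic_pos:
            raise VariantTableError(
                f"rows {a.id}/{b.id}: coordinates are not strictly increasing in both systems"
            )
    return out


def write_variant_table(variants: Sequence[Polymorphism], path: str | Path) -> None:
    rows = [
        {
            "id": v.id,
            "genomic_pos": v.genomic_pos,
            "cdna_pos": v.cdna_pos,
            "ref_allele": v.ref_allele,
            "var_allele": v.var_allele,
            "region": v.region,
            "dbsnp_id": v.dbsnp_id or ".",
        }
        for v in variants
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | Path, variants: Sequence[Polymorphism]) -> list[GenotypeCall]:
    """Read a genotype panel TSV (dog_id, breed, group, one ``A1/A2`` column
    per marker id) against a loaded variant panel."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    ids = {v.id for v in variants}
    site_cols = [c for c in df.columns if c not in ("dog_id", "breed", "group")]
    unknown = set(site_cols) - ids
    if unknown:
        raise GenotypeParseError(f"{path}: columns {sorted(unknown)} are not in the variant panel")
    absent = ids - set(site_cols)
    if absent:
        raise GenotypeParseError(f"{path}: missing genotype columns for {sorted(absent)}")
    by_id = {v.id: v for v in variants}
    calls: list[GenotypeCall] = []
    for i, row in df.iterrows():
        alleles: dict[str, tuple[str, str]] = {}
        for site in site_cols:
            cell = row[site]
            parts = cell.split("/")
            if len(parts) != 2:
                raise GenotypeParseError(f"{path} line {i + 2}: genotype {cell!r} at {site} is not 'A1/A2'")
            a1, a2 = parts
            by_id[site].allele_code(a1)  # validates
            by_id[site].allele_code(a2)
            alleles[site] = (a1, a2)
        calls.append(
            GenotypeCall(
                dog_id=row["dog_id"],
                alleles=alleles,
                breed=row.get("breed", ""),
                group=row.get("group", ""),
            )
        )
    return calls


def write_genotypes(calls: Sequence[GenotypeCall], variants: Sequence[Polymorphism], path: str | Path) -> None:
    site_ids = [v.id for v in variants]
    rows = []
    for c in calls:
        row = {"dog_id": c.dog_id, "breed": c.breed, "group": c.group}
        for s in site_ids:
            row[s] = "/".join(c.alleles[s])
        rows.append(row)
    pd.DataFrame(rows, columns=["dog_id", "breed", "group", *site_ids]).to_csv(path, sep="\t", index=False)


def read_genotypes_vcf(path: str | Path, variants: Sequence[Polymorphism]) -> list[GenotypeCall]:
    """Minimal VCF 4.2 subset reader (CHROM/POS/REF/ALT/GT only).

    Records must be biallelic and match the variant panel by genomic position
    and allele pair; anything else is rejected.
    """
    from cyvcf2 import VCF

    by_pos = {v.genomic_pos: v for v in variants}
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    alleles: dict[str, dict[str, tuple[str, str]]] = {s: {} for s in samples}
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenotypeParseError(f"{path}: record at {rec.POS} is not biallelic")
        site = by_pos.get(rec.POS)
        if site is None:
            raise GenotypeParseError(f"{path}: position {rec.POS} not in the variant panel")
        if rec.REF != site.ref_allele or rec.ALT[0] != site.var_allele:
            raise GenotypeParseError(
                f"{path}: alleles {rec.REF}/{rec.ALT[0]} at {rec.POS} do not match marker {site.id}"
            )
        for sample, gt in zip(samples, rec.gt_types):
            # gts012: 0=hom-ref, 1=het, 2=hom-alt, 3=missing
            pair = {
                0: (site.ref_allele, site.ref_allele),
                1: (site.ref_allele, site.var_allele),
                2: (site.var_allele, site.var_allele),
                3: (MISSING, MISSING),
            }[int(gt)]
            alleles[sample][site.id] = pair
    calls = []
    for s in samples:
        for v in variants:
            alleles[s].setdefault(v.id, (MISSING, MISSING))
        calls.append(GenotypeCall(dog_id=s, alleles=alleles[s]))
    return calls


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into ``{record id: uppercase sequence}``; U is converted to
    T so mRNA-style input is accepted everywhere."""
    return {
        rec.id: str(rec.seq).upper().replace("U", "T")
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()],
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# Applying variants to a sequence, with an explicit offset map

class PositionMap:
    """Maps 1-based positions between a reference sequence and the same
    sequence with variants applied.

    Insertions shift downstream positions; positions inside an inserted run
    map back to the first reference base of the variant that created them.
    Coordinates are in the same frame as the sequence they index (the caller
    supplies ``seq_start`` when the sequence does not begin at position 1).
    """

    def __init__(self, breakpoints: list[tuple[int, int]]):
        # (ref_threshold, cumulative_shift): the shift applies to reference
        # positions strictly greater than the threshold (the variant's last
        # reference base).
        self._thresholds = [p for p, _ in breakpoints]
        self._shifts = [s for _, s in breakpoints]

    def _shift_at(self, ref_pos: int) -> int:
        idx = bisect.bisect_left(self._thresholds, ref_pos)
        return self._shifts[idx - 1] if idx else 0

    def ref_to_alt(self, ref_pos: int) -> int:
        return ref_pos + self._shift_at(ref_pos)

    def alt_to_ref(self, alt_pos: int) -> int:
        candidates = [alt_pos - s for s in (0, *self._shifts)]
        best = None
        for ref in candidates:
            if self.ref_to_alt(ref) <= alt_pos and (best is None or ref > best):
                best = ref
        return best if best is not None else alt_pos


def apply_variants(
    seq: str,
    variants: Sequence[Polymorphism],
    seq_start: int = 1,
) -> tuple[str, PositionMap]:
    """Substitute every marker's variant allele into ``seq``.

    ``seq_start`` is the cDNA coordinate of ``seq[0]``.  The reference allele
    must match the sequence at each marker position (integrity check).
    Returns the variant sequence and a :class:`PositionMap` over cDNA
    coordinates.
    """
    ordered = sorted(variants, key=lambda v: v.cdna_pos)
    pieces: list[str] = []
    cursor = 0  # 0-based index into seq
    breakpoints: list[tuple[int, int]] = []
    shift = 0
    for v in ordered:
        i = v.cdna_pos - seq_start
        if i < 0 or i + len(v.ref_allele) > len(seq):
            raise GenotypeParseError(f"marker {v.id} does not fit in the supplied sequence")
        found = seq[i : i + len(v.ref_allele)]
        if found != v.ref_allele:
            raise GenotypeParseError(
                f"marker {v.id}: sequence has {found!r} at c.{v.cdna_pos}, expected {v.ref_allele!r}"
            )
        pieces.append(seq[cursor:i])
        pieces.append(v.var_allele)
        cursor = i + len(v.ref_allele)
        shift += len(v.var_allele) - len(v.ref_allele)
        if len(v.var_allele) != len(v.ref_allele):
            breakpoints.append((v.cdna_pos + len(v.ref_allele) - 1, shift))
    pieces.append(seq[cursor:])
    return "".join(pieces), PositionMap(breakpoints)
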