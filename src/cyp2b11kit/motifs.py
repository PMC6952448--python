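"""Polyadenylation-signal scanning of 3'-UTR sequences.

The scan is strand-specific: sequences are the sense (mRNA-equivalent)
strand and only the canonical AAUAAA hexamer (AATAAA in DNA alphabet) is
searched by default.  Alternative hexamers such as AUUAAA exist in the
polyadenylation literature but are excluded from the default because the
replication question is whether the *canonical* signal is created or
destroyed by the 3'-UTR variants.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .variants import Polymorphism, apply_variants

__all__ = ["CANONICAL_POLYA", "ALTERNATIVE_HEXAMERS", "MotifHit", "scan_motif", "motif_diff"]

CANONICAL_POLYA = "AATAAA"
#: Common non-canonical polyadenylation hexamers, available behind a flag.
ALTERNATIVE_HEXAMERS = ("ATTAAA", "TATAAA", "AGTAAA", "AATACA", "AATATA")

_ALLOWED = frozenset("ACGT")


@dataclass(frozen=True)
class MotifHit:
    motif: str
    cdna_start: int  # 1-based position of the first motif base
    context: str     # +/- 10 bases around the motif


def _clean(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _ALLOWED
    if bad:
        raise ValueError(f"sequence contains non-ACGT/U characters: {sorted(bad)}")
    return seq


def scan_motif(seq: str, motif: str = CANONICAL_POLYA, seq_start: int = 1) -> list[MotifHit]:
    """All exact (possibly overlapping) motif matches, ascending position.

    ``seq_start`` is the cDNA coordinate of ``seq[0]`` so hits are reported
    in transcript coordinates.
    """
    seq = _clean(seq)
    motif = _clean(motif)
    hits: list[MotifHit] = []
    i = seq.find(motif)
    while i != -1:
        hits.append(
            MotifHit(
                motif=motif,
                cdna_start=i + seq_start,
                context=seq[max(0, i - 10) : i + len(motif) + 10],
            )
        )
        i = seq.find(motif, i + 1)
    return hits


def motif_diff(
    ref_seq: str,
    variants: Sequence[Polymorphism],
    motif: str = CANONICAL_POLYA,
    seq_start: int = 1,
) -> tuple[list[MotifHit], list[MotifHit]]:
    """Motif sites created and destroyed by applying ``variants``.

    The variant sequence is built through the coordinate map so hits are
    compared in *reference* transcript coordinates (positions downstream of
    an insertion are mapped back before comparison).  Returns
    ``(created, destroyed)``: created hits carry the reference coordinate
    of the position where they arise in the variant sequence.
    """
    ref_seq = _clean(ref_seq)
    alt_seq, posmap = apply_variants(ref_seq, variants, seq_start=seq_start)
    ref_hits = scan_motif(ref_seq, motif, seq_start)
    alt_hits = scan_motif(alt_seq, motif, seq_start)
    ref_positions = {h.cdna_start for h in ref_hits}
    alt_positions_ref_frame = {posmap.alt_to_ref(h.cdna_start): h for h in alt_hits}
    created = [
        MotifHit(motif=h.motif, cdna_start=pos, context=h.context)
        for pos, h in sorted(alt_positions_ref_frame.items())
        if pos not in ref_positions
    ]
    destroyed = [h for h in ref_hits if h.cdna_start not in alt_positions_ref_frame]
    return created, destroyed
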