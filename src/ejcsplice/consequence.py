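"""Protein-level consequences of multi-exon skipping.

Removing internal exons from a transcript deletes their coding
nucleotides from the CDS.  Three things can happen to the protein:
nothing (the skipped exons are untranslated), an in-frame internal
deletion (skipped coding length divisible by 3), or a frameshift.
Either route can expose a premature termination codon (PTC), and lost
or truncated residues can take annotated protein domains with them,
partially or totally.

Domain coordinates always refer to the ORIGINAL annotated protein;
losses are mapped back onto it rather than forward onto the mutant.
A PTC is defined purely positionally: a stop strictly before the
codon homologous to the annotated stop.  No NMD heuristics are applied.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

from Bio.Seq import Seq

from .gene_model import ExonChain
from .junctions import SkipEvent

logger = logging.getLogger(__name__)

__all__ = [
    "DomainAnnotation",
    "ConsequenceCall",
    "skipped_cds_span",
    "frame_effect",
    "detect_ptc",
    "domain_impact",
    "classify_consequence",
]

FrameEffect = Literal["none", "in_frame", "frameshift"]
DomainEffect = Literal["none", "partial", "total"]


@dataclass(frozen=True)
class DomainAnnotation:
    """Pfam-style domain interval in 1-based inclusive protein coordinates."""

    protein_id: str
    domain_name: str
    aa_start: int
    aa_end: int

    def __post_init__(self) -> None:
        if not 1 <= self.aa_start <= self.aa_end:
            raise ValueError(
                f"invalid domain interval {self.aa_start}..{self.aa_end} "
                f"for {self.domain_name}"
            )


@dataclass
class ConsequenceCall:
    event: SkipEvent
    skipped_cds_nt: int
    frame: FrameEffect
    ptc_codon: Optional[int]  # first premature stop, mutant frame, 1-based
    domain_effects: list[tuple[str, DomainEffect]]


def _check_indices(chain: ExonChain, skipped: Sequence[int]) -> None:
    for i in skipped:
        if not 1 <= i <= chain.n_exons:
            raise IndexError(f"exon index {i} outside 1..{chain.n_exons}")


def skipped_cds_span(chain: ExonChain, skipped: Sequence[int]) -> int:
    """Total coding nucleotides removed when the given exons are skipped."""
    if chain.cds_start is None or chain.cds_end is None:
        raise ValueError(f"chain {chain.transcript_id} has no CDS")
    _check_indices(chain, skipped)
    return sum(chain.coding_len(i) for i in skipped)


def frame_effect(skipped_cds_nt: int) -> FrameEffect:
    """none (no coding nt removed) / in_frame (multiple of 3) / frameshift."""
    if skipped_cds_nt < 0:
        raise ValueError("skipped_cds_nt must be non-negative")
    if skipped_cds_nt == 0:
        return "none"
    return "in_frame" if skipped_cds_nt % 3 == 0 else "frameshift"


def _cds_intervals_of_exons(chain: ExonChain) -> list[tuple[int, int]]:
    """Per-exon [start, end) intervals in CDS (spliced, 5'->3') coordinates."""
    out = []
    off = 0
    for i in range(1, chain.n_exons + 1):
        ln = chain.coding_len(i)
        out.append((off, off + ln))
        off += ln
    return out


def _delete_skipped(cds_sequence: str, chain: ExonChain, skipped: Sequence[int]) -> str:
    """Remove the skipped exons' coding nucleotides from the spliced CDS."""
    ivs = _cds_intervals_of_exons(chain)
    drop = sorted(ivs[i - 1] for i in skipped if ivs[i - 1][1] > ivs[i - 1][0])
    keep = []
    pos = 0
    for a, b in drop:
        keep.append(cds_sequence[pos:a])
        pos = b
    keep.append(cds_sequence[pos:])
    return "".join(keep)


def detect_ptc(
    cds_sequence: str, chain: ExonChain, skipped: Sequence[int]
) -> tuple[bool, Optional[int]]:
    """Splice out the skipped coding span, translate, and look for a premature stop.

    Returns (has_ptc, first_stop_codon_position) where the position is in the
    mutant reading frame (1-based).  A stop is premature when it appears
    strictly before the codon homologous to the annotated stop — i.e. before
    the last complete codon of the mutant sequence.
    """
    cds_sequence = cds_sequence.upper()
    _check_indices(chain, skipped)
    total_coding = sum(chain.coding_len(i) for i in range(1, chain.n_exons + 1))
    if len(cds_sequence) != total_coding:
        raise ValueError(
            f"CDS length {len(cds_sequence)} does not match annotated coding "
            f"length {total_coding} of {chain.transcript_id}"
        )
    if len(cds_sequence) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    if str(Seq(cds_sequence[-3:]).translate()) != "*":
        raise ValueError("CDS must end in a stop codon")

    mutant = _delete_skipped(cds_sequence, chain, skipped)
    if mutant == cds_sequence:
        return False, None
    n_codons = len(mutant) // 3
    aa = str(Seq(mutant[: n_codons * 3]).translate())
    first_stop = aa.find("*")
    if first_stop == -1:
        return False, None
    # homologous annotated stop = last complete codon of the mutant sequence
    if first_stop + 1 < n_codons:
        return True, first_stop + 1
    return False, None


def _union_covers(
    intervals: Sequence[tuple[int, int]], a: int, b: int
) -> tuple[bool, bool]:
    """(fully covered, overlaps at all) of [a, b] by a union of inclusive intervals."""
    ivs = sorted(i for i in intervals if i[0] <= i[1])
    overlaps = any(not (e < a or s > b) for s, e in ivs)
    pos = a
    for s, e in ivs:
        if s > pos:
            break
        if e >= pos:
            pos = e + 1
        if pos > b:
            return True, overlaps
    return pos > b, overlaps


def domain_impact(
    domains: Sequence[DomainAnnotation],
    lost_aa_intervals: Sequence[tuple[int, int]],
    truncation_from: Optional[int] = None,
) -> list[tuple[str, DomainEffect]]:
    """Classify each domain as none / partial / total loss.

    ``lost_aa_intervals`` are 1-based inclusive residue intervals of the
    original protein deleted by the event; ``truncation_from`` marks the
    first original residue no longer produced (everything at/after it is
    lost).  Total = the domain lies entirely within the lost set; partial =
    proper overlap; none otherwise.
    """
    lost = list(lost_aa_intervals)
    if truncation_from is not None:
        lost.append((truncation_from, 10**9))
    out = []
    for d in domains:
        full, some = _union_covers(lost, d.aa_start, d.aa_end)
        effect: DomainEffect = "total" if full else ("partial" if some else "none")
        out.append((d.domain_name, effect))
    return out


def _lost_protein_intervals(
    chain: ExonChain, skipped: Sequence[int]
) -> list[tuple[int, int]]:
    """Skipped coding spans mapped to original-protein residue intervals.

    Codons only partially encoded by a skipped exon change identity, so any
    partially-overlapped codon counts as lost.
    """
    ivs = _cds_intervals_of_exons(chain)
    out = []
    for i in skipped:
        a, b = ivs[i - 1]
        if b > a:
            out.append((a // 3 + 1, (b + 2) // 3))
    return out


def classify_consequence(
    event: SkipEvent,
    chain: ExonChain,
    cds_sequence: str,
    domains: Sequence[DomainAnnotation],
) -> ConsequenceCall:
    """Compose span/frame/PTC/domain logic into one call for a skip event."""
    skipped = event.skipped_exons
    nt = skipped_cds_span(chain, skipped)
    frame = frame_effect(nt)
    if frame == "none":
        return ConsequenceCall(
            event=event,
            skipped_cds_nt=0,
            frame="none",
            ptc_codon=None,
            domain_effects=[(d.domain_name, "none") for d in domains],
        )
    has_ptc, ptc_pos = detect_ptc(cds_sequence, chain, skipped)
    lost = _lost_protein_intervals(chain, skipped)
    truncation: Optional[int] = None
    if frame == "frameshift":
        # downstream of the first lost codon every residue diverges
        truncation = min(s for s, _ in lost)
    elif has_ptc and ptc_pos is not None:
        # map the mutant stop position back to original coordinates
        orig = ptc_pos
        for s, e in sorted(lost):
            if s <= orig:
                orig += e - s + 1
        truncation = orig
    effects = domain_impact(domains, lost if frame == "in_frame" else [], truncation)
    return ConsequenceCall(
        event=event,
        skipped_cds_nt=nt,
        frame=frame,
        ptc_codon=ptc_pos if has_ptc else None,
        domain_effects=effects,
    )
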