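"""Reference transcript models and strand-oriented exon chains.

All downstream analyses (junction classification, occupancy ratios,
consequence calls) are expressed in the coordinate frame of a single
reference transcript per gene — the MANE transcript where one is
annotated, otherwise the longest-CDS isoform.  Genes are only eligible
for skipping analysis when their reference transcript has at least
three exons: a junction can only skip an exon that has neighbours on
both sides.

Coordinates are 0-based half-open internally; the GTF convention
(1-based inclusive) is converted at the parser boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "ExonChain",
    "AnnotationParseError",
    "AnnotationValidationError",
    "load_annotation",
    "select_reference",
    "build_exon_chain",
    "build_reference_chains",
    "filter_eligible_genes",
    "write_chains",
    "read_chains",
]


class AnnotationParseError(ValueError):
    """A record in the annotation file could not be parsed."""


class AnnotationValidationError(ValueError):
    """Parsed records are mutually inconsistent."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start must precede end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, start: int, end: int) -> int:
        """Length of the intersection with [start, end)."""
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class TranscriptModel:
    """One transcript: exons in genomic ascending order plus optional CDS span."""

    gene_id: str
    transcript_id: str
    exons: list[GenomicInterval]
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None
    is_mane: bool = False

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id} has no exons"
            )
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id} mixes chromosomes/strands"
            )
        self.exons = _merge_sorted(self.exons, self.transcript_id)
        if self.cds_start is not None and self.cds_end is not None:
            lo, hi = self.exons[0].start, self.exons[-1].end
            if not (lo <= self.cds_start < self.cds_end <= hi):
                raise AnnotationValidationError(
                    f"CDS [{self.cds_start},{self.cds_end}) of {self.transcript_id} "
                    f"outside exon union [{lo},{hi})"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def exonic_span(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_len(self) -> int:
        """Total coding length (sum of exon/CDS-span intersections)."""
        if self.cds_start is None or self.cds_end is None:
            return 0
        return sum(e.overlap(self.cds_start, self.cds_end) for e in self.exons)


def _merge_sorted(
    exons: Sequence[GenomicInterval], transcript_id: str
) -> list[GenomicInterval]:
    """Sort exons; merge overlapping ones with a warning (messy annotations)."""
    out: list[GenomicInterval] = []
    for e in sorted(exons, key=lambda x: (x.start, x.end)):
        if out and e.start < out[-1].end:
            warnings.warn(
                f"overlapping exons in {transcript_id}; merging", stacklevel=2
            )
            prev = out.pop()
            e = GenomicInterval(e.chrom, prev.start, max(prev.end, e.end), e.strand)
        out.append(e)
    return out


@dataclass
class ExonChain:
    """Exon list in transcript orientation (exon 1 = 5'-most exon).

    On the minus strand exon 1 is the genomically last interval.  ``exon(i)``
    uses 1-based transcript indices throughout the package.
    """

    gene_id: str
    transcript_id: str
    exons: list[GenomicInterval] = field(repr=False)
    cds_start: Optional[int] = None
    cds_end: Optional[int] = None

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def eligible(self) -> bool:
        return self.n_exons >= 3

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (min start, max end) over all exons."""
        return (
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
        )

    def exon(self, i: int) -> GenomicInterval:
        """1-based, transcript-orientation exon access."""
        if not 1 <= i <= self.n_exons:
            raise IndexError(f"exon index {i} outside 1..{self.n_exons}")
        return self.exons[i - 1]

    def exon_len(self, i: int) -> int:
        return len(self.exon(i))

    def coding_len(self, i: int) -> int:
        """Coding nucleotides of exon i (0 when no CDS annotated)."""
        if self.cds_start is None or self.cds_end is None:
            return 0
        return self.exon(i).overlap(self.cds_start, self.cds_end)


def load_annotation(path: str, dialect: str = "gtf") -> list[TranscriptModel]:
    """Parse a GTF into one TranscriptModel per transcript.

    Exons are deduplicated and stored in genomic ascending order; MANE
    membership is read from ``tag "MANE_Select"`` attributes.  CDS features
    (plus stop_codon features, when present) define the coding span.
    """
    if dialect != "gtf":
        raise ValueError(f"unsupported annotation dialect: {dialect!r}")
    exons: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}
    mane: dict[str, bool] = {}
    cds: dict[str, list[int]] = {}
    tx_span: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if line.count("\t") != 8:
                raise AnnotationParseError(
                    f"{path}: malformed record at line {lineno}: expected 9 "
                    f"tab-separated fields, got {line.count(chr(9)) + 1}"
                )
            try:
                feat = feature_from_line(line, dialect=None)
            except Exception as exc:  # noqa: BLE001 - gffutils raises various types
                raise AnnotationParseError(
                    f"{path}: malformed record at line {lineno}: {exc}"
                ) from exc
            ftype = feat.featuretype
            if ftype not in ("exon", "CDS", "stop_codon", "transcript"):
                continue
            try:
                tid = feat.attributes["transcript_id"][0]
                gid = feat.attributes["gene_id"][0]
            except KeyError as exc:
                raise AnnotationParseError(
                    f"{path}: line {lineno} lacks {exc} attribute"
                ) from exc
            start0, end0 = feat.start - 1, feat.end  # GTF 1-based incl -> half-open
            genes[tid] = gid
            if ftype == "transcript":
                tx_span[tid] = (start0, end0)
            elif ftype == "exon":
                iv = GenomicInterval(feat.seqid, start0, end0, feat.strand)
                exons.setdefault(tid, []).append(iv)
            else:  # CDS / stop_codon
                cds.setdefault(tid, []).extend((start0, end0))
            tags = feat.attributes.get("tag", [])
            if "MANE_Select" in tags:
                mane[tid] = True

    models = []
    for tid, ivs in exons.items():
        ivs = sorted(set(ivs), key=lambda e: (e.start, e.end))
        if tid in tx_span:
            lo, hi = tx_span[tid]
            for e in ivs:
                if e.start < lo or e.end > hi:
                    raise AnnotationValidationError(
                        f"exon {e.chrom}:{e.start}-{e.end} of {tid} outside "
                        f"declared transcript span [{lo},{hi})"
                    )
        c = cds.get(tid)
        models.append(
            TranscriptModel(
                gene_id=genes[tid],
                transcript_id=tid,
                exons=ivs,
                cds_start=min(c) if c else None,
                cds_end=max(c) if c else None,
                is_mane=mane.get(tid, False),
            )
        )
    models.sort(key=lambda m: (m.gene_id, m.transcript_id))
    return models


def select_reference(
    transcripts: Sequence[TranscriptModel],
    mane_ids: Optional[set[str]] = None,
) -> TranscriptModel:
    """Choose one reference transcript for a gene.

    A unique MANE transcript wins; otherwise the longest CDS, ties broken by
    lexicographically smallest transcript id; transcripts with no CDS at all
    fall back to the longest exonic span.
    """
    if not transcripts:
        raise ValueError("cannot select a reference from an empty transcript list")
    stripped = {t.split(".")[0] for t in mane_ids} if mane_ids else set()

    def _is_mane(t: TranscriptModel) -> bool:
        return t.is_mane or t.transcript_id.split(".")[0] in stripped

    tagged = [t for t in transcripts if _is_mane(t)]
    if len(tagged) == 1:
        return tagged[0]
    if len(tagged) > 1:
        raise AnnotationValidationError(
            f"gene {transcripts[0].gene_id}: ambiguous reference — "
            f"{len(tagged)} MANE-tagged transcripts"
        )
    if any(t.cds_len > 0 for t in transcripts):
        return min(transcripts, key=lambda t: (-t.cds_len, t.transcript_id))
    return min(transcripts, key=lambda t: (-t.exonic_span, t.transcript_id))


def build_exon_chain(t: TranscriptModel) -> ExonChain:
    """Orient a transcript's exons 5'->3' (reversed genomic order on minus strand)."""
    exons = list(t.exons) if t.strand == "+" else list(reversed(t.exons))
    return ExonChain(
        gene_id=t.gene_id,
        transcript_id=t.transcript_id,
        exons=exons,
        cds_start=t.cds_start,
        cds_end=t.cds_end,
    )


def build_reference_chains(
    transcripts: Iterable[TranscriptModel],
    mane_ids: Optional[set[str]] = None,
) -> list[ExonChain]:
    """Group transcripts by gene, pick one reference each, build chains."""
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return [
        build_exon_chain(select_reference(ts, mane_ids))
        for _, ts in sorted(by_gene.items())
    ]


def filter_eligible_genes(
    chains: Sequence[ExonChain], min_exons: int = 3
) -> list[ExonChain]:
    """Keep chains with at least ``min_exons`` exons (order preserved)."""
    if min_exons < 1:
        raise ValueError(f"min_exons must be >= 1, got {min_exons}")
    return [c for c in chains if c.n_exons >= min_exons]


_CHAIN_COLUMNS = [
    "gene_id",
    "transcript_id",
    "chrom",
    "strand",
    "exon_index",
    "start",
    "end",
    "cds_start",
    "cds_end",
]


def write_chains(chains: Sequence[ExonChain], path: str) -> None:
    """Write chains to TSV, one row per exon in transcript orientation."""
    rows = []
    for c in chains:
        for i in range(1, c.n_exons + 1):
            e = c.exon(i)
            rows.append(
                (
                    c.gene_id,
                    c.transcript_id,
                    c.chrom,
                    c.strand,
                    i,
                    e.start,
                    e.end,
                    "" if c.cds_start is None else c.cds_start,
                    "" if c.cds_end is None else c.cds_end,
                )
            )
    pd.DataFrame(rows, columns=_CHAIN_COLUMNS).to_csv(path, sep="\t", index=False)


def read_chains(path: str) -> list[ExonChain]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    chains = []
    for (_, tid), grp in df.groupby(["gene_id", "transcript_id"], sort=True):
        grp = grp.sort_values("exon_index")
        exons = [
            GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
            for r in grp.itertuples()
        ]
        first = grp.iloc[0]
        chains.append(
            ExonChain(
                gene_id=first.gene_id,
                transcript_id=tid,
                exons=exons,
                cds_start=None if pd.isna(first.cds_start) else int(first.cds_start),
                cds_end=None if pd.isna(first.cds_end) else int(first.cds_end),
            )
        )
    return chains
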