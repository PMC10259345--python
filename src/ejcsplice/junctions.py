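"""Splice-junction classification and exon-skipping quantification.

A junction read spans an intron; interpreted against a gene's reference
exon chain it is *canonical* (joins adjacent exons), a *skip* of k
exons (joins exons i and j with j = i + k + 1), or *unannotated*
(either boundary off an annotated exon edge).  Skip junctions are the
direct read-level evidence of single- and multi-exon skipping, and
their knockdown/control read-count ratio is the summary used to ask
whether a perturbation increases multi-exon skipping.

Skipped-exon (SE) event calling uses a junction-count PSI:
``PSI = ((inc_up + inc_down)/2) / ((inc_up + inc_down)/2 + exc)``
with an exact 2x2 test on pooled inclusion/exclusion counts and
Benjamini-Hochberg FDR; an event is significant when both
|dPSI| > 0.2 and FDR < 0.01 (the two gates are fixed defaults, not a
fitted quantity).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gene_model import ExonChain

logger = logging.getLogger(__name__)

__all__ = [
    "JunctionRecord",
    "JunctionClass",
    "SkipEvent",
    "SEEventCall",
    "load_junctions",
    "classify_junction",
    "assign_and_classify",
    "tabulate_skip_events",
    "skip_read_ratio_profile",
    "compute_psi",
    "call_se_events",
]

Condition = Literal["control", "kd"]


@dataclass(frozen=True)
class JunctionRecord:
    """One observed junction in one sample, 0-based half-open intron [donor_end, acceptor_start)."""

    chrom: str
    donor_end: int
    acceptor_start: int
    strand: str  # '+', '-' or '.' (unknown; resolved against the chain)
    sample_id: str
    condition: str
    read_count: int

    def __post_init__(self) -> None:
        if self.donor_end >= self.acceptor_start:
            raise ValueError(
                f"junction donor_end {self.donor_end} must precede acceptor_start "
                f"{self.acceptor_start} ({self.chrom})"
            )
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")


@dataclass(frozen=True)
class JunctionClass:
    kind: Literal["canonical", "skip", "unannotated"]
    k_skipped: int = 0
    upstream_exon: int = 0
    downstream_exon: int = 0


UNANNOTATED = JunctionClass(kind="unannotated")


@dataclass
class SkipEvent:
    """One distinct skip junction of a gene with per-sample read counts."""

    gene_id: str
    upstream_exon: int
    downstream_exon: int
    reads_by_sample: dict[str, int] = field(default_factory=dict)

    @property
    def k_skipped(self) -> int:
        return self.downstream_exon - self.upstream_exon - 1

    @property
    def skipped_exons(self) -> list[int]:
        return list(range(self.upstream_exon + 1, self.downstream_exon))


@dataclass
class SEEventCall:
    gene_id: str
    exon_index: int
    psi_control: float
    psi_kd: float
    delta_psi: float
    p_value: float
    fdr: float
    significant: bool


_SJ_STRAND = {"0": ".", "1": "+", "2": "-"}


def load_junctions(
    path: str,
    dialect: Literal["sj_tab", "bed"],
    sample_id: str,
    condition: str,
    known_chroms: Optional[set[str]] = None,
) -> list[JunctionRecord]:
    """Read a junction table; records with zero (unique) reads are dropped.

    ``sj_tab``: STAR SJ.out.tab layout — chrom, intron start (1-based),
    intron end (1-based inclusive), strand code 0/1/2, motif, annotated,
    unique reads, multi reads, overhang; unique reads are used.
    ``bed``: minimal 4-column TSV — chrom, donor_end, acceptor_start, count
    (0-based half-open), strand unknown.
    """
    records: list[JunctionRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            try:
                if dialect == "sj_tab":
                    chrom = f[0]
                    donor_end = int(f[1]) - 1  # intron start (1-based) -> exon end
                    acceptor_start = int(f[2])  # intron end (1-based incl) -> exon start
                    strand = _SJ_STRAND.get(f[3], ".")
                    count = int(f[6])
                elif dialect == "bed":
                    chrom, donor_end, acceptor_start, count = (
                        f[0],
                        int(f[1]),
                        int(f[2]),
                        int(f[3]),
                    )
                    strand = f[4] if len(f) > 4 else "."
                else:
                    raise ValueError(f"unknown junction dialect {dialect!r}")
            except (IndexError, ValueError) as exc:
                if isinstance(exc, ValueError) and "dialect" in str(exc):
                    raise
                raise ValueError(
                    f"{path}: malformed junction record at line {lineno}: {exc}"
                ) from exc
            if count == 0:
                continue
            if acceptor_start <= donor_end:
                raise ValueError(
                    f"{path}: line {lineno}: acceptor {acceptor_start} <= donor {donor_end}"
                )
            if known_chroms is not None and chrom not in known_chroms:
                warnings.warn(
                    f"{path}: line {lineno}: unknown chromosome {chrom!r} retained",
                    stacklevel=2,
                )
            records.append(
                JunctionRecord(
                    chrom=chrom,
                    donor_end=donor_end,
                    acceptor_start=acceptor_start,
                    strand=strand,
                    sample_id=sample_id,
                    condition=condition,
                    read_count=count,
                )
            )
    return records


def classify_junction(
    j: JunctionRecord, chain: ExonChain, slop: int = 0
) -> JunctionClass:
    """Classify one junction against an exon chain.

    Boundary matching is exact by default (``slop`` widens it).  Donor and
    acceptor are resolved in transcript orientation: on the plus strand the
    junction's left edge must hit the end of exon i and its right edge the
    start of exon j; on the minus strand the junction's genomically-right
    edge is the donor side (end of transcript-upstream exon).
    """
    if j.chrom != chain.chrom:
        raise ValueError(
            f"junction on {j.chrom} classified against chain on {chain.chrom}"
        )
    if j.strand not in (".", chain.strand):
        raise ValueError(
            f"junction strand {j.strand} does not match chain strand {chain.strand}"
        )

    def _match(boundary_of: dict[int, int], pos: int) -> Optional[int]:
        if pos in boundary_of:
            return boundary_of[pos]
        for d in range(1, slop + 1):
            for cand in (pos - d, pos + d):
                if cand in boundary_of:
                    return boundary_of[cand]
        return None

    if chain.strand == "+":
        donor_of = {chain.exon(i).end: i for i in range(1, chain.n_exons + 1)}
        accept_of = {chain.exon(i).start: i for i in range(1, chain.n_exons + 1)}
        u = _match(donor_of, j.donor_end)
        v = _match(accept_of, j.acceptor_start)
    else:
        donor_of = {chain.exon(i).start: i for i in range(1, chain.n_exons + 1)}
        accept_of = {chain.exon(i).end: i for i in range(1, chain.n_exons + 1)}
        u = _match(donor_of, j.acceptor_start)
        v = _match(accept_of, j.donor_end)

    if u is None or v is None or v <= u:
        return UNANNOTATED
    if v == u + 1:
        return JunctionClass("canonical", 0, u, v)
    return JunctionClass("skip", v - u - 1, u, v)


def _chains_by_chrom(chains: Sequence[ExonChain]) -> dict[str, list[ExonChain]]:
    idx: dict[str, list[ExonChain]] = {}
    for c in chains:
        idx.setdefault(c.chrom, []).append(c)
    return idx


def assign_and_classify(
    junctions: Iterable[JunctionRecord],
    chains: Sequence[ExonChain],
    slop: int = 0,
) -> list[tuple[JunctionRecord, ExonChain, JunctionClass]]:
    """Assign each junction to the chain whose genomic span contains it and classify.

    Junctions falling in no chain's span are returned classified unannotated
    with chain None is not useful downstream, so they are skipped.
    """
    idx = _chains_by_chrom(chains)
    out = []
    for j in junctions:
        for c in idx.get(j.chrom, []):
            lo, hi = c.span
            if lo <= j.donor_end and j.acceptor_start <= hi and j.strand in (".", c.strand):
                out.append((j, c, classify_junction(j, c, slop=slop)))
                break
    return out


def tabulate_skip_events(
    junctions: Iterable[JunctionRecord],
    chains: Sequence[ExonChain],
    sample_ids: Optional[Sequence[str]] = None,
    slop: int = 0,
) -> list[SkipEvent]:
    """Aggregate skip-classified junction reads into one event per
    (gene, upstream exon, downstream exon) with a complete per-sample count map
    (samples with no reads recorded as 0)."""
    junctions = list(junctions)
    if sample_ids is None:
        sample_ids = sorted({j.sample_id for j in junctions})
    events: dict[tuple[str, int, int], SkipEvent] = {}
    for j, chain, cls in assign_and_classify(junctions, chains, slop=slop):
        if cls.kind != "skip":
            continue
        key = (chain.gene_id, cls.upstream_exon, cls.downstream_exon)
        ev = events.get(key)
        if ev is None:
            ev = SkipEvent(
                gene_id=chain.gene_id,
                upstream_exon=cls.upstream_exon,
                downstream_exon=cls.downstream_exon,
                reads_by_sample={s: 0 for s in sample_ids},
            )
            events[key] = ev
        ev.reads_by_sample[j.sample_id] = ev.reads_by_sample.get(j.sample_id, 0) + j.read_count
    return [events[k] for k in sorted(events)]


def skip_read_ratio_profile(
    events: Sequence[SkipEvent],
    per_sample_totals: dict[str, int],
    sample_conditions: dict[str, str],
    pseudocount: float = 0.5,
    method: Literal["per_event", "per_class"] = "per_event",
    max_k: int = 5,
) -> pd.DataFrame:
    """Median knockdown/control skip-read ratio per skip class k.

    Counts are scaled to counts-per-million of each sample's total junction
    reads; per event the ratio is (mean normalized kd + c)/(mean normalized
    control + c).  Returns one row per observed k plus a pooled ``2+`` class,
    columns k, n_events, median_ratio.  ``method='per_class'`` instead forms
    a single ratio from class-level mean normalized counts.
    """
    if not events:
        raise ValueError("no skip events to profile")
    ctrl = [s for s, c in sample_conditions.items() if c == "control"]
    kd = [s for s, c in sample_conditions.items() if c == "kd"]
    if not ctrl or not kd:
        raise ValueError("both control and kd samples are required")
    scale = {
        s: 1e6 / per_sample_totals[s] if per_sample_totals[s] > 0 else 0.0
        for s in list(ctrl) + list(kd)
    }

    def _means(ev: SkipEvent) -> tuple[float, float]:
        m_kd = float(np.mean([ev.reads_by_sample.get(s, 0) * scale[s] for s in kd]))
        m_ct = float(np.mean([ev.reads_by_sample.get(s, 0) * scale[s] for s in ctrl]))
        return m_kd, m_ct

    rows = []
    classes: dict[object, list[SkipEvent]] = {}
    for ev in events:
        k = min(ev.k_skipped, max_k)
        classes.setdefault(k, []).append(ev)
        if ev.k_skipped >= 2:
            classes.setdefault("2+", []).append(ev)
    c = pseudocount
    for k in sorted(classes, key=str):
        evs = classes[k]
        if method == "per_event":
            ratios = [(mk + c) / (mc + c) for mk, mc in map(_means, evs)]
            med = float(np.median(ratios))
        else:
            mk = float(np.mean([_means(e)[0] for e in evs]))
            mc = float(np.mean([_means(e)[1] for e in evs]))
            med = (mk + c) / (mc + c)
        rows.append({"k": k, "n_events": len(evs), "median_ratio": med})
    return pd.DataFrame(rows)


def compute_psi(inc_up: int, inc_down: int, exc: int) -> float:
    """Junction-count PSI; NaN when there is no evidence at all.

    The two inclusion junctions are averaged so that one included copy of the
    exon contributes the same weight as one excluding read.
    """
    if min(inc_up, inc_down, exc) < 0:
        raise ValueError("junction counts must be non-negative")
    inc = (inc_up + inc_down) / 2.0
    if inc == 0 and exc == 0:
        return math.nan
    return inc / (inc + exc)


def call_se_events(
    junctions: Iterable[JunctionRecord],
    chains: Sequence[ExonChain],
    dpsi_min: float = 0.2,
    fdr_max: float = 0.01,
    slop: int = 0,
) -> list[SEEventCall]:
    """Call differential skipped-exon events between control and kd.

    For each internal exon of each eligible chain with any junction evidence:
    inclusion = the two flanking canonical junctions, exclusion = the direct
    skip junction over the exon; counts pooled across replicates per
    condition; Fisher exact test on the pooled 2x2 (rounded mean inclusion,
    exclusion), Benjamini-Hochberg FDR across all tested exons, and the two
    significance gates |dPSI| > dpsi_min and FDR < fdr_max.
    """
    classified = assign_and_classify(junctions, chains, slop=slop)
    # counts[(gene, kind, u, v)][condition] pooled across replicates
    counts: dict[tuple[str, int, int], dict[str, int]] = {}
    genes_seen = set()
    for j, chain, cls in classified:
        if cls.kind == "unannotated" or not chain.eligible:
            continue
        genes_seen.add(chain.gene_id)
        key = (chain.gene_id, cls.upstream_exon, cls.downstream_exon)
        d = counts.setdefault(key, {"control": 0, "kd": 0})
        d[j.condition] += j.read_count

    chain_by_gene = {c.gene_id: c for c in chains}
    rows = []
    for gid in sorted(genes_seen):
        chain = chain_by_gene[gid]
        for i in range(2, chain.n_exons):
            def _cnt(u: int, v: int, cond: str) -> int:
                return counts.get((gid, u, v), {}).get(cond, 0)

            inc_up = {c: _cnt(i - 1, i, c) for c in ("control", "kd")}
            inc_down = {c: _cnt(i, i + 1, c) for c in ("control", "kd")}
            exc = {c: _cnt(i - 1, i + 1, c) for c in ("control", "kd")}
            if all(
                inc_up[c] == 0 and inc_down[c] == 0 and exc[c] == 0
                for c in ("control", "kd")
            ):
                continue
            psi_c = compute_psi(inc_up["control"], inc_down["control"], exc["control"])
            psi_k = compute_psi(inc_up["kd"], inc_down["kd"], exc["kd"])
            if math.isnan(psi_c) or math.isnan(psi_k):
                continue
            inc_c = round((inc_up["control"] + inc_down["control"]) / 2)
            inc_k = round((inc_up["kd"] + inc_down["kd"]) / 2)
            _, p = stats.fisher_exact(
                [[inc_c, exc["control"]], [inc_k, exc["kd"]]]
            )
            rows.append(
                SEEventCall(
                    gene_id=gid,
                    exon_index=i,
                    psi_control=psi_c,
                    psi_kd=psi_k,
                    delta_psi=psi_k - psi_c,
                    p_value=float(p),
                    fdr=math.nan,
                    significant=False,
                )
            )
    if not rows:
        warnings.warn("no testable exons; returning empty call list", stacklevel=2)
        return []
    _, fdrs, _, _ = multipletests([r.p_value for r in rows], method="fdr_bh")
    for r, q in zip(rows, fdrs):
        r.fdr = float(q)
        r.significant = abs(r.delta_psi) > dpsi_min and r.fdr < fdr_max
    return rows
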