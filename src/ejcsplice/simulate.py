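"""Ground-truth synthetic data emulating the statistical structure the pipeline assumes.

The generator produces, from one seeded configuration: gene models
(GTF + exon chains), replicate junction-count tables with
condition-dependent single- and multi-exon skip rates, exon-level
crosslink/RNA-seq occupancy tables with optional enrichment on the
exon immediately upstream of each designated skipped exon, CDS
sequences and domain annotations engineered to give known
frame/PTC/domain-loss outcomes, and a truth record tying it all
together.  Every artifact is a pure function of the configuration,
including its seed.

Noise model: Poisson counts for junction reads (shot noise of a
sequencing experiment at fixed expected depth) and negative-binomial
counts for crosslink coverage (CLIP libraries are overdispersed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.Seq import Seq

from .gene_model import ExonChain, GenomicInterval
from .junctions import JunctionRecord, SkipEvent

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "TrueEvent",
    "GeneTruth",
    "GroundTruth",
    "simulate_gene_models",
    "designate_events",
    "simulate_junction_reads",
    "simulate_occupancy",
    "simulate_cds_and_domains",
    "simulate_dataset",
    "write_gtf",
    "write_junctions_sj",
    "write_junctions_bed",
]

_TABLE = unambiguous_dna_by_id[1]
_SENSE = sorted(_TABLE.forward_table)
_NONSTOP_NONMET = [c for c in _SENSE if c != "ATG"]


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the package's study conditions.

    Rates are per expected junction read; ``kd_multiplier`` encodes how much
    more frequent a skip of k exons becomes under knockdown (defaults rise
    from 1.5x for single-exon skips to 3x for five-exon skips, matching the
    observed pattern that higher skip classes respond more).  ``enrichment_gamma``
    multiplies expected crosslink counts on the exon immediately upstream of
    each designated skipped exon.
    """

    seed: int = 0
    n_genes: int = 200
    exon_count_range: tuple[int, int] = (15, 30)
    exon_len_range: tuple[int, int] = (80, 300)
    intron_len_range: tuple[int, int] = (200, 2000)
    replicates_per_condition: int = 3
    depth_per_gene: float = 10_000.0
    base_skip_rate: dict[int, float] = field(
        default_factory=lambda: {1: 0.01, 2: 0.003, 3: 0.001, 4: 0.0005, 5: 0.0002}
    )
    kd_multiplier: dict[int, float] = field(
        default_factory=lambda: {1: 1.5, 2: 2.0, 3: 2.3, 4: 2.6, 5: 3.0}
    )
    skip_classes: tuple[int, ...] = (1, 2, 3, 4, 5)
    occ_mean: float = 50.0
    occ_dispersion: float = 0.3
    enrichment_gamma: float = 3.0
    fraction_affected_genes: float = 0.8
    silent_gene_fraction: float = 0.1
    rnaseq_mean: float = 20.0

    def __post_init__(self) -> None:
        for k, r in self.base_skip_rate.items():
            if not 0 <= r <= 1:
                raise ValueError(f"base_skip_rate[{k}]={r} outside [0,1]")
        for k, m in self.kd_multiplier.items():
            if m <= 0:
                raise ValueError(f"kd_multiplier[{k}]={m} must be > 0")
        for name in ("exon_count_range", "exon_len_range", "intron_len_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ValueError(f"degenerate {name}: ({lo}, {hi})")
        if not 0 <= self.fraction_affected_genes <= 1:
            raise ValueError("fraction_affected_genes outside [0,1]")
        if not 0 <= self.silent_gene_fraction <= 1:
            raise ValueError("silent_gene_fraction outside [0,1]")


@dataclass
class TrueEvent:
    gene_id: str
    k: int
    upstream_exon: int
    downstream_exon: int
    rate_control: float
    rate_kd: float

    @property
    def skipped_exons(self) -> list[int]:
        return list(range(self.upstream_exon + 1, self.downstream_exon))

    def as_skip_event(self) -> SkipEvent:
        return SkipEvent(
            gene_id=self.gene_id,
            upstream_exon=self.upstream_exon,
            downstream_exon=self.downstream_exon,
        )


@dataclass
class GeneTruth:
    gene_id: str
    affected: bool
    expressed: bool
    events: list[TrueEvent] = field(default_factory=list)

    @property
    def enriched_exons(self) -> list[int]:
        return sorted({e.upstream_exon for e in self.events})


@dataclass
class GroundTruth:
    genes: dict[str, GeneTruth]

    def all_events(self) -> list[TrueEvent]:
        return [e for g in self.genes.values() for e in g.events]

    def skip_events(self, expressed_only: bool = False) -> list[SkipEvent]:
        return [
            e.as_skip_event()
            for g in self.genes.values()
            if not expressed_only or g.expressed
            for e in g.events
        ]

    def to_json(self, path: str, extra: Optional[dict] = None) -> None:
        payload = {
            "genes": {
                gid: {
                    "affected": g.affected,
                    "expressed": g.expressed,
                    "events": [dataclasses.asdict(e) for e in g.events],
                }
                for gid, g in sorted(self.genes.items())
            }
        }
        if extra:
            payload.update(extra)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def simulate_gene_models(
    cfg: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> list[ExonChain]:
    """Generate one multi-exon transcript per gene, both strands represented.

    The CDS starts inside the transcript's first exon and ends inside its
    last, so every internal exon is fully coding; total coding length is a
    multiple of 3 (the last codon is the stop).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    chains = []
    cursors: dict[str, int] = {}
    for g in range(cfg.n_genes):
        gid = f"G{g:04d}"
        tid = f"T{g:04d}"
        chrom = f"chr{g % 5 + 1}"
        strand = "+" if g % 2 == 0 else "-"
        n = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
        lens = rng.integers(cfg.exon_len_range[0], cfg.exon_len_range[1] + 1, size=n)
        introns = rng.integers(
            cfg.intron_len_range[0], cfg.intron_len_range[1] + 1, size=n - 1
        )
        start = cursors.get(chrom, 1000)
        exons = []
        pos = start
        for i in range(n):
            exons.append(GenomicInterval(chrom, pos, pos + int(lens[i]), strand))
            pos += int(lens[i]) + (int(introns[i]) if i < n - 1 else 0)
        cursors[chrom] = pos + 50_000  # keep gene spans disjoint

        # coding span: into first and last genomic exon, >= 10 nt margin each
        utr5 = int(rng.integers(10, max(11, len(exons[0]) - 30)))
        utr3 = int(rng.integers(10, max(11, len(exons[-1]) - 30)))
        cds_start = exons[0].start + utr5
        cds_end = exons[-1].end - utr3
        coding = sum(e.overlap(cds_start, cds_end) for e in exons)
        rem = coding % 3
        if strand == "+":  # trim the 3' end to a codon boundary
            cds_end -= rem
        else:
            cds_start += rem
        chain_exons = exons if strand == "+" else list(reversed(exons))
        chains.append(
            ExonChain(
                gene_id=gid,
                transcript_id=tid,
                exons=chain_exons,
                cds_start=cds_start,
                cds_end=cds_end,
            )
        )
    return chains


def designate_events(
    chains: Sequence[ExonChain],
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> GroundTruth:
    """Choose affected genes and their designated skip events.

    Exactly round(n_genes * fraction_affected_genes) genes are affected; each
    affected gene gets one event per configured skip class its geometry
    allows, with the first skipped exon at index >= 3 so the upstream ratio
    (and its offset-2 variant where possible) is defined.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    gene_ids = [c.gene_id for c in chains]
    n_aff = round(len(gene_ids) * cfg.fraction_affected_genes)
    affected = set(rng.choice(gene_ids, size=n_aff, replace=False)) if n_aff else set()
    n_silent = round(len(gene_ids) * cfg.silent_gene_fraction)
    silent = set(rng.choice(gene_ids, size=n_silent, replace=False)) if n_silent else set()

    genes: dict[str, GeneTruth] = {}
    for chain in chains:
        gid = chain.gene_id
        gt = GeneTruth(
            gene_id=gid, affected=gid in affected, expressed=gid not in silent
        )
        if gt.affected:
            n = chain.n_exons
            for k in cfg.skip_classes:
                if n < k + 3:  # need first skipped exon >= 3 and downstream <= n
                    continue
                s = int(rng.integers(3, n - k + 1))  # first skipped exon
                rate = cfg.base_skip_rate.get(k, 0.0)
                gt.events.append(
                    TrueEvent(
                        gene_id=gid,
                        k=k,
                        upstream_exon=s - 1,
                        downstream_exon=s + k,
                        rate_control=rate,
                        rate_kd=rate * cfg.kd_multiplier.get(k, 1.0),
                    )
                )
        genes[gid] = gt
    return GroundTruth(genes=genes)


def _junction_coords(chain: ExonChain, u: int, v: int) -> tuple[int, int]:
    """Genomic (donor_end, acceptor_start) of the junction joining transcript exons u < v."""
    if chain.strand == "+":
        return chain.exon(u).end, chain.exon(v).start
    return chain.exon(v).end, chain.exon(u).start


def simulate_junction_reads(
    chains: Sequence[ExonChain],
    truth: GroundTruth,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, list[JunctionRecord]], dict[str, str]]:
    """Poisson junction counts per sample.

    Canonical junctions share the gene's expected depth equally; each
    designated skip event draws Poisson(depth x rate) reads with the rate
    multiplied by its skip class's knockdown multiplier in kd samples.
    Returns (records by sample, sample -> condition).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    samples = {
        **{f"ctrl_{i+1}": "control" for i in range(cfg.replicates_per_condition)},
        **{f"kd_{i+1}": "kd" for i in range(cfg.replicates_per_condition)},
    }
    out: dict[str, list[JunctionRecord]] = {s: [] for s in samples}
    for chain in chains:
        gt = truth.genes[chain.gene_id]
        n = chain.n_exons
        canon_mu = cfg.depth_per_gene / max(1, n - 1)
        for sample, cond in samples.items():
            recs = out[sample]
            for i in range(1, n):
                c = int(rng.poisson(canon_mu))
                if c == 0:
                    continue
                d, a = _junction_coords(chain, i, i + 1)
                recs.append(
                    JunctionRecord(
                        chrom=chain.chrom,
                        donor_end=d,
                        acceptor_start=a,
                        strand=chain.strand,
                        sample_id=sample,
                        condition=cond,
                        read_count=c,
                    )
                )
            for ev in gt.events:
                rate = ev.rate_kd if cond == "kd" else ev.rate_control
                c = int(rng.poisson(cfg.depth_per_gene * rate))
                if c == 0:
                    continue
                d, a = _junction_coords(chain, ev.upstream_exon, ev.downstream_exon)
                recs.append(
                    JunctionRecord(
                        chrom=chain.chrom,
                        donor_end=d,
                        acceptor_start=a,
                        strand=chain.strand,
                        sample_id=sample,
                        condition=cond,
                        read_count=c,
                    )
                )
    return out, samples


def simulate_occupancy(
    chains: Sequence[ExonChain],
    truth: GroundTruth,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Negative-binomial crosslink counts per exon, two crosslink and two
    RNA-seq columns per row (the loader aggregates them).

    The expected crosslink count is ``occ_mean``, multiplied by
    ``enrichment_gamma`` on the exon immediately upstream of each designated
    skipped exon.  RNA-seq columns are Poisson for expressed genes and all
    zero for silent ones.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 3)
    rows = []
    size = cfg.occ_dispersion
    for chain in chains:
        gt = truth.genes[chain.gene_id]
        enriched = set(gt.enriched_exons)
        for i in range(1, chain.n_exons + 1):
            mu = cfg.occ_mean * (cfg.enrichment_gamma if i in enriched else 1.0)
            p = size / (size + mu)
            xl = rng.negative_binomial(size / 2.0, p, size=2)
            rs = (
                rng.poisson(cfg.rnaseq_mean / 2.0, size=2)
                if gt.expressed
                else np.zeros(2, dtype=int)
            )
            rows.append(
                {
                    "gene_id": chain.gene_id,
                    "exon_index": i,
                    "crosslink_1": int(xl[0]),
                    "crosslink_2": int(xl[1]),
                    "rnaseq_1": int(rs[0]),
                    "rnaseq_2": int(rs[1]),
                }
            )
    return pd.DataFrame(rows)


def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random internal-stop-free codons + TAA."""
    body = rng.choice(_NONSTOP_NONMET, size=max(0, n_codons - 2))
    return "ATG" + "".join(body) + "TAA"


def _coding_offsets(chain: ExonChain) -> list[tuple[int, int]]:
    out = []
    off = 0
    for i in range(1, chain.n_exons + 1):
        ln = chain.coding_len(i)
        out.append((off, off + ln))
        off += ln
    return out


def _expected_call(
    chain: ExonChain,
    ev: TrueEvent,
    cds: str,
    domains: list[tuple[str, int, int]],
) -> dict:
    """Generator-side expectation for one event (independent interval logic
    plus direct translation of the constructed mutant)."""
    offs = _coding_offsets(chain)
    a = offs[ev.skipped_exons[0] - 1][0]
    b = offs[ev.skipped_exons[-1] - 1][1]
    nt = b - a
    frame = "none" if nt == 0 else ("in_frame" if nt % 3 == 0 else "frameshift")
    d0, d1 = a // 3 + 1, (b + 2) // 3  # lost residues, original protein
    mutant = cds[:a] + cds[b:]
    n_codons = len(mutant) // 3
    aa = str(Seq(mutant[: n_codons * 3]).translate())
    stop = aa.find("*")
    ptc = stop + 1 if stop != -1 and stop + 1 < n_codons else None
    effects = []
    for name, s, e in domains:
        if frame == "frameshift":
            if s >= d0:
                eff = "total"
            elif e >= d0:
                eff = "partial"
            else:
                eff = "none"
        elif frame == "in_frame":
            if d0 <= s and e <= d1:
                eff = "total"
            elif not (e < d0 or s > d1):
                eff = "partial"
            else:
                eff = "none"
        else:
            eff = "none"
        effects.append([name, eff])
    return {
        "gene_id": ev.gene_id,
        "upstream_exon": ev.upstream_exon,
        "downstream_exon": ev.downstream_exon,
        "skipped_cds_nt": nt,
        "frame": frame,
        "ptc_codon": ptc,
        "domain_effects": effects,
    }


def simulate_cds_and_domains(
    chains: Sequence[ExonChain],
    truth: GroundTruth,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    max_retries: int = 50,
) -> tuple[dict[str, str], dict[str, list[tuple[str, int, int]]], list[dict]]:
    """CDS per transcript plus domains engineered for known outcomes.

    For each gene's first designated event the deleted residue interval
    [d0, d1] anchors three domains: one strictly inside it (total loss for
    an in-frame skip), one straddling d0 (partial), one strictly before
    (none).  In-frame events are guaranteed PTC-free by regenerating the
    CDS if a junction-spanning codon happens to become a stop.

    Returns (cds by transcript_id, domains by transcript_id as
    (name, aa_start, aa_end) tuples, expected consequence calls).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 4)
    cds_by_tid: dict[str, str] = {}
    domains_by_tid: dict[str, list[tuple[str, int, int]]] = {}
    expected: list[dict] = []
    for chain in chains:
        gt = truth.genes[chain.gene_id]
        total = sum(chain.coding_len(i) for i in range(1, chain.n_exons + 1))
        n_codons = total // 3
        offs = _coding_offsets(chain)

        def _in_frame_ok(cds: str) -> bool:
            for ev in gt.events:
                a = offs[ev.skipped_exons[0] - 1][0]
                b = offs[ev.skipped_exons[-1] - 1][1]
                if (b - a) % 3 != 0 or b == a:
                    continue
                mutant = cds[:a] + cds[b:]
                if "*" in str(Seq(mutant[:-3]).translate()):
                    return False
            return True

        cds = _random_cds(n_codons, rng)
        for _ in range(max_retries):
            if _in_frame_ok(cds):
                break
            cds = _random_cds(n_codons, rng)
        cds_by_tid[chain.transcript_id] = cds

        domains: list[tuple[str, int, int]] = []
        if gt.events:
            ev = gt.events[0]
            a = offs[ev.skipped_exons[0] - 1][0]
            b = offs[ev.skipped_exons[-1] - 1][1]
            d0, d1 = a // 3 + 1, (b + 2) // 3
            if d1 - d0 >= 4 and d0 >= 8:
                domains = [
                    (f"{chain.gene_id}_DOM_IN", d0 + 1, d1 - 1),
                    (f"{chain.gene_id}_DOM_EDGE", d0 - 4, d0 + 2),
                    (f"{chain.gene_id}_DOM_BEFORE", 1, d0 - 6),
                ]
        domains_by_tid[chain.transcript_id] = domains
        for ev in gt.events:
            expected.append(_expected_call(chain, ev, cds, domains))
    return cds_by_tid, domains_by_tid, expected


# ---------------------------------------------------------------- writers

def write_gtf(chains: Sequence[ExonChain], path: str) -> None:
    """Emit gene/transcript/exon/CDS features; the reference transcript is
    tagged MANE_Select.  CDS features span the full coding interval
    (including the stop codon) so the chain round-trips exactly."""
    with open(path, "w") as fh:
        for c in chains:
            lo, hi = c.span
            attrs = f'gene_id "{c.gene_id}"; transcript_id "{c.transcript_id}"; tag "MANE_Select";'
            base = f"{c.chrom}\tejcsplice_sim"
            fh.write(f'{base}\tgene\t{lo+1}\t{hi}\t.\t{c.strand}\t.\tgene_id "{c.gene_id}";\n')
            fh.write(f"{base}\ttranscript\t{lo+1}\t{hi}\t.\t{c.strand}\t.\t{attrs}\n")
            for e in sorted(c.exons, key=lambda x: x.start):
                fh.write(
                    f"{base}\texon\t{e.start+1}\t{e.end}\t.\t{c.strand}\t.\t{attrs}\n"
                )
                if c.cds_start is not None:
                    ov = e.overlap(c.cds_start, c.cds_end)
                    if ov:
                        s = max(e.start, c.cds_start)
                        fh.write(
                            f"{base}\tCDS\t{s+1}\t{s+ov}\t.\t{c.strand}\t0\t{attrs}\n"
                        )


def write_junctions_sj(records: Sequence[JunctionRecord], path: str) -> None:
    """STAR SJ.out.tab-style: intron 1-based inclusive, unique reads in col 7."""
    code = {"+": 1, "-": 2, ".": 0}
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda x: (x.chrom, x.donor_end, x.acceptor_start)):
            fh.write(
                f"{r.chrom}\t{r.donor_end+1}\t{r.acceptor_start}\t{code[r.strand]}"
                f"\t0\t1\t{r.read_count}\t0\t30\n"
            )


def write_junctions_bed(records: Sequence[JunctionRecord], path: str) -> None:
    with open(path, "w") as fh:
        for r in sorted(records, key=lambda x: (x.chrom, x.donor_end, x.acceptor_start)):
            fh.write(
                f"{r.chrom}\t{r.donor_end}\t{r.acceptor_start}\t{r.read_count}\t{r.strand}\n"
            )


def write_cds_fasta(cds_by_tid: dict[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for tid in sorted(cds_by_tid):
            fh.write(f">{tid}\n")
            seq = cds_by_tid[tid]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_domains(domains_by_tid: dict[str, list[tuple[str, int, int]]], path: str) -> None:
    rows = [
        {"protein_id": tid, "domain_name": n, "aa_start": s, "aa_end": e}
        for tid in sorted(domains_by_tid)
        for n, s, e in domains_by_tid[tid]
    ]
    pd.DataFrame(rows, columns=["protein_id", "domain_name", "aa_start", "aa_end"]).to_csv(
        path, sep="\t", index=False
    )


def simulate_dataset(cfg: SimulationConfig, outdir: str) -> dict[str, str]:
    """Generate and write a complete dataset; returns the emitted file map.

    Layout: annotation.gtf, junctions/<sample>.sj.tab, samples.tsv,
    occupancy.tsv, cds.fasta, domains.tsv, truth.json.
    """
    os.makedirs(os.path.join(outdir, "junctions"), exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    chains = simulate_gene_models(cfg, rng)
    truth = designate_events(chains, cfg, rng)
    per_sample, conditions = simulate_junction_reads(chains, truth, cfg, rng)
    occ = simulate_occupancy(chains, truth, cfg, rng)
    cds, domains, expected = simulate_cds_and_domains(chains, truth, cfg, rng)

    files = {"annotation": os.path.join(outdir, "annotation.gtf")}
    write_gtf(chains, files["annotation"])
    sample_rows = []
    for sample, recs in per_sample.items():
        p = os.path.join(outdir, "junctions", f"{sample}.sj.tab")
        write_junctions_sj(recs, p)
        files[f"junctions/{sample}"] = p
        sample_rows.append(
            {
                "sample_id": sample,
                "condition": conditions[sample],
                # relative to the dataset directory, so the tree is relocatable
                "path": os.path.join("junctions", f"{sample}.sj.tab"),
            }
        )
    files["samples"] = os.path.join(outdir, "samples.tsv")
    pd.DataFrame(sample_rows).to_csv(files["samples"], sep="\t", index=False)
    files["occupancy"] = os.path.join(outdir, "occupancy.tsv")
    occ.to_csv(files["occupancy"], sep="\t", index=False)
    files["cds"] = os.path.join(outdir, "cds.fasta")
    write_cds_fasta(cds, files["cds"])
    files["domains"] = os.path.join(outdir, "domains.tsv")
    write_domains(domains, files["domains"])
    files["truth"] = os.path.join(outdir, "truth.json")
    truth.to_json(files["truth"], extra={"expected_consequences": expected})
    return files
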