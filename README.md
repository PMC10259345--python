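# ejcsplice

Toolkit for analysing exon-junction-complex (EJC) occupancy and
multi-exon skipping from splice-junction count data.

## The problem

The EJC (eIF4A3 · RBM8A · MAGOH/MAGOHB) is deposited just upstream of
exon–exon junctions during splicing and represses cryptic splice sites
that would otherwise re-splice the newly formed junction.  When the
MAGOH/MAGOHB paralogs are depleted, junctions normally protected by high
EJC occupancy can re-splice, which shows up in RNA-seq as junction reads
that jump one or several annotated exons.  This package provides the
computational chain needed to study that phenomenon without raw-read
processing:

* **gene_model** — parse a GTF, pick one reference transcript per gene
  (MANE tag, else longest CDS), build strand-oriented exon chains, and
  keep genes with ≥ 3 exons.
* **junctions** — classify junction reads against the exon chain
  (canonical / skip-of-k-exons / unannotated), quantify per-k
  knockdown-vs-control skip-read ratios, and call differential
  skipped-exon events with a junction-count PSI
  (significant ⇔ |ΔPSI| > 0.2 and BH-FDR < 0.01).
* **occupancy** — the core statistic: for each skip event, the crosslink
  count of the exon immediately upstream of the skipped exon divided by
  the gene's internal-exon mean (exons 2..n−1), compared against a
  bootstrap null of B = 100,000 resampled exons with a two-tailed
  empirical p-value, at offsets 1 and 2.  Exposed as a
  statsmodels-style model: `EJCOccupancyTest(events, occupancy).fit(...)`
  returns results with `summary()`.
* **consequence** — frame status (in-frame / frameshift), premature
  termination codons, and per-domain none / partial / total loss for
  multi-exon skip events.
* **divergence** — global pairwise identity (protein and CDS) and
  Nei–Gojobori dN/dS with Jukes–Cantor correction for a paralog pair;
  ω ≪ 1 indicates purifying selection.
* **simulate** — a fully seeded generator for annotation, junction
  tables, occupancy tables, CDS and domains with emitted ground truth,
  so every stage is testable without downloads.

## Worked example

```python
import numpy as np
from ejcsplice import (EJCOccupancyTest, load_bundled_paralogs,
                       paralog_divergence)
from ejcsplice.occupancy import occupancy_from_frame
from ejcsplice.simulate import (SimulationConfig, designate_events,
                                simulate_gene_models, simulate_occupancy)

# paralog divergence of the bundled synthetic MAGOH/MAGOHB stand-in
s = load_bundled_paralogs()
d = paralog_divergence(s["MAGOH_protein"], s["MAGOHB_protein"],
                       s["MAGOH_cds"], s["MAGOHB_cds"])
print(f"protein identity {d.pct_identity_protein:.2f}%  "
      f"CDS identity {d.pct_identity_nt:.1f}%  omega {d.omega:.4f}")

# occupancy bootstrap test on a simulated dataset with 3x enrichment
cfg = SimulationConfig(seed=1, n_genes=250, skip_classes=(2,),
                       silent_gene_fraction=0.0)
rng = np.random.default_rng(cfg.seed)
chains = simulate_gene_models(cfg, rng)
truth = designate_events(chains, cfg, rng)
occ = occupancy_from_frame(simulate_occupancy(chains, truth, cfg, rng), chains)
res = EJCOccupancyTest(truth.skip_events(), occ).fit(B=100_000, seed=2)
print(res.summary())
```

prints

```
protein identity 98.63%  CDS identity 85.9%  omega 0.0064
EJC occupancy bootstrap test
  events (dedup): 200   pool: internal (5210 exons)
offset      m   observed  null_mean   null_sd        B          p
     1    200     2.5957     1.0009    0.1218   100000      2e-05
     2    191     1.0188     0.9999    0.1244   100000     0.8511
```

Reading this: the exons immediately upstream of skipped exons (offset 1)
carry 2.6× the typical internal-exon crosslink signal — far outside the
bootstrap null (p at the 2/(B+1) floor) — while the next exon 5′-ward
(offset 2) is indistinguishable from randomly chosen internal exons.
That is the red-line / blue-line dissociation the occupancy statistic is
designed to detect.

The same stages are available from a shell:

```bash
ejcsplice simulate --seed 1 --out data/
ejcsplice ejc-test --annotation data/annotation.gtf --samples data/samples.tsv \
    --occupancy data/occupancy.tsv --B 100000 --seed 1 --out ejc.json
ejcsplice run-all --seed 1 --out runs/demo
```

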