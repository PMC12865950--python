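# paircore

Paired-design, multi-platform oral-microbiome analysis: from
taxa-by-sample count tables and a patient/partner pair map to
**core-dysbiosis consensus calls**.

## The problem

Microbiome case–control studies are notoriously sensitive to the
sequencing technology (shotgun metagenomics vs full-length vs
short-read 16S amplicons) and to the differential-abundance method.
One way to extract robust disease signal is a *combinatorial* design:
recruit patients together with their healthy life partners — people
sharing a household harbour more similar microbiota, so the pairing
absorbs environmental variation and boosts power — sequence every
sample on several platforms, run several differential-abundance
methods, and keep only taxa identified *recurrently*.

`paircore` implements that whole analysis as a tested library + CLI:

- **data model** — taxa × sample tables (counts/relative) tagged by
  material (saliva / supragingival), platform (WGS / FL / SR) and rank,
  with the standard prevalence, low-count and mean-abundance filters;
- **synthetic cohort generator** — a hierarchical
  log-normal–multinomial model with household and subject effects,
  designated disease-/health-enriched taxa, per-platform multiplicative
  bias and realistic depth regimes (heavy-tailed shotgun depths with a
  low-coverage tail), so every stage is testable without any download;
- **pair similarity** — intra-pair Pearson/Spearman/Bray-Curtis vs a
  random-perfect-matching permutation null (the co-housing test);
- **diversity** — scaling-with-ranked-subsampling (SRS) depth
  normalisation, Shannon and Gini-Simpson indices, and a
  Shapiro/Levene-gated choice between paired/unpaired t and rank tests;
- **beta diversity** — Bray-Curtis, classical PCoA, PERMANOVA with
  covariates and *block-restricted* permutations (within-pair label
  swaps, exhaustively enumerated when feasible), a beta-dispersion
  test, Mantel tests between platforms, and taxon-overlap accounting;
- **differential-abundance engines** — three simplified engines with a
  common record schema: a Dirichlet-Monte-Carlo/CLR paired Wilcoxon
  engine, a TMM/log-CPM covariate linear-model engine with
  empirical-Bayes variance shrinkage and pair blocking, and a
  bias-corrected log-linear engine with structural-zero flagging and a
  pseudo-count sensitivity sweep;
- **consensus calling** — a taxon joins the core dysbiosis when it is
  identified ≥ 3 times (engine × platform × material rows), always in
  the same direction, by ≥ 2 sequencing platforms; plus two
  cross-validations (re-pairing permutation, combined-platform batch
  integration with the platform as a covariate).

## Worked example

The package ships the published species- and genus-level evidence
tables (one row per identification).  Calling the consensus on the
species table:

```python
import paircore as pc

calls = pc.call_core(pc.packaged_evidence("species"))
print(pc.summarize_core(calls).to_string(index=False))
```

```
   rank  patient  control  total
species       14        6     20
```

Twenty species satisfy the three rules; six of them are enriched in the
healthy partners, the rest in patients.  Each call records its evidence:

```
                    taxon direction  n_evidence           engines platforms
   Anaeroglobus geminatus   patient           5 ALDEX,ANCOM,LIMMA     FL,SR
        Dialister invisus   patient           4             ANCOM FL,SR,WGS
Lachnoanaerobaculum orale   control           3       ANCOM,LIMMA     FL,SR
    Leptotrichia buccalis   patient           3             ANCOM    FL,WGS
   Leptotrichia hofstadii   patient           3 ALDEX,ANCOM,LIMMA    FL,WGS
```

`n_evidence` counts identification rows — methods need not be distinct
(three same-engine rows on two platforms suffice), but a single mixed
direction vetoes the call.

An end-to-end run on a simulated cohort:

```sh
paircore run-all --n-pairs 10 --seed 3 --out results/
```

writes one TSV per stage (similarity, diversity, beta, DA records, core
calls, cross-validations) plus a `manifest.json` with parameters and
seeds; identical config + seed gives byte-identical outputs.

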