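# prenataldx

A tested toolkit for **simultaneous low-pass whole-genome CNV calling and
trio whole-exome analysis** in prenatal diagnosis of fetal structural
anomalies. Instead of the sequential karyotype → microarray → exome cascade —
which stops at the first pathogenic copy-number variant and silently loses
sequence-variant information — both channels are analyzed jointly for each
father–mother–fetus trio, so *double diagnoses* (a causative CNV **and** a
causative sequence variant in the same fetus) and compound-heterozygous
CNV+SNV configurations in trans are detectable.

The toolkit is aimed at developers and analysts of prenatal sequencing
pipelines who need a transparent, fully testable re-implementation of each
analytic step, exercised end-to-end on a bundled synthetic trio-cohort
generator with known ground truth.

## What is implemented

| Module | Step |
|---|---|
| `prenataldx.synthdata` | synthetic genome, 20 kb bin counts, exon-depth matrices, trio genotypes, phenotype ontology — all with serializable planted truth |
| `prenataldx.cnv_lowpass` | genome-wide CNV calling from shallow-WGS read depth: batch normalization, smoothness regression, first-order-difference breakpoints, paired-breakpoint segments |
| `prenataldx.cnv_exonic` | multi-exon CNV calling from cohort exon depths: PCA normalization, z-scoring, 3-state Viterbi with a ≥3-contiguous-exon rule |
| `prenataldx.wes_filter` | variant quality screen: GQ ≥ 15, depth ≥ 3, low-quality-base fraction < 0.4 |
| `prenataldx.trio` | candidate integration, inheritance classification (de novo, X-linked maternal, biparental homozygous, parental), CNV+SNV compound-het phasing, double-diagnosis flagging |
| `prenataldx.prioritizer` | information-content phenotype matching (Phrank-style), frequency/consequence filters, simplified "ACMG-lite" P/LP tiering |
| `prenataldx.cohortstats` | diagnostic-yield tables, exact two-tailed Fisher tests, de novo fraction, recurrence summaries |

### The statistics at the core

**Low-pass CNV calling.** Reads are binned at 20 kb; samples in a batch are
scaled to a common total and ratioed to the per-bin batch median. The log2
series is smoothed with a centered local linear regression (window *W* = 15
bins) and differenced; breakpoints are the positions where the window-scaled
difference `W·(s_j − s_{j−1})` exceeds `τ = max(k·1.4826·MAD, 0.1)` (*k* = 5).
Consecutive opposite-direction breakpoints bound a candidate segment, called
when ≥ 3 bins with mean ratio outside [0.75, 1.25]; copy number is
`round(2·ratio)`.

**Exonic CNV calling.** After removing dominant principal components
(variance > 0.7× the mean component variance) and z-scoring, each sample's z
series is decoded with a DEL/diploid/DUP hidden Markov model (emissions
N(∓3, 1)/N(0, 1), event entry 10⁻⁴, persistence 0.9); only runs of ≥ 3
contiguous non-diploid exons are reported.

**Phenotype match.** For ontology term *t* with *n(t)* genes carrying *t* in
their annotation closure and *n_pa(t)* genes carrying all of *t*'s parents,
the marginal information is Φ(t) = −log₂(n(t)/n_pa(t)) bits; a gene's score
against a patient profile is ΣΦ over the shared ancestor closure.

**Cohort statistics.** Exact two-tailed Fisher p-values are the sum of
hypergeometric probabilities of all same-margin tables no more probable than
the observed one; diagnostic yields are half-up rounded percentages.

## Worked example

Simulate a 12-trio cohort, run the full report pipeline, and compute cohort
statistics from the bundled per-class count table:

```bash
prenataldx simulate --seed 5 --n-trios 12 --out cohort/
prenataldx prioritize --fixtures cohort/ --out report.json
prenataldx cohort-stats --out stats.json
```

The second command prints

```
7/12 trios diagnosed -> report.json
```

and `report.json` holds, per trio, the reported P/LP findings, e.g.:

```json
"TRIO0008": {
 "diagnosed": true,
 "double_diagnosis": false,
 "findings": [{"kind": "cnv", "genes": ["GENE_2_08"], "chrom": "2",
               "start": 8520000, "inheritance": "de_novo",
               "tier": "P", "phrank_score": 6.041}]
}
```

— at this seed, seven trios carry a planted causal mechanism and all seven
(and only those seven) are diagnosed, each with the planted gene. The third
command prints the per-class diagnostic yields; the totals row works out to

```
"Total": 23.67        # percent of 959 trios with a P/LP finding
"multisystem_vs_single_p": 0.0183
```

meaning 227 of 959 trios are diagnosed and multisystem anomalies have a
significantly higher yield (32.28%) than single-system anomalies (22.36%).

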