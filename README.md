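# vbflow

Multi-tube **TCR Vβ flow-cytometry repertoire analysis**: pooling of an
8-tube Vβ antibody panel into a single event matrix, Vβ-blind phenotype
clustering, tube-aware Vβ frequency reconstruction, diversity indices,
oligoclonal-expansion calling, and the companion **TRB clonotype-table**
analyses (Shannon diversity, artifact filtering, CDR3 spectra,
cross-sample overlap, antigen-database matching).

## Who this is for

Commercial Vβ typing kits spread 24 Vβ-family antibodies over 8 staining
tubes (3 per tube) on top of a shared backbone of lineage,
differentiation and exhaustion markers (CD3, CD4, CD8, CCR7, CD45RA,
CD27, CD28, TIGIT, PD-1). Labs using such kits to screen for clonal
T-cell expansions — e.g. in long-term transplant follow-up — face a
bookkeeping problem: each Vβ antibody only ever sees one eighth of the
cells, so naive per-cluster percentages are misleading. vbflow does the
bookkeeping, clustering and calling reproducibly, and ships a synthetic
generator with planted ground truth so the whole chain is testable.

## The statistics at the core

**Tube-relative frequency.** After each tube is proportionally
downsampled to an equal event count *n* per tube and tubes are pooled,
the frequency of family *f* (antibody in tube *t(f)*) within a scope *S*
(a cluster or subset) is

```
freq_tube(f, S) = #{Vβ f+ events in S} / #{events in S from tube t(f)}
```

The naive within-scope fraction `#Vβf+ / |S|` is also reported; for a
fully monoclonal scope over 8 balanced tubes it tops out at
**1/8 = 12.5%** — for every Vβ+ cell, seven Vβ− cells of the same clone
sit in the pool from the other tubes.

**Diversity.** Inverse Simpson `D = 1/Σ pᵢ²` over the tube-relative
frequencies renormalized across detected families (1 ≤ D ≤ 24, 24 iff
uniform); Shannon `H = −Σ pᵢ ln pᵢ` over clonotype read frequencies.

**Expansion calls.** Cluster Vβ profiles are hierarchically clustered
(correlation distance, average linkage) together with the naive
reference profile; a cluster is *oligoclonal* when it fails to join the
naive clade at cophenetic similarity ≥ τ (default 0.8) **or** its
dominance (max tube-relative frequency) exceeds δ (default 0.5).
Flagged clusters sharing a dominant family and TIGIT/PD-1/CD45RA
fingerprint are merged, and tracked over timepoints.

**Clustering.** A batch-trained self-organizing map plus average-linkage
metaclustering of node codebooks, in the FlowSOM style, using scatter +
backbone markers *excluding CD3 and all Vβ channels*, so clustering can
never be driven by the gates it is later scored against.

## Worked example

The default configuration simulates a four-sample, 8-tube study with
three planted late-memory clonal expansions (one outside antibody
coverage) and runs everything:

```
$ vbflow run-all --outdir demo --seed 1
done: 60407 pooled events, 9 clusters, 2 expansion calls -> demo
```

`demo/expansion_calls.tsv` — both planted *covered* clones are found,
with a pure-clone dominance of 1.0 and a homogeneous exhaustion-marker
fingerprint (the third planted clone expresses a Vβ outside the kit's
coverage and is, correctly, not callable by flow):

```
lineage clusters dominant_family dominance fingerprint           naive_similarity total_frequency
CD4     2        Vb13.2          1         TIGIT-/PD-1+/CD45RA-  -0.0714808       0.434219
CD8     0        Vb12            1         TIGIT+/PD-1-/CD45RA+  -0.0773651       0.355944
```

`demo/expansion_kinetics.tsv` tracks each call across the four samples
(total frequency = the call's Vβ+ events over the late-memory events of
that family's tube; `ND` marks timepoints where it is absent):

```
lineage dominant_family fingerprint           pre_boost post_2005 post_2018 donor
CD4     Vb13.2          TIGIT-/PD-1+/CD45RA-  0.408451  0.426357  0.459834  0.442308
CD8     Vb12            TIGIT+/PD-1-/CD45RA+  0.343575  0.384     0.335244  0.359195
```

`demo/vb_diversity.tsv` shows the expected ordering: the diverse naive
compartment sits near the top of the 1–24 scale, while the late-memory
compartment, carrying the planted clones, is strongly reduced:

```
sample_id  subset        inverse_simpson  n_vb_pos_total
pre_boost  early_memory  13.0411          269
pre_boost  late_memory   5.9303           501
pre_boost  naive         16.093           536
```

The same run also writes cluster medians and subset assignments, the
per-family subset profiles, the γδ-surrogate exclusion report, and the
companion clonotype-table analysis (Shannon diversity per sample and the
clonotypes shared between the simulated blood-memory and skin samples).
Identical config + seed reproduce every table byte for byte; each table
header carries the configuration hash.

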