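# Methods

## Problem setting

An 8-tube Vβ typing panel measures 24 Vβ families, three per tube, on
top of a backbone of surface markers stained in every tube (CD3, CD4,
CD8, CCR7, CD45RA, CD27, CD28, TIGIT, PD-1) plus forward/side scatter.
Because a family's antibody is present in only one tube, any frequency
must be computed against the events *of that tube*; vbflow's central
object, the `VbProfile`, therefore carries three counts per family —
Vβ+ events in scope, scope events from the family's tube, and all scope
events — and derives both the tube-relative and the within-scope
frequency from them.

## Pipeline

1. **Gating.** Per tube, events are labeled with one of the tube's three
   families or `Vb-`. Thresholds act on post-transform intensities; an
   event above several thresholds goes to the brightest channel (the
   antibodies are biologically mutually exclusive, so double positives
   are noise), ties broken by the tube's antibody order. Externally
   supplied labels (manual gates) bypass thresholds entirely.
2. **Transform.** Fluorescence channels: `x → asinh(x / c)` with default
   cofactor `c = 150` (common conventional-cytometer practice; any
   monotone choice preserves gate logic). Scatter channels are instead
   rescaled linearly to 0–5 per sample; a constant channel is set to 0
   with a warning. Whether scatter scaling should be per-sample or
   global is genuinely open; per-sample is implemented and recorded in
   the config.
3. **Tube equalization.** Each sample's tubes are downsampled without
   replacement to the smallest tube's count, stratified by gate label
   with largest-remainder apportionment, so every gated population's
   share is preserved to within one event. Equal tube counts are the
   precondition for the 1/8 = 12.5% pooling bound.
4. **Pooling and γδ-surrogate exclusion.** Tubes are concatenated on the
   shared channels (scatter + backbone); Vβ channels never pool — only
   the gate label survives. Optionally, events with CD3 above the 90th
   percentile of pooled CD3 AND CD4 below its gate are excluded as
   likely γδ T cells. Note the quantile form of this rule removes, by
   construction, up to 10% × P(CD4−) of ordinary events in addition to
   the CD3-bright contaminant; the per-tube exclusion report makes the
   cost visible, and both the quantile and a fixed CD4 threshold are
   configurable. With a dedicated γδ channel the same predicate can be
   pointed at it instead.
5. **Clustering.** A batch self-organizing map (default 10×10 grid, 10
   epochs, Gaussian neighborhood with radius decaying linearly from half
   the grid dimension to 1, codebook initialized from a seeded data
   sample) on z-scored clustering channels — scatter + backbone minus
   CD3, never Vβ — followed by average-linkage agglomeration of node
   codebooks (Euclidean) into a user-set number of metaclusters
   (default 10). This is a deliberately deterministic, dependency-light
   rendition of the FlowSOM idea; the original tool's consensus
   metaclustering elaboration is omitted. Determinism given (data,
   seed) is exact.
6. **Subset assignment.** Per cluster, marker positivity is called on
   median expression against per-marker cutoffs: the valley of a
   two-component 1-D Gaussian mixture over cluster medians when at least
   four distinct medians exist, otherwise the median-range midpoint;
   manual cutoffs override. Rules: naive = CCR7+CD45RA+CD27+CD28+;
   early memory = CD27+CD28+ not naive; late memory = CD27− and/or
   CD28−. CD4+ clusters (including CD4+CD8dim, which is flagged) are
   CD4 lineage; CD4−CD8− clusters get the double-negative labels.
7. **Expansion calling.** Cluster profiles (tube-relative vectors,
   missing families zero-filled for this step only) are linked together
   with the naive reference by average-linkage hierarchical clustering
   under correlation distance. A cluster is flagged when its cophenetic
   similarity to the reference (1 − cophenetic distance) falls below
   τ = 0.8 or its dominance exceeds δ = 0.5; both thresholds are
   reported alongside every call. Clusters with zero Vβ+ events carry no
   evidence and are never flagged (an expansion outside antibody
   coverage is invisible to flow — the clonotype-table side is the
   instrument that can see it). Profiles with zero variance are excluded
   from the linkage and fall back to the dominance rule. Calls are made
   on cluster profiles pooled over samples (the heatmap view); kinetics
   then re-expresses each call per timepoint as Σ Vβ+ events of its
   clusters ÷ late-memory events of the family's tube at that timepoint,
   with absent timepoints printed as ND. Calls are matched across
   timepoints by (dominant family, TIGIT/PD-1/CD45RA fingerprint);
   when one family hosts two phenotypically distinct expansions the
   fingerprint disambiguates.

The correlation-clade criterion deserves a caveat: it compares *shapes*
of Vβ usage. It works because polyclonal human Vβ usage is skewed and
that skew is shared across the diverse subsets of one individual; for a
hypothetical perfectly uniform repertoire the correlation between two
noisy profiles is driven by noise alone and the clade rule loses power
against small scopes. Scope size matters: at roughly 10³ scope events
per tube the similarity of truly naive-like profiles sits comfortably
above τ; far below that, dominance is the reliable half of the rule.

## Clonotype tables

AIRR-style TSVs (sample_id, v_call, junction, junction_aa, j_call,
duplicate_count, productive). On load: unproductive rows removed, gene
calls stripped to gene level (`TRBV9*01 → TRBV9`), within-sample
duplicate keys aggregated by read sum, and frequencies computed against
the sample's total productive reads. The artifact filter removes
clonotypes **below** `min_reads = 50` (exactly 50 is retained);
frequencies are deliberately *not* recomputed after filtering so
reported percentages keep the full-library denominator, as sequencing
reports conventionally state them (configurable by re-loading the
filtered table). Within-study clonotype identity is the stringent
(V gene, nucleotide junction, J gene) key; antigen-database matching
uses the amino-acid junction, with HLA compatibility evaluated at the
resolution of the less specific call. Overlap between samples
intersects keys after per-sample filtering, so a shared clone must
clear the artifact filter everywhere it is claimed.

## Synthetic data: what it emulates and what it does not

The generator plants: naive and early-memory CD4/CD8 populations,
polyclonal late-memory backgrounds, clonal late-memory spikes with
homogeneous TIGIT/PD-1 phenotypes (one clone deliberately outside
antibody coverage), a small CD4−CD3-bright contaminant, and clonotype
tables with spiked/geometric clone-size distributions, a configurable
unproductive read fraction, and clonotypes planted verbatim across
samples.

Choices made once, as study conditions:

- Marker intensities are log-normal per marker per population
  (fluorescence is right-skewed), moment-matched to a raw-scale mean and
  SD. Defaults (positive ≈ 5000 ± 2000, negative ≈ 80 ± 40, CD3-bright
  ≈ 20000 ± 6000 arbitrary units) are **synthetic**: no per-population
  intensity distributions are published for this panel, so values were
  chosen to give realistic arcsinh-scale separation (~5 SD between
  positive and negative), not fitted to an instrument.
- Polyclonal Vβ usage is a fixed exponentially decaying distribution
  over families (≈6.6% down to ≈0.4% of T cells), with 30% of mass
  outside antibody coverage to mimic the ~70% kit coverage. The skew is
  shared across all polyclonal populations of a sample, as it is within
  a real individual; a uniform distribution is available for closed-form
  tests.
- Default mixture: naive 40% (CD4+CD8 combined), early memory 20%,
  polyclonal late memory 20%, clonal spikes 8% (CD4, Vβ13.2), 7%
  (CD8, Vβ12) and 3% (CD8, uncovered), γδ-surrogate 2%.
- CDR3 junctions are random in-frame nucleotide strings (21–60 nt,
  cysteine start, no stop codons), frameshifted for unproductive rows.
  No V(D)J recombination realism, no sequencing-error model.
- One RNG stream per (sample, tube) and per named stage, derived from
  the master seed by SHA-256 of the labels, so adding a tube or sample
  never perturbs other draws and every output is reproducible across
  processes.

Not emulated: spillover/compensation, doublets, dead cells,
acquisition-time anomalies, batch effects between samples, or biological
sharing structure beyond the explicitly planted clonotypes. Passing
tests therefore demonstrate the correctness of the bookkeeping,
clustering and calling machinery under clean, well-separated
conditions — not robustness to instrument artifacts or to weakly
separated phenotypes.

## Numerical conventions

- Largest-remainder apportionment everywhere integers must honour
  fractions (downsampling quotas, read counts); remainder ties broken by
  stable ordering.
- Families whose tube contributed no scope events are *missing* (NaN),
  never zero; diversity renormalizes over detected families only, so an
  empty tube cannot inflate evenness. A scope without Vβ+ events has
  undefined (NaN) diversity and dominant family "undetected".
- Event CSVs are comma-separated, UTF-8, `.` decimal, written with 9
  significant digits (round-trips within 1e-6 relative).
- Planted/spiked clonotype read counts are allocated deterministically,
  so a spiked top clone's emitted frequency matches its specification to
  within one read.

## Problem sizes

The test suite runs on 8-tube samples of 300–10,000 events per tube;
the headline recovery figures use 25 simulations at 10,000 events/tube
(frequency recovery, expansion recall) and 100 simulations for the null
false-positive rate; clustering recovery uses three ~5 SD-separated
populations at 800 events/tube. These sizes were chosen so the full
chain, including property-based suites, completes in a few minutes on a
single CPU while keeping binomial noise well inside the stated
tolerances.

## Known limitations

- The expansion rule's clade half is an operational stand-in for visual
  heatmap grouping; τ and δ are reported with every call precisely
  because reasonable alternatives exist.
- Whether inverse Simpson should use within-cluster or tube-relative
  proportions is not standardized; tube-relative is implemented (the
  within-cluster variant is a constant 1/n_tubes rescaling only in the
  balanced case).
- Reference ranges from healthy-control cohorts are external data; the
  API accepts a user-supplied reference profile but ships none.
- FCS container I/O is out of scope; events move as CSV (the format the
  upstream gating software exports).
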