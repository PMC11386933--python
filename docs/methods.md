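# Methods

## Scope and data model

The pipeline operates on three count matrices (circRNA, miRNA, mRNA; one
row per feature, one column per sample) under a two-group design —
control vs treated, at least two replicates per group, three by default to
mirror the whole-transcriptome design the pipeline is modeled on. All
stages run on desk-scale synthetic data generated in-package; nothing is
downloaded. Read-level processing (alignment, circRNA calling,
quantification) is out of scope: counts are the input contract.

## Differential expression

Normalization is CPM by default; DESeq-style median-of-ratios size factors
are available (`method="median_ratio"`; rows containing any zero are
excluded from the median, the standard convention). Significance uses
Welch's t on log2(normalized + 0.5) with BH-FDR per RNA class. This is a
deliberate, documented substitute for a negative-binomial GLM fit: at 3v3
with moderate dispersion the Welch test on log counts is well calibrated,
carries no extra dependencies, and the package's acceptance surface
(fixture gating, planted recovery) does not require parity with any
particular NB implementation. Features with zero variance in both groups
and equal means get p = 1 rather than an error.

Gate defaults follow the reference protocol: |FC| > 2 (circRNA) or > 1.5
(miRNA/mRNA), α = 0.05. The boundary is inclusive (|log2FC| ≥ log2(1.5)):
the smallest magnitude in the packaged mRNA table, 0.5977 ≈ log2(1.513),
must survive. α applies to the raw p-value by default because the printed
result tables report raw p; `alpha_applies_to="fdr"` switches to the
FDR-gated variant described in the protocol's methods text.

## Over-representation analysis

`hypergeometric_p(N, n, M, m)` returns P(X ≥ m) for X ~
Hypergeometric(N, M, n), summing the tail in log space (gammaln); it is
verified against exhaustive enumeration on the full N ≤ 12 grid and
against `scipy.stats.hypergeom.sf` at larger sizes. Terms with zero DE
overlap are excluded from testing by default — they cannot be enriched
and only inflate the BH denominator — with a flag to include them. The
universe is an explicit argument; the pipeline passes the measured
features of the class (annotated ∩ measured), since whether "annotated
genes" means genome-wide or measured-only is ambiguous in the field's
practice.

## GSEA

Ranking is signal-to-noise on log2(CPM + 0.5) with each group σ floored at
max(0.2·|μ|, 0.2) — the desktop-implementation convention, necessary at
n = 3 to stop near-zero variances from exploding scores. Ties are broken
by feature id for determinism. The enrichment score is the standard
weighted running sum (weight 1, configurable): hits add
|s|^w / Σ_hits |s|^w, misses subtract 1/(n − n_hits), ES is the extreme
deviation; when the positive and negative extremes tie within 1e-9 the
positive side wins (a deterministic tie-break; exact ties occur whenever
all hits sit in a central block). Permutations default to random gene
sets of matching size — with 3v3 there are only C(6,3) = 20 phenotype
relabelings, so phenotype permutation is statistically vacuous (it is
implemented, but refuses designs with < 20 distinct relabelings). Null ES
values are shared across sets of equal size, which the gene-set null
permits by construction. NES divides ES by the mean |null ES| of matching
sign; nominal p uses the add-one rule (floor 1/(n_perm+1)); FDR q is the
standard ratio of normalized-null to observed tail fractions per sign,
clipped to [0,1]. Gates: p < 0.05, |NES| > 1, q < 0.25.

## Target prediction

The two detectors are deliberately lightweight stand-ins for the
TargetScan and miRanda site taxonomies (the protocol names the tools but
no parameters); externally computed target tables can be supplied instead
(`read_target_table`) without changing the intersection semantics.

* Seed detector: scans the target 5'→3' for the reverse complement of
  miRNA positions 2–8 plus an A opposite position 1 (8mer), positions 2–8
  (7mer-m8), or positions 2–7 plus the A (7mer-A1); overlapping weaker
  sites are suppressed by the stronger type (8mer > 7mer-m8 > 7mer-A1).
* Alignment detector: local alignment of the reversed miRNA against the
  target under complementarity scoring (+5 WC, +2 G:U, −3 mismatch, gap
  −8 open / −2 extend), pair rewards doubled at seed positions 2–8,
  site reported at score ≥ 80 (perfect 22-mer duplex = 145). The score is
  computed by a vectorized row scan (in-row affine gaps via a prefix-max
  transform, exact because a within-row path is a single gap run); site
  coordinates come from a plain traceback DP run only on pairs that pass
  the threshold, and the two implementations are cross-checked in tests.

Coordinates are 0-based half-open on the supplied target sequence, plus
strand only; U and T are equivalent. Intersection is at pair level — a
(miRNA, target) pair is kept iff both detectors fire anywhere on the
target — matching a protocol that intersects per-pair prediction lists.

## ceRNA network

Correlations are computed on log2(CPM + 0.5) over all samples pooled
(both groups; the only way to get n = 6 from a 3v3 design). Filter (1)
keeps target-supported circ–miR and mRNA–miR pairs with Spearman
ρ < −0.7: the protocol's text says "SCC less than 0.7" while labeling the
pairs negatively coexpressed, and the sponge model requires
anti-correlation, so the negative reading is implemented (threshold and
sign configurable). Filter (2) keeps circ–mRNA pairs with Pearson r
strictly > 0.9 that share a retained miRNA. Filter (3) is the shared-
sponge test: with K = DE miRNAs having ≥ 1 predicted target (the smallest
well-defined universe containing both margins), k1 and k2 the regulator
counts of the circRNA and mRNA, and s the shared count, p = P(X ≥ s) from
the same hypergeometric routine as the ORA; pairs need p < 0.05.
Constant-expression features yield an undefined-correlation sentinel and
the pair is dropped rather than failing the run. Accepted triplets carry
all four statistics; network edges carry triplet provenance, which is what
`extract_subnetwork` uses for focal-gene extraction.

## Synthetic data generator

The generator emulates the study conditions: 3 vs 3 replicates, three RNA
layers (200 circRNA / 150 miRNA / 600 mRNA by default), planted DE
features at |log2FC| = 2 (30/20/40 per class — a desk-scale echo of the
reference study's 371/37/30), and 10 planted ceRNA triplets.

* **Counts.** Log-normal–Poisson with the log-normal variance matched to a
  negative binomial with dispersion 0.02 (typical of cell-line
  replicates); feature means span 10^1.5–10^3.5 (miRNA shifted +0.5
  decades — miRNA libraries concentrate reads on fewer features);
  per-sample library scale factors are log-normal (σ = 0.15). The
  log-normal mixing (rather than a gamma) is what makes exact correlation
  control possible below.
* **Coupling.** Each triplet owns a per-sample latent factor w_s with the
  same variance as the NB noise. A member's noise is
  ±c·w_s + sqrt(1−c²)·ε — positive sign for circRNA and mRNA, negative
  for the miRNA — so coupling c rotates noise into the shared factor
  without inflating within-group variance (DE power is independent of
  coupling), and the sponge sign pattern (circ↑ mRNA↑ miR↓ or mirrored)
  holds across samples. Triplet base abundances are drawn from the top
  half of the mean range: sponge stoichiometry requires abundant players,
  and low-expression triplets would drown in Poisson noise at n = 6.
* **Sequences.** miRNAs are random 22-mers; targets random 300-mers. Every
  planted (miRNA, target) pair gets the reverse complement of miRNA
  positions 2–14 plus an A opposite position 1 embedded at a recorded
  position: the trailing 8 nt are exactly the canonical 8mer site, and
  the 3'-supplementary extension makes the alignment detector fire as
  well (score ≥ 100 > 80) — canonical "both-detector" sites. Each triplet
  additionally grants 2 support DE miRNAs sites in both its circRNA and
  mRNA, emulating ceRNA pairs that share several response elements; this
  is also what gives the shared-sponge test s ≥ 3 and a p-value well
  below 0.05 (a pair sharing a single regulator can never beat p = 1/K).
* **Gene sets.** 40 background terms sampled uniformly over mRNAs plus 5
  planted direction-coherent terms (12 same-direction DE mRNAs + 4 random
  members), so planted terms are enriched for ORA and coordinated for
  GSEA.

Determinism: one seed drives everything; sub-generators (sequences, gene
sets) derive independent streams from it, so identical configs give
byte-identical outputs.

What the generator does **not** emulate: overdispersion heterogeneity
across features, GC/length biases, isoform structure, miRNA-family shared
seeds, correlated gene programs outside the planted terms, and any form
of read-level noise. Passing the planted-recovery tests therefore shows
the chain is implemented correctly and is well calibrated under its own
model — not that the thresholds are optimal for real transcriptomes.

## Orchestration

`PipelineConfig` is one YAML-serializable object whose defaults are the
protocol's thresholds; stages write TSV/FASTA/GMT/JSON artifacts under
`outdir` and append a manifest entry (config hash, seed, row counts at
each filter, timestamp), so every "N survived" is inspectable. `run_all`
executes stages in dependency order and re-runs a stage only when forced,
missing outputs, or an upstream stage re-ran — deleting an intermediate
regenerates it and everything downstream.

## Known limitations

* With only six samples, correlation thresholds of |ρ| > 0.7/0.9 are
  near the resolution limit of rank statistics (Spearman at n = 6 takes
  discrete steps of ≈ 0.03); triplet acceptance is correspondingly
  seed-sensitive at the margins.
* All DE features share the group contrast, so among them correlations
  are inflated toward ±1 regardless of any sponge mechanism: at 3v3 an
  opposite-signed DE pair has E[SCC] ≈ −0.77 from the contrast alone.
  Consequently filters (1)–(2) reject little among DE features, and
  chance triplets (supported by coincidental target-site intersections)
  appear at a low but nonzero rate even without any planted coupling.
  This mirrors a recognized failure mode of correlation-based ceRNA
  inference on real two-group designs; the sponge test and the
  target-intersection requirement are the effective null filters.
* The target detectors approximate the named tools' site logic, not their
  scores; absolute alignment scores are not comparable to miRanda's.
* The Welch-on-log substitute for an NB GLM loses power for very low
  counts (< ~10 per sample); at the generator's depth this is immaterial,
  but real low-depth data would warrant the median-of-ratios + NB route.
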