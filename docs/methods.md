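# Methods

`mirstress` re-implements, as a tested library, the computational path of a
drought/rehydration small-RNA study in barley: conserved-miRNA
quantification from 12 sRNA libraries (3 biological replicates × 4
conditions: control_1, drought, control_2, rehydration), negative-binomial
differential-accumulation testing with a restoration analysis, degradome
(PARE) cleavage-site profiling with t-plots, miRNA:target duplex scoring
with a 0–18 compliance score, and 2^−ΔΔCt qPCR integration. This note
records the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic data do and do not establish.

## Read processing and the miRNA catalogue

Reads are 3′-adapter trimmed by exact match on the adapter's first 6 nt,
leftmost occurrence wins; inserts shorter than 14 nt are discarded.
Adapter trimming in production pipelines is usually delegated to a
dedicated trimmer with mismatch tolerance; the exact-prefix rule is chosen
here because it is deterministic, testable against a brute-force substring
oracle, and sufficient for error-free synthetic reads. The adapter
sequence is a run parameter (kit adapters differ; no default is baked in).

Distinct trimmed sequences are tallied per library, and only sequences
reaching **≥ 10 counts in at least one library** (inclusive boundary) are
analysed further. Conserved miRNA identity is assigned by exact
containment against a mature miRNA reference (miRBase-style FASTA, IDs up
to first whitespace, U→T normalized): a read matches a mature entry iff
the shorter sequence is an exact substring of the longer — zero
substitutions anywhere — and the length difference is at most
`max_length_diff` (default 4, chosen so a 20–24-nt read can still match a
21-nt mature sequence; configurable). With zero substitutions required,
exact substring search is equivalent to a short-read BLAST step and fully
deterministic. A read matching several reference entries is assigned to
the best-ranked one only (smallest |length difference|, then lexicographic
ID); ambiguity is logged rather than double-counted.

IsomiR collapsing — a manual curation step in typical studies — is
automated as: per miRNA name, the variant with the highest total count
across all libraries is canonical; ties break to the smaller |length
difference|, then to the lexicographically smallest sequence. This is a
reproducible proxy for "keep the dominant variant". Only canonical rows
enter the per-miRNA count matrix.

## Differential accumulation

The testing engine is a compact NB Wald test in the DESeq2 mould, written
for self-containedness and testability rather than feature parity.

* **Normalization** — median-of-ratios size factors: the pseudo-reference
  is the per-row geometric mean over libraries (rows containing any zero
  are excluded); a library's factor is the median of its count/reference
  ratios. This assumes most rows are not differential; the generator's
  default design (49 of 150 miRNAs drought-affected) respects that
  assumption, and heavily-DE matrices will show the usual normalization
  bias.
* **Dispersion** — per-row method-of-moments on normalized counts, using
  the Bessel-corrected within-condition variances pooled across the two
  groups (so a real condition effect does not inflate the estimate), with
  variance model var = μ + αμ². With 3+3 replicates the per-row estimate
  is noisy and roughly half the rows undercut their true dispersion,
  which makes a purely row-wise Wald test anti-conservative (empirically
  ~0.12 rejection at nominal 0.05). Rather than empirical-Bayes
  shrinkage, each row's estimate is floored at the **median of the
  per-row estimates across rows** (and at 10⁻⁸): rows may exceed the
  typical dispersion but not undercut it. This one-line moderation brings
  the simulated type-I error to ~0.05–0.06 while leaving genuinely
  overdispersed rows untouched.
* **Effect size** — log2FC = log2(μ̂_treated + 0.5) − log2(μ̂_control + 0.5)
  on normalized condition means; the 0.5 pseudo-count handles zero rows.
  The fold change is unshrunk: the classification threshold below is
  applied to the raw estimate.
* **Test** — Wald statistic log2FC/SE with the delta-method standard
  error SE² = Σ_groups Var(μ̂)/( (μ̂+0.5)² ln²2 ), where Var(μ̂) sums the NB
  variances μ/s_j + αμ² of the normalized counts; two-sided p from the
  standard normal; Benjamini–Hochberg adjustment (statsmodels) over all
  tested rows.
* **Classification** — up iff log2FC ≥ 0.6 **and** adjusted p ≤ 0.05;
  down symmetrically; both boundaries inclusive; everything else
  unchanged. Adjusted p is the default significance column (a raw-p mode
  exists); when classifying the packaged printed table, which carries
  significance star classes instead of p-values, any star class counts as
  significant.

Omitted relative to full DESeq2: dispersion-trend empirical-Bayes
shrinkage, independent filtering, Cook's-distance outlier handling,
GLM covariates, LRT. These matter for genome-scale RNA-seq; for a
150-row miRNA matrix the simplified engine is calibrated (see the
acceptance tests) and transparent.

The **restoration summary** cross-tabulates drought calls against
rehydration calls over the same miRNA universe: "restored" = changed in
drought and unchanged after rehydration; "common" = the same
non-unchanged call in both. A 3×3 pri-miRNA/miRNA cross-tab counts name
pairs over the intersection of two call sets (dropped names are
reported, not silently ignored).

## Degradome profiles and t-plots

PARE tags (≥ 14 nt after trimming, inclusive) are mapped to transcripts
by exact, zero-mismatch, forward-strand substring search with **every
occurrence counted** — the semantics of an exhaustive exact mapper run in
report-all-alignments mode. PARE tags are sense-strand by construction,
so reverse-strand hits are not considered. Whether a multi-transcript tag
should be counted once or distributed is not decidable from first
principles; all-occurrences counting is used and stated. Each placement
increments the transcript profile at the 1-based coordinate of the tag's
5′ end (internal arrays are 0-based half-open; conversion happens at the
API boundary).

Profiles are rendered in three views: raw counts; counts per million
mapped library placements (the normalization constant is a convention —
per-million of mapped tags — since no single standard exists); and
average-based, raw/mean over all transcript positions, defined as all-zero
for a signal-free transcript. Sites are ranked by count with competition
ranking (ties share a rank; the next rank is 1 + the number of strictly
greater positions); zero positions are unranked.

## Target scoring

Candidate sites are ungapped windows of the miRNA's length; every
transcript window is scored against the miRNA with plant-style penalties:
Watson–Crick pair 0, G:U wobble 0.5, mismatch 1, with weights doubled for
miRNA positions 2–13. Windows with penalty ≤ `penalty_max` (default 7.5)
are reported. Bulged duplexes are excluded by default: ungapped scanning
keeps an exact all-windows brute-force oracle feasible, and a gapped mode
could be added without changing the score contract. U and T are
interchangeable; wobble is evaluated on the mRNA sense strand (mRNA G
opposite miRNA U, mRNA U opposite miRNA G). The predicted cleavage
coordinate is the transcript nucleotide paired to miRNA position 10 —
AGO slices between the nucleotides opposite positions 10 and 11.

The compliance score combines alignment quality with degradome evidence:

    compliance = 2 × min(penalty, 7.5) + rank_penalty

with rank_penalty 0 for a cleavage site ranked 1 on its transcript, 1 for
ranks 2–3, 2 for ranks 4–10, and 3 for an unsupported site (rank > 10 or
no degradome signal at the position). The score therefore spans exactly
[0, 18], lower is better, and is monotone in penalty and in rank
category. The 2× rescaling and the 4-level rank penalty are this
package's concrete choice for a score whose published description fixes
only the range and the lower-is-better semantics; all constants are
exposed, and per-target scores from other implementations are not
expected to match numerically — only the ordering behaviour is contracted
(and tested end-to-end on planted targets).

Best-target reports keep every hit within Δ = 1.0 of the lowest
compliance score (ties always co-reported). Cleavage validation checks
whether a maximal-count degradome position inside the site lies within
±1 nt (configurable) of the predicted coordinate.

## qPCR integration

ΔCt = Ct(gene) − Ct(reference) per library; ΔΔCt is the difference of
condition means; FC = 2^−ΔΔCt, assuming perfect doubling (no
amplification-efficiency correction). Significance is a two-tailed
two-sample t-test on the replicate ΔCt values — the standard choice for
this design. Fold changes in (0, 1) are reported as −1/FC so magnitudes
are symmetric about ±1; FC = 1 maps to +1 (the ≥ 1 branch). Printed
"n-fold increase" statements use the treated/control ratio rounded half
away from zero. A target counts as negatively correlated with its miRNA
iff the miRNA is called up and the target's signed FC is significantly
negative, or the miRNA is down and the signed FC is significantly above
1 (target-test significance only; no joint criterion).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the statistical structure the analysis assumes,
with defaults mirroring the study design:

| parameter | default | meaning |
|---|---|---|
| `n_mirnas` | 150 | conserved miRNAs (two of them the printed miR172b-5p/3p arms) |
| planted effects | 11↑/38↓ drought; 9↑/16↓ rehydration (5↑/11↓ common) | per-condition log2FC, magnitudes drawn once from 1.0–2.5 |
| `dispersion` | 0.1 | NB dispersion α, var = μ + αμ² (matches the test engine's model) |
| `mean_count_range` | 20–1000 | per-miRNA baseline means, log-uniform |
| `isomir_rate` | 0.1 | fraction of a miRNA's reads emitted as ±1–2-nt 3′ variants |
| `degradome_peak_fraction` | 0.5 | fraction of a target's tags starting exactly at the cleavage site |
| `degradome_site_tags` / `degradome_background_tags` | 200 / 2000 | per-target and uniform background tag counts |
| `ct_noise_sd` | 0.2 | Gaussian sd on every measured Ct (reference included) |

Counts are NB(mean · 2^effect, α) per library; degradome tags are 20-nt
sense-strand copies (post-trim length; comfortably above the 14-nt
floor), with the drought library's peak intensity scaled by 2^(miRNA
drought log2FC) so cleavage strength tracks miRNA abundance; Ct tables
place the planted fold change as a −log2(FC) shift of the treated
condition's target Ct. All randomness derives from one seed through
per-stage integer streams, so outputs are byte-identical under a fixed
seed and independent of stage call order.

Deliberately not simulated: sequencing-error substitutions (they would
violate the zero-substitution matching contract by design, so error
robustness is out of scope), pri-miRNA dynamics, adapter remnants,
reverse-strand degradome signal. Passing tests on this generator
demonstrate correctness of the algorithms under the stated statistical
model — not robustness to base-call errors, mapping ambiguity in real
transcriptomes, or reference-gene instability in real qPCR.

One propagation fact is worth recording because it bounds what Ct-level
simulation can show: with sd-0.2 noise on every Ct, a replicate ΔCt
carries sd 0.2√2 ≈ 0.28 and the ΔΔCt estimate (difference of two
3-replicate means) sd ≈ 0.23, so only ~65–80 % of recovered fold changes
can land within 15 % of the planted value at n = 3 — a property of the
design, not of the estimator. The simulate tests therefore check
unbiasedness and agreement of the error spread with this formula; pushing
the within-15 % fraction above 90 % would require per-Ct noise ≈ 0.12 or
more replicates.

## Numerical conventions and degenerate inputs

* Coordinates: 1-based inclusive on the transcript sense strand
  everywhere in the public API; 0-based half-open internally.
* All thresholds inclusive at their boundary (≥ 10 counts, ≥ 14 nt,
  |log2FC| ≥ 0.6, p ≤ 0.05, penalty ≤ 7.5).
* Dispersion floor 10⁻⁸; SE floor 10⁻¹²; penalty cap applied inside the
  compliance score, not in the aligner.
* Empty library → all-zero column with a warning; empty hit list → empty
  report; zero-signal transcript → all-zero average-based view; a Ct
  table with zero replicate variance (noise-free synthetic input) returns
  p = 1 for ΔΔCt = 0 and p = 0 otherwise rather than a 0/0 t-statistic.
* Fixture numbers printed with decimal commas are normalized at load.

## Problem sizes used in the test suite

Simulation-backed tests run at deliberately small scale: the null
calibration uses 2000 rows × 6 libraries; effect recovery plants 100
rows among 2000; end-to-end target recovery uses 100 miRNA/target pairs
against 100 transcripts of 300–800 nt; the CLI round-trip uses 12 miRNAs
and 6 transcripts. These sizes give stable Monte-Carlo estimates for the
tested bands while keeping the whole suite in well under a minute.

## Known limitations

* The NB engine is not a DESeq2 replacement for genome-scale data (no
  dispersion trend, no outlier handling); it is calibrated for
  matrices of order 10²–10³ rows with small replicate numbers.
* Compliance-score constants reproduce range and ordering semantics, not
  any particular published per-target score table.
* The exact-containment matcher cannot tolerate sequencing errors or
  internal isomiR editing; only 3′/5′ length variants are handled.
* Degradome mapping is exact and ungapped; spliced or variant-containing
  transcripts will lose tags to the unmapped pool.
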