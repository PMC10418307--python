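# Methods

This note documents the statistical model behind each stage of `allorep`,
the assumptions it makes, the default parameters and why they were chosen,
what the synthetic generator does and does not emulate, and the numerical
choices. All empirical claims here are computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted beyond what those runs check.

## Input model

A sample is a clonotype table: CDR3 amino-acid sequence, V/J gene, read
count, frequency. Two dialects are parsed (AIRR Rearrangement TSV and
MiXCR export TSV); rows with non-standard residues or CDR3s shorter than
5 aa are dropped and tallied. Duplicate (CDR3, V) rows are merged by
summing counts, resolving V-gene conflicts (in `cdr3` key mode) by
majority count. Clonotype identity defaults to the CDR3 alone
(`key_mode="cdr3"`); `"cdr3v"` appends the V gene for stricter matching.

## Normalization (TMM)

Between-sample scaling uses the trimmed mean of M-values: for each sample
vs a reference, log-ratios (M) and average log-abundances (A) over shared
nonzero clonotypes are doubly trimmed (30% on M, 5% on A) and averaged
with precision weights (inverse asymptotic binomial variance); factors are
rescaled to geometric mean 1. The reference sample is the one whose
upper-quartile-scaled count is closest to the mean. Effective library size
= total count × factor. Defaults (30/5% trims, precision weighting) are
the standard TMM choices; the implementation agrees with edgeR 4.0.16 to
1e-8 on the frozen matrices in `tests/test_normalization.py` (the tests
carry the frozen factors and never invoke R).

TMM assumes most clonotypes are not differentially abundant between
samples; strong global expansion violates this and is exactly why scaling
is computed on trimmed log-ratios rather than totals.

## Expansion calling

Counts for clonotype *i* in sample *j* are modeled as negative binomial
with mean proportional to the effective library size and a per-clonotype
dispersion φᵢ. The question "did clonotype *i* expand under stimulation?"
is a model comparison:

- **H0** — one relative abundance shared by stimulated and control groups;
- **H1** — independent abundances per group.

Marginal likelihoods integrate the abundance over an empirical prior: a
Gaussian kernel density estimate of the pooled log10 abundances of up to
10,000 clonotypes, evaluated on a 200-point log-spaced grid extended 1.5
decades below and 2 above the observed range (weights floored at 1e-4 of
the maximum to keep the support broad). H1 multiplies two independent
group integrals, so H0 benefits from a single Occam factor and H1 pays
two — the usual automatic complexity penalty. A 10-iteration EM estimates
the mixing proportion of expanded clonotypes, starting at 0.1 and clipped
to [1e-6, 1−1e-6]; the reported `posterior_de` is P(H1 | data).

Dispersions are method-of-moments estimates from within-group residuals
(residuals are taken against each group's own mean — pooling the means
would absorb true between-group differences into φ), shrunk 50/50 toward
a 25%-trimmed-mean common dispersion and floored at 5e-3. The floor
prevents near-Poisson clonotypes from generating overconfident calls.

Fold change is estimated from pooled pseudocounted counts
((Σ stim + 0.5)/stim effective size ÷ (Σ ctrl + 0.5)/ctrl effective
size) and binned at thresholds 2, 4, 8, 16, 32 — only when
`posterior_de` exceeds the 0.95 threshold, and downward-closed (a 8×
call is also a 2× and 4× call). The 0.95 posterior cut and the 2–32×
ladder correspond to roughly five cell divisions over a stimulation
culture. Calibration on null simulations (depth 1e5, 3 vs 3 samples,
20 seeds) and recovery of planted 8× expansions are checked in
`tests/test_acceptance.py`.

Assumptions: replicates within a group are exchangeable; library sizes
are well estimated by TMM; clonotype counts are independent given the
abundances (multinomial competition is ignored, adequate when no single
clonotype dominates).

## Overlap

The Morisita–Horn index
C = 2Σxᵢyᵢ / ((Σxᵢ²/X² + Σyᵢ²/Y²)·X·Y) is computed over the key union of
two samples. Overlap grids restrict both samples to clonotypes whose
expansion call includes each threshold of (1, 2, 4, 8, 16, 32); an empty
restricted repertoire yields NaN rather than 0, so "no data" is
distinguishable from "no overlap".

## Similarity graphs

Vertices are CDR3s (size = summed counts), edges connect pairs at Hamming
distance exactly 1 (equal length, one substitution). Construction hashes
each CDR3's L single-position-masked variants per length bucket, giving
near-linear cost; tests verify exact agreement with the O(n²) scan up to
n = 500. Cluster statistics (count, max, mean ± SEM of sizes) cover
components strictly larger than `min_size` = 5 (a display mode uses ≥);
the edges/vertices ratio is computed over the union of those components
— the ratio exceeds 1 only when clusters contain cycles, i.e. denser
than tree-like variant chains.

## Specificity patterns

Local patterns are k-mers (k = 4–7) of the trimmed CDR3 (3 N-terminal, 2
C-terminal residues removed — the conserved anchors carry no specificity
signal). A motif present in *a* of *n* query clonotypes and *b* of *m*
reference clonotypes is reported when a one-sided hypergeometric tail
p ≤ 1e-3 (computed as `hypergeom.sf(a−1, n+m, a+b, n)`), enrichment fold
≥ 10 (pseudocount 0.5 applied only when b = 0), and support ≥ 3 distinct
clonotypes. Global patterns are same-length CDR3 groups identical except
at one trimmed-region position, written with a `%` wildcard, requiring
≥ 3 distinct residues at the wildcard.

Pattern identity is (kind, pattern string). The exclusive-set algebra
removes patterns found in both arms from each arm (the shared set is kept
separately) and optionally subtracts unstimulated-repertoire patterns;
unstimulated patterns are discovered through the same enrichment route
against a naive reference (or, absent one, the unstimulated pool itself,
in which case only global templates can qualify — mere presence of a
motif in controls must not count as "unstimulated-specific", because
alloreactive precursors exist unexpanded in every control). Clonotypes
matching exclusive patterns of exactly one arm are labeled with that arm;
matches to both arms are ambiguous and excluded.

## Repertoire features

Cumulative frequency and the per-clonotype frequency-ratio statistics of
a labeled subset are compared against the whole repertoire (or against
the expanded subset) with a two-sided Mann–Whitney U test on log10
frequencies (exact null distribution when both sides have n < 50).
V-usage vectors are frequency-weighted ("read") or unweighted
("clonotype") distributions over a fixed gene order with an "other"
bucket, compared by cosine similarity. The spectratype's long/short ratio
divides clonotypes with CDR3 > 14 aa by those ≤ 14 aa — 14 aa is the
repertoire's modal length, making the ratio a symmetric skew measure.
Positional amino-acid profiles are computed over deduplicated CDR3s of
exactly the target length (default 14), positions numbered from 1.

## Annotation

Exact, case-sensitive CDR3 matching against a specificity table (VDJdb,
McPAS-TCR, or generic column dialects). The annotated share is matched
distinct CDR3s / total distinct CDR3s; a CDR3 with several pathologies
counts once in the share and once per pathology bucket.

## Synthetic data

The generator emulates the statistical structure the analysis relies on,
with planted ground truth:

- background clonotypes with Zipf(1.1) base clone sizes, CDR3s of the
  form CASS…QYF with a G/S-rich interior, lengths 9–20 centered at 14
  (discretized Gaussian, sd 1.6), and a 20-gene mouse-like TRBV usage;
- planted specificity groups (default 10 direct, 10 indirect, 3 shared;
  8 members plus 2 Hamming-1 variants of an anchor) sharing a random
  4–6-mer interior motif, base weights 10× the background median;
- feature skews giving the arms measurable signatures: direct carriers
  prefer TRBV31 and short CDR3s, indirect carriers TRBV13-1, both avoid
  TRBV13-2;
- per-condition sampling: responsive groups' expected frequencies are
  multiplied by the expansion factor (default 8), then counts are
  multinomial at depth 1e5, 3 replicates per condition. Direct-pathway
  stimulations expand direct + shared groups, indirect-pathway
  stimulations indirect + shared, controls nothing — the shared groups
  are the designed source of the between-arm pattern intersection.

It does **not** emulate: sequencing error or PCR amplification bias, VDJ
generation probabilities or convergent recombination, J-gene structure
beyond the fixed suffix, biological correlation between replicates
(animals are i.i.d. draws), or antigen-driven selection dynamics beyond a
single fold factor. Conclusions about those phenomena cannot be validated
with this generator.

All randomness flows from a single integer seed through named
`numpy.random.default_rng([seed, *stream])` child streams, so every stage
is independently reproducible.

## Numerical choices

- All likelihood computations are in log space with `logsumexp`
  marginalization; NB log-pmf via `gammaln`.
- Hypergeometric tails via `scipy.stats.hypergeom.sf`, exact to the
  1e-10 oracle tolerance enforced in tests.
- NaN (never 0 or an arbitrary sentinel) encodes undefined statistics:
  overlap of an empty restricted repertoire, cluster statistics with no
  qualifying cluster, spectratype of an empty set.
- Configuration hashes are the first 16 hex characters of the SHA-256 of
  the sorted-key JSON of the run configuration; every output bundle and
  run log carries the hash and seed.

## Limitations

- Exact-match annotation understates true specificity sharing (no fuzzy
  or k-mer matching against databases).
- The expansion caller assumes assay-matched controls exist; conditions
  without controls are a configuration error rather than a fallback.
- The empirical prior is shared across clonotypes; abundance-dependent
  dispersion trends are only captured through the 50% shrinkage toward
  the common value.
- Pattern discovery tests each motif marginally at α = 1e-3 with a fold
  and support floor instead of a formal multiple-testing correction; the
  spurious-report rate is checked empirically on synthetic data, not
  guaranteed analytically.
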