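# Methods

## Data model

The unit of analysis is the MaxQuant protein group. `proteinGroups.txt` is
read verbatim — no rows are dropped at parse time — with every
`LFQ intensity <label>` column becoming a sample, `+`-coded flag columns
(`Reverse`, `Potential contaminant`, `Only identified by site`) becoming
booleans, and intensity 0 stored as missing, since MaxQuant writes 0 for
"not quantified". Flag columns absent in older MaxQuant dialects are
treated as all-false with a warning rather than an error.

Display identifiers come from the gene-symbol column: the first token of a
semicolon-delimited symbol, the first accession when the symbol is empty,
and `.1`, `.2`, … suffixes for duplicates (first occurrence bare). All
downstream matching (pathway, consensome, lookup) is case-insensitive and
suffix-insensitive, so a duplicated symbol's rows are all found.

The experimental design is one row per sample — label, condition,
replicate, order — validated to have ≥ 2 conditions, ≥ 2 replicates per
condition, unique (condition, replicate) pairs, and a label set exactly
matching the data. The `order` column is parsed and carried but unused by
any computation; it exists for compatibility with completed design files
that include it, and is optional on input.

## Filtering

With threshold $t$ (default 0), a protein is kept iff some condition
detected it in at least $n_c - t$ of its $n_c$ replicates. $t$ must be
smaller than the smallest replicate count; at the boundary the rule would
degenerate to "any detection anywhere", which is rejected as meaningless.
The filter only removes rows; surviving values are never altered. The rule
is monotone in $t$ and is verified in the tests against exhaustive
enumeration of every detection pattern for small designs.

## Imputation

LFQ dropout is predominantly left-censored: values vanish because they sit
near the detection limit. Missing entries in sample $s$ are therefore
drawn from a down-shifted Gaussian $\mathcal N(\mu_s, \sigma)$ —
"MinProb-like" — with

* $\mu_s$: the `downshift_quantile` (default 0.01) quantile of the
  sample's observed log2 values, anchoring imputations at the low tail;
* $\sigma$: `width` (default 0.3) × the median per-protein observed SD, so
  imputed spread is a fraction of typical biological/technical spread.

Observed entries are never modified; a sample with fewer than two observed
values is a fatal error (no censoring distribution is estimable). One seed
governs the whole pipeline, with per-step substreams derived
deterministically from it; the full chain is bit-reproducible.

Median normalization (shift each sample's observed median onto the grand
median) is available but off by default. Variance-stabilizing
normalization was considered and deliberately not implemented; median
alignment covers the common loading-offset case and keeps the pipeline's
assumptions easy to state.

## Differential testing

Each unordered condition pair is tested per protein with a two-sample
statistic on pooled residual variance $s_g^2$, $d = n_1+n_2-2$ df. With
moderation (default), the per-protein variances are shrunk toward a prior
estimated across proteins: modelling $s_g^2 \sim s_0^2 F(d, d_0)$, the
statistic $e_g = \log s_g^2 - \psi(d/2) + \log(d/2)$ has
$\mathrm E[e] = \log s_0^2 - \psi(d_0/2) + \log(d_0/2)$ and
$\mathrm{Var}[e] = \psi'(d/2) + \psi'(d_0/2)$, so $d_0$ is obtained by
inverting the trigamma function (Newton iteration) on the excess variance
of $e$ and $s_0^2$ from its mean. When the spread of log variances is no
larger than sampling noise explains, $d_0$ is effectively infinite (capped
at $10^{12}$ so degrees of freedom stay finite) and every protein shares
$s_0^2$. The moderated statistic is referred to Student t with $d + d_0$
df; `moderated=False` gives the ordinary pooled t ($d_0 = 0$). The
implementation is checked in the tests against limma's `lmFit`/`eBayes`
(agreement ≈ 1e-10) and, unmoderated, against the textbook pooled t.

Benjamini–Hochberg adjustment is applied within each contrast separately
(the limma/DEP convention; pooling p-values across contrasts would couple
unrelated comparisons). Significance requires both `padj < alpha` (0.05)
and `|log2FC| > lfc_cutoff` (0.5), strict inequalities. Contrast direction
is numerator − denominator on the log2 scale, lexicographic by default and
user-selectable; reversing a contrast negates every log2FC bitwise and
leaves p-values untouched. The DEP set is the union of significant
proteins over all contrasts.

## Visualization

* PCA uses the top-N proteins by row variance of the imputed log2 matrix
  (default 500, clamped to the number of proteins with a warning). Rows
  are centered, not scaled; "most variable" is the row variance, the
  ranking the paper-of-record tools use when nothing else is specified.
  Component signs are fixed (largest-magnitude loading positive) for
  reproducibility.
* Heatmaps z-score each row (mean 0, SD 1; constant rows become zeros with
  a warning), cluster rows with k-means (fixed seed, 10 restarts, best
  inertia), renumber clusters by descending size, order rows within a
  cluster by correlation with the centroid, and clamp the *display* to
  ±`z_cap` (default 2) while exports keep unclamped values.
* Every plot (PCA, volcano, heatmap, bar) writes its numbers to a TSV next
  to the PNG/SVG, so no figure is ever the only source of a number.

## Mining

Pathway gene sets are read from GMT-style files (`set_id`, name, genes);
Reactome-style ids (`R-HSA-…`) are treated as human and converted to mouse
symbols before matching — via a user-supplied ortholog table
(one-to-many allowed, union taken) when available, else the
capitalization heuristic (CYP4A14 → Cyp4a14). The heuristic is not true
orthology and is documented as such; a mapping table overrides it.

Consensome tables (gene, receptor, percentile ∈ [0, 100]) load in long or
wide form; duplicate (receptor, gene) rows keep the maximum score with a
warning. Targets are genes scoring **at or above** the percentile cutoff
(default 95; "top 95th percentile" read inclusively). The annotated export
carries one percentile column per receptor, blank where the gene misses
that receptor's threshold. Enrichment summaries report the base rate
(targets among detected, one decimal) and up-/down-set rates (nearest
integer, the reporting precision of the source counts), plus an optional
one-sided hypergeometric p — an extension beyond the informal rate
comparison, clearly optional. Cross-receptor overlap (pairwise
intersection sizes and per-receptor unique targets) supports Venn-style
interpretation, since consensomes share genes.

## Synthetic data generator

The generator emulates a 4-condition × 3-replicate LFQ study
(~2000 proteins) the way the pipeline models it: per-protein baseline log2
abundance $\mathcal N(25, 2)$, replicate noise SD 0.5, planted
per-condition log2 shifts on disjoint protein subsets, logistic
intensity-dependent dropout
$P(\text{miss}) = \mathrm{sigmoid}((m - x)\,k)$ with midpoint $m = 22$
and slope $k = 3$ per log2 unit (≈ 8% missingness concentrated at low
abundance; the steep slope models a detection limit — a shallow slope
would leak missing-at-random dropout into high-abundance proteins, which
is not the mechanism left-censored imputation assumes), an optional
uniform missing-at-random floor (default 0), and decoy/contaminant rows
carrying the MaxQuant `+` flags. Output uses exactly the column dialect
the parser consumes, with truth tables (per-contrast true log2FC, dropout
mask, true DE set) alongside.

What it does **not** emulate: peptide-level structure and roll-up,
between-sample loading differences, correlated protein co-regulation,
batch effects, and intensity-dependent variance. Tests passing on this
generator therefore demonstrate the pipeline's statistical behavior under
its own assumptions, not performance on any particular real dataset.

The end-to-end recovery check plants |log2FC| = 2 on 170 of 2000 proteins
(≈ the DEP fraction a real multi-condition liver study yields) in a
2-condition × 3-replicate design and requires ≥ 90% recall with ≤ 10%
observed false discoveries, averaged over 50 seeds. Recall is measured
among planted proteins that pass the detection filter: a planted protein
censored below the detection limit in every condition carries no
quantitative signal, so counting it against the pipeline would measure
simulated instrument sensitivity, not inference. The 2-condition design is
used because DEP-set false-discovery proportions are controlled per
contrast; a union over many informative contrasts accumulates distinct
false positives against a fixed true set and is not a 10%-controlled
quantity even in the no-missingness limit.

## Numerical and design choices

* Trigamma inversion: Newton iteration from $y_0 = 0.5 + 1/x$, tolerance
  1e-10, with asymptotic guards for extreme arguments.
* Zero residual variance for every protein is a fatal degenerate input;
  a single protein with zero variance gets p = 1 (lfc 0) or p = 0
  (lfc ≠ 0) rather than NaN.
* BH adjustment delegates to statsmodels' `fdr_bh`; the O(m²) step-up
  definition is kept in the tests as an independent oracle.
* k-means and PCA delegate to scikit-learn; a dense eigendecomposition
  serves as the PCA oracle in tests.
* Percentages: base rate rounded to 1 decimal, up/down percentages to the
  nearest integer (Python round-half-even, indistinguishable at the
  reported precisions).
* Exit codes: 0 success, 2 user/validation error, 1 internal fault.

## Known limitations

* Exact reproduction of any particular published DEP count from real data
  is not guaranteed: the imputation method family and normalization state
  of other tools' deployments vary, and imputation is stochastic.
* The ortholog heuristic mishandles genuinely divergent human/mouse
  symbols and one-to-many families unless a mapping table is supplied.
* No multi-factor models, covariates, paired designs or permutation
  tests; contrasts are all-pairwise two-group comparisons.
* Consensome files are user-supplied snapshots; the package never
  downloads or refreshes them.
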