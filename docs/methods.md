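# Methods

## Model and simulation procedure

Sequences evolve site-independently along a fixed rooted tree under a
continuous-time Markov chain on a finite state alphabet (4 nucleotides, 20
amino acids, the 61 sense codons of the standard genetic code, or a custom
state set).  A model is an instantaneous rate matrix Q (non-negative
off-diagonals, zero row sums) together with its stationary distribution π.
Unless disabled, every Q is rescaled so that −Σ_i π_i Q_ii = 1: branch
lengths are then expected substitutions per site (per codon site for codon
models).  The root sequence is drawn i.i.d. from π (or supplied as an MRCA
string); each branch transforms parent states by sampling from the rows of
P(t·r) = exp(Q·t·r), where r is the site's rate factor.  The matrix
exponential is computed densely (scipy `expm`); entries in (−1e−12, 0) from
round-off are clipped to zero and rows renormalized, so every row is a
valid categorical distribution.

One seeded random stream drives a whole simulation, consumed in a fixed
order: pre-order over branches, sites left to right, one uniform per site
per branch inverted against the appropriate P row.  Output is therefore
bit-identical for identical inputs and independent of the
transition-matrix cache (which is keyed on model, rate, and branch length).

Ancestral (internal-node) sequences are retained by default; unnamed
internal nodes receive stable pre-order identifiers (`root`,
`internal_1`, …).

## Model families

* **GTR family** — Q_ij = r_ij π_j over the six unordered nucleotide pairs;
  HKY85 (r = κ for transitions, 1 for transversions), TN93 (two transition
  rates), and JC69 (all rates and frequencies equal) are constraint
  constructors on the same type.
* **Empirical amino-acid models** — Q_ij = s_ij π_j from symmetric
  exchangeabilities shipped as plain-text lower-triangle files (WAG, JTT,
  LG, DAYHOFF, mtMAM, mtREV24) with model-default or user frequencies.
  The loader is generic (any state count, `# state order:` header, values
  re-ordered into the canonical alphabet ordering) and validates symmetry
  and non-negativity.  The AB and ECM empirical codon models are recognized
  names whose numeric data is not bundled; the loader accepts a
  user-supplied file of the same layout, and the restricted-ECM structural
  property (zero exchangeability for multi-nucleotide codon pairs) is
  exercised with a synthetic file in the tests.
* **Mechanistic codon models** — state space is the 61 sense codons; all
  multi-nucleotide instantaneous changes have rate 0.  A single-nucleotide
  change x→y at one position is rated (β if nonsynonymous else α)·μ_xy·T;
  ω = β/α, and specifying ω alone means α = 1, β = ω.  μ is either the
  κ-parameterized bias (transitions κ, transversions 1) or a full table of
  12 ordered (or 6 symmetric) rates.  T is the target codon frequency π_j
  in GY style.  In MG style T is the target-nucleotide frequency at the
  changed position: we use the *implied* product-model nucleotide
  frequencies — the position-specific (default) or global nucleotide
  distribution whose product measure, restricted to sense codons,
  reproduces the supplied codon vector, obtained by iterative proportional
  fitting of the positional marginals.  The raw positional marginals are
  skewed by stop-codon exclusion even for a uniform codon vector; the
  implied frequencies are exactly uniform there, which makes GY and MG
  coincide at uniform frequencies and keeps rate ratios equal to their
  parameter ratios (e.g. Q(AAA→AAG)/Q(AAA→AAT) = ακ/β).
* **Mutation–selection (Halpern–Bruno)** — Q_ij = μ_ij·S_ij/(1−e^(−S_ij))
  with S_ij = f_j − f_i; the fixation factor is set to 1 for |S| < 1e−9
  (its continuous limit).  Fitnesses are per state; for codons they may be
  given per amino acid (expanded to synonymous codons) or as target
  frequencies (f = ln π).  Codon mutation–selection models are restricted
  to single-nucleotide steps.  The stationary distribution is solved from
  the null space of Qᵀ; under symmetric μ it equals e^f/Σe^f.
* **Custom matrices** — any non-negative off-diagonal matrix over any
  alphabet; the user's diagonal is ignored and recomputed as the negative
  row sum, and the stationary distribution is solved numerically (a
  reducible matrix triggers a warning, not an error).

## Heterogeneity and partitions

Site-rate heterogeneity uses discrete distributions over categories:
discrete-gamma with k equal-probability bins and mean-of-bin rates
(computed via the Gamma(α+1) CDF identity, renormalized so the categorywise
mean is exactly 1, which the scaling convention requires), Γ+I (an extra
rate-0 class with probability p_inv, gamma rates rescaled by 1/(1−p_inv)),
arbitrary rate categories, or *model* categories that attach whole
substitution models to sites — the mechanism used for site-wise dN/dS
variation, where categories are MG-style models differing only in ω.
Sites are assigned to categories i.i.d. (default) or by deterministic
tiling in blocks matching the proportions exactly; tiling refuses
proportions that are not exactly representable at the partition size.  The
per-site assignment is recorded and can be written to a sidecar TSV.

Branch heterogeneity uses `#flag` tokens in the Newick string (after the
branch length, or after the node name / closing parenthesis); a flag
selects a named model for its branch and is inherited by descendant
branches until overridden.  Precedence on a branch: flag, else the site's
category model, else the partition's root model.  Partitions are
contiguous blocks of sites with their own size, models, site distribution,
and optional MRCA.

## dN/dS counting

Counting operates on the simulator's true ancestral sequences, so each
branch contributes parent→child codon pairs at every site; no ancestral
reconstruction is involved.  Per pair: identical codons contribute
nothing; single-nucleotide differences contribute one synonymous or
nonsynonymous change by direct translation; multi-nucleotide differences
are averaged over all minimal single-step paths through sense codons with
equal weights (paths through stops are discarded; in the rare case that
every path is blocked the event contributes no counts).  Opportunities
partition each codon's 3 sites: over its ≤9 non-stop single-nucleotide
neighbors, S = 3·(synonymous flux)/(total flux) and N = 3 − S, where the
flux weights are 1 by default or μ_xy times the target nucleotide
frequency when the mutational model is supplied.  Model-aware weighting
matters: under κ > 1 transitions are enriched for synonymous changes, and
unweighted opportunities systematically depress counted ω.

The raw estimator is ω̂ = (n/N)/(s/S), reported as missing when s = 0.
Because endpoint counting cannot see back- and multiple substitutions
within a branch, the faster class saturates on long branches (measured
here: ~10% synonymous undercount at ω = 0.1 on a 0.15-length branch,
inflating raw ω̂ by ~10%).  `SubstitutionCounts` therefore also exposes the
standard Nei–Gojobori-style correction dN = −(3/4)ln(1 − 4pN/3) (and
likewise dS), and `omega_corrected` = dN/dS; the validation harness and
the acceptance script use the corrected estimator.  Scopes: global,
per-site (summed over branches), and per-branch (labeled by child node).

The analytic counterpart `expected_dnds_from_mutsel` computes, at the
mutation–selection model's stationary distribution, the nonsynonymous
substitution flux relative to the neutral (mutation-only) nonsynonymous
flux, divided by the same ratio over synonymous pairs:
ω = [Σ_NS π_i μ_ij F(S_ij)/Σ_NS π_i μ_ij] / [Σ_S π_i μ_ij F(S_ij)/Σ_S π_i μ_ij].
With amino-acid-level fitnesses the synonymous factor is identically 1.

## Validation experiments and problem sizes

The validation harness simulates under known parameters and measures
recovery; these are also the quantities the acceptance script reports.
Conditions:

* **rate_recovery** — JC69, two-taxon trees, branch lengths
  {0.01, 0.05, 0.1, 0.3, 0.5}, 50 replicates × 100,000 sites; estimator:
  half the JC-corrected tip-tip distance, d = −(3/4)ln(1 − 4p/3).
* **dnds_recovery** — MG-style model, equal codon frequencies, two-taxon
  tree with branch lengths 0.1, 50 replicates × 100,000 codons; the
  headline condition is ω = 0.75, κ = 3.25.
* **site_het** — balanced 2^12-taxon tree (4,096 tips), all branch lengths
  0.01, 400 codon sites, four ω categories 0.2/0.4/0.6/0.8 in equal
  proportions tiled deterministically, κ = 1; per-site counted ω grouped
  by true category.  The 2^12 tree is our default problem size for this
  experiment; per-site counting is noisy by nature, and the tree supplies
  ~82 substitution units per site, which separates the four categories
  cleanly while keeping the experiment inside a routine desktop run.
* **branch_het** — four-taxon tree
  `(A:0.15#mA,B:0.15#mB,(C:0.15#mC,D:0.15#mD)#mI:0.15);` with terminal ω
  values 0.4/0.7/1.0/1.5 and ω = 0.1 on the internal branch, κ = 1,
  10 replicates × 100,000 codons; per-branch counted ω.

κ = 1 and equal codon frequencies are used for the heterogeneity
experiments (the headline ω/κ pair applies to the homogeneous recovery
condition); these were fixed once as the experiments' defining conditions.

## What the synthetic data does and does not emulate

The simulator *is* the data generator, so validation demonstrates internal
consistency: sequences drawn from the stated Markov models are correctly
sampled (rates, ω, site and branch heterogeneity all recoverable by an
independent counting path).  The generated data share the model class's
idealizations — site independence, no indels, a single stationary process
per branch/category, true ancestors available to the counter.  Passing
tests therefore say nothing about model adequacy for real alignments, nor
about counting accuracy when ancestors must be reconstructed rather than
known.

## Numerical choices and edge cases

- Stationary distributions from `scipy.linalg.null_space` (rcond 1e−10);
  multiple null vectors (reducible generators) warn and pick one.
- Scaling is idempotent and scale-invariant; `scaled` matrices satisfy
  mean rate 1 within 1e−8.
- Transition matrices: entries clipped at −1e−12, rows renormalized;
  larger negative entries are an error, as are non-finite entries.
- Gamma discretization pins the category mean to exactly 1 after the
  CDF-identity computation.
- Deterministic category tiling requires size·probability integral within
  1e−9, otherwise it instructs the user to switch to stochastic mode.
- ω̂ with s = 0 (or empty opportunity) is NaN, never infinity; summaries
  drop missing sites.
- Frequency vectors must sum to 1 within 1e−10; counting from files skips
  gaps and fully ambiguous characters and supports an optional pseudocount
  (default 0) for models that cannot tolerate zero frequencies.
- Seeds: any source of randomness takes either an integer seed or a live
  `numpy` Generator, so composite experiments can share one stream.

## Known limitations

- No insertions/deletions; alignments are gap-free by construction.
- Only the standard genetic code is bundled (the code table is plain data,
  so alternative codes can be supplied).
- AB and ECM empirical data are not shipped (loader-compatible files can
  be provided by the user).
- IUPAC ambiguity states are not simulated; `U` on input is normalized to
  `T`.
- The multiple-hit correction assumes JC-style saturation within each
  class; it is an approximation (synonymous sites in two-fold boxes
  saturate faster than four-fold ones), accurate at the branch lengths
  used here but not exact on very long branches.
- The global counting scope averages opportunities across branches; for
  strongly heterogeneous trees per-branch scope is the meaningful unit.
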