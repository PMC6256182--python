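# Methods

## The model

`lexnetgrow` simulates the growth of a reader's orthographic lexicon as
frequency-driven sampling from a print environment, and analyzes the
resulting similarity networks with graph theory.

A **frequency lexicon** is an ordered list of word types with positive token
frequencies — the learning environment. A **growth schedule** is an ordered
list of grade checkpoints with strictly increasing target lexicon sizes (in
types). Each **virtual participant** starts by drawing the first checkpoint's
number of types from the full corpus, without replacement, with inclusion
probability proportional to token frequency (successive sampling). At every
later checkpoint, the participant draws the size difference from the
*learning environment* — the corpus minus the words already known — under the
same law. Lexicons are therefore exactly schedule-sized, nested along grades,
and biased toward high-frequency (hence short, neighbor-rich) words early.
The model deliberately assumes no between-participant differences in lexicon
size or growth rate, no forgetting, and a constant learning environment
across grades.

For each (participant, grade) lexicon, an unweighted, undirected
**orthographic network** is built: types are nodes, and two types are
connected iff their Levenshtein distance is exactly 1 (one substitution,
insertion, or deletion). Types without any neighbor — **lexical hermits** —
are excluded from the graph but counted; the hermit proportion is taken over
the whole lexicon. The network measures are the node count *n*, mean degree
⟨k⟩ = 2|E|/n, degree distribution P(k), average shortest-path length *L*,
diameter *D*, and average clustering coefficient
C_i = 2T_i / (k_i(k_i−1)) averaged into *C*. Trajectories of these measures
over grades are summarized with one-way ANOVA, Tukey-HSD-corrected
consecutive-grade comparisons, and orthogonal-polynomial trend fits; the
degree distribution is checked for scale-free shape by OLS on log₁₀P(k)
versus log₁₀k.

## Sampling law and randomness

The text-level description of the learning model fixes only that sampling is
"sensitive to frequency"; we implement the simplest such law, successive
sampling (probability proportional to size, without replacement). The
implementation uses the exponential-race equivalence: item *i* receives key
E_i/w_i with E_i ~ Exp(1), and the m smallest keys are the ordered draw.
This induces exactly the successive-sampling distribution over ordered draws
and exhausts the environment gracefully. Ties (measure zero) break by input
order, which is why corpus entry order is part of the I/O contract.

All randomness derives from one base seed through numpy `SeedSequence`
objects keyed by `(base_seed, participant_id, stage_index)`: participants
and stages are independent streams, runs are platform-stable, and reruns
are bit-identical.

## The synthetic corpus

The corpus the original analysis used (a proprietary corpus of German
children's books, ~180,000 types) is not redistributable, so the package
ships a generator that emulates the three properties the analysis actually
relies on:

1. **Zipfian frequencies** — frequency of rank r proportional to
   r^(−`zipf_exponent`), default exponent 1.0. Frequencies are strictly
   decreasing, so sampling ties cannot occur.
2. **Frequency–length coupling** — each word's length is drawn from a
   discretized normal (SD `length_sd`, default 1.2) clamped to
   [`length_min`, `length_max`] (defaults 2 and 7) whose mean shifts
   linearly from the low to the high end of that range as rank grows, scaled
   by `length_frequency_link` (default 0.6). At link 0 length is independent
   of frequency; at the defaults the log-frequency/length correlation is
   clearly negative, mirroring the linguistic principle of economy that makes
   frequent words short.
3. **A realistic hermit share** — with the default alphabet (26 lowercase
   letters) and length bounds, roughly 60–70% of a 5,000-type corpus has no
   Levenshtein-1 neighbor, close to the ~63% neighborless share reported for
   the real German type inventory. The induced degree distribution is
   right-skewed (few hubs, many low-degree words).

The defaults were calibrated once, to make these directional properties
stable, and then frozen. The generator produces random character strings: it
has no morphology, inflection, or phonotactics. Results on synthetic corpora
are therefore *directional* — growth increases mean degree and decreases
clustering — not numerical reproductions of the corpus-specific values
(e.g., ⟨k⟩ ≈ 6.8–7.0, L ≈ 9.8–10.6, C ≈ 0.38–0.49, hermits ≈ 46–49% at
31,570–130,675 types). Passing tests show the machinery and the qualitative
developmental signature, not German-specific magnitudes.

## Problem sizes

Two scales are exercised routinely. The *published schedule*
(31,570; 32,606; 46,757; 58,238; 71,344; 93,293; 130,675 types for grades
1–6 and 8) is run against a 180,000-type synthetic corpus with 50
participants to verify growth arithmetic — the grade-2 step adds exactly
1,036 types, and the cohort comprises 350 lexicons. The *demo schedule*
(875; 1,300; 2,000; 3,630 types — the grades-1/3/5/8 sizes rescaled to a
5,000-type corpus) with 10 participants is the default for full network
analysis; it keeps exact path-length computation and repeated seeded runs
comfortable on one CPU.

## Numerical conventions

- **Distances.** Levenshtein distance is computed over Unicode code points
  after NFC normalization ("ä" is one symbol), case-sensitively. The graph
  index finds substitution pairs via single-position wildcard buckets and
  indel pairs via exact membership of single-deletion variants; the
  shared-deletion-variant shortcut is rejected because it admits
  transpositions, which are distance 2.
- **Path lengths.** Hermit removal does not guarantee connectedness, so *L*
  averages over ordered *reachable* pairs only and *D* is the maximum finite
  distance. Exact mode runs BFS from every node (used automatically up to
  5,000 nodes); above that, BFS from 1,000 uniformly sampled sources pools
  distances — a ratio estimator whose numerator and denominator are each
  unbiased — and yields a lower bound for *D*; the measures record flags the
  mode.
- **Clustering.** C_i is undefined at degree < 2; such nodes are excluded
  from *C* by default. A `count-as-zero` policy is available because the
  convention is genuinely ambiguous in the literature.
- **ANOVA.** The default is one-way between-groups, which with 7 grades × 50
  participants yields df = (6, 343) — the layout consistent with the
  reported statistics; a true repeated-measures decomposition is available
  via `repeated=True`. Tukey adjustment is computed over all pairs, with
  consecutive pairs reported.
- **Trend fits.** Grade enters as a numeric variable with its actual unequal
  spacing (1–6, then 8). The basis is orthonormal polynomial contrasts (QR of
  the Vandermonde matrix, signs fixed against x^j), so per-order coefficients
  are mutually orthogonal; fits are pooled OLS over all participant-level
  observations.
- **Power-law fit.** OLS of log₁₀P(k) on log₁₀k over observed
  positive-frequency degrees. This is the descriptive method matching the
  analysis being reproduced; it is *not* a maximum-likelihood tail estimator
  and should not be read as a formal power-law test. On small demo-scale
  graphs the raw high-degree tail is noisy and per-participant R² can be
  modest; at the published scale (tens of thousands of nodes) the same
  procedure is much more stable.
- **Power analysis.** Power of the two-sided zero-correlation test by the
  Fisher-z approximation, Φ(λ − z₁₋α/₂) + Φ(−λ − z₁₋α/₂) with
  λ = |atanh r|·√(n−3); at r = 0 it returns α exactly. At n = 50, r = 0.4,
  α = 0.05 the power is ≈ 0.83, which is the justification for simulating 50
  virtual participants.

## Design choices and limitations

- Word types are case-sensitive distinct orthographic sequences (German
  nouns are capitalized); any case-folding is an upstream decision of
  whoever prepares the corpus TSV.
- Duplicate types arising from NFC normalization on read are merged by
  summing frequencies, with a logged warning.
- The trajectory diagnostic (mean corpus frequency of newly acquired words
  per grade) needs corpus frequencies and therefore takes the corpus as an
  argument alongside the cohort.
- Graph distance computations are delegated to scipy's sparse-graph BFS;
  clustering and degree statistics are computed directly on adjacency sets.
  networkx is used in the test suite only, as an independent cross-check.
- Out of scope by design: lemma-level analysis, age-of-acquisition
  validation, frequency-weighted edges, Damerau (transposition-aware)
  distance, forgetting, inter-individual variation in size or growth rate,
  and grade-specific subcorpora.
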