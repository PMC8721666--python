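# Methods

This note records the models and procedures abbrevkit implements, the
defaults and why they were chosen, the numerical choices, and what the
synthetic-data experiments do and do not demonstrate.

## Spelling-convention alignment

A definition "long form (SF)" fixes the LF's right edge at the
parenthesis; the left edge is recovered by mapping SF characters onto the
left context. The mapping rules:

1. SF characters are compared case-insensitively; non-alphanumeric SF
   characters are ignored.
2. The first SF character must be the first character of the first LF
   token (the anchor).
3. Later SF characters map, in order, to word-initial or word-internal
   positions; hyphens are token-internal, so "Alpha-Beta (AB)" matches
   with B word-internal.
4. Function words (*of, the, and, for, a, an, in, to*) may be skipped
   without consuming an SF character. Every **non**-function token of the
   candidate LF must receive at least one SF character; without this
   constraint any suffix whose extra tokens are simply unused would
   validate, and "alpha nice beta (AB)" would wrongly pass.
5. The last token must receive at least one SF character (a trailing
   plural *s* counts), since the LF abuts the parenthesis.
6. Among all token suffixes of the left context that satisfy 1–5, the
   shortest wins. Off-by-one analysis of n-best candidate lists shows
   that the dominant error is one extra word at the left edge, so a
   shorter satisfying span is the safer hypothesis.

The search window is min(|SF| + 5, 2·|SF|) tokens left of the parenthesis
— the classical heuristic for this task family. Matching uses a small
backtracking recursion over (SF position, token); windows are ≤ 15 tokens,
so cost is negligible.

The "SF (long form)" pattern is accepted when the token left of the
parenthesis is a plausible SF and the *entire* inner text satisfies the
same mapping.

Known limitations, by design: pairs that violate the convention in their
first character ("chloride current (ICl)") are not extracted by rule —
they are only reachable through external n-best input; sentence splitting
is the plain `[.!?] + space + uppercase` rule with no abbreviation
awareness; no LaTeX or markup handling.

The SF gate accepts tokens of 2–10 characters with at least one letter,
an alphanumeric first character, not purely numeric, and not a
function-word stop list entry — with the nuance that the stop list only
fires on tokens that are not fully uppercase, because "AN" or "IN" as
written are acronyms, not articles/prepositions.

## Features

**charmatch** compares raw first characters of SF and candidate LF,
case-insensitively, with no skipping. It is deliberately cruder than full
alignment: "what counts as salient" is hard to pin down, but the first
character targets the left-edge failure mode that dominates.

**freq** counts exact occurrences of `normalize(LF) + " (" + SF` over a
corpus (internal LF whitespace collapsed to single spaces; one space
before the parenthesis, matching how definitions are typeset). Counting is
case-sensitive by default — expansions vary in case across documents and
that variation is signal — with a fold-case option. The counter is a
suffix array over the separator-joined corpus, built by prefix doubling
(numpy `lexsort`; O(n log² n) time, O(n) memory — a direct
comparison sort of suffix strings materializes O(n²) characters and is
unusable beyond toy corpora). Queries are two bisections, O(|pattern| ·
log n). The separator (NUL) may not appear in documents or patterns, which
guarantees no match crosses a document boundary. Only log(1 + freq) enters
the models; no additional length normalization is applied.

**agreement** flags equality (ignoring whitespace) between a candidate and
a named system's top output.

## The logistic reranker

z = β₀ + β₁·rank + β₂·charmatch + β₃·log(1+freq), Pr(correct) ≈ σ(z).
Fitting is unpenalized maximum likelihood via Newton–Raphson — the default
of standard GLM stacks — converging when the log-likelihood changes by
< 1e-8 (cap 100 iterations). Inactive coefficients are pinned to exactly
0. Standard errors are Wald (inverse Hessian). On separable data Newton
sends coefficients to infinity while the likelihood creeps to 0; the fit
aborts with a separation error once any |β| exceeds 30 (fitted magnitudes
on realistic data are ≲ 6) and recommends the L2 ridge option, which
bounds the problem. The `fit:` modes of the CLI retry with ridge 0.1
automatically.

Reranking sorts one (doc, SF) group by descending z with ties broken by
original rank, so a rank-only model with β₁ < 0 provably never reorders —
it reproduces the upstream system.

Twelve preset coefficient vectors are shipped (three nested formulas ×
four benchmark gold sets); they are data, not fits performed here. No
train/test split is applied by default: the reranker is an error-analysis
instrument, fitted and read in-sample. The estimator follows the
scikit-learn protocol (`get_params`/`set_params`, clonable, fitted
attributes with trailing underscores), so users who want generalization
estimates can hand it to `sklearn.model_selection.cross_val_score` or a
pipeline directly.

## Decision trees

Greedy binary CART on Gini impurity, authored here because the tree's
reporting convention — every node carries (best label, accuracy of best
label, coverage), child coverages summing to the parent's — is the point
of the analysis. Binary features split as equality tests; rank splits as
thresholds. Defaults max_depth 4, min_leaf 20 (rpart-like). No pruning or
cost-complexity: the trees are read, not deployed. The split choice is
cross-checked against scikit-learn's tree on fixtures in the test suite.

## Evaluation conventions

A predicted (doc, SF, LF) matches gold iff doc and SF match exactly and
the LFs match after whitespace collapsing, case-insensitively (exact-case
mode available). Duplicate triples collapse to one. Empty predictions
score precision 0 by convention. Off-by-one means exactly one token added
or removed at one edge; the edge (left/right) and direction (too
many/too few) are recorded rather than hard-coded, so the left-edge
dominance can be verified from data.

## Synthetic generator: what it emulates, what it does not

`generate_corpus` emits documents whose definitions are built backwards
from the model: an LF phrase of 2–5 words drawn from a fixed vocabulary,
the SF its uppercased word initials (so charmatch holds by construction),
an optional distractor modifier immediately before the LF, filler
sentences from a fixed word list, and geometric repeat mentions of the SF
(`repeat_rate` 0.7 — a definition presupposes re-use). Defaults: 100
documents, Poisson(2) pairs per document, vocabulary of 50 phrases,
modifier rate 0.3, exception rate 0.02 (convention violations are rare in
real text; exceptions get an extra leading SF letter, like ICl).
Vocabulary phrases have pairwise-distinct word initials, which makes the
shortest satisfying suffix provably the generated LF; the in-text
distractor modifier never shares an initial with the phrase. One SF is
defined at most once per document (one sense per discourse).

`generate_nbest` plants the error profile of span-extraction systems:
with p_correct (0.83) the gold LF at rank 0; with p_off_by_one (0.11) a
one-word left-edge perturbation at rank 0 and gold at a uniform lower
rank; with p_otherwise (0.06) an unrelated span at rank 0 and gold absent.
Remaining ranks are filled with further left-edge perturbations; exactly
5 candidates per SF. N-best perturbation words are *unconstrained*, so a
wrong candidate occasionally passes charmatch — the feature is a good but
imperfect discriminator, as on real output. The simulated reference
system for agreement features returns gold with probability 0.95
(a strong companion system).

`generate_adaptive_corpus` plants terms at document rate 0.05 that, once
present, recur with continuation probability 0.85 (adaptive mode), or
draws independent Poisson counts at the matched mean rate (control). The
expected adaptation ratio Pr(k≥2|k≥1)/Pr(k≥1) is ≈ 0.85/0.05 = 17
adaptive and ≈ 0.56 Poisson.

What passing on this generator shows: the pipeline's mechanics — pattern
detection, alignment, feature computation, fitting, reranking, scoring —
are correct, and the qualitative orderings (charmatch conditional gap,
more-features-better reranking, burstiness contrast) emerge when the
generating process has the assumed structure. What it does not show:
performance on real PubMed text, whose definitions use richer syntax
(appositives, nested parentheses, non-initial salient letters), whose
tokenization is messier, and whose n-best errors are not independent
across SFs. Benchmark F-scores on real data cannot be inferred from these
numbers.

## Problem sizes and numerical choices

The acceptance script uses 300-document corpora (≈ 3,000 candidate rows)
per seed for the reranking/tree/conditional analyses, 10 seeds for the
ordering check, 50,000 rows for parameter recovery, 10,000 documents for
the repetition contrast and the end-to-end extraction run — sizes at
which the binomial noise on every reported proportion is well below the
effects being measured. All randomness flows from the `--seed` argument
through deterministic sub-seeds; `random.Random` drives text generation
and `numpy.random.default_rng` the numeric simulations. Log-likelihoods
use `logaddexp` for stability; the log1p_freq field is validated to equal
ln(1+freq) within 1e-12; coverage bookkeeping in trees is exact fractions
of the root count.
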