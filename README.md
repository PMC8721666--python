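# abbrevkit

Abbreviation definition identification (ADI) for biomedical text: find
short-form/long-form (SF–LF) pairs such as **HSV** → *herpes simplex virus*
in abstracts and articles, rerank n-best LF candidate lists from external
systems, and run the error-analysis machinery that explains *why* candidate
lists go wrong.

The toolkit is aimed at text-mining practitioners who work with
PubMed-scale literature — the people who build acronym dictionaries for
entity normalization, evaluate span-extraction systems, or want a fast,
rule-based ADI baseline that exploits what neural QA models tend to miss:
the acronym **spelling convention**.

## The model

**Extraction.** Definitions parenthesize either the LF ("long form (SF)")
or the SF ("SF (long form)"). The right edge of the LF is delimited by the
parenthesis; the crux is the left edge. abbrevkit recovers it with the
spelling convention: each SF character maps, in order and
case-insensitively, onto a salient character of the LF, with the first SF
character anchored at the first character of the first LF word. Function
words (*of, the, and, …*) may be skipped, plural *s* may ride on the last
word, and later SF characters may match word-internal positions (AVMs →
*arterioVenous Malformations*). Among all token suffixes of the left
context that satisfy the mapping, the **shortest** wins — extra left words
("Total creatine kinase" for CK) are the dominant error mode of
span-extraction systems.

**Reranking.** Each candidate LF for an SF gets a correctness probability

    Pr(correct) ≈ σ(z),   z = β₀ + β₁·rank + β₂·charmatch + β₃·log(1 + freq)

where *rank* is the candidate's 0-based n-best position, *charmatch* is 1
iff the first characters of SF and candidate LF agree (a one-character
proxy for the spelling convention), and *freq* counts occurrences of
`LF (SF` across a corpus via a suffix array — a pair co-defined in many
documents is almost surely correct. Three nested formulas (rank only;
+charmatch; +log(1+freq)) can be fitted by maximum likelihood
(Newton–Raphson, optional L2 ridge), and twelve preset coefficient vectors
are shipped. β₁ < 0: less is more for rank. β₂, β₃ > 0: more is more for
spelling agreement and cross-document frequency.

**Error analysis.** Pair-level P/R/F1, off-by-one categorization (candidate
differs from gold by exactly one token at an edge), Pr(correct | charmatch)
conditional tables, per-rank correct counts, and a small Gini decision tree
whose nodes report (best label, accuracy, coverage).

**Aggregation.** Cross-document SF dictionaries with one-sense-per-discourse
counting, the two-uppercase SF noise filter, and the repetition statistic
Pr(k≥2 | k≥1) vs Pr(k≥1): real SFs are re-used within documents far more
than a Poisson process predicts, math fragments are not.

**Synthetic data.** A seeded generator produces definition-bearing corpora
(configurable convention-exception rate, distractor modifiers, SF
repetition) and simulated n-best lists with a configurable
correct/off-by-one/otherwise error profile, so every pipeline stage is
testable without downloads.

## Worked example

```python
from abbrevkit import Document, extract_document, preset, score
from abbrevkit.features import FeatureVector

doc = Document(
    "pmid1",
    "Latent herpes simplex virus (HSV) has been demonstrated in vestibular ganglia. "
    "Total creatine kinase (CK) and CK-B activity were measured in healthy controls (HC) T cells.",
)
for m in extract_document(doc):
    print(f"{m.sf}\t{m.lf}\t{m.pattern}")

model = preset(5)  # z = -1.2 - 3.2*rank + 3.5*charmatch
for cm in (1, 0):
    fv = FeatureVector(rank=0, charmatch=cm)
    print(f"rank=0 charmatch={cm}  Pr(correct) = {score(model, fv):.4f}")
```

prints

```
HSV	herpes simplex virus	LF_PAREN_SF
CK	creatine kinase	LF_PAREN_SF
HC	healthy controls	LF_PAREN_SF
rank=0 charmatch=1  Pr(correct) = 0.9089
rank=0 charmatch=0  Pr(correct) = 0.2315
```

Note that the aligner excludes the distractors "Latent" and "Total": they
carry no SF character. The preset model says a top-ranked candidate that
passes charmatch is believable (0.91); one that fails it probably lost its
first word (0.23).

A shell pipeline over the bundled generator:

```bash
abbrev synth --seed 3 --n-docs 200 --out-dir fixtures/
abbrev extract --in fixtures/docs.txt --out pred.tsv
abbrev eval --pred pred.tsv --gold fixtures/gold.tsv --report report.json
abbrev index --in fixtures/docs.txt --out corpus.idx
abbrev featurize --nbest fixtures/nbest.tsv --index corpus.idx --gold fixtures/gold.tsv --out features.tsv
abbrev rerank --features features.tsv --model fit:eq6 --out reranked.tsv
abbrev analyze --features features.tsv --tree rank,charmatch --out tree.txt
```

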