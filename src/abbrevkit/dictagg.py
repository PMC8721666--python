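"""Cross-document aggregation of SF-LF pairs and the repetition statistic.

An SF such as "AI" keeps one sense within a document ("one sense per
discourse") but can expand differently across documents ("artificial
intelligence" vs "absorption index").  Aggregating pairs over a corpus
yields a dictionary mapping each SF to its expansion counts, with the
dominant expansion and its share.

The repetition (adaptation) statistic contrasts Pr(k>=1), the probability
a word appears in a document at all, with Pr(k>=2 | k>=1), the
probability it recurs once present.  Content terms — and short forms in
particular, whose definitions presuppose re-use — recur far more often
than independence (a Poisson process) predicts; math fragments and other
noise do not, which makes the ratio a usable noise filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from abbrevkit.extract import tokenize
from abbrevkit.textio import Document

_WS_RE = re.compile(r"\s+")


def uppercase_filter(sf: str) -> bool:
    """True iff the SF contains at least two uppercase alphabetic characters.

    Unicode uppercase code points count; digits never do.
    """
    return sum(1 for c in sf if c.isalpha() and c.isupper()) >= 2


@dataclass
class DictEntry:
    """Aggregated expansions of one SF across a corpus."""

    sf: str
    counts: dict[str, int]  # normalized LF -> number of defining documents

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def dominant(self) -> str:
        return max(self.counts, key=lambda lf: (self.counts[lf], lf))

    @property
    def dominant_share(self) -> float:
        return self.counts[self.dominant] / self.total


def _norm_lf(lf: str, fold_case: bool) -> str:
    lf = _WS_RE.sub(" ", lf.strip())
    return lf.lower() if fold_case else lf


def aggregate(
    pairs: Iterable, fold_case: bool = True, sf_filter: bool = False
) -> list[DictEntry]:
    """Group (doc_id, sf, lf) pairs into dictionary entries.

    Each (sf, lf) is counted once per defining document (one sense per
    discourse accounting).  LFs are whitespace-collapsed and, by default,
    case-folded; ``fold_case=False`` keeps raw case.  ``sf_filter``
    restricts to SFs passing :func:`uppercase_filter`.
    """
    seen: set[tuple[str, str, str]] = set()
    counts: dict[str, dict[str, int]] = {}
    for p in pairs:
        if sf_filter and not uppercase_filter(p.sf):
            continue
        lf = _norm_lf(p.lf, fold_case)
        key = (p.doc_id, p.sf, lf)
        if key in seen:
            continue
        seen.add(key)
        counts.setdefault(p.sf, {}).setdefault(lf, 0)
        counts[p.sf][lf] += 1
    return [DictEntry(sf, lf_counts) for sf, lf_counts in sorted(counts.items())]


@dataclass
class RepetitionStats:
    """Document-frequency repetition statistics for one word."""

    word: str
    n_docs: int
    n_ge1: int  # documents with >=1 occurrence
    n_ge2: int  # documents with >=2 occurrences

    @property
    def pr_ge1(self) -> float:
        return self.n_ge1 / self.n_docs

    @property
    def pr_ge2_given_ge1(self) -> Optional[float]:
        return self.n_ge2 / self.n_ge1 if self.n_ge1 else None


def repetition_stats(word: str, docs: Sequence[Document]) -> RepetitionStats:
    """Count per-document occurrences of ``word`` (whole-token, case-sensitive)."""
    if not word:
        raise ValueError("word must be non-empty")
    if not docs:
        raise ValueError("need at least one document")
    n_ge1 = n_ge2 = 0
    for doc in docs:
        count = sum(1 for tok, _, _ in tokenize(doc.text) if _strip(tok) == word)
        if count >= 1:
            n_ge1 += 1
        if count >= 2:
            n_ge2 += 1
    return RepetitionStats(word, len(docs), n_ge1, n_ge2)


def _strip(token: str) -> str:
    start, end = 0, len(token)
    while start < end and not token[start].isalnum():
        start += 1
    while end > start and not token[end - 1].isalnum():
        end -= 1
    return token[start:end]


def adaptation_score(stats: RepetitionStats) -> Optional[float]:
    """Pr(k>=2 | k>=1) / Pr(k>=1): burstiness relative to presence.

    Large for SF-like content terms; near 1 for Poisson-like fragments at
    small rates.  Undefined (None) when the word is absent everywhere.
    """
    if stats.n_ge1 == 0 or stats.pr_ge1 == 0:
        return None
    return stats.pr_ge2_given_ge1 / stats.pr_ge1
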