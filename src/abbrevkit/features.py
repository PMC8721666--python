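"""Candidate features: charmatch, corpus frequency via a suffix array, rank.

``charmatch`` is the one-character proxy for the acronym spelling
convention: does the first character of the SF equal the first character
of the candidate LF (case-insensitive)?  It is deliberately cruder than
full salient-letter alignment but targets the dominant failure mode, the
left edge of the LF.

``freq`` counts exact occurrences of ``LF + " (" + SF`` across a corpus:
a pair that is co-defined in many documents is very likely correct, and an
off-by-one variant ("Latent herpes simplex virus (HSV") is rare.  Counting
is served by a suffix array over the concatenated corpus, giving
O(|pattern| * log corpus) queries.
"""

from __future__ import annotations

import math
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from abbrevkit.textio import Document

#: Documents are concatenated with this separator; queries never cross it.
SEPARATOR = "\x00"

_WS_RE = re.compile(r"\s+")


def charmatch(sf: str, lf: str) -> int:
    """1 iff the first characters of SF and LF agree, case-insensitively.

    The comparison is on raw first characters; no skipping.  Exceptions
    such as "chloride current (ICl)" therefore score 0 even though the
    pair is correct — the feature is a heuristic, not a validator.
    """
    if not sf or not lf:
        raise ValueError("sf and lf must be non-empty")
    return int(sf[0].lower() == lf[0].lower())


def _normalize_ws(s: str) -> str:
    return _WS_RE.sub(" ", s.strip())


@dataclass
class SuffixIndex:
    """Suffix array over a concatenated document collection.

    Suffix start positions are sorted lexicographically (code-point
    order, identical to Python string comparison) by prefix doubling, so
    construction is O(n log^2 n) time and O(n) memory.  The separator
    character sorts below all document text, and since patterns may not
    contain it, no match can cross a document boundary.
    """

    corpus: str
    suffixes: list[int]
    doc_boundaries: list[int]

    def count(self, pattern: str) -> int:
        return count(self, pattern)


def build_index(docs: Sequence[Document]) -> SuffixIndex:
    """Build a suffix array over the documents (deterministic)."""
    for doc in docs:
        if SEPARATOR in doc.text:
            raise ValueError(
                f"document {doc.doc_id!r} contains the reserved separator character"
            )
    corpus = SEPARATOR.join(doc.text for doc in docs)
    boundaries = []
    offset = 0
    for doc in docs:
        boundaries.append(offset)
        offset += len(doc.text) + 1
    return SuffixIndex(
        corpus=corpus, suffixes=_suffix_array(corpus), doc_boundaries=boundaries
    )


def _suffix_array(s: str) -> list[int]:
    """Suffix start positions in lexicographic order (prefix doubling)."""
    n = len(s)
    if n == 0:
        return []
    rank = np.array([ord(c) for c in s], dtype=np.int64)
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order[0]] = 0
        changed = (rank[order[1:]] != rank[order[:-1]]) | (
            second[order[1:]] != second[order[:-1]]
        )
        new_rank[order[1:]] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.tolist()
        k *= 2


class _SuffixKey:
    """Adapter exposing suffix i as corpus[i:i+len(pattern)] for bisection."""

    __slots__ = ("corpus", "plen")

    def __init__(self, corpus: str, plen: int):
        self.corpus = corpus
        self.plen = plen

    def __call__(self, i: int) -> str:
        return self.corpus[i:i + self.plen]


def count(index: SuffixIndex, pattern: str) -> int:
    """Exact substring-occurrence count of ``pattern`` in the corpus.

    Equals the naive per-document scan count; occurrences may overlap.
    """
    if not pattern:
        raise ValueError("pattern must be non-empty")
    if SEPARATOR in pattern:
        raise ValueError("pattern may not contain the document separator")
    key = _SuffixKey(index.corpus, len(pattern))
    lo = bisect_left(index.suffixes, pattern, key=key)
    hi = bisect_right(index.suffixes, pattern, key=key)
    return hi - lo


def freq_feature(index: SuffixIndex, lf: str, sf: str) -> int:
    """Corpus count of 'LF (SF' — how often the pair is co-defined.

    Internal whitespace in the LF is collapsed to single spaces before
    querying; one space precedes the opening parenthesis.
    """
    if not lf or not sf:
        raise ValueError("lf and sf must be non-empty")
    return count(index, _normalize_ws(lf) + " (" + sf)


@dataclass
class FeatureVector:
    """Features for one candidate: rank, charmatch, freq and agreement flags."""

    rank: int
    charmatch: int
    freq: int = 0
    log1p_freq: float = 0.0
    agreement: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.log1p_freq - math.log1p(self.freq)) > 1e-12:
            raise ValueError("log1p_freq must equal ln(1 + freq)")


def _ws_free(s: str) -> str:
    return _WS_RE.sub("", s)


def featurize(
    candidate,
    index: Optional[SuffixIndex] = None,
    top_outputs: Optional[Mapping[str, str]] = None,
) -> FeatureVector:
    """Assemble the feature vector for one candidate.

    ``top_outputs`` maps a system label to that system's top LF; the
    agreement flag is 1 iff the candidate equals it ignoring whitespace.
    ``freq`` is 0 when no index is supplied.
    """
    freq = 0
    if index is not None:
        freq = freq_feature(index, candidate.lf_candidate, candidate.sf)
    agreement = {}
    if top_outputs:
        cand_key = _ws_free(candidate.lf_candidate)
        for system, top_lf in top_outputs.items():
            agreement[system] = int(cand_key == _ws_free(top_lf))
    return FeatureVector(
        rank=candidate.rank,
        charmatch=charmatch(candidate.sf, candidate.lf_candidate),
        freq=freq,
        log1p_freq=math.log1p(freq),
        agreement=agreement,
    )


def naive_count(docs: Sequence[Document], pattern: str) -> int:
    """Brute-force per-document overlapping substring count (test oracle)."""
    if not pattern:
        raise ValueError("pattern must be non-empty")
    total = 0
    for doc in docs:
        start = 0
        while True:
            pos = doc.text.find(pattern, start)
            if pos < 0:
                break
            total += 1
            start = pos + 1
    return total
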