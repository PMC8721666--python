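"""Definition-pattern detection and spelling-convention SF-LF alignment.

Acronym definitions parenthesize either the short form ("long form (SF)")
or the long form ("SF (long form)").  The right edge of the LF is given by
the parenthesis; the crux is the left edge.  That left edge is recovered
with the acronym spelling convention: every character of the SF refers to
a "salient" character of the LF, in order, with the first SF character
anchored at the first character of the first LF word.  Function words
("of", "the", ...) may be skipped without consuming an SF character, and a
plural "s" may ride on the end of the last LF word.

The aligner returns the SHORTEST token suffix of the left context that
satisfies the mapping: off-by-one analysis of n-best outputs shows extra
left words ("Total creatine kinase" for CK) are the dominant error mode,
so shorter is safer.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Optional, Sequence

from abbrevkit.textio import Document

logger = logging.getLogger(__name__)

#: Function words that may be skipped inside an LF without consuming an SF
#: character ("Alpha of the Beta (AB)").
FUNCTION_WORDS = frozenset(
    {"of", "the", "and", "for", "a", "an", "in", "to"}
)

#: Short-form gate: small stop list of function words that are never SFs.
SF_STOPLIST = FUNCTION_WORDS | frozenset({"is", "was", "it", "at", "on", "by", "or", "as"})

MAX_SF_LEN = 10
MIN_SF_LEN = 2

LF_PAREN_SF = "LF_PAREN_SF"
SF_PAREN_LF = "SF_PAREN_LF"

_TOKEN_RE = re.compile(r"\S+")
_SENT_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z])")


@dataclass(frozen=True)
class DefinitionMention:
    """A detected definition: SF and LF with spans into the context sentence."""

    doc_id: str
    sentence: str
    sf: str
    sf_span: tuple[int, int]
    lf: str
    lf_span: tuple[int, int]
    pattern: str  # LF_PAREN_SF or SF_PAREN_LF

    def __post_init__(self) -> None:
        for span, string in ((self.sf_span, self.sf), (self.lf_span, self.lf)):
            if self.sentence[span[0]:span[1]] != string:
                raise ValueError(f"span {span} does not hold {string!r} in sentence")
        if not (self.sf_span[1] <= self.lf_span[0] or self.lf_span[1] <= self.sf_span[0]):
            raise ValueError("sf and lf spans overlap")


@dataclass(frozen=True)
class Candidate:
    """One LF hypothesis for an SF, with its n-best rank and optional gold label."""

    doc_id: str
    sf: str
    lf_candidate: str
    rank: int
    source: str = "rule"  # rule | external
    gold: Optional[int] = None


def split_sentences(text: str) -> list[tuple[int, int]]:
    """Sentence spans: boundaries at [.!?] + whitespace + uppercase.

    Deliberately simple; abbreviation-aware splitting is not attempted.
    """
    spans = []
    start = 0
    for m in _SENT_BOUNDARY_RE.finditer(text):
        spans.append((start, m.start()))
        start = m.end()
    if start < len(text):
        spans.append((start, len(text)))
    return spans


def tokenize(text: str) -> list[tuple[str, int, int]]:
    """Whitespace tokenization with character spans (token, start, end)."""
    return [(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


def find_parentheticals(text: str) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """Depth-1 balanced round-bracket groups with their same-sentence left context.

    Returns (inner_span, left_context_span) pairs, offsets into ``text``.
    Nested groups are ignored; unbalanced brackets yield no group.
    """
    results = []
    for sent_start, sent_end in split_sentences(text):
        depth = 0
        open_pos = -1
        for i in range(sent_start, sent_end):
            ch = text[i]
            if ch == "(":
                depth += 1
                if depth == 1:
                    open_pos = i
            elif ch == ")":
                if depth == 0:
                    logger.debug("unbalanced ')' at offset %d", i)
                    continue
                depth -= 1
                if depth == 0:
                    results.append(((open_pos + 1, i), (sent_start, open_pos)))
        if depth > 0:
            logger.debug("unbalanced '(' in sentence at %d-%d", sent_start, sent_end)
    return results


def is_valid_sf(token: str) -> bool:
    """Gate for short-form candidates.

    Length 2-10, at least one letter, alphanumeric first character, not a
    pure number, not a stop-listed function word.
    """
    if not (MIN_SF_LEN <= len(token) <= MAX_SF_LEN):
        return False
    if not token[0].isalnum():
        return False
    if not any(c.isalpha() for c in token):
        return False
    if token.isdigit():
        return False
    # the stop list targets function words as written; an all-caps token
    # ("AN", "IN") is an acronym, not a function word
    if token.lower() in SF_STOPLIST and not token.isupper():
        return False
    return True


def _sf_chars(sf: str) -> list[str]:
    return [c.lower() for c in sf if c.isalnum()]


def _clean(token: str) -> str:
    return "".join(c for c in token if c.isalnum()).lower()


def _window(sf: str) -> int:
    return min(len(sf) + 5, 2 * len(sf))


def _max_prefix_subseq(chars: Sequence[str], token: str, token_from: int = 0) -> int:
    """Longest prefix of ``chars`` that is a subsequence of token[token_from:]."""
    j = token_from
    count = 0
    for c in chars:
        pos = token.find(c, j)
        if pos < 0:
            break
        j = pos + 1
        count += 1
    return count


def _match(chars: Sequence[str], tokens: Sequence[str]) -> bool:
    """Can all SF characters map onto the token sequence under the convention?

    The first character anchors at tokens[0][0]; later characters map to
    word-initial or word-internal positions in order; function words may be
    skipped; every non-function token (and the last token, always) must
    receive at least one character.
    """
    cleaned = [_clean(t) for t in tokens]
    if any(not t for t in cleaned):
        return False
    if cleaned[0][0] != chars[0]:
        return False

    n_tok = len(cleaned)

    def rec(i: int, t: int) -> bool:
        if t == n_tok:
            return i == len(chars)
        token = cleaned[t]
        if t == 0:
            # first char already anchored; remainder maps into token[1:]
            m = 1 + _max_prefix_subseq(chars[1:], token, 1)
            lo = 1
            i0 = i  # == 0
        else:
            m = _max_prefix_subseq(chars[i:], token)
            lo = 0 if (token in FUNCTION_WORDS and t != n_tok - 1) else 1
            i0 = i
        if m < lo:
            return False
        # prefer consuming more characters here (tends to terminate faster)
        for j in range(m, lo - 1, -1):
            if rec(i0 + j, t + 1):
                return True
        return False

    return rec(0, 0)


def align_sf_lf(sf: str, left_tokens: Sequence[str]) -> Optional[list[str]]:
    """Shortest token suffix of the left context satisfying the spelling convention.

    Returns the LF as a list of tokens, or None when no suffix maps.  The
    search is limited to a window of min(|SF|+5, 2|SF|) tokens left of the
    parenthesis.
    """
    if not sf:
        raise ValueError("sf must be non-empty")
    chars = _sf_chars(sf)
    if not chars:
        return None
    toks = list(left_tokens)[-_window(sf):]
    for k in range(1, len(toks) + 1):
        suffix = toks[-k:]
        if _match(chars, suffix):
            return suffix
    return None


def enumerate_candidates(
    sf: str, left_tokens: Sequence[str], n: int, doc_id: str = ""
) -> list[Candidate]:
    """Rule-based n-best LF candidates for one SF.

    Rank 0 is the aligned LF; later ranks perturb the left edge by +1, -1,
    +2, -2, ... words.  When alignment fails, candidates are the k-token
    suffixes for k = |SF|, |SF|+1, |SF|-1, ...
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    toks = list(left_tokens)[-_window(sf):]
    aligned = align_sf_lf(sf, toks)
    k0 = len(aligned) if aligned is not None else len(_sf_chars(sf))

    schedule = [k0]
    for d in range(1, len(toks) + 1):
        schedule.extend([k0 + d, k0 - d])

    out: list[Candidate] = []
    seen: set[str] = set()
    for k in schedule:
        if not (1 <= k <= len(toks)):
            continue
        lf = " ".join(toks[-k:])
        if lf in seen:
            continue
        seen.add(lf)
        out.append(Candidate(doc_id, sf, lf, rank=len(out), source="rule"))
        if len(out) == n:
            break
    return out


def _strip_token(token: str) -> str:
    """Strip surrounding punctuation from a token (keeps interior hyphens)."""
    start, end = 0, len(token)
    while start < end and not token[start].isalnum():
        start += 1
    while end > start and not token[end - 1].isalnum():
        end -= 1
    return token[start:end]


def extract_document(doc: Document) -> list[DefinitionMention]:
    """Detect SF-LF definitions in one document, in text order.

    For each depth-1 parenthetical: if the inner text is a valid SF, align
    the left context as its LF ("long form (SF)"); otherwise, if the token
    left of the parenthesis is a valid SF and the inner text satisfies the
    convention as its LF, emit the "SF (long form)" pattern.  Single pass;
    no document-length cap.
    """
    mentions: list[DefinitionMention] = []
    text = doc.text
    sent_spans = split_sentences(text)

    for (in_start, in_end), (ctx_start, ctx_end) in find_parentheticals(text):
        sent_start, sent_end = ctx_start, max(in_end + 1, ctx_end)
        for s, e in sent_spans:
            if s <= in_start < e:
                sent_start, sent_end = s, e
                break
        sentence = text[sent_start:sent_end]
        inner_raw = text[in_start:in_end].strip()
        inner_start = in_start + text[in_start:in_end].index(inner_raw) if inner_raw else in_start
        left_tokens = tokenize(text[ctx_start:ctx_end])

        if is_valid_sf(inner_raw) and " " not in inner_raw:
            aligned = align_sf_lf(inner_raw, [t for t, _, _ in left_tokens])
            if aligned is None:
                continue
            k = len(aligned)
            lf_tok = left_tokens[-k:]
            lf_start = ctx_start + lf_tok[0][1]
            lf_end = ctx_start + lf_tok[-1][2]
            mentions.append(
                DefinitionMention(
                    doc_id=doc.doc_id,
                    sentence=sentence,
                    sf=inner_raw,
                    sf_span=(inner_start - sent_start, inner_start - sent_start + len(inner_raw)),
                    lf=text[lf_start:lf_end],
                    lf_span=(lf_start - sent_start, lf_end - sent_start),
                    pattern=LF_PAREN_SF,
                )
            )
        elif left_tokens:
            sf_token, tok_s, tok_e = left_tokens[-1]
            sf = _strip_token(sf_token)
            if not is_valid_sf(sf):
                continue
            inner_tokens = tokenize(inner_raw)
            if len(inner_tokens) < 2:
                continue
            aligned = align_sf_lf(sf, [t for t, _, _ in inner_tokens])
            if aligned is None or len(aligned) != len(inner_tokens):
                continue
            sf_abs = ctx_start + tok_s + sf_token.index(sf)
            mentions.append(
                DefinitionMention(
                    doc_id=doc.doc_id,
                    sentence=sentence,
                    sf=sf,
                    sf_span=(sf_abs - sent_start, sf_abs - sent_start + len(sf)),
                    lf=inner_raw,
                    lf_span=(inner_start - sent_start, inner_start - sent_start + len(inner_raw)),
                    pattern=SF_PAREN_LF,
                )
            )
    return mentions  # find_parentheticals already yields text order


def extract_pairs(docs: Sequence[Document]):
    """Extract (doc_id, sf, lf) pairs from a document collection, in order."""
    from abbrevkit.textio import ExtractedPair

    out = []
    for doc in docs:
        for m in extract_document(doc):
            out.append(ExtractedPair(doc.doc_id, m.sf, m.lf))
    return out
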