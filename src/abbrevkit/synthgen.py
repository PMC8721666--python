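"""Synthetic definition-bearing corpora and simulated n-best candidate lists.

The generator emulates the statistical structure the analysis assumes:

* first-mention definitions "long form (SF)" where the SF is built from
  the initials of the LF words (so charmatch = 1 by construction), with a
  small rate of spelling-convention exceptions whose SF starts with a
  different letter (like "chloride current (ICl)");
* optional distractor modifiers immediately before the LF, the raw
  material for off-by-one errors;
* repeated subsequent mentions of the SF later in the document (a
  definition presupposes re-use);
* n-best candidate lists with a configurable error profile
  (correct-at-rank-0 / off-by-one / otherwise), defaulting to the
  0.83/0.11/0.06 profile observed for BERT-SQuAD-style systems;
* an "adaptive vs. Poisson" corpus pair for the repetition statistic:
  content terms recur within documents far more than independence
  predicts, fragments do not.

Everything is driven by one seeded generator; identical seeds reproduce
identical corpora byte-for-byte.  Filler text comes from a fixed word
list below — no external corpus.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional, Sequence

from abbrevkit.extract import FUNCTION_WORDS, Candidate
from abbrevkit.textio import Document, GoldPair

#: Fixed filler vocabulary (lowercase, alphabetic, no function words).
WORD_LIST = [
    "activation", "baseline", "cellular", "membrane", "protein", "kinase",
    "receptor", "binding", "gradient", "signal", "pathway", "nuclear",
    "factor", "growth", "tissue", "sample", "plasma", "serum", "analysis",
    "method", "patient", "clinical", "chronic", "acute", "response",
    "immune", "vector", "genome", "sequence", "variant",
    "mutation", "expression", "transcript", "enzyme", "substrate", "ligand",
    "channel", "current", "voltage", "neural", "cortical", "synaptic",
    "vascular", "cardiac", "hepatic", "renal", "pulmonary", "dermal",
    "oxidative", "metabolic", "glucose", "insulin", "lipid", "hormone",
    "antibody", "antigen", "epitope", "domain", "complex", "assembly",
    "dynamic", "kinetic", "thermal", "optical", "density", "fraction",
    "molecular", "weight", "buffer", "culture", "medium", "colony",
    "bacterial", "viral", "fungal", "parasite", "host", "strain",
    "diagnosis", "therapy", "treatment", "outcome", "survival", "relapse",
    "tumor", "lesion", "biopsy", "imaging", "resonance", "ultrasound",
    "frequency", "amplitude", "waveform", "threshold", "latency",
    "cohort", "control", "placebo", "dosage", "infusion", "injection",
    "oral", "topical", "systemic", "regional", "global", "partial",
    "quantitative", "relative", "absolute", "nominal", "ordinal", "scalar",
    "juvenile", "neonatal", "maternal", "western", "eastern", "upstream",
    "downstream", "flanking", "terminal", "residue", "peptide", "fragment",
    "yield", "ratio", "index", "score", "model", "estimate", "error",
    "noise", "drift", "offset", "phase", "cycle", "period", "interval",
    "window", "region", "zone", "layer", "surface", "matrix", "fiber",
    "muscle", "skeletal", "cranial", "spinal", "humoral", "gastric",
    "xenon", "krypton", "quartz", "zinc", "yeast", "quinone", "xylose",
]


def _dedup(words: Sequence[str]) -> list[str]:
    seen = set()
    out = []
    for w in words:
        if w not in seen:
            seen.add(w)
            out.append(w)
    return out


WORD_LIST = _dedup(WORD_LIST)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    ``nbest_profile`` is (p_correct_at_0, p_off_by_one, p_otherwise) and
    must sum to 1; the default mirrors the observed BERT-SQuAD error
    profile on biomedical benchmarks (~83% correct at the top rank, ~11%
    off by one word).
    """

    seed: int = 0
    n_docs: int = 100
    pairs_per_doc: float = 2.0
    vocab_size: int = 50
    min_phrase_words: int = 2
    max_phrase_words: int = 5
    exception_rate: float = 0.02
    modifier_rate: float = 0.3
    repeat_rate: float = 0.7
    nbest_profile: tuple[float, float, float] = (0.83, 0.11, 0.06)
    n_best: int = 5
    agreement_accuracy: float = 0.95
    # adaptive/Poisson corpus knobs
    n_planted: int = 20
    plant_doc_rate: float = 0.05
    repeat_prob: float = 0.85

    def __post_init__(self) -> None:
        for name in ("exception_rate", "modifier_rate", "repeat_rate",
                     "plant_doc_rate", "repeat_prob", "agreement_accuracy"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.nbest_profile) - 1.0) > 1e-9:
            raise ValueError("nbest_profile must sum to 1")


def _build_vocabulary(cfg: SynthConfig, rng: random.Random) -> list[tuple[str, ...]]:
    """LF phrases of 2-5 words with pairwise-distinct word initials.

    Distinct initials make the spelling-convention alignment unambiguous:
    the shortest satisfying suffix is exactly the generated LF.
    """
    vocab: list[tuple[str, ...]] = []
    seen: set[tuple[str, ...]] = set()
    attempts = 0
    while len(vocab) < cfg.vocab_size and attempts < 100 * cfg.vocab_size:
        attempts += 1
        k = rng.randint(cfg.min_phrase_words, cfg.max_phrase_words)
        words = tuple(rng.sample(WORD_LIST, k))
        initials = [w[0] for w in words]
        if len(set(initials)) != len(initials) or "t" in initials[:1]:
            # 't' first word would let "The" anchor the alignment
            continue
        if words in seen:
            continue
        seen.add(words)
        vocab.append(words)
    if not vocab:
        raise ValueError("could not build a vocabulary (empty or exhausted word list)")
    return vocab


def _sf_for(phrase: Sequence[str], exception: bool, rng: random.Random) -> str:
    sf = "".join(w[0] for w in phrase).upper()
    if exception:
        alphabet = [c for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ" if c != sf[0]]
        sf = rng.choice(alphabet) + sf  # extra leading letter, like ICl
    return sf


def _pick_modifier(phrase: Sequence[str], rng: random.Random) -> str:
    """A distractor word whose initial differs from every phrase initial."""
    initials = {w[0] for w in phrase}
    for _ in range(100):
        w = rng.choice(WORD_LIST)
        if w[0] not in initials and w not in phrase:
            return w
    return "extra"


def _filler_sentence(rng: random.Random, mention: Optional[str] = None) -> str:
    words = [rng.choice(WORD_LIST) for _ in range(rng.randint(4, 8))]
    if mention is not None:
        words.insert(rng.randrange(len(words) + 1), mention)
    return "The " + " ".join(words) + "."


def generate_corpus(cfg: SynthConfig) -> tuple[list[Document], list[GoldPair]]:
    """Generate definition-bearing documents plus their gold SF-LF pairs.

    Each document holds one or more definitions "LF (SF)", optional
    distractor modifiers before the LF, filler sentences, and
    geometric-distributed repeat mentions of the SF.
    """
    rng = random.Random(cfg.seed)
    vocab = _build_vocabulary(cfg, rng)
    docs: list[Document] = []
    gold: list[GoldPair] = []

    for i in range(cfg.n_docs):
        doc_id = f"d{i + 1}"
        n_pairs = max(1, _poisson(cfg.pairs_per_doc, rng))
        n_pairs = min(n_pairs, len(vocab))
        phrases = rng.sample(vocab, n_pairs)
        sentences: list[str] = [_filler_sentence(rng)]
        used_sfs: set[str] = set()
        for phrase in phrases:
            exception = rng.random() < cfg.exception_rate
            sf = _sf_for(phrase, exception, rng)
            lf = " ".join(phrase)
            if sf in used_sfs:  # one sense per discourse
                continue
            used_sfs.add(sf)
            lead = "The "
            if rng.random() < cfg.modifier_rate:
                lead += _pick_modifier(phrase, rng) + " "
            trail = " ".join(rng.choice(WORD_LIST) for _ in range(rng.randint(2, 5)))
            sentences.append(f"{lead}{lf} ({sf}) was linked to {trail}.")
            gold.append(GoldPair(doc_id, sf, lf))
            # repeated subsequent mentions: a definition presupposes re-use
            while rng.random() < cfg.repeat_rate:
                sentences.append(_filler_sentence(rng, mention=sf))
                if len(sentences) > 60:
                    break
        sentences.append(_filler_sentence(rng))
        docs.append(Document(doc_id, " ".join(sentences)))
    return docs, gold


def _poisson(lam: float, rng: random.Random) -> int:
    # Knuth's method; lam is small here
    import math

    l_exp = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= l_exp:
            return k
        k += 1


def _perturbations(lf_tokens: Sequence[str], rng: random.Random) -> list[str]:
    """Left-edge variants of an LF, nearest first: prepend 1, drop 1, prepend 2, ...

    Unlike the in-text distractor modifiers, prepended words here are
    unconstrained, so a perturbation occasionally passes charmatch — the
    feature is a good but imperfect discriminator, as on real n-best
    output.
    """
    out: list[str] = []
    prefix: list[str] = []
    for d in range(1, 5):
        w = rng.choice([w for w in WORD_LIST if w not in lf_tokens])
        prefix.insert(0, w)
        out.append(" ".join(prefix + list(lf_tokens)))
        if d < len(lf_tokens):
            out.append(" ".join(lf_tokens[d:]))
    return _dedup(out)


def _unrelated_span(lf_tokens: Sequence[str], sf: str, rng: random.Random) -> str:
    for _ in range(100):
        words = [rng.choice(WORD_LIST) for _ in range(rng.randint(2, 3))]
        if tuple(words) != tuple(lf_tokens):
            return " ".join(words)
    return "unrelated span"


def generate_nbest(
    gold_pairs: Sequence[GoldPair], cfg: SynthConfig
) -> list[Candidate]:
    """Simulated n-best candidate lists with gold labels.

    Per pair: with p_correct the gold LF sits at rank 0; with
    p_off_by_one a one-word left-edge perturbation sits at rank 0 and the
    gold LF at a uniform lower rank; with p_otherwise an unrelated span
    sits at rank 0 and the gold LF is absent.  Remaining ranks are filled
    with further left-edge perturbations; exactly ``n_best`` candidates
    per SF.
    """
    rng = random.Random(cfg.seed * 1_000_003 + 17)
    p_correct, p_off, p_other = cfg.nbest_profile
    out: list[Candidate] = []
    for pair in gold_pairs:
        lf_tokens = pair.lf.split()
        if not lf_tokens:
            continue
        perturbs = [p for p in _perturbations(lf_tokens, rng) if p != pair.lf]
        u = rng.random()
        slots: list[tuple[str, int]] = []  # (lf_candidate, gold)
        if u < p_correct:
            slots.append((pair.lf, 1))
            fillers = perturbs
        elif u < p_correct + p_off:
            gold_rank = rng.randint(1, cfg.n_best - 1)
            off = perturbs[0] if rng.random() < 0.5 or len(lf_tokens) < 2 else perturbs[1]
            slots.append((off, 0))
            fillers = [p for p in perturbs if p != off]
            while len(slots) < gold_rank:
                slots.append((fillers.pop(0), 0))
            slots.append((pair.lf, 1))
        else:
            slots.append((_unrelated_span(lf_tokens, pair.sf, rng), 0))
            fillers = perturbs
        for p in fillers:
            if len(slots) >= cfg.n_best:
                break
            if p not in [s for s, _ in slots]:
                slots.append((p, 0))
        while len(slots) < cfg.n_best:  # degenerate LFs with few variants
            slots.append((_unrelated_span(lf_tokens, pair.sf, rng), 0))
        for rank, (lf_cand, is_gold) in enumerate(slots[: cfg.n_best]):
            out.append(
                Candidate(pair.doc_id, pair.sf, lf_cand, rank, source="external", gold=is_gold)
            )
    return out


def generate_system_outputs(
    gold_pairs: Sequence[GoldPair], cfg: SynthConfig, accuracy: Optional[float] = None
) -> dict[tuple[str, str], str]:
    """Top outputs of a simulated reference system (for agreement features).

    With probability ``accuracy`` the system's top LF is the gold LF;
    otherwise a one-word left-edge perturbation.
    """
    acc = cfg.agreement_accuracy if accuracy is None else accuracy
    rng = random.Random(cfg.seed * 2_000_003 + 29)
    out: dict[tuple[str, str], str] = {}
    for pair in gold_pairs:
        if rng.random() < acc:
            out[(pair.doc_id, pair.sf)] = pair.lf
        else:
            out[(pair.doc_id, pair.sf)] = _perturbations(pair.lf.split(), rng)[0]
    return out


def planted_terms(cfg: SynthConfig) -> list[str]:
    """The deterministic list of terms planted by generate_adaptive_corpus."""
    return [f"PT{i + 1}X" for i in range(cfg.n_planted)]


def generate_adaptive_corpus(cfg: SynthConfig, mode: str = "adaptive") -> list[Document]:
    """Documents exhibiting adaptive (bursty) or Poisson term repetition.

    ``adaptive``: each planted term appears in a document with probability
    ``plant_doc_rate``; once present, each further mention follows with
    probability ``repeat_prob`` (first mentions are rare, recurrence is
    probable).  ``poisson``: independent Poisson counts with the matched
    marginal rate, the null model for fragments.
    """
    if mode not in ("adaptive", "poisson"):
        raise ValueError(f"mode must be 'adaptive' or 'poisson', got {mode!r}")
    rng = random.Random(cfg.seed * 3_000_017 + 43)
    terms = planted_terms(cfg)
    mean_count_present = 1.0 / (1.0 - cfg.repeat_prob) if cfg.repeat_prob < 1 else 20.0
    lam = cfg.plant_doc_rate * mean_count_present

    docs = []
    for i in range(cfg.n_docs):
        sentences = [_filler_sentence(rng) for _ in range(3)]
        for term in terms:
            if mode == "adaptive":
                if rng.random() >= cfg.plant_doc_rate:
                    continue
                count = 1
                while rng.random() < cfg.repeat_prob and count < 50:
                    count += 1
            else:
                count = _poisson(lam, rng)
                if count == 0:
                    continue
            for _ in range(count):
                sentences.append(_filler_sentence(rng, mention=term))
        rng.shuffle(sentences)
        docs.append(Document(f"d{i + 1}", " ".join(sentences)))
    return docs
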