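import pandas as pd
import pytest

from abbrevkit.features import build_index, featurize
from abbrevkit.synthgen import (
    SynthConfig,
    generate_corpus,
    generate_nbest,
    generate_system_outputs,
)


@pytest.fixture(scope="session")
def synth_bundle():
    """One mid-sized synthetic study: corpus, gold, index, n-best feature table."""
    cfg = SynthConfig(seed=7, n_docs=300, exception_rate=0.02)
    docs, gold = generate_corpus(cfg)
    index = build_index(docs)
    cands = generate_nbest(gold, cfg)
    tops = generate_system_outputs(gold, cfg)
    rows = []
    for c in cands:
        fv = featurize(c, index=index, top_outputs={"ref": tops[(c.doc_id, c.sf)]})
        rows.append(
            (c.doc_id, c.sf, c.lf_candidate, fv.rank, fv.charmatch, fv.freq,
             fv.log1p_freq, fv.agreement["ref"], c.gold)
        )
    table = pd.DataFrame(
        rows,
        columns=["doc_id", "sf", "lf_candidate", "rank", "charmatch", "freq",
                 "log1p_freq", "agreement", "gold"],
    )
    return {"cfg": cfg, "docs": docs, "gold": gold, "index": index,
            "candidates": cands, "table": table}
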