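"""Embedding-branch association analysis (SC-WEAT).

Reads the synthetic corpora written by 01_simulate_inputs.py, computes
per-target association scores and the classic SC-WEAT effect per corpus, then
the pooled standardized-regression estimate across corpora. Writes
results/scweat_associations.csv (one row per target × corpus) and
results/scweat_effects.csv (per-corpus d plus the pooled slope, with SE/CI/p),
which the meta-analysis script consumes.
"""
import importlib
from pathlib import Path

import pandas as pd

from stereolang.embeddings import load_embeddings
from stereolang.lexicons import load_lexicon, make_contrast
from stereolang.scweat import (association_score, pooled_regression,
                               scweat_effect, similarity_table)

sim = importlib.import_module("01_simulate_inputs")
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    inputs = RESULTS / "inputs"
    targets = load_lexicon(inputs / "targets.csv", name="targets")
    pair = make_contrast(load_lexicon(inputs / "attributes_high.csv"),
                         load_lexicon(inputs / "attributes_low.csv"),
                         label="competence")

    assoc_rows, effect_rows, tables = [], [], []
    for i in range(len(sim.EMBEDDING_SPECS)):
        model = load_embeddings(inputs / f"embeddings_corpus{i}.glove.txt",
                                model_id=f"corpus{i}")
        records = [association_score(model, t, pair, dictionary_id="synthA")
                   for t in targets.words]
        assoc_rows += [vars(r) for r in records]
        d = scweat_effect(records, source={"method": "scweat", "model": model.id})
        effect_rows.append({"unit": model.id, "kind": "classic_d",
                            "estimate": d.estimate, "se": d.se,
                            "ci_low": d.ci_low, "ci_high": d.ci_high,
                            "p": d.p, "n_obs": d.n_obs})
        tables.append(similarity_table(model, targets, pair, "synthA"))
        print(f"{model.id}: classic SC-WEAT d = {d.estimate:.3f} "
              f"(n = {d.n_obs} targets)")

    pooled = pooled_regression(pd.concat(tables, ignore_index=True))
    effect_rows.append({"unit": "pooled", "kind": "pooled_slope",
                        "estimate": pooled.estimate, "se": pooled.se,
                        "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
                        "p": pooled.p, "n_obs": pooled.n_obs})
    print(f"pooled standardized slope (Cohen's d scale) = "
          f"{pooled.estimate:.3f}, SE {pooled.se:.3f}, "
          f"95% CI [{pooled.ci_low:.3f}, {pooled.ci_high:.3f}], p = {pooled.p:.2g}")

    pd.DataFrame(assoc_rows).to_csv(RESULTS / "scweat_associations.csv",
                                    index=False)
    pd.DataFrame(effect_rows).to_csv(RESULTS / "scweat_effects.csv", index=False)


if __name__ == "__main__":
    main()
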