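"""Internal meta-analysis pooling the embedding- and fill-mask-branch effects.

Reads the standardized effect estimates written by scripts 02 and 03, takes
the squared standard errors as within-source variances, and pools them under
all three models (fixed, DerSimonian-Laird, REML). Writes
results/meta_pooled.json.
"""
import json
from pathlib import Path

import pandas as pd

from stereolang.metaanalysis import MetaInput, pool_effects

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    scweat = pd.read_csv(RESULTS / "scweat_effects.csv")
    fmat = pd.read_csv(RESULTS / "fmat_effects.csv")
    rows = pd.concat([
        scweat[scweat["kind"] == "classic_d"],
        fmat[fmat["kind"] == "standardized_slope"],
    ], ignore_index=True)
    effects = tuple((float(r.estimate), float(r.se) ** 2, str(r.unit))
                    for r in rows.itertuples())
    print(f"pooling {len(effects)} effects: "
          + ", ".join(f"{lbl}={est:.3f}" for est, _, lbl in effects))

    out = {}
    for model in ("fixed", "dl_random", "reml_random"):
        res = pool_effects(MetaInput(effects, model))
        out[model] = {"pooled": res.pooled, "se": res.se, "ci_low": res.ci_low,
                      "ci_high": res.ci_high, "p": res.p, "tau2": res.tau2,
                      "q_het": res.q_het, "k": res.k}
        print(f"{model:12s} pooled d = {res.pooled:.3f} "
              f"[{res.ci_low:.3f}, {res.ci_high:.3f}], tau^2 = {res.tau2:.4f}")
    (RESULTS / "meta_pooled.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
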