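"""Place AI and eight synthetic demographic groups in the 4D
competence-warmth space and test whether AI sits closer to advantaged groups.

Each group's coordinate on a (dimension, dictionary) axis is its pooled
SC-WEAT association effect in a synthetic embedding space whose planted bias
encodes the group's profile: advantaged groups are planted with biases close
to the AI category's, disadvantaged groups with clearly lower ones. Distances
from the AI point to each group are then regressed on status (disadvantaged
= 1) with a method fixed effect. A positive slope = disadvantaged groups sit
farther from AI. Writes results/stereospace_points.csv,
results/stereospace_distances.csv, results/stereospace_contrast.json.
"""
import json
from pathlib import Path

import pandas as pd

from stereolang.scweat import pooled_regression, similarity_table
from stereolang.stereospace import (advantaged_contrast, build_point,
                                    distances_from)
from stereolang.synthetic import EmbeddingSpec, gen_embeddings

RESULTS = Path(__file__).resolve().parents[1] / "results"
BASE_SEED = 20350

# planted association biases: AI high-competence/mid-warmth; advantaged
# groups near the AI profile, disadvantaged ones away from it
GROUP_BIAS = {
    "ai": {"status": "none", "competence": 0.50, "warmth": 0.30},
    "men": {"status": "advantaged", "competence": 0.45, "warmth": 0.30},
    "young": {"status": "advantaged", "competence": 0.42, "warmth": 0.35},
    "rich": {"status": "advantaged", "competence": 0.48, "warmth": 0.25},
    "white": {"status": "advantaged", "competence": 0.44, "warmth": 0.32},
    "women": {"status": "disadvantaged", "competence": 0.15, "warmth": 0.60},
    "old": {"status": "disadvantaged", "competence": 0.12, "warmth": 0.55},
    "poor": {"status": "disadvantaged", "competence": 0.10, "warmth": 0.50},
    "nonwhite": {"status": "disadvantaged", "competence": 0.14, "warmth": 0.58},
}
DICTIONARIES = ("a", "b")


def group_effect(group_index: int, dim_index: int, dict_index: int,
                 bias: float) -> float:
    """Pooled association effect for one group on one (dimension, dictionary)
    axis, from its own synthetic embedding space."""
    seed = BASE_SEED + group_index * 10 + dim_index * 2 + dict_index
    model, targets, pair, _ = gen_embeddings(EmbeddingSpec(
        dimension=50, n_targets=20, n_high=15, n_low=15,
        bias=bias, noise_sd=0.15, seed=seed))
    return pooled_regression(similarity_table(model, targets, pair,
                                              f"dict{dict_index}")).estimate


def main():
    points, rows = [], []
    for gi, (group, cfg) in enumerate(GROUP_BIAS.items()):
        coords = {}
        for di, dim in enumerate(("competence", "warmth")):
            for ki, dictionary in enumerate(DICTIONARIES):
                coords[f"{dim}_{dictionary}"] = group_effect(
                    gi, di, ki, cfg[dim])
        pt = build_point(group, coords, method="scweat", status=cfg["status"])
        points.append(pt)
        rows.append({"group": group, "status": cfg["status"], **coords})
        print(f"{group:9s} {cfg['status']:13s} "
              + " ".join(f"{c:+.3f}" for c in pt.coords))

    ai = next(p for p in points if p.group == "ai")
    records = distances_from(ai, [p for p in points if p.group != "ai"])
    eff = advantaged_contrast(records)
    print(f"\nstatus slope (extra distance of disadvantaged groups from AI) = "
          f"{eff.estimate:.3f}, SE {eff.se:.3f}, "
          f"95% CI [{eff.ci_low:.3f}, {eff.ci_high:.3f}], p = {eff.p:.2g}")

    pd.DataFrame(rows).to_csv(RESULTS / "stereospace_points.csv", index=False)
    pd.DataFrame([vars(r) for r in records]).to_csv(
        RESULTS / "stereospace_distances.csv", index=False)
    (RESULTS / "stereospace_contrast.json").write_text(json.dumps({
        "estimate": eff.estimate, "se": eff.se, "ci_low": eff.ci_low,
        "ci_high": eff.ci_high, "p": eff.p, "n_obs": eff.n_obs}, indent=1))


if __name__ == "__main__":
    main()
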