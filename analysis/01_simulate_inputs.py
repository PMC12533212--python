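"""Generate the synthetic study inputs and write them under results/inputs/.

Produces, with a fixed base seed:
  * two synthetic embedding "corpora" (GloVe-text files) with a planted
    target→high-competence bias in the range of published language-bias
    effects (d ≈ 0.15–0.40);
  * the target and attribute lexicons used by the embedding analyses;
  * a mock masked-LM probability table with a planted log-probability
    contrast for the fill-mask analysis;
  * an occupation/prestige table plus a mock top-k provider table with a
    planted linear prestige→q relationship.

Every later script reads only these files (or regenerates the same fixtures
from the recorded specs), so the whole analysis chain is reproducible offline.
"""
import json
from pathlib import Path

from stereolang.embeddings import write_embeddings
from stereolang.lexicons import write_lexicon
from stereolang.synthetic import (EmbeddingSpec, ProbeSpec, gen_embeddings,
                                  gen_fillmask_table, gen_probe_table)

BASE_SEED = 20250
OUT = Path(__file__).resolve().parents[1] / "results" / "inputs"

# two synthetic corpora, moderate planted bias, realistic noise
EMBEDDING_SPECS = [
    EmbeddingSpec(dimension=50, n_targets=40, n_high=25, n_low=25,
                  bias=0.10, noise_sd=0.15, seed=BASE_SEED),
    EmbeddingSpec(dimension=50, n_targets=40, n_high=25, n_low=25,
                  bias=0.10, noise_sd=0.15, seed=BASE_SEED + 1),
]
FILLMASK = dict(delta=0.3, n_pairs=24, noise_sd=0.2, seed=BASE_SEED + 2)
PROBE = ProbeSpec(n_occupations=65, prestige_range=(20.0, 80.0),
                  slope=0.8, noise_sd=0.6, n_obs_per_family=4,
                  seed=BASE_SEED + 3)


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for i, spec in enumerate(EMBEDDING_SPECS):
        model, targets, pair, truth = gen_embeddings(spec)
        write_embeddings(model, OUT / f"embeddings_corpus{i}.glove.txt")
        if i == 0:
            write_lexicon(targets, OUT / "targets.csv")
            write_lexicon(pair.high, OUT / "attributes_high.csv")
            write_lexicon(pair.low, OUT / "attributes_low.csv")
        print(f"corpus {i}: {len(model)} vectors, dim {model.dimension}, "
              f"planted bias {truth.bias}")

    adapter, queries, truth = gen_fillmask_table(**FILLMASK)
    table = {f"{ctx}␟{tok}": p for (ctx, tok), p in adapter.table.items()}
    (OUT / "fillmask_mock_table.json").write_text(json.dumps(table, indent=1))
    print(f"fill-mask table: {len(queries)} queries, planted delta "
          f"{truth.delta} (noise {truth.noise_sd})")

    fx = gen_probe_table(PROBE)
    with open(OUT / "occupations.csv", "w") as fh:
        fh.write("occupation,prestige\n")
        for occ in fx.occupations:
            fh.write(f"{occ},{fx.prestige[occ]:.4f}\n")
    (OUT / "probe_mock_table.json").write_text(
        json.dumps(fx.provider.table, indent=1))
    print(f"probe table: {len(fx.occupations)} occupations, planted "
          f"prestige slope {PROBE.slope} (noise {PROBE.noise_sd})")


if __name__ == "__main__":
    main()
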