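"""Occupation-probe analysis (q scores) on the mock generative-LM provider.

Rebuilds the probe fixture from the recorded spec, runs the batched
collection end to end through the provider, computes per-occupation q
scores, the one-sample t / Cohen's d summary, the JZS Bayes factor and the
prestige correlation. As a worked check, also reproduces the same summary
statistics from the published Study-level inputs (mean -0.551, SD 1.920,
n = 65). Writes results/probe_q_scores.csv and results/probe_summary.json.
"""
import importlib
import json
from pathlib import Path

import pandas as pd

from stereolang.llmprobe import (collect_probabilities, jzs_bayes_factor,
                                 make_batches, one_sample_summary,
                                 prestige_correlation, q_score,
                                 summary_from_stats)
from stereolang.synthetic import gen_probe_table

sim = importlib.import_module("01_simulate_inputs")
RESULTS = Path(__file__).resolve().parents[1] / "results"


def main():
    fx = gen_probe_table(sim.PROBE)
    tasks = make_batches(fx.prompt_set)
    probes = collect_probabilities(fx.provider, tasks, fx.prestige,
                                   k=len(fx.occupations))
    qs = [q_score(p) for p in probes]
    summary = one_sample_summary(qs)
    bf = jzs_bayes_factor(summary.t, summary.n)
    corr = prestige_correlation(probes)

    print(f"{len(probes)} occupations probed over {len(tasks)} prompt tasks")
    print(f"mean q = {summary.mean:.3f} (SD {summary.sd:.3f}); "
          f"t({summary.df}) = {summary.t:.3f}, p = {summary.p:.3g}")
    print(f"Cohen's d = {summary.d:.3f}, 95% CI "
          f"[{summary.d_ci_low:.3f}, {summary.d_ci_high:.3f}]; BF10 = {bf:.3f}")
    print(f"prestige-q correlation r = {corr['r']:.3f}, p = {corr['p']:.3g} "
          f"(n = {corr['n']})")

    ref = summary_from_stats(-0.551, 1.920, 65)
    print(f"published-summary check: t(64) = {ref.t:.3f}, d = {ref.d:.3f}, "
          f"d 95% CI [{ref.d_ci_low:.3f}, {ref.d_ci_high:.3f}]")

    pd.DataFrame([{
        "occupation": p.occupation, "prestige": p.prestige,
        "n1": p.n1, "n2": p.n2, "q": q,
    } for p, q in zip(probes, qs)]).to_csv(RESULTS / "probe_q_scores.csv",
                                           index=False)
    (RESULTS / "probe_summary.json").write_text(json.dumps({
        "mean_q": summary.mean, "sd_q": summary.sd, "n": summary.n,
        "t": summary.t, "df": summary.df, "p": summary.p,
        "d": summary.d, "d_ci_low": summary.d_ci_low,
        "d_ci_high": summary.d_ci_high, "bf10": bf, **corr}, indent=1))


if __name__ == "__main__":
    main()
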