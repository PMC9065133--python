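#!/usr/bin/env python
"""Per-condition stoichiometry statistics and cross-condition comparison.

Reads the pooled counts table of 03_count_steps.py, computes the
box-and-whisker summary of steps per intasome for each NaCl condition
(median, quartiles, 10th/90th percentile whiskers, outliers), tests each
condition pair with the Wilcoxon rank-sum, and draws the box plot.
"""

import json
from itertools import combinations
from pathlib import Path

import pandas as pd

from smstoich import compare_conditions, summarize_condition
from smstoich.io import write_summary_json
from smstoich.steps import StepCountResult

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    df = pd.read_csv(RESULTS / "counts.csv", keep_default_na=False)
    summaries = {}
    cohorts = {}
    for cond, grp in df.groupby("condition"):
        results = [
            StepCountResult(
                spot_id=int(r.spot_id),
                k_steps=int(r.k_steps),
                exclusion_reason=r.exclusion_reason or None,
                step_size_estimate=float(r.step_size_estimate),
            )
            for r in grp.itertuples()
        ]
        label = f"{cond} M NaCl"
        s = summarize_condition(results, label)
        summaries[label] = s
        cohorts[label] = [r.k_steps for r in results if r.exclusion_reason is None]
        print(
            f"{label}: n={s.n_included} mean={s.mean:.2f} median={s.median:.1f} "
            f"IQR=[{s.q25:.1f}, {s.q75:.1f}] whiskers=[{s.p10:.1f}, {s.p90:.1f}] "
            f"max={s.max_count}"
        )
    write_summary_json(summaries, RESULTS / "summary.json")

    comparisons = {}
    for (la, ca), (lb, cb) in combinations(cohorts.items(), 2):
        z, p = compare_conditions(ca, cb)
        comparisons[f"{la} vs {lb}"] = {"z": z, "p": p}
        print(f"{la} vs {lb}: rank-sum z={z:+.2f}, p={p:.3g}")
    (RESULTS / "comparisons.json").write_text(json.dumps(comparisons, indent=2))

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    labels = list(cohorts)
    ax.boxplot(
        [cohorts[k] for k in labels],
        whis=(10, 90),
        tick_labels=[lbl.replace(" NaCl", "") for lbl in labels],
        showmeans=True,
    )
    ax.set_ylabel("Surf649 photobleaching steps per intasome")
    ax.set_xlabel("NaCl concentration")
    fig.tight_layout()
    fig.savefig(RESULTS / "boxplot_steps_per_intasome.png", dpi=150)
    print(f"wrote summary.json, comparisons.json and box plot to {RESULTS}")


if __name__ == "__main__":
    main()
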