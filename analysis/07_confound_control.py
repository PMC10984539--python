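#!/usr/bin/env python
"""Confound-removal control: a High/Low difference carried only by the
confound geometry must vanish under partial correlation.

Simulates an experiment with zero base/divergence amplitude where the
"GIST-like" confound is expressed twice as strongly in the High set, then
compares the High>Low difference fusion series with the confound partialled
out against the same contrast computed with an irrelevant dummy RDM
partialled out (leaving the confound in).  Also runs the memory-ROI style
group test of the memorability-magnitude model RDM.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from memfusion import benchmarks
from memfusion.inference import roi_model_test

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 2026


def main() -> None:
    study = benchmarks.confound_removal_study(seed=SEED)
    pd.DataFrame([study]).to_csv(ROOT / "confound_control.tsv", sep="\t", index=False)
    print(f"partialled |time-mean difference|: {study['partialled_abs_mean']:.4f} (target ~0)")
    print(f"unpartialled time-mean difference: {study['unpartialled_mean']:.4f} (confound retained)")

    # group-level ROI-model correlation test on planted subject correlations
    rng = np.random.default_rng(SEED)
    groups = {
        "planted_roi": 0.2 + 0.05 * rng.standard_normal(15),
        "null_roi_a": 0.02 * rng.standard_normal(15),
        "null_roi_b": 0.02 * rng.standard_normal(15),
        "null_roi_c": 0.02 * rng.standard_normal(15),
    }
    res = roi_model_test(groups, q=0.05)
    table = pd.DataFrame(res).T.rename_axis("roi").reset_index()
    table.to_csv(ROOT / "roi_model_test.tsv", sep="\t", index=False)
    for roi, row in res.items():
        print(f"{roi}: mean r = {row['mean_correlation']:+.3f}, Holm-adjusted p_t = {row['p_t_holm']:.4g}, "
              f"reject = {row['reject_t']}")


if __name__ == "__main__":
    main()
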