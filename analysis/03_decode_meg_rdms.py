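#!/usr/bin/env python
"""MEG decoding RDM time series per subject and condition set.

For each subject, bins trials into pseudo-trials (groups of 3), decodes every
condition pair with a linear SVM at every time point, and averages accuracy
over 30 random binnings.  Writes the subject-averaged High- and Low-set RDM
series plus a time course summary under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from memfusion import io as mio
from memfusion.decoding import DecodingConfig, TrialSet, decode_rdm_series

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"


def main() -> None:
    data = np.load(DATA / "meg_trials.npz")
    stim = pd.read_csv(DATA / "stimuli.tsv", sep="\t")
    ids = stim.condition_id.tolist()
    sets = {
        "High": stim[stim.set_label == "High"].condition_id.tolist(),
        "Low": stim[stim.set_label == "Low"].condition_id.tolist(),
    }
    trials, t = data["trials"], data["time_axis"]
    config = DecodingConfig(n_iterations=30, seed=2026)

    rows = []
    for label, subset in sets.items():
        per_subject = []
        for s in range(trials.shape[0]):
            ts = TrialSet(trials[s], t, ids).subset(subset)
            per_subject.append(decode_rdm_series(ts, config))
        mean_series = per_subject[0].mean_with(per_subject[1:])
        mio.write_rdm(mean_series, ROOT / f"meg_rdm_series_{label}.npz")
        acc = mean_series.vectors()
        for window, sel in (("baseline", t < 0), ("post", t >= 0)):
            rows.append(
                {
                    "set": label,
                    "window": window,
                    "mean_accuracy_pct": acc[sel].mean(),
                    "max_accuracy_pct": acc[sel].max(),
                }
            )
        print(f"{label}: baseline {acc[t < 0].mean():.1f}%, post-stimulus {acc[t >= 0].mean():.1f}%")
    pd.DataFrame(rows).to_csv(ROOT / "decoding_summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
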