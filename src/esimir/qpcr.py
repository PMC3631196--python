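"""Relative quantification from Ct values by the 2^-ddCt method.

Per replicate, dCt = Ct(target) - Ct(reference gene); ddCt is the mean dCt of
a sample minus the mean dCt of the calibrator sample, and the fold change is
2^-ddCt.  Replicate spread is summarized as the SD of dCt and mapped through
2^-x as asymmetric fold bounds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ["target", "sample", "replicate", "ct_target", "ct_reference"]


def ddct(table: pd.DataFrame, calibrator: str = "female") -> pd.DataFrame:
    """Per-(target, sample) fold change relative to the calibrator sample.

    Returns columns: target, sample, n_reps, dct_mean, dct_sd, ddct, fold,
    fold_lo, fold_hi.  Raises if any target lacks calibrator replicates or
    any Ct is non-positive / non-finite.
    """
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns: {sorted(missing)}")
    ct = table[["ct_target", "ct_reference"]].to_numpy(dtype=float)
    if not np.isfinite(ct).all() or (ct <= 0).any():
        raise ValueError("Ct values must be finite and > 0")

    df = table.assign(dct=table.ct_target - table.ct_reference)
    rows = []
    for target, sub in df.groupby("target", sort=True):
        cal = sub[sub["sample"] == calibrator]
        if cal.empty:
            raise ValueError(f"target {target!r} has no calibrator "
                             f"({calibrator!r}) replicates")
        cal_mean = cal.dct.mean()
        for sample, grp in sub.groupby("sample", sort=True):
            dd = grp.dct.mean() - cal_mean
            sd = grp.dct.std(ddof=1) if len(grp) > 1 else 0.0
            rows.append({
                "target": target,
                "sample": sample,
                "n_reps": len(grp),
                "dct_mean": grp.dct.mean(),
                "dct_sd": sd,
                "ddct": dd,
                "fold": 2.0 ** -dd,
                "fold_lo": 2.0 ** -(dd + sd),
                "fold_hi": 2.0 ** -(dd - sd),
            })
    return pd.DataFrame(rows)


def concordance(qpcr_folds: dict[str, float],
                cpm_ratios: dict[str, float]) -> tuple[pd.DataFrame, float]:
    """Direction agreement between qPCR fold changes and sequencing CPM ratios.

    Both inputs are male-relative-to-female ratios keyed by target name;
    agreement means the signs of the log ratios match.  Returns the
    per-target table and the summary agreement fraction.
    """
    shared = sorted(set(qpcr_folds) & set(cpm_ratios))
    if not shared:
        raise ValueError("no shared target names")
    rows = []
    for t in shared:
        sq = np.sign(np.log(qpcr_folds[t]))
        ss = np.sign(np.log(cpm_ratios[t]))
        rows.append({
            "target": t,
            "qpcr_fold": qpcr_folds[t],
            "cpm_ratio": cpm_ratios[t],
            "agree": bool(sq == ss),
        })
    df = pd.DataFrame(rows)
    return df, float(df.agree.mean())
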