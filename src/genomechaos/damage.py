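"""Radiation-induced DNA damage response: 2^-ddCt quantification and the
p53 functional call.

Relative induction of the p53 targets CDKN1A (p21) and BAX 8 h after
irradiation, normalised to an endogenous reference gene (TBP), is computed
with the standard 2^-ddCt method: technical-replicate Ct values are averaged
per condition, dCt_t = Ct_target,t - Ct_ref,t at each timepoint, and the
fold change is 2^-(dCt_8h - dCt_0h). A sample is called p53-functional when
both targets are induced at least ``induction_threshold``-fold (default 2).
"""

from __future__ import annotations

import pandas as pd

TIMEPOINTS = ("0h", "8h")


def delta_delta_ct(ct_table: pd.DataFrame, sample: str, target: str) -> float:
    """Fold change 2^-ddCt for one sample x target.

    ``ct_table`` columns: sample, target, reference_flag, timepoint,
    replicate, ct. Replicates are averaged per condition before
    differencing. Raises naming the missing condition if a sample/target/
    timepoint combination is absent.
    """
    sub = ct_table[ct_table["sample"] == sample]
    ref = sub[sub["reference_flag"].astype(int) == 1]
    tgt = sub[(sub["target"] == target) & (sub["reference_flag"].astype(int) == 0)]
    means = {}
    for label, frame in (("reference", ref), (target, tgt)):
        for tp in TIMEPOINTS:
            vals = frame.loc[frame["timepoint"] == tp, "ct"].astype(float)
            if vals.empty:
                raise ValueError(f"missing Ct: sample={sample} target={label} "
                                 f"timepoint={tp}")
            means[(label, tp)] = float(vals.mean())
    d0 = means[(target, "0h")] - means[("reference", "0h")]
    d8 = means[(target, "8h")] - means[("reference", "8h")]
    return float(2.0 ** (-(d8 - d0)))


def fold_changes(ct_table: pd.DataFrame,
                 targets: tuple[str, ...] = ("CDKN1A", "BAX")) -> pd.DataFrame:
    """Per sample x target 2^-ddCt fold changes as a tidy frame."""
    rows = []
    for sample in sorted(ct_table["sample"].unique()):
        for target in targets:
            rows.append({"sample": sample, "target": target,
                         "fold_change": delta_delta_ct(ct_table, sample, target)})
    return pd.DataFrame(rows)


def p53_functional_call(folds: dict[str, float],
                        induction_threshold: float = 2.0,
                        partial_category: bool = False) -> str:
    """'functional' iff every target fold >= threshold, else 'deficient'.

    With ``partial_category`` enabled, exactly one induced target (the
    MDM2-amplified borderline phenotype) is reported as 'partial'.
    """
    if not folds:
        raise ValueError("no fold changes given")
    induced = [f >= induction_threshold for f in folds.values()]
    if all(induced):
        return "functional"
    if partial_category and any(induced):
        return "partial"
    return "deficient"


def call_cohort(ct_table: pd.DataFrame,
                targets: tuple[str, ...] = ("CDKN1A", "BAX"),
                induction_threshold: float = 2.0,
                partial_category: bool = False) -> pd.DataFrame:
    """Fold changes and p53 functional calls for every sample in the table."""
    ff = fold_changes(ct_table, targets)
    rows = []
    for sample, grp in ff.groupby("sample"):
        folds = dict(zip(grp["target"], grp["fold_change"]))
        row = {"sample": sample,
               "p53_call": p53_functional_call(folds, induction_threshold,
                                               partial_category)}
        row.update({f"fold_{t}": folds[t] for t in targets})
        rows.append(row)
    return pd.DataFrame(rows)
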