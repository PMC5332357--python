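"""Relative expression by the 2^-ddCt method and feedback-repression calls.

Technical replicates are collapsed by the arithmetic mean of their Ct
values; biological replicates are the unit of inference.  For each
(condition, biological replicate): dCt = Ct_target - Ct_reference;
ddCt = dCt - mean dCt of the calibrator condition; fold = 2^-ddCt.
Amplification efficiency is fixed at 100% (the base of 2).  Statistical
comparison uses a two-sided Welch t-test on the per-replicate dCt
values — dCt, not fold, is approximately normal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_COLUMNS = ["condition", "gene", "bio_rep", "tech_rep", "ct"]


@dataclass
class RelExpressionResult:
    """Per-condition fold changes plus the per-replicate dCt detail."""

    target: str
    reference: str
    calibrator: str
    table: pd.DataFrame      # condition, fold, dct_mean, dct_sd, n_bio
    per_rep: pd.DataFrame    # condition, bio_rep, dct, ddct, fold

    def dct_values(self, condition: str) -> np.ndarray:
        sub = self.per_rep[self.per_rep["condition"] == condition]
        if sub.empty:
            raise KeyError(f"condition {condition!r} absent from the result")
        return sub["dct"].to_numpy()


def ddct(
    ct_table: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str,
    condition_col: str = "condition",
    efficiency: tuple[float, float] = (2.0, 2.0),
) -> RelExpressionResult:
    """2^-ddCt relative expression of ``target`` against ``reference``.

    The condition-level fold change is 2^-(mean dCt_condition - mean
    dCt_calibrator), so the calibrator's fold is exactly 1 by
    construction; the spread over biological replicates is reported as
    the dCt mean +/- sd and per-replicate folds.

    ``efficiency`` gives the per-cycle amplification factors of the
    target and reference assays (2.0 = 100% efficiency).  With unequal
    factors the Pfaffl ratio E_t^(dCt_t) / E_r^(dCt_r) is used, where
    each dCt is taken against the calibrator's mean Ct of that gene;
    the default reduces exactly to plain 2^-ddCt.
    """
    e_target, e_ref = efficiency
    if e_target <= 1.0 or e_ref <= 1.0:
        raise ValueError("amplification efficiencies must exceed 1.0")
    missing = [c for c in REQUIRED_COLUMNS if c not in ct_table.columns and c != "condition"]
    if condition_col not in ct_table.columns:
        raise ValueError(f"Ct table lacks condition column {condition_col!r}")
    if missing:
        raise ValueError(f"Ct table lacks columns {missing}")
    if (ct_table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    sub = ct_table[ct_table["gene"].isin([target, reference])]
    # collapse technical replicates
    tech = (
        sub.groupby([condition_col, "bio_rep", "gene"], sort=True)["ct"]
        .mean()
        .unstack("gene")
    )
    for gene in (target, reference):
        if gene not in tech.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
    bad = tech[tech[reference].isna() & tech[target].notna()]
    if len(bad):
        reps = ", ".join(f"{c}/bio{b}" for c, b in bad.index)
        raise ValueError(f"reference gene {reference!r} missing for: {reps}")
    tech = tech.dropna()
    per_rep = tech.reset_index().rename(columns={condition_col: "condition"})
    per_rep["dct"] = per_rep[target] - per_rep[reference]
    cal = per_rep[per_rep["condition"] == calibrator]
    if cal.empty:
        raise ValueError(f"calibrator condition {calibrator!r} absent")
    cal_mean = cal["dct"].mean()
    cal_t_mean = cal[target].mean()
    cal_r_mean = cal[reference].mean()
    per_rep["ddct"] = per_rep["dct"] - cal_mean
    # Pfaffl ratio; equals 2^-ddct when both efficiencies are 2
    per_rep["fold"] = (
        e_target ** (cal_t_mean - per_rep[target])
        / e_ref ** (cal_r_mean - per_rep[reference])
    )
    rows = []
    for cond, grp in per_rep.groupby("condition", sort=True):
        rows.append(
            {
                "condition": cond,
                "fold": (
                    e_target ** (cal_t_mean - grp[target].mean())
                    / e_ref ** (cal_r_mean - grp[reference].mean())
                ),
                "dct_mean": grp["dct"].mean(),
                "dct_sd": grp["dct"].std(ddof=1) if len(grp) > 1 else 0.0,
                "n_bio": len(grp),
            }
        )
    table = pd.DataFrame(rows)
    return RelExpressionResult(
        target=target,
        reference=reference,
        calibrator=calibrator,
        table=table,
        per_rep=per_rep[["condition", "bio_rep", "dct", "ddct", "fold"]],
    )


@dataclass(frozen=True)
class ComparisonResult:
    condition_a: str
    condition_b: str
    p_value: float
    significant: bool
    mean_dct_diff: float  # dct_b - dct_a; positive = lower expression in b


def compare_conditions(
    result: RelExpressionResult,
    condition_a: str,
    condition_b: str,
    alpha: float = 0.01,
) -> ComparisonResult:
    """Two-sided Welch t-test on per-replicate dCt between two conditions."""
    a = result.dct_values(condition_a)
    b = result.dct_values(condition_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 biological replicates per condition")
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if math.isclose(a.mean(), b.mean()) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return ComparisonResult(
        condition_a=condition_a,
        condition_b=condition_b,
        p_value=p,
        significant=p < alpha,
        mean_dct_diff=float(b.mean() - a.mean()),
    )


def feedback_report(
    ct_table: pd.DataFrame,
    target: str,
    reference: str,
    organ_col: str = "organ",
    genotype_col: str = "genotype",
    treatment_col: str = "treatment",
    control_treatment: str = "mock",
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Per-organ, per-genotype hormone-feedback contrasts.

    For each (organ, genotype), expression under each non-control
    treatment is compared with the control by 2^-ddCt (control as
    calibrator) and a Welch t-test on dCt, then classified: repressed
    (significant, fold < 1), induced (significant, fold > 1), unchanged
    (not significant), or incomplete (a treatment arm is missing).
    """
    rows = []
    treatments = [t for t in ct_table[treatment_col].unique() if t != control_treatment]
    for (organ, genotype), grp in ct_table.groupby([organ_col, genotype_col], sort=True):
        present = set(grp[treatment_col])
        for tr in treatments:
            if tr not in present or control_treatment not in present:
                rows.append(
                    {"organ": organ, "genotype": genotype, "treatment": tr,
                     "fold": float("nan"), "p_value": float("nan"),
                     "status": "incomplete"}
                )
                continue
            sub = grp.copy()
            sub["condition"] = sub[treatment_col]
            rel = ddct(sub, target, reference, calibrator=control_treatment)
            comp = compare_conditions(rel, control_treatment, tr, alpha=alpha)
            fold = float(
                rel.table.loc[rel.table["condition"] == tr, "fold"].iloc[0]
            )
            if not comp.significant:
                status = "unchanged"
            else:
                status = "repressed" if fold < 1.0 else "induced"
            rows.append(
                {"organ": organ, "genotype": genotype, "treatment": tr,
                 "fold": fold, "p_value": comp.p_value, "status": status}
            )
    return pd.DataFrame(rows)
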