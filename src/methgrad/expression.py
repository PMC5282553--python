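"""Relative mRNA quantification by double-delta Ct and segment-wise RM-ANOVA.

ΔCt is the target gene's mean Ct minus the endogenous control's (technical
replicates averaged first); ΔΔCt subtracts the mean ΔCt of a reference group
(default: segment 3 of the same stratum); fold change is 2^-ΔΔCt with
amplification efficiency fixed at 2.  Because ΔΔCt is normalised on the Ct
(log2) scale, the *geometric* mean fold of the reference group is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidDesignError, InvalidInputError
from .gradient_assoc import tukey_hsd

CT_COLUMNS = ["sample", "gene", "replicate", "ct"]


def delta_delta_ct(ct: pd.DataFrame, target: str, control: str,
                   reference_samples) -> pd.DataFrame:
    """Relative expression per sample via the 2^-ΔΔCt method.

    Parameters
    ----------
    ct
        Long table with columns ``sample, gene, replicate, ct``.
    target, control
        Gene names; every sample quantified for the target must also carry
        control rows, else :class:`InvalidInputError`.
    reference_samples
        Samples whose mean ΔCt defines the calibrator (must be non-empty and
        present in the table).
    """
    missing_cols = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing_cols:
        raise InvalidInputError(f"Ct table lacks columns {missing_cols}")
    if (ct["ct"] <= 0).any():
        raise InvalidInputError("Ct values must be positive cycles")
    piv = (ct.groupby(["sample", "gene"])["ct"].mean().unstack())
    if target not in piv.columns:
        raise InvalidInputError(f"no rows for target gene {target!r}")
    if control not in piv.columns:
        raise InvalidInputError(f"no rows for control gene {control!r}")
    has_target = piv[target].notna()
    no_control = has_target & piv[control].isna()
    if no_control.any():
        raise InvalidInputError(
            f"samples missing control-gene rows: "
            f"{list(piv.index[no_control])[:5]}")
    out = piv.loc[has_target, [target, control]].copy()
    out.columns = ["ct_target", "ct_control"]
    out["delta_ct"] = out["ct_target"] - out["ct_control"]
    ref = [s for s in reference_samples]
    if not ref:
        raise InvalidInputError("reference group is empty")
    absent = [s for s in ref if s not in out.index]
    if absent:
        raise InvalidInputError(f"reference samples absent from table: {absent}")
    out["delta_delta_ct"] = out["delta_ct"] - out.loc[ref, "delta_ct"].mean()
    out["fold"] = np.exp2(-out["delta_delta_ct"])
    out.index.name = "sample"
    return out


def reference_group(annot: pd.DataFrame, segment: int = 3,
                    **strata) -> list[str]:
    """Samples of one segment (default 3) within an age/diet stratum."""
    keep = annot["segment"] == segment
    for col, val in strata.items():
        keep &= annot[col] == val
    return list(annot.index[keep])


@dataclass(eq=False)
class RMAnovaResult:
    F: float
    df_num: float
    df_den: float
    p: float
    tukey: pd.DataFrame
    n_mice: int
    dropped_mice: list


def rm_anova_segments(values, annot: pd.DataFrame,
                      alpha: float = 0.05) -> RMAnovaResult:
    """One-way repeated-measures ANOVA of expression across segments.

    ``values`` is a per-sample Series (e.g. fold change); the mouse is the
    repeated factor, segment the within factor.  Mice missing any segment are
    dropped (the design must be complete for the uncorrected RM F); fewer
    than 3 complete mice is an invalid design.  Tukey HSD on segment means is
    returned alongside (between-segment comparisons, unpaired).
    """
    from statsmodels.stats.anova import AnovaRM

    v = pd.Series(values).dropna()
    df = pd.DataFrame({"y": v,
                       "mouse": annot.loc[v.index, "mouse"],
                       "segment": annot.loc[v.index, "segment"]})
    wide = df.pivot_table(index="mouse", columns="segment", values="y",
                          aggfunc="mean")
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if len(complete) < 3:
        raise InvalidDesignError(
            f"need >= 3 mice with complete segment data, have {len(complete)}")
    if complete.shape[1] < 2:
        raise InvalidDesignError("need >= 2 segments")
    long = complete.stack().rename("y").reset_index()
    res = AnovaRM(long, depvar="y", subject="mouse",
                  within=["segment"]).fit()
    row = res.anova_table.iloc[0]
    tukey = tukey_hsd(long["y"], long["segment"], alpha=alpha)
    return RMAnovaResult(F=float(row["F Value"]),
                         df_num=float(row["Num DF"]),
                         df_den=float(row["Den DF"]),
                         p=float(row["Pr > F"]),
                         tukey=tukey,
                         n_mice=len(complete),
                         dropped_mice=dropped)
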