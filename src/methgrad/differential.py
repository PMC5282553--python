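"""Group contrasts of modification density: age, diet, and segment scans.

Per cytosine and segment, the contrast is the difference of per-mouse density
means between two groups (e.g. adult minus infant, or lactose-free minus
lactose-fed), tested with a two-sided Welch t-test on per-mouse densities
(the mouse, not the read, is the unit of replication).  Bonferroni correction
runs over every tested site x segment (or site x segment-pair) combination.
Positional delta profiles are smoothed with a textbook LOESS: tricube weights
over the ceil(span*n) nearest neighbours, local polynomial of degree 1, no
robustness iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .density import (DEFAULT_MIN_SAMPLE_FRACTION, DensityMatrix,
                      MethylationCountTable)
from .errors import InvalidArgumentError, InvalidDesignError
from .gradient_assoc import DEFAULT_ALPHA, SLP_CAP, bonferroni, slp

DEFAULT_LOESS_SPAN = 0.3
DEFAULT_LOESS_DEGREE = 1


def _welch_arrays(A: np.ndarray, B: np.ndarray):
    """Vectorised Welch t-test along axis 1 with NaN-aware group summaries.

    Degenerate rows (zero pooled variance) get p = 1 when the means agree and
    p = 0 otherwise.
    """
    def summarise(X):
        fin = np.isfinite(X)
        n = fin.sum(1).astype(float)
        s = np.where(fin, X, 0.0).sum(1)
        mean = np.divide(s, n, out=np.full(n.shape, np.nan), where=n > 0)
        dev = np.where(fin, X - mean[:, None], 0.0)
        var = np.divide((dev ** 2).sum(1), n - 1,
                        out=np.full(n.shape, np.nan), where=n > 1)
        return n, mean, var

    na, ma, va = summarise(A)
    nb, mb, vb = summarise(B)
    with np.errstate(invalid="ignore", divide="ignore"):
        se2 = va / na + vb / nb
        t = (ma - mb) / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se2 == 0
    p = np.where(zero_se & (ma == mb), 1.0, p)
    p = np.where(zero_se & (ma != mb), 0.0, p)
    return na, ma, nb, mb, p


def _proportion_arrays(counts: MethylationCountTable, cols_a, cols_b):
    """Two-proportion z-test on read counts pooled within each group."""
    ma = counts.meth[cols_a].sum(1).to_numpy(float)
    ta = counts.total[cols_a].sum(1).to_numpy(float)
    mb = counts.meth[cols_b].sum(1).to_numpy(float)
    tb = counts.total[cols_b].sum(1).to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pa, pb = ma / ta, mb / tb
        pool = (ma + mb) / (ta + tb)
        se = np.sqrt(pool * (1 - pool) * (1 / ta + 1 / tb))
        z = (pa - pb) / se
        p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where((se == 0) & (pa == pb), 1.0, p)
    return pa, pb, p


@dataclass(eq=False)
class DeltaProfile:
    """Per-site contrast table plus optional LOESS-smoothed positional curves."""

    table: pd.DataFrame  # columns: segment, chrom, pos, context, n_a, n_b,
    #                      mean_a, mean_b, delta, p, p_bonferroni, slp,
    #                      significant, tested
    group_a: str
    group_b: str
    span: float | None = None
    degree: int | None = None
    smoothed: dict[int, pd.DataFrame] = field(default_factory=dict)

    def smooth(self, span: float = DEFAULT_LOESS_SPAN,
               degree: int = DEFAULT_LOESS_DEGREE,
               context: str | None = "CpG") -> "DeltaProfile":
        """Fit a per-segment LOESS curve through the (position, delta) points."""
        self.span, self.degree = span, degree
        for seg, grp in self.table.groupby("segment"):
            sub = grp[grp["tested"]]
            if context is not None:
                sub = sub[sub["context"] == context]
            sub = sub.dropna(subset=["delta"]).sort_values("pos")
            if len(sub) < degree + 2:
                continue
            fitted = loess_smooth(sub["pos"].to_numpy(float),
                                  sub["delta"].to_numpy(float),
                                  span=span, degree=degree)
            self.smoothed[int(seg)] = pd.DataFrame(
                {"pos": sub["pos"].to_numpy(), "delta": sub["delta"].to_numpy(),
                 "fitted": fitted})
        return self


def site_contrast(density: DensityMatrix, annot: pd.DataFrame,
                  group_by: str, group_a: str, group_b: str,
                  segments, alpha: float = DEFAULT_ALPHA,
                  test: str = "welch",
                  counts: MethylationCountTable | None = None,
                  min_sample_fraction: float = DEFAULT_MIN_SAMPLE_FRACTION,
                  m: int | None = None) -> DeltaProfile:
    """Per-cytosine group contrast on matched segments.

    delta = mean(group A) - mean(group B) of per-mouse densities within each
    segment; antisymmetric under swapping the groups, with identical p-values.
    ``test='proportion'`` switches to a pooled-read two-proportion z-test and
    requires ``counts``.
    """
    if test not in ("welch", "proportion"):
        raise InvalidArgumentError(f"unknown test {test!r}")
    if test == "proportion" and counts is None:
        raise InvalidArgumentError("proportion test requires the count table")
    segments = [int(s) for s in segments]
    rows = []
    for seg in segments:
        in_seg = annot["segment"] == seg
        cols_a = [s for s in annot.index[in_seg & (annot[group_by] == group_a)]
                  if s in density.values.columns]
        cols_b = [s for s in annot.index[in_seg & (annot[group_by] == group_b)]
                  if s in density.values.columns]
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise InvalidDesignError(
                f"segment {seg}: need >= 2 mice per group "
                f"({group_a}: {len(cols_a)}, {group_b}: {len(cols_b)})")
        if test == "welch":
            A = density.values[cols_a].to_numpy(float)
            B = density.values[cols_b].to_numpy(float)
            na, ma, nb, mb, p = _welch_arrays(A, B)
            need_a = max(2, math.ceil(min_sample_fraction * len(cols_a)))
            need_b = max(2, math.ceil(min_sample_fraction * len(cols_b)))
            tested = (na >= need_a) & (nb >= need_b) & np.isfinite(p)
        else:
            ma, mb, p = _proportion_arrays(counts, cols_a, cols_b)
            na = np.full(len(ma), len(cols_a), dtype=float)
            nb = np.full(len(mb), len(cols_b), dtype=float)
            tested = np.isfinite(p)
        seg_df = density.sites.reset_index(drop=True).copy()
        seg_df["segment"] = seg
        seg_df["n_a"], seg_df["n_b"] = na.astype(int), nb.astype(int)
        seg_df["mean_a"], seg_df["mean_b"] = ma, mb
        seg_df["delta"] = ma - mb
        seg_df["p"] = np.where(tested, p, np.nan)
        seg_df["tested"] = tested
        rows.append(seg_df)
    out = pd.concat(rows, ignore_index=True)
    if m is None:
        m = int(out["tested"].sum())
    p_adj, sig = bonferroni(out["p"].to_numpy(), m=m, alpha=alpha)
    out["p_bonferroni"] = p_adj
    out["significant"] = sig
    out["slp"] = [slp(d, pv) if np.isfinite(d) and np.isfinite(pv) else np.nan
                  for d, pv in zip(out["delta"], out["p"])]
    out.attrs["m"] = m
    return DeltaProfile(table=out, group_a=group_a, group_b=group_b)


def between_segment_scan(density: DensityMatrix, annot: pd.DataFrame,
                         segment_pairs, selector: dict | None = None,
                         alpha: float = DEFAULT_ALPHA,
                         min_sample_fraction: float = DEFAULT_MIN_SAMPLE_FRACTION
                         ) -> pd.DataFrame:
    """Welch contrast of every site between segment pairs within one group.

    ``selector`` restricts the samples (e.g. ``{"age": "P60"}``).  Bonferroni
    runs over sites x pairs.  Self-pairs are rejected as an invalid design.
    """
    keep = pd.Series(True, index=annot.index)
    for col, val in (selector or {}).items():
        keep &= annot[col] == val
    frames = []
    for s1, s2 in segment_pairs:
        if s1 == s2:
            raise InvalidDesignError(f"self-comparison of segment {s1}")
        cols_a = [s for s in annot.index[keep & (annot["segment"] == s1)]
                  if s in density.values.columns]
        cols_b = [s for s in annot.index[keep & (annot["segment"] == s2)]
                  if s in density.values.columns]
        if len(cols_a) < 2 or len(cols_b) < 2:
            raise InvalidDesignError(
                f"pair ({s1},{s2}): need >= 2 mice per segment")
        A = density.values[cols_a].to_numpy(float)
        B = density.values[cols_b].to_numpy(float)
        na, ma, nb, mb, p = _welch_arrays(A, B)
        need_a = max(2, math.ceil(min_sample_fraction * len(cols_a)))
        need_b = max(2, math.ceil(min_sample_fraction * len(cols_b)))
        tested = (na >= need_a) & (nb >= need_b) & np.isfinite(p)
        df = density.sites.reset_index(drop=True).copy()
        df["segment_a"], df["segment_b"] = s1, s2
        df["delta"] = ma - mb
        df["p"] = np.where(tested, p, np.nan)
        df["tested"] = tested
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    m = int(out["tested"].sum())
    p_adj, sig = bonferroni(out["p"].to_numpy(), m=m, alpha=alpha)
    out["p_bonferroni"] = p_adj
    out["significant"] = sig
    out["slp"] = [slp(d, pv) if np.isfinite(d) and np.isfinite(pv) else np.nan
                  for d, pv in zip(out["delta"], out["p"])]
    out.attrs["m"] = m
    return out


def loess_smooth(x, y, span: float = DEFAULT_LOESS_SPAN,
                 degree: int = DEFAULT_LOESS_DEGREE) -> np.ndarray:
    """Textbook LOESS evaluated at the input points.

    For each x_i, the ceil(span*n) nearest neighbours (at least degree+2) are
    weighted by the tricube kernel (1-(d/dmax)^3)^3 and a degree-``degree``
    polynomial is fit by weighted least squares in local coordinates.  No
    robustness iterations.  Exactly reproduces polynomials of degree <= the
    local degree for any span.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise InvalidArgumentError("x and y must be equal-length 1-D arrays")
    n = len(x)
    if degree < 0:
        raise InvalidArgumentError("degree must be non-negative")
    if n < degree + 2:
        raise InvalidArgumentError(f"need >= {degree + 2} points")
    if not 0 < span <= 1:
        raise InvalidArgumentError("span must be in (0, 1]")
    k = min(n, max(math.ceil(span * n), degree + 2))
    fitted = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argpartition(d, k - 1)[:k]
        dmax = d[idx].max()
        if dmax == 0:
            fitted[i] = y[idx].mean()
            continue
        w = np.clip(1.0 - (d[idx] / dmax) ** 3, 0.0, None) ** 3
        # the farthest neighbour gets weight 0; keep the system full rank
        w = np.maximum(w, 1e-9)
        u = x[idx] - x[i]  # local coordinates for conditioning
        beta = np.polyfit(u, y[idx], degree, w=np.sqrt(w))
        fitted[i] = beta[-1]
    return fitted


@dataclass(eq=False)
class FactorialAnovaResult:
    table: pd.DataFrame  # index: term; columns sum_sq, df, F, p
    tukey_within: dict   # level of factor_b -> Tukey HSD frame for factor_a

    def term(self, name: str) -> tuple[float, float]:
        row = self.table.loc[name]
        return float(row["F"]), float(row["p"])


def factorial_region_anova(values, annot: pd.DataFrame,
                           factor_a: str = "diet",
                           factor_b: str = "segment") -> FactorialAnovaResult:
    """Two-way ANOVA with interaction (Type II sums of squares).

    ``values`` is a per-sample Series of region densities.  Type II SS keeps
    the unbalanced 5-7 mice/arm designs free of ordering artifacts.  Tukey HSD
    for ``factor_a`` is run within each level of ``factor_b``.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    v = pd.Series(values).dropna()
    df = pd.DataFrame({
        "y": v,
        "fa": annot.loc[v.index, factor_a].astype(str),
        "fb": annot.loc[v.index, factor_b].astype(str),
    })
    for name, col in (("factor_a", "fa"), ("factor_b", "fb")):
        if df[col].nunique() < 2:
            raise InvalidDesignError(f"{name} has < 2 levels")
    counts = df.groupby(["fa", "fb"]).size()
    for a in df["fa"].unique():
        for b in df["fb"].unique():
            if (a, b) not in counts.index:
                raise InvalidDesignError(
                    f"empty design cell {factor_a}={a}, {factor_b}={b}")
    model = smf.ols("y ~ C(fa) * C(fb)", data=df).fit()
    tab = anova_lm(model, typ=2)
    rename = {"C(fa)": factor_a, "C(fb)": factor_b,
              "C(fa):C(fb)": f"{factor_a}:{factor_b}"}
    tab = tab.rename(index=rename)
    tab = tab.rename(columns={"PR(>F)": "p"})
    tukey = {}
    from .gradient_assoc import tukey_hsd
    for b, grp in df.groupby("fb"):
        if grp["fa"].nunique() >= 2 and grp.groupby("fa").size().min() >= 2:
            tukey[b] = tukey_hsd(grp["y"], grp["fa"])
    return FactorialAnovaResult(table=tab, tukey_within=tukey)
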