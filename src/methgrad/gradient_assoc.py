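"""Per-cytosine association with the expression gradient and cluster calling.

For each cytosine, modification density across samples is correlated with
relative mRNA (Pearson r; two-sided p from the t transform with n-2 df).
P-values are reported as SLP, the signed log p: sign(r) * -log10(p), and
family-wise error is controlled by Bonferroni over the testing universe m
(the number of sites actually tested after coverage/missingness filters).
Runs of >= 3 significant cytosines in which consecutive positions are at most
500 bp apart become cluster calls; chains are split where the correlation
sign flips, so every call has a single direction.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .density import DEFAULT_MIN_SAMPLE_FRACTION, DensityMatrix
from .errors import InvalidArgumentError, InvalidDesignError, ParseError

DEFAULT_ALPHA = 0.01
DEFAULT_MIN_CLUSTER = 3
DEFAULT_MAX_GAP_BP = 500
SLP_CAP = 300.0


@dataclass(frozen=True)
class SiteCorrelation:
    r: float
    r_squared: float
    p: float
    n: int
    degenerate: bool = False


def correlate_site(density, mrna) -> SiteCorrelation:
    """Pearson correlation of one cytosine's densities with relative mRNA.

    NaN pairs are dropped.  Fewer than 4 complete pairs or zero variance in
    either vector yields a degenerate result (r undefined, excluded from the
    testing universe) rather than an error.
    """
    x = np.asarray(density, dtype=float)
    y = np.asarray(mrna, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("density and mrna vectors differ in length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return SiteCorrelation(np.nan, np.nan, np.nan, n, degenerate=True)
    r, p = stats.pearsonr(x, y)
    return SiteCorrelation(float(r), float(r) ** 2, float(p), n)


def slp(r: float, p: float, cap: float = SLP_CAP) -> float:
    """Signed log p: sign(r) * min(-log10 p, cap); p == 0 hits the cap."""
    if not np.isfinite(r):
        return np.nan
    if p < 0 or p > 1:
        raise InvalidArgumentError(f"p-value {p} outside [0,1]")
    mag = cap if p == 0 else min(-math.log10(p), cap)
    return math.copysign(mag, r) if r != 0 else 0.0


def bonferroni(p_values, m: int, alpha: float = DEFAULT_ALPHA):
    """Bonferroni adjustment: p_adj = min(1, m*p); significant iff p_adj < alpha."""
    p = np.asarray(p_values, dtype=float)
    if m < np.isfinite(p).sum():
        raise InvalidArgumentError(
            f"testing universe m={m} smaller than number of tested p-values")
    p_adj = np.minimum(p * m, 1.0)
    with np.errstate(invalid="ignore"):
        sig = p_adj < alpha
    return p_adj, sig & np.isfinite(p_adj)


def associate_sites(density: DensityMatrix, mrna: pd.Series,
                    alpha: float = DEFAULT_ALPHA, m: int | None = None,
                    min_sample_fraction: float = DEFAULT_MIN_SAMPLE_FRACTION,
                    normality: bool = False,
                    cap: float = SLP_CAP) -> pd.DataFrame:
    """Vectorised per-site Pearson association against relative mRNA.

    Returns one row per site with n, r, r2, p, p_bonferroni, slp, significant,
    tested and degenerate flags (and Shapiro-Wilk W/p when ``normality``;
    advisory only, never gates results).  ``m`` defaults to the number of
    tested, non-degenerate sites.
    """
    common = [s for s in density.values.columns if s in mrna.index]
    if len(common) < 4:
        raise InvalidArgumentError("need >= 4 samples shared with the mRNA table")
    D = density.values[common].to_numpy(float)
    y = mrna[common].to_numpy(float)
    mask = np.isfinite(D) & np.isfinite(y)[None, :]
    n = mask.sum(axis=1)
    need = max(4, math.ceil(min_sample_fraction * len(common)))
    tested = n >= need

    W = mask.astype(float)
    X = np.where(mask, D, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Sx, Sy = X.sum(1), W @ y
        Sxx, Syy, Sxy = (X ** 2).sum(1), W @ (y * y), X @ y
        nf = n.astype(float)
        covxy = Sxy - Sx * Sy / np.where(nf > 0, nf, np.nan)
        varx = Sxx - Sx ** 2 / np.where(nf > 0, nf, np.nan)
        vary = Syy - Sy ** 2 / np.where(nf > 0, nf, np.nan)
        denom = np.sqrt(varx * vary)
        r = np.where(denom > 0, covxy / denom, np.nan)
        r = np.clip(r, -1.0, 1.0)
        degenerate = tested & ~np.isfinite(r)
        tt = r * np.sqrt((nf - 2) / np.maximum(1.0 - r ** 2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(tt), nf - 2)
        p = np.where(np.abs(r) >= 1.0, 0.0, p)
    r = np.where(tested, r, np.nan)
    p = np.where(tested & ~degenerate, p, np.nan)

    if m is None:
        m = int((tested & ~degenerate).sum())
    p_adj, sig = bonferroni(p, m=m, alpha=alpha)

    out = density.sites.copy().reset_index(drop=True)
    out["n"] = n
    out["r"] = r
    out["r_squared"] = r ** 2
    out["p"] = p
    out["p_bonferroni"] = p_adj
    out["slp"] = [slp(ri, pi, cap) if np.isfinite(ri) and np.isfinite(pi)
                  else np.nan for ri, pi in zip(r, p)]
    out["significant"] = sig
    out["tested"] = tested
    out["degenerate"] = degenerate
    out.attrs["m"] = m
    if normality:
        w_stat = np.full(len(out), np.nan)
        w_p = np.full(len(out), np.nan)
        for i in range(len(out)):
            x = D[i][mask[i]]
            if len(x) >= 3 and np.ptp(x) > 0:
                res = stats.shapiro(x)
                w_stat[i], w_p[i] = res.statistic, res.pvalue
        out["shapiro_w"] = w_stat
        out["shapiro_p"] = w_p
    return out


# ---------------------------------------------------------------------------
# Cluster calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClusterCall:
    """A maximal run of same-direction significant cytosines within 500 bp gaps."""

    chrom: str
    start: int  # 1-based, position of the first member
    end: int    # 1-based, position of the last member
    members: tuple[int, ...]  # row labels into the association frame
    positions: tuple[int, ...]
    direction: int  # +1 / -1, sign of the members' correlations
    label: str

    @property
    def n(self) -> int:
        return len(self.members)


def detect_clusters(results: pd.DataFrame,
                    min_size: int = DEFAULT_MIN_CLUSTER,
                    max_gap_bp: int = DEFAULT_MAX_GAP_BP,
                    span_cap_bp: int | None = None,
                    direction_col: str = "r") -> list[ClusterCall]:
    """Chain significant sites into cluster calls.

    A chain grows while the next significant site (strand-merged coordinate
    order) is at most ``max_gap_bp`` downstream of the previous member and
    carries the same correlation sign; non-significant sites break nothing by
    themselves but cannot join.  Chains of >= ``min_size`` members become
    calls.  ``span_cap_bp`` switches to the alternative reading in which the
    whole cluster span is capped.
    """
    if min_size < 1 or max_gap_bp <= 0:
        raise InvalidArgumentError("min_size and max_gap_bp must be positive")
    req = {"chrom", "pos", "significant", direction_col}
    if not req.issubset(results.columns):
        raise InvalidArgumentError(f"results frame lacks columns {req}")
    sig = results[results["significant"].astype(bool)]
    calls: list[ClusterCall] = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        grp = grp.sort_values("pos")
        chain: list[tuple] = []  # (row label, pos, sign)
        def flush():
            if len(chain) >= min_size:
                positions = tuple(p for _, p, _ in chain)
                calls.append(ClusterCall(
                    chrom=chrom, start=positions[0], end=positions[-1],
                    members=tuple(i for i, _, _ in chain),
                    positions=positions, direction=chain[0][2],
                    label=f"{chrom}:{positions[0]}-{positions[-1]}"))
        for idx, row in grp.iterrows():
            sgn = 1 if row[direction_col] >= 0 else -1
            pos = int(row["pos"])
            if chain:
                gap_ok = pos - chain[-1][1] <= max_gap_bp
                span_ok = (span_cap_bp is None
                           or pos - chain[0][1] <= span_cap_bp)
                if not (gap_ok and span_ok and sgn == chain[-1][2]):
                    flush()
                    chain = []
            chain.append((idx, pos, sgn))
        flush()
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def clusters_to_bed(calls: list[ClusterCall], path,
                    json_path=None) -> None:
    """Write calls as BED6 (0-based half-open) plus an optional JSON sidecar."""
    with open(path, "w") as fh:
        for c in calls:
            strand = "+" if c.direction > 0 else "-"
            fh.write(f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.label}\t"
                     f"{c.n}\t{strand}\n")
    if json_path is not None:
        payload = [{"label": c.label, "chrom": c.chrom, "start": c.start,
                    "end": c.end, "direction": c.direction,
                    "members": list(map(int, c.members)),
                    "positions": list(map(int, c.positions))} for c in calls]
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=1)


# ---------------------------------------------------------------------------
# Region summaries
# ---------------------------------------------------------------------------

def region_anova(values, groups):
    """One-way ANOVA of per-sample region densities across groups -> (F, p)."""
    v = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups))
    ok = v.notna()
    v, g = v[ok], g[ok]
    sizes = v.groupby(g.to_numpy()).size()
    if len(sizes) < 2 or (sizes < 2).any():
        raise InvalidDesignError("need >= 2 groups with >= 2 samples each")
    arrays = [v[g.to_numpy() == lvl].to_numpy() for lvl in sizes.index]
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (studentized range) as a DataFrame."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    v = pd.Series(np.asarray(values, dtype=float))
    g = pd.Series(np.asarray(groups).astype(str))
    ok = v.notna()
    res = pairwise_tukeyhsd(v[ok].to_numpy(), g[ok].to_numpy(), alpha=alpha)
    pairs = list(itertools.combinations(res.groupsunique, 2))
    return pd.DataFrame({
        "group1": [a for a, _ in pairs],
        "group2": [b for _, b in pairs],
        "meandiff": res.meandiffs,
        "p_adj": res.pvalues,
        "lower": res.confint[:, 0],
        "upper": res.confint[:, 1],
        "reject": res.reject,
    })


# ---------------------------------------------------------------------------
# BED track overlap annotation
# ---------------------------------------------------------------------------

def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Minimal BED reader (0-based half-open); errors name the line number."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}: line {ln}: expected >= 3 BED fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: non-integer coordinates"
                                 ) from exc
            if start < 0 or end <= start:
                raise ParseError(f"{path}: line {ln}: invalid interval "
                                 f"[{start},{end})")
            out.append((parts[0], start, end,
                        parts[3] if len(parts) > 3 else f"iv{ln}"))
    return out


def annotate_overlap(clusters: list[ClusterCall],
                     tracks: dict[str, list[tuple]]) -> pd.DataFrame:
    """Flag, per cluster and track, whether any member cytosine falls in an
    interval (member 1-based position converted to 0-based)."""
    trees: dict[str, dict[str, IntervalTree]] = {}
    for name, ivs in tracks.items():
        per_chrom: dict[str, IntervalTree] = {}
        for iv in ivs:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            per_chrom.setdefault(chrom, IntervalTree()).addi(start, end)
        trees[name] = per_chrom
    flags = {}
    for name, per_chrom in trees.items():
        col = []
        for c in clusters:
            tree = per_chrom.get(c.chrom)
            col.append(bool(tree) and any(tree.overlaps_point(p - 1)
                                          for p in c.positions))
        flags[name] = col
    return pd.DataFrame(flags, index=[c.label for c in clusters])
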