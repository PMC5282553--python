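"""Per-cytosine modification densities: containers, TSV I/O, and filters.

The primary input of the pipeline is a count table holding, for every targeted
cytosine and every enterocyte sample, the number of reads reporting a modified
base and the total read depth.  Densities are the ratio methylated/total and
are only trusted where depth is strictly greater than ``min_reads`` (default
30 reads).  Sites whose mean density saturates (above 90% by default) carry no
usable between-sample deviation and can be masked out entirely.

Coordinates are 1-based internally (tabular genomics convention); BED exports
convert to 0-based half-open.  Opposite-strand cytosines of the same CpG are
distinct sites: no strand collapsing is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyRegionError, InvalidArgumentError, ParseError

SITE_COLUMNS = ["chrom", "pos", "strand", "context"]


def _nanmean(arr: np.ndarray, axis: int) -> np.ndarray:
    """nanmean that returns NaN (silently) for all-NaN slices."""
    finite = np.isfinite(arr)
    cnt = finite.sum(axis=axis)
    sums = np.where(finite, arr, 0.0).sum(axis=axis)
    return np.divide(sums, cnt, out=np.full(cnt.shape, np.nan), where=cnt > 0)

#: depth must be strictly greater than this for a density estimate to be kept
DEFAULT_MIN_READS = 30
#: sites whose group-mean density exceeds this are removed by the saturation filter
DEFAULT_SATURATION = 0.90
#: a site must be non-missing in at least this fraction of samples per compared group
DEFAULT_MIN_SAMPLE_FRACTION = 0.75


@dataclass(eq=False)
class MethylationCountTable:
    """Methylated/total read counts on a site x sample grid.

    Parameters
    ----------
    sites
        DataFrame with columns ``chrom, pos, strand, context`` (pos 1-based;
        context ``CpG`` or ``CpH``), one row per cytosine, RangeIndex aligned
        with the count frames.
    meth, total
        Integer DataFrames (site row index x sample columns) of modified-read
        and total-read counts.
    """

    sites: pd.DataFrame
    meth: pd.DataFrame
    total: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SITE_COLUMNS if c not in self.sites.columns]
        if missing:
            raise InvalidArgumentError(f"sites frame lacks columns {missing}")
        if not (self.meth.shape == self.total.shape
                and len(self.sites) == len(self.meth)):
            raise InvalidArgumentError("sites/meth/total shapes disagree")
        if list(self.meth.columns) != list(self.total.columns):
            raise InvalidArgumentError("meth and total sample columns disagree")
        key = self.sites[["chrom", "pos", "strand"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise InvalidArgumentError(
                f"duplicate site key {dup.chrom}:{dup.pos}({dup.strand})")
        m = self.meth.to_numpy()
        t = self.total.to_numpy()
        if (m < 0).any() or (t < 0).any():
            raise InvalidArgumentError("negative read counts")
        if (m > t).any():
            i, j = np.argwhere(m > t)[0]
            raise InvalidArgumentError(
                f"meth > total at site {self.site_key(i)} sample "
                f"{self.meth.columns[j]}")

    # -- basic introspection ------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.meth.columns)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def site_key(self, i: int) -> str:
        r = self.sites.iloc[i]
        return f"{r.chrom}:{r.pos}({r.strand})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylationCountTable):
            return NotImplemented
        return (self.sites.reset_index(drop=True).equals(
                    other.sites.reset_index(drop=True))
                and self.meth.reset_index(drop=True).equals(
                    other.meth.reset_index(drop=True))
                and self.total.reset_index(drop=True).equals(
                    other.total.reset_index(drop=True)))

    # -- TSV round trip -----------------------------------------------------
    def write_tsv(self, path) -> None:
        """Write the table as TSV with per-sample ``meth,total`` cells."""
        out = self.sites[SITE_COLUMNS].copy()
        for s in self.samples:
            out[s] = (self.meth[s].astype(str) + "," + self.total[s].astype(str))
        out.to_csv(path, sep="\t", index=False)


def read_count_table(path) -> MethylationCountTable:
    """Read a count table written by :meth:`MethylationCountTable.write_tsv`.

    Malformed cells (meth > total, negative or non-integer counts) raise
    :class:`ParseError` naming the offending row and sample.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: header lacks columns {missing}")
    sites = df[SITE_COLUMNS].copy()
    try:
        sites["pos"] = sites["pos"].astype(int)
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer position ({exc})") from exc
    sample_cols = [c for c in df.columns if c not in SITE_COLUMNS]
    meth = {}
    total = {}
    for s in sample_cols:
        if df.empty:
            meth[s] = pd.Series(dtype=int)
            total[s] = pd.Series(dtype=int)
            continue
        parts = df[s].str.split(",", expand=True)
        if parts.shape[1] != 2 or parts.isna().any().any():
            bad = int(df.index[parts.isna().any(axis=1)][0]) if parts.shape[1] == 2 \
                else 0
            raise ParseError(f"{path}: row {bad + 2} sample {s}: "
                             "expected 'meth,total' cell")
        try:
            m = parts[0].astype(int)
            t = parts[1].astype(int)
        except ValueError as exc:
            raise ParseError(f"{path}: sample {s}: non-integer count "
                             f"({exc})") from exc
        bad = (m > t) | (m < 0) | (t < 0)
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path}: row {i + 2} sample {s}: invalid counts "
                f"meth={m.iloc[i]} total={t.iloc[i]}")
        meth[s] = m
        total[s] = t
    meth_df = pd.DataFrame(meth, index=sites.index, dtype=int)
    total_df = pd.DataFrame(total, index=sites.index, dtype=int)
    if not sample_cols:
        meth_df = pd.DataFrame(index=sites.index)
        total_df = pd.DataFrame(index=sites.index)
    return MethylationCountTable(sites=sites, meth=meth_df, total=total_df)


def write_count_table(table: MethylationCountTable, path) -> None:
    table.write_tsv(path)


# ---------------------------------------------------------------------------
# Sample annotation
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["sample", "mouse", "segment", "age", "diet", "sex"]


def validate_annotation(annot: pd.DataFrame, samples=None) -> pd.DataFrame:
    """Check and normalise a sample annotation frame (indexed by sample id)."""
    a = annot.copy()
    if a.index.name != "sample":
        if "sample" in a.columns:
            a = a.set_index("sample")
        else:
            raise InvalidArgumentError("annotation needs a 'sample' column/index")
    for col, default in (("age", "P60"), ("diet", "none"), ("sex", "NA")):
        if col not in a.columns:
            a[col] = default
    if "segment" not in a.columns or "mouse" not in a.columns:
        raise InvalidArgumentError("annotation needs 'mouse' and 'segment' columns")
    a["segment"] = a["segment"].astype(int)
    if not a["segment"].isin(range(1, 10)).all():
        raise InvalidArgumentError("segment must be in 1..9")
    if samples is not None:
        absent = [s for s in samples if s not in a.index]
        if absent:
            raise InvalidArgumentError(f"samples without annotation: {absent[:5]}")
    return a


def read_annotation(path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t"))


def write_annotation(annot: pd.DataFrame, path) -> None:
    validate_annotation(annot).reset_index().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Density matrix and filters
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class DensityMatrix:
    """Per-cytosine modification densities; NaN marks filtered/absent cells."""

    sites: pd.DataFrame
    values: pd.DataFrame  # float, site rows x sample columns

    def __post_init__(self) -> None:
        if len(self.sites) != len(self.values):
            raise InvalidArgumentError("sites/values row counts disagree")
        v = self.values.to_numpy(float)
        with np.errstate(invalid="ignore"):
            if np.nanmin(v, initial=0.0) < 0 or np.nanmax(v, initial=0.0) > 1:
                raise InvalidArgumentError("densities outside [0,1]")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples) -> "DensityMatrix":
        return DensityMatrix(self.sites, self.values[list(samples)])


def compute_density(table: MethylationCountTable,
                    min_reads: int = DEFAULT_MIN_READS) -> DensityMatrix:
    """Densities meth/total where depth is *strictly* above ``min_reads``.

    Cells at or below the threshold (e.g. total = 30 with the default) are
    missing: a 30-read estimate is exactly what the coverage filter excludes.
    """
    t = table.total.to_numpy(float)
    m = table.meth.to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(t > min_reads, m / t, np.nan)
    return DensityMatrix(table.sites.copy(),
                         pd.DataFrame(d, index=table.meth.index,
                                      columns=table.meth.columns))


def saturation_filter(density: DensityMatrix,
                      threshold: float = DEFAULT_SATURATION,
                      samples=None) -> DensityMatrix:
    """Mask sites whose mean density over the analysis group exceeds threshold.

    Heavily modified cytosines sit at the top of the density scale and show no
    between-sample deviation, so they are uninformative for contrasts.  The
    mean is taken over non-missing cells of ``samples`` (default: all).  The
    operation is idempotent: a fully-masked site has no mean and is left alone.
    """
    vals = density.values if samples is None else density.values[list(samples)]
    site_mean = (_nanmean(vals.to_numpy(float), axis=1) if vals.shape[1]
                 else np.full(len(vals), np.nan))
    out = density.values.copy()
    out.iloc[np.nan_to_num(site_mean, nan=0.0) > threshold, :] = np.nan
    return DensityMatrix(density.sites.copy(), out)


def aggregate_region(density: DensityMatrix, start: int, end: int,
                     chrom: str | None = None,
                     context: str = "both") -> pd.Series:
    """Per-sample unweighted mean density over sites in [start, end] (1-based).

    Missing cells are ignored; a sample with no member data yields NaN.
    Raises :class:`EmptyRegionError` when the region covers no sites.
    """
    if context not in ("CpG", "CpH", "both"):
        raise InvalidArgumentError(f"unknown context filter {context!r}")
    s = density.sites
    mask = (s["pos"] >= start) & (s["pos"] <= end)
    if chrom is not None:
        mask &= s["chrom"] == chrom
    if context != "both":
        mask &= s["context"] == context
    if not mask.any():
        raise EmptyRegionError(
            f"region {chrom or '*'}:{start}-{end} ({context}) has no member sites")
    mean = _nanmean(density.values.loc[mask.to_numpy()].to_numpy(float), axis=0)
    return pd.Series(mean, index=density.values.columns, name="region_density")


def aggregate_sites(density: DensityMatrix, row_indices) -> pd.Series:
    """Per-sample mean density over an explicit list of site row indices."""
    rows = list(row_indices)
    if not rows:
        raise EmptyRegionError("empty site list")
    mean = _nanmean(density.values.iloc[rows].to_numpy(float), axis=0)
    return pd.Series(mean, index=density.values.columns, name="region_density")


def sites_to_bed(sites: pd.DataFrame, path, name_prefix: str = "site") -> None:
    """Export site positions as BED6 (0-based half-open)."""
    with open(path, "w") as fh:
        for i, r in sites.reset_index(drop=True).iterrows():
            fh.write(f"{r.chrom}\t{r.pos - 1}\t{r.pos}\t"
                     f"{name_prefix}{i}\t0\t{r.strand}\n")
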