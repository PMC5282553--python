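"""Synthetic data with planted effects for every stage of the pipeline.

The generator emulates a targeted-bisulfite experiment over a ~100 kb
two-gene locus assayed in villi enterocytes from nine small-intestine
segments: ~600 CpG and ~7,000 CpH cytosines, negative-binomial read depth,
binomial methylated-read sampling, and planted cytosine clusters whose
density is tied (inversely) to a per-segment mRNA gradient.  Named scenarios
plant the effect sizes the analysis is expected to recover:

* ``GRAD1`` — adult mRNA gradient peaking at segment 3; the planted C1
  cluster's density runs inversely from 34.7% (segment 3) to 77.1%
  (segment 9).
* ``AGE1`` — uniform infant cluster density (0.45) with adult gains of
  +30 pp (segment 7), +18 pp (segment 1) and +12 pp (segment 3).
* ``DIET1`` — lactose-feeding decreases of 5.2/4.7 pp (exon-12-like cluster,
  segments 7/8), 3.6 pp (intron-8-like, segment 8) and 6.4 pp
  (intron-2-like, segment 8) in the LAC+ arm.
* ``NULL1`` — no density–mRNA link anywhere; used for type-I calibration.

Everything is driven by one :class:`numpy.random.Generator`; identical
(scenario, config, seed) gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .density import MethylationCountTable, validate_annotation
from .errors import InvalidArgumentError, InvalidScenarioError

SEGMENTS = tuple(range(1, 10))

# CpH cytosines carry essentially no modification signal in enterocytes;
# only CpG sites respond to age/diet in this system.
CPH_DENSITY = 0.01


# ---------------------------------------------------------------------------
# Locus model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedCluster:
    cluster_id: str
    start: int  # bp, 1-based inclusive
    end: int
    members: tuple[int, ...]  # row indices into LocusModel.sites


@dataclass(eq=False)
class LocusModel:
    """Site positions/contexts plus the ground-truth planted clusters."""

    locus_name: str
    sites: pd.DataFrame  # columns pos, strand, context; sorted by pos
    planted_clusters: tuple[PlantedCluster, ...]
    chrom: str = "chrLct"

    def __post_init__(self) -> None:
        pos = self.sites["pos"].to_numpy()
        for strand in ("+", "-"):
            p = pos[self.sites["strand"].to_numpy() == strand]
            if len(p) and not (np.diff(p) > 0).all():
                raise InvalidScenarioError(
                    f"positions not strictly increasing on strand {strand}")
        if not self.sites["context"].isin(["CpG", "CpH"]).all():
            raise InvalidScenarioError("context must be CpG or CpH")
        n = len(self.sites)
        for c in self.planted_clusters:
            if any(i < 0 or i >= n for i in c.members):
                raise InvalidScenarioError(
                    f"cluster {c.cluster_id} member index out of range")

    def cluster(self, cluster_id: str) -> PlantedCluster:
        for c in self.planted_clusters:
            if c.cluster_id == cluster_id:
                return c
        raise InvalidArgumentError(f"no planted cluster {cluster_id!r}")

    def truth_bed(self, path) -> None:
        """Write planted clusters as BED6 (0-based half-open)."""
        with open(path, "w") as fh:
            for c in self.planted_clusters:
                fh.write(f"{self.chrom}\t{c.start - 1}\t{c.end}\t"
                         f"{c.cluster_id}\t{len(c.members)}\t.\n")


def generate_locus(n_cpg: int, n_cph: int, span_bp: int, n_clusters: int,
                   seed: int, cluster_sizes: tuple[int, ...] | None = None,
                   cluster_width_bp: int = 450,
                   locus_name: str = "locus") -> LocusModel:
    """Lay out a synthetic locus with tightly grouped planted CpG clusters.

    Each planted cluster spans less than 500 bp and has at least 3 CpG
    members; remaining CpG and all CpH positions are scattered uniformly.
    Deterministic for a fixed seed.
    """
    if n_cpg <= 0 or n_cph < 0:
        raise InvalidArgumentError("site counts must be positive")
    if span_bp <= 0 or n_clusters < 0:
        raise InvalidArgumentError("span and cluster count must be positive")
    if n_cpg < 3 * n_clusters:
        raise InvalidArgumentError("need at least 3 CpGs per planted cluster")
    if cluster_sizes is None:
        # first cluster mirrors the large enhancer cluster (18 CpGs), the
        # rest the smaller promoter/intronic clusters (6 CpGs each)
        cluster_sizes = ((18,) + (6,) * (n_clusters - 1)
                         if n_cpg >= 18 + 6 * (n_clusters - 1) and n_clusters
                         else (3,) * n_clusters)
    cluster_sizes = tuple(int(s) for s in cluster_sizes)
    if len(cluster_sizes) != n_clusters or any(s < 3 for s in cluster_sizes):
        raise InvalidArgumentError("cluster_sizes must give >=3 CpGs per cluster")
    if sum(cluster_sizes) > n_cpg:
        raise InvalidArgumentError("cluster_sizes exceed n_cpg")
    n_total = n_cpg + n_cph
    if n_total > span_bp:
        raise InvalidArgumentError("more sites than base pairs in span")
    if n_clusters and span_bp // n_clusters <= cluster_width_bp + 10:
        raise InvalidArgumentError("span too small to separate planted clusters")

    rng = np.random.default_rng(seed)
    cluster_pos: list[np.ndarray] = []
    block = span_bp // n_clusters if n_clusters else span_bp
    for k, size in enumerate(cluster_sizes):
        center = k * block + block // 2
        offsets = np.sort(rng.choice(cluster_width_bp, size=size, replace=False))
        cluster_pos.append(center + offsets + 1)
    taken = (np.concatenate(cluster_pos) if cluster_pos
             else np.empty(0, dtype=int))

    avail = np.setdiff1d(np.arange(1, span_bp + 1), taken)
    n_bg_cpg = n_cpg - sum(cluster_sizes)
    bg = rng.choice(avail, size=n_bg_cpg + n_cph, replace=False)
    bg_cpg, bg_cph = bg[:n_bg_cpg], bg[n_bg_cpg:]

    pos = np.concatenate([taken, bg_cpg, bg_cph])
    context = np.array(["CpG"] * (len(taken) + n_bg_cpg) + ["CpH"] * n_cph)
    strand = rng.choice(np.array(["+", "-"]), size=n_total)
    order = np.argsort(pos, kind="stable")
    sites = pd.DataFrame({"pos": pos[order].astype(int),
                          "strand": strand[order],
                          "context": context[order]}).reset_index(drop=True)

    sorted_pos = sites["pos"].to_numpy()
    clusters = []
    for k, cp in enumerate(cluster_pos):
        members = tuple(int(i) for i in np.searchsorted(sorted_pos, cp))
        clusters.append(PlantedCluster(cluster_id=f"C{k + 1}",
                                       start=int(cp.min()), end=int(cp.max()),
                                       members=members))
    return LocusModel(locus_name=locus_name, sites=sites,
                      planted_clusters=tuple(clusters))


# ---------------------------------------------------------------------------
# Scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradientScenario:
    """Adult mRNA gradient with an inverse affine link to cluster density."""

    name: str
    segment_mrna_means: tuple[float, ...]  # relative, peak segment = 1
    d_min: float  # cluster density at the mRNA peak
    d_max: float  # cluster density at the mRNA trough
    background_density: float = 0.50
    biological_sd: float = 0.02
    coverage_mean: float = 200.0
    n_mice_per_segment: int = 6
    linked: bool = True  # False => no density-mRNA link (null scenario)
    cluster_id: str = "C1"

    def __post_init__(self) -> None:
        if len(self.segment_mrna_means) != 9:
            raise InvalidScenarioError("need 9 segment mRNA means")
        if any(m <= 0 for m in self.segment_mrna_means):
            raise InvalidScenarioError("segment mRNA means must be positive")
        if not (0 <= self.d_min < self.d_max <= 1):
            raise InvalidScenarioError("require 0 <= d_min < d_max <= 1")
        if not 0 <= self.background_density <= 1:
            raise InvalidScenarioError("background density outside [0,1]")

    def cluster_density(self, mrna) -> np.ndarray:
        """Affine inverse link: mRNA peak -> d_min, mRNA trough -> d_max."""
        m = np.asarray(mrna, dtype=float)
        m_max = max(self.segment_mrna_means)
        m_min = min(self.segment_mrna_means)
        d = self.d_min + (self.d_max - self.d_min) * (m_max - m) / (m_max - m_min)
        return np.clip(d, 0.0, 1.0)


@dataclass(frozen=True)
class AgingScenario:
    """Uniform infant cluster density shifted upward per segment in adults."""

    name: str
    base: GradientScenario
    infant_cluster_density: float
    segment_shifts: dict[int, float]  # segment -> adult gain (fraction)
    segments: tuple[int, ...] = (1, 3, 7)
    cluster_id: str = "C1"

    def __post_init__(self) -> None:
        for seg, shift in self.segment_shifts.items():
            if seg not in SEGMENTS:
                raise InvalidScenarioError(f"segment {seg} outside 1..9")
            d = self.infant_cluster_density + shift
            if not 0 <= d <= 1:
                raise InvalidScenarioError(
                    f"shifted density {d:.3f} outside [0,1] at segment {seg}")


@dataclass(frozen=True)
class DietScenario:
    """LAC+ arm decreases planted cluster densities relative to lac-."""

    name: str
    base: GradientScenario
    baseline_cluster_density: float
    cluster_shifts: dict[tuple[str, int], float]  # (cluster, segment) -> decrease
    segments: tuple[int, ...] = (1, 3, 4, 7, 8)
    n_lac_plus: int = 6
    n_lac_minus: int = 7

    def __post_init__(self) -> None:
        for (cid, seg), dec in self.cluster_shifts.items():
            if seg not in SEGMENTS:
                raise InvalidScenarioError(f"segment {seg} outside 1..9")
            d = self.baseline_cluster_density - dec
            if not 0 <= d <= 1:
                raise InvalidScenarioError(
                    f"shifted density {d:.3f} outside [0,1] at {cid}/seg {seg}")


@dataclass(frozen=True)
class SimulationConfig:
    """Read-depth model and seed; identical config+seed => identical output."""

    seed: int
    coverage_mean: float | None = None  # default: scenario's coverage_mean
    coverage_dispersion: float = 5.0
    low_coverage_fraction: float = 0.05
    low_coverage_range: tuple[int, int] = (5, 30)
    fixed_coverage: int | None = None  # overrides the depth model entirely

    def __post_init__(self) -> None:
        if not 0 <= self.low_coverage_fraction < 1:
            raise InvalidScenarioError("low_coverage_fraction outside [0,1)")


# -- named default scenarios -------------------------------------------------

GRAD1 = GradientScenario(
    name="GRAD-1",
    segment_mrna_means=(0.55, 0.80, 1.00, 0.95, 0.85, 0.60, 0.35, 0.20, 0.10),
    d_min=0.347, d_max=0.771,
    background_density=0.50, biological_sd=0.02,
    coverage_mean=200.0, n_mice_per_segment=6)

NULL1 = dataclasses.replace(GRAD1, name="NULL-1", linked=False)

AGE1 = AgingScenario(
    name="AGE-1",
    base=GRAD1,
    infant_cluster_density=0.45,
    segment_shifts={7: 0.30, 1: 0.18, 3: 0.12})

#: cluster roles in DIET-1: C1 ~ Lct exon 12, C2 ~ Lct intron 8, C3 ~ Lct intron 2
DIET1 = DietScenario(
    name="DIET-1",
    base=GRAD1,
    baseline_cluster_density=0.50,
    cluster_shifts={("C1", 7): 0.052, ("C1", 8): 0.047,
                    ("C2", 8): 0.036, ("C3", 8): 0.064})

SCENARIOS = {s.name: s for s in (GRAD1, NULL1, AGE1, DIET1)}


def default_locus(scenario, seed: int = 0) -> LocusModel:
    """Full-scale locus (609 CpG + 6,971 CpH over 100 kb, 3 planted clusters)."""
    return generate_locus(n_cpg=609, n_cph=6971, span_bp=100_000,
                          n_clusters=3, seed=seed)


# ---------------------------------------------------------------------------
# Expression simulation
# ---------------------------------------------------------------------------

CT_CONTROL = 15.0   # endogenous-control Ct (Villin-1 role), cycles
DCT_REFERENCE = 5.0  # target-minus-control Ct at relative mRNA = 1


def simulate_expression(scenario: GradientScenario, seed: int) -> pd.DataFrame:
    """Per-mouse relative mRNA plus consistent target/control Ct pairs.

    Mice are shared across segments (each of the ``n_mice_per_segment`` mice
    contributes one sample per segment), matching a repeated-measures design.
    Relative mRNA is the segment mean times multiplicative Gaussian noise of
    relative sd ``biological_sd``; with sd = 0 every mouse sits exactly on the
    segment mean.  Ct pairs are constructed so that a noise-free double-delta
    Ct against the segment-3 reference reproduces relative mRNA exactly:
    ``ct_target = CT_CONTROL + DCT_REFERENCE - log2(rel_mrna)``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for seg in SEGMENTS:
        mean = scenario.segment_mrna_means[seg - 1]
        for j in range(1, scenario.n_mice_per_segment + 1):
            noise = rng.normal(0.0, scenario.biological_sd)
            rel = max(mean * (1.0 + noise), 1e-6)
            rows.append({"sample": f"m{j}s{seg}", "mouse": f"m{j}",
                         "segment": seg, "rel_mrna": rel,
                         "ct_target": CT_CONTROL + DCT_REFERENCE - math.log2(rel),
                         "ct_control": CT_CONTROL})
    return pd.DataFrame(rows)


def expression_to_ct_table(expr: pd.DataFrame, target_gene: str = "Lct",
                           control_gene: str = "Vil1",
                           n_replicates: int = 3,
                           tech_sd: float = 0.0,
                           seed: int = 0) -> pd.DataFrame:
    """Expand an expression table into long (sample, gene, replicate, ct) form."""
    rng = np.random.default_rng(seed)
    rows = []
    for _, r in expr.iterrows():
        for gene, ct in ((target_gene, r.ct_target), (control_gene, r.ct_control)):
            for rep in range(1, n_replicates + 1):
                rows.append({"sample": r["sample"], "gene": gene,
                             "replicate": rep,
                             "ct": ct + (rng.normal(0.0, tech_sd) if tech_sd
                                         else 0.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Sample annotation per scenario
# ---------------------------------------------------------------------------

def scenario_annotation(scenario, expression: pd.DataFrame | None = None
                        ) -> pd.DataFrame:
    """Sample annotation (mouse, segment, age, diet, sex) for a scenario."""
    if isinstance(scenario, GradientScenario):
        if expression is None:
            raise InvalidArgumentError(
                "gradient scenarios derive samples from an expression table")
        a = expression[["sample", "mouse", "segment"]].copy()
        a["age"] = "P60"
        a["diet"] = "none"
    elif isinstance(scenario, AgingScenario):
        rows = []
        for age in ("P6", "P60"):
            for seg in scenario.segments:
                for j in range(1, scenario.base.n_mice_per_segment + 1):
                    rows.append({"sample": f"{age}m{j}s{seg}",
                                 "mouse": f"{age}m{j}", "segment": seg,
                                 "age": age, "diet": "none"})
        a = pd.DataFrame(rows)
    elif isinstance(scenario, DietScenario):
        rows = []
        for diet, n in (("LAC+", scenario.n_lac_plus),
                        ("lac-", scenario.n_lac_minus)):
            tag = "p" if diet == "LAC+" else "n"
            for seg in scenario.segments:
                for j in range(1, n + 1):
                    rows.append({"sample": f"{tag}m{j}s{seg}",
                                 "mouse": f"{tag}m{j}", "segment": seg,
                                 "age": "P90", "diet": diet})
        a = pd.DataFrame(rows)
    else:
        raise InvalidArgumentError(f"unknown scenario type {type(scenario)}")
    a["sex"] = "NA"
    return validate_annotation(a)


# ---------------------------------------------------------------------------
# Methylation count simulation
# ---------------------------------------------------------------------------

def _true_densities(locus: LocusModel, scenario, annot: pd.DataFrame,
                    expression: pd.DataFrame | None) -> np.ndarray:
    """Planted per-cell density before mouse-level noise (sites x samples)."""
    n_sites, n_samples = len(locus.sites), len(annot)
    context = locus.sites["context"].to_numpy()
    base = scenario.base if not isinstance(scenario, GradientScenario) else scenario
    dens = np.full((n_sites, n_samples), base.background_density, dtype=float)
    dens[context == "CpH", :] = CPH_DENSITY

    if isinstance(scenario, GradientScenario):
        if scenario.linked:
            if expression is None:
                raise InvalidArgumentError("linked scenario needs expression")
            rel = expression.set_index("sample")["rel_mrna"].reindex(annot.index)
            if rel.isna().any():
                raise InvalidArgumentError("expression missing for some samples")
            cluster = locus.cluster(scenario.cluster_id)
            dens[list(cluster.members), :] = scenario.cluster_density(
                rel.to_numpy())[None, :]
    elif isinstance(scenario, AgingScenario):
        cluster = locus.cluster(scenario.cluster_id)
        seg = annot["segment"].to_numpy()
        adult = (annot["age"] == "P60").to_numpy()
        col = np.full(len(annot), scenario.infant_cluster_density)
        for s, shift in scenario.segment_shifts.items():
            col[adult & (seg == s)] += shift
        dens[list(cluster.members), :] = col[None, :]
    elif isinstance(scenario, DietScenario):
        seg = annot["segment"].to_numpy()
        lac = (annot["diet"] == "LAC+").to_numpy()
        for c in locus.planted_clusters:
            col = np.full(len(annot), scenario.baseline_cluster_density)
            for (cid, s), dec in scenario.cluster_shifts.items():
                if cid == c.cluster_id:
                    col[lac & (seg == s)] -= dec
            dens[list(c.members), :] = col[None, :]
    else:
        raise InvalidArgumentError(f"unknown scenario type {type(scenario)}")

    if dens.min() < 0 or dens.max() > 1:
        raise InvalidScenarioError("planted densities outside [0,1]")
    return dens


def simulate_methylation(locus: LocusModel, scenario,
                         config: SimulationConfig,
                         expression: pd.DataFrame | None = None,
                         annotation: pd.DataFrame | None = None
                         ) -> MethylationCountTable:
    """Draw a count table: NB read depth, binomial methylated reads.

    Per-cell density = planted density + a per-sample Gaussian offset
    (sd ``biological_sd``, truncated so densities stay in [0,1]).  A fraction
    of cells is resampled to depths in ``low_coverage_range`` so the >30-read
    coverage filter is exercised downstream.
    """
    annot = (annotation if annotation is not None
             else scenario_annotation(scenario, expression))
    base = scenario.base if not isinstance(scenario, GradientScenario) else scenario
    rng = np.random.default_rng(config.seed)
    dens = _true_densities(locus, scenario, annot, expression)
    n_sites, n_samples = dens.shape

    offsets = rng.normal(0.0, base.biological_sd, size=n_samples)
    dens = np.clip(dens + offsets[None, :], 0.0, 1.0)

    if config.fixed_coverage is not None:
        totals = np.full(dens.shape, int(config.fixed_coverage))
    else:
        mean = (config.coverage_mean if config.coverage_mean is not None
                else base.coverage_mean)
        r = config.coverage_dispersion
        p = r / (r + mean)
        totals = rng.negative_binomial(r, p, size=dens.shape)
        totals = np.maximum(totals, 1)
        if config.low_coverage_fraction > 0:
            lo, hi = config.low_coverage_range
            mask = rng.random(dens.shape) < config.low_coverage_fraction
            totals[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    meth = rng.binomial(totals, dens)

    sites = locus.sites.copy()
    sites.insert(0, "chrom", locus.chrom)
    cols = list(annot.index)
    return MethylationCountTable(
        sites=sites,
        meth=pd.DataFrame(meth, columns=cols),
        total=pd.DataFrame(totals, columns=cols))


@dataclass(eq=False)
class SimulatedDataset:
    """Everything one scenario run produces, ready for the analysis stages."""

    scenario_name: str
    locus: LocusModel
    counts: MethylationCountTable
    annotation: pd.DataFrame
    expression: pd.DataFrame | None


def simulate_scenario(name_or_scenario, seed: int,
                      locus: LocusModel | None = None,
                      config: SimulationConfig | None = None
                      ) -> SimulatedDataset:
    """One-call simulation of a named (or custom) scenario."""
    scenario = (SCENARIOS[name_or_scenario]
                if isinstance(name_or_scenario, str) else name_or_scenario)
    if locus is None:
        locus = default_locus(scenario, seed=0)
    if config is None:
        config = SimulationConfig(seed=seed)
    expression = (simulate_expression(scenario, seed=seed + 1)
                  if isinstance(scenario, GradientScenario) else None)
    annot = scenario_annotation(scenario, expression)
    counts = simulate_methylation(locus, scenario, config,
                                  expression=expression, annotation=annot)
    return SimulatedDataset(scenario_name=getattr(scenario, "name", "custom"),
                            locus=locus, counts=counts, annotation=annot,
                            expression=expression)


# ---------------------------------------------------------------------------
# ChIP-qPCR simulation
# ---------------------------------------------------------------------------

#: CTCF-like adult occupancy (net percent input) peaking at segment 3
ADULT_CHIP_PROFILE = {
    "Mcm6_int13": {1: 2.0, 3: 6.0, 5: 3.0, 7: 1.2, 9: 0.6},
    "Lct_int8":   {1: 1.0, 3: 2.5, 5: 1.5, 7: 0.8, 9: 0.4},
    "Lct_int2":   {1: 1.5, 3: 4.0, 5: 2.0, 7: 1.0, 9: 0.5},
    "Lct_ex1":    {1: 1.0, 3: 3.0, 5: 1.8, 7: 0.9, 9: 0.5},
}
#: infant occupancy: background everywhere (absence of binding)
INFANT_CHIP_PROFILE = {locus: {seg: 0.0 for seg in segs}
                       for locus, segs in ADULT_CHIP_PROFILE.items()}


def simulate_chip(segments, age_group: str, profile: dict, seed: int,
                  n_mice: int = 3, input_fraction: float = 0.01,
                  ct_input_mean: float = 30.0, igg_percent: float = 0.1,
                  noise_sd: float = 0.1) -> pd.DataFrame:
    """ChIP-qPCR Ct table whose percent-input recovers the planted enrichment.

    ``profile[locus][segment]`` is the planted *net* percent input (target
    minus IgG background); the emitted target percent input is the planted
    value plus ``igg_percent`` so that IgG subtraction recovers it in
    expectation.  Cts follow the standard identity: a locus recovered at P%
    of input measured against an ``input_fraction`` aliquot has
    ``ct_ip = ct_input + log2(100 * input_fraction / P)``.
    ``noise_sd`` (cycles) is added independently to every Ct.
    """
    if not 0 < input_fraction <= 1:
        raise InvalidArgumentError("input_fraction must be in (0, 1]")
    if igg_percent <= 0:
        raise InvalidArgumentError("igg_percent must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for locus, by_seg in profile.items():
        for seg in segments:
            if seg not in by_seg:
                raise InvalidArgumentError(
                    f"profile for {locus} lacks segment {seg}")
            target_pct = by_seg[seg] + igg_percent
            for j in range(1, n_mice + 1):
                ct_input = ct_input_mean + (rng.normal(0, noise_sd) if noise_sd
                                            else 0.0)
                ct_ip = (ct_input
                         + math.log2(100.0 * input_fraction / target_pct)
                         + (rng.normal(0, noise_sd) if noise_sd else 0.0))
                ct_igg = (ct_input
                          + math.log2(100.0 * input_fraction / igg_percent)
                          + (rng.normal(0, noise_sd) if noise_sd else 0.0))
                rows.append({"locus": locus, "segment": seg,
                             "mouse": f"{age_group}c{j}", "age": age_group,
                             "ct_ip": ct_ip, "ct_input": ct_input,
                             "input_fraction": input_fraction,
                             "ct_igg": ct_igg})
    return pd.DataFrame(rows)
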