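import numpy as np
import pandas as pd
import pytest

import methgrad as mg


@pytest.fixture(scope="session")
def small_locus():
    """Compact locus: 60 CpG + 100 CpH over 10 kb with 2 planted clusters."""
    return mg.generate_locus(n_cpg=60, n_cph=100, span_bp=10_000,
                             n_clusters=2, seed=7, cluster_sizes=(6, 4))


@pytest.fixture(scope="session")
def full_locus():
    """Full-scale locus matching the targeted experiment's footprint."""
    return mg.default_locus(mg.GRAD1, seed=0)


@pytest.fixture(scope="session")
def grad_dataset(full_locus):
    return mg.simulate_scenario("GRAD-1", seed=11, locus=full_locus)


def make_count_table(meth, total, positions=None, contexts=None,
                     samples=None, chrom="chrT"):
    """Small helper to build a count table from plain 2-D lists/arrays."""
    meth = np.atleast_2d(np.asarray(meth))
    total = np.atleast_2d(np.asarray(total))
    n_sites, n_samples = meth.shape
    positions = positions if positions is not None else np.arange(
        100, 100 + 10 * n_sites, 10)
    contexts = contexts if contexts is not None else ["CpG"] * n_sites
    samples = samples if samples is not None else [f"s{j}" for j in
                                                   range(n_samples)]
    sites = pd.DataFrame({"chrom": chrom, "pos": positions,
                          "strand": "+", "context": contexts})
    return mg.MethylationCountTable(
        sites=sites,
        meth=pd.DataFrame(meth, columns=samples),
        total=pd.DataFrame(total, columns=samples))


def naive_cluster_oracle(positions, significant, signs, min_size=3,
                         max_gap_bp=500):
    """Quadratic chain enumeration: independent reference for detect_clusters.

    Builds the adjacency relation between all pairs of significant sites
    (same sign, gap <= max_gap_bp between *consecutive* significant sites)
    and enumerates maximal runs.
    """
    order = np.argsort(positions, kind="stable")
    sig = [(int(positions[i]), int(np.sign(signs[i]) or 1), int(i))
           for i in order if significant[i]]
    clusters = []
    i = 0
    while i < len(sig):
        j = i
        while (j + 1 < len(sig)
               and sig[j + 1][0] - sig[j][0] <= max_gap_bp
               and sig[j + 1][1] == sig[j][1]):
            j += 1
        run = sig[i:j + 1]
        if len(run) >= min_size:
            clusters.append(tuple(p for p, _, _ in run))
        i = j + 1
    return clusters
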