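"""Shared test utilities: micro-table builders and independent oracles.

Every oracle here is deliberately written from the defining formula or by
exhaustive enumeration, independent of the library code paths it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from rootcue.feature_table import FeatureTable


# --------------------------------------------------------------------------
# table builders
# --------------------------------------------------------------------------
def micro_table(specs, intensities, root_types=None, genotypes=None) -> FeatureTable:
    """Build a FeatureTable from (feature_id, mz, rt) specs and a 2-D array."""
    intensities = np.asarray(intensities, dtype=float)
    n_samples = intensities.shape[1]
    fids = [s[0] for s in specs]
    features = pd.DataFrame(
        {"mz": [s[1] for s in specs], "rt": [s[2] for s in specs]},
        index=pd.Index(fids, name="feature_id"),
    )
    if root_types is None:
        root_types = ["embryonic" if i < n_samples // 2 else "postembryonic"
                      for i in range(n_samples)]
    if genotypes is None:
        genotypes = ["WT"] * n_samples
    sample_ids = [f"s{i}" for i in range(n_samples)]
    samples = pd.DataFrame(
        {"root_type": root_types, "genotype": genotypes,
         "replicate": list(range(1, n_samples + 1))},
        index=pd.Index(sample_ids, name="sample_id"),
    )
    intens = pd.DataFrame(intensities, index=features.index, columns=sample_ids)
    return FeatureTable(features, intens, samples)


def random_table(rng, n_features=30, n_samples=8) -> FeatureTable:
    """Random table with clumped retention times to exercise grouping."""
    rts = rng.uniform(0.5, 2.0, n_features)
    # clump a third of the features around shared apexes
    for k in range(0, n_features, 3):
        rts[k : k + 2] = rts[k] + rng.uniform(-0.02, 0.02, size=len(rts[k : k + 2]))
    specs = [(f"f{i:03d}", 100 + i, rts[i]) for i in range(n_features)]
    base = rng.lognormal(8, 1, size=(n_features, n_samples))
    # make neighbouring features correlated sometimes
    for k in range(0, n_features - 1, 3):
        shared = rng.lognormal(8, 1, size=n_samples)
        base[k] = shared * rng.lognormal(0, 0.05, n_samples)
        base[k + 1] = shared * rng.lognormal(0, 0.05, n_samples)
    return micro_table(specs, base)


# --------------------------------------------------------------------------
# grouping oracle: brute-force union-find over the explicit edge list
# --------------------------------------------------------------------------
def union_find_groups(table: FeatureTable, rt_window=0.04, r_min=0.8):
    ids = list(table.feature_ids)
    rt = table.features["rt"].to_dict()
    X = table.intensities
    parent = {f: f for f in ids}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for a, b in itertools.combinations(ids, 2):
        if abs(rt[a] - rt[b]) > rt_window:
            continue
        xa, xb = X.loc[a].to_numpy(), X.loc[b].to_numpy()
        if xa.std(ddof=1) == 0 or xb.std(ddof=1) == 0:
            continue  # correlation undefined
        r = np.corrcoef(xa, xb)[0, 1]
        if r > r_min:
            union(a, b)
    comps: dict[str, set] = {}
    for f in ids:
        comps.setdefault(find(f), set()).add(f)
    return {frozenset(c) for c in comps.values()}


# --------------------------------------------------------------------------
# textbook pooled t-test from the t CDF
# --------------------------------------------------------------------------
def pooled_t_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


# --------------------------------------------------------------------------
# Wilcoxon signed-rank: exhaustive enumeration over sign patterns
# --------------------------------------------------------------------------
def wilcoxon_enumeration_oracle(diffs):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    total = ranks.sum()
    lo, hi = min(w_obs, total - w_obs), max(w_obs, total - w_obs)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= lo + 1e-9 or w >= hi - 1e-9:
            count += 1
    return min(count / 2**n, 1.0)


# --------------------------------------------------------------------------
# Kruskal-Wallis H with tie correction, from the textbook formula
# --------------------------------------------------------------------------
def kruskal_formula_oracle(groups):
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1 - (counts**3 - counts).sum() / (n**3 - n)
    return h / correction


# --------------------------------------------------------------------------
# Spearman exact permutation oracle (full n! enumeration)
# --------------------------------------------------------------------------
def spearman_permutation_oracle(x, y):
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho_obs = np.corrcoef(rx, ry)[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(range(len(y))):
        rho = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


# --------------------------------------------------------------------------
# compound-level recovery against ground truth
# --------------------------------------------------------------------------
def recovery_stats(results, curator, truth, label_by_direction):
    """Sensitivity / false discoveries of a differential screen vs GroundTruth.

    *label_by_direction* maps planted direction -> expected enrichment label.
    Returns (n_true_positive, n_false_positive, n_planted).
    """
    membership = truth.group_membership
    planted = dict(truth.diff_compounds)
    tp_compounds = set()
    fp = 0
    for fid, row in results.iterrows():
        if row["enrichment"] == "not_significant":
            continue
        comp = membership.get(fid)
        want = label_by_direction.get(planted.get(comp))
        if want == row["enrichment"]:
            tp_compounds.add(comp)
        else:
            fp += 1
    return len(tp_compounds), fp, len(planted)
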