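"""Statistics for herbivore choice assays, damage scoring and
preference-performance correlation.

Choice assays release a fixed number of larvae per dish and count how many
sit on each of two options at each timepoint; larvae on neither option are
"undecided" and excluded from the binomial denominator by default. The
preference test fits, per treatment x timepoint cell, an intercept-only
binomial model of the option-A count, estimates the Pearson dispersion over
dishes and, when it exceeds 1, inflates the Wald standard error by its
square root (the quasi-binomial correction); p-values are BH-adjusted
across the cells of an experiment. Cells with all larvae on one option fall
back to an exact binomial test, where the Wald statistic degenerates.

Root damage is scored per root on an ordinal 0-5 scale (no visible damage
up to root fully removed). The embryonic-vs-postembryonic comparison is a
Wilcoxon signed-rank test on paired per-plant mean scores with zeros
dropped; the exact null distribution is enumerated (via the standard
generating-function convolution over signed midranks) for up to 15 nonzero
pairs, with a tie-corrected continuity-corrected normal approximation
beyond. Treatment comparisons use Kruskal-Wallis with tie correction,
followed by Tukey HSD on joint midranks with a compact letter display.
Preference-performance association is a Spearman rank correlation with an
exact permutation p-value for n <= 9.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffstats import bh_fdr


# --------------------------------------------------------------------------
# choice-assay preference test
# --------------------------------------------------------------------------
def _cell_preference(count_a: np.ndarray, count_b: np.ndarray) -> dict:
    totals = count_a + count_b
    used = totals > 0
    a = int(count_a[used].sum())
    b = int(count_b[used].sum())
    n = a + b
    k = int(used.sum())
    if n == 0:
        return {"skipped": True}
    phat = a / n
    if a == 0 or b == 0:
        p = stats.binomtest(a, n, 0.5).pvalue
        return {
            "skipped": False, "n_dishes": k, "n_decided": n, "prop_a": phat,
            "logit": np.inf if b == 0 else -np.inf, "se": np.nan,
            "dispersion": np.nan, "p": float(p), "method": "exact-binomial",
        }
    logit = np.log(a / b)
    se = np.sqrt(1.0 / a + 1.0 / b)
    # Pearson dispersion over dishes (intercept-only binomial GLM)
    expect = totals[used] * phat
    var = totals[used] * phat * (1 - phat)
    x2 = float(np.sum((count_a[used] - expect) ** 2 / var))
    dispersion = x2 / (k - 1) if k > 1 else 1.0
    if dispersion > 1:
        se *= np.sqrt(dispersion)
    z = logit / se
    p = 2.0 * stats.norm.sf(abs(z))
    return {
        "skipped": False, "n_dishes": k, "n_decided": n, "prop_a": phat,
        "logit": float(logit), "se": float(se), "dispersion": float(dispersion),
        "p": float(p), "method": "wald-quasibinomial" if dispersion > 1 else "wald",
    }


def preference_test(
    records: pd.DataFrame,
    by: tuple[str, ...] = ("treatment", "timepoint"),
) -> pd.DataFrame:
    """Per-cell preference estimates with dispersion-corrected Wald tests.

    *records* columns: ``count_a``, ``count_b`` per dish plus the grouping
    columns in *by*. Undecided larvae (released minus counted) are excluded
    from the denominator. Returns one row per cell with the estimate,
    dispersion, raw p and BH-adjusted q across all cells.
    """
    rows = []
    keys = []
    for key, grp in records.groupby(list(by), sort=True):
        res = _cell_preference(
            grp["count_a"].to_numpy(dtype=float),
            grp["count_b"].to_numpy(dtype=float),
        )
        if res.pop("skipped"):
            warnings.warn(f"cell {key}: no decided larvae; skipped", stacklevel=2)
            continue
        keys.append(key if isinstance(key, tuple) else (key,))
        rows.append(res)
    if not rows:
        return pd.DataFrame(columns=list(by))
    out = pd.DataFrame(rows)
    out[list(by)] = pd.DataFrame(keys, columns=list(by))
    out["q"] = bh_fdr(out["p"])
    return out[list(by) + [c for c in out.columns if c not in by]]


# --------------------------------------------------------------------------
# Wilcoxon signed-rank with exact small-sample null
# --------------------------------------------------------------------------
@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of positive signed ranks)
    n_used: int  # nonzero pairs
    p: float
    method: str
    no_difference: bool = False


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p via convolution of the signed-rank distribution.

    Midranks are doubled to integers; the null distribution of 2*W+ is the
    convolution of fair coin flips over rank weights. The two-sided p is
    P(W+ <= min(w, S-w)) + P(W+ >= max(w, S-w)), capped at 1.
    """
    r2 = np.round(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = 0.5 * (dist + shifted)
    w2 = int(round(2 * w_plus))
    lo = min(w2, total - w2)
    hi = max(w2, total - w2)
    p = dist[: lo + 1].sum() + dist[hi:].sum()
    return float(min(p, 1.0))


def wilcoxon_signed_rank(
    x, y=None, exact_max_n: int = 15
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test with drop-zeros convention.

    Tests the symmetry of ``x - y`` (or of *x* alone when *y* is omitted)
    about zero. Zero differences are dropped. The null distribution is
    enumerated exactly for up to *exact_max_n* nonzero pairs (ties handled
    through midranks); larger samples use the tie-corrected normal
    approximation with continuity correction.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    nonzero = d[d != 0]
    n = len(nonzero)
    if n == 0:
        return WilcoxonResult(0.0, 0, float("nan"), "degenerate", True)
    if n < 2:
        warnings.warn("fewer than 2 nonzero pairs; p undefined", stacklevel=2)
        return WilcoxonResult(float(nonzero[0] > 0), n, float("nan"), "degenerate")
    ranks = stats.rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    if n <= exact_max_n:
        p = _exact_signed_rank_p(ranks, w_plus)
        return WilcoxonResult(w_plus, n, p, "exact")
    mean = n * (n + 1) / 4.0
    # variance with tie correction over midrank groups
    _, counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (counts**3 - counts).sum() / 48.0
    diff = w_plus - mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return WilcoxonResult(w_plus, n, min(p, 1.0), "normal-approx")


def damage_roottype_test(records: pd.DataFrame) -> dict:
    """Embryonic vs postembryonic damage via paired per-plant mean scores.

    *records* columns: ``plant_id``, ``root_type``, ``score``. Every plant
    must carry both root types. Returns the per-plant means, the signed-rank
    statistic and p-value.
    """
    means = records.pivot_table(
        index="plant_id", columns="root_type", values="score", aggfunc="mean"
    )
    if means.isna().any().any():
        raise ValueError("every plant needs scores for both root types")
    res = wilcoxon_signed_rank(
        means["postembryonic"].to_numpy(), means["embryonic"].to_numpy()
    )
    return {
        "per_plant_means": means,
        "statistic": res.statistic,
        "n_pairs": res.n_used,
        "p": res.p,
        "method": res.method,
        "no_difference": res.no_difference,
    }


# --------------------------------------------------------------------------
# Kruskal-Wallis with Tukey-on-ranks post hoc
# --------------------------------------------------------------------------
def _compact_letters(names: list[str], sig: np.ndarray) -> dict[str, str]:
    """Insert-and-absorb compact letter display from a significance matrix."""
    letters: list[set[str]] = [set(names)]  # start: everyone shares a letter
    for i, j in zip(*np.where(np.triu(sig, 1))):
        a, b = names[i], names[j]
        for grp in list(letters):
            if a in grp and b in grp:
                letters.remove(grp)
                g1, g2 = grp - {a}, grp - {b}
                for g in (g1, g2):
                    if g and not any(g <= other for other in letters):
                        letters.append(g)
    letters.sort(key=lambda g: sorted(g))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for lab, grp in zip(alphabet, letters):
        for name in grp:
            out[name] += lab
    return out


def damage_treatment_test(
    scores: pd.DataFrame,
    value_col: str = "score",
    group_col: str = "treatment",
    alpha: float = 0.05,
) -> dict:
    """Kruskal-Wallis on ranks across treatments plus Tukey HSD post hoc.

    *scores* holds one row per experimental unit (e.g. per-plant mean
    damage). All-tied data short-circuit to H=0, p=1. Post hoc pairwise
    comparisons apply Tukey's HSD to the joint midranks and emit a compact
    letter display (treatments sharing a letter are not separable).
    """
    groups = [grp[value_col].to_numpy(dtype=float)
              for _, grp in scores.groupby(group_col, sort=True)]
    names = [str(k) for k, _ in scores.groupby(group_col, sort=True)]
    if len(groups) < 2 or min(len(g) for g in groups) < 2:
        raise ValueError("need >= 2 treatments with >= 2 units each")
    pooled = np.concatenate(groups)
    if np.allclose(pooled, pooled[0]):
        return {"H": 0.0, "p": 1.0, "posthoc": None,
                "letters": {n: "a" for n in names}}
    H, p = stats.kruskal(*groups)

    ranks = stats.rankdata(pooled)
    rank_groups, start = [], 0
    for g in groups:
        rank_groups.append(ranks[start : start + len(g)])
        start += len(g)
    tuk = stats.tukey_hsd(*rank_groups)
    pmat = tuk.pvalue
    posthoc = pd.DataFrame(pmat, index=names, columns=names)
    letters = _compact_letters(names, pmat < alpha)
    return {"H": float(H), "p": float(p), "posthoc": posthoc, "letters": letters}


# --------------------------------------------------------------------------
# preference-performance correlation
# --------------------------------------------------------------------------
def performance_correlation(
    x, y, exact_max_n: int = 9
) -> tuple[float, float, str]:
    """Spearman rank correlation with exact permutation p for small n.

    Uses midranks for ties. For n <= *exact_max_n* the p-value enumerates
    all n! permutations of one margin (two-sided on |rho|); otherwise the
    usual t approximation applies. Constant input is flagged (rho NaN).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("constant vector; Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan"), "degenerate"
    rho, p_t = stats.spearmanr(x, y)
    rho = float(rho)
    if n > exact_max_n:
        return rho, float(p_t), "t-approx"
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    perms = np.array(list(itertools.permutations(range(n))))
    rho_null = (rx[perms] * ry).mean(axis=1) / 1.0
    count = np.sum(np.abs(rho_null) >= abs(rho) - 1e-12)
    return rho, float(count / len(perms)), "exact-permutation"
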