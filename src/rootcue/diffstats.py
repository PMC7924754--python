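"""Normalization and differential screening of curated feature tables.

Raw peak areas are variance-stabilized with the inverse hyperbolic sine,
``arcsinh(x) = ln(x + sqrt(x^2 + 1))``, which behaves like ``ln(2x)`` for
large intensities but is defined at zero. Per-feature two-sample Student
t-tests (pooled variance by default, Welch optional) compare the two root
types on the transformed scale; p-values are Benjamini-Hochberg adjusted
across features, and a fold-change cut-off on the *raw* intensity means
classifies features into a volcano-style enrichment call.

For the root-type x genotype design, a per-feature fixed-effects two-way
ANOVA with interaction (Type II sums of squares on unbalanced data) screens
for interaction and genotype main effects. The residual-projection
computation is vectorized across features: the four design matrices are
shared, so each model's residual sum of squares for every feature comes
from one QR decomposition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .feature_table import FeatureTable

NOT_SIGNIFICANT = "not_significant"


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------
def arcsinh_transform(x):
    """Inverse hyperbolic sine, ln(x + sqrt(x^2+1)); requires x >= 0."""
    arr = np.asarray(x, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("intensities must be finite")
    if (arr < 0).any():
        raise ValueError("intensities must be non-negative")
    out = np.arcsinh(arr)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def feature_t_test(a, b, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance unless *welch*).

    Degenerate zero-variance input follows the documented convention:
    equal means give (t=0, p=1); unequal means with zero pooled variance
    give p=0 with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("observations must be finite")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("zero pooled variance with unequal means", stacklevel=2)
        return np.inf if a.mean() > b.mean() else -np.inf, 0.0
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change(mean_a: float, mean_b: float) -> tuple[float, str]:
    """Raw-intensity fold change as a ratio >= 1 with a direction label.

    Returns (ratio, direction) where direction is "A", "B" or "none".
    A zero mean in one group gives an infinite ratio; both zero is
    flagged (ratio 1, direction "none").
    """
    if mean_a < 0 or mean_b < 0:
        raise ValueError("means must be non-negative")
    if mean_a == mean_b == 0:
        warnings.warn("both means are zero; fold change undefined", stacklevel=2)
        return 1.0, "none"
    if mean_a == mean_b:
        return 1.0, "none"
    if mean_b == 0:
        return np.inf, "A"
    if mean_a == 0:
        return np.inf, "B"
    return (
        (mean_a / mean_b, "A") if mean_a > mean_b else (mean_b / mean_a, "B")
    )


# --------------------------------------------------------------------------
# volcano screen
# --------------------------------------------------------------------------
@dataclass
class DifferentialResult:
    feature_id: str
    mean_a: float
    mean_b: float
    fold_change: float
    direction: str
    t_stat: float
    p: float
    q: float
    enrichment: str


class DifferentialScreen(BaseEstimator):
    """Per-feature two-sample screen between the two levels of one factor.

    Parameters
    ----------
    factor, level_a, level_b:
        Sample-metadata column and the two levels compared (level A minus
        level B, A-up meaning enriched in ``level_a``).
    sample_filter:
        Optional dict restricting samples first, e.g. ``{"genotype": "WT"}``
        for the wild-type-only screen.
    alpha, fc_cut:
        Significance threshold and fold-change cut (both strict: q (or p)
        below alpha AND ratio above fc_cut).
    p_mode:
        ``"fdr"`` thresholds the BH-adjusted q (default), ``"raw"`` the
        unadjusted p.
    welch:
        Use Welch's unequal-variance t-test instead of the pooled test.

    Fitted attributes: ``results_`` (per-feature DataFrame),
    ``class_counts_`` (dict of enrichment-class counts).
    """

    def __init__(
        self,
        factor: str = "root_type",
        level_a: str = "postembryonic",
        level_b: str = "embryonic",
        sample_filter: dict | None = None,
        alpha: float = 0.05,
        fc_cut: float = 2.0,
        p_mode: str = "fdr",
        welch: bool = False,
    ):
        self.factor = factor
        self.level_a = level_a
        self.level_b = level_b
        self.sample_filter = sample_filter
        self.alpha = alpha
        self.fc_cut = fc_cut
        self.p_mode = p_mode
        self.welch = welch

    def fit(self, table: FeatureTable):
        if self.p_mode not in ("fdr", "raw"):
            raise ValueError("p_mode must be 'fdr' or 'raw'")
        sub = table.subset_samples(self.sample_filter)
        meta = sub.samples
        ids_a = meta.index[meta[self.factor] == self.level_a]
        ids_b = meta.index[meta[self.factor] == self.level_b]
        if len(ids_a) < 2 or len(ids_b) < 2:
            raise ValueError("each level needs at least 2 samples")

        raw_a = sub.intensities[ids_a].to_numpy()
        raw_b = sub.intensities[ids_b].to_numpy()
        ta = arcsinh_transform(raw_a)
        tb = arcsinh_transform(raw_b)

        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(ta, tb, axis=1, equal_var=not self.welch)
        t = np.asarray(t, dtype=float)
        p = np.asarray(p, dtype=float)
        # zero-variance conventions
        degen = ~np.isfinite(p)
        if degen.any():
            eq = degen & np.isclose(ta.mean(axis=1), tb.mean(axis=1))
            t[eq], p[eq] = 0.0, 1.0
            ne = degen & ~eq
            t[ne] = np.where(ta.mean(axis=1)[ne] > tb.mean(axis=1)[ne], np.inf, -np.inf)
            p[ne] = 0.0
        q = bh_fdr(p)

        mean_a = raw_a.mean(axis=1)
        mean_b = raw_b.mean(axis=1)
        with np.errstate(divide="ignore"):
            hi = np.maximum(mean_a, mean_b)
            lo = np.minimum(mean_a, mean_b)
            ratio = np.where(lo > 0, hi / lo, np.where(hi > 0, np.inf, 1.0))
        direction = np.where(
            mean_a > mean_b, "A", np.where(mean_b > mean_a, "B", "none")
        )

        crit = q if self.p_mode == "fdr" else p
        significant = (crit < self.alpha) & (ratio > self.fc_cut)
        label_a = f"{self.level_a}_enriched"
        label_b = f"{self.level_b}_enriched"
        enrichment = np.where(
            significant & (direction == "A"),
            label_a,
            np.where(significant & (direction == "B"), label_b, NOT_SIGNIFICANT),
        )

        self.results_ = pd.DataFrame(
            {
                "mean_a": mean_a,
                "mean_b": mean_b,
                "fold_change": ratio,
                "direction": direction,
                "t_stat": t,
                "p": p,
                "q": q,
                "enrichment": enrichment,
            },
            index=sub.feature_ids,
        )
        counts = self.results_["enrichment"].value_counts()
        self.class_counts_ = {
            label_a: int(counts.get(label_a, 0)),
            label_b: int(counts.get(label_b, 0)),
            NOT_SIGNIFICANT: int(counts.get(NOT_SIGNIFICANT, 0)),
        }
        return self


def differential_screen(table: FeatureTable, **params) -> pd.DataFrame:
    """Functional wrapper around :class:`DifferentialScreen`."""
    return DifferentialScreen(**params).fit(table).results_


def volcano_classify(
    results: pd.DataFrame, alpha: float = 0.05, fc_cut: float = 2.0,
    label_a: str = "postembryonic_enriched", label_b: str = "embryonic_enriched",
    p_col: str = "q",
) -> pd.Series:
    """Re-classify an existing results frame under new thresholds."""
    significant = (results[p_col] < alpha) & (results["fold_change"] > fc_cut)
    return pd.Series(
        np.where(
            significant & (results["direction"] == "A"),
            label_a,
            np.where(
                significant & (results["direction"] == "B"), label_b, NOT_SIGNIFICANT
            ),
        ),
        index=results.index,
        name="enrichment",
    )


def plot_volcano(results: pd.DataFrame, path=None, alpha: float = 0.05):
    """Volcano plot (log2 fold change vs -log10 q), optionally written to *path*."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    signed = np.where(
        results["direction"] == "B", -1.0, 1.0
    ) * np.log2(np.clip(results["fold_change"], 1.0, 1e12))
    neglog = -np.log10(np.clip(results["q"], 1e-300, 1.0))
    colors = np.where(results["enrichment"] == NOT_SIGNIFICANT, "0.6", "crimson")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(signed, neglog, s=6, c=colors, linewidths=0)
    ax.axhline(-np.log10(alpha), ls=":", c="k", lw=0.8)
    for x in (-1, 1):
        ax.axvline(x, ls=":", c="k", lw=0.8)
    ax.set_xlabel("signed log2 fold change (A vs B)")
    ax.set_ylabel("-log10 q")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


# --------------------------------------------------------------------------
# two-way ANOVA screen
# --------------------------------------------------------------------------
def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual sum of squares of Y ~ X for every column-feature of Y."""
    Q, _ = np.linalg.qr(X)
    proj = Q.T @ Y
    return (Y**2).sum(axis=0) - (proj**2).sum(axis=0)


class TwoWayAnovaScreen(BaseEstimator):
    """Per-feature fixed-effects two-way ANOVA with interaction.

    Factors default to ``root_type`` and ``genotype``. Main-effect sums of
    squares are Type II (each main effect adjusted for the other, the
    interaction adjusted for both), which reduces to the classical balanced
    decomposition when cell sizes are equal. Tests run on
    arcsinh-transformed intensities; p-values are BH-adjusted per term
    across features.

    Fitted attribute ``results_``: DataFrame with F, p and q per term
    (``F_<factor>``, ``p_<factor>``, ``q_<factor>``, and ``*_interaction``).
    """

    def __init__(
        self,
        factor_a: str = "root_type",
        factor_b: str = "genotype",
        ss_type: int = 2,
    ):
        self.factor_a = factor_a
        self.factor_b = factor_b
        self.ss_type = ss_type

    def fit(self, table: FeatureTable):
        if self.ss_type != 2:
            raise ValueError("only Type II sums of squares are implemented")
        meta = table.samples
        lev_a = sorted(meta[self.factor_a].unique())
        lev_b = sorted(meta[self.factor_b].unique())
        if len(lev_a) != 2 or len(lev_b) != 2:
            raise ValueError("both factors must have exactly 2 levels")
        for la in lev_a:
            for lb in lev_b:
                n_cell = int(
                    ((meta[self.factor_a] == la) & (meta[self.factor_b] == lb)).sum()
                )
                if n_cell == 0:
                    raise ValueError(f"design cell ({la}, {lb}) is empty")
                if n_cell < 2:
                    raise ValueError(
                        f"design cell ({la}, {lb}) needs >= 2 replicates for "
                        "the interaction term"
                    )

        a = (meta[self.factor_a] == lev_a[1]).to_numpy(dtype=float)
        b = (meta[self.factor_b] == lev_b[1]).to_numpy(dtype=float)
        one = np.ones_like(a)
        X_full = np.column_stack([one, a, b, a * b])
        X_ab = np.column_stack([one, a, b])
        X_a = np.column_stack([one, b])  # model without factor A
        X_b = np.column_stack([one, a])  # model without factor B

        Y = arcsinh_transform(
            table.intensities[meta.index].to_numpy(dtype=float)
        ).T  # samples x features
        n = Y.shape[0]
        df_resid = n - 4

        rss_full = _rss(Y, X_full)
        rss_ab = _rss(Y, X_ab)
        ss_a = _rss(Y, X_a) - rss_ab
        ss_b = _rss(Y, X_b) - rss_ab
        ss_int = rss_ab - rss_full
        mse = rss_full / df_resid

        out = {}
        for term, ss in (
            (self.factor_a, ss_a),
            (self.factor_b, ss_b),
            ("interaction", ss_int),
        ):
            with np.errstate(invalid="ignore", divide="ignore"):
                F = np.clip(ss, 0.0, None) / mse
            F = np.where(mse > 0, F, 0.0)
            p = stats.f.sf(F, 1, df_resid)
            p = np.where(mse > 0, p, 1.0)
            out[f"F_{term}"] = F
            out[f"p_{term}"] = p
            out[f"q_{term}"] = bh_fdr(p)
        self.results_ = pd.DataFrame(out, index=table.feature_ids)
        self.levels_ = {self.factor_a: lev_a, self.factor_b: lev_b}
        return self


def two_way_anova(table: FeatureTable, **params) -> pd.DataFrame:
    """Functional wrapper around :class:`TwoWayAnovaScreen`."""
    return TwoWayAnovaScreen(**params).fit(table).results_


def interaction_screen(
    anova_results: pd.DataFrame,
    identified_ids=(),
    alpha: float = 0.05,
) -> dict:
    """Interaction and genotype-effect feature lists at FDR *alpha*.

    Identified compounds are excluded from both lists (they are examined
    individually); the genotype list counts *additional* features, i.e.
    those not already in the interaction list.
    """
    identified = pd.Index(identified_ids)
    anon = anova_results.drop(index=identified, errors="ignore")
    inter = anon.index[anon["q_interaction"] < alpha]
    geno = anon.index[
        (anon["q_genotype"] < alpha) & ~anon.index.isin(inter)
    ]
    return {
        "interaction_features": list(inter),
        "genotype_features": list(geno),
        "n_interaction": len(inter),
        "n_genotype": len(geno),
        "alpha": alpha,
        "n_excluded_identified": int(anova_results.index.isin(identified).sum()),
    }
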