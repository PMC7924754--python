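"""Untargeted feature-table curation.

Four stages turn a raw feature table into the set of *informative
features*, one representative per co-eluting fragment group:

1. retention-time exclusion — unretained features (rt below 0.3 min by
   default) co-elute excessively and are discarded;
2. mass-decimal exclusion — m/z values whose fractional part exceeds 0.8
   do not correspond to feasible compounds of biological origin and are
   treated as instrument artifacts;
3. fragment grouping — features eluting within 0.04 min of each other whose
   raw intensities correlate with Pearson r > 0.8 across all samples are
   considered fragments of one compound (connected components of the
   co-elution graph by default; a stricter clique mode is available);
4. representative selection — the [M-H]- feature of an identified compound,
   otherwise the member with the highest mean raw intensity.

Grouping operates on raw (untransformed) intensities because curation
precedes normalization in the workflow.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .feature_table import FeatureTable


# --------------------------------------------------------------------------
# identification map
# --------------------------------------------------------------------------
class IdentificationMap:
    """Maps feature ids to identified compounds.

    Backed by a DataFrame with columns ``feature_id``, ``compound``,
    ``adduct`` and ``is_mh`` (whether the feature is the deprotonated
    molecular ion, the preferred representative). Adduct labels come from
    a small controlled vocabulary.
    """

    ADDUCTS = ("[M-H]-", "[M+HCOO-]-", "fragment", "isotope", "unknown")

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            frame = pd.DataFrame(columns=["feature_id", "compound", "adduct", "is_mh"])
        frame = frame.copy()
        if "is_mh" not in frame.columns:
            frame["is_mh"] = frame["adduct"] == "[M-H]-"
        bad = set(frame["adduct"]) - set(self.ADDUCTS)
        if bad:
            raise ValueError(f"unknown adduct labels: {sorted(bad)}")
        self.frame = frame.set_index("feature_id", drop=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "IdentificationMap":
        return cls(pd.read_csv(path))

    def __len__(self) -> int:
        return len(self.frame)

    def lookup(self, feature_ids) -> pd.DataFrame:
        idx = self.frame.index.intersection(pd.Index(feature_ids))
        return self.frame.loc[idx]


# --------------------------------------------------------------------------
# filtering
# --------------------------------------------------------------------------
def filter_retention_time(
    table: FeatureTable, min_rt: float = 0.3
) -> tuple[FeatureTable, int]:
    """Drop unretained features (rt < *min_rt*; the boundary value is kept).

    Returns the filtered table and the number of removed features.
    """
    keep = table.features.index[table.features["rt"] >= min_rt]
    removed = table.n_features - len(keep)
    return table.subset_features(keep), removed


def filter_mass_decimal(
    table: FeatureTable, max_frac: float = 0.8
) -> tuple[FeatureTable, int]:
    """Drop features whose m/z fractional part is strictly above *max_frac*."""
    frac = np.mod(table.features["mz"].to_numpy(), 1.0)
    # tolerance absorbs float representation error at the boundary
    # (e.g. 250.80 % 1 == 0.8000000000000114); mass decimals are only
    # meaningful to ~1e-4 anyway
    keep = table.features.index[frac <= max_frac + 1e-9]
    removed = table.n_features - len(keep)
    return table.subset_features(keep), removed


# --------------------------------------------------------------------------
# grouping
# --------------------------------------------------------------------------
@dataclass
class FeatureGroup:
    member_ids: tuple
    representative_id: str | None = None
    identified_compound: str | None = None
    selection_rule: str | None = None


def _coelution_edges(
    table: FeatureTable, rt_window: float, r_min: float
) -> list[tuple[str, str]]:
    """Edges between features with |delta rt| <= rt_window and Pearson r > r_min.

    Correlation is computed on raw intensities across all samples.
    Zero-variance intensity vectors have undefined correlation and receive
    no edges.
    """
    feats = table.features
    X = table.intensities.to_numpy(dtype=float)
    n = X.shape[1]
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    ok = sd[:, 0] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd

    order = np.argsort(feats["rt"].to_numpy(), kind="stable")
    rt = feats["rt"].to_numpy()[order]
    ids = feats.index.to_numpy()[order]
    Zo = Z[order]
    oko = ok[order]

    pairs_i, pairs_j = [], []
    j0 = 0
    m = len(order)
    for i in range(m):
        while rt[i] - rt[j0] > rt_window:
            j0 += 1
        for j in range(j0, i):
            pairs_i.append(j)
            pairs_j.append(i)
    if not pairs_i:
        return []
    pi = np.asarray(pairs_i)
    pj = np.asarray(pairs_j)
    valid = oko[pi] & oko[pj]
    pi, pj = pi[valid], pj[valid]
    if len(pi) == 0:
        return []
    r = np.einsum("ij,ij->i", Zo[pi], Zo[pj]) / (n - 1)
    hit = r > r_min
    return [(ids[a], ids[b]) for a, b in zip(pi[hit], pj[hit])]


def group_fragments(
    table: FeatureTable,
    rt_window: float = 0.04,
    r_min: float = 0.8,
    group_mode: str = "component",
) -> list[FeatureGroup]:
    """Group co-eluting, correlated features into fragment groups.

    ``group_mode="component"`` (default) takes connected components of the
    co-elution graph, the usual chain-wise behavior of co-elution grouping
    tools; ``"clique"`` partitions each component into cliques greedily
    (seeded at the most abundant unassigned member), so every pair inside a
    group satisfies both conditions.

    Singleton features form singleton groups. Groups partition the feature
    set; member ids are sorted so the output is order-invariant.
    """
    if group_mode not in ("component", "clique"):
        raise ValueError("group_mode must be 'component' or 'clique'")
    if table.n_samples < 3:
        warnings.warn(
            "fewer than 3 samples: Pearson correlations are unstable",
            stacklevel=2,
        )
    graph = nx.Graph()
    graph.add_nodes_from(table.feature_ids)
    graph.add_edges_from(_coelution_edges(table, rt_window, r_min))

    groups: list[FeatureGroup] = []
    if group_mode == "component":
        for comp in nx.connected_components(graph):
            groups.append(FeatureGroup(member_ids=tuple(sorted(comp))))
    else:
        mean_int = table.intensities.mean(axis=1)
        for comp in nx.connected_components(graph):
            # greedy clique partition, deterministic seed order
            pending = sorted(comp, key=lambda f: (-mean_int[f], f))
            while pending:
                seed = pending.pop(0)
                clique = [seed]
                rest = []
                for cand in pending:
                    if all(graph.has_edge(cand, m) for m in clique):
                        clique.append(cand)
                    else:
                        rest.append(cand)
                pending = rest
                groups.append(FeatureGroup(member_ids=tuple(sorted(clique))))
    groups.sort(key=lambda g: g.member_ids)
    return groups


# --------------------------------------------------------------------------
# representative selection
# --------------------------------------------------------------------------
def select_representative(
    group: FeatureGroup,
    table: FeatureTable,
    ids: IdentificationMap | None = None,
) -> str:
    """Pick the representative feature of a fragment group.

    If the group contains an identified compound, its [M-H]- feature is
    retained; otherwise the member with the highest mean raw intensity.
    A group containing an identified compound without an [M-H]- flag falls
    back to the most abundant member with a warning; if two identified
    compounds collide in one group, the one whose [M-H]- feature has the
    lowest m/z wins (with a warning).
    """
    if not group.member_ids:
        raise ValueError("empty group")
    members = list(group.member_ids)

    def most_abundant() -> str:
        means = table.intensities.loc[members].mean(axis=1)
        # ties broken lexicographically for order invariance
        best = means.sort_index().sort_values(kind="stable", ascending=False)
        return str(best.index[0])

    if ids is None or not len(ids):
        group.selection_rule = "most_abundant"
        rep = most_abundant()
        group.representative_id = rep
        return rep

    hits = ids.lookup(members)
    if hits.empty:
        group.selection_rule = "most_abundant"
        rep = most_abundant()
        group.representative_id = rep
        return rep

    compounds = sorted(hits["compound"].unique())
    if len(compounds) > 1:
        mh = hits[hits["is_mh"]]
        if not mh.empty:
            mzs = table.features.loc[mh["feature_id"], "mz"]
            chosen = str(hits.loc[mzs.idxmin(), "compound"])
        else:
            chosen = compounds[0]
        warnings.warn(
            f"group contains {len(compounds)} identified compounds "
            f"{compounds}; keeping {chosen!r} (lowest [M-H]- m/z)",
            stacklevel=2,
        )
    else:
        chosen = compounds[0]
    group.identified_compound = chosen

    mh = hits[(hits["compound"] == chosen) & hits["is_mh"]]
    if mh.empty:
        warnings.warn(
            f"identified compound {chosen!r} has no [M-H]- member; "
            "falling back to most abundant feature",
            stacklevel=2,
        )
        group.selection_rule = "most_abundant_fallback"
        rep = most_abundant()
    else:
        group.selection_rule = "identified_mh"
        mzs = table.features.loc[mh["feature_id"], "mz"]
        rep = str(mzs.idxmin())
    group.representative_id = rep
    return rep


# --------------------------------------------------------------------------
# full curation
# --------------------------------------------------------------------------
@dataclass
class CurationReport:
    n_input: int = 0
    n_removed_rt: int = 0
    n_after_rt: int = 0
    n_removed_decimal: int = 0
    n_after_decimal: int = 0
    n_groups: int = 0
    n_informative: int = 0
    group_size_hist: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


class FeatureCurator(BaseEstimator):
    """Sklearn-style transformer running the full curation chain.

    Parameters
    ----------
    min_rt:
        Retention-time cut in minutes; features below it are unretained.
    max_mz_decimal:
        Largest feasible m/z fractional part; larger decimals are artifacts.
    rt_window, r_min:
        Co-elution window (minutes) and Pearson correlation threshold for
        fragment grouping.
    group_mode:
        ``"component"`` (chain-wise, default) or ``"clique"``.

    Fitted attributes
    -----------------
    groups_ : list[FeatureGroup]
        Fragment groups with representatives and selection rules.
    representatives_ : list[str]
        Informative feature ids, one per group.
    report_ : CurationReport
        Per-stage bookkeeping.
    """

    def __init__(
        self,
        min_rt: float = 0.3,
        max_mz_decimal: float = 0.8,
        rt_window: float = 0.04,
        r_min: float = 0.8,
        group_mode: str = "component",
    ):
        self.min_rt = min_rt
        self.max_mz_decimal = max_mz_decimal
        self.rt_window = rt_window
        self.r_min = r_min
        self.group_mode = group_mode

    def fit(self, table: FeatureTable, ids: IdentificationMap | None = None):
        report = CurationReport(n_input=table.n_features, params=self.get_params())
        filtered, report.n_removed_rt = filter_retention_time(table, self.min_rt)
        report.n_after_rt = filtered.n_features
        filtered, report.n_removed_decimal = filter_mass_decimal(
            filtered, self.max_mz_decimal
        )
        report.n_after_decimal = filtered.n_features

        groups = group_fragments(
            filtered, self.rt_window, self.r_min, self.group_mode
        )
        for group in groups:
            select_representative(group, filtered, ids)
        report.n_groups = len(groups)
        report.n_informative = len(groups)
        sizes = pd.Series([len(g.member_ids) for g in groups])
        report.group_size_hist = {
            int(k): int(v) for k, v in sizes.value_counts().sort_index().items()
        }

        self.groups_ = groups
        self.representatives_ = [g.representative_id for g in groups]
        self.report_ = report
        self._filtered = filtered
        return self

    def transform(self, table: FeatureTable | None = None) -> FeatureTable:
        """Return the informative-feature table (representatives only)."""
        if not hasattr(self, "groups_"):
            raise RuntimeError("FeatureCurator is not fitted")
        source = self._filtered if table is None else table
        return source.subset_features(sorted(self.representatives_))

    def fit_transform(
        self, table: FeatureTable, ids: IdentificationMap | None = None
    ) -> FeatureTable:
        return self.fit(table, ids).transform()

    def compound_of_representative(self) -> dict:
        """Representative feature id -> identified compound name (if any)."""
        return {
            g.representative_id: g.identified_compound
            for g in self.groups_
            if g.identified_compound is not None
        }


def curate(
    table: FeatureTable,
    ids: IdentificationMap | None = None,
    **params,
) -> tuple[FeatureTable, CurationReport]:
    """Functional wrapper: run the curation chain, return table + report."""
    curator = FeatureCurator(**params)
    informative = curator.fit_transform(table, ids)
    return informative, curator.report_
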