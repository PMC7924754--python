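"""Candidate foraging-cue identification.

Cross-references the identified metabolites that accumulate at higher
levels in postembryonic roots with a literature-derived table of compounds
known to elicit behavioral responses in the western corn rootworm
(attractants, feeding stimulants, host-recognition cues). The intersection
— after compound-name normalization through an explicit synonym map — is
the list of candidate cues that may mediate postembryonic root preference.

The packaged activity and identified-metabolite tables are synthetic
stand-ins for the study's supplementary tables: rows sourced from the main
text are tagged ``main-text``, filler rows ``synthetic-placeholder`` (see
the ``source_tag`` column of the CSVs).
"""

from __future__ import annotations

import warnings
from importlib import resources

import edlib
import pandas as pd

_DATA = resources.files("rootcue") / "data"


def load_activity_table() -> pd.DataFrame:
    """Literature-derived behaviorally active compounds (synthetic stand-in)."""
    with resources.as_file(_DATA / "activity_table_synthetic.csv") as path:
        return pd.read_csv(path)


def load_identified_metabolites() -> pd.DataFrame:
    """Identified metabolites with enrichment directions (synthetic stand-in)."""
    with resources.as_file(_DATA / "identified_metabolites_synthetic.csv") as path:
        return pd.read_csv(path)


def load_synonyms() -> dict[str, str]:
    with resources.as_file(_DATA / "synonyms.csv") as path:
        frame = pd.read_csv(path)
    return {
        str(a).casefold().strip(): str(c).casefold().strip()
        for a, c in zip(frame["alias"], frame["canonical"])
    }


def normalize_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    """Case-fold, trim, and apply the explicit synonym map (no fuzzy matching)."""
    if synonyms is None:
        synonyms = load_synonyms()
    key = str(name).casefold().strip()
    return synonyms.get(key, key)


def cross_reference(
    enriched: pd.DataFrame,
    activity: pd.DataFrame | None = None,
    synonyms: dict[str, str] | None = None,
    near_miss_distance: int = 2,
) -> pd.DataFrame:
    """Intersect enriched identified metabolites with the activity table.

    *enriched* needs a ``compound`` column (and optionally ``direction``);
    *activity* needs ``compound`` and ``activity``. Matching happens on
    normalized names only; unmatched names within edit distance
    *near_miss_distance* of an activity entry are reported as warnings,
    never auto-matched. The result is a subset of both inputs and
    idempotent under re-application.
    """
    if activity is None:
        activity = load_activity_table()
    if synonyms is None:
        synonyms = load_synonyms()
    if activity.empty:
        warnings.warn("empty activity table; no candidates", stacklevel=2)
        return pd.DataFrame(columns=["compound", "direction", "activity"])

    act = activity.copy()
    act["_norm"] = [normalize_name(c, synonyms) for c in act["compound"]]
    enr = enriched.drop(columns=["activity"], errors="ignore").copy()
    enr["_norm"] = [normalize_name(c, synonyms) for c in enr["compound"]]

    merged = enr.merge(
        act[["_norm", "activity"]], on="_norm", how="left", validate="m:1"
    )
    matched = merged[merged["activity"].notna()]

    unmatched = merged.loc[merged["activity"].isna(), ["compound", "_norm"]]
    for _, row in unmatched.iterrows():
        for cand in act["_norm"]:
            dist = edlib.align(row["_norm"], cand, task="distance")["editDistance"]
            if 0 < dist <= near_miss_distance:
                warnings.warn(
                    f"compound {row['compound']!r} is within edit distance "
                    f"{dist} of activity entry {cand!r}; not auto-matched — "
                    "add a synonym if they are the same compound",
                    stacklevel=2,
                )
    cols = ["compound"] + (["direction"] if "direction" in matched.columns else [])
    out = matched[cols + ["activity"]].drop_duplicates("compound")
    return out.reset_index(drop=True)
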