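"""Synthetic-data generators for every pipeline input.

The generators emit data with the statistical structure the downstream
analysis assumes, together with the planted ground truth, so that curation,
differential screening, targeted quantification and the behavioral
statistics are all testable offline.

Model for the untargeted feature table
--------------------------------------
Each synthetic *compound* has a latent log-abundance per sample,

    log A_cs = mu_c + effects(root_type, genotype) + eps_cs,
    eps_cs ~ N(0, noise_sigma^2),

and each of its *fragments* observes that latent abundance through a
fragment-specific ionisation yield and small independent multiplicative
noise,

    I_fs = A_cs * yield_f * exp(eta_fs),   eta_fs ~ N(0, fragment_sigma^2).

Because fragments share the latent term, their raw intensities are highly
correlated across samples by construction, and all fragments of a compound
elute within a narrow retention-time window around the compound's apex.
Planted effects are multiplicative: a root-type fold change (split half up,
half down on the log scale so the mean ratio equals ``diff_fold``), a
mutant-only root-type shift (an interaction with no wild-type footprint),
a genotype shift, and the benzoxazinoid knockout that multiplies mutant
intensities by ``knockout_fraction``.

Default parameters encode the study conditions of the maize-root data set
the package emulates: 4,956 mass features of which 444 are unretained
(retention time < 0.3 min), fragment groups averaging ~2.7 features so that
roughly 1,563 informative features remain after curation, 81 postembryonic-
and 137 embryonic-enriched compounds, 47 interaction and 244
genotype-differential compounds, and a >97% benzoxazinoid knockout in the
bx1 mutant.

All generators derive their random streams from one integer seed through
``numpy.random.SeedSequence(seed, spawn_key=(stream,))`` with a fixed
stream number per generator, so a single seed reproduces every table
byte-identically while keeping the generators independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_table import FeatureTable, ROOT_TYPES, GENOTYPES

# fixed sub-stream numbers of the global seed
_STREAMS = {"features": 0, "targeted": 1, "behavior": 2, "damage": 3, "qpcr": 4}

#: benzoxazinoid compounds knocked out in the bx1 mutant, with wild-type
#: concentration means (ug per g fresh weight) per root type used by the
#: targeted panel generator; ratios follow the tissue contrasts the
#: untargeted screen reports (4-fold DIMBOA, 2-3-fold glucosides up in
#: postembryonic roots, HDMBOA-Glc down).
BENZOXAZINOID_MEANS = {
    # compound: (embryonic, postembryonic) ug/g FW
    "DIMBOA": (50.0, 200.0),
    "DIMBOA-Glc": (120.0, 300.0),
    "DIM2BOA-Glc": (25.0, 60.0),
    "HDMBOA-Glc": (180.0, 90.0),
    "HMBOA": (12.0, 15.0),
    "MBOA": (6.0, 8.0),
}

#: compounds with an external calibration standard; DIM2BOA-Glc has none and
#: is quantified on the DIMBOA-Glc curve downstream.
STANDARD_COMPOUNDS = ("HMBOA", "DIMBOA", "DIMBOA-Glc", "HDMBOA-Glc", "MBOA")


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[stream],))
    )


# --------------------------------------------------------------------------
# parameters and ground truth
# --------------------------------------------------------------------------
@dataclass
class SynthParams:
    """Parameters of the untargeted feature-table generator.

    The defaults are the emulated study's conditions; tests use smaller
    tables by overriding ``n_features`` and the planted-effect counts.
    """

    seed: int = 0
    n_features: int = 4956
    n_samples_per_cell: int = 10  # per root_type x genotype cell
    rt_range: tuple[float, float] = (0.0, 8.5)  # minutes
    mz_range: tuple[float, float] = (100.0, 1200.0)  # Da
    frac_unretained: float = 444 / 4956  # features eluting before 0.3 min
    frac_bad_decimal: float = 0.05  # m/z fractional part > 0.8
    #: distribution of fragments per compound (size -> probability)
    group_size_dist: dict = field(
        default_factory=lambda: {1: 0.28, 2: 0.23, 3: 0.19, 4: 0.14, 5: 0.10, 6: 0.06}
    )
    noise_sigma: float = 0.5  # log-scale biological SD of latent abundance
    fragment_sigma: float = 0.05  # log-scale SD of fragment-specific noise
    n_diff_features: int = 218  # root-type differential compounds (81 + 137)
    frac_postembryonic_up: float = 81 / 218
    diff_fold: float = 4.0
    n_interaction_features: int = 47  # mutant-only root-type shift
    interaction_fold: float = 8.0
    n_genotype_features: int = 244  # genotype main-effect compounds
    genotype_fold: float = 3.0
    knockout_fraction: float = 0.03  # residual fraction in the bx1 mutant

    def validate(self) -> None:
        if self.n_features <= 0:
            raise ValueError("n_features must be positive")
        if self.n_samples_per_cell < 2:
            raise ValueError("n_samples_per_cell must be at least 2")
        if not 0 <= self.frac_unretained < 1 or not 0 <= self.frac_bad_decimal < 1:
            raise ValueError("junk-feature fractions must lie in [0, 1)")
        if self.frac_unretained + self.frac_bad_decimal >= 1:
            raise ValueError("junk-feature fractions sum to >= 1")
        if self.diff_fold < 1 or self.interaction_fold < 1 or self.genotype_fold < 1:
            raise ValueError("fold effects must be >= 1")
        if not 0 <= self.knockout_fraction <= 1:
            raise ValueError("knockout_fraction must lie in [0, 1]")
        if min(self.n_diff_features, self.n_interaction_features,
               self.n_genotype_features) < 0:
            raise ValueError("planted-effect counts must be non-negative")
        probs = np.array(list(self.group_size_dist.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("group_size_dist probabilities must sum to 1")


@dataclass
class GroundTruth:
    """Planted structure emitted next to every synthetic feature table."""

    #: fragment feature_id -> synthetic compound id
    group_membership: dict
    #: compound id -> deprotonated-molecular-ion feature_id
    representative: dict
    #: compound id -> enrichment direction ("postembryonic" / "embryonic")
    diff_compounds: dict
    knockout_compound_ids: list
    interaction_compound_ids: list
    genotype_compound_ids: list
    #: compound id -> identified compound name (subset of compounds)
    identified: dict

    @property
    def diff_feature_ids(self) -> set:
        diff = set(self.diff_compounds)
        return {f for f, c in self.group_membership.items() if c in diff}

    def direction_of_feature(self, feature_id: str) -> str | None:
        comp = self.group_membership.get(feature_id)
        return self.diff_compounds.get(comp)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# untargeted feature table
# --------------------------------------------------------------------------
def _sample_frame(n_per_cell: int) -> pd.DataFrame:
    rows = []
    for geno in GENOTYPES:
        for root in ROOT_TYPES:
            for rep in range(1, n_per_cell + 1):
                rows.append((f"{geno}_{root[:4]}_{rep}", root, geno, rep))
    frame = pd.DataFrame(
        rows, columns=["sample_id", "root_type", "genotype", "replicate"]
    )
    return frame.set_index("sample_id")


def generate_feature_table(
    params: SynthParams, identified: pd.DataFrame | None = None
) -> tuple[FeatureTable, GroundTruth]:
    """Generate an untargeted feature table plus its planted ground truth.

    Parameters
    ----------
    params:
        Generator settings; ``params.validate()`` is called first.
    identified:
        Optional table of identified compounds (columns ``compound``,
        ``compound_class``, ``direction``) used to (a) name a subset of the
        synthetic compounds, (b) pin the benzoxazinoid class as the
        knockout set, and (c) force the named compounds' enrichment
        directions. When omitted, all compounds are anonymous.
    """
    params.validate()
    rng = _rng(params.seed, "features")

    n_unret = int(round(params.frac_unretained * params.n_features))
    n_baddec = int(round(params.frac_bad_decimal * params.n_features))
    n_good = params.n_features - n_unret - n_baddec
    if n_good <= 0:
        raise ValueError("junk fractions leave no retained features")

    sizes_support = np.array(sorted(params.group_size_dist), dtype=int)
    sizes_probs = np.array(
        [params.group_size_dist[s] for s in sizes_support], dtype=float
    )
    sizes: list[int] = []
    total = 0
    while total < n_good:
        s = int(rng.choice(sizes_support, p=sizes_probs))
        sizes.append(min(s, n_good - total))
        total += sizes[-1]
    n_compounds = len(sizes)

    samples = _sample_frame(params.n_samples_per_cell)
    is_post = (samples["root_type"] == "postembryonic").to_numpy()
    is_mut = (samples["genotype"] == "bx1").to_numpy()
    n_samp = len(samples)

    # ---- assign compound roles ------------------------------------------
    identified_names: dict[int, str] = {}
    knockout_ids: list[int] = []
    forced_direction: dict[int, str] = {}
    taken: set[int] = set()
    order = rng.permutation(n_compounds)
    cursor = 0

    def _take(k: int) -> list[int]:
        nonlocal cursor
        if cursor + k > n_compounds:
            raise ValueError(
                "not enough compounds for the requested planted effects; "
                "increase n_features or reduce the planted counts"
            )
        out = [int(c) for c in order[cursor : cursor + k]]
        cursor += k
        return out

    if identified is not None and len(identified):
        ident = identified.reset_index(drop=True)
        ids = _take(len(ident))
        for cid, row in zip(ids, ident.itertuples()):
            identified_names[cid] = row.compound
            if row.compound_class == "benzoxazinoid":
                knockout_ids.append(cid)
            if row.direction in ROOT_TYPES:
                forced_direction[cid] = row.direction
        taken.update(ids)

    n_forced_post = sum(d == "postembryonic" for d in forced_direction.values())
    n_forced_emb = sum(d == "embryonic" for d in forced_direction.values())
    n_post = int(round(params.n_diff_features * params.frac_postembryonic_up))
    n_emb = params.n_diff_features - n_post
    extra_post = max(n_post - n_forced_post, 0)
    extra_emb = max(n_emb - n_forced_emb, 0)

    diff_compounds = dict(forced_direction)
    for cid in _take(extra_post):
        diff_compounds[cid] = "postembryonic"
    for cid in _take(extra_emb):
        diff_compounds[cid] = "embryonic"
    interaction_ids = _take(params.n_interaction_features)
    genotype_ids = _take(params.n_genotype_features)
    if not identified_names and params.knockout_fraction < 1:
        # anonymous tables: no knockout class unless compounds are named
        knockout_ids = []

    # ---- latent abundances ----------------------------------------------
    mu = rng.normal(np.log(2.0e4), 1.2, size=n_compounds)
    log_lat = mu[:, None] + rng.normal(0.0, params.noise_sigma, (n_compounds, n_samp))

    half = 0.5 * np.log(params.diff_fold)
    for cid, direction in diff_compounds.items():
        sign = 1.0 if direction == "postembryonic" else -1.0
        log_lat[cid] += sign * np.where(is_post, half, -half)
    kappa = np.log(params.interaction_fold)
    inter_sign = rng.choice([-1.0, 1.0], size=len(interaction_ids))
    for sgn, cid in zip(inter_sign, interaction_ids):
        # mutant-only root-type shift (random direction): an interaction
        # with no wild-type footprint; the random sign also keeps planted
        # interaction compounds mutually uncorrelated so co-eluting ones do
        # not merge during fragment grouping
        log_lat[cid] += sgn * kappa * (is_post & is_mut)
    geno_sign = rng.choice([-1.0, 1.0], size=len(genotype_ids))
    for sgn, cid in zip(geno_sign, genotype_ids):
        log_lat[cid] += sgn * np.log(params.genotype_fold) * is_mut
    if params.knockout_fraction < 1 and knockout_ids:
        log_knock = np.log(max(params.knockout_fraction, 1e-12))
        for cid in knockout_ids:
            log_lat[cid] += log_knock * is_mut

    # ---- fragments -------------------------------------------------------
    rt_lo, rt_hi = params.rt_range
    mz_lo, mz_hi = params.mz_range
    comp_rt = rng.uniform(max(rt_lo, 0.3) + 0.05, rt_hi, size=n_compounds)
    comp_mz = rng.uniform(mz_lo + 150, mz_hi, size=n_compounds)

    fid, mz, rt, rows = [], [], [], []
    membership: dict[str, int] = {}
    representative: dict[int, str] = {}
    k = 0
    for cid, size in enumerate(sizes):
        for j in range(size):
            name = f"F{k:05d}"
            k += 1
            membership[name] = cid
            if j == 0:  # deprotonated molecular ion
                representative[cid] = name
                m = comp_mz[cid]
                y = 1.0
            else:
                m = max(mz_lo, comp_mz[cid] - rng.uniform(10.0, 150.0))
                y = float(np.exp(rng.normal(-0.7, 0.5)))
            m = np.floor(m) + rng.uniform(0.0, 0.8)  # feasible mass decimal
            fid.append(name)
            mz.append(m)
            rt.append(comp_rt[cid] + rng.uniform(-0.015, 0.015))
            eta = rng.normal(0.0, params.fragment_sigma, n_samp)
            rows.append(np.exp(log_lat[cid] + np.log(y) + eta))

    # ---- junk features ---------------------------------------------------
    for i in range(n_unret):
        name = f"U{i:05d}"
        fid.append(name)
        mz.append(np.floor(rng.uniform(mz_lo, mz_hi)) + rng.uniform(0.0, 0.8))
        rt.append(rng.uniform(0.0, 0.295))
        rows.append(np.exp(rng.normal(np.log(5e3), 1.0) +
                           rng.normal(0.0, 0.6, n_samp)))
    for i in range(n_baddec):
        name = f"D{i:05d}"
        fid.append(name)
        mz.append(np.floor(rng.uniform(mz_lo, mz_hi)) + rng.uniform(0.801, 0.999))
        rt.append(rng.uniform(max(rt_lo, 0.3) + 0.05, rt_hi))
        rows.append(np.exp(rng.normal(np.log(5e3), 1.0) +
                           rng.normal(0.0, 0.6, n_samp)))

    features = pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(fid, name="feature_id"))
    intens = pd.DataFrame(
        np.asarray(rows), index=features.index, columns=samples.index
    )
    table = FeatureTable(features, intens, samples)
    truth = GroundTruth(
        group_membership=membership,
        representative={int(c): f for c, f in representative.items()},
        diff_compounds={int(c): d for c, d in diff_compounds.items()},
        knockout_compound_ids=[int(c) for c in knockout_ids],
        interaction_compound_ids=[int(c) for c in interaction_ids],
        genotype_compound_ids=[int(c) for c in genotype_ids],
        identified={int(c): n for c, n in identified_names.items()},
    )
    return table, truth


def identification_table(truth: GroundTruth) -> pd.DataFrame:
    """Feature-level identification map derived from the ground truth.

    One row per fragment of each identified compound, flagging the
    deprotonated molecular ion ([M-H]-) that curation should retain.
    """
    rows = []
    for feat, cid in truth.group_membership.items():
        name = truth.identified.get(cid)
        if name is None:
            continue
        is_mh = truth.representative.get(cid) == feat
        rows.append((feat, name, "[M-H]-" if is_mh else "fragment", is_mh))
    return pd.DataFrame(
        rows, columns=["feature_id", "compound", "adduct", "is_mh"]
    )


# --------------------------------------------------------------------------
# targeted benzoxazinoid panel
# --------------------------------------------------------------------------
def generate_targeted_panel(
    seed: int,
    reduction: float = 0.975,
    n_per_cell: int = 12,
    noise_sigma: float = 0.12,
    extract_volume_ml: float = 1.0,
) -> dict:
    """Generate a targeted benzoxazinoid panel with paired UV and MS signals.

    Returns a dict with keys ``panel`` (per-compound, per-sample UV/MS areas
    and tissue masses), ``standards`` (external calibration points for the
    five compounds with standards), and ``truth`` (the generating
    parameters: per-compound UV response slopes, MS-to-UV factors and the
    planted knockout ``reduction``).

    Wild-type concentration means follow :data:`BENZOXAZINOID_MEANS`;
    mutant concentrations are the wild-type draw scaled by
    ``1 - reduction``. UV areas are proportional to the amount injected
    with log-normal measurement noise; MS areas are proportional to UV
    through a compound-specific conversion factor.
    """
    if not 0 <= reduction <= 1:
        raise ValueError("reduction must lie in [0, 1]")
    if n_per_cell < 2:
        raise ValueError("n_per_cell must be at least 2")
    rng = _rng(seed, "targeted")

    uv_slope = {c: float(rng.uniform(40.0, 120.0)) for c in BENZOXAZINOID_MEANS}
    ms_per_uv = {c: float(rng.uniform(8.0, 40.0)) for c in BENZOXAZINOID_MEANS}

    rows = []
    for geno in GENOTYPES:
        scale = 1.0 if geno == "WT" else 1.0 - reduction
        for root in ROOT_TYPES:
            for rep in range(1, n_per_cell + 1):
                sample = f"{geno}_{root[:4]}_{rep}"
                mass_mg = float(rng.normal(100.0, 8.0))
                for comp, (m_emb, m_post) in BENZOXAZINOID_MEANS.items():
                    mean = m_post if root == "postembryonic" else m_emb
                    conc = mean * scale * float(
                        np.exp(rng.normal(0.0, noise_sigma))
                    )  # ug/g FW
                    ug_in_extract = conc * mass_mg / 1000.0
                    conc_extract = ug_in_extract / extract_volume_ml  # ug/mL
                    uv = uv_slope[comp] * conc_extract * float(
                        np.exp(rng.normal(0.0, noise_sigma / 2))
                    )
                    ms = ms_per_uv[comp] * uv_slope[comp] * conc_extract * float(
                        np.exp(rng.normal(0.0, noise_sigma / 2))
                    )
                    rows.append(
                        (comp, sample, geno, root, rep, uv, ms, mass_mg, conc)
                    )
    panel = pd.DataFrame(
        rows,
        columns=[
            "compound", "sample_id", "genotype", "root_type", "replicate",
            "uv_area", "ms_area", "tissue_mass_mg", "true_concentration",
        ],
    )

    std_rows = []
    for comp in STANDARD_COMPOUNDS:
        for conc in (0.5, 1.0, 2.0, 5.0, 10.0, 20.0):  # ug/mL in vial
            area = uv_slope[comp] * conc * float(
                np.exp(rng.normal(0.0, noise_sigma / 4))
            )
            std_rows.append((comp, conc, area))
    standards = pd.DataFrame(std_rows, columns=["compound", "concentration", "uv_area"])

    truth = {
        "reduction": reduction,
        "uv_slope": uv_slope,
        "ms_per_uv": ms_per_uv,
        "extract_volume_ml": extract_volume_ml,
    }
    return {"panel": panel, "standards": standards, "truth": truth}


# --------------------------------------------------------------------------
# behavioral choice assays
# --------------------------------------------------------------------------
def generate_behavior_data(
    seed: int,
    n_dishes: int = 15,
    larvae_per_dish: int = 6,
    p_pref: float = 0.5,
    overdispersion: float = 0.0,
    p_undecided: float = 0.1,
    treatment: str = "treatment",
    timepoint: float = 1.0,
) -> pd.DataFrame:
    """Per-dish larval counts on two options for one treatment x timepoint cell.

    Each larva is first undecided with probability ``p_undecided``; decided
    larvae pick option A with probability ``p_pref``. With
    ``overdispersion`` rho in (0, 1) the dish-level preference is drawn from
    a Beta distribution with mean ``p_pref`` and intra-dish correlation rho
    (a beta-binomial); rho = 0 gives plain binomial counts.
    """
    if not 0 < p_pref <= 1:
        raise ValueError("p_pref must lie in (0, 1]")
    if larvae_per_dish < 1 or n_dishes < 1:
        raise ValueError("dish counts must be positive")
    if not 0 <= overdispersion < 1:
        raise ValueError("overdispersion must lie in [0, 1)")
    rng = _rng(seed, "behavior")

    rows = []
    for d in range(1, n_dishes + 1):
        decided = rng.binomial(larvae_per_dish, 1.0 - p_undecided)
        if overdispersion > 0 and 0 < p_pref < 1:
            rho = overdispersion
            a = p_pref * (1 - rho) / rho
            b = (1 - p_pref) * (1 - rho) / rho
            p_dish = rng.beta(a, b)
        else:
            p_dish = p_pref
        a_count = rng.binomial(decided, p_dish)
        rows.append(
            (f"dish_{d}", treatment, timepoint, a_count, decided - a_count,
             larvae_per_dish)
        )
    return pd.DataFrame(
        rows,
        columns=["dish_id", "treatment", "timepoint", "count_a", "count_b",
                 "dish_total"],
    )


# --------------------------------------------------------------------------
# root damage scores
# --------------------------------------------------------------------------
def generate_damage_scores(
    seed: int, n_plants: int = 20, effect: float = 0.0
) -> pd.DataFrame:
    """Ordinal 0-5 damage scores for 2 embryonic + 6 postembryonic roots per plant.

    Scores come from a latent-normal threshold model: the latent damage of a
    root is N(mu, 1) cut at fixed thresholds; ``effect`` shifts the
    postembryonic mean, so ``effect=0`` gives identical score distributions
    for both root types.
    """
    if n_plants < 1:
        raise ValueError("n_plants must be positive")
    rng = _rng(seed, "damage")
    thresholds = np.array([-0.4, 0.3, 0.9, 1.5, 2.1])  # cuts between scores 0..5
    rows = []
    for p in range(1, n_plants + 1):
        for root_type, n_roots, prefix in (
            ("embryonic", 2, "E"),
            ("postembryonic", 6, "PE"),
        ):
            mu = effect if root_type == "postembryonic" else 0.0
            z = rng.normal(mu, 1.0, n_roots)
            scores = np.searchsorted(thresholds, z)
            for i, s in enumerate(scores, start=1):
                rows.append((f"plant_{p}", f"{prefix}{i}", root_type, int(s)))
    return pd.DataFrame(rows, columns=["plant_id", "root_id", "root_type", "score"])


# --------------------------------------------------------------------------
# qPCR cycle thresholds
# --------------------------------------------------------------------------
def generate_qpcr(
    seed: int,
    n_per_group: int = 10,
    knockdown: float = 0.75,
    ct_sd: float = 0.25,
) -> pd.DataFrame:
    """Ct values for a silencing experiment (control vs dsRNA-fed group).

    The treatment group's target-gene expression is ``1 - knockdown`` of
    the control mean, i.e. its delta-Ct is shifted by -log2(1 - knockdown)
    cycles relative to the control group.
    """
    if not 0 <= knockdown < 1:
        raise ValueError("knockdown must lie in [0, 1)")
    rng = _rng(seed, "qpcr")
    delta0 = 5.0  # control target-minus-reference cycles
    shift = -np.log2(1.0 - knockdown) if knockdown > 0 else 0.0
    rows = []
    for group, extra in (("control", 0.0), ("treatment", shift)):
        for i in range(1, n_per_group + 1):
            ct_ref = float(rng.normal(18.0, 0.3))
            ct_tgt = ct_ref + float(rng.normal(delta0 + extra, ct_sd))
            rows.append((f"{group}_{i}", group, ct_tgt, ct_ref))
    return pd.DataFrame(
        rows, columns=["sample_id", "group", "ct_target", "ct_reference"]
    )
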