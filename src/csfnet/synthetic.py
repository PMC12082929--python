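"""Synthetic two-platform CSF proteomic cohorts with planted co-expression modules.

The generator emulates the statistical structure of a two-cohort ALS CSF
study: a single-center TMT-like cohort (6 batches, one pooled reference
channel per batch) and a multicenter DIA-like cohort, each with six
diagnosis groups (control, sporadic ALS, C9orf72 ALS and asymptomatic
carriers, SOD1 ALS and asymptomatic carriers).

Protein abundances follow a latent-factor model on the log2 scale:

    x_ps = baseline_p + lambda_p * (f_{m(p),s} + delta_{m(p),g(s)})
           + age/sex/batch terms + noise

where each planted module m has one latent factor per sample f ~ N(0,1),
lambda_p are loadings, and delta are group shifts of the module factor.
The first principal component of a module's members is consistent for the
latent factor under this model, which makes eigenprotein and kME behavior
directly testable against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats, special

from ._util import child_rng
from .exceptions import InvalidDesignError

GROUPS = ["control", "sALS", "C9_ALS", "C9_asym", "SOD1_ALS", "SOD1_asym"]
SYMPTOMATIC = {"sALS", "C9_ALS", "SOD1_ALS"}
CELL_TYPES = ["astrocyte", "microglia", "neuron", "oligodendrocyte", "endothelia"]

AGE_CENTER = 55.0  # fixed centering constant for the age term (years)

# Field-known CSF markers placed into planted modules with the direction of
# change the literature reports, so named proteins exist in fixtures.  The
# module index is 1-based into the planted module list.
NAMED_MARKERS: dict[str, int] = {
    # neurodegeneration / inflammation markers, increased in symptomatic ALS
    "NEFL": 10, "NEFM": 10, "CHIT1": 7, "CHI3L1": 7, "CHI3L2": 7,
    "UCHL1": 10, "GFAP": 7, "FABP5": 10, "SERPINA3": 5, "WARS": 10,
    "TMEM198": 5, "HYOU1": 5, "XXYLT1": 5, "C1QB": 2, "MERTK": 7,
    "SLC39A10": 5, "TGFBR3": 5, "MINPP1": 10,
    # decreased in C9orf72 ALS (neuronal / synaptic modules)
    "DPP6": 11, "C2CD5": 11, "SORCS3": 4, "PCDH11X": 12,
    "HIST1H4A": 1, "PCDHB11": 12, "GRHL2": 4, "IL6R": 11,
    # SOD1 itself: a lysosome-like module with no planted disease effect
    "SOD1": 9,
}
MARKER_ACCESSIONS = {"SOD1": "P00441"}  # canonical accession kept for realism


@dataclass(frozen=True)
class CohortDesign:
    """Sample-level layout of one cohort."""

    group_sizes: dict[str, int]
    platform: str = "TMT_like"  # or "DIA_like"
    n_batches: int = 6
    n_centers: int = 4
    gis_per_batch: int = 1
    age_mean_sd: dict[str, tuple[float, float]] = field(default_factory=dict)
    sex_fraction: dict[str, float] = field(default_factory=dict)
    center_composition: dict[str, dict[str, int]] | None = None
    name: str = "cohort"

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes.values()))

    def validate(self) -> None:
        if any(v < 0 for v in self.group_sizes.values()):
            raise InvalidDesignError("group sizes must be non-negative")
        if self.platform not in ("TMT_like", "DIA_like"):
            raise InvalidDesignError(f"unknown platform {self.platform!r}")
        if self.platform == "TMT_like" and self.n_batches < 1:
            raise InvalidDesignError("TMT-like designs need at least one batch")
        unknown = set(self.group_sizes) - set(GROUPS)
        if unknown:
            raise InvalidDesignError(f"unknown groups: {sorted(unknown)}")


def single_center_design() -> CohortDesign:
    """Single-center TMT-like cohort: 101 subjects in 6 batches, 1 GIS each."""
    return CohortDesign(
        group_sizes={"control": 44, "C9_asym": 6, "C9_ALS": 10, "SOD1_ALS": 6, "sALS": 35},
        platform="TMT_like",
        n_batches=6,
        gis_per_batch=1,
        age_mean_sd={
            "control": (64.1, 7.6), "C9_asym": (51.5, 18.5), "C9_ALS": (57.2, 8.7),
            "SOD1_ALS": (59.3, 4.6), "sALS": (56.7, 10.9),
        },
        sex_fraction={
            "control": 27 / 44, "C9_asym": 2 / 6, "C9_ALS": 4 / 10,
            "SOD1_ALS": 2 / 6, "sALS": 13 / 35,
        },
        name="single_center",
    )


def multicenter_design() -> CohortDesign:
    """Four-center DIA-like cohort: 259 subjects, no reference channels."""
    return CohortDesign(
        group_sizes={
            "control": 72, "C9_asym": 59, "C9_ALS": 43,
            "SOD1_asym": 13, "SOD1_ALS": 22, "sALS": 50,
        },
        platform="DIA_like",
        n_centers=4,
        age_mean_sd={
            "control": (59.4, 12.5), "C9_asym": (44.8, 12.8), "C9_ALS": (58.0, 7.0),
            "SOD1_asym": (54.3, 12.0), "SOD1_ALS": (54.6, 12.2), "sALS": (58.4, 10.8),
        },
        sex_fraction={
            "control": 41 / 72, "C9_asym": 34 / 59, "C9_ALS": 20 / 43,
            "SOD1_asym": 9 / 13, "SOD1_ALS": 7 / 22, "sALS": 22 / 50,
        },
        center_composition={
            "control": {"E": 54, "M": 18},
            "C9_asym": {"E": 6, "M": 53},
            "C9_ALS": {"E": 10, "I": 18, "W": 15},
            "SOD1_asym": {"M": 13},
            "SOD1_ALS": {"E": 6, "I": 13, "W": 3},
            "sALS": {"E": 42, "W": 8},
        },
        name="multicenter",
    )


@dataclass(frozen=True)
class TruthParams:
    """Specification of the planted ground truth (before realization)."""

    n_proteins: int = 2300
    n_modules: int = 12
    max_module_size: int = 476
    min_module_size: int = 29
    subthreshold_module_size: int = 10  # one module below the detection minimum
    loading_range: tuple[float, float] = (0.4, 0.95)
    noise_sd: float = 0.5
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    group_effects: dict[int, dict[str, float]] = field(default_factory=dict)
    age_slope_frac: float = 0.2
    age_slope_sd: float = 0.03  # log2 per decade
    sex_offset_frac: float = 0.1
    sex_offset_sd: float = 0.2
    batch_sd: float = 0.3
    mcar_rate: float = 0.03
    mnar_strength: float = 0.5


def default_group_effects() -> dict[int, dict[str, float]]:
    """Planted module-factor shifts (log2) per diagnosis group.

    Mirrors the qualitative pattern of ALS CSF: matrix/microglial/
    ubiquitination-like modules (M5, M7, M10) rise with symptomatic disease,
    neuronal/synaptic modules (M1, M4, M11, M12) fall in C9orf72 ALS, and
    asymptomatic carriers show attenuated, genotype-dependent shifts.
    """
    return {
        1: {"C9_ALS": -0.8, "sALS": -0.3, "SOD1_ALS": 0.3},
        2: {"C9_ALS": 0.5},
        3: {"C9_ALS": 0.5},
        4: {"C9_ALS": -0.8, "sALS": -0.3, "SOD1_ALS": 0.3},
        5: {"sALS": 1.0, "C9_ALS": 1.0, "SOD1_ALS": 1.0, "C9_asym": 0.8, "SOD1_asym": -0.4},
        7: {"sALS": 1.0, "C9_ALS": 1.0, "SOD1_ALS": 1.0},
        8: {"C9_asym": 0.6, "SOD1_asym": -0.4},
        10: {"sALS": 1.2, "C9_ALS": 1.2, "SOD1_ALS": 1.2, "C9_asym": 0.5, "SOD1_asym": -0.5},
        11: {"C9_ALS": -0.8, "sALS": -0.8, "SOD1_ALS": -0.8},
        12: {"C9_ALS": -0.8, "sALS": -0.3, "SOD1_ALS": 0.3},
    }


def default_truth_params() -> TruthParams:
    return TruthParams(group_effects=default_group_effects())


def scaled_truth_params(n_proteins: int, null: bool = False) -> TruthParams:
    """Default truth rescaled so the planted modules fit ``n_proteins``
    (module sizes shrink proportionally; ~12% of proteins stay unassigned)."""
    base = null_truth_params(n_proteins) if null else default_truth_params()
    planted = sum(planted_module_sizes(base))
    f = min(1.0, 0.88 * n_proteins / planted)
    params = replace(
        base,
        n_proteins=n_proteins,
        max_module_size=max(int(round(base.max_module_size * f)), 20),
        min_module_size=max(int(round(base.min_module_size * f)), 8),
        subthreshold_module_size=base.subthreshold_module_size if f == 1.0 else 0,
    )
    # size floors can inflate small designs: drop trailing modules to fit
    while params.n_modules > 2 and sum(planted_module_sizes(params)) > 0.9 * n_proteins:
        params = replace(params, n_modules=params.n_modules - 1)
    return params


def null_truth_params(n_proteins: int = 2000) -> TruthParams:
    """A no-effect design for type-I calibration: no group, age, sex, batch,
    or missingness effects (module structure is still planted)."""
    return TruthParams(
        n_proteins=n_proteins, max_module_size=400, min_module_size=25,
        group_effects={}, age_slope_frac=0.0,
        sex_offset_frac=0.0, batch_sd=0.0, mcar_rate=0.0, mnar_strength=0.0,
    )


@dataclass
class GroundTruth:
    """Realized planted truth shared by every cohort drawn from it."""

    protein_ids: list[str]
    module_of_protein: pd.Series  # protein -> "M1".. or "none"
    loading: pd.Series  # per protein, 0 for unassigned
    group_effect: pd.DataFrame  # module x group, log2 shift of the factor
    age_slope: pd.Series  # log2 per decade
    sex_offset: pd.Series  # log2, added for female samples
    baseline: pd.Series  # log2 abundance level
    noise_sd: float
    batch_sd: float
    mcar_rate: float
    mnar_strength: float

    @property
    def module_sizes(self) -> pd.Series:
        counts = self.module_of_protein[self.module_of_protein != "none"].value_counts()
        return counts.sort_index(key=lambda ix: [int(m[1:]) for m in ix])

    def module_labels(self) -> np.ndarray:
        """Integer labels aligned with protein_ids; 0 = unassigned."""
        lab = self.module_of_protein.reindex(self.protein_ids)
        return np.array([0 if m == "none" else int(m[1:]) for m in lab])

    def to_dict(self) -> dict:
        return {
            "protein_ids": self.protein_ids,
            "module_of_protein": self.module_of_protein.to_dict(),
            "loading": self.loading.to_dict(),
            "group_effect": {m: row.to_dict() for m, row in self.group_effect.iterrows()},
            "age_slope": self.age_slope.to_dict(),
            "sex_offset": self.sex_offset.to_dict(),
            "baseline": self.baseline.to_dict(),
            "noise_sd": self.noise_sd,
            "batch_sd": self.batch_sd,
            "mcar_rate": self.mcar_rate,
            "mnar_strength": self.mnar_strength,
        }


def planted_module_sizes(params: TruthParams) -> list[int]:
    """Geometrically spaced module sizes, largest to smallest, plus one
    module below the detection minimum for negative tests."""
    sizes = np.geomspace(params.max_module_size, params.min_module_size, params.n_modules)
    sizes = [int(round(s)) for s in sizes]
    if params.subthreshold_module_size:
        sizes.append(int(params.subthreshold_module_size))
    return sizes


def realize_truth(params: TruthParams, seed: int) -> GroundTruth:
    """Draw the planted truth (protein identities, memberships, loadings,
    effect sizes) from a truth specification."""
    rng = child_rng(seed, "realize_truth")
    sizes = planted_module_sizes(params)
    n_planted = sum(sizes)
    if n_planted > params.n_proteins:
        raise InvalidDesignError(
            f"planted modules need {n_planted} proteins but n_proteins={params.n_proteins}"
        )

    module_ids = [f"M{k + 1}" for k in range(len(sizes))]
    membership = np.array(
        sum(([m] * s for m, s in zip(module_ids, sizes)), [])
        + ["none"] * (params.n_proteins - n_planted)
    )
    # shuffle protein order so membership is not recoverable from row order
    order = rng.permutation(params.n_proteins)
    membership = membership[order]

    protein_ids = [f"X{i:05d}|G{i:04d}" for i in range(params.n_proteins)]
    # overwrite a few ids with field-known marker names in suitable modules
    used = set()
    for gene, mod_idx in NAMED_MARKERS.items():
        mod = f"M{mod_idx}"
        cand = [i for i in np.flatnonzero(membership == mod) if i not in used]
        if not cand:
            continue
        i = cand[0]
        used.add(i)
        acc = MARKER_ACCESSIONS.get(gene, f"X{i:05d}")
        protein_ids[i] = f"{acc}|{gene}"

    lo, hi = params.loading_range
    loading = np.where(membership != "none", rng.uniform(lo, hi, params.n_proteins), 0.0)

    effects = pd.DataFrame(0.0, index=module_ids, columns=GROUPS)
    for mod_idx, per_group in params.group_effects.items():
        for grp, eff in per_group.items():
            effects.loc[f"M{mod_idx}", grp] = eff
    effects["control"] = 0.0  # control is the reference level by contract

    n = params.n_proteins
    age_slope = np.zeros(n)
    k_age = int(round(params.age_slope_frac * n))
    if k_age:
        idx = rng.choice(n, size=k_age, replace=False)
        age_slope[idx] = rng.normal(0.0, params.age_slope_sd, k_age)
    sex_offset = np.zeros(n)
    k_sex = int(round(params.sex_offset_frac * n))
    if k_sex:
        idx = rng.choice(n, size=k_sex, replace=False)
        sex_offset[idx] = rng.normal(0.0, params.sex_offset_sd, k_sex)

    baseline = rng.normal(params.baseline_mean, params.baseline_sd, n)

    return GroundTruth(
        protein_ids=protein_ids,
        module_of_protein=pd.Series(membership, index=protein_ids),
        loading=pd.Series(loading, index=protein_ids),
        group_effect=effects,
        age_slope=pd.Series(age_slope, index=protein_ids),
        sex_offset=pd.Series(sex_offset, index=protein_ids),
        baseline=pd.Series(baseline, index=protein_ids),
        noise_sd=params.noise_sd,
        batch_sd=params.batch_sd,
        mcar_rate=params.mcar_rate,
        mnar_strength=params.mnar_strength,
    )


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, n: int,
               lo: float = 18.0, hi: float = 90.0) -> np.ndarray:
    if sd <= 0:
        return np.full(n, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _make_traits(design: CohortDesign, seed: int) -> pd.DataFrame:
    rng = child_rng(seed, f"traits:{design.name}")
    rows = []
    for grp in GROUPS:
        count = design.group_sizes.get(grp, 0)
        if count == 0:
            continue
        mean, sd = design.age_mean_sd.get(grp, (58.0, 10.0))
        ages = _truncnorm(rng, mean, sd, count)
        frac_f = design.sex_fraction.get(grp, 0.5)
        n_f = int(round(frac_f * count))
        sexes = np.array(["F"] * n_f + ["M"] * (count - n_f))
        rng.shuffle(sexes)
        if design.platform == "DIA_like" and design.center_composition:
            comp = design.center_composition.get(grp, {})
            centers = sum(([c] * k for c, k in comp.items()), [])
            if len(centers) < count:  # pad round-robin if composition is short
                pool = sorted(comp) or [f"C{i + 1}" for i in range(design.n_centers)]
                centers += [pool[i % len(pool)] for i in range(count - len(centers))]
            centers = centers[:count]
        elif design.platform == "DIA_like":
            centers = [f"C{(i % design.n_centers) + 1}" for i in range(count)]
        else:
            centers = [None] * count
        for i in range(count):
            rows.append({
                "sample_id": f"{design.name}.{grp}.{i + 1:03d}",
                "group": grp,
                "symptomatic": grp in SYMPTOMATIC,
                "age": float(np.round(ages[i], 1)),
                "sex": sexes[i],
                "batch": None,
                "center": centers[i],
                "platform": design.platform,
                "is_reference": False,
            })
    traits = pd.DataFrame(rows)
    if design.platform == "TMT_like":
        # round-robin within group across batches balances diagnosis per batch
        batches = []
        counters: dict[str, int] = {}
        for grp in traits["group"]:
            j = counters.get(grp, 0)
            counters[grp] = j + 1
            batches.append(f"b{(j % design.n_batches) + 1}")
        traits["batch"] = batches
    return traits


def generate_cohort(
    design: CohortDesign,
    truth: TruthParams | GroundTruth,
    seed: int,
    inject_missing: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one cohort: (abundance proteins x samples, traits, truth).

    ``truth`` may be a :class:`TruthParams` spec (realized here) or an
    already-realized :class:`GroundTruth`, which lets two cohorts share one
    planted structure for cross-cohort preservation studies.
    """
    design.validate()
    if isinstance(truth, TruthParams):
        for mod_idx, per_group in truth.group_effects.items():
            for grp, eff in per_group.items():
                if eff != 0 and design.group_sizes.get(grp, None) == 0:
                    raise InvalidDesignError(
                        f"nonzero effect on empty group {grp!r} (module M{mod_idx})"
                    )
        truth = realize_truth(truth, seed)

    traits = _make_traits(design, seed)
    rng = child_rng(seed, f"cohort:{design.name}")
    n_prot = len(truth.protein_ids)
    n_samp = len(traits)
    modules = list(truth.group_effect.index)
    mod_index = {m: k for k, m in enumerate(modules)}

    # latent module factors per sample: shared N(0,1) + group shift
    factors = rng.standard_normal((len(modules), n_samp))
    grp_arr = traits["group"].to_numpy()
    for m in modules:
        shifts = truth.group_effect.loc[m].reindex(grp_arr).to_numpy()
        factors[mod_index[m]] += shifts

    membership = truth.module_of_protein.to_numpy()
    loading = truth.loading.to_numpy()
    values = np.tile(truth.baseline.to_numpy()[:, None], (1, n_samp))
    assigned = membership != "none"
    mod_rows = np.array([mod_index[m] for m in membership[assigned]])
    values[assigned] += loading[assigned, None] * factors[mod_rows]

    ages = traits["age"].to_numpy(dtype=float)
    values += truth.age_slope.to_numpy()[:, None] * ((ages - AGE_CENTER) / 10.0)[None, :]
    is_f = (traits["sex"] == "F").to_numpy()
    values += truth.sex_offset.to_numpy()[:, None] * is_f[None, :]

    if design.platform == "TMT_like":
        block_col, blocks = "batch", sorted(traits["batch"].dropna().unique())
    else:
        block_col, blocks = "center", sorted(traits["center"].dropna().unique())
    if truth.batch_sd > 0 and blocks:
        offsets = rng.normal(0.0, truth.batch_sd, (n_prot, len(blocks)))
        for j, b in enumerate(blocks):
            cols = (traits[block_col] == b).to_numpy()
            values[:, cols] += offsets[:, [j]]

    values += rng.normal(0.0, truth.noise_sd, (n_prot, n_samp))

    matrix = pd.DataFrame(values, index=truth.protein_ids, columns=traits["sample_id"])

    # pooled reference (GIS) channels: per-batch average subject signal
    if design.platform == "TMT_like" and design.gis_per_batch > 0:
        gis_cols, gis_rows = {}, []
        for b in blocks:
            batch_cols = traits.loc[traits["batch"] == b, "sample_id"]
            batch_mean = matrix[batch_cols].mean(axis=1)
            for g in range(design.gis_per_batch):
                sid = f"{design.name}.GIS.{b}.{g + 1}"
                gis_cols[sid] = batch_mean + rng.normal(0.0, 0.1, n_prot)
                gis_rows.append({
                    "sample_id": sid, "group": "GIS", "symptomatic": False,
                    "age": np.nan, "sex": "", "batch": b, "center": None,
                    "platform": design.platform, "is_reference": True,
                })
        matrix = pd.concat([matrix, pd.DataFrame(gis_cols, index=matrix.index)], axis=1)
        traits = pd.concat([traits, pd.DataFrame(gis_rows)], ignore_index=True)

    if inject_missing and (truth.mcar_rate > 0 or truth.mnar_strength > 0):
        matrix = inject_missingness(matrix, truth.mcar_rate, truth.mnar_strength, seed)

    return matrix, traits, truth


def inject_missingness(
    matrix: pd.DataFrame, mcar_rate: float, mnar_strength: float, seed: int
) -> pd.DataFrame:
    """Blank out entries completely at random (``mcar_rate``) and
    preferentially at low abundance (logistic in the global abundance rank,
    scaled by ``mnar_strength``)."""
    if not 0 <= mcar_rate < 1:
        raise ValueError(f"mcar_rate must be in [0, 1), got {mcar_rate}")
    if mnar_strength < 0:
        raise ValueError("mnar_strength must be >= 0")
    out = matrix.copy()
    if mcar_rate == 0 and mnar_strength == 0:
        return out
    rng = child_rng(seed, "inject_missingness")
    vals = out.to_numpy()
    finite = np.isfinite(vals)
    p = np.zeros_like(vals)
    p[finite] = mcar_rate
    if mnar_strength > 0:
        flat = vals[finite]
        ranks = stats.rankdata(flat) / flat.size  # 0 = lowest abundance
        p_mnar = mnar_strength * special.expit((0.1 - ranks) * 20.0)
        p[finite] = p[finite] + (1 - p[finite]) * p_mnar
    drop = rng.random(vals.shape) < p
    vals = vals.copy()
    vals[drop] = np.nan
    return pd.DataFrame(vals, index=out.index, columns=out.columns)


def generate_genesets(
    truth: GroundTruth, n_decoy_sets: int, seed: int
) -> tuple[dict[str, tuple[str, list[str]]], pd.DataFrame]:
    """Gene sets matched to planted modules plus size-matched decoys, and
    five cell-type marker lists overlapping designated modules.

    Each module's matched set takes 80% of its members and pads with 20%
    random genes; decoy sets are random draws of matched sizes.  Marker
    lists follow the canonical CSF assignment: neuron->M1, endothelia->M2,
    oligodendrocyte->M4, astrocyte->M5, microglia->M7.
    """
    if truth.module_sizes.empty:
        raise ValueError("ground truth has no planted modules")
    rng = child_rng(seed, "generate_genesets")
    symbols = pd.Series(
        [pid.split("|", 1)[1] for pid in truth.protein_ids], index=truth.protein_ids
    )
    all_genes = symbols.to_numpy()
    sets: dict[str, tuple[str, list[str]]] = {}
    module_list = list(truth.module_sizes.index)
    for m in module_list:
        members = symbols[truth.module_of_protein == m].to_numpy()
        n_in = int(round(0.8 * len(members)))
        chosen = list(rng.choice(members, size=n_in, replace=False))
        outside = np.setdiff1d(all_genes, members)
        chosen += list(rng.choice(outside, size=len(members) - n_in, replace=False))
        sets[f"SET_{m}"] = (f"planted set matched to module {m}", chosen)
    for d in range(n_decoy_sets):
        size = int(truth.module_sizes.iloc[d % len(module_list)])
        sets[f"DECOY_{d + 1:03d}"] = (
            "size-matched random decoy set",
            list(rng.choice(all_genes, size=size, replace=False)),
        )

    marker_modules = {
        "neuron": "M1", "endothelia": "M2", "oligodendrocyte": "M4",
        "astrocyte": "M5", "microglia": "M7",
    }
    rows = []
    for ct in CELL_TYPES:
        m = marker_modules[ct]
        members = symbols[truth.module_of_protein == m].to_numpy()
        n_in = min(40, max(5, len(members) // 2))
        picked = list(rng.choice(members, size=min(n_in, len(members)), replace=False))
        outside = np.setdiff1d(all_genes, members)
        picked += list(rng.choice(outside, size=20, replace=False))
        rows += [{"gene": g, "cell_type": ct} for g in picked]
    markers = pd.DataFrame(rows)
    return sets, markers
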