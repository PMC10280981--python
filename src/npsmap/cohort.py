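"""Seeded synthetic cohorts emulating a five-group neurodegenerative/cerebrovascular study.

The generator produces one row per participant with diagnostic group, sex,
age, education, MoCA, 68 Desikan-Killiany cortical-thickness values (mm),
10 region-by-hemisphere raw white-matter-hyperintensity volumes (mm^3),
supratentorial total intracranial volume (mm^3), four vascular-risk flags,
and 12 NPI-Q item severities (0-3) with study-partner distress (0-5).

NPI-Q items are generated from four latent subsyndrome propensities: each
propensity is a linear combination of z-scored predictor columns (the
``effect_spec``) plus Gaussian noise, distributed evenly over the
subsyndrome's items and discretized to the 0-3 severity scale.  An empty
``effect_spec`` yields a null cohort in which every predictor-outcome
association is chance-level, which is what the permutation-calibration
tests consume.

Group sizes and sex ratios are fixed margins, not sampled: the default
spec reproduces the modelling sample of the study design this package
emulates (117 + 39 + 51 + 138 + 145 = 490 participants).
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "CohortSpecError",
    "generate_cohort",
    "null_cohort",
    "write_cohort",
    "read_cohort",
    "DX_GROUPS",
    "DK_REGIONS",
    "WMH_REGIONS",
    "HEMISPHERES",
    "NPIQ_SYMPTOMS",
    "SUBSYNDROME_ITEMS",
    "VASCULAR_FLAGS",
    "thickness_columns",
    "wmh_columns",
]

DX_GROUPS = ["ADMCI", "ALS", "FTD", "PD", "CVD"]

#: Desikan-Killiany cortical parcellation, 34 regions per hemisphere.
DK_REGIONS = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "frontalpole",
    "temporalpole", "transversetemporal", "insula",
]

WMH_REGIONS = ["frontal", "parietal", "temporal", "occipital", "bgt"]
HEMISPHERES = ["l", "r"]

NPIQ_SYMPTOMS = [
    "delusions", "hallucinations", "agitation", "depression", "anxiety",
    "euphoria", "apathy", "disinhibition", "irritability", "aberrant_motor",
    "nighttime", "appetite",
]

#: EADC subsyndrome grouping of the 12 NPI-Q items (night-time behaviours
#: grouped with the psychotic items).
SUBSYNDROME_ITEMS = {
    "hyperactivity": ["agitation", "euphoria", "irritability", "disinhibition",
                      "aberrant_motor"],
    "psychotic": ["hallucinations", "delusions", "nighttime"],
    "affective": ["depression", "anxiety"],
    "apathy": ["apathy", "appetite"],
}

VASCULAR_FLAGS = ["hypertension", "diabetes", "high_cholesterol", "smoked_3mo"]


def thickness_columns() -> list[str]:
    """Names of the 68 cortical-thickness columns (``thick_<hemi>h_<region>``)."""
    return [f"thick_{h}h_{r}" for h in HEMISPHERES for r in DK_REGIONS]


def wmh_columns() -> list[str]:
    """Names of the 10 raw regional WMH volume columns (``wmh_<region>_<hemi>``)."""
    return [f"wmh_{r}_{h}" for r in WMH_REGIONS for h in HEMISPHERES]


class CohortSpecError(ValueError):
    """Raised when a cohort specification violates its invariants."""


# Group-level defaults: per-dx (mean, SD) of age and MoCA and sex-by-dx
# counts of the modelling sample; per-dx education means for realism.
_DEFAULT_GROUP_SIZES = {
    "ADMCI": (52, 65), "ALS": (16, 23), "FTD": (19, 32),
    "PD": (31, 107), "CVD": (46, 99),
}
_DEFAULT_AGE = {
    "ADMCI": (71.03, 8.16), "ALS": (61.98, 8.74), "FTD": (67.81, 7.12),
    "PD": (67.94, 6.34), "CVD": (69.35, 7.36),
}
_DEFAULT_MOCA = {
    "ADMCI": (22.67, 2.99), "ALS": (25.46, 2.83), "FTD": (21.48, 3.96),
    "PD": (25.84, 2.57), "CVD": (25.29, 2.99),
}
_DEFAULT_EDUCATION = {
    "ADMCI": (15.23, 3.08), "ALS": (13.83, 2.88), "FTD": (13.89, 2.73),
    "PD": (15.49, 2.73), "CVD": (14.69, 2.88),
}
# Mild global atrophy in the dementia groups; offsets are additive on the mm
# scale and configurable.
_DEFAULT_THICKNESS = {"baseline_mean": 2.5, "sd": 0.15,
                      "dx_offset": {"FTD": -0.15, "ADMCI": -0.15}}
# Log-normal location/scale of raw per-hemisphere WMH volume (mm^3); the
# regional ordering (frontal/parietal > occipital/temporal > BGT) and the
# CVD-highest group offset follow the typical small-vessel-disease pattern.
_DEFAULT_WMH = {
    "log_mean": {"frontal": 6.9, "parietal": 6.7, "temporal": 5.9,
                 "occipital": 6.0, "bgt": 4.3},
    "log_sd": 1.0,
    "dx_offset": {"CVD": 0.8, "PD": 0.2},
}
_DEFAULT_STTIV = (1.4e6, 1.3e5)
# Marginal prevalence of the four vascular-risk flags.
_DEFAULT_VASC_RATES = {"hypertension": 0.72, "diabetes": 0.25,
                       "high_cholesterol": 0.85, "smoked_3mo": 0.51}


@dataclass
class CohortSpec:
    """Configuration of the synthetic cohort generator.

    Parameters
    ----------
    group_sizes
        Mapping dx -> (n_female, n_male).  These are exact margins.
    effect_spec
        List of ``(predictor_column, subsyndrome, coefficient)`` triples.
        Coefficients are on the standardized scale of the latent subsyndrome
        propensity (predictors are z-scored within the generated cohort;
        ``wmh_*`` predictors enter through their head-size-corrected log
        transform).  Empty list = null cohort.
    noise_sd
        Residual SD of the latent subsyndrome propensity.
    item_noise_sd
        SD of the per-item discretization noise.
    wmh_vascular_beta
        Optional planted standardized association between the vascular-risk
        burden count and log-transformed total WMH load (0 = none).
    seed
        Master seed of the cohort RNG stream.
    """

    group_sizes: dict = field(default_factory=lambda: dict(_DEFAULT_GROUP_SIZES))
    age_params: dict = field(default_factory=lambda: dict(_DEFAULT_AGE))
    moca_params: dict = field(default_factory=lambda: dict(_DEFAULT_MOCA))
    education_params: dict = field(default_factory=lambda: dict(_DEFAULT_EDUCATION))
    thickness_params: dict = field(default_factory=lambda: {
        "baseline_mean": _DEFAULT_THICKNESS["baseline_mean"],
        "sd": _DEFAULT_THICKNESS["sd"],
        "dx_offset": dict(_DEFAULT_THICKNESS["dx_offset"]),
    })
    wmh_params: dict = field(default_factory=lambda: {
        "log_mean": dict(_DEFAULT_WMH["log_mean"]),
        "log_sd": _DEFAULT_WMH["log_sd"],
        "dx_offset": dict(_DEFAULT_WMH["dx_offset"]),
    })
    sttiv_params: tuple = _DEFAULT_STTIV
    vascular_rates: dict = field(default_factory=lambda: dict(_DEFAULT_VASC_RATES))
    effect_spec: list = field(default_factory=list)
    noise_sd: float = 1.0
    item_noise_sd: float = 0.5
    wmh_vascular_beta: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for dx, counts in self.group_sizes.items():
            if dx not in DX_GROUPS:
                raise CohortSpecError(f"group_sizes: unknown dx group {dx!r}")
            nf, nm = counts
            if nf < 0 or nm < 0:
                raise CohortSpecError(f"group_sizes[{dx!r}]: counts must be >= 0")
        for name, params in (("age_params", self.age_params),
                             ("moca_params", self.moca_params),
                             ("education_params", self.education_params)):
            for dx, (mean, sd) in params.items():
                if sd <= 0:
                    raise CohortSpecError(f"{name}[{dx!r}]: SD must be > 0")
        if self.thickness_params["sd"] <= 0:
            raise CohortSpecError("thickness_params: sd must be > 0")
        if self.wmh_params["log_sd"] <= 0:
            raise CohortSpecError("wmh_params: log_sd must be > 0")
        if self.sttiv_params[1] <= 0:
            raise CohortSpecError("sttiv_params: SD must be > 0")
        if self.noise_sd <= 0:
            raise CohortSpecError("noise_sd must be > 0")
        if self.item_noise_sd < 0:
            raise CohortSpecError("item_noise_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise CohortSpecError("missing_rate must be in [0, 1)")
        for pred, sub, coef in self.effect_spec:
            if sub not in SUBSYNDROME_ITEMS:
                raise CohortSpecError(
                    f"effect_spec: unknown subsyndrome {sub!r} "
                    f"(expected one of {sorted(SUBSYNDROME_ITEMS)})")

    @property
    def n_total(self) -> int:
        return int(sum(nf + nm for nf, nm in self.group_sizes.values()))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sttiv_params"] = list(self.sttiv_params)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        if "sttiv_params" in d:
            d["sttiv_params"] = tuple(d["sttiv_params"])
        if "group_sizes" in d:
            d["group_sizes"] = {k: tuple(v) for k, v in d["group_sizes"].items()}
        if "effect_spec" in d:
            d["effect_spec"] = [tuple(e) for e in d["effect_spec"]]
        return cls(**d)


def _block_rngs(seed: int, names: list[str]) -> dict:
    """One deterministic child RNG per generation block from a single seed."""
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x, dtype=float)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a complete synthetic cohort table from ``spec``.

    Deterministic given ``spec.seed``.  The returned frame carries the
    planted ``effect_spec`` and seed in ``DataFrame.attrs``.
    """
    spec.validate()
    rngs = _block_rngs(spec.seed, [
        "demographics", "thickness", "wmh", "sttiv", "vascular",
        "latent", "items", "distress", "missing",
    ])

    dx_col, sex_col = [], []
    for dx in DX_GROUPS:
        if dx not in spec.group_sizes:
            continue
        nf, nm = spec.group_sizes[dx]
        dx_col += [dx] * (nf + nm)
        sex_col += ["F"] * nf + ["M"] * nm
    n = len(dx_col)
    if n == 0:
        raise CohortSpecError("group_sizes: cohort is empty")
    dx_arr = np.array(dx_col)

    df = pd.DataFrame({"dx": dx_col, "sex": sex_col})

    rng = rngs["demographics"]
    for col, params, lo, hi, as_int in (
            ("age", spec.age_params, 40.0, 95.0, False),
            ("moca", spec.moca_params, 0.0, 30.0, True),
            ("education", spec.education_params, 5.0, 25.0, True)):
        vals = np.empty(n)
        for dx in spec.group_sizes:
            mask = dx_arr == dx
            mean, sd = params[dx]
            vals[mask] = rng.normal(mean, sd, mask.sum())
        vals = np.clip(vals, lo, hi)
        df[col] = np.round(vals).astype(int) if as_int else np.round(vals, 2)

    blocks: dict[str, np.ndarray] = {}

    rng = rngs["thickness"]
    tp = spec.thickness_params
    offsets = np.array([tp["dx_offset"].get(dx, 0.0) for dx in dx_arr])
    for col in thickness_columns():
        vals = rng.normal(tp["baseline_mean"], tp["sd"], n) + offsets
        blocks[col] = np.round(np.clip(vals, 0.5, None), 4)

    rng = rngs["wmh"]
    wp = spec.wmh_params
    wmh_off = np.array([wp["dx_offset"].get(dx, 0.0) for dx in dx_arr])
    for region in WMH_REGIONS:
        for hemi in HEMISPHERES:
            logv = rng.normal(wp["log_mean"][region], wp["log_sd"], n) + wmh_off
            blocks[f"wmh_{region}_{hemi}"] = np.exp(logv)

    rng = rngs["sttiv"]
    mean, sd = spec.sttiv_params
    blocks["sttiv"] = np.clip(rng.normal(mean, sd, n), 5e5, None)

    rng = rngs["vascular"]
    for flag in VASCULAR_FLAGS:
        blocks[flag] = (rng.random(n) < spec.vascular_rates[flag]).astype(int)

    df = pd.concat([df, pd.DataFrame(blocks, index=df.index)], axis=1)

    if spec.wmh_vascular_beta:
        _plant_wmh_vascular(df, spec.wmh_vascular_beta)

    df = _generate_npiq(df, spec, rngs["latent"], rngs["items"],
                        rngs["distress"])

    if spec.missing_rate > 0:
        rng = rngs["missing"]
        for col in ("moca", "education"):
            mask = rng.random(n) < spec.missing_rate
            df.loc[mask, col] = np.nan

    df.attrs["effect_spec"] = list(spec.effect_spec)
    df.attrs["seed"] = spec.seed
    return df


def _plant_wmh_vascular(df: pd.DataFrame, beta: float) -> None:
    """Scale regional WMH volumes so that the standardized coefficient of the
    vascular-burden count on log total WMH load is approximately ``beta``."""
    burden = df[VASCULAR_FLAGS].sum(axis=1).to_numpy(dtype=float)
    z = _zscore(burden)
    cols = wmh_columns()
    total = df[cols].sum(axis=1).to_numpy()
    base = np.log(total / df["sttiv"].to_numpy() + 1e-4)
    # beta is a correlation target: the multiplier adds beta/sqrt(1-beta^2)
    # baseline-SDs of signal per SD of burden so corr(burden, outcome) = beta.
    slope = beta / np.sqrt(1.0 - beta ** 2) * base.std()
    df[cols] = df[cols].to_numpy() * np.exp(slope * z)[:, None]


def _effect_predictor(df: pd.DataFrame, name: str) -> np.ndarray:
    if name not in df.columns:
        raise CohortSpecError(f"effect_spec: predictor column {name!r} not found")
    x = df[name].to_numpy(dtype=float)
    if name.startswith("wmh_"):
        x = np.log(x / df["sttiv"].to_numpy() + 1e-4)
    return x


def _generate_npiq(df, spec, rng_latent, rng_items,
                   rng_distress) -> pd.DataFrame:
    n = len(df)
    effects: dict[str, list] = {s: [] for s in SUBSYNDROME_ITEMS}
    for pred, sub, coef in spec.effect_spec:
        effects[sub].append((pred, coef))

    cols: dict[str, np.ndarray] = {}
    for sub, items in SUBSYNDROME_ITEMS.items():
        latent = rng_latent.normal(0.0, spec.noise_sd, n)
        for pred, coef in effects[sub]:
            latent = latent + coef * _zscore(_effect_predictor(df, pred))
        k = len(items)
        for item in items:
            noise = rng_items.normal(0.0, spec.item_noise_sd, n)
            sev = np.clip(np.round(latent / k + noise), 0, 3).astype(int)
            cols[f"npiq_{item}_sev"] = sev
            distress = np.clip(np.round(sev + rng_distress.normal(0, 1, n)),
                               0, 5).astype(int)
            cols[f"npiq_{item}_distress"] = np.where(sev > 0, distress, 0)
    return pd.concat([df, pd.DataFrame(cols, index=df.index)], axis=1)


def null_cohort(n_per_stratum: int, seed: int) -> pd.DataFrame:
    """Cohort with no planted effects and ``n_per_stratum`` rows in each of
    the ten sex-by-dx cells; all predictor-outcome associations are
    chance-level."""
    if n_per_stratum < 2:
        raise CohortSpecError(
            "n_per_stratum must be >= 2 (stratified resampling impossible)")
    spec = CohortSpec(
        group_sizes={dx: (n_per_stratum, n_per_stratum) for dx in DX_GROUPS},
        effect_spec=[], seed=seed)
    return generate_cohort(spec)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort as a tab-delimited text table (one header row)."""
    df.to_csv(path, sep="\t", index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort written by :func:`write_cohort`."""
    if isinstance(path, io.TextIOBase):
        return pd.read_csv(path, sep="\t")
    return pd.read_csv(path, sep="\t")
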