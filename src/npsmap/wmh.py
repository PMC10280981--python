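"""White-matter-hyperintensity volume combination and head-size normalization.

Periventricular and deep WMH parcels are summed into five regional volumes
per hemisphere (frontal, parietal, temporal, occipital, basal
ganglia/thalamus).  Each regional volume x (mm^3) is corrected for head
size by the supratentorial total intracranial volume (STTIV) and variance
stabilized:

    corrected = log((x / STTIV) + 0.0001)

The additive constant applies to the volume *fraction*, so zero-volume
regions map to log(0.0001) and the transform is invariant to rescaling
x and STTIV jointly.  Natural log is the default; base 10 is available
and recorded in the output metadata.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import HEMISPHERES, WMH_REGIONS, wmh_columns

__all__ = [
    "WMH_CONSTANT",
    "WmhError",
    "combine_pwmh_dwmh",
    "correct_and_transform",
    "normalize_cohort",
    "regional_summaries",
    "wmhlog_columns",
]

#: Additive constant applied to the volume fraction before the log.
WMH_CONSTANT = 1e-4

_WMH_CLASSES = {"pWMH", "dWMH"}


class WmhError(ValueError):
    pass


def wmhlog_columns() -> list[str]:
    return [f"wmhlog_{r}_{h}" for r in WMH_REGIONS for h in HEMISPHERES]


def combine_pwmh_dwmh(parcels) -> dict[str, float]:
    """Sum labelled parcel volumes into region-by-hemisphere totals.

    ``parcels`` is an iterable of ``(region, hemisphere, wmh_class, volume)``
    tuples with ``wmh_class`` in {"pWMH", "dWMH"}.  Regions with no parcels
    contribute 0.  Returns a dict keyed ``wmh_<region>_<hemi>``.
    """
    totals = {col: 0.0 for col in wmh_columns()}
    for region, hemi, cls, volume in parcels:
        region = str(region).lower()
        hemi = str(hemi).lower()[:1]
        if region not in WMH_REGIONS:
            raise WmhError(
                f"unknown WMH region {region!r}; valid regions: {WMH_REGIONS}")
        if hemi not in HEMISPHERES:
            raise WmhError(f"unknown hemisphere {hemi!r}; valid: {HEMISPHERES}")
        if cls not in _WMH_CLASSES:
            raise WmhError(
                f"unknown WMH class {cls!r}; valid classes: {sorted(_WMH_CLASSES)}")
        if volume < 0:
            raise WmhError(f"negative parcel volume for {region}/{hemi}: {volume}")
        totals[f"wmh_{region}_{hemi}"] += float(volume)
    return totals


def correct_and_transform(x, sttiv, constant: float = WMH_CONSTANT,
                          log_base: str = "e"):
    """Head-size-corrected, log-transformed WMH volume.

    Computes ``log((x / sttiv) + constant)`` elementwise; ``x`` may be a
    scalar or array of raw volumes (mm^3) with ``sttiv`` scalar or aligned.
    """
    x = np.asarray(x, dtype=float)
    sttiv_arr = np.asarray(sttiv, dtype=float)
    if np.any(sttiv_arr <= 0):
        raise WmhError("sttiv must be > 0")
    if np.any(x < 0):
        raise WmhError("raw WMH volume must be >= 0")
    frac = x / sttiv_arr + constant
    if log_base == "e":
        out = np.log(frac)
    elif log_base in ("10", 10):
        out = np.log10(frac)
    else:
        raise WmhError(f"log_base must be 'e' or '10', got {log_base!r}")
    return out if out.ndim else float(out)


def normalize_cohort(df: pd.DataFrame, log_base: str = "e") -> pd.DataFrame:
    """Append ``wmhlog_<region>_<hemi>`` columns and the total WMH load.

    ``wmhlog_total`` is the corrected, transformed sum over all ten
    regional volumes; the log base used is recorded in ``attrs``.
    """
    missing = [c for c in wmh_columns() + ["sttiv"] if c not in df.columns]
    if missing:
        raise WmhError(f"cohort lacks WMH columns: {missing}")
    out = df.copy()
    sttiv = out["sttiv"].to_numpy()
    for region in WMH_REGIONS:
        for hemi in HEMISPHERES:
            out[f"wmhlog_{region}_{hemi}"] = correct_and_transform(
                out[f"wmh_{region}_{hemi}"].to_numpy(), sttiv, log_base=log_base)
    total = out[wmh_columns()].sum(axis=1).to_numpy()
    out["wmhlog_total"] = correct_and_transform(total, sttiv, log_base=log_base)
    out.attrs["wmh_log_base"] = log_base
    return out


def regional_summaries(df: pd.DataFrame) -> pd.DataFrame:
    """Per-region raw-volume summaries, both per hemisphere and
    hemisphere-summed, by diagnostic group."""
    rows = []
    for region in WMH_REGIONS:
        per_hemi = {h: f"wmh_{region}_{h}" for h in HEMISPHERES}
        for dx, grp in df.groupby("dx"):
            row = {"region": region, "dx": dx,
                   "mean_sum": grp[list(per_hemi.values())].sum(axis=1).mean()}
            for h, col in per_hemi.items():
                row[f"mean_{h}"] = grp[col].mean()
            rows.append(row)
    return pd.DataFrame(rows)
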