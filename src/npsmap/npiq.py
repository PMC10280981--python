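"""NPI-Q subsyndrome scoring and vascular-risk burden.

The 12-item Neuropsychiatric Inventory-Questionnaire records, for each
symptom, an informant-rated severity (0-3; 0 = absent) and study-partner
distress (0-5).  Items are grouped into four composite subsyndromes
(hyperactivity, psychotic, affective, apathy); each subsyndrome score is
the sum of its item severities, so total severity decomposes exactly into
the four subsyndromes.  The vascular-risk burden is the count of four
history flags (hypertension, diabetes, high cholesterol, smoking for three
or more months).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import NPIQ_SYMPTOMS, SUBSYNDROME_ITEMS, VASCULAR_FLAGS

__all__ = [
    "NpiqValidationError",
    "SubsyndromeScores",
    "VascularBurden",
    "subsyndrome_scores",
    "vascular_burden",
    "score_cohort",
    "SUBSYNDROME_COLUMNS",
]

SUBSYNDROME_COLUMNS = [f"sub_{s}" for s in SUBSYNDROME_ITEMS]


class NpiqValidationError(ValueError):
    pass


@dataclass(frozen=True)
class SubsyndromeScores:
    hyperactivity: int
    psychotic: int
    affective: int
    apathy: int
    total_severity: int
    total_distress: int


@dataclass(frozen=True)
class VascularBurden:
    count: int
    hypertension: bool
    diabetes: bool
    high_cholesterol: bool
    smoked_3mo: bool


def _check_item(symptom: str, sev, distress) -> tuple[int, int]:
    if sev is None or (isinstance(sev, float) and sev != sev):
        raise NpiqValidationError(f"missing severity for symptom {symptom!r}")
    sev = int(sev)
    if sev not in (0, 1, 2, 3):
        raise NpiqValidationError(
            f"severity for symptom {symptom!r} must be in 0..3, got {sev}")
    distress = 0 if distress is None else int(distress)
    if not 0 <= distress <= 5:
        raise NpiqValidationError(
            f"distress for symptom {symptom!r} must be in 0..5, got {distress}")
    if distress > 0 and sev == 0:
        raise NpiqValidationError(
            f"distress for symptom {symptom!r} is positive but severity is 0")
    return sev, distress


def subsyndrome_scores(record) -> SubsyndromeScores:
    """Score one NPI-Q record into the four subsyndromes and totals.

    ``record`` maps symptom names (see :data:`~npsmap.cohort.NPIQ_SYMPTOMS`)
    to severities 0-3; optional ``<symptom>_distress`` keys hold distress
    values 0-5.  Severity of an absent symptom is 0.
    """
    sev, dis = {}, {}
    for symptom in NPIQ_SYMPTOMS:
        if symptom not in record:
            raise NpiqValidationError(f"missing severity for symptom {symptom!r}")
        s, d = _check_item(symptom, record[symptom],
                           record.get(f"{symptom}_distress", 0))
        sev[symptom], dis[symptom] = s, d
    subs = {name: sum(sev[item] for item in items)
            for name, items in SUBSYNDROME_ITEMS.items()}
    return SubsyndromeScores(
        hyperactivity=subs["hyperactivity"], psychotic=subs["psychotic"],
        affective=subs["affective"], apathy=subs["apathy"],
        total_severity=sum(sev.values()), total_distress=sum(dis.values()))


def vascular_burden(hypertension: bool, diabetes: bool,
                    high_cholesterol: bool, smoked_3mo: bool) -> VascularBurden:
    """Count of positive vascular-risk history flags (0-4)."""
    flags = (bool(hypertension), bool(diabetes), bool(high_cholesterol),
             bool(smoked_3mo))
    return VascularBurden(sum(flags), *flags)


def score_cohort(df: pd.DataFrame, skip_missing: bool = False) -> pd.DataFrame:
    """Append subsyndrome, total, and vascular-burden columns to a cohort.

    Expects ``npiq_<symptom>_sev`` / ``npiq_<symptom>_distress`` columns and
    the four vascular-risk flags.  Records with missing NPI-Q items are
    rejected unless ``skip_missing`` is set, in which case missing items
    count as 0.
    """
    out = df.copy()
    sev_cols = [f"npiq_{s}_sev" for s in NPIQ_SYMPTOMS]
    missing_cols = [c for c in sev_cols if c not in out.columns]
    if missing_cols:
        raise NpiqValidationError(f"cohort lacks NPI-Q columns: {missing_cols}")

    sev = out[sev_cols]
    if sev.isna().any().any():
        if not skip_missing:
            bad = sev.isna().any(axis=1)
            raise NpiqValidationError(
                f"{int(bad.sum())} records have missing NPI-Q items "
                "(pass skip_missing=True to treat missing as 0)")
        sev = sev.fillna(0)
    sev = sev.astype(int)
    if ((sev < 0) | (sev > 3)).any().any():
        bad = [c for c in sev_cols if ((sev[c] < 0) | (sev[c] > 3)).any()]
        raise NpiqValidationError(f"severities outside 0..3 in columns: {bad}")

    for name, items in SUBSYNDROME_ITEMS.items():
        out[f"sub_{name}"] = sev[[f"npiq_{i}_sev" for i in items]].sum(axis=1)
    out["npiq_total_sev"] = sev.sum(axis=1)

    dis_cols = [f"npiq_{s}_distress" for s in NPIQ_SYMPTOMS]
    present = [c for c in dis_cols if c in out.columns]
    out["npiq_total_distress"] = (
        out[present].fillna(0).astype(int).sum(axis=1) if present else 0)

    flag_cols = [c for c in VASCULAR_FLAGS if c in out.columns]
    if len(flag_cols) == len(VASCULAR_FLAGS):
        out["vasc_burden"] = out[flag_cols].astype(bool).sum(axis=1)
    return out
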