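"""Co-IP immunoblot quantification and the lesion-validation gate.

Fluorescence intensities arrive as numbers (densitometry is upstream).  The
co-IP normalization is (coprecipitated protein / precipitated protein) /
(coprecipitated protein in the input): prey signal in the bait IP, corrected
for how much bait was pulled down, then for prey expression in the lysate.
Values are made comparable across gels by dividing every lane by the
reference condition on the same gel.

The tyrosine-hydroxylase (TH) gate validates unilateral 6-OHDA lesions:
an animal passes only when striatal TH immunoreactivity on the lesioned side
is reduced by strictly more than the threshold (default 90%) relative to the
intact side.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InvalidInputError, SchemaError, UndefinedRatioError

__all__ = [
    "normalized_coip",
    "ratio_to_reference",
    "th_gate",
    "th_gate_table",
    "LesionValidation",
]


@dataclass(frozen=True)
class LesionValidation:
    """TH-based lesion-efficiency check for one animal."""

    animal_id: str
    intact_intensity: float
    lesion_intensity: float
    percent_reduction: float
    passed: bool


def normalized_coip(
    coip_prey: float, ip_bait: float, input_prey: float
) -> float:
    """(coIP prey / IP bait) / input prey.

    Note the deliberate non-invariance: a uniform gain change on all three
    channels halves the value (the bait correction cancels, the input does
    not), which is why cross-gel comparisons go through
    :func:`ratio_to_reference` on a per-gel basis.
    """
    if coip_prey < 0 or ip_bait < 0 or input_prey < 0:
        raise InvalidInputError("blot intensities must be nonnegative")
    if ip_bait == 0 or input_prey == 0:
        raise UndefinedRatioError(
            "normalized co-IP undefined: IP bait and input prey must be > 0"
        )
    return (coip_prey / ip_bait) / input_prey


def ratio_to_reference(
    records: pd.DataFrame,
    reference: dict[str, object],
    value_column: str = "normalized",
    gel_column: str = "gel",
) -> pd.Series:
    """Divide each lane's value by its gel's reference-condition value.

    ``reference`` maps condition columns to the level defining the reference
    (e.g. ``{"genotype": "WT", "p35": "absent"}``).  When a gel carries
    several reference lanes their mean is used; a gel with none is a
    configuration error.  The reference condition maps to 1.0 on every gel,
    and scaling all lanes of one gel by a constant leaves every ratio
    unchanged.
    """
    if value_column not in records.columns or gel_column not in records.columns:
        raise SchemaError(
            f"blot table needs columns {value_column!r} and {gel_column!r}"
        )
    mask = pd.Series(True, index=records.index)
    for col, level in reference.items():
        if col not in records.columns:
            raise SchemaError(f"reference condition column {col!r} missing")
        mask &= records[col] == level
    out = pd.Series(index=records.index, dtype=float)
    for gel, group in records.groupby(gel_column):
        ref_values = group.loc[mask.loc[group.index], value_column]
        if ref_values.empty:
            raise SchemaError(f"gel {gel!r} has no reference-condition lane")
        ref = float(ref_values.mean())
        if ref <= 0:
            raise UndefinedRatioError(f"gel {gel!r}: reference value is not > 0")
        out.loc[group.index] = group[value_column] / ref
    return out


def th_gate(
    intact_intensity: float,
    lesion_intensity: float,
    animal_id: str = "",
    threshold_percent: float = 90.0,
) -> LesionValidation:
    """Strict lesion-efficiency gate on TH immunoreactivity.

    reduction = 100 * (1 - lesion/intact); the animal passes iff the
    reduction strictly exceeds ``threshold_percent``.
    """
    if intact_intensity <= 0:
        raise UndefinedRatioError("intact TH intensity must be > 0")
    if lesion_intensity < 0:
        raise InvalidInputError("lesion TH intensity must be >= 0")
    reduction = 100.0 * (1.0 - lesion_intensity / intact_intensity)
    return LesionValidation(
        animal_id=animal_id,
        intact_intensity=intact_intensity,
        lesion_intensity=lesion_intensity,
        percent_reduction=reduction,
        passed=reduction > threshold_percent,
    )


def th_gate_table(
    th: pd.DataFrame,
    threshold_percent: float = 90.0,
    sum_fractions: bool = True,
) -> pd.DataFrame:
    """Apply the TH gate to a table of per-animal intensities.

    Expected columns: ``animal_id``, ``intact``, ``lesion`` and optionally a
    ``fraction`` column (cytosolic/membrane blots).  By default intensities
    are summed over fractions per animal before gating; with
    ``sum_fractions=False`` every fraction must pass on its own.
    """
    for col in ("animal_id", "intact", "lesion"):
        if col not in th.columns:
            raise SchemaError(f"TH table missing column {col!r}")
    if sum_fractions or "fraction" not in th.columns:
        agg = th.groupby("animal_id")[["intact", "lesion"]].sum()
        rows = [
            th_gate(r["intact"], r["lesion"], str(a), threshold_percent)
            for a, r in agg.iterrows()
        ]
        return pd.DataFrame([vars(v) for v in rows])
    results = []
    for animal, group in th.groupby("animal_id"):
        checks = [
            th_gate(r["intact"], r["lesion"], str(animal), threshold_percent)
            for _, r in group.iterrows()
        ]
        reduction = min(c.percent_reduction for c in checks)
        results.append(
            LesionValidation(
                animal_id=str(animal),
                intact_intensity=float(group["intact"].sum()),
                lesion_intensity=float(group["lesion"].sum()),
                percent_reduction=reduction,
                passed=all(c.passed for c in checks),
            )
        )
    return pd.DataFrame([vars(v) for v in results])
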