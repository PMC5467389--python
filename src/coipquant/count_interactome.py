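"""Bait-normalized spectral-count comparison of co-IP interactomes.

Spectral counts (MS/MS spectra matched to a protein) from bait
immunoprecipitates are compared between the lesioned and intact hemispheres
within each subcellular fraction (S2 extrasynaptic, S3 synaptic):

1. proteins with fewer than ``min_total`` counts summed over all samples are
   discarded (an average of 2 counts per sample across the 24-sample design);
2. within each (fraction, hemisphere) stratum, replicate counts are summed
   and each prey total is divided by the bait total — bait normalization
   cancels IP efficiency and instrument-loading differences;
3. the lesion-normalized value over the intact-normalized value gives the
   per-protein, per-fraction ratio;
4. ratios are classified as increased / decreased / unchanged against a
   symmetric percent-change threshold, after a per-fraction depth filter.

Per-animal ratios (each animal contributes its own lesion and intact sample)
are also emitted so a one-sample t-test against 1 can be run downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError, UndefinedRatioError

__all__ = [
    "HEMISPHERES",
    "FRACTIONS",
    "CountMatrix",
    "min_count_filter",
    "stratum_totals",
    "bait_normalize",
    "delta_ratio",
    "classify_delta",
    "interactome_deltas",
    "per_animal_ratios",
    "category_rollup",
]

HEMISPHERES = ("intact", "lesion")
FRACTIONS = ("S2", "S3")

CLASS_INCREASED = "increased"
CLASS_DECREASED = "decreased"
CLASS_UNCHANGED = "unchanged"
CLASS_FILTERED = "filtered_out"

META_COLUMNS = ("animal_id", "hemisphere", "fraction", "replicate_day")


@dataclass
class CountMatrix:
    """Spectral counts (proteins x samples) plus sample metadata and bait id.

    ``counts`` is indexed by protein id with one column per sample id;
    ``meta`` is indexed by sample id with columns ``animal_id``,
    ``hemisphere`` (intact/lesion), ``fraction`` (S2/S3), ``replicate_day``.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    bait: str

    def __post_init__(self) -> None:
        missing_meta = [c for c in META_COLUMNS if c not in self.meta.columns]
        if missing_meta:
            raise SchemaError(f"sample metadata missing columns {missing_meta}")
        unknown = set(self.counts.columns) - set(self.meta.index)
        if unknown:
            raise SchemaError(
                f"count columns without metadata: {sorted(unknown)[:5]}"
            )
        bad_hemi = set(self.meta["hemisphere"]) - set(HEMISPHERES)
        if bad_hemi:
            raise SchemaError(f"unknown hemisphere labels {sorted(bad_hemi)}")
        bad_frac = set(self.meta["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise SchemaError(f"unknown fraction labels {sorted(bad_frac)}")
        arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise InvalidInputError("spectral counts must be nonnegative")
        if not np.allclose(arr, np.round(arr)):
            raise InvalidInputError("spectral counts must be integers")
        if self.bait not in self.counts.index:
            raise SchemaError(f"bait protein {self.bait!r} not in count matrix")
        self.counts.index.name = "protein"

    @property
    def proteins(self) -> pd.Index:
        return self.counts.index

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_in(self, fraction: str, hemisphere: str) -> list[str]:
        m = self.meta
        sel = m[(m["fraction"] == fraction) & (m["hemisphere"] == hemisphere)]
        return [s for s in self.counts.columns if s in sel.index]


def min_count_filter(matrix: CountMatrix, min_total: int = 48) -> CountMatrix:
    """Retain proteins with at least ``min_total`` counts over all samples.

    The default of 48 is an average of 2 spectra per sample across the full
    24-sample design (6 animals x 2 hemispheres x 2 fractions); for other
    designs pass ``min_total = 2 * n_samples``.  The filter is idempotent and
    the bait is retained regardless (it is the normalizer).
    """
    totals = matrix.counts.sum(axis=1)
    keep = (totals >= min_total) | (matrix.counts.index == matrix.bait)
    return CountMatrix(matrix.counts.loc[keep].copy(), matrix.meta, matrix.bait)


def stratum_totals(matrix: CountMatrix) -> pd.DataFrame:
    """Counts summed across replicates, proteins x (fraction, hemisphere)."""
    cols = {}
    for frac in FRACTIONS:
        for hemi in HEMISPHERES:
            samples = matrix.samples_in(frac, hemi)
            cols[(frac, hemi)] = (
                matrix.counts[samples].sum(axis=1)
                if samples
                else pd.Series(0, index=matrix.counts.index)
            )
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["fraction", "hemisphere"])
    return out


def bait_normalize(matrix: CountMatrix) -> pd.DataFrame:
    """Divide each prey's stratum total by the bait's stratum total.

    Counts are summed across the replicates of each (fraction, hemisphere)
    stratum before dividing, so the normalized value is a total-over-total
    ratio; the bait row normalizes to exactly 1 in every stratum.
    """
    totals = stratum_totals(matrix)
    bait_totals = totals.loc[matrix.bait]
    zero = bait_totals[bait_totals == 0]
    if len(zero):
        raise UndefinedRatioError(
            f"bait {matrix.bait!r} has zero counts in strata {list(zero.index)}"
        )
    return totals / bait_totals


def delta_ratio(normalized: pd.DataFrame, protein: str, fraction: str) -> float:
    """Normalized lesion/intact ratio for one protein in one fraction."""
    intact = normalized.loc[protein, (fraction, "intact")]
    lesion = normalized.loc[protein, (fraction, "lesion")]
    if intact == 0:
        raise UndefinedRatioError(
            f"{protein} has zero intact counts in {fraction}; ratio undefined"
        )
    return float(lesion / intact)


def classify_delta(
    ratio: float,
    fraction_totals: tuple[float, float],
    min_fraction_counts: int = 50,
    change: float = 0.18,
) -> str:
    """Classify one ratio against the depth filter and change threshold.

    ``fraction_totals`` are the protein's total counts in (S2, S3), each
    summed over both hemispheres; the protein must reach
    ``min_fraction_counts`` in at least one fraction to be classified at all.
    Thresholds are inclusive: ratio >= 1 + change is increased, ratio <=
    1 - change is decreased.
    """
    if max(fraction_totals) < min_fraction_counts:
        return CLASS_FILTERED
    if ratio >= 1.0 + change:
        return CLASS_INCREASED
    if ratio <= 1.0 - change:
        return CLASS_DECREASED
    return CLASS_UNCHANGED


def interactome_deltas(
    matrix: CountMatrix,
    min_fraction_counts: int = 50,
    change: float = 0.18,
) -> pd.DataFrame:
    """Per-(protein, fraction) ratio table with classification.

    A protein with zero intact counts but nonzero lesion counts has no finite
    ratio; it is kept with ``ratio_defined = False`` and classified as
    increased (subject to the depth filter) rather than dropped silently.
    """
    totals = stratum_totals(matrix)
    normalized = bait_normalize(matrix)
    rows = []
    for protein in matrix.proteins:
        frac_tot = {
            f: float(totals.loc[protein, (f, "intact")] + totals.loc[protein, (f, "lesion")])
            for f in FRACTIONS
        }
        for frac in FRACTIONS:
            intact = float(normalized.loc[protein, (frac, "intact")])
            lesion = float(normalized.loc[protein, (frac, "lesion")])
            defined = intact > 0
            if defined:
                ratio = lesion / intact
                cls = classify_delta(
                    ratio,
                    (frac_tot["S2"], frac_tot["S3"]),
                    min_fraction_counts,
                    change,
                )
            else:
                ratio = np.nan
                if lesion > 0:
                    cls = classify_delta(
                        np.inf,
                        (frac_tot["S2"], frac_tot["S3"]),
                        min_fraction_counts,
                        change,
                    )
                else:
                    cls = CLASS_FILTERED  # absent from this fraction entirely
            rows.append(
                {
                    "protein": protein,
                    "fraction": frac,
                    "intact_total": float(totals.loc[protein, (frac, "intact")]),
                    "lesion_total": float(totals.loc[protein, (frac, "lesion")]),
                    "fraction_total": frac_tot[frac],
                    "normalized_intact": intact,
                    "normalized_lesion": lesion,
                    "ratio": ratio,
                    "ratio_defined": defined,
                    "classification": cls,
                }
            )
    return pd.DataFrame(rows)


def per_animal_ratios(matrix: CountMatrix, pseudocount: float = 0.0) -> pd.DataFrame:
    """Per-animal, per-fraction bait-normalized lesion/intact ratios.

    For each animal the lesion and intact samples of a fraction are paired:
    (prey/bait)_lesion over (prey/bait)_intact.  Animals with a zero
    denominator for a protein yield NaN for that protein.  Feeds the
    one-sample t-test against a theoretical ratio of 1.
    """
    meta = matrix.meta
    rows = []
    for frac in FRACTIONS:
        for animal in sorted(meta["animal_id"].unique()):
            sel = meta[(meta["fraction"] == frac) & (meta["animal_id"] == animal)]
            by_hemi = {
                h: [s for s in sel[sel["hemisphere"] == h].index if s in matrix.counts]
                for h in HEMISPHERES
            }
            if not by_hemi["intact"] or not by_hemi["lesion"]:
                continue
            intact = matrix.counts[by_hemi["intact"]].sum(axis=1) + pseudocount
            lesion = matrix.counts[by_hemi["lesion"]].sum(axis=1) + pseudocount
            bait_i, bait_l = intact[matrix.bait], lesion[matrix.bait]
            if bait_i == 0 or bait_l == 0:
                continue
            norm_i, norm_l = intact / bait_i, lesion / bait_l
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = (norm_l / norm_i).replace([np.inf, -np.inf], np.nan)
            for protein, r in ratio.items():
                rows.append(
                    {
                        "protein": protein,
                        "fraction": frac,
                        "animal_id": animal,
                        "ratio": r,
                    }
                )
    return pd.DataFrame(rows)


def category_rollup(
    deltas: pd.DataFrame, category_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Count classified proteins per (fraction, classification, category).

    Proteins missing from ``category_map`` roll up under "other".  Members
    are listed alphabetically so the report is deterministic.
    """
    if deltas.empty:
        return pd.DataFrame(
            columns=["fraction", "classification", "category", "n", "members"]
        )
    category_map = category_map or {}
    work = deltas.copy()
    work["category"] = [
        category_map.get(p, "other") for p in work["protein"]
    ]
    grouped = (
        work.groupby(["fraction", "classification", "category"])["protein"]
        .agg(n="size", members=lambda s: ";".join(sorted(s)))
        .reset_index()
    )
    return grouped
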