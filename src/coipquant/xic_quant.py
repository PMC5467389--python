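"""Extracted-ion-chromatogram quantification.

An XIC is the intensity-versus-retention-time trace of all chromatogram
points whose m/z falls inside a narrow ppm window around a target ion; its
trapezoid area (AUC) is the label-free abundance proxy used throughout the
package.  On top of XIC extraction this module computes

* phospho-occupancy, phospho/(phospho + total), per sample — with the
  reference-peptide fallback used when the nonphosphorylated counterpart of a
  phosphopeptide is not detected;
* bait-referenced abundance (target AUC over the mean AUC of named reference
  peptides of the immunoprecipitated protein);
* within-animal lesion/intact condition ratios.

Traces for the same modified peptide observed at several charge states are
summed after per-charge extraction (summation-first), which preserves scale
invariance of every downstream ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, UndefinedRatioError
from .peptide_core import IonSpecies, ModifiedPeptide, ion_mz, monoisotopic_mass

__all__ = [
    "ChromatogramSet",
    "XicTrace",
    "ppm_window",
    "extract_xic",
    "trapezoid_auc",
    "species_auc",
    "phospho_occupancy",
    "condition_ratio",
    "normalized_abundance",
    "StoichiometryRecord",
    "AbundanceRatio",
]

#: retention times closer than this (minutes) are treated as the same scan
RT_DECIMALS = 4


@dataclass
class ChromatogramSet:
    """Point cloud of one LC-MS run: (retention time, m/z, intensity) triples."""

    points: pd.DataFrame
    sample: dict | None = None

    REQUIRED = ("rt_min", "mz", "intensity")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.points.columns]
        if missing:
            raise InvalidInputError(f"chromatogram missing columns {missing}")
        pts = self.points
        if len(pts) == 0:
            raise InvalidInputError("chromatogram has no points")
        if not np.isfinite(pts["rt_min"].to_numpy()).all():
            raise InvalidInputError("non-finite retention times")
        if (pts["intensity"].to_numpy() < 0).any():
            raise InvalidInputError("negative intensities")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class XicTrace:
    """An extracted trace: summed intensity on an ordered retention-time grid."""

    rt_grid: np.ndarray
    intensities: np.ndarray
    ion: IonSpecies | None = None
    label: str = ""

    @property
    def auc(self) -> float:
        return trapezoid_auc(self)


def ppm_window(mz: float, tol_ppm: float) -> tuple[float, float]:
    """Symmetric relative mass window [mz(1 - tol*1e-6), mz(1 + tol*1e-6)]."""
    if mz <= 0 or tol_ppm <= 0:
        raise InvalidInputError("mz and tol_ppm must be positive")
    half = mz * tol_ppm * 1e-6
    return (mz - half, mz + half)


def trapezoid_auc(trace: "XicTrace") -> float:
    """Trapezoid-rule area of a trace in intensity * minutes.

    A trace with fewer than two points has zero area.
    """
    if len(trace.rt_grid) < 2:
        return 0.0
    return float(np.trapezoid(trace.intensities, trace.rt_grid))


def extract_xic(
    chromatograms: ChromatogramSet | pd.DataFrame,
    target_mz: float | IonSpecies,
    tol_ppm: float = 10.0,
    rt_range: tuple[float, float] | None = None,
    label: str = "",
) -> XicTrace:
    """Extract the XIC for one ion from one run.

    The trace grid is the *scan grid*: every retention time sampled inside
    ``rt_range`` (rounded to 1e-4 min) becomes a node, and its intensity is
    the sum of all co-eluting points whose m/z falls inside the ppm window —
    zero where the run sampled but nothing matched.  This mirrors how LC-MS
    acquisition works (each scan covers the full m/z range) and makes the
    AUC nondecreasing in the tolerance.  A selection with no in-window
    signal yields a flat-zero trace with AUC 0.
    """
    if isinstance(chromatograms, ChromatogramSet):
        pts = chromatograms.points
    else:
        pts = chromatograms
    ion = target_mz if isinstance(target_mz, IonSpecies) else None
    mz0 = target_mz.mz if ion is not None else float(target_mz)
    lo, hi = ppm_window(mz0, tol_ppm)
    mz = pts["mz"].to_numpy(dtype=float)
    rt = pts["rt_min"].to_numpy(dtype=float)
    inten = pts["intensity"].to_numpy(dtype=float)
    in_rt = np.ones(rt.size, dtype=bool)
    if rt_range is not None:
        in_rt = (rt >= rt_range[0]) & (rt <= rt_range[1])
    if not in_rt.any():
        return XicTrace(np.empty(0), np.empty(0), ion=ion, label=label)
    rt_sel = np.round(rt[in_rt], RT_DECIMALS)
    grid, inverse = np.unique(rt_sel, return_inverse=True)
    summed = np.zeros_like(grid)
    in_window = (mz[in_rt] >= lo) & (mz[in_rt] <= hi)
    np.add.at(summed, inverse[in_window], inten[in_rt][in_window])
    return XicTrace(grid, summed, ion=ion, label=label)


def species_auc(
    chromatograms: ChromatogramSet | pd.DataFrame,
    modified_peptide: ModifiedPeptide,
    charges: Sequence[int] = (2,),
    tol_ppm: float = 10.0,
    rt_range: tuple[float, float] | None = None,
) -> float:
    """Total AUC of one modified peptide: per-charge XICs extracted then summed."""
    neutral = monoisotopic_mass(modified_peptide)
    total = 0.0
    for z in charges:
        trace = extract_xic(
            chromatograms, ion_mz(neutral, z), tol_ppm=tol_ppm, rt_range=rt_range
        )
        total += trace.auc
    return total


# ---------------------------------------------------------------------------
# ratios


def phospho_occupancy(
    phospho_auc: float,
    nonphospho_auc_or_reference: float,
    mode: str = "paired",
) -> float:
    """Phosphorylation stoichiometry of a peptide in one sample.

    ``paired`` mode is phospho/(phospho + total): the phospho AUC divided by
    the sum of phospho and nonphospho AUCs of the same peptide in the same
    run, bounded in [0, 1].  ``reference`` mode is the fallback used when the
    nonphosphorylated counterpart was not detected: the phospho AUC divided by
    the AUC of a designated nonphosphorylated reference peptide (unbounded
    above, still proportional to occupancy at fixed reference).
    """
    if phospho_auc < 0 or nonphospho_auc_or_reference < 0:
        raise InvalidInputError("AUCs must be nonnegative")
    if mode == "paired":
        denom = phospho_auc + nonphospho_auc_or_reference
        if denom == 0:
            raise UndefinedRatioError(
                "paired occupancy undefined: phospho + nonphospho AUC is 0"
            )
        return phospho_auc / denom
    if mode == "reference":
        if nonphospho_auc_or_reference == 0:
            raise UndefinedRatioError("reference AUC is 0")
        return phospho_auc / nonphospho_auc_or_reference
    raise InvalidInputError(f"unknown occupancy mode {mode!r}")


def condition_ratio(lesion_value: float, intact_value: float) -> float:
    """Within-animal lesion/intact ratio (lesion divided by matched intact)."""
    if intact_value <= 0:
        raise UndefinedRatioError(
            f"intact value must be > 0 to form a ratio, got {intact_value}"
        )
    return lesion_value / intact_value


def normalized_abundance(
    target_auc: float, reference_peptide_aucs: Iterable[float]
) -> float:
    """Target AUC over the arithmetic mean of reference-peptide AUCs.

    Normalizing to an average of several peptides of the immunoprecipitated
    (bait) protein cancels run-to-run loading and ionization differences.
    """
    refs = np.asarray(list(reference_peptide_aucs), dtype=float)
    if refs.size == 0:
        raise InvalidInputError("at least one reference peptide required")
    if (refs < 0).any() or target_auc < 0:
        raise InvalidInputError("AUCs must be nonnegative")
    mean_ref = float(refs.mean())
    if mean_ref == 0:
        raise UndefinedRatioError("all reference-peptide AUCs are 0")
    return target_auc / mean_ref


# ---------------------------------------------------------------------------
# per-peptide result containers


@dataclass
class StoichiometryRecord:
    """Per-sample occupancies and per-animal lesion/intact ratios for one site."""

    modified_peptide: ModifiedPeptide
    normalization_mode: str
    occupancy: pd.Series = field(default_factory=pd.Series)  # index: sample key
    lesion_over_intact: pd.Series = field(default_factory=pd.Series)  # index: animal


@dataclass
class AbundanceRatio:
    """Reference-normalized abundances and per-animal lesion/intact ratios."""

    target: str
    normalized: pd.Series = field(default_factory=pd.Series)  # index: sample key
    lesion_over_intact: pd.Series = field(default_factory=pd.Series)  # index: animal
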