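"""Model/Results interface over the quantification pipeline.

Three model classes mirror the three experimental readouts.  Each is built
from data containers, has a ``fit()`` returning a Results object carrying the
estimates, their uncertainties and a ``summary()`` table, and each Results
object exposes plotting helpers:

* :class:`InteractomeModel` — bait-normalized spectral-count comparison of
  the lesioned vs intact interactome per subcellular fraction;
* :class:`OccupancyModel` — XIC-based phosphopeptide occupancy and
  reference-normalized abundance with within-animal lesion/intact ratios;
* :class:`CoIPBlotModel` — co-IP immunoblot normalization with the two-way
  ANOVA + Fisher-LSD analysis of a 2x2 design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import count_interactome as ci
from .blot_quant import normalized_coip, ratio_to_reference
from .errors import (
    DegenerateSampleError,
    InvalidInputError,
    UndefinedRatioError,
)
from .peptide_core import ModifiedPeptide, Peptide
from .stats_core import one_sample_t_vs_1, two_way_anova_lsd
from .synthetic_data import XicTargetSpec
from .xic_quant import (
    ChromatogramSet,
    condition_ratio,
    normalized_abundance,
    phospho_occupancy,
    species_auc,
)

__all__ = [
    "InteractomeModel",
    "InteractomeResults",
    "OccupancyModel",
    "OccupancyResults",
    "CoIPBlotModel",
    "BlotResults",
]


# ---------------------------------------------------------------------------
# interactome


class InteractomeModel:
    """Differential interactome model over a spectral-count matrix.

    Parameters
    ----------
    counts : CountMatrix
        Proteins x samples spectral counts with sample metadata and bait id.
    category_map : mapping, optional
        protein id -> functional category, used for the per-category roll-up.
    """

    def __init__(
        self,
        counts: ci.CountMatrix,
        category_map: Mapping[str, str] | None = None,
    ) -> None:
        self.counts = counts
        self.category_map = dict(category_map or {})

    @classmethod
    def from_tsv(
        cls,
        counts_path,
        meta_path,
        bait: str,
        category_map: Mapping[str, str] | None = None,
    ) -> "InteractomeModel":
        from .io import read_count_matrix

        return cls(read_count_matrix(counts_path, meta_path, bait), category_map)

    def fit(
        self,
        min_total: int = 48,
        min_fraction_counts: int = 50,
        change: float = 0.18,
        alpha: float = 0.05,
    ) -> "InteractomeResults":
        filtered = ci.min_count_filter(self.counts, min_total=min_total)
        deltas = ci.interactome_deltas(
            filtered, min_fraction_counts=min_fraction_counts, change=change
        )
        changed = deltas[deltas["classification"].isin(["increased", "decreased"])]
        rollup = ci.category_rollup(changed, self.category_map)
        replicate_ratios = ci.per_animal_ratios(filtered)
        tests = _ratio_t_tests(replicate_ratios, alpha)
        return InteractomeResults(
            model=self,
            filtered=filtered,
            deltas=deltas,
            rollup=rollup,
            replicate_ratios=replicate_ratios,
            t_tests=tests,
            params={
                "min_total": min_total,
                "min_fraction_counts": min_fraction_counts,
                "change": change,
                "alpha": alpha,
            },
        )


def _ratio_t_tests(replicate_ratios: pd.DataFrame, alpha: float) -> pd.DataFrame:
    rows = []
    if replicate_ratios.empty:
        return pd.DataFrame(columns=["protein", "fraction", "n", "mean_ratio", "t", "df", "p"])
    for (protein, fraction), grp in replicate_ratios.groupby(["protein", "fraction"]):
        vals = grp["ratio"].dropna().to_numpy()
        row = {
            "protein": protein,
            "fraction": fraction,
            "n": vals.size,
            "mean_ratio": vals.mean() if vals.size else np.nan,
        }
        try:
            res = one_sample_t_vs_1(vals, alpha=alpha)
            row.update(t=res.statistic, df=res.df, p=res.p_value)
        except (InvalidInputError, DegenerateSampleError):
            row.update(t=np.nan, df=np.nan, p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class InteractomeResults:
    """Fitted differential interactome: ratios, classifications, tests."""

    model: InteractomeModel
    filtered: ci.CountMatrix
    deltas: pd.DataFrame
    rollup: pd.DataFrame
    replicate_ratios: pd.DataFrame
    t_tests: pd.DataFrame
    params: dict = field(default_factory=dict)

    def classification_counts(self) -> pd.DataFrame:
        """Proteins per (fraction, classification)."""
        return (
            self.deltas.groupby(["fraction", "classification"])
            .size()
            .rename("n")
            .reset_index()
        )

    def summary(self) -> str:
        counts = self.classification_counts()
        lines = [
            "Differential interactome (bait-normalized spectral counts)",
            "=" * 58,
            f"bait: {self.filtered.bait}   proteins after total-count filter: "
            f"{len(self.filtered.proteins)}   samples: {self.filtered.n_samples}",
            f"thresholds: min_total={self.params['min_total']}, "
            f"min_fraction={self.params['min_fraction_counts']}, "
            f"change=+-{self.params['change']:.0%}",
            "",
            counts.to_string(index=False),
            "",
            "changed proteins:",
        ]
        changed = self.deltas[
            self.deltas["classification"].isin(["increased", "decreased"])
        ][["protein", "fraction", "ratio", "classification"]]
        lines.append(
            changed.to_string(index=False, float_format=lambda v: f"{v:.3f}")
            if len(changed)
            else "  (none)"
        )
        return "\n".join(lines)

    def plot_ratios(self, fraction: str = "S3", ax=None):
        from .plotting import plot_delta_ratios

        return plot_delta_ratios(self.deltas, fraction=fraction, ax=ax)


# ---------------------------------------------------------------------------
# XIC occupancy / abundance


class OccupancyModel:
    """Phospho-occupancy and abundance model over per-run chromatograms.

    Parameters
    ----------
    chromatograms : mapping
        run key (``"<animal>_<hemisphere>"``) -> :class:`ChromatogramSet` or
        raw point DataFrame.
    targets : sequence of XicTargetSpec
        Quantification targets; ``phospho_pair`` targets yield occupancies,
        ``abundance`` targets yield reference-normalized abundances, and
        ``reference`` targets provide the normalizer.
    fallback_reference : str, optional
        Name of the reference target used when a phosphopeptide's
        nonphosphorylated counterpart is not detected.
    """

    def __init__(
        self,
        chromatograms: Mapping[str, ChromatogramSet | pd.DataFrame],
        targets: Sequence[XicTargetSpec],
        fallback_reference: str | None = None,
        tol_ppm: float = 10.0,
        sigma: float = 0.05,
        window_sigmas: float = 4.0,
    ) -> None:
        self.chromatograms = dict(chromatograms)
        self.targets = list(targets)
        self.fallback_reference = fallback_reference
        self.tol_ppm = tol_ppm
        self.sigma = sigma
        self.window_sigmas = window_sigmas

    # -- helpers -----------------------------------------------------------
    def _sample_info(self, key: str, chrom) -> tuple[str, str]:
        if isinstance(chrom, ChromatogramSet) and chrom.sample:
            return str(chrom.sample["animal_id"]), str(chrom.sample["hemisphere"])
        animal, hemisphere = key.rsplit("_", 1)
        return animal, hemisphere

    def _auc(self, chrom, target: XicTargetSpec, n_phospho: int) -> float:
        positions = target.phospho_positions[:n_phospho] if n_phospho else ()
        mp = ModifiedPeptide(
            peptide=Peptide(
                sequence=target.peptide, parent=target.name, occurrences=(1,)
            ),
            phospho_positions=tuple(positions),
        )
        return species_auc(
            chrom,
            mp,
            charges=target.charges,
            tol_ppm=self.tol_ppm,
            rt_range=target.rt_range(self.sigma, self.window_sigmas),
        )

    def fit(self, alpha: float = 0.05) -> "OccupancyResults":
        by_kind = {"phospho_pair": [], "abundance": [], "reference": []}
        for t in self.targets:
            if t.kind not in by_kind:
                raise InvalidInputError(f"unknown target kind {t.kind!r}")
            by_kind[t.kind].append(t)
        references = [
            t
            for t in by_kind["reference"]
            if t.name != self.fallback_reference
        ]
        fallback = next(
            (t for t in by_kind["reference"] if t.name == self.fallback_reference),
            None,
        )

        ref_aucs: dict[str, dict[str, float]] = {}
        fallback_aucs: dict[str, float] = {}
        for key, chrom in self.chromatograms.items():
            ref_aucs[key] = {t.name: self._auc(chrom, t, 0) for t in references}
            if fallback is not None:
                fallback_aucs[key] = self._auc(chrom, fallback, 0)

        occ_rows, ab_rows = [], []
        for key, chrom in self.chromatograms.items():
            animal, hemisphere = self._sample_info(key, chrom)
            for t in by_kind["phospho_pair"]:
                p_auc = self._auc(chrom, t, len(t.phospho_positions))
                n_auc = self._auc(chrom, t, 0)
                occ_rows.append(
                    {
                        "target": t.name,
                        "sample": key,
                        "animal_id": animal,
                        "hemisphere": hemisphere,
                        "phospho_auc": p_auc,
                        "nonphospho_auc": n_auc,
                    }
                )
            for t in by_kind["abundance"]:
                auc = self._auc(chrom, t, 0)
                refs = list(ref_aucs[key].values())
                ab_rows.append(
                    {
                        "target": t.name,
                        "sample": key,
                        "animal_id": animal,
                        "hemisphere": hemisphere,
                        "auc": auc,
                        "normalized": normalized_abundance(auc, refs)
                        if refs
                        else np.nan,
                    }
                )

        occupancies = pd.DataFrame(occ_rows)
        if not occupancies.empty:
            # Paired mode needs the nonphospho species detected in every run of
            # the target; otherwise the whole target falls back to the
            # reference peptide so its per-sample values stay comparable.
            modes = {}
            for name, grp in occupancies.groupby("target"):
                modes[name] = (
                    "paired" if (grp["nonphospho_auc"] > 0).all() else "reference"
                )
            occupancies["mode"] = occupancies["target"].map(modes)
            values = []
            for _, r in occupancies.iterrows():
                if r["mode"] == "paired":
                    values.append(
                        phospho_occupancy(r["phospho_auc"], r["nonphospho_auc"], "paired")
                    )
                else:
                    if fallback is None:
                        raise UndefinedRatioError(
                            f"target {r['target']}: nonphospho species missing and "
                            "no fallback reference configured"
                        )
                    values.append(
                        phospho_occupancy(
                            r["phospho_auc"], fallback_aucs[r["sample"]], "reference"
                        )
                    )
            occupancies["occupancy"] = values
        abundances = pd.DataFrame(ab_rows)

        frames = [
            f
            for f in (
                _pair_condition_ratios(occupancies, "occupancy"),
                _pair_condition_ratios(abundances, "normalized"),
            )
            if not f.empty
        ]
        all_ratios = (
            pd.concat(frames, ignore_index=True)
            if frames
            else pd.DataFrame(columns=["target", "animal_id", "ratio"])
        )
        tests = _occupancy_t_tests(all_ratios, alpha)
        return OccupancyResults(
            model=self,
            occupancies=occupancies,
            abundances=abundances,
            ratios=all_ratios,
            t_tests=tests,
            params={"tol_ppm": self.tol_ppm, "alpha": alpha},
        )


def _pair_condition_ratios(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    """Within-animal lesion/intact ratios of a per-sample value table."""
    if table.empty:
        return pd.DataFrame(columns=["target", "animal_id", "ratio"])
    rows = []
    for (target, animal), grp in table.groupby(["target", "animal_id"]):
        by_hemi = grp.set_index("hemisphere")[value_col]
        if "intact" not in by_hemi.index or "lesion" not in by_hemi.index:
            continue
        try:
            ratio = condition_ratio(
                float(by_hemi["lesion"]), float(by_hemi["intact"])
            )
        except UndefinedRatioError:
            ratio = np.nan
        rows.append({"target": target, "animal_id": animal, "ratio": ratio})
    return pd.DataFrame(rows)


def _occupancy_t_tests(ratios: pd.DataFrame, alpha: float) -> pd.DataFrame:
    rows = []
    if ratios.empty:
        return pd.DataFrame(columns=["target", "n", "mean_ratio", "t", "df", "p"])
    for target, grp in ratios.groupby("target"):
        vals = grp["ratio"].dropna().to_numpy()
        row = {
            "target": target,
            "n": vals.size,
            "mean_ratio": vals.mean() if vals.size else np.nan,
        }
        try:
            res = one_sample_t_vs_1(vals, alpha=alpha)
            row.update(t=res.statistic, df=res.df, p=res.p_value)
        except (InvalidInputError, DegenerateSampleError):
            row.update(t=np.nan, df=np.nan, p=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class OccupancyResults:
    """Fitted occupancies, abundances, per-animal ratios and t-tests vs 1."""

    model: OccupancyModel
    occupancies: pd.DataFrame
    abundances: pd.DataFrame
    ratios: pd.DataFrame
    t_tests: pd.DataFrame
    params: dict = field(default_factory=dict)

    def mean_ratio(self, target: str) -> float:
        sel = self.ratios[self.ratios["target"] == target]["ratio"].dropna()
        return float(sel.mean())

    def summary(self) -> str:
        lines = [
            "XIC phospho-occupancy / abundance",
            "=" * 40,
            f"tolerance: {self.params['tol_ppm']} ppm   "
            f"runs: {len(self.model.chromatograms)}",
            "",
            "lesion/intact ratios (t-test vs theoretical 1):",
        ]
        if len(self.t_tests):
            tbl = self.t_tests[["target", "n", "mean_ratio", "t", "df", "p"]]
            lines.append(tbl.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        else:
            lines.append("  (no targets)")
        return "\n".join(lines)

    def plot_occupancy(self, target: str, ax=None):
        from .plotting import plot_occupancy

        return plot_occupancy(self.occupancies, target, ax=ax)


# ---------------------------------------------------------------------------
# co-IP blots


class CoIPBlotModel:
    """Co-IP immunoblot model for a two-factor design.

    Each lane carries coIP prey, IP bait and input prey intensities; the
    normalized value per lane is (coIP/IP)/input, lanes are expressed
    relative to the reference condition of the same gel, and the resulting
    ratios are analyzed with a two-way ANOVA plus uncorrected Fisher LSD.
    """

    REQUIRED = ("gel", "coip_prey", "ip_bait", "input_prey")

    def __init__(
        self,
        records: pd.DataFrame,
        factors: tuple[str, str] = ("genotype", "p35"),
        reference: Mapping[str, object] | None = None,
    ) -> None:
        missing = [c for c in (*self.REQUIRED, *factors) if c not in records.columns]
        if missing:
            raise InvalidInputError(f"blot table missing columns {missing}")
        self.records = records.copy()
        self.factors = factors
        self.reference = dict(
            reference
            if reference is not None
            else {factors[0]: "WT", factors[1]: "absent"}
        )

    def fit(self, alpha: float = 0.05) -> "BlotResults":
        work = self.records.copy()
        work["normalized"] = [
            normalized_coip(r["coip_prey"], r["ip_bait"], r["input_prey"])
            for _, r in work.iterrows()
        ]
        work["ratio"] = ratio_to_reference(work, self.reference)
        anova = two_way_anova_lsd(
            work["ratio"],
            work[self.factors[0]],
            work[self.factors[1]],
            alpha=alpha,
            names=self.factors,
        )
        return BlotResults(model=self, table=work, anova=anova, alpha=alpha)


@dataclass
class BlotResults:
    """Normalized blot ratios with the two-way ANOVA and LSD post hoc."""

    model: CoIPBlotModel
    table: pd.DataFrame
    anova: "object"
    alpha: float = 0.05

    def cell_means(self) -> pd.DataFrame:
        return self.anova.cell_means

    def summary(self) -> str:
        fa, fb = self.model.factors
        lines = [
            "Co-IP immunoblot analysis",
            "=" * 40,
            f"design: {fa} x {fb}   lanes: {len(self.table)}   "
            f"reference: {self.model.reference}",
            "",
            "two-way ANOVA (Type II SS):",
            self.anova.table.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            "Fisher LSD (uncorrected):",
            self.anova.lsd.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)

    def plot_cells(self, ax=None):
        from .plotting import plot_blot_cells

        return plot_blot_cells(self.table, self.model.factors, ax=ax)
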