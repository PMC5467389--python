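"""File formats, run configuration, and the end-to-end pipeline.

All tables are plain TSV with a header row; numeric output is written at
full precision (display rounding happens only in ``summary()`` text).
Readers validate schemas eagerly and raise :class:`SchemaError` with
file/column/row context so a malformed input fails loudly at parse time.
"""

from __future__ import annotations

import hashlib
import json
import re
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .blot_quant import th_gate_table
from .count_interactome import CountMatrix
from .errors import GateError, SchemaError
from .models import CoIPBlotModel, InteractomeModel, OccupancyModel
from .peptide_core import ProteinRecord
from .synthetic_data import (
    BlotSimConfig,
    ChromSimConfig,
    CountSimConfig,
    ThSimConfig,
    XicTargetSpec,
    simulate_blots,
    simulate_chromatograms,
    simulate_counts,
    simulate_th,
    synthetic_nfm,
    synthetic_spinophilin,
)
from .xic_quant import ChromatogramSet

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "read_count_matrix",
    "write_count_matrix",
    "read_count_matrix_s1",
    "read_chromatogram_tsv",
    "write_chromatogram_tsv",
    "read_blot_tsv",
    "read_th_tsv",
    "read_category_map",
    "read_targets_tsv",
    "write_targets_tsv",
    "RunConfig",
    "load_run_config",
    "write_synthetic_bundle",
    "run_pipeline",
    "PipelineReport",
]


# ---------------------------------------------------------------------------
# basic formats


def read_fasta(path, allow_unknown: bool = False) -> list[ProteinRecord]:
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), allow_unknown=allow_unknown)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SchemaError(f"{path}: no FASTA records found")
    return records


def write_fasta(proteins, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(p.sequence), id=p.id, description="") for p in proteins],
        str(path),
        "fasta",
    )


def read_tsv(path, required_columns=(), numeric_columns=()) -> pd.DataFrame:
    """Read a TSV with schema validation; empty files are errors."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty input file") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    for col in numeric_columns:
        bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at row "
                f"{int(bad.index[0]) + 2}"  # +2: header + 1-based
            )
        df[col] = pd.to_numeric(df[col])
    return df


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)


# ---------------------------------------------------------------------------
# count matrices


def read_count_matrix(counts_path, meta_path, bait: str) -> CountMatrix:
    """Counts TSV (first column ``protein``) + sample-metadata TSV."""
    counts = read_tsv(counts_path)
    first = counts.columns[0]
    if first.lower() not in ("protein", "protein_id", "id"):
        raise SchemaError(
            f"{counts_path}: first column must be the protein id, got {first!r}"
        )
    counts = counts.set_index(first)
    counts.index.name = "protein"
    meta = read_tsv(
        meta_path,
        required_columns=("sample_id", "animal_id", "hemisphere", "fraction", "replicate_day"),
    ).set_index("sample_id")
    missing = [c for c in counts.columns if c not in meta.index]
    if missing:
        raise SchemaError(
            f"{counts_path}: sample column {missing[0]!r} missing from metadata"
        )
    return CountMatrix(counts=counts, meta=meta, bait=bait)


def write_count_matrix(matrix: CountMatrix, counts_path, meta_path) -> None:
    write_tsv(matrix.counts.reset_index(), counts_path)
    write_tsv(matrix.meta.reset_index(), meta_path)


_S1_COLUMN = re.compile(
    r"^(?P<fraction>S2|S3)[ _](?P<hemisphere>intact|lesion)[ _](?P<rep>\d+)$",
    re.IGNORECASE,
)


def read_count_matrix_s1(path, bait: str) -> CountMatrix:
    """Ingest the published supplementary-table layout ("S1 dialect").

    The "Spectral Counts and Ratios" tab layout: first column protein id,
    one column per (fraction, hemisphere, replicate) sample named like
    ``S2 Intact 1`` / ``S3_lesion_4`` (separator and case are tolerated),
    plus ratio/total columns that are ignored.  Sample metadata is derived
    from the column names; replicate number doubles as the animal id.
    """
    df = read_tsv(path)
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "protein"
    sample_cols, meta_rows = [], []
    for col in df.columns:
        m = _S1_COLUMN.match(col.strip())
        if m is None:
            continue  # ratio/total columns of the published layout
        frac = m.group("fraction").upper()
        hemi = m.group("hemisphere").lower()
        rep = int(m.group("rep"))
        sid = f"{frac}_{hemi}_a{rep}"
        sample_cols.append((col, sid))
        meta_rows.append(
            {
                "sample_id": sid,
                "animal_id": f"a{rep}",
                "hemisphere": hemi,
                "fraction": frac,
                "replicate_day": 1 if rep <= 3 else 2,
            }
        )
    if not sample_cols:
        raise SchemaError(f"{path}: no sample columns matching the S1 layout")
    counts = df[[c for c, _ in sample_cols]].copy()
    counts.columns = [sid for _, sid in sample_cols]
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return CountMatrix(counts=counts, meta=meta, bait=bait)


# ---------------------------------------------------------------------------
# chromatograms / blots / misc tables


def read_chromatogram_tsv(path, sample: dict | None = None) -> ChromatogramSet:
    df = read_tsv(
        path,
        required_columns=("rt_min", "mz", "intensity"),
        numeric_columns=("rt_min", "mz", "intensity"),
    )
    return ChromatogramSet(points=df, sample=sample)


def write_chromatogram_tsv(chrom: ChromatogramSet, path) -> None:
    write_tsv(chrom.points, path)


def read_blot_tsv(path) -> pd.DataFrame:
    return read_tsv(
        path,
        required_columns=("gel", "coip_prey", "ip_bait", "input_prey"),
        numeric_columns=("coip_prey", "ip_bait", "input_prey"),
    )


def read_th_tsv(path) -> pd.DataFrame:
    return read_tsv(
        path,
        required_columns=("animal_id", "intact", "lesion"),
        numeric_columns=("intact", "lesion"),
    )


def read_category_map(path) -> dict[str, str]:
    df = read_tsv(path, required_columns=("protein", "category"))
    return dict(zip(df["protein"], df["category"]))


_TARGET_COLUMNS = (
    "name",
    "peptide",
    "kind",
    "phospho_positions",
    "charges",
    "rt_apex",
    "amplitude",
    "occupancy_intact",
    "occupancy_lesion",
    "abundance_ratio",
    "include_nonphospho",
    "sigma",
    "rt_low",
    "rt_high",
)


def write_targets_tsv(targets, path) -> None:
    rows = []
    for t in targets:
        d = asdict(t)
        d["phospho_positions"] = ";".join(str(p) for p in t.phospho_positions)
        d["charges"] = ";".join(str(z) for z in t.charges)
        rows.append(d)
    write_tsv(pd.DataFrame(rows, columns=_TARGET_COLUMNS), path)


def _opt_float(value):
    return None if pd.isna(value) else float(value)


def read_targets_tsv(path) -> list[XicTargetSpec]:
    df = read_tsv(path, required_columns=("name", "peptide", "kind", "charges"))
    targets = []
    for _, r in df.iterrows():
        pp = r.get("phospho_positions", "")
        positions = (
            tuple(int(float(x)) for x in str(pp).split(";") if str(x).strip())
            if pd.notna(pp)
            else ()
        )
        charges = tuple(int(x) for x in str(r["charges"]).split(";") if str(x).strip())
        targets.append(
            XicTargetSpec(
                name=r["name"],
                peptide=r["peptide"],
                kind=r["kind"],
                phospho_positions=positions,
                charges=charges,
                rt_apex=float(r.get("rt_apex", 30.0)),
                amplitude=float(r.get("amplitude", 1e6)) if pd.notna(r.get("amplitude")) else 1e6,
                occupancy_intact=_opt_float(r.get("occupancy_intact")),
                occupancy_lesion=_opt_float(r.get("occupancy_lesion")),
                abundance_ratio=float(r.get("abundance_ratio", 1.0)) if pd.notna(r.get("abundance_ratio")) else 1.0,
                include_nonphospho=bool(r.get("include_nonphospho", True)),
                sigma=_opt_float(r.get("sigma")),
                rt_low=_opt_float(r.get("rt_low")),
                rt_high=_opt_float(r.get("rt_high")),
            )
        )
    return targets


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Paths, thresholds and the seed for one pipeline run."""

    outdir: str = "results"
    seed: int = 0
    # inputs (any subset; branches without inputs are skipped)
    counts: str | None = None
    sample_meta: str | None = None
    bait: str = "Spinophilin"
    counts_s1_dialect: bool = False
    chromatogram_dir: str | None = None
    targets: str | None = None
    fallback_reference: str | None = None
    blots: str | None = None
    th: str | None = None
    category_map: str | None = None
    fasta: str | None = None
    # thresholds
    min_total: int = 48
    min_fraction: int = 50
    change: float = 0.18
    tol_ppm: float = 10.0
    alpha: float = 0.05
    th_cut: float = 90.0

    def __post_init__(self) -> None:
        for name in ("min_total", "min_fraction", "change", "tol_ppm", "alpha", "th_cut"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"threshold {name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_run_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**data)


# ---------------------------------------------------------------------------
# synthetic bundle


def write_synthetic_bundle(
    outdir,
    seed: int = 0,
    count_config: CountSimConfig | None = None,
    chrom_config: ChromSimConfig | None = None,
    blot_config: BlotSimConfig | None = None,
    th_config: ThSimConfig | None = None,
) -> RunConfig:
    """Generate every pipeline input under ``outdir`` and return its RunConfig.

    Writes FASTA (synthetic sequences), count + metadata TSVs, one
    chromatogram TSV per run, the target table, blot and TH tables, and the
    ground-truth JSONs alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([synthetic_spinophilin(), synthetic_nfm()], outdir / "proteins.fasta")

    matrix, count_truth = simulate_counts(count_config, seed=seed)
    write_count_matrix(matrix, outdir / "counts.tsv", outdir / "sample_meta.tsv")
    count_truth.to_json(outdir / "counts.ground_truth.json")

    chrom_config = chrom_config or ChromSimConfig()
    runs, chrom_truth = simulate_chromatograms(chrom_config, seed=seed)
    chrom_dir = outdir / "chromatograms"
    chrom_dir.mkdir(exist_ok=True)
    for key, chrom in runs.items():
        write_chromatogram_tsv(chrom, chrom_dir / f"{key}.tsv")
    chrom_truth.to_json(outdir / "chromatograms.ground_truth.json")
    write_targets_tsv(chrom_config.targets, outdir / "targets.tsv")

    blots, blot_truth = simulate_blots(blot_config, seed=seed)
    write_tsv(blots, outdir / "blots.tsv")
    blot_truth.to_json(outdir / "blots.ground_truth.json")

    th, th_truth = simulate_th(th_config, seed=seed)
    write_tsv(th, outdir / "th.tsv")
    th_truth.to_json(outdir / "th.ground_truth.json")

    categories = pd.DataFrame(
        [
            {"protein": "NFM", "category": "cytoskeletal"},
            {"protein": "Sptan1", "category": "cytoskeletal"},
            {"protein": "Actb", "category": "cytoskeletal"},
            {"protein": "Tubb4a", "category": "cytoskeletal"},
            {"protein": "PP1", "category": "signaling"},
            {"protein": "Camk2a", "category": "signaling"},
            {"protein": "Gnao1", "category": "signaling"},
            {"protein": "Myo5a", "category": "myosin"},
            {"protein": "Myh10", "category": "myosin"},
            {"protein": "Cltc", "category": "vesicle_trafficking"},
            {"protein": "Syn1", "category": "vesicle_trafficking"},
            {"protein": "Cntn1", "category": "cell_adhesion"},
            {"protein": "Atp1a3", "category": "ATPase"},
            {"protein": "Dync1h1", "category": "motor"},
            {"protein": "Dlg4", "category": "scaffolding"},
            {"protein": "Gria2", "category": "receptor"},
        ]
    )
    write_tsv(categories, outdir / "categories.tsv")

    return RunConfig(
        outdir=str(outdir / "results"),
        seed=seed,
        counts=str(outdir / "counts.tsv"),
        sample_meta=str(outdir / "sample_meta.tsv"),
        bait=(count_config or CountSimConfig()).bait,
        chromatogram_dir=str(chrom_dir),
        targets=str(outdir / "targets.tsv"),
        fallback_reference="fallback_EQLQGLNDR",
        blots=str(outdir / "blots.tsv"),
        th=str(outdir / "th.tsv"),
        category_map=str(outdir / "categories.tsv"),
        fasta=str(outdir / "proteins.fasta"),
    )


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineReport:
    """In-memory results of one pipeline run plus the paths written."""

    config: RunConfig
    th_validation: pd.DataFrame | None = None
    excluded_animals: tuple[str, ...] = ()
    interactome: "object" = None
    occupancy: "object" = None
    blot: "object" = None
    written: dict[str, str] = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute every branch the config provides inputs for.

    Order: TH lesion gate -> spectral-count branch (total-count filter, bait
    normalization, lesion/intact ratios, classification, category roll-up,
    per-animal t-tests) -> XIC branch (occupancy, abundance, condition
    ratios, t-tests vs 1) -> blot branch (normalization, two-way ANOVA +
    LSD).  Animals failing the TH gate are excluded from every downstream
    branch and listed in the run log.  Numeric outputs are deterministic
    given the config and input files.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config=config)

    excluded: set[str] = set()
    if config.th:
        th = read_th_tsv(config.th)
        validation = th_gate_table(th, threshold_percent=config.th_cut)
        report.th_validation = validation
        excluded = set(validation.loc[~validation["passed"], "animal_id"])
        write_tsv(validation, outdir / "th_validation.tsv")
        report.written["th_validation"] = str(outdir / "th_validation.tsv")
        if validation["passed"].sum() == 0:
            raise GateError("no animal passed the TH lesion-validation gate")
    report.excluded_animals = tuple(sorted(excluded))

    if config.counts:
        if config.counts_s1_dialect:
            matrix = read_count_matrix_s1(config.counts, config.bait)
        else:
            if not config.sample_meta:
                raise SchemaError("counts given without sample_meta")
            matrix = read_count_matrix(config.counts, config.sample_meta, config.bait)
        if excluded:
            keep = [
                s
                for s in matrix.counts.columns
                if str(matrix.meta.loc[s, "animal_id"]) not in excluded
            ]
            matrix = CountMatrix(matrix.counts[keep], matrix.meta.loc[keep], matrix.bait)
        categories = read_category_map(config.category_map) if config.category_map else None
        res = InteractomeModel(matrix, categories).fit(
            min_total=config.min_total,
            min_fraction_counts=config.min_fraction,
            change=config.change,
            alpha=config.alpha,
        )
        report.interactome = res
        write_tsv(res.deltas, outdir / "interactome_deltas.tsv")
        write_tsv(res.rollup, outdir / "category_rollup.tsv")
        write_tsv(res.t_tests, outdir / "interactome_t_tests.tsv")
        report.written["interactome_deltas"] = str(outdir / "interactome_deltas.tsv")

    if config.chromatogram_dir and config.targets:
        chrom_dir = Path(config.chromatogram_dir)
        runs = {}
        for path in sorted(chrom_dir.glob("*.tsv")):
            key = path.stem
            animal = key.rsplit("_", 1)[0]
            if animal in excluded:
                continue
            runs[key] = read_chromatogram_tsv(path)
        if not runs:
            raise SchemaError(f"{chrom_dir}: no chromatogram TSVs found")
        targets = read_targets_tsv(config.targets)
        res = OccupancyModel(
            runs,
            targets,
            fallback_reference=config.fallback_reference,
            tol_ppm=config.tol_ppm,
        ).fit(alpha=config.alpha)
        report.occupancy = res
        write_tsv(res.occupancies, outdir / "occupancies.tsv")
        write_tsv(res.abundances, outdir / "abundances.tsv")
        write_tsv(res.ratios, outdir / "condition_ratios.tsv")
        write_tsv(res.t_tests, outdir / "xic_t_tests.tsv")
        report.written["occupancies"] = str(outdir / "occupancies.tsv")

    if config.blots:
        blots = read_blot_tsv(config.blots)
        res = CoIPBlotModel(blots).fit(alpha=config.alpha)
        report.blot = res
        write_tsv(res.table, outdir / "blot_normalized.tsv")
        write_tsv(res.anova.table.reset_index(names="effect"), outdir / "blot_anova.tsv")
        write_tsv(res.anova.lsd, outdir / "blot_lsd.tsv")
        report.written["blot_anova"] = str(outdir / "blot_anova.tsv")

    log = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "package_version": __version__,
        "excluded_animals": list(report.excluded_animals),
        "outputs": report.written,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    report.written["run_log"] = str(outdir / "run_log.json")
    return report
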