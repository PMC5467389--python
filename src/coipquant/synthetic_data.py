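"""Synthetic study-design generator with known ground truth.

Every input the pipeline consumes can be generated here: protein sequences,
chromatogram point tables, spectral-count matrices with sample metadata, blot
intensity tables, and the TH lesion-validation table.  The generators emulate
the study design the package targets — 6 animals, each contributing a
lesioned and an intact striatal hemisphere, each fractionated into an
extrasynaptic (S2) and synaptic (S3) fraction (24 count samples) — with
planted, serializable effect sizes so recovery can be checked exactly.

Sequences
---------
Real accession sequences are not bundled; :func:`synthetic_nfm` and
:func:`synthetic_spinophilin` build *synthetic analogs* that reproduce the
features the pipeline exercises.  The neurofilament-medium analog carries a
KSP repeat domain in which the tryptic peptide SPVPKSPVEEK occurs at parent
positions 615, 628, 641 and 654, so a phosphate on its second serine maps to
the ambiguous site set {620, 633, 646, 659}; the doubly-phosphorylatable
blocked-cleavage forms AKSPVPKSPVEEK / GKSPVPKSPVEEK / AKSPVPKSPVEEAK arise
at the positions the site numbering implies.  Named quantification peptides
(EQLQGLNDR, QASHAQLGDAYDQEIR, VQSLQDEVAFLR on the NF-M analog; AAGAPQVNSK,
VLEESELAR, SVPAASGGDKEAVAR and the Ser17/Ser100 phosphopeptides on the
spinophilin analog) are embedded exactly once each.

Noise model defaults (the study conditions, not tuning knobs)
-------------------------------------------------------------
* spectral counts: negative binomial, dispersion 10 (variance mu + mu^2/10);
  bait mean 500 per replicate per stratum;
* elution peaks: Gaussian, sigma 0.05 min, sampled at sigma/5 over +-4 sigma;
  m/z jitter N(0, 3 ppm) so a 10 ppm window is exercised meaningfully;
  amplitude noise lognormal with 10% CV; near-zero flat baseline;
* planted effects mirror the magnitudes the pipeline is built to detect:
  an 18% decrease of NF-M, a 28% increase of PP1 in the synaptic fraction,
  elevated Ser17/Ser100 phospho-occupancy in the lesioned hemisphere;
* blots: lognormal channel noise (sigma_log 0.2), per-gel gain factors,
  2x2 genotype x p35 design with cell sizes 8/8/7/7 (error df 26).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .count_interactome import CountMatrix
from .errors import InvalidInputError
from .peptide_core import ProteinRecord, find_occurrences, ion_mz, peptide_mass
from .xic_quant import ChromatogramSet

__all__ = [
    "synthetic_nfm",
    "synthetic_spinophilin",
    "GroundTruth",
    "ProteinEffect",
    "CountSimConfig",
    "XicTargetSpec",
    "ChromSimConfig",
    "BlotSimConfig",
    "ThSimConfig",
    "simulate_counts",
    "simulate_chromatograms",
    "simulate_blots",
    "simulate_th",
    "sample_key",
]

_FILLER = "AEGDTVHLNQAGK"  # serine-free tryptic filler segment


def _pad(n_residues: int) -> list[str]:
    """Filler segments totalling exactly ``n_residues`` residues."""
    if n_residues < 0:
        raise InvalidInputError("cannot pad a negative length")
    reps, rest = divmod(n_residues, len(_FILLER))
    segments = [_FILLER] * reps
    if rest == 1:
        # a lone residue cannot end in K without colliding; borrow from a filler
        if not segments:
            raise InvalidInputError("cannot pad a single residue")
        segments[-1] = _FILLER[:-2] + "K"
        segments.append("AK")
    elif rest > 1:
        segments.append("A" * (rest - 1) + "K")
    return segments


def synthetic_nfm() -> ProteinRecord:
    """Synthetic neurofilament-medium analog (916 aa) with a KSP repeat domain.

    SPVPKSPVEEK occurs at 1-based positions 615, 628, 641 and 654; the second
    serine of each copy sits at 620, 633, 646 and 659.  EQLQGLNDR,
    QASHAQLGDAYDQEIR and VQSLQDEVAFLR each occur exactly once.
    """
    head = [
        "MDSLGSPR",
        "EQLQGLNDR",
        "FAGYIETLR",
        "QASHAQLGDAYDQEIR",
        "TLEGLDK",
        "VQSLQDEVAFLR",
    ]
    head_len = sum(len(s) for s in head)
    segments = head + _pad(612 - head_len)
    segments += ["AK", "SPVPK", "SPVEEK"]  # 613..625, repeat copy 1 at 615
    segments += ["GK", "SPVPK", "SPVEEK"] * 3  # copies at 628, 641, 654
    segments += ["EGDTVHLNQAGEK"]  # 665..677
    segments += ["AK", "SPVPK", "SPVEEAK"]  # 678..691, EEAK breaks the repeat
    tail_len = 916 - sum(len(s) for s in segments)
    segments += _pad(tail_len)
    seq = "".join(segments)
    assert len(seq) == 916
    assert find_occurrences(seq, "SPVPKSPVEEK") == (615, 628, 641, 654)
    for pep in ("EQLQGLNDR", "QASHAQLGDAYDQEIR", "VQSLQDEVAFLR"):
        assert len(find_occurrences(seq, pep)) == 1
    return ProteinRecord(id="NFM_SYNTH", sequence=seq)


def synthetic_spinophilin() -> ProteinRecord:
    """Synthetic spinophilin analog (125 aa) carrying Ser17 and Ser100.

    Ser17 lies in the tryptic peptide LGDAVTPQSGR (peptide-relative position
    9) and Ser100 in AVDEGHLTASPLLR (position 10, an S-P site).  The three
    reference peptides AAGAPQVNSK, VLEESELAR and SVPAASGGDKEAVAR (the latter
    a 1-missed-cleavage product) are embedded once each.
    """
    segments = [
        "MAEVLDTK",  # 1-8
        "LGDAVTPQSGR",  # 9-19, Ser17
        "AAGAPQVNSK",  # 20-29
        "VLEESELAR",  # 30-38
        "TAEDGHVNPADLK",  # 39-51
        "SVPAASGGDK",  # 52-61
        "EAVAR",  # 62-66
        "TGDLAPHEVNQK",  # 67-78
        "LDTPGAVEHQGR",  # 79-90
        "AVDEGHLTASPLLR",  # 91-104, Ser100
        "EGSDEVTAK",  # 105-113
        "AQEPTSDAHDQR",  # 114-125
    ]
    seq = "".join(segments)
    assert seq[16] == "S" and seq[99] == "S"
    for pep in ("AAGAPQVNSK", "VLEESELAR", "SVPAASGGDKEAVAR"):
        assert len(find_occurrences(seq, pep)) == 1
    return ProteinRecord(id="SPINO_SYNTH", sequence=seq)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruth:
    """Serializable record of what a generator planted."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {"kind": self.kind, "seed": self.seed, "params": self.params},
            indent=2,
            sort_keys=True,
            default=_jsonable,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        obj = json.loads(text)
        return cls(kind=obj["kind"], seed=obj["seed"], params=obj["params"])


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def sample_key(animal: str, hemisphere: str) -> str:
    return f"{animal}_{hemisphere}"


# ---------------------------------------------------------------------------
# spectral counts


@dataclass(frozen=True)
class ProteinEffect:
    """One prey protein: relative abundance and planted lesion/intact ratios."""

    name: str
    relative_abundance: float
    ratio_s2: float = 1.0
    ratio_s3: float = 1.0

    def ratio(self, fraction: str) -> float:
        return self.ratio_s2 if fraction == "S2" else self.ratio_s3


def _default_panel() -> tuple[ProteinEffect, ...]:
    """Default prey panel.

    Mirrors the effects the pipeline is designed around (NF-M at 0.82 in both
    fractions, PP1 at 1.28 in S3) and adds six strong changers at 2x / 0.5x /
    3x / 0.33x — comfortably above the classification thresholds given the
    ~18% ratio CV that dispersion-10 counts over 6 replicates imply — plus
    moderate boundary effects, abundant null proteins, and two low-abundance
    proteins that exercise the total-count filter.
    """
    return (
        ProteinEffect("NFM", 0.30, 0.82, 0.82),
        ProteinEffect("PP1", 0.25, 1.00, 1.28),
        ProteinEffect("Myo5a", 0.20, 1.00, 2.00),
        ProteinEffect("Myh10", 0.25, 1.00, 0.50),
        ProteinEffect("Cltc", 0.20, 2.00, 1.00),
        ProteinEffect("Cntn1", 0.15, 0.50, 1.00),
        ProteinEffect("Atp1a3", 0.30, 1.00, 0.33),
        ProteinEffect("Dync1h1", 0.25, 3.00, 1.00),
        ProteinEffect("Gnao1", 0.20, 1.28, 1.00),
        ProteinEffect("Sptan1", 0.40, 1.00, 0.82),
        ProteinEffect("Actb", 0.60, 1.00, 1.00),
        ProteinEffect("Tubb4a", 0.50, 1.00, 1.00),
        ProteinEffect("Camk2a", 0.35, 1.00, 1.00),
        ProteinEffect("Syn1", 0.30, 1.00, 1.00),
        ProteinEffect("Dlg4", 0.15, 1.00, 1.00),
        ProteinEffect("Gria2", 0.10, 1.00, 1.00),
        ProteinEffect("LowAbund1", 0.004, 1.00, 1.00),
        ProteinEffect("LowAbund2", 0.001, 1.00, 1.00),
    )


@dataclass
class CountSimConfig:
    """Design and noise parameters for the spectral-count generator."""

    bait: str = "Spinophilin"
    bait_mean: float = 500.0
    dispersion: float = 10.0
    n_animals: int = 6
    proteins: tuple[ProteinEffect, ...] = field(default_factory=_default_panel)

    def __post_init__(self) -> None:
        if self.dispersion <= 0:
            raise InvalidInputError("dispersion must be > 0")
        if self.bait_mean <= 0 or self.n_animals < 1:
            raise InvalidInputError("bait_mean must be > 0 and n_animals >= 1")


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative-binomial draw with variance mean + mean^2/dispersion."""
    if mean == 0:
        return 0
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_counts(
    config: CountSimConfig | None = None, seed: int = 0
) -> tuple[CountMatrix, GroundTruth]:
    """Simulate the 24-sample spectral-count matrix with planted ratios.

    Each (protein, fraction, hemisphere, animal) cell is a negative-binomial
    draw around bait_mean x relative abundance x planted hemisphere ratio.
    Deterministic under (config, seed).
    """
    config = config or CountSimConfig()
    rng = np.random.default_rng(seed)
    animals = [f"a{i + 1}" for i in range(config.n_animals)]
    meta_rows, columns = [], []
    for frac in ("S2", "S3"):
        for hemi in ("intact", "lesion"):
            for i, animal in enumerate(animals):
                sid = f"{frac}_{hemi}_{animal}"
                columns.append(sid)
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "animal_id": animal,
                        "hemisphere": hemi,
                        "fraction": frac,
                        "replicate_day": 1 if i < (config.n_animals + 1) // 2 else 2,
                    }
                )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    proteins = [
        ProteinEffect(config.bait, 1.0, 1.0, 1.0),
        *config.proteins,
    ]
    data = {}
    for sid in columns:
        frac = meta.loc[sid, "fraction"]
        hemi = meta.loc[sid, "hemisphere"]
        col = []
        for prot in proteins:
            mu = config.bait_mean * prot.relative_abundance
            if hemi == "lesion":
                mu *= prot.ratio(frac)
            col.append(_nb_draw(rng, mu, config.dispersion))
        data[sid] = col
    counts = pd.DataFrame(data, index=[p.name for p in proteins])
    truth = GroundTruth(
        kind="counts",
        seed=seed,
        params={
            "bait": config.bait,
            "bait_mean": config.bait_mean,
            "dispersion": config.dispersion,
            "n_animals": config.n_animals,
            "planted_ratios": {
                p.name: {"S2": p.ratio_s2, "S3": p.ratio_s3} for p in proteins
            },
            "relative_abundance": {
                p.name: p.relative_abundance for p in proteins
            },
        },
    )
    return CountMatrix(counts=counts, meta=meta, bait=config.bait), truth


# ---------------------------------------------------------------------------
# chromatograms


@dataclass(frozen=True)
class XicTargetSpec:
    """One quantification target for the chromatogram generator / XIC branch.

    ``kind`` is one of:

    * ``"phospho_pair"`` — a phospho/nonphospho peptide pair whose amplitude
      is split by the planted per-hemisphere occupancy; with
      ``include_nonphospho=False`` only the phospho species is emitted,
      forcing the reference-peptide fallback downstream;
    * ``"abundance"`` — a single species whose lesion amplitude is scaled by
      ``abundance_ratio``;
    * ``"reference"`` — a bait-normalization peptide (ratio 1 unless stated).
    """

    name: str
    peptide: str
    kind: str
    phospho_positions: tuple[int, ...] = ()
    charges: tuple[int, ...] = (2,)
    rt_apex: float = 30.0
    amplitude: float = 1e6
    occupancy_intact: float | None = None
    occupancy_lesion: float | None = None
    abundance_ratio: float = 1.0
    include_nonphospho: bool = True
    sigma: float | None = None
    rt_low: float | None = None
    rt_high: float | None = None

    def rt_range(
        self, default_sigma: float, window_sigmas: float
    ) -> tuple[float, float]:
        if self.rt_low is not None and self.rt_high is not None:
            return (self.rt_low, self.rt_high)
        s = self.sigma if self.sigma is not None else default_sigma
        return (self.rt_apex - window_sigmas * s, self.rt_apex + window_sigmas * s)

    def occupancy(self, hemisphere: str) -> float:
        occ = (
            self.occupancy_intact if hemisphere == "intact" else self.occupancy_lesion
        )
        if occ is None:
            raise InvalidInputError(f"target {self.name}: occupancy not set")
        return occ


def default_chromatogram_targets() -> tuple[XicTargetSpec, ...]:
    """Targets mirroring the quantification panel on the synthetic sequences."""
    return (
        XicTargetSpec(
            "Spino_pSer17", "LGDAVTPQSGR", "phospho_pair", (9,), (2,),
            rt_apex=22.0, amplitude=8e5,
            occupancy_intact=0.25, occupancy_lesion=0.40,
        ),
        XicTargetSpec(
            "Spino_pSer100", "AVDEGHLTASPLLR", "phospho_pair", (10,), (2, 3),
            rt_apex=35.0, amplitude=6e5,
            occupancy_intact=0.20, occupancy_lesion=0.32,
        ),
        XicTargetSpec(
            "NFM_KSP_pS2", "SPVPKSPVEEK", "phospho_pair", (6,), (2,),
            rt_apex=18.0, amplitude=5e5,
            occupancy_intact=0.30, occupancy_lesion=0.45,
        ),
        XicTargetSpec(
            "NFM_pQLSDIEER", "QLSDIEER", "phospho_pair", (3,), (2,),
            rt_apex=28.0, amplitude=4e5,
            occupancy_intact=0.30, occupancy_lesion=0.45,
            include_nonphospho=False,  # exercises the EQLQGLNDR fallback
        ),
        XicTargetSpec(
            "NFM_QASHAQLGDAYDQEIR", "QASHAQLGDAYDQEIR", "abundance", (), (2, 3),
            rt_apex=45.0, amplitude=1e6, abundance_ratio=0.82,
        ),
        XicTargetSpec(
            "NFM_VQSLQDEVAFLR", "VQSLQDEVAFLR", "abundance", (), (2,),
            rt_apex=52.0, amplitude=9e5, abundance_ratio=0.82,
        ),
        XicTargetSpec(
            "ref_AAGAPQVNSK", "AAGAPQVNSK", "reference", (), (2,),
            rt_apex=15.0, amplitude=1.2e6,
        ),
        XicTargetSpec(
            "ref_VLEESELAR", "VLEESELAR", "reference", (), (2,),
            rt_apex=25.0, amplitude=1.0e6,
        ),
        XicTargetSpec(
            "ref_SVPAASGGDKEAVAR", "SVPAASGGDKEAVAR", "reference", (), (2,),
            rt_apex=40.0, amplitude=8e5,
        ),
        XicTargetSpec(
            "fallback_EQLQGLNDR", "EQLQGLNDR", "reference", (), (2,),
            rt_apex=30.0, amplitude=7e5,
        ),
    )


@dataclass
class ChromSimConfig:
    """Noise and sampling parameters for the chromatogram generator."""

    targets: tuple[XicTargetSpec, ...] = field(
        default_factory=default_chromatogram_targets
    )
    n_animals: int = 6
    sigma_min: float = 0.05  # elution peak width, minutes
    rt_step_sigmas: float = 0.2  # grid step as a fraction of sigma
    window_sigmas: float = 4.0
    mz_jitter_ppm: float = 3.0
    amplitude_cv: float = 0.10
    baseline_points: int = 30
    baseline_level: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_min <= 0:
            raise InvalidInputError("sigma_min must be > 0")
        if any(t.amplitude <= 0 for t in self.targets):
            raise InvalidInputError("peak amplitudes must be > 0")
        if self.amplitude_cv < 0:
            raise InvalidInputError("amplitude_cv must be >= 0")


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-1 multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(rng.lognormal(-0.5 * sigma * sigma, sigma))


def _species_list(target: XicTargetSpec, hemisphere: str) -> list[tuple[str, int, float]]:
    """(species label, n_phospho, amplitude) for one target in one hemisphere."""
    if target.kind == "phospho_pair":
        occ = target.occupancy(hemisphere)
        out = [("phospho", len(target.phospho_positions), target.amplitude * occ)]
        if target.include_nonphospho:
            out.append(("nonphospho", 0, target.amplitude * (1.0 - occ)))
        return out
    scale = target.abundance_ratio if hemisphere == "lesion" else 1.0
    return [("total", 0, target.amplitude * scale)]


def simulate_chromatograms(
    config: ChromSimConfig | None = None, seed: int = 0
) -> tuple[dict[str, ChromatogramSet], GroundTruth]:
    """Simulate one chromatogram point table per (animal, hemisphere) run.

    Each species elutes as a Gaussian peak sampled on a grid of step
    sigma x ``rt_step_sigmas`` over apex +- ``window_sigmas`` x sigma; point
    m/z values jitter around the theoretical value by N(0, mz_jitter_ppm);
    per-charge amplitudes split the species amplitude equally.  Amplitude
    noise is multiplicative lognormal per (sample, species).
    """
    config = config or ChromSimConfig()
    rng = np.random.default_rng(seed)
    animals = [f"a{i + 1}" for i in range(config.n_animals)]
    runs: dict[str, ChromatogramSet] = {}
    planted_amplitudes: dict[str, dict[str, float]] = {}
    for animal in animals:
        for hemi in ("intact", "lesion"):
            key = sample_key(animal, hemi)
            rts, mzs, intens = [], [], []
            amps: dict[str, float] = {}
            for target in config.targets:
                sigma = target.sigma if target.sigma is not None else config.sigma_min
                step = sigma * config.rt_step_sigmas
                grid = np.arange(
                    target.rt_apex - config.window_sigmas * sigma,
                    target.rt_apex + config.window_sigmas * sigma + 0.5 * step,
                    step,
                )
                for label, n_phospho, amplitude in _species_list(target, hemi):
                    amp = amplitude * _lognormal_factor(rng, config.amplitude_cv)
                    amps[f"{target.name}:{label}"] = amp
                    neutral = peptide_mass(target.peptide, n_phospho)
                    shape = np.exp(
                        -0.5 * ((grid - target.rt_apex) / sigma) ** 2
                    )
                    for z in target.charges:
                        mz0 = ion_mz(neutral, z)
                        jitter = rng.normal(0.0, config.mz_jitter_ppm * 1e-6, grid.size)
                        rts.append(grid)
                        mzs.append(mz0 * (1.0 + jitter))
                        intens.append(amp / len(target.charges) * shape)
            if config.baseline_points:
                rts.append(rng.uniform(5.0, 90.0, config.baseline_points))
                mzs.append(rng.uniform(300.0, 1500.0, config.baseline_points))
                intens.append(rng.uniform(0.0, config.baseline_level, config.baseline_points))
            pts = pd.DataFrame(
                {
                    "rt_min": np.concatenate(rts),
                    "mz": np.concatenate(mzs),
                    "intensity": np.concatenate(intens),
                }
            )
            runs[key] = ChromatogramSet(points=pts, sample={"animal_id": animal, "hemisphere": hemi})
            planted_amplitudes[key] = amps
    truth = GroundTruth(
        kind="chromatograms",
        seed=seed,
        params={
            "n_animals": config.n_animals,
            "sigma_min": config.sigma_min,
            "mz_jitter_ppm": config.mz_jitter_ppm,
            "amplitude_cv": config.amplitude_cv,
            "occupancies": {
                t.name: {
                    "intact": t.occupancy_intact,
                    "lesion": t.occupancy_lesion,
                }
                for t in config.targets
                if t.kind == "phospho_pair"
            },
            "abundance_ratios": {
                t.name: t.abundance_ratio
                for t in config.targets
                if t.kind == "abundance"
            },
            "amplitudes": planted_amplitudes,
        },
    )
    return runs, truth


# ---------------------------------------------------------------------------
# blots


@dataclass
class BlotSimConfig:
    """2x2 genotype x p35 co-IP blot design with per-gel gains.

    Default cell sizes (8, 8, 7, 7) give 30 lanes and an ANOVA error df of
    26, the df structure of the design this generator emulates.
    """

    genotypes: tuple[str, str] = ("WT", "S17A")
    p35_levels: tuple[str, str] = ("absent", "present")
    n_per_cell: dict[tuple[str, str], int] = field(
        default_factory=lambda: {
            ("WT", "absent"): 8,
            ("WT", "present"): 8,
            ("S17A", "absent"): 7,
            ("S17A", "present"): 7,
        }
    )
    coip_base: float = 1000.0
    ip_bait_base: float = 500.0
    input_prey_base: float = 200.0
    p35_effect: float = 0.6  # multiplies coIP prey when p35 is present
    genotype_effect: float = 1.0  # S17A multiplier (no planted effect)
    interaction_effect: float = 1.0
    sigma_log: float = 0.2
    gel_gain_sigma_log: float = 0.3


def simulate_blots(
    config: BlotSimConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the co-IP blot table: one row per lane.

    Replicate r of every cell runs on gel r, so each gel carries the full
    2x2 design (the last gels lack the smaller cells) including the
    reference condition; a per-gel lognormal gain multiplies all channels.
    """
    config = config or BlotSimConfig()
    rng = np.random.default_rng(seed)
    max_n = max(config.n_per_cell.values())
    gains = {
        g: float(rng.lognormal(0.0, config.gel_gain_sigma_log))
        for g in range(1, max_n + 1)
    }
    rows = []
    for genotype in config.genotypes:
        for p35 in config.p35_levels:
            n = config.n_per_cell[(genotype, p35)]
            effect = 1.0
            if p35 == "present":
                effect *= config.p35_effect
            if genotype == "S17A":
                effect *= config.genotype_effect
            if p35 == "present" and genotype == "S17A":
                effect *= config.interaction_effect
            for rep in range(1, n + 1):
                gain = gains[rep]
                noise = rng.lognormal(0.0, config.sigma_log, 3)
                rows.append(
                    {
                        "gel": rep,
                        "genotype": genotype,
                        "p35": p35,
                        "coip_prey": config.coip_base * effect * noise[0] * gain,
                        "ip_bait": config.ip_bait_base * noise[1] * gain,
                        "input_prey": config.input_prey_base * noise[2] * gain,
                    }
                )
    table = pd.DataFrame(rows)
    truth = GroundTruth(
        kind="blots",
        seed=seed,
        params={
            "p35_effect": config.p35_effect,
            "genotype_effect": config.genotype_effect,
            "interaction_effect": config.interaction_effect,
            "sigma_log": config.sigma_log,
            "n_per_cell": {f"{g}|{p}": n for (g, p), n in config.n_per_cell.items()},
        },
    )
    return table, truth


# ---------------------------------------------------------------------------
# TH lesion validation


@dataclass
class ThSimConfig:
    """Planted TH reductions; one animal below the gate by default."""

    reductions: dict[str, float] = field(
        default_factory=lambda: {
            "a1": 0.92,
            "a2": 0.94,
            "a3": 0.95,
            "a4": 0.97,
            "a5": 0.93,
            "a6": 0.98,
            "a7": 0.85,  # fails the >90% gate; excluded downstream
        }
    )
    base_intensity: float = 1000.0
    sigma_log: float = 0.05


def simulate_th(
    config: ThSimConfig | None = None, seed: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate cytosolic + membrane TH blot intensities per animal."""
    config = config or ThSimConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for animal, reduction in config.reductions.items():
        for fraction in ("cytosolic", "membrane"):
            intact = config.base_intensity * float(
                rng.lognormal(0.0, config.sigma_log)
            )
            lesion = intact * (1.0 - reduction) * float(
                rng.lognormal(0.0, config.sigma_log)
            )
            rows.append(
                {
                    "animal_id": animal,
                    "fraction": fraction,
                    "intact": intact,
                    "lesion": lesion,
                }
            )
    truth = GroundTruth(
        kind="th", seed=seed, params={"reductions": dict(config.reductions)}
    )
    return pd.DataFrame(rows), truth
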