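"""Protein digestion, peptide mass arithmetic, and phosphosite mapping.

This module turns protein sequences into the ion-level quantities the rest of
the pipeline consumes: tryptic peptides with *all* of their occurrence
positions on the parent (repeat-domain peptides occur more than once),
monoisotopic masses and m/z values of (optionally phosphorylated) peptides,
b/y fragment series for spectrum annotation, and the mapping of
peptide-relative phosphosites to sets of parent-protein residue numbers.

The site-ambiguity machinery exists because identical tryptic peptides from
sequence repeats (e.g. the Lys-Ser-Pro repeat domain of neurofilament medium)
make it impossible to say which copy of the repeat carried the phosphate: a
single peptide-relative phosphosite therefore maps to a *set* of candidate
protein residues, one per occurrence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

from .constants import (
    CANONICAL_RESIDUES,
    MONOISOTOPIC_RESIDUE_MASS,
    PHOSPHO,
    PHOSPHORYLATABLE,
    PROTON,
    WATER,
)
from .errors import InvalidInputError

__all__ = [
    "ProteinRecord",
    "Peptide",
    "ModifiedPeptide",
    "IonSpecies",
    "digest",
    "digest_segments",
    "monoisotopic_mass",
    "peptide_mass",
    "ion_mz",
    "fragment_series",
    "resolve_site_ambiguity",
    "find_occurrences",
    "digest_table",
]


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with 1-based residue numbering.

    Site labels such as "Ser17" refer to 1-based positions on ``sequence``
    including the initiator methionine; no N-terminal processing is applied.
    """

    id: str
    sequence: str
    allow_unknown: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError(f"protein {self.id!r}: empty sequence")
        alphabet = CANONICAL_RESIDUES | ({"X"} if self.allow_unknown else set())
        bad = set(self.sequence) - alphabet
        if bad:
            raise InvalidInputError(
                f"protein {self.id!r}: non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.sequence):
            raise InvalidInputError(
                f"position {position} outside 1..{len(self.sequence)}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class Peptide:
    """A peptide with every 1-based start position it occupies on its parent."""

    sequence: str
    parent: str
    occurrences: tuple[int, ...]
    missed_cleavages: int = 0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidInputError("empty peptide sequence")
        if not self.occurrences:
            raise InvalidInputError(
                f"peptide {self.sequence!r}: occurrences must be non-empty"
            )
        if list(self.occurrences) != sorted(self.occurrences):
            raise InvalidInputError(
                f"peptide {self.sequence!r}: occurrences must be sorted"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ModifiedPeptide:
    """A peptide plus phosphosites, with the parent-residue ambiguity resolved.

    ``phospho_positions`` are peptide-relative 1-based indices of S/T/Y
    residues.  ``ambiguous_site_sets`` holds, for each phosphosite, the sorted
    tuple of parent-protein residue numbers it may correspond to — one entry
    per occurrence of the peptide on the parent.
    """

    peptide: Peptide
    phospho_positions: tuple[int, ...] = ()
    ambiguous_site_sets: tuple[tuple[int, ...], ...] = ()

    def __post_init__(self) -> None:
        seq = self.peptide.sequence
        for pos in self.phospho_positions:
            if not 1 <= pos <= len(seq):
                raise InvalidInputError(
                    f"phospho position {pos} outside peptide 1..{len(seq)}"
                )
            if seq[pos - 1] not in PHOSPHORYLATABLE:
                raise InvalidInputError(
                    f"phospho position {pos} is {seq[pos - 1]!r}, not S/T/Y"
                )
        if self.ambiguous_site_sets and len(self.ambiguous_site_sets) != len(
            self.phospho_positions
        ):
            raise InvalidInputError(
                "one ambiguity set required per phospho position"
            )

    @property
    def sequence(self) -> str:
        return self.peptide.sequence

    @property
    def n_phospho(self) -> int:
        return len(self.phospho_positions)


@dataclass(frozen=True)
class IonSpecies:
    """A (modified peptide, charge) pair with its theoretical monoisotopic m/z."""

    modified_peptide: ModifiedPeptide
    charge: int
    mz: float

    @classmethod
    def from_peptide(cls, modified_peptide: ModifiedPeptide, charge: int) -> "IonSpecies":
        return cls(modified_peptide, charge, ion_mz(modified_peptide, charge))


# ---------------------------------------------------------------------------
# digestion


def _cleavage_boundaries(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cleaves between i and i+1.

    Cleaves C-terminal to K or R, except when the next residue is proline.
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest_segments(sequence: str) -> list[str]:
    """Ordered fully-cleaved (0 missed cleavages) tryptic segments.

    Concatenating the returned segments reproduces ``sequence`` exactly.
    """
    if not sequence:
        raise InvalidInputError("empty sequence")
    bounds = [-1] + _cleavage_boundaries(sequence) + [len(sequence) - 1]
    return [sequence[bounds[k] + 1 : bounds[k + 1] + 1] for k in range(len(bounds) - 1)]


def find_occurrences(parent_sequence: str, peptide_sequence: str) -> tuple[int, ...]:
    """All 1-based start positions of ``peptide_sequence`` in the parent.

    Overlapping matches are found (exhaustive substring search).
    """
    pattern = re.compile(f"(?={re.escape(peptide_sequence)})")
    return tuple(m.start() + 1 for m in pattern.finditer(parent_sequence))


def digest(
    protein: ProteinRecord,
    max_missed_cleavages: int = 2,
    phospho_blocks_cleavage: bool = False,
) -> list[Peptide]:
    """In-silico tryptic digest with occurrence tracking.

    Trypsin rule: cleave C-terminal to K/R unless followed by P.  Peptides are
    deduplicated by sequence; each carries *all* of its occurrence positions on
    the parent (repeat peptides therefore appear once, with several starts).

    With ``phospho_blocks_cleavage``, a cleavage site whose following segment
    begins with a serine (a phosphorylatable-S-first repeat peptide, where
    phosphorylation of that serine may prevent cleavage of the preceding
    lysine) does not count against the missed-cleavage budget, so the longer
    blocked-cleavage forms are *additionally* emitted; the fully cleaved
    products are never removed.
    """
    if max_missed_cleavages < 0:
        raise InvalidInputError("max_missed_cleavages must be >= 0")
    segments = digest_segments(protein.sequence)
    n = len(segments)
    best: dict[str, int] = {}
    order: list[str] = []
    for i in range(n):
        counted = 0
        pieces: list[str] = []
        for j in range(i, n):
            if j > i:
                # junction between segment j-1 and segment j
                if not (phospho_blocks_cleavage and segments[j].startswith("S")):
                    counted += 1
                if counted > max_missed_cleavages:
                    break
            pieces.append(segments[j])
            seq = "".join(pieces)
            if seq not in best:
                best[seq] = j - i
                order.append(seq)
            else:
                best[seq] = min(best[seq], j - i)
    return [
        Peptide(
            sequence=seq,
            parent=protein.id,
            occurrences=find_occurrences(protein.sequence, seq),
            missed_cleavages=best[seq],
        )
        for seq in order
    ]


# ---------------------------------------------------------------------------
# mass arithmetic


def peptide_mass(sequence: str, n_phospho: int = 0) -> float:
    """Neutral monoisotopic mass of a linear peptide with ``n_phospho`` phosphates."""
    if not sequence:
        raise InvalidInputError("empty peptide sequence")
    try:
        mass = sum(MONOISOTOPIC_RESIDUE_MASS[aa] for aa in sequence)
    except KeyError as exc:
        raise InvalidInputError(f"unknown residue {exc.args[0]!r}") from None
    return mass + WATER + n_phospho * PHOSPHO


def monoisotopic_mass(modified_peptide: ModifiedPeptide) -> float:
    """Neutral monoisotopic mass of a modified peptide (Da)."""
    return peptide_mass(modified_peptide.sequence, modified_peptide.n_phospho)


def ion_mz(modified_peptide: ModifiedPeptide | float, charge: int) -> float:
    """Theoretical monoisotopic m/z: (M + z * proton) / z.

    Accepts either a :class:`ModifiedPeptide` or a precomputed neutral mass.
    """
    if charge < 1:
        raise InvalidInputError(f"charge must be >= 1, got {charge}")
    if isinstance(modified_peptide, ModifiedPeptide):
        neutral = monoisotopic_mass(modified_peptide)
    else:
        neutral = float(modified_peptide)
    return (neutral + charge * PROTON) / charge


def fragment_series(
    modified_peptide: ModifiedPeptide, charge: int = 1
) -> tuple[list[float], list[float]]:
    """b- and y-series fragment m/z values for MS/MS annotation.

    Returns (b_ions, y_ions), each of length n-1 for a peptide of length n.
    The phospho mass travels with its residue, so b_i includes phosphates on
    residues 1..i and y_j those on the last j residues.  At charge 1,
    b_i + y_(n-i) = M + 2 * proton for every i.
    """
    if charge < 1:
        raise InvalidInputError(f"charge must be >= 1, got {charge}")
    seq = modified_peptide.sequence
    if len(seq) < 2:
        raise InvalidInputError("fragment series requires peptide length >= 2")
    phospho = set(modified_peptide.phospho_positions)
    residue_masses = []
    for idx, aa in enumerate(seq, start=1):
        try:
            m = MONOISOTOPIC_RESIDUE_MASS[aa]
        except KeyError:
            raise InvalidInputError(f"unknown residue {aa!r}") from None
        residue_masses.append(m + (PHOSPHO if idx in phospho else 0.0))
    n = len(seq)
    b_ions, y_ions = [], []
    prefix = 0.0
    for i in range(n - 1):
        prefix += residue_masses[i]
        b_ions.append((prefix + charge * PROTON) / charge)
    suffix = 0.0
    for j in range(n - 1):
        suffix += residue_masses[n - 1 - j]
        y_ions.append((suffix + WATER + charge * PROTON) / charge)
    return b_ions, y_ions


# ---------------------------------------------------------------------------
# site ambiguity


def resolve_site_ambiguity(
    peptide: Peptide, phospho_positions: tuple[int, ...] | list[int]
) -> ModifiedPeptide:
    """Map peptide-relative phosphosites to candidate parent residues.

    For each phosphosite, the candidate set is ``{start + position - 1}`` over
    every occurrence of the peptide on the parent, sorted ascending.  A peptide
    occurring once yields singleton sets; a repeat-domain peptide yields one
    candidate per repeat copy, which is exactly the ambiguity that makes
    site-level assignment impossible from the peptide alone.
    """
    positions = tuple(int(p) for p in phospho_positions)
    site_sets = tuple(
        tuple(sorted(start + pos - 1 for start in peptide.occurrences))
        for pos in positions
    )
    return ModifiedPeptide(
        peptide=peptide, phospho_positions=positions, ambiguous_site_sets=site_sets
    )


# ---------------------------------------------------------------------------
# tabular export


def digest_table(
    protein: ProteinRecord,
    max_missed_cleavages: int = 2,
    charges: tuple[int, ...] = (1, 2, 3, 4),
    phospho_blocks_cleavage: bool = False,
) -> pd.DataFrame:
    """Digest a protein and tabulate peptides with masses and per-charge m/z."""
    rows = []
    for pep in digest(protein, max_missed_cleavages, phospho_blocks_cleavage):
        mass = peptide_mass(pep.sequence)
        row = {
            "peptide": pep.sequence,
            "parent": pep.parent,
            "starts": ";".join(str(s) for s in pep.occurrences),
            "missed_cleavages": pep.missed_cleavages,
            "neutral_mass": mass,
        }
        for z in charges:
            row[f"mz_z{z}"] = ion_mz(mass, z)
        rows.append(row)
    return pd.DataFrame(rows)
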