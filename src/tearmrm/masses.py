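"""Monoisotopic peptide/fragment mass calculus and tryptic digestion.

All masses are monoisotopic, in daltons.  No fixed or variable
modifications are applied anywhere (in particular no carbamidomethylation
of cysteine and no methionine oxidation): the bundled transition table's
printed m/z values are only consistent with unmodified residues.
Only b and y fragment series are supported, at charges 1-3.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterator, Literal, Mapping

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "MONOISOTOPIC_RESIDUE_MASSES",
    "ResidueMassTable",
    "Peptide",
    "FragmentIon",
    "digest",
    "peptide_mass",
    "precursor_mz",
    "fragment_mz",
]

#: Mass of a proton (Da), used for protonation in positive-mode m/z.
PROTON_MASS: float = 1.00728

#: Monoisotopic mass of H2O (Da), the N+C terminal group of a free peptide.
WATER_MASS: float = 18.01056

#: Monoisotopic residue (not free amino acid) masses for the 20 canonical
#: residues, Da, to 5 decimal places.
MONOISOTOPIC_RESIDUE_MASSES: Mapping[str, float] = MappingProxyType({
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
})

FragmentSeries = Literal["b", "y"]


class NonCanonicalResidueError(ValueError):
    """A sequence contains a symbol outside the 20 canonical residues."""

    def __init__(self, sequence: str, position: int):
        self.sequence = sequence
        self.position = position
        super().__init__(
            f"non-canonical residue {sequence[position]!r} at position "
            f"{position} in sequence {sequence!r}"
        )


def _check_sequence(sequence: str) -> None:
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for i, ch in enumerate(sequence):
        if ch not in MONOISOTOPIC_RESIDUE_MASSES:
            raise NonCanonicalResidueError(sequence, i)


@dataclass(frozen=True)
class ResidueMassTable:
    """Immutable residue-mass lookup with the terminal/proton constants.

    The default table carries the standard monoisotopic values; a custom
    table may be supplied for what-if calculations but must stay positive.
    """

    residues: Mapping[str, float] = field(
        default_factory=lambda: MONOISOTOPIC_RESIDUE_MASSES
    )
    water: float = WATER_MASS
    proton: float = PROTON_MASS

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", MappingProxyType(dict(self.residues)))
        if any(m <= 0 for m in self.residues.values()):
            raise ValueError("all residue masses must be positive")

    def __getitem__(self, symbol: str) -> float:
        return self.residues[symbol]


@dataclass(frozen=True)
class Peptide:
    """A (possibly missed-cleavage) tryptic peptide within a parent protein."""

    sequence: str
    missed_cleavages: int = 0
    protein: str | None = None
    start: int = 0  # 0-based offset in the parent sequence

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")

    @property
    def mass(self) -> float:
        return peptide_mass(self.sequence)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class FragmentIon:
    """A b- or y-series fragment of a peptide, with its m/z."""

    series: FragmentSeries
    index: int
    charge: int
    mz: float

    def __post_init__(self) -> None:
        if self.series not in ("b", "y"):
            raise ValueError(f"unknown fragment series {self.series!r}")
        if self.index < 1:
            raise ValueError("fragment index must be >= 1")
        if self.charge < 1:
            raise ValueError("fragment charge must be >= 1")
        if self.mz <= 0:
            raise ValueError("fragment m/z must be positive")

    @property
    def annotation(self) -> str:
        """Compact annotation, e.g. ``y5`` or ``b7^2``."""
        base = f"{self.series}{self.index}"
        return base if self.charge == 1 else f"{base}^{self.charge}"


def _cleavage_sites(sequence: str) -> list[int]:
    """0-based positions *after* which trypsin cuts (K/R not before P)."""
    sites = []
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            sites.append(i)
    return sites


def digest(sequence: str, max_missed_cleavages: int = 0) -> list[Peptide]:
    """Tryptic digest of ``sequence`` allowing up to ``max_missed_cleavages``.

    Cleaves C-terminal to K or R unless the next residue is P.  Returns
    every peptide carrying 0..``max_missed_cleavages`` internal missed
    sites, ordered by start position (then by length).  The peptides with
    0 missed cleavages concatenate back to the input.

    Raises
    ------
    NonCanonicalResidueError
        If the sequence contains a symbol outside the canonical 20; the
        exception reports the offending position.
    """
    _check_sequence(sequence)
    if max_missed_cleavages < 0:
        raise ValueError("max_missed_cleavages must be >= 0")
    # Boundaries: start indices of fully cleaved peptides plus the end.
    bounds = [0] + [s + 1 for s in _cleavage_sites(sequence)] + [len(sequence)]
    peptides = []
    for a in range(len(bounds) - 1):
        for b in range(a + 1, len(bounds)):
            missed = b - a - 1
            if missed > max_missed_cleavages:
                break
            peptides.append(
                Peptide(
                    sequence=sequence[bounds[a]:bounds[b]],
                    missed_cleavages=missed,
                    start=bounds[a],
                )
            )
    peptides.sort(key=lambda p: (p.start, len(p.sequence)))
    return peptides


def peptide_mass(sequence: str, table: ResidueMassTable | None = None) -> float:
    """Monoisotopic neutral mass of a free peptide (residues + water)."""
    _check_sequence(sequence)
    t = table or _DEFAULT_TABLE
    return sum(t[ch] for ch in sequence) + t.water


def precursor_mz(
    sequence: str, charge: int, table: ResidueMassTable | None = None
) -> float:
    """m/z of the peptide protonated ``charge`` times."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    t = table or _DEFAULT_TABLE
    return (peptide_mass(sequence, t) + charge * t.proton) / charge


def fragment_mz(
    sequence: str,
    series: FragmentSeries,
    index: int,
    charge: int = 1,
    table: ResidueMassTable | None = None,
) -> float:
    """m/z of a b- or y-series fragment ion.

    b(i) carries the first ``i`` residues, y(i) the last ``i`` residues
    plus water; both are protonated ``charge`` times.  For b ions
    ``index`` must be < peptide length; the full-length y ion equals the
    singly protonated peptide.
    """
    _check_sequence(sequence)
    if charge < 1:
        raise ValueError("charge must be >= 1")
    t = table or _DEFAULT_TABLE
    n = len(sequence)
    if series == "b":
        if not 1 <= index <= n - 1:
            raise ValueError(f"b-ion index must be in 1..{n - 1}, got {index}")
        residues = sum(t[ch] for ch in sequence[:index])
        return (residues + charge * t.proton) / charge
    if series == "y":
        if not 1 <= index <= n:
            raise ValueError(f"y-ion index must be in 1..{n}, got {index}")
        residues = sum(t[ch] for ch in sequence[n - index:])
        return (residues + t.water + charge * t.proton) / charge
    raise ValueError(f"unknown fragment series {series!r}")


def fragment_ions(
    sequence: str,
    charges: tuple[int, ...] = (1,),
    table: ResidueMassTable | None = None,
) -> Iterator[FragmentIon]:
    """Yield every b/y fragment of the peptide at the given charges."""
    _check_sequence(sequence)
    n = len(sequence)
    for series in ("b", "y"):
        for index in range(1, n):
            for z in charges:
                yield FragmentIon(
                    series=series,
                    index=index,
                    charge=z,
                    mz=fragment_mz(sequence, series, index, z, table),
                )


_DEFAULT_TABLE = ResidueMassTable()
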