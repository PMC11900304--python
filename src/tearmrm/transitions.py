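"""Signature-peptide selection and MRM transition-table construction.

A transition is one (precursor m/z, product m/z) pair monitored for a
signature peptide.  Tables can be *designed* from a protein panel (the
m/z values are computed here) or *declared* (read from a file carrying an
instrument method's printed values); declared tables are verified against
the mass calculus in :mod:`tearmrm.masses`.

Collision energies and retention times are carried as declared metadata
only — they are never predicted.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .masses import (
    FragmentIon,
    digest,
    fragment_mz,
    precursor_mz,
)

__all__ = [
    "ProteinEntry",
    "Transition",
    "TransitionTable",
    "VerificationReport",
    "read_panel",
    "select_signature_peptides",
    "build_transition_table",
    "verify_transition_table",
    "read_transition_table",
    "write_transition_table",
    "bundled_reference_table",
]

TABLE_COLUMNS = [
    "protein",
    "peptide",
    "precursor_mz",
    "precursor_charge",
    "product_mz",
    "fragment_annotation",
    "collision_energy",
    "retention_time_min",
    "quantifier",
]

_ANNOTATION_RE = re.compile(r"^([by])(\d+)(?:\^(\d+))?$")


@dataclass(frozen=True)
class ProteinEntry:
    """One panel protein: an analyte or the internal standard paired to one."""

    accession: str
    species: str
    role: Literal["analyte", "internal_standard"]
    sequence: str
    partner: str | None = None  # accession of the paired analyte (IS only)

    def __post_init__(self) -> None:
        if self.role not in ("analyte", "internal_standard"):
            raise ValueError(f"unknown role {self.role!r} for {self.accession}")
        if self.role == "internal_standard" and not self.partner:
            raise ValueError(f"internal standard {self.accession} has no partner")


def validate_panel(panel: Sequence[ProteinEntry]) -> None:
    """Check analyte/IS pairing: every IS names exactly one existing analyte."""
    by_acc = {p.accession: p for p in panel}
    seen_partners: dict[str, str] = {}
    for p in panel:
        if p.role != "internal_standard":
            continue
        partner = by_acc.get(p.partner or "")
        if partner is None or partner.role != "analyte":
            raise ValueError(
                f"IS {p.accession} partner {p.partner!r} is not an analyte in the panel"
            )
        if p.partner in seen_partners:
            raise ValueError(
                f"analyte {p.partner} has two internal standards: "
                f"{seen_partners[p.partner]} and {p.accession}"
            )
        if partner.sequence == p.sequence:
            raise ValueError(f"IS {p.accession} has the same sequence as its analyte")
        seen_partners[p.partner] = p.accession


def read_panel(fasta_path: str | Path, manifest_path: str | Path) -> list[ProteinEntry]:
    """Load a protein panel from a FASTA file plus a manifest CSV.

    The manifest has columns ``accession,species,role,partner``; sequences
    are matched by the first whitespace-delimited token of each FASTA
    description line.
    """
    sequences = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    manifest = pd.read_csv(manifest_path, dtype=str).fillna("")
    required = {"accession", "species", "role", "partner"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"panel manifest missing columns: {sorted(missing)}")
    panel = []
    for row in manifest.itertuples(index=False):
        if row.accession not in sequences:
            raise ValueError(f"accession {row.accession!r} not found in {fasta_path}")
        panel.append(
            ProteinEntry(
                accession=row.accession,
                species=row.species,
                role=row.role,
                partner=row.partner or None,
                sequence=sequences[row.accession],
            )
        )
    validate_panel(panel)
    return panel


@dataclass(frozen=True)
class Transition:
    protein: str
    peptide: str
    precursor_mz: float
    precursor_charge: int
    product_mz: float
    fragment_annotation: str  # e.g. "y5", "b7", "y5^2"
    quantifier: bool = False
    collision_energy: float | None = None
    retention_time_min: float | None = None

    def __post_init__(self) -> None:
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be >= 1")
        if self.precursor_mz <= 0 or self.product_mz <= 0:
            raise ValueError("m/z values must be positive")
        if self.retention_time_min is not None and self.retention_time_min <= 0:
            raise ValueError("retention time must be positive")

    def fragment(self) -> tuple[str, int, int]:
        """Parse the annotation into (series, index, charge).

        Raises ``ValueError`` for annotations outside the b/y grammar.
        """
        m = _ANNOTATION_RE.match(self.fragment_annotation.strip())
        if m is None:
            raise ValueError(
                f"unparsable fragment annotation {self.fragment_annotation!r}"
            )
        return m.group(1), int(m.group(2)), int(m.group(3) or 1)


@dataclass(frozen=True)
class TransitionTable:
    transitions: tuple[Transition, ...]
    provenance: Literal["designed", "declared"] = "declared"

    def __post_init__(self) -> None:
        object.__setattr__(self, "transitions", tuple(self.transitions))
        pairs = [(t.precursor_mz, t.product_mz) for t in self.transitions]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (precursor, product) pair in table")
        peptide_of: dict[tuple[str, str], set[str]] = {}
        for t in self.transitions:
            peptide_of.setdefault((t.protein,), set()).add(t.peptide)
        quant: dict[str, int] = {}
        for t in self.transitions:
            if t.quantifier:
                quant[t.peptide] = quant.get(t.peptide, 0) + 1
        bad = [p for p, n in quant.items() if n > 1]
        if bad:
            raise ValueError(f"more than one quantifier for peptide(s) {bad}")

    def __len__(self) -> int:
        return len(self.transitions)

    def __iter__(self):
        return iter(self.transitions)

    def proteins(self) -> list[str]:
        out: list[str] = []
        for t in self.transitions:
            if t.protein not in out:
                out.append(t.protein)
        return out

    def quantifiers(self) -> dict[str, Transition]:
        """Map protein label -> its quantifier transition."""
        return {t.protein: t for t in self.transitions if t.quantifier}


def select_signature_peptides(
    panel: Sequence[ProteinEntry],
    length_range: tuple[int, int] = (7, 25),
    exclude_residues: str = "CM",
    max_missed_cleavages: int = 0,
) -> dict[str, list[str]]:
    """Pick candidate signature peptides per panel protein.

    A peptide qualifies when it is a fully tryptic peptide with 0 missed
    cleavages, falls in ``length_range``, avoids ``exclude_residues``,
    and its sequence occurs in exactly one protein of the panel
    (uniqueness is asserted within the analysed panel, not a proteome).
    Proteins with no qualifying peptide map to an empty list.
    """
    validate_panel(panel)
    candidates: dict[str, list[str]] = {}
    lo, hi = length_range
    for entry in panel:
        peps = []
        for pep in digest(entry.sequence, max_missed_cleavages=0):
            if pep.missed_cleavages > max_missed_cleavages:
                continue
            s = pep.sequence
            if not lo <= len(s) <= hi:
                continue
            if any(ch in s for ch in exclude_residues):
                continue
            peps.append(s)
        candidates[entry.accession] = peps
    # Uniqueness: drop any peptide occurring (as a substring) in another protein.
    result: dict[str, list[str]] = {}
    for entry in panel:
        unique = []
        for s in candidates[entry.accession]:
            hits = sum(1 for other in panel if s in other.sequence)
            if hits == 1:
                unique.append(s)
        result[entry.accession] = unique
    return result


def _choose_precursor_charge(
    peptide: str,
    mz_window: tuple[float, float] = (300.0, 1000.0),
    charges: Iterable[int] = (1, 2, 3),
) -> int:
    """Smallest charge placing the precursor inside the instrument window.

    If no charge fits (very short or very long peptides), the charge
    whose m/z lands closest to the window is used instead of failing.
    """
    lo, hi = mz_window
    best, best_dist = None, float("inf")
    for z in charges:
        mz = precursor_mz(peptide, z)
        if lo <= mz <= hi:
            return z
        dist = lo - mz if mz < lo else mz - hi
        if dist < best_dist:
            best, best_dist = z, dist
    return best  # type: ignore[return-value]


def _ranked_fragments(peptide: str, precursor: float) -> list[FragmentIon]:
    """Product-ion ranking for designed tables.

    y ions are preferred over b ions; within a series, products *above*
    the precursor m/z come first (nearest first) — they sit clear of the
    low-mass interference region — and below-precursor products follow
    by decreasing m/z.  All products are singly charged.
    """
    n = len(peptide)

    def key(ion: FragmentIon):
        above = ion.mz > precursor
        return (
            0 if ion.series == "y" else 1,
            0 if above else 1,
            ion.mz if above else -ion.mz,
        )

    ions = [
        FragmentIon(series, i, 1, fragment_mz(peptide, series, i, 1))
        for series in ("y", "b")
        for i in range(1, n)
    ]
    return sorted(ions, key=key)


def build_transition_table(
    peptides: Mapping[str, str] | Sequence[tuple[str, str]],
    fragments_per_peptide: int = 2,
    mz_window: tuple[float, float] = (300.0, 1000.0),
) -> TransitionTable:
    """Design a transition table for (protein, signature peptide) pairs.

    Per peptide: one precursor at the smallest charge landing inside
    ``mz_window``, and the top ``fragments_per_peptide`` products by the
    ranking rule of :func:`_ranked_fragments`; the first-ranked product
    is flagged as the quantifier.
    """
    items = list(peptides.items()) if isinstance(peptides, Mapping) else list(peptides)
    transitions = []
    for protein, pep in items:
        if len(pep) < 2:
            raise ValueError(f"peptide {pep!r} too short for fragmentation")
        z = _choose_precursor_charge(pep, mz_window)
        prec = precursor_mz(pep, z)
        frags = _ranked_fragments(pep, prec)[:fragments_per_peptide]
        for k, ion in enumerate(frags):
            transitions.append(
                Transition(
                    protein=protein,
                    peptide=pep,
                    precursor_mz=prec,
                    precursor_charge=z,
                    product_mz=ion.mz,
                    fragment_annotation=ion.annotation,
                    quantifier=(k == 0),
                )
            )
    return TransitionTable(tuple(transitions), provenance="designed")


@dataclass(frozen=True)
class VerificationRow:
    protein: str
    peptide: str
    kind: str  # "precursor" or the fragment annotation
    declared: float
    recomputed: float | None
    ok: bool

    @property
    def delta(self) -> float | None:
        if self.recomputed is None:
            return None
        return abs(self.declared - self.recomputed)


@dataclass(frozen=True)
class VerificationReport:
    rows: tuple[VerificationRow, ...]
    tolerance: float

    @property
    def passed(self) -> bool:
        return all(r.ok for r in self.rows)

    @property
    def unverifiable(self) -> list[VerificationRow]:
        return [r for r in self.rows if r.recomputed is None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": [r.protein for r in self.rows],
                "peptide": [r.peptide for r in self.rows],
                "kind": [r.kind for r in self.rows],
                "declared_mz": [r.declared for r in self.rows],
                "recomputed_mz": [r.recomputed for r in self.rows],
                "abs_delta": [r.delta for r in self.rows],
                "ok": [r.ok for r in self.rows],
            }
        )


def verify_transition_table(
    table: TransitionTable, tolerance: float = 0.1
) -> VerificationReport:
    """Recompute every declared m/z from its peptide sequence and compare.

    Each table row yields two comparisons (precursor and product).  Rows
    whose fragment annotation cannot be interpreted are reported as
    unverifiable (recomputed = None, ok = False) rather than passed.
    """
    rows = []
    seen_precursors: set[tuple[str, str, int]] = set()
    for t in table:
        key = (t.protein, t.peptide, t.precursor_charge)
        if key not in seen_precursors:
            seen_precursors.add(key)
            rec = precursor_mz(t.peptide, t.precursor_charge)
            rows.append(
                VerificationRow(
                    t.protein, t.peptide, "precursor", t.precursor_mz, rec,
                    abs(t.precursor_mz - rec) <= tolerance,
                )
            )
        try:
            series, index, charge = t.fragment()
            rec = fragment_mz(t.peptide, series, index, charge)
        except ValueError:
            rows.append(
                VerificationRow(
                    t.protein, t.peptide, t.fragment_annotation, t.product_mz,
                    None, False,
                )
            )
            continue
        rows.append(
            VerificationRow(
                t.protein, t.peptide, t.fragment_annotation, t.product_mz, rec,
                abs(t.product_mz - rec) <= tolerance,
            )
        )
    return VerificationReport(tuple(rows), tolerance)


def table_to_frame(table: TransitionTable) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein": [t.protein for t in table],
            "peptide": [t.peptide for t in table],
            "precursor_mz": [t.precursor_mz for t in table],
            "precursor_charge": [t.precursor_charge for t in table],
            "product_mz": [t.product_mz for t in table],
            "fragment_annotation": [t.fragment_annotation for t in table],
            "collision_energy": [t.collision_energy for t in table],
            "retention_time_min": [t.retention_time_min for t in table],
            "quantifier": [t.quantifier for t in table],
        }
    )


def write_transition_table(table: TransitionTable, path: str | Path) -> None:
    """Write a comma-delimited UTF-8 transition list (fixed header)."""
    df = table_to_frame(table)
    df["quantifier"] = df["quantifier"].map({True: "true", False: "false"})
    df.to_csv(path, index=False, float_format="%.10g", encoding="utf-8")


def _parse_float(value, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ValueError(f"unparsable {column} {value!r} in row {row}") from None


def read_transition_table(
    path: str | Path, provenance: Literal["designed", "declared"] = "declared"
) -> TransitionTable:
    df = pd.read_csv(path, encoding="utf-8")
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transition file {path} missing columns: {sorted(missing)}")
    transitions = []
    for i, row in enumerate(df.to_dict("records")):
        prec = _parse_float(row["precursor_mz"], i, "precursor_mz")
        prod = _parse_float(row["product_mz"], i, "product_mz")
        if prec is None or prod is None:
            raise ValueError(f"missing m/z in row {i} of {path}")
        quant = str(row["quantifier"]).strip().lower() in ("true", "1", "yes", "*")
        transitions.append(
            Transition(
                protein=str(row["protein"]),
                peptide=str(row["peptide"]),
                precursor_mz=prec,
                precursor_charge=int(row["precursor_charge"]),
                product_mz=prod,
                fragment_annotation=str(row["fragment_annotation"]),
                quantifier=quant,
                collision_energy=_parse_float(row["collision_energy"], i, "collision_energy"),
                retention_time_min=_parse_float(
                    row["retention_time_min"], i, "retention_time_min"
                ),
            )
        )
    return TransitionTable(tuple(transitions), provenance=provenance)


def bundled_reference_table() -> TransitionTable:
    """The packaged six-peptide reference MRM table (declared values).

    Note: the albumin internal standard's signature peptide is carried as
    LVNELTEFAK; an 11-residue variant of this sequence circulates in
    print, but only the 10-residue bovine tryptic peptide reproduces the
    declared precursor (582.3) and product (708.4/837.4) m/z values.
    """
    ref = resources.files("tearmrm.data").joinpath("reference_transitions.csv")
    with resources.as_file(ref) as p:
        return read_transition_table(p)


def bundled_panel() -> list[ProteinEntry]:
    """Synthetic surrogate panel embedding the reference signature peptides.

    The surrogate sequences are minimal stand-ins (real accessions would
    need a database download); each embeds its signature peptide in a
    tryptic context plus one filler peptide.
    """
    data = resources.files("tearmrm.data")
    with resources.as_file(data.joinpath("panel.fasta")) as f, resources.as_file(
        data.joinpath("panel.csv")
    ) as m:
        return read_panel(f, m)
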