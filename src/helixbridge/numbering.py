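"""Generic (x.50-style) residue numbering across the inferred alignment.

Each helix carries a reference column numbered 50 (its family's most
conserved position, Ballesteros–Weinstein style); other columns are
numbered by offset. Once a shift between two families is inferred, columns
map across families so that generic numbers agree, letting motifs
described in one family's numbering be read off in the other.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

from .errors import MissingNumberingError
from .families import AlignedFamily, HelixRegion

DEFAULT_NUMBERING_PAD = 8


@dataclass(frozen=True)
class GenericNumber:
    """A helix-relative generic residue number, e.g. TM3 index 50 = 3.50."""

    helix_id: str
    index: int

    def __str__(self) -> str:
        tm = self.helix_id[2:] if self.helix_id.upper().startswith("TM") else self.helix_id
        return f"{tm}.{self.index}"


@dataclass(frozen=True)
class MotifAnnotation:
    """A motif stated in generic numbers, with its functional role."""

    motif_id: str
    family_class: str  # which family convention the motif is described in
    helix_id: str
    generic_start: int
    generic_end: int
    role: str  # structure | activation | g-protein
    expected: str = ""  # residue pattern, if the motif has a canonical one

    def generic_positions(self) -> list[int]:
        return list(range(self.generic_start, self.generic_end + 1))


def to_generic(
    family: AlignedFamily,
    helix_id: str,
    column: int,
    pad: int = DEFAULT_NUMBERING_PAD,
) -> GenericNumber:
    """Generic number of an alignment column: 50 + (column - ref50)."""
    region = family.region(helix_id)
    if region.ref50_col is None:
        raise MissingNumberingError(
            f"{family.family_id}/{helix_id}: no ref50_col, cannot number"
        )
    if not region.start_col - pad <= column <= region.end_col + pad:
        raise ValueError(
            f"{family.family_id}/{helix_id}: column {column} outside window "
            f"[{region.start_col - pad}, {region.end_col + pad}]"
        )
    return GenericNumber(helix_id=helix_id, index=50 + column - region.ref50_col)


def from_generic(
    family: AlignedFamily,
    number: GenericNumber,
    pad: int = DEFAULT_NUMBERING_PAD,
) -> int:
    """Alignment column carrying a generic number (inverse of to_generic)."""
    region = family.region(number.helix_id)
    if region.ref50_col is None:
        raise MissingNumberingError(
            f"{family.family_id}/{number.helix_id}: no ref50_col, cannot number"
        )
    column = region.ref50_col + number.index - 50
    if not region.start_col - pad <= column <= region.end_col + pad:
        raise ValueError(
            f"{family.family_id}/{number.helix_id}: generic {number} maps to "
            f"column {column}, outside the window"
        )
    return column


def cross_map(
    source: AlignedFamily,
    target: AlignedFamily,
    helix_id: str,
    shift: int,
    column: int,
) -> int:
    """Map a source column into the target family under an inferred shift.

    Offsets are taken from each family's window start; a negative shift
    displaces the target family's sequences left, so the target offset is
    the source offset minus the shift. cross_map(target, source, -shift)
    inverts the mapping.
    """
    src = source.region(helix_id)
    tgt = target.region(helix_id)
    offset = column - src.start_col
    mapped = tgt.start_col + offset - shift
    if not 1 <= mapped <= target.n_columns:
        raise ValueError(
            f"{helix_id}: column {column} maps to {mapped}, outside "
            f"{target.family_id}'s alignment"
        )
    return mapped


def propagate_ref50(
    source: AlignedFamily,
    target: AlignedFamily,
    helix_id: str,
    shift: int,
) -> HelixRegion:
    """Target region with its ref50 derived from the source via the shift.

    Used to extend one family's numbering scheme to the other once the
    alignment is fixed, making to_generic shift-covariant between the two.
    """
    src = source.region(helix_id)
    if src.ref50_col is None:
        raise MissingNumberingError(
            f"{source.family_id}/{helix_id}: no ref50_col to propagate"
        )
    mapped = cross_map(source, target, helix_id, shift, src.ref50_col)
    tgt = target.region(helix_id)
    lo = min(tgt.start_col, mapped)
    hi = max(tgt.end_col, mapped)
    return replace(tgt, start_col=lo, end_col=hi, ref50_col=mapped)


def read_motif_table(path: str | Path) -> list[MotifAnnotation]:
    """Read a motif CSV: motif_id, family_class, helix_id, generic_start,
    generic_end, role, expected."""
    motifs = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            motifs.append(
                MotifAnnotation(
                    motif_id=row["motif_id"],
                    family_class=row["family_class"],
                    helix_id=row["helix_id"],
                    generic_start=int(row["generic_start"]),
                    generic_end=int(row["generic_end"]),
                    role=row["role"],
                    expected=row.get("expected", "") or "",
                )
            )
    return motifs


def annotate_motifs(
    families: list[AlignedFamily],
    motifs: list[MotifAnnotation],
    pad: int = DEFAULT_NUMBERING_PAD,
):
    """Read each motif's residues off each family's consensus sequence.

    Positions are resolved through each family's generic numbering (use
    :func:`propagate_ref50` beforehand to number a family through an
    inferred shift). Unresolvable positions are reported as unmapped ('?'),
    never fatal. Ties for the modal residue appear as ambiguity sets in
    brackets, e.g. ``[AG]``.
    """
    import pandas as pd

    rows = []
    for motif in motifs:
        for fam in families:
            residues = []
            unmapped = 0
            for g in motif.generic_positions():
                number = GenericNumber(helix_id=motif.helix_id, index=g)
                try:
                    col = from_generic(fam, number, pad=pad)
                    modal = fam.consensus_residues(col)
                except Exception:
                    residues.append("?")
                    unmapped += 1
                    continue
                residues.append(modal[0] if len(modal) == 1 else "[" + "".join(modal) + "]")
            found = "".join(residues)
            rows.append(
                {
                    "motif_id": motif.motif_id,
                    "family_class": motif.family_class,
                    "helix_id": motif.helix_id,
                    "generic_span": f"{motif.generic_start}-{motif.generic_end}",
                    "role": motif.role,
                    "family_id": fam.family_id,
                    "residues": found,
                    "expected": motif.expected,
                    "matches_expected": bool(motif.expected) and found == motif.expected,
                    "n_unmapped": unmapped,
                }
            )
    return pd.DataFrame(rows)
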