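"""Aligned sequence families and their transmembrane-region annotations.

An :class:`AlignedFamily` wraps a validated multiple sequence alignment
(aligned FASTA) together with per-helix transmembrane windows read from a
small YAML or CSV region-configuration table. Columns are 1-based inclusive
in every file and report; internally arithmetic uses 0-based half-open
indices, exposed through the ``*_idx`` helpers.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio import SeqIO

from .errors import (
    EmptyColumnError,
    InvalidRegionError,
    NoSequencesError,
    RaggedAlignmentError,
    RegionOutOfBoundsError,
)

logger = logging.getLogger(__name__)

#: Canonical amino-acid alphabet, the index order used for every
#: 20-component frequency vector in the package.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
GAP = "-"
UNKNOWN = "X"
#: Ambiguity / non-standard letters collapsed to X on input.
_REMAPPED = set("BZJUO")
_VALID = set(AMINO_ACIDS) | {GAP, UNKNOWN}

MIN_REGION_LENGTH = 3


@dataclass(frozen=True)
class HelixRegion:
    """A transmembrane helix window in alignment coordinates.

    ``start_col``/``end_col`` are 1-based inclusive alignment columns;
    ``ref50_col``, when present, is the column carrying the generic number
    x.50 for this helix (the family's most conserved position, used to
    anchor Ballesteros–Weinstein-style numbering).
    """

    helix_id: str
    start_col: int
    end_col: int
    ref50_col: int | None = None

    def __post_init__(self) -> None:
        if self.start_col > self.end_col:
            raise InvalidRegionError(
                f"{self.helix_id}: start_col {self.start_col} > end_col {self.end_col}"
            )
        if self.length < MIN_REGION_LENGTH:
            raise InvalidRegionError(
                f"{self.helix_id}: region length {self.length} < {MIN_REGION_LENGTH}"
            )
        if self.ref50_col is not None and not (
            self.start_col <= self.ref50_col <= self.end_col
        ):
            raise InvalidRegionError(
                f"{self.helix_id}: ref50_col {self.ref50_col} outside "
                f"[{self.start_col}, {self.end_col}]"
            )

    @property
    def length(self) -> int:
        return self.end_col - self.start_col + 1

    @property
    def start_idx(self) -> int:
        """0-based index of the first window column."""
        return self.start_col - 1

    @property
    def stop_idx(self) -> int:
        """0-based exclusive index one past the last window column."""
        return self.end_col


@dataclass
class AlignedFamily:
    """A validated MSA plus per-helix transmembrane annotations."""

    family_id: str
    ids: list[str]
    sequences: list[str]
    regions: dict[str, HelixRegion] = field(default_factory=dict)
    _freq: np.ndarray | None = field(default=None, repr=False, compare=False)
    _gapfrac: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise NoSequencesError(f"{self.family_id}: no sequences")
        n = len(self.sequences[0])
        for rid, seq in zip(self.ids, self.sequences):
            if len(seq) != n:
                raise RaggedAlignmentError(
                    f"{self.family_id}: ragged alignment — record '{rid}' has "
                    f"length {len(seq)}, expected {n}"
                )
            bad = set(seq) - _VALID
            if bad:
                raise ValueError(
                    f"{self.family_id}: record '{rid}' has invalid letters {sorted(bad)}"
                )
        for region in self.regions.values():
            if region.end_col > n or region.start_col < 1:
                raise RegionOutOfBoundsError(
                    f"{self.family_id}/{region.helix_id}: region out of bounds "
                    f"[{region.start_col}, {region.end_col}] for {n}-column alignment"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])

    def region(self, helix_id: str) -> HelixRegion:
        try:
            return self.regions[helix_id]
        except KeyError:
            raise KeyError(
                f"{self.family_id}: no region defined for helix '{helix_id}' "
                f"(available: {sorted(self.regions)})"
            ) from None

    # -- column statistics -------------------------------------------------

    def _encode(self) -> None:
        """Cache per-column residue frequencies and gap fractions."""
        n_seq, n_col = self.n_sequences, self.n_columns
        counts = np.zeros((n_col, len(AMINO_ACIDS)), dtype=np.float64)
        gaps = np.zeros(n_col, dtype=np.float64)
        for seq in self.sequences:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for aa, k in AA_INDEX.items():
                counts[arr == ord(aa), k] += 1.0
            gaps[arr == ord(GAP)] += 1.0
        totals = counts.sum(axis=1)
        freq = np.full_like(counts, np.nan)
        nonempty = totals > 0
        freq[nonempty] = counts[nonempty] / totals[nonempty, None]
        self._freq = freq
        self._gapfrac = gaps / n_seq

    def frequency_matrix(self) -> np.ndarray:
        """(n_columns, 20) residue frequencies; NaN rows mark empty columns.

        Gaps and X are excluded from the normalization, so each non-empty
        row sums to 1 over the 20 canonical residues.
        """
        if self._freq is None:
            self._encode()
        return self._freq

    def gap_fractions(self) -> np.ndarray:
        if self._gapfrac is None:
            self._encode()
        return self._gapfrac

    def column_frequencies(self, col: int) -> tuple[np.ndarray, float]:
        """Residue frequencies and gap fraction for 1-based column ``col``.

        Raises :class:`EmptyColumnError` if the column holds only gaps/X.
        """
        if not 1 <= col <= self.n_columns:
            raise IndexError(f"column {col} outside [1, {self.n_columns}]")
        f = self.frequency_matrix()[col - 1]
        if np.isnan(f).any():
            raise EmptyColumnError(f"{self.family_id}: empty column {col}")
        return f, float(self.gap_fractions()[col - 1])

    def consensus_residues(self, col: int) -> list[str]:
        """Modal residue(s) of a column; more than one entry on a tie."""
        f, _ = self.column_frequencies(col)
        top = f.max()
        return [AMINO_ACIDS[i] for i in np.flatnonzero(f == top)]


def _normalize_sequence(raw: str, record_id: str, family_id: str) -> str:
    seq = raw.upper().replace(".", GAP)
    remapped = sorted(set(seq) & _REMAPPED)
    if remapped:
        logger.warning(
            "%s/%s: letters %s mapped to X", family_id, record_id, ",".join(remapped)
        )
        for letter in remapped:
            seq = seq.replace(letter, UNKNOWN)
    return seq


def read_region_config(path: str | Path, family_id: str) -> dict[str, HelixRegion]:
    """Read helix regions for one family from a YAML or CSV table.

    Both formats are row-oriented with fields ``family_id, helix_id,
    start_col, end_col, ref50_col`` (``ref50_col`` optional / blank). YAML
    files hold a list of mappings; CSV files a header plus rows.
    """
    path = Path(path)
    rows: list[dict]
    if path.suffix.lower() in {".yaml", ".yml"}:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if not isinstance(loaded, list):
            raise ValueError(f"{path}: expected a YAML list of region records")
        rows = loaded
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    regions: dict[str, HelixRegion] = {}
    for row in rows:
        if str(row["family_id"]) != family_id:
            continue
        ref50 = row.get("ref50_col")
        ref50 = None if ref50 in (None, "", "NA") else int(ref50)
        region = HelixRegion(
            helix_id=str(row["helix_id"]),
            start_col=int(row["start_col"]),
            end_col=int(row["end_col"]),
            ref50_col=ref50,
        )
        regions[region.helix_id] = region
    return regions


def read_alignment(
    path: str | Path,
    family_id: str,
    region_config: str | Path | None = None,
) -> AlignedFamily:
    """Read an aligned FASTA (gap ``-`` or ``.``) into an AlignedFamily.

    Lowercase letters are uppercased; ``.`` gaps become ``-``; ambiguity
    letters (B, Z, J, U, O) are mapped to X with a logged warning. Any
    structural defect raises a typed error naming the offending record.
    """
    path = Path(path)
    ids: list[str] = []
    seqs: list[str] = []
    for record in SeqIO.parse(str(path), "fasta"):
        ids.append(record.id)
        seqs.append(_normalize_sequence(str(record.seq), record.id, family_id))
    if not seqs:
        raise NoSequencesError(f"{family_id}: no sequences in {path}")
    regions = (
        read_region_config(region_config, family_id) if region_config is not None else {}
    )
    return AlignedFamily(family_id=family_id, ids=ids, sequences=seqs, regions=regions)


def write_alignment(family: AlignedFamily, path: str | Path) -> None:
    """Write the family back to aligned FASTA (gap character ``-``)."""
    with open(path, "w") as fh:
        for rid, seq in zip(family.ids, family.sequences):
            fh.write(f">{rid}\n{seq}\n")


def write_region_config(
    families: list[AlignedFamily], path: str | Path
) -> None:
    """Write all families' helix regions to one CSV region table."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["family_id", "helix_id", "start_col", "end_col", "ref50_col"])
        for fam in families:
            for region in fam.regions.values():
                writer.writerow(
                    [
                        fam.family_id,
                        region.helix_id,
                        region.start_col,
                        region.end_col,
                        "" if region.ref50_col is None else region.ref50_col,
                    ]
                )
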