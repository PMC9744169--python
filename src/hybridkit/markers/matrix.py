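"""Binary band-matrix container and CSV I/O.

The band matrix is the interface between upstream gel scoring (out of
scope) and everything downstream: each cell records whether a scored
band is present (1), absent (0), or uncallable (NA) for one individual
at one band locus.  Loci are grouped by the primer pair that amplified
them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import ParseError, ValidationError

#: separator between primer and locus labels in CSV column headers
COLUMN_SEP = "__"

PRESENT = 1.0
ABSENT = 0.0

_IUPAC_DNA = re.compile(r"^[ACGTRYSWKMBDHVNacgtryswkmbdhvn]+$")


@dataclass(frozen=True)
class PrimerInfo:
    """Optional primer-pair metadata; echoed into reports, never computed on."""

    primer_id: str
    forward_seq: str | None = None
    reverse_seq: str | None = None
    annealing_temp: float | None = None

    def __post_init__(self) -> None:
        for seq in (self.forward_seq, self.reverse_seq):
            if seq is not None and not _IUPAC_DNA.match(seq):
                raise ValidationError(
                    f"primer {self.primer_id!r}: sequence {seq!r} contains "
                    "non-IUPAC DNA characters"
                )


@dataclass
class BandMatrix:
    """Presence/absence calls for a set of individuals at grouped band loci.

    Parameters
    ----------
    calls
        DataFrame indexed by individual id with one column per locus;
        values are 0.0 (absent), 1.0 (present) or NaN (missing).
    locus_to_primer
        Series mapping each locus id to its primer id, in locus order.
    mother_id, father_id
        Row labels of the two designated parents.
    """

    calls: pd.DataFrame
    locus_to_primer: pd.Series
    mother_id: str
    father_id: str

    def __post_init__(self) -> None:
        self.calls = self.calls.astype(float)
        self.locus_to_primer = self.locus_to_primer.astype(str)
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        idx = self.calls.index
        if idx.duplicated().any():
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate individual ids: {dups}")
        if self.calls.columns.duplicated().any():
            dups = sorted(self.calls.columns[self.calls.columns.duplicated()].unique())
            raise ValidationError(f"duplicate locus ids: {dups}")
        for role, label in (("mother", self.mother_id), ("father", self.father_id)):
            if label not in idx:
                raise ValidationError(f"{role} id {label!r} not present in matrix rows")
        if self.mother_id == self.father_id:
            raise ValidationError("mother_id and father_id must differ")
        unmapped = [c for c in self.calls.columns if c not in self.locus_to_primer.index]
        if unmapped:
            raise ValidationError(f"loci without a primer assignment: {unmapped}")
        values = self.calls.to_numpy()
        bad = ~(np.isnan(values) | (values == 0.0) | (values == 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"cell ({idx[i]!r}, {self.calls.columns[j]!r}) is "
                f"{values[i, j]!r}; expected 0, 1 or NA"
            )
        all_missing = self.calls.isna().all(axis=0)
        if all_missing.any():
            loci = list(self.calls.columns[all_missing])
            raise ValidationError(f"loci with no non-missing call: {loci}")

    # -- accessors --------------------------------------------------------

    @property
    def individual_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def offspring_ids(self) -> list[str]:
        parents = {self.mother_id, self.father_id}
        return [i for i in self.calls.index if i not in parents]

    @property
    def locus_ids(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def primer_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for locus in self.calls.columns:
            seen.setdefault(self.locus_to_primer[locus], None)
        return list(seen)

    def loci_of_primer(self, primer_id: str) -> list[str]:
        return [l for l in self.calls.columns if self.locus_to_primer[l] == primer_id]

    @property
    def mother_calls(self) -> pd.Series:
        return self.calls.loc[self.mother_id]

    @property
    def father_calls(self) -> pd.Series:
        return self.calls.loc[self.father_id]

    def offspring_calls(self) -> pd.DataFrame:
        return self.calls.loc[self.offspring_ids]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return (
            self.mother_id == other.mother_id
            and self.father_id == other.father_id
            and self.locus_to_primer.equals(other.locus_to_primer)
            and self.calls.equals(other.calls)
        )


def read_band_matrix(path: str | Path, mother_id: str, father_id: str) -> BandMatrix:
    """Read a band matrix from CSV.

    Dialect: first column ``individual_id``; remaining column headers are
    ``primer__locus`` (double-underscore separated); cells are ``0``, ``1``
    or ``NA``/empty.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"band matrix file not found: {path}")
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: expected individual_id plus locus columns")
    id_col = raw.columns[0]
    locus_ids, primers = [], []
    for col in raw.columns[1:]:
        if COLUMN_SEP not in col:
            raise ParseError(
                f"{path}: column {col!r} lacks the '{COLUMN_SEP}' primer/locus separator"
            )
        primer, locus = col.split(COLUMN_SEP, 1)
        primers.append(primer)
        locus_ids.append(locus)
    cells = raw.iloc[:, 1:].copy()
    cells.columns = locus_ids
    cells.index = raw[id_col].astype(str)
    cells.index.name = "individual_id"

    def _parse(value: str, row: str, col: str) -> float:
        v = value.strip()
        if v in {"", "NA", "NaN", "nan"}:
            return np.nan
        if v in {"0", "0.0"}:
            return ABSENT
        if v in {"1", "1.0"}:
            return PRESENT
        raise ParseError(
            f"{path}: cell (row {row!r}, column {col!r}) is {value!r}; expected 0, 1 or NA"
        )

    parsed = pd.DataFrame(
        {
            col: [_parse(v, r, col) for r, v in cells[col].items()]
            for col in cells.columns
        },
        index=cells.index,
    )
    for role, label in (("mother", mother_id), ("father", father_id)):
        if label not in parsed.index:
            raise ParseError(f"{path}: designated {role} row {label!r} missing")
    mapping = pd.Series(primers, index=pd.Index(locus_ids, name="locus_id"), name="primer_id")
    if mapping.index.duplicated().any():
        dups = sorted(mapping.index[mapping.index.duplicated()].unique())
        raise ParseError(f"{path}: duplicate locus ids: {dups}")
    try:
        return BandMatrix(parsed, mapping, mother_id, father_id)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_band_matrix(m: BandMatrix, path: str | Path) -> None:
    """Write a band matrix in the CSV dialect accepted by read_band_matrix."""
    out = m.calls.copy()
    out.columns = [
        f"{m.locus_to_primer[locus]}{COLUMN_SEP}{locus}" for locus in m.calls.columns
    ]
    formatted = out.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    formatted.index.name = "individual_id"
    formatted.to_csv(path)
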