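"""Characteristic-band detection: which loci distinguish the parents."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .matrix import ABSENT, PRESENT, BandMatrix

logger = logging.getLogger(__name__)


@dataclass
class PrimerBands:
    """Parent-informative loci for a single primer pair."""

    primer_id: str
    paternal_only: frozenset[str]
    maternal_only: frozenset[str]
    shared: frozenset[str]

    @property
    def ff1(self) -> int:
        """Number of maternal characteristic bands."""
        return len(self.maternal_only)

    @property
    def mf1(self) -> int:
        """Number of paternal characteristic bands."""
        return len(self.paternal_only)

    def __post_init__(self) -> None:
        sets = [self.paternal_only, self.maternal_only, self.shared]
        total = sum(len(s) for s in sets)
        if len(frozenset().union(*sets)) != total:
            raise ValueError(f"primer {self.primer_id!r}: band sets overlap")


@dataclass
class CharacteristicBandSet:
    """Per-primer characteristic-band classification of all parent-callable loci."""

    per_primer: dict[str, PrimerBands]
    excluded_loci: frozenset[str] = field(default_factory=frozenset)

    @property
    def paternal_only(self) -> frozenset[str]:
        return frozenset().union(*(b.paternal_only for b in self.per_primer.values()))

    @property
    def maternal_only(self) -> frozenset[str]:
        return frozenset().union(*(b.maternal_only for b in self.per_primer.values()))

    @property
    def shared(self) -> frozenset[str]:
        return frozenset().union(*(b.shared for b in self.per_primer.values()))

    def counts_frame(self) -> pd.DataFrame:
        """FF1/MF1 counts per primer, one row per primer."""
        rows = [
            {"primer_id": p, "FF1": b.ff1, "MF1": b.mf1}
            for p, b in self.per_primer.items()
        ]
        return pd.DataFrame(rows).set_index("primer_id")


def detect_characteristic_bands(m: BandMatrix) -> CharacteristicBandSet:
    """Partition loci by parental band phenotype.

    A locus is *paternal-only* when the father shows the band and the
    mother does not, *maternal-only* in the symmetric case, and *shared*
    when both parents show it.  Loci absent in both parents carry no
    parental information and are dropped; loci with a missing parent call
    are unclassifiable, excluded from every set, and logged.
    """
    mother = m.mother_calls
    father = m.father_calls
    per_primer: dict[str, PrimerBands] = {}
    excluded: set[str] = set()
    for primer in m.primer_ids:
        pat, mat, shared = set(), set(), set()
        for locus in m.loci_of_primer(primer):
            mo, fa = mother[locus], father[locus]
            if pd.isna(mo) or pd.isna(fa):
                excluded.add(locus)
                logger.warning(
                    "locus %r (primer %r) excluded: missing parent call", locus, primer
                )
                continue
            if fa == PRESENT and mo == ABSENT:
                pat.add(locus)
            elif mo == PRESENT and fa == ABSENT:
                mat.add(locus)
            elif mo == PRESENT and fa == PRESENT:
                shared.add(locus)
            # absent in both parents: uninformative, dropped silently
        per_primer[primer] = PrimerBands(
            primer, frozenset(pat), frozenset(mat), frozenset(shared)
        )
    return CharacteristicBandSet(per_primer, frozenset(excluded))
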