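"""Hybrid/selfed-offspring classification and population purity.

Classification rule: an offspring carrying at least ``min_paternal_bands``
paternal characteristic bands is a true hybrid; one whose paternal
characteristic loci are all callable and all absent is a maternal type
(putative maternal self); anything else cannot be resolved from the
available calls.  Purity is the percentage of tested (resolved) offspring
that are not maternal types.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from ..errors import AnalysisError, InputError
from .bands import CharacteristicBandSet
from .matrix import PRESENT, ABSENT, BandMatrix

TRUE_HYBRID = "true_hybrid"
MATERNAL_TYPE = "maternal_type"
UNRESOLVED = "unresolved"


@dataclass
class HybridCallTable:
    """Per-offspring hybrid calls plus the derived population purity."""

    calls: pd.DataFrame  # index individual_id; columns: call, n_paternal_bands_carried

    @property
    def n_tested(self) -> int:
        return int((self.calls["call"] != UNRESOLVED).sum())

    @property
    def n_maternal_type(self) -> int:
        return int((self.calls["call"] == MATERNAL_TYPE).sum())

    @property
    def n_true_hybrid(self) -> int:
        return int((self.calls["call"] == TRUE_HYBRID).sum())

    @property
    def purity(self) -> float:
        """100 x (tested - maternal types) / tested."""
        if self.n_tested == 0:
            raise AnalysisError("no resolvable offspring; purity undefined")
        return 100.0 * (self.n_tested - self.n_maternal_type) / self.n_tested

    @property
    def false_hybrid_ids(self) -> list[str]:
        return list(self.calls.index[self.calls["call"] == MATERNAL_TYPE])

    def to_csv(self, path: str | Path) -> None:
        out = self.calls.copy()
        out.index.name = "individual_id"
        out.to_csv(path)


def classify_offspring(
    m: BandMatrix,
    c: CharacteristicBandSet,
    min_paternal_bands: int = 1,
) -> HybridCallTable:
    """Call each offspring true hybrid / maternal type / unresolved."""
    if min_paternal_bands < 1:
        raise InputError(f"min_paternal_bands must be >= 1, got {min_paternal_bands}")
    paternal = [l for l in m.locus_ids if l in c.paternal_only]
    if not paternal:
        raise AnalysisError("no paternal characteristic bands; classification impossible")

    sub = m.offspring_calls()[paternal]
    records = []
    for ind, row in sub.iterrows():
        n_present = int((row == PRESENT).sum())
        n_missing = int(row.isna().sum())
        if n_present >= min_paternal_bands:
            call = TRUE_HYBRID
        elif n_missing == 0:
            call = MATERNAL_TYPE
        else:
            # partially missing with too few present bands: cannot rule
            # out hybridity, so the plant is not counted as tested
            call = UNRESOLVED
        records.append((ind, call, n_present))
    calls = pd.DataFrame.from_records(
        records, columns=["individual_id", "call", "n_paternal_bands_carried"]
    ).set_index("individual_id")
    return HybridCallTable(calls)


def purity_from_counts(n_tested: int, n_maternal_type: int) -> float:
    """Purity percentage straight from counts (no matrix required)."""
    if n_tested <= 0:
        raise InputError(f"n_tested must be positive, got {n_tested}")
    if not 0 <= n_maternal_type <= n_tested:
        raise InputError(
            f"n_maternal_type ({n_maternal_type}) must lie in [0, {n_tested}]"
        )
    return 100.0 * (n_tested - n_maternal_type) / n_tested
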