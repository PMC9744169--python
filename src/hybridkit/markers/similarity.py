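"""Pairwise genetic similarity from binary band profiles.

For a pair of individuals, over loci called in both:

    a = bands present in both        b, c = present in exactly one
    d = absent in both

    simple_matching = (a + d) / (a + b + c + d)
    dice            = 2a / (2a + b + c)
    jaccard         = a / (a + b + c)

Dice and Jaccard are conventionally 1 for two all-absent profiles
(no evidence of difference); this implementation follows that.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import AnalysisError, InputError
from .matrix import BandMatrix

COEFFICIENTS = ("simple_matching", "dice", "jaccard")


def pair_similarity(x: np.ndarray, y: np.ndarray, coefficient: str) -> float:
    """Similarity between two 0/1/NaN profiles; NaN-in-either loci dropped."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if not ok.any():
        raise AnalysisError("no shared non-missing loci for the pair")
    xs, ys = x[ok], y[ok]
    a = float(np.sum((xs == 1) & (ys == 1)))
    b = float(np.sum((xs == 1) & (ys == 0)))
    c = float(np.sum((xs == 0) & (ys == 1)))
    d = float(np.sum((xs == 0) & (ys == 0)))
    if coefficient == "simple_matching":
        return (a + d) / (a + b + c + d)
    if coefficient == "dice":
        return 1.0 if (2 * a + b + c) == 0 else 2 * a / (2 * a + b + c)
    if coefficient == "jaccard":
        return 1.0 if (a + b + c) == 0 else a / (a + b + c)
    raise InputError(f"unknown coefficient {coefficient!r}; choose from {COEFFICIENTS}")


@dataclass
class SimilarityMatrix:
    coefficient_name: str
    values: pd.DataFrame  # square, symmetric, unit diagonal

    @property
    def individual_ids(self) -> list[str]:
        return list(self.values.index)

    def pair(self, i: str, j: str) -> float:
        return float(self.values.loc[i, j])

    def to_csv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.index.name = "individual_id"
        out.to_csv(path)


def similarity_matrix(m: BandMatrix, coefficient: str = "simple_matching") -> SimilarityMatrix:
    """All-pairs similarity over the matrix rows (parents included)."""
    if coefficient not in COEFFICIENTS:
        raise InputError(f"unknown coefficient {coefficient!r}; choose from {COEFFICIENTS}")
    ids = m.individual_ids
    data = m.calls.to_numpy(dtype=float)
    n = len(ids)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                s = pair_similarity(data[i], data[j], coefficient)
            except AnalysisError as exc:
                raise AnalysisError(
                    f"pair ({ids[i]!r}, {ids[j]!r}): {exc}"
                ) from exc
            out[i, j] = out[j, i] = s
    return SimilarityMatrix(coefficient, pd.DataFrame(out, index=ids, columns=ids))


@dataclass
class SimilaritySummary:
    """Extreme similarity values relative to the parents and overall."""

    progeny_father_min: tuple[str, float]
    progeny_father_max: tuple[str, float]
    progeny_mother_min: tuple[str, float]
    progeny_mother_max: tuple[str, float]
    parent_parent: float
    overall_min: tuple[str, str, float]
    overall_max: tuple[str, str, float]

    def as_dict(self) -> dict:
        return {
            "progeny_father_min": self.progeny_father_min,
            "progeny_father_max": self.progeny_father_max,
            "progeny_mother_min": self.progeny_mother_min,
            "progeny_mother_max": self.progeny_mother_max,
            "parent_parent": self.parent_parent,
            "overall_min": self.overall_min,
            "overall_max": self.overall_max,
        }


def similarity_summary(
    s: SimilarityMatrix, mother_id: str, father_id: str
) -> SimilaritySummary:
    """Ranges of progeny-parent similarity plus the extreme offspring pair."""
    ids = s.individual_ids
    for label in (mother_id, father_id):
        if label not in ids:
            raise InputError(f"parent {label!r} absent from similarity matrix")
    progeny = [i for i in ids if i not in {mother_id, father_id}]
    if not progeny:
        raise AnalysisError("no progeny rows in similarity matrix")

    def extremes(parent: str) -> tuple[tuple[str, float], tuple[str, float]]:
        col = s.values.loc[progeny, parent]
        return (col.idxmin(), float(col.min())), (col.idxmax(), float(col.max()))

    f_min, f_max = extremes(father_id)
    m_min, m_max = extremes(mother_id)

    best = worst = None
    for i_pos, i in enumerate(progeny):
        for j in progeny[i_pos + 1 :]:
            v = s.pair(i, j)
            if worst is None or v < worst[2]:
                worst = (i, j, v)
            if best is None or v > best[2]:
                best = (i, j, v)
    if worst is None:  # single offspring: degenerate but defined
        only = progeny[0]
        worst = best = (only, only, 1.0)
    return SimilaritySummary(
        progeny_father_min=f_min,
        progeny_father_max=f_max,
        progeny_mother_min=m_min,
        progeny_mother_max=m_max,
        parent_parent=s.pair(mother_id, father_id),
        overall_min=worst,
        overall_max=best,
    )
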