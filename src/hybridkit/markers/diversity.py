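"""Dominant-marker allele frequencies and diversity statistics.

Each band locus is treated as biallelic (band allele vs. null allele).
Two frequency estimators are offered:

``phenotypic``
    p is the band (phenotype) frequency.  This treats the band score
    itself as the allele — appropriate when dominance is ignored.
``hwe_dominant``
    q = sqrt(freq of band-absent phenotype) under Hardy-Weinberg
    proportions, the square-root rule used by classic dominant-data
    software; p = 1 - q.

Per-locus statistics (p + q = 1):

    na = 2 if 0 < p < 1 else 1          observed allele number
    ne = 1 / (p^2 + q^2)                effective allele number
    h  = 1 - p^2 - q^2                  gene diversity (expected het.)
    I  = -p ln p - q ln q               Shannon information index

Per-primer values are arithmetic means over that primer's loci; the
panel-level "mean" row averages the per-primer rows (not pooled loci).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..errors import AnalysisError, InputError
from .matrix import PRESENT, BandMatrix

ESTIMATORS = ("phenotypic", "hwe_dominant")


def allele_frequencies(
    m: BandMatrix,
    estimator: str = "phenotypic",
    include_parents: bool = True,
) -> pd.DataFrame:
    """Per-locus band-allele frequency (p) and null frequency (q)."""
    if estimator not in ESTIMATORS:
        raise InputError(f"unknown estimator {estimator!r}; choose from {ESTIMATORS}")
    calls = m.calls if include_parents else m.offspring_calls()
    n_called = calls.notna().sum(axis=0)
    if (n_called == 0).any():
        empty = list(n_called.index[n_called == 0])
        raise AnalysisError(f"loci with no non-missing call in the chosen rows: {empty}")
    band_freq = (calls == PRESENT).sum(axis=0) / n_called
    if estimator == "phenotypic":
        p = band_freq
    else:
        q_null = np.sqrt(1.0 - band_freq)
        p = 1.0 - q_null
    p = p.clip(0.0, 1.0)
    out = pd.DataFrame({"p": p, "q": 1.0 - p})
    out.index.name = "locus_id"
    return out


def _locus_stats(freqs: pd.DataFrame) -> pd.DataFrame:
    p = freqs["p"].to_numpy()
    q = freqs["q"].to_numpy()
    polymorphic = (p > 0.0) & (p < 1.0)
    na = np.where(polymorphic, 2.0, 1.0)
    homo_sum = p**2 + q**2
    ne = 1.0 / homo_sum
    h = 1.0 - homo_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        i_p = np.where(p > 0.0, -p * np.log(p), 0.0)
        i_q = np.where(q > 0.0, -q * np.log(q), 0.0)
    return pd.DataFrame(
        {"na": na, "ne": ne, "h": h, "I": i_p + i_q, "polymorphic": polymorphic},
        index=freqs.index,
    )


@dataclass
class DiversityStats:
    """Diversity summary: one row per primer plus a panel-mean row."""

    per_primer: pd.DataFrame  # index primer_id; na_mean ne_mean h_mean i_mean T ppb
    per_locus: pd.DataFrame
    estimator: str

    @property
    def panel_means(self) -> pd.Series:
        """Mean over primers of each per-primer column (T averaged too)."""
        return self.per_primer.mean(axis=0)

    def to_csv(self, path: str | Path) -> None:
        table = self.per_primer.copy()
        table.loc["mean"] = self.panel_means
        table.index.name = "primer_id"
        table.to_csv(path)


def diversity_stats(
    m: BandMatrix,
    estimator: str = "phenotypic",
    include_parents: bool = True,
) -> DiversityStats:
    """Compute na/ne/h/I, total band count T and %polymorphic per primer."""
    freqs = allele_frequencies(m, estimator=estimator, include_parents=include_parents)
    locus = _locus_stats(freqs)
    rows = {}
    for primer in m.primer_ids:
        loci = m.loci_of_primer(primer)
        sub = locus.loc[loci]
        t = len(loci)
        rows[primer] = {
            "na_mean": sub["na"].mean(),
            "ne_mean": sub["ne"].mean(),
            "h_mean": sub["h"].mean(),
            "i_mean": sub["I"].mean(),
            "T": float(t),
            "ppb": 100.0 * sub["polymorphic"].sum() / t,
        }
    per_primer = pd.DataFrame.from_dict(rows, orient="index")
    per_primer.index.name = "primer_id"
    return DiversityStats(per_primer, locus, estimator)
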