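"""Quantitative-trait statistics for hybrid populations.

Covers normality screening (one-sample KS with plug-in parameters, or
Lilliefors), moment-based skewness/kurtosis, coefficient of variation,
pairwise Pearson correlation with significance tiers, mid-parent
heterosis and heterobeltiosis, spike self-fertility summaries, and the
marker-vs-selfing purity cross-check.

Conventions: sample SD (n-1 denominator) throughout; kurtosis is excess
kurtosis (normal -> 0); heterosis is reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .errors import AnalysisError, InputError

KS_VARIANTS = ("estimated_params", "lilliefors")

WITHIN_RANGE = "within_range"
BELOW_RANGE = "below_range"
ABOVE_RANGE = "above_range"


# ---------------------------------------------------------------------------
# basic statistics


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[~np.isnan(arr)]


def ks_normality(values, variant: str = "estimated_params") -> tuple[float, float]:
    """One-sample KS test of normality with estimated mean/SD.

    ``estimated_params`` reports the classical asymptotic KS p-value with
    plug-in parameters (anticonservative but the consumer-software
    convention); ``lilliefors`` corrects for the estimation.
    """
    if variant not in KS_VARIANTS:
        raise InputError(f"unknown variant {variant!r}; choose from {KS_VARIANTS}")
    x = _clean(values)
    if x.size < 8:
        raise InputError(f"need >= 8 non-missing values, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise InputError("zero standard deviation; KS test undefined")
    if variant == "estimated_params":
        stat, p = stats.kstest(x, "norm", args=(x.mean(), sd))
        return float(stat), float(p)
    stat, p = _lilliefors(x, dist="norm", pvalmethod="table")
    return float(stat), float(p)


def moments(values) -> tuple[float, float, float, float]:
    """Mean, sample SD, moment skewness g1 and excess kurtosis g2.

    g1 = m3 / m2^(3/2), g2 = m4 / m2^2 - 3 with central moments over n.
    """
    x = _clean(values)
    if x.size < 3:
        raise InputError(f"need >= 3 non-missing values, got {x.size}")
    mean = x.mean()
    sd = x.std(ddof=1)
    centered = x - mean
    m2 = (centered**2).mean()
    if m2 == 0:
        raise InputError("zero variance; skewness/kurtosis undefined")
    z = centered / np.sqrt(m2)  # scale-invariant; avoids m2**k underflow
    return float(mean), float(sd), float((z**3).mean()), float((z**4).mean() - 3.0)


def cv(values) -> float:
    """Coefficient of variation: sample SD / mean."""
    x = _clean(values)
    if x.size < 2:
        raise InputError("need >= 2 non-missing values for CV")
    mean = x.mean()
    if mean == 0:
        raise InputError("zero mean; CV undefined")
    return float(x.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# normality report


@dataclass
class NormalityReport:
    table: pd.DataFrame  # index trait; ks_statistic ks_p skewness kurtosis verdict
    histograms: dict[str, tuple[np.ndarray, np.ndarray]]  # trait -> (edges, counts)

    def to_csv(self, path: str | Path) -> None:
        out = self.table.copy()
        out.index.name = "trait"
        out.to_csv(path)


def normality_report(
    traits: pd.DataFrame,
    variant: str = "estimated_params",
    alpha: float = 0.05,
    bins: int = 10,
) -> NormalityReport:
    """Per-trait KS verdict, skewness/kurtosis and histogram."""
    rows, hists = {}, {}
    for trait in traits.columns:
        x = _clean(traits[trait])
        stat, p = ks_normality(x, variant=variant)
        _, _, skew, kurt = moments(x)
        rows[trait] = {
            "ks_statistic": stat,
            "ks_p": p,
            "skewness": skew,
            "kurtosis": kurt,
            "verdict": "normal" if p >= alpha else "non-normal",
        }
        counts, edges = np.histogram(x, bins=bins)
        hists[trait] = (edges, counts)
    return NormalityReport(pd.DataFrame.from_dict(rows, orient="index"), hists)


# ---------------------------------------------------------------------------
# correlation


def _tier(p: float) -> str:
    if np.isnan(p):
        return "none"
    if p <= 0.01:
        return "***"
    if p <= 0.05:
        return "**"
    if p <= 0.1:
        return "*"
    return "none"


def correlation_matrix(traits: pd.DataFrame, min_n: int = 4) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations with significance tiers.

    Returns a long-format frame (trait_a, trait_b, n, r, p, tier) over
    all unordered pairs including the diagonal.  Pairs with a constant
    trait or fewer than ``min_n`` complete observations get NaN r/p.
    """
    cols = list(traits.columns)
    records = []
    for i, a in enumerate(cols):
        for b in cols[i:]:
            sub = traits[[a, b]].dropna() if a != b else traits[[a]].dropna()
            n = len(sub)
            if a == b:
                x = sub[a].to_numpy()
                r, p = (1.0, 0.0) if n >= min_n and x.std() > 0 else (np.nan, np.nan)
            elif n < min_n or sub[a].std() == 0 or sub[b].std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(sub[a], sub[b])
            records.append((a, b, n, float(r), float(p), _tier(p)))
    return pd.DataFrame(records, columns=["trait_a", "trait_b", "n", "r", "p", "tier"])


def correlation_wide(long: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-format correlation frame into a symmetric r matrix."""
    traits = list(dict.fromkeys(long["trait_a"]))
    wide = pd.DataFrame(np.nan, index=traits, columns=traits)
    for _, row in long.iterrows():
        wide.loc[row["trait_a"], row["trait_b"]] = row["r"]
        wide.loc[row["trait_b"], row["trait_a"]] = row["r"]
    return wide


# ---------------------------------------------------------------------------
# heterosis


def mid_parent_heterosis(f1_mean: float, mother_mean: float, father_mean: float) -> float:
    """(F1 - MP) / MP as a percentage."""
    mp = (mother_mean + father_mean) / 2.0
    if mp == 0:
        raise AnalysisError("zero mid-parent value; heterosis undefined")
    return 100.0 * (f1_mean - mp) / mp


def heterobeltiosis(f1_mean: float, mother_mean: float, father_mean: float) -> float:
    """(F1 - HP) / HP as a percentage, HP the higher parent mean."""
    hp = max(mother_mean, father_mean)
    if hp == 0:
        raise AnalysisError("zero higher-parent value; heterobeltiosis undefined")
    return 100.0 * (f1_mean - hp) / hp


def heterosis_table(f1: pd.DataFrame, parents: pd.DataFrame) -> pd.DataFrame:
    """Per-trait F1 mean, CV, mid-parent heterosis and heterobeltiosis.

    ``parents`` is indexed by trait with mother_mean/father_mean columns.
    Traits without both parent means, or with a zero reference value, get
    NaN ("undefined") heterosis but the run succeeds.
    """
    rows = {}
    for trait in f1.columns:
        x = _clean(f1[trait])
        f1_mean = float(x.mean()) if x.size else np.nan
        trait_cv = float(x.std(ddof=1) / f1_mean) if x.size >= 2 and f1_mean else np.nan
        mph = hb = mp = hp = np.nan
        if trait in parents.index:
            mo = float(parents.loc[trait, "mother_mean"])
            fa = float(parents.loc[trait, "father_mean"])
            if not (np.isnan(mo) or np.isnan(fa)):
                mp = (mo + fa) / 2.0
                hp = max(mo, fa)
                if mp != 0 and not np.isnan(f1_mean):
                    mph = mid_parent_heterosis(f1_mean, mo, fa)
                if hp != 0 and not np.isnan(f1_mean):
                    hb = heterobeltiosis(f1_mean, mo, fa)
        rows[trait] = {
            "f1_mean": f1_mean,
            "mp": mp,
            "hp": hp,
            "cv_pct": 100.0 * trait_cv if not np.isnan(trait_cv) else np.nan,
            "mph_pct": mph,
            "hb_pct": hb,
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "trait"
    return table


def heterosis_sign_means(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of the positive and of the negative heterosis values per column."""
    out = {}
    for col in ("mph_pct", "hb_pct"):
        vals = table[col].dropna()
        out[col] = {
            "positive_mean": float(vals[vals > 0].mean()) if (vals > 0).any() else np.nan,
            "negative_mean": float(vals[vals < 0].mean()) if (vals < 0).any() else np.nan,
        }
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# fertility and cross-checks

FERTILITY_LEVELS = ("parent_spike", "f1_plant", "f1_spike")


@dataclass
class SelfFertilityResult:
    records: pd.DataFrame  # unit_id level seeds spikelets rate
    summary: pd.DataFrame  # index level; max min mean sd n
    welch_t: float
    welch_p: float
    rejected: pd.DataFrame


def self_fertility(records: pd.DataFrame) -> SelfFertilityResult:
    """Per-spike self-fertility rates, per-level summaries and the
    parent-vs-F1-plant Welch test.

    ``records`` columns: unit_id, level in {parent_spike, f1_plant,
    f1_spike}, seeds, spikelets.  Records with spikelets <= 0 are
    rejected (returned separately), not fatal.
    """
    required = {"unit_id", "level", "seeds", "spikelets"}
    missing = required - set(records.columns)
    if missing:
        raise InputError(f"fertility records missing columns: {sorted(missing)}")
    bad_level = set(records["level"]) - set(FERTILITY_LEVELS)
    if bad_level:
        raise InputError(f"unknown fertility levels: {sorted(bad_level)}")
    ok = records["spikelets"] > 0
    rejected = records.loc[~ok].copy()
    kept = records.loc[ok].copy()
    if kept.empty:
        raise InputError("no fertility records with spikelets > 0")
    kept["rate"] = 100.0 * kept["seeds"] / kept["spikelets"]
    summary = (
        kept.groupby("level")["rate"]
        .agg(max="max", min="min", mean="mean", sd=lambda v: v.std(ddof=1), n="count")
    )
    parent = kept.loc[kept["level"] == "parent_spike", "rate"]
    f1 = kept.loc[kept["level"] == "f1_plant", "rate"]
    if len(parent) >= 2 and len(f1) >= 2:
        t, p = stats.ttest_ind(parent, f1, equal_var=False)
        welch_t, welch_p = float(t), float(p)
    else:
        welch_t = welch_p = float("nan")
    return SelfFertilityResult(kept, summary, welch_t, welch_p, rejected)


def purity_cross_check(
    false_hybrid_pct: float, selfing_min_pct: float, selfing_max_pct: float
) -> str:
    """Is the marker-estimated false-hybrid percentage explained by the
    measured maternal self-fertility range?  Boundaries count as within."""
    if selfing_min_pct > selfing_max_pct:
        raise InputError("selfing_min must be <= selfing_max")
    if false_hybrid_pct < selfing_min_pct:
        return BELOW_RANGE
    if false_hybrid_pct > selfing_max_pct:
        return ABOVE_RANGE
    return WITHIN_RANGE


def combination_summary(records: pd.DataFrame, min_seeds: int = 50) -> pd.DataFrame:
    """Per-cross survival/overwintering/fertile percentages.

    ``records`` columns: cross, seeds, survived, overwintered, fertile.
    Rates chain through the cohort: survival = survived/seeds,
    overwintering = overwintered/survived, fertile = fertile/overwintered.
    Crosses with fewer than ``min_seeds`` seeds (or a zero denominator)
    are reported not-evaluated (NaN rates).
    """
    required = {"cross", "seeds", "survived", "overwintered", "fertile"}
    missing = required - set(records.columns)
    if missing:
        raise InputError(f"combination records missing columns: {sorted(missing)}")
    rows = {}
    for _, r in records.iterrows():
        evaluated = r["seeds"] >= min_seeds
        def _pct(num, den):
            if not evaluated or den <= 0:
                return np.nan
            return round(100.0 * num / den, 2)
        rows[r["cross"]] = {
            "seeds": int(r["seeds"]),
            "survival_pct": _pct(r["survived"], r["seeds"]),
            "overwintering_pct": _pct(r["overwintered"], r["survived"]),
            "fertile_pct": _pct(r["fertile"], r["overwintered"]),
            "evaluated": bool(evaluated),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "cross"
    return out


# ---------------------------------------------------------------------------
# I/O helpers


def read_trait_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    return df.astype(float)


def read_parent_means(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    for col in ("mother_mean", "father_mean"):
        if col not in df.columns:
            raise InputError(f"{path}: parent means file lacks column {col!r}")
    return df.astype(float)
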