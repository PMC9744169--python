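"""Synthetic data generator for the whole pipeline.

Simulates diploid parents scored at dominant band loci, F1/BC1 offspring
with a known rate of maternal-self contamination, and correlated
quantitative trait tables — so every downstream stage can be exercised
with known ground truth and no external data.

Limitations (deliberate): loci segregate independently (no linkage map),
selfing is the only contamination mode, and missingness is completely at
random.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .markers.matrix import BandMatrix, write_band_matrix

F1 = "F1"
BC1 = "BC1"

TRUE_HYBRID_LABEL = "true_hybrid"
MATERNAL_SELF_LABEL = "maternal_self"

#: skew strength for the exponential-tilt map applied to skewed traits
_SKEW_S = 0.8


# ---------------------------------------------------------------------------
# parent genotypes


@dataclass
class ParentGenotypes:
    """Diploid band-allele dosages (0/1/2) of the two parents per locus."""

    primer_ids: list[str]
    locus_ids: list[str]
    locus_to_primer: dict[str, str]
    mother_genotype: np.ndarray  # int dosage per locus
    father_genotype: np.ndarray

    def __post_init__(self) -> None:
        self.mother_genotype = np.asarray(self.mother_genotype, dtype=int)
        self.father_genotype = np.asarray(self.father_genotype, dtype=int)
        n = len(self.locus_ids)
        if self.mother_genotype.shape != (n,) or self.father_genotype.shape != (n,):
            raise InputError("genotype arrays must have one dosage per locus")
        for g in (self.mother_genotype, self.father_genotype):
            if not np.isin(g, [0, 1, 2]).all():
                raise InputError("dosages must be integers in {0, 1, 2}")
        missing = [l for l in self.locus_ids if l not in self.locus_to_primer]
        if missing:
            raise InputError(f"loci without a primer: {missing}")
        unknown = set(self.locus_to_primer.values()) - set(self.primer_ids)
        if unknown:
            raise InputError(f"locus mapped to unknown primer(s): {sorted(unknown)}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "primer_id": [self.locus_to_primer[l] for l in self.locus_ids],
                "locus_id": self.locus_ids,
                "mother_dosage": self.mother_genotype,
                "father_dosage": self.father_genotype,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ParentGenotypes":
        primer_ids = list(dict.fromkeys(df["primer_id"].astype(str)))
        locus_ids = list(df["locus_id"].astype(str))
        mapping = dict(zip(locus_ids, df["primer_id"].astype(str)))
        return cls(
            primer_ids,
            locus_ids,
            mapping,
            df["mother_dosage"].to_numpy(int),
            df["father_dosage"].to_numpy(int),
        )


def simulate_parents(
    n_primers: int, loci_per_primer: int, p_polymorphic: float, seed: int
) -> ParentGenotypes:
    """Draw parental dosage pairs, discordant in band phenotype with
    probability ``p_polymorphic`` per locus.

    Discordant loci give one parent a dosage in {1, 2} and the other 0;
    concordant loci are, with equal probability, present in both parents
    (independent dosages in {1, 2}) or absent in both.
    """
    if n_primers < 1 or loci_per_primer < 1:
        raise InputError("n_primers and loci_per_primer must be >= 1")
    if not 0.0 <= p_polymorphic <= 1.0:
        raise InputError(f"p_polymorphic must be in [0, 1], got {p_polymorphic}")
    rng = np.random.default_rng(seed)
    primer_ids = [f"P{i + 1}" for i in range(n_primers)]
    locus_ids, mapping = [], {}
    for p in primer_ids:
        for j in range(loci_per_primer):
            locus = f"{p}L{j + 1}"
            locus_ids.append(locus)
            mapping[locus] = p
    n = len(locus_ids)
    mother = np.zeros(n, dtype=int)
    father = np.zeros(n, dtype=int)
    for k in range(n):
        if rng.random() < p_polymorphic:
            carrier_dosage = rng.integers(1, 3)
            if rng.random() < 0.5:
                father[k] = carrier_dosage
            else:
                mother[k] = carrier_dosage
        else:
            if rng.random() < 0.5:
                mother[k] = rng.integers(1, 3)
                father[k] = rng.integers(1, 3)
            # else both stay 0
    return ParentGenotypes(primer_ids, locus_ids, mapping, mother, father)


# ---------------------------------------------------------------------------
# offspring


@dataclass
class SimulationConfig:
    n_offspring: int
    generation: str = F1
    selfing_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    mother_id: str = "MOTHER"
    father_id: str = "FATHER"

    def __post_init__(self) -> None:
        if self.generation not in (F1, BC1):
            raise InputError(f"generation must be {F1!r} or {BC1!r}")
        if self.n_offspring < 1:
            raise InputError("n_offspring must be >= 1")
        for name in ("selfing_rate", "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must be in [0, 1], got {v}")


def _gametes(rng: np.random.Generator, dosage: np.ndarray, n: int) -> np.ndarray:
    """n haploid gametes: band allele carried with probability dosage/2."""
    return (rng.random((n, dosage.size)) < dosage / 2.0).astype(int)


def simulate_offspring(
    parents: ParentGenotypes,
    config: SimulationConfig,
    f1_mother_genotype: np.ndarray | None = None,
) -> tuple[BandMatrix, pd.DataFrame]:
    """Simulate a progeny band matrix plus its ground-truth labels.

    Each offspring is a maternal self with probability ``selfing_rate``
    (two independent gametes from the seed parent); otherwise a true
    cross (one gamete from each parent).  For BC1 the seed parent is the
    supplied F1 plant and the pollen parent is the recurrent father.
    Band phenotype is 1 iff dosage > 0; offspring cells are masked
    missing independently at ``missing_rate`` (parent rows stay called).
    """
    if config.generation == BC1:
        if f1_mother_genotype is None:
            raise InputError("generation=BC1 requires f1_mother_genotype")
        mother_dosage = np.asarray(f1_mother_genotype, dtype=int)
        if mother_dosage.shape != (len(parents.locus_ids),):
            raise InputError("f1_mother_genotype must supply one dosage per locus")
        if not np.isin(mother_dosage, [0, 1, 2]).all():
            raise InputError("f1_mother_genotype dosages must be in {0, 1, 2}")
    else:
        if f1_mother_genotype is not None:
            raise InputError("f1_mother_genotype is only meaningful for BC1")
        mother_dosage = parents.mother_genotype
    father_dosage = parents.father_genotype

    rng = np.random.default_rng(config.seed)
    n = config.n_offspring
    is_self = rng.random(n) < config.selfing_rate
    maternal_a = _gametes(rng, mother_dosage, n)
    maternal_b = _gametes(rng, mother_dosage, n)
    paternal = _gametes(rng, father_dosage, n)
    dosage = np.where(is_self[:, None], maternal_a + maternal_b, maternal_a + paternal)
    phenotype = (dosage > 0).astype(float)
    mask = rng.random(phenotype.shape) < config.missing_rate
    phenotype[mask] = np.nan

    width = max(3, len(str(n)))
    offspring_ids = [f"O{i + 1:0{width}d}" for i in range(n)]
    rows = [
        (mother_dosage > 0).astype(float),
        (parents.father_genotype > 0).astype(float),
        *phenotype,
    ]
    calls = pd.DataFrame(
        rows,
        index=pd.Index([config.mother_id, config.father_id, *offspring_ids],
                       name="individual_id"),
        columns=parents.locus_ids,
    )
    mapping = pd.Series(
        {l: parents.locus_to_primer[l] for l in parents.locus_ids}, name="primer_id"
    )
    matrix = BandMatrix(calls, mapping, config.mother_id, config.father_id)
    truth = pd.DataFrame(
        {
            "individual_id": offspring_ids,
            "truth": np.where(is_self, MATERNAL_SELF_LABEL, TRUE_HYBRID_LABEL),
        }
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# quantitative traits

#: the 12 agronomic traits measured on each plant
TRAIT_NAMES = [
    "tiller_height_cm",
    "second_leaf_length_cm",
    "second_leaf_width_cm",
    "reproductive_tiller_number",
    "nutritional_tiller_number",
    "spike_length_cm",
    "spike_width_cm",
    "spikelet_number_per_spike",
    "seed_number_per_spike",
    "seed_weight_per_spike_g",
    "seed_number_per_plant_k",
    "thousand_kernel_weight_g",
]


@dataclass
class TraitSimSpec:
    """Targets for the correlated-trait simulator."""

    trait_names: list[str]
    mother_means: np.ndarray
    father_means: np.ndarray
    mph_targets: np.ndarray  # intended mid-parent heterosis, proportion
    correlation: np.ndarray  # target noise correlation, PSD
    cv_targets: np.ndarray  # coefficient of variation, proportion
    skew_traits: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.trait_names)
        self.mother_means = np.asarray(self.mother_means, dtype=float)
        self.father_means = np.asarray(self.father_means, dtype=float)
        self.mph_targets = np.asarray(self.mph_targets, dtype=float)
        self.cv_targets = np.asarray(self.cv_targets, dtype=float)
        self.correlation = np.asarray(self.correlation, dtype=float)
        for name, arr in (
            ("mother_means", self.mother_means),
            ("father_means", self.father_means),
            ("mph_targets", self.mph_targets),
            ("cv_targets", self.cv_targets),
        ):
            if arr.shape != (k,):
                raise InputError(f"{name} must have one value per trait")
        if (self.cv_targets <= 0).any():
            raise InputError("cv_targets must be > 0")
        if self.correlation.shape != (k, k):
            raise InputError("correlation must be square with one row per trait")
        if not np.allclose(self.correlation, self.correlation.T):
            raise InputError("correlation must be symmetric")
        if not np.allclose(np.diag(self.correlation), 1.0):
            raise InputError("correlation must have unit diagonal")
        eigvals = np.linalg.eigvalsh(self.correlation)
        if eigvals.min() < -1e-8:
            raise InputError(
                f"correlation is not positive semidefinite: eigenvalue {eigvals.min():.3e}"
            )
        unknown = set(self.skew_traits) - set(self.trait_names)
        if unknown:
            raise InputError(f"skew_traits not among trait_names: {sorted(unknown)}")


def _skew_tilt(z: np.ndarray, s: float = _SKEW_S) -> np.ndarray:
    """Monotone right-skewing map with zero mean and unit variance.

    Standardized lognormal: y = (exp(sz) - e^{s^2/2}) / sqrt((e^{s^2}-1) e^{s^2}).
    Preserves the target mean/SD exactly; rank correlation is preserved,
    Pearson correlation only approximately.
    """
    m = np.exp(s * s / 2.0)
    sd = np.sqrt((np.exp(s * s) - 1.0) * np.exp(s * s))
    return (np.exp(s * z) - m) / sd


def simulate_traits(spec: TraitSimSpec, n_offspring: int, seed: int) -> pd.DataFrame:
    """Correlated offspring trait table hitting mean/CV/heterosis targets."""
    if n_offspring < 2:
        raise InputError("n_offspring must be >= 2")
    k = len(spec.trait_names)
    rng = np.random.default_rng(seed)
    eigval, eigvec = np.linalg.eigh(spec.correlation)
    root = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0.0, None)))
    z = rng.standard_normal((n_offspring, k)) @ root.T
    for trait in spec.skew_traits:
        j = spec.trait_names.index(trait)
        z[:, j] = _skew_tilt(z[:, j])
    mid_parent = (spec.mother_means + spec.father_means) / 2.0
    target_mean = (1.0 + spec.mph_targets) * mid_parent
    target_sd = spec.cv_targets * np.abs(target_mean)
    values = target_mean + target_sd * z
    width = max(3, len(str(n_offspring)))
    ids = [f"O{i + 1:0{width}d}" for i in range(n_offspring)]
    return pd.DataFrame(values, index=pd.Index(ids, name="individual_id"),
                        columns=spec.trait_names)


def default_trait_spec() -> TraitSimSpec:
    """Trait targets modeled on a published perennial-grass F1 trial.

    Parent means, heterosis and CV targets follow the reference cross
    used throughout the docs; noise correlation is a one-factor model
    (uniform off-diagonal 0.25) and the two count traits known to
    segregate non-normally are generated right-skewed.
    """
    mother = np.array([109.40, 17.94, 0.34, 17.67, 31.33, 9.11,
                       0.65, 26.33, 41.31, 0.11, 0.77, 2.00])
    father = np.array([128.67, 20.70, 0.34, 41.33, 95.00, 10.00,
                       0.71, 34.33, 126.25, 0.27, 3.55, 2.22])
    mph = np.array([0.0664, 0.1721, 0.0248, 1.1631, 1.7139, 0.0490,
                    -0.1279, 0.0198, 0.0029, 0.1848, 1.4317, 0.3680])
    cv = np.array([0.1267, 0.1789, 0.1640, 0.7018, 0.3414, 0.1526,
                   0.1324, 0.1382, 0.3330, 0.3922, 0.9958, 0.1575])
    lam = 0.5
    corr = np.full((12, 12), lam * lam)
    np.fill_diagonal(corr, 1.0)
    return TraitSimSpec(
        trait_names=list(TRAIT_NAMES),
        mother_means=mother,
        father_means=father,
        mph_targets=mph,
        correlation=corr,
        cv_targets=cv,
        skew_traits=["reproductive_tiller_number", "seed_number_per_plant_k"],
    )


def parent_means_frame(spec: TraitSimSpec) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trait": spec.trait_names,
            "mother_mean": spec.mother_means,
            "father_mean": spec.father_means,
        }
    ).set_index("trait")


# ---------------------------------------------------------------------------
# fixture sets

SCENARIOS = ("tiny", "paper-like-F1", "paper-like-BC1")


def _scenario_params(scenario: str) -> dict:
    if scenario == "tiny":
        return dict(n_primers=2, loci_per_primer=3, p_polymorphic=0.9,
                    n_offspring=10, generation=F1, selfing_rate=0.1,
                    missing_rate=0.05, n_traits_offspring=10)
    if scenario == "paper-like-F1":
        # 123 putative hybrids, maternal-self contamination near the
        # observed 4/123 = 3.25% false-hybrid proportion
        return dict(n_primers=3, loci_per_primer=13, p_polymorphic=0.8,
                    n_offspring=123, generation=F1, selfing_rate=0.0325,
                    missing_rate=0.01, n_traits_offspring=105)
    if scenario == "paper-like-BC1":
        return dict(n_primers=3, loci_per_primer=10, p_polymorphic=0.6,
                    n_offspring=143, generation=BC1, selfing_rate=0.042,
                    missing_rate=0.01, n_traits_offspring=137)
    raise InputError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")


def write_fixture_set(out_dir: str | Path, scenario: str, seed: int = 0) -> list[Path]:
    """Write a complete, deterministic fixture set for one scenario.

    Files: parents.csv, band_matrix.csv, truth_labels.csv, traits.csv,
    parent_means.csv and config.json.  Returns the paths written.
    """
    params = _scenario_params(scenario)
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out}: {exc}") from exc

    parents = simulate_parents(
        params["n_primers"], params["loci_per_primer"], params["p_polymorphic"], seed
    )
    f1_mother = None
    if params["generation"] == BC1:
        # realize one F1 plant (non-self) to act as the seed parent
        rng = np.random.default_rng(seed + 1)
        f1_mother = (
            _gametes(rng, parents.mother_genotype, 1)
            + _gametes(rng, parents.father_genotype, 1)
        )[0]
    config = SimulationConfig(
        n_offspring=params["n_offspring"],
        generation=params["generation"],
        selfing_rate=params["selfing_rate"],
        missing_rate=params["missing_rate"],
        seed=seed + 2,
    )
    matrix, truth = simulate_offspring(parents, config, f1_mother_genotype=f1_mother)
    spec = default_trait_spec()
    traits = simulate_traits(spec, params["n_traits_offspring"], seed + 3)

    manifest: list[Path] = []

    def _write(name: str, writer) -> None:
        p = out / name
        writer(p)
        manifest.append(p)

    _write("parents.csv", lambda p: parents.to_frame().to_csv(p, index=False))
    _write("band_matrix.csv", lambda p: write_band_matrix(matrix, p))
    _write("truth_labels.csv", lambda p: truth.to_csv(p, index=False))
    _write("traits.csv", lambda p: traits.to_csv(p))
    _write("parent_means.csv", lambda p: parent_means_frame(spec).to_csv(p))

    snapshot = {
        "scenario": scenario,
        "seed": seed,
        "params": {k: v for k, v in params.items()},
        "config": asdict(config),
        "f1_mother_genotype": None if f1_mother is None else f1_mother.tolist(),
    }
    _write(
        "config.json",
        lambda p: p.write_text(json.dumps(snapshot, indent=2, sort_keys=True) + "\n"),
    )
    return manifest
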