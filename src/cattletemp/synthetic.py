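"""Synthetic herd generator: pedigrees, breeding values, phenotypes, scale traces.

The study population this package targets (weaned beef calves scored for
temperament) is not publicly deposited, so every downstream stage is exercised
on simulated data with the same statistical structure:

* a multi-generation pedigree with known/unknown parents,
* additive-genetic (co)variation among five analysis traits — the two latent
  temperament factors *difficult* and *easy*, the docility-score liability,
  and the two movement scores SSD and CVSSD — following ``u ~ N(0, Sigma_u ⊗ A)``,
* a two-factor measurement model generating 13 observed subjective traits
  (temperament score plus 12 qualitative behavior assessment attributes),
* raw four-platform standing scale (FPSS) traces at ~15 Hz with an entry
  transient, from which SSD and CVSSD are re-measured downstream.

All randomness flows from one integer seed through ``numpy.random.SeedSequence``
spawning, so a dataset is bit-reproducible from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import UNKNOWN, Pedigree, build_A

# ---------------------------------------------------------------------------
# trait naming

ANALYSIS_TRAITS = ["difficult", "easy", "ds", "ssd", "cvssd"]

#: Subjective traits in measurement-model order: the *difficult* block first
#: (temperament score + negative attributes), then the *easy* block
#: (positive attributes).
DIFFICULT_TRAITS = ["ts", "active", "fearful", "agitated", "irritated", "distressed"]
EASY_TRAITS = ["relaxed", "calm", "attentive", "positively_occupied", "curious",
               "apathetic", "happy"]
SUBJECTIVE_TRAITS = DIFFICULT_TRAITS + EASY_TRAITS

#: QBA attributes in their conventional (alphabetical) listing order, used for
#: phenotype CSV columns; each is scored on a 136 mm visual-analog line.
QBA_TRAITS = ["active", "agitated", "apathetic", "attentive", "calm", "curious",
              "distressed", "fearful", "happy", "irritated", "positively_occupied",
              "relaxed"]

QBA_LINE_MM = 136.0
TS_LEVELS = (1, 2, 4, 5)  # 5-point scale with the neutral 3 removed
DS_LEVELS = (1, 2, 3, 4, 5, 6)

#: Reference standardized loadings of the two-factor confirmatory model
#: (trait -> (factor, loading)); the default generating truth.
REFERENCE_LOADINGS: dict[str, tuple[str, float]] = {
    "ts": ("difficult", 0.861),
    "active": ("difficult", 0.820),
    "fearful": ("difficult", 0.840),
    "agitated": ("difficult", 0.937),
    "irritated": ("difficult", 0.844),
    "distressed": ("difficult", 0.607),
    "relaxed": ("easy", 0.968),
    "calm": ("easy", 0.982),
    "attentive": ("easy", 0.079),
    "positively_occupied": ("easy", 0.636),
    "curious": ("easy", 0.514),
    "apathetic": ("easy", 0.761),
    "happy": ("easy", 0.730),
}


def as_rng(seed) -> np.random.Generator:
    """Coerce an int / SeedSequence / Generator into a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def as_seed_sequence(seed) -> np.random.SeedSequence:
    """Coerce an int (or pass through a SeedSequence) for spawning substreams."""
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _nearest_correlation(R: np.ndarray) -> np.ndarray:
    """Higham-style projection to the nearest correlation matrix."""
    from statsmodels.stats.correlation_tools import corr_nearest

    return corr_nearest(R, threshold=1e-10)


# ---------------------------------------------------------------------------
# specifications


@dataclass
class GeneticArchitecture:
    """Additive-genetic architecture of the five analysis traits.

    ``genetic_correlations`` defaults to the reference estimates: a strong
    negative difficult–easy correlation (−0.92), moderate correlations of the
    docility score with the factors and movement scores, and a large positive
    SSD–CVSSD correlation (no point estimate is available for the latter;
    0.95 by default, configurable).  Heritabilities default to 0.40 for the
    factors, 0.28 for docility and 0.20 for the movement scores, honoring the
    reported 0.18–0.40 range and ordering.
    """

    trait_names: list[str] = field(default_factory=lambda: list(ANALYSIS_TRAITS))
    heritabilities: np.ndarray = field(
        default_factory=lambda: np.array([0.40, 0.40, 0.28, 0.20, 0.20])
    )
    genetic_correlations: np.ndarray | None = None
    phenotypic_variances: np.ndarray = field(default_factory=lambda: np.ones(5))
    residual_correlations: np.ndarray | None = None  # default: identity
    ssd_cvssd_correlation: float = 0.95

    def __post_init__(self) -> None:
        self.heritabilities = np.asarray(self.heritabilities, dtype=float)
        self.phenotypic_variances = np.asarray(self.phenotypic_variances, dtype=float)
        k = len(self.trait_names)
        if self.genetic_correlations is None:
            self.genetic_correlations = default_genetic_correlations(
                self.ssd_cvssd_correlation
            )
        self.genetic_correlations = np.asarray(self.genetic_correlations, dtype=float)
        if self.residual_correlations is None:
            self.residual_correlations = np.eye(k)
        self.residual_correlations = np.asarray(self.residual_correlations, dtype=float)
        if np.any(self.heritabilities <= 0) or np.any(self.heritabilities >= 1):
            raise ValueError("heritabilities must lie strictly in (0, 1)")
        if np.any(self.phenotypic_variances <= 0):
            raise ValueError("phenotypic variances must be positive")
        for name in ("genetic_correlations", "residual_correlations"):
            R = getattr(self, name)
            if R.shape != (k, k) or not np.allclose(R, R.T) or not np.allclose(np.diag(R), 1):
                raise ValueError(f"{name} must be a symmetric {k}x{k} correlation matrix")
            if np.linalg.eigvalsh(R).min() <= 1e-10:
                setattr(self, name, _nearest_correlation(R))

    @property
    def Sigma_u(self) -> np.ndarray:
        """Genetic covariance: D_g^(1/2) R_g D_g^(1/2)."""
        sg = np.sqrt(self.heritabilities * self.phenotypic_variances)
        return self.genetic_correlations * np.outer(sg, sg)

    @property
    def Sigma_e(self) -> np.ndarray:
        """Residual covariance matching the phenotypic variances and h²."""
        se = np.sqrt((1.0 - self.heritabilities) * self.phenotypic_variances)
        Se = self.residual_correlations * np.outer(se, se)
        if np.linalg.eigvalsh(Se).min() <= 0:
            raise ValueError("residual covariance not positive definite")
        return Se


def default_genetic_correlations(ssd_cvssd: float = 0.95) -> np.ndarray:
    """Reference 5x5 genetic correlation matrix (difficult, easy, ds, ssd, cvssd)."""
    R = np.eye(5)
    pairs = {
        (0, 1): -0.92,
        (0, 2): 0.36, (1, 2): -0.31,
        (0, 3): 0.42, (1, 3): -0.40, (2, 3): 0.42,
        (0, 4): 0.35, (1, 4): -0.35, (2, 4): 0.34, (3, 4): ssd_cvssd,
    }
    for (i, j), r in pairs.items():
        R[i, j] = R[j, i] = r
    if np.linalg.eigvalsh(R).min() <= 1e-10:
        R = _nearest_correlation(R)
    return R


@dataclass
class MeasurementModelSpec:
    """Two-factor, cross-loading-free measurement model for the 13 subjective traits.

    With standardized traits and unit-variance factors, the specific variance
    of each trait is ``1 - loading**2``, so trait variances are 1 by
    construction.
    """

    trait_names: list[str] = field(default_factory=lambda: list(SUBJECTIVE_TRAITS))
    factor_names: list[str] = field(default_factory=lambda: ["difficult", "easy"])
    loadings: dict[str, tuple[str, float]] = field(
        default_factory=lambda: dict(REFERENCE_LOADINGS)
    )

    def __post_init__(self) -> None:
        for trait in self.trait_names:
            factor, lam = self.loadings[trait]
            if factor not in self.factor_names:
                raise ValueError(f"unknown factor {factor!r} for trait {trait!r}")
            if not -1.0 < lam < 1.0:
                raise ValueError(f"loading for {trait!r} must be in (-1, 1)")

    @property
    def Lambda(self) -> np.ndarray:
        """t x q loading matrix (one nonzero per row)."""
        L = np.zeros((len(self.trait_names), len(self.factor_names)))
        for i, trait in enumerate(self.trait_names):
            factor, lam = self.loadings[trait]
            L[i, self.factor_names.index(factor)] = lam
        return L

    @property
    def specific_variances(self) -> np.ndarray:
        return 1.0 - np.array([self.loadings[t][1] ** 2 for t in self.trait_names])

    @property
    def structure(self) -> np.ndarray:
        """Binary t x q map of which factor loads on which trait."""
        return (self.Lambda != 0).astype(int)


@dataclass
class FixedEffectsSpec:
    """Fixed-effect layout: year-by-collection-date, primary breed, and sex.

    Effect sizes are deterministic and small relative to the phenotypic SD
    (≤ 0.25 σ_P) so parameter-recovery exercises are not dominated by fixed
    effects.  The sex effect is nonzero only for CVSSD and *easy*; the breed
    contrast is zero (breed is still fitted downstream).
    """

    n_years: int = 4
    dates_per_year: int = 2
    breeds: tuple[str, ...] = ("angus", "hereford")
    breed_probs: tuple[float, ...] = (0.877, 0.123)
    sexes: tuple[str, ...] = ("heifer", "steer")
    year_date_effect_sd: float = 0.25  # in units of sigma_P, spread over levels
    sex_effect: float = 0.20           # heifers more temperamental, in sigma_P

    @property
    def n_year_date(self) -> int:
        return self.n_years * self.dates_per_year

    def year_date_effects(self, k: int) -> np.ndarray:
        """(n_levels, k) deterministic evenly spaced contrasts, same for all traits."""
        levels = np.linspace(-1.0, 1.0, self.n_year_date) * self.year_date_effect_sd
        return np.tile(levels[:, None], (1, k))

    def sex_effects(self, trait_names: list[str]) -> np.ndarray:
        """Per-trait heifer-minus-steer contrast (applied +/- half to each sex)."""
        out = np.zeros(len(trait_names))
        for j, t in enumerate(trait_names):
            if t in ("cvssd", "easy"):
                out[j] = self.sex_effect if t == "cvssd" else -self.sex_effect
        return out


@dataclass
class FPSSTrace:
    """Raw four-platform standing scale trace for one animal."""

    animal_id: str
    rate_hz: float
    quadrant_weights: np.ndarray  # (n_records, 4), kg

    def __post_init__(self) -> None:
        self.quadrant_weights = np.atleast_2d(np.asarray(self.quadrant_weights, float))
        if self.quadrant_weights.shape[1] != 4:
            raise ValueError("quadrant_weights must have 4 columns")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def total_weight(self) -> np.ndarray:
        return self.quadrant_weights.sum(axis=1)

    @property
    def n_records(self) -> int:
        return self.quadrant_weights.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_records / self.rate_hz

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.quadrant_weights, columns=["q1_kg", "q2_kg", "q3_kg", "q4_kg"])
        df.insert(0, "record_index", np.arange(self.n_records))
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# simulators


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    matings_per_generation: int,
    offspring_per_mating: int = 1,
    seed=0,
) -> Pedigree:
    """Random discrete-generation pedigree.

    Founders (generation 0) have both parents unknown.  Each later generation
    draws ``matings_per_generation`` sire/dam pairs (without selfing) from the
    union of all previous generations and produces ``offspring_per_mating``
    full sibs per pair.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders to form matings")
    if min(n_generations, matings_per_generation, offspring_per_mating) < 1:
        raise ValueError("generation/mating/offspring counts must be positive")
    rng = as_rng(seed)
    animals = [f"G0_{i:04d}" for i in range(n_founders)]
    sires = [UNKNOWN] * n_founders
    dams = [UNKNOWN] * n_founders
    generation = [0] * n_founders
    pool = list(animals)
    for g in range(1, n_generations + 1):
        new: list[str] = []
        for m in range(matings_per_generation):
            sire, dam = rng.choice(len(pool), size=2, replace=False)
            for o in range(offspring_per_mating):
                aid = f"G{g}_{m:04d}_{o}"
                animals.append(aid)
                sires.append(pool[sire])
                dams.append(pool[dam])
                generation.append(g)
                new.append(aid)
        pool.extend(new)
    return Pedigree(animals, sires, dams, generation)


def simulate_breeding_values(
    pedigree: Pedigree, Sigma_u: np.ndarray, seed=0, inbreeding: np.ndarray | None = None
) -> np.ndarray:
    """Draw breeding values ``u ~ N(0, Sigma_u ⊗ A)`` by gene-dropping recursion.

    Founders are drawn from ``N(0, Sigma_u)``; each non-founder is the parent
    average plus a Mendelian-sampling deviation with covariance
    ``c * Sigma_u`` where ``c = 1/2 - (F_s + F_d)/4`` for two known parents,
    ``3/4 - F_known/4`` for one known parent, and 1 for founders; unknown
    parents contribute 0.

    Returns an (n_animals, k) matrix in pedigree order.
    """
    Sigma_u = np.atleast_2d(np.asarray(Sigma_u, dtype=float))
    k = Sigma_u.shape[0]
    try:
        L = np.linalg.cholesky(Sigma_u)
    except np.linalg.LinAlgError as err:
        raise ValueError("Sigma_u must be positive definite") from err
    rng = as_rng(seed)
    if inbreeding is None:
        inbreeding = build_A(pedigree).inbreeding
    par = pedigree.parent_indices()
    n = len(pedigree)
    z = rng.standard_normal((n, k))
    u = np.zeros((n, k))
    for i in range(n):
        s, d = par[i]
        mean = np.zeros(k)
        c = 1.0
        if s >= 0 and d >= 0:
            mean = 0.5 * (u[s] + u[d])
            c = 0.5 - 0.25 * (inbreeding[s] + inbreeding[d])
        elif s >= 0 or d >= 0:
            p = s if s >= 0 else d
            mean = 0.5 * u[p]
            c = 0.75 - 0.25 * inbreeding[p]
        u[i] = mean + np.sqrt(c) * (L @ z[i])
    return u


@dataclass
class SimulatedPhenotypes:
    """Phenotype table plus the latent truths used to generate it."""

    table: pd.DataFrame            # observed, on observation scales
    latent: pd.DataFrame           # the 5 latent analysis-trait values
    breeding_values: pd.DataFrame  # true u for the 5 analysis traits
    factor_scores: pd.DataFrame    # unit-variance factor scores fed to Lambda F
    ssd_kg: pd.Series              # latent SSD on the kg scale (trace target)
    cvssd: pd.Series               # latent CVSSD (dimensionless)
    weight_kg: pd.Series           # true standing weight ssd/cvssd, clipped

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


# observation-scale mapping constants: QBA lines are scored around mid-line with
# ~22 mm spread; SSD ~2 kg, CVSSD ~1% with genetic + residual spread around them
QBA_CENTER_MM, QBA_SCALE_MM = 68.0, 22.0
SSD_CENTER_KG, SSD_SCALE_KG = 2.0, 0.5
CVSSD_CENTER, CVSSD_SCALE = 0.010, 0.002


def simulate_phenotypes(
    pedigree: Pedigree,
    architecture: GeneticArchitecture | None = None,
    measurement: MeasurementModelSpec | None = None,
    fixed_effects: FixedEffectsSpec | None = None,
    seed=0,
    recorded_ids: list[str] | None = None,
) -> SimulatedPhenotypes:
    """Generate observed phenotypes for recorded animals.

    Pipeline per animal: (1) draw the five latent analysis traits as fixed
    effects + breeding value + residual; (2) take unit-variance *difficult*
    and *easy* factor scores from the first two; (3) emit the 13 subjective
    traits as ``Lambda F + specific noise`` mapped to their observation scales
    (TS 4-level, QBA clamped to the 136 mm line); (4) threshold the docility
    liability into the ordinal 1–6 score; (5) map latent SSD / CVSSD onto kg /
    dimensionless scales for downstream trace simulation.
    """
    architecture = architecture or GeneticArchitecture()
    measurement = measurement or MeasurementModelSpec()
    fixed_effects = fixed_effects or FixedEffectsSpec()
    ss = as_seed_sequence(seed).spawn(4)

    k = len(architecture.trait_names)
    u = simulate_breeding_values(pedigree, architecture.Sigma_u, seed=ss[0])
    ids = list(pedigree.animal_ids) if recorded_ids is None else list(recorded_ids)
    idx = pedigree.index
    rows = np.array([idx[a] for a in ids])
    n = len(ids)

    rng = as_rng(ss[1])
    # fixed-effect levels per animal
    year_date = rng.integers(fixed_effects.n_year_date, size=n)
    breed = rng.choice(len(fixed_effects.breeds), size=n, p=fixed_effects.breed_probs)
    sex = rng.integers(2, size=n)
    sig_p = np.sqrt(architecture.phenotypic_variances)
    fx = fixed_effects.year_date_effects(k)[year_date] * sig_p
    sex_fx = fixed_effects.sex_effects(architecture.trait_names) * sig_p
    fx += np.where(sex[:, None] == 0, 0.5, -0.5) * sex_fx  # heifer +, steer -

    Le = np.linalg.cholesky(architecture.Sigma_e)
    resid = rng.standard_normal((n, k)) @ Le.T
    latent = fx + u[rows] + resid  # (n, 5)

    # unit-variance factor scores for the measurement model
    F = latent[:, :2] / sig_p[:2]
    rng_m = as_rng(ss[2])
    T = F @ measurement.Lambda.T + rng_m.standard_normal(
        (n, len(measurement.trait_names))
    ) * np.sqrt(measurement.specific_variances)
    obs = pd.DataFrame(T, columns=measurement.trait_names)

    # map to observation scales
    ts_cuts = np.quantile(np.asarray(obs["ts"]), [0.25, 0.5, 0.75])
    ts = np.asarray(TS_LEVELS)[np.searchsorted(ts_cuts, obs["ts"])]
    qba = {
        t: np.clip(QBA_CENTER_MM + QBA_SCALE_MM * obs[t], 0.0, QBA_LINE_MM)
        for t in QBA_TRAITS
    }
    ds_z = latent[:, 2] / sig_p[2]
    ds_cuts = np.quantile(ds_z, np.arange(1, 6) / 6.0)  # equal-probability bins
    ds = np.asarray(DS_LEVELS)[np.searchsorted(ds_cuts, ds_z)]
    ssd_kg = np.maximum(SSD_CENTER_KG + SSD_SCALE_KG * latent[:, 3] / sig_p[3], 0.2)
    cvssd = np.maximum(CVSSD_CENTER + CVSSD_SCALE * latent[:, 4] / sig_p[4], 0.002)
    weight = np.clip(ssd_kg / cvssd, 80.0, 500.0)

    table = pd.DataFrame({"animal_id": ids,
                          "year_date": [f"y{v // fixed_effects.dates_per_year}_d{v % fixed_effects.dates_per_year}" for v in year_date],
                          "breed": [fixed_effects.breeds[b] for b in breed],
                          "sex": [fixed_effects.sexes[s] for s in sex],
                          "ds": ds, "ts": ts})
    for t in QBA_TRAITS:
        table[t] = qba[t]
    table["ssd"] = ssd_kg
    table["cvssd"] = cvssd

    return SimulatedPhenotypes(
        table=table,
        latent=pd.DataFrame(latent, columns=architecture.trait_names, index=ids),
        breeding_values=pd.DataFrame(u[rows], columns=architecture.trait_names, index=ids),
        factor_scores=pd.DataFrame(F, columns=["difficult", "easy"], index=ids),
        ssd_kg=pd.Series(ssd_kg, index=ids, name="ssd_kg"),
        cvssd=pd.Series(cvssd, index=ids, name="cvssd"),
        weight_kg=pd.Series(weight, index=ids, name="weight_kg"),
    )


def simulate_measurement_observations(
    n: int,
    measurement: MeasurementModelSpec | None = None,
    factor_correlation: float = -0.37,
    seed=0,
) -> pd.DataFrame:
    """Draw n observations directly from the two-factor confirmatory model.

    Factors are unit-variance with the given correlation (default −0.37, the
    phenotypic correlation implied by the default architecture: genetic
    correlation −0.92 times h² = 0.40); observations are ``Lambda F +
    specific noise`` with variances ``1 - loading²``, i.e. already on the
    standardized scale.  This is the generating model for factor-count and
    loading-recovery studies.
    """
    measurement = measurement or MeasurementModelSpec()
    rng = as_rng(seed)
    Phi = np.array([[1.0, factor_correlation], [factor_correlation, 1.0]])
    F = rng.standard_normal((n, 2)) @ np.linalg.cholesky(Phi).T
    eps = rng.standard_normal((n, len(measurement.trait_names)))
    T = F @ measurement.Lambda.T + eps * np.sqrt(measurement.specific_variances)
    df = pd.DataFrame(T, columns=measurement.trait_names)
    df.attrs["factor_scores"] = F
    return df


def simulate_fpss_trace(
    true_weight: float,
    target_ssd: float,
    duration_s: float = 60.0,
    rate_hz: float = 15.0,
    entry_transient_s: float = 5.0,
    seed=0,
    animal_id: str = "sim",
) -> FPSSTrace:
    """Simulate one raw scale trace: an entry transient, then a stationary segment.

    During the transient the total weight ramps from near zero up to the
    animal's weight with large step spikes (the animal climbing on).  The
    stationary segment has mean ``true_weight`` and standard deviation
    ``target_ssd`` (iid Gaussian around the mean; exactly constant when
    ``target_ssd == 0``).  Quadrant weights are a Dirichlet convex
    decomposition of the total, so rows sum to the total exactly.
    """
    if duration_s < 45.0:
        raise ValueError("trace must cover at least 45 s")
    if target_ssd < 0:
        raise ValueError("target_ssd must be nonnegative")
    if true_weight <= 0:
        raise ValueError("true_weight must be positive")
    rng = as_rng(seed)
    n = int(round(duration_s * rate_hz))
    n_trans = int(round(entry_transient_s * rate_hz))
    total = np.empty(n)
    if n_trans > 0:
        ramp = np.linspace(0.15, 0.92, n_trans) * true_weight
        spikes = rng.normal(0.0, 0.08 * true_weight, size=n_trans)
        total[:n_trans] = np.maximum(ramp + spikes, 0.0)
    total[n_trans:] = true_weight + (
        rng.standard_normal(n - n_trans) * target_ssd if target_ssd > 0 else 0.0
    )
    total = np.maximum(total, 0.0)
    # slowly varying stance: Dirichlet shares around equal loading
    shares = rng.dirichlet(np.full(4, 25.0), size=n)
    quad = shares * total[:, None]
    return FPSSTrace(animal_id=animal_id, rate_hz=rate_hz, quadrant_weights=quad)
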