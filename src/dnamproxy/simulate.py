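"""Synthetic methylation cohorts with known ground truth.

The generator emulates the statistical structure that a serum-biomarker
episcore analysis assumes: a latent chronic inflammatory trait that is read
out noisily by a single serum measurement, sparse causal CpGs whose
methylation tracks the latent trait, smoking-responsive CpGs, cell-composition
driven CpGs mixed from reference leukocyte methylomes, batch structure usable
as cross-validation folds, and a battery of correlated lifestyle phenotypes
(BMI, alcohol, deprivation, cognition).

All effects act on the logit of the beta value and are mapped back through
the inverse logit, so simulated betas stay strictly inside (0, 1) without
clipping artifacts.  The serum trait is exponentiated (log-normal) so that
the log / rank-based inverse-normal preprocessing downstream is exercised
nontrivially.

Every random draw derives from a single integer master seed through
independent named substreams; the same seed reproduces the cohort
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .methdata import BetaMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "TruthTable",
    "CellReference",
    "simulate_cohort",
    "simulate_cell_reference",
    "null_config",
    "CELL_TYPES",
    "SMOKING_LEVELS",
]

CELL_TYPES = ("granulocytes", "NK", "B", "CD4T", "CD8T", "monocytes")

# Ordered smoking categories: never < quit >12 months ago < quit within
# 12 months < current smoker.
SMOKING_LEVELS = ("never", "ex_long", "ex_recent", "current")
# Category frequencies roughly matching a middle-aged population cohort
# (52% never, 32% ex split ~5:1 long:recent, 16% current).
_SMOKING_PROBS = (0.52, 0.27, 0.05, 0.16)

# Dirichlet mean ≈ (0.58, 0.05, 0.05, 0.16, 0.10, 0.06): typical whole-blood
# leukocyte composition dominated by granulocytes.
_DEFAULT_DIRICHLET = (17.4, 1.5, 1.5, 4.8, 3.0, 1.8)

# Minimum guaranteed separation between reference cell-type profiles: each
# probe assigns the 6 types a random permutation of 6 levels evenly spaced
# across [0.08, 0.92] (spacing 0.168) plus jitter of sd 0.02, so any two
# types differ by ≥ 0.1 in mean absolute beta across probes.
_REF_LEVELS = np.linspace(0.08, 0.92, 6)
_REF_JITTER_SD = 0.02


class ConfigurationError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    The defaults describe a well-powered training scenario: 500 samples on a
    2000-probe array with 20 causal CpGs whose logit-scale effects give
    per-probe correlations of roughly 0.3–0.7 with the latent chronic trait,
    and a serum readout carrying half chronic and half acute (occasion)
    variance.
    """

    n_samples: int = 500
    n_probes: int = 2000
    n_causal: int = 20
    n_smoking_probes: int = 30
    n_celltype_probes: int = 200
    n_batches: int = 12
    chronic_variance_fraction: float = 0.5
    causal_effect_sd: float = 0.15      # logit-scale; magnitudes U[0.9,1.1]×sd
    probe_noise_sd: float = 0.25        # logit-scale technical noise
    celltype_noise_sd: float = 0.02     # logit-scale noise on mixture probes
    age_range: tuple[float, float] = (30.0, 75.0)
    dirichlet_concentration: tuple[float, ...] = _DEFAULT_DIRICHLET
    detection_fail_rate: float = 0.0
    seed: int = 0
    # Seed of the probe architecture (role assignment, baselines, effect
    # sizes, cell reference).  None → same as ``seed``.  Two cohorts sharing
    # an architecture_seed but differing in seed have independent samples on
    # an identical array design, enabling train/project-cohort designs.
    architecture_seed: int | None = None

    # Wiring of the latent chronic trait L and correlated phenotypes.  Values
    # are approximate correlations with L (phenotypes) or raw weights in the
    # L linear predictor (age/sex/smoking); latent residual noise has sd 1.
    age_effect: float = 0.25
    sex_effect: float = 0.20
    smoking_effect: float = 0.25
    bmi_effect: float = 0.35
    alcohol_effect: float = 0.25
    deprivation_effect: float = -0.30
    cognitive_effect: float = -0.25
    # Log-serum scale: log(serum) = serum_log_mean + serum_log_sd · (mix of L
    # and acute noise).
    serum_log_mean: float = 0.3
    serum_log_sd: float = 0.8

    def validate(self) -> None:
        counts = {
            "n_samples": self.n_samples,
            "n_probes": self.n_probes,
            "n_causal": self.n_causal,
            "n_smoking_probes": self.n_smoking_probes,
            "n_celltype_probes": self.n_celltype_probes,
            "n_batches": self.n_batches,
        }
        for name, v in counts.items():
            if v < 0 or int(v) != v:
                raise ConfigurationError(f"{name} must be a nonnegative integer")
        if self.n_samples < 2:
            raise ConfigurationError("n_samples must be ≥ 2")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be ≥ 1")
        special = self.n_causal + self.n_smoking_probes + self.n_celltype_probes
        if special > self.n_probes:
            raise ConfigurationError(
                "n_causal + n_smoking_probes + n_celltype_probes exceeds n_probes"
            )
        if not (0.0 < self.chronic_variance_fraction <= 1.0):
            raise ConfigurationError("chronic_variance_fraction must be in (0, 1]")
        for name in ("causal_effect_sd", "probe_noise_sd", "celltype_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if not (0.0 <= self.detection_fail_rate < 1.0):
            raise ConfigurationError("detection_fail_rate must be in [0, 1)")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError("age_range must satisfy lo < hi")
        conc = tuple(self.dirichlet_concentration)
        if len(conc) != len(CELL_TYPES) or any(c <= 0 for c in conc):
            raise ConfigurationError(
                f"dirichlet_concentration needs {len(CELL_TYPES)} positive values"
            )


def null_config(**overrides) -> SimulationConfig:
    """A configuration with every simulated effect switched off.

    Probes become pure baseline + noise and all phenotypes are mutually
    independent (given the latent trait has no outlets), so every association
    in the downstream battery is null.  Used for calibration checks.
    """
    base = SimulationConfig(
        causal_effect_sd=0.0,
        age_effect=0.0,
        sex_effect=0.0,
        smoking_effect=0.0,
        bmi_effect=0.0,
        alcohol_effect=0.0,
        deprivation_effect=0.0,
        cognitive_effect=0.0,
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class CellReference:
    """Mean beta methylomes for the six leukocyte reference types."""

    probe_ids: tuple[str, ...]
    cell_types: tuple[str, ...]
    means: np.ndarray  # probes × types, in [0, 1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.means, index=list(self.probe_ids), columns=list(self.cell_types)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CellReference":
        return cls(
            probe_ids=tuple(df.index.astype(str)),
            cell_types=tuple(df.columns.astype(str)),
            means=df.to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class TruthTable:
    """Ground truth recorded by the generator for parameter-recovery tests."""

    latent_chronic: pd.Series                  # per-sample, sample mean 0 / sd 1
    causal_probe_ids: tuple[str, ...]
    causal_effects: np.ndarray                 # logit-scale slopes on L
    smoking_probe_ids: tuple[str, ...]
    smoking_effects: np.ndarray                # logit-scale slopes on smoking z
    cell_proportions_true: pd.DataFrame        # samples × 6, rows sum to 1
    reference_used: CellReference


@dataclass(frozen=True)
class SyntheticCohort:
    beta: BetaMatrix
    phenotypes: pd.DataFrame
    truth: TruthTable

    @property
    def detection_p(self) -> pd.DataFrame | None:
        return self.beta.detection_p


def simulate_cell_reference(n_ref_probes: int, seed: int) -> CellReference:
    """Six well-separated leukocyte mean methylomes on ``n_ref_probes`` probes.

    Per probe the six types receive a random permutation of six evenly spaced
    beta levels (0.08 … 0.92) plus small jitter, guaranteeing a pairwise mean
    absolute difference of at least 0.1 between any two reference columns.
    """
    if n_ref_probes < 6:
        raise ConfigurationError("n_ref_probes must be ≥ 6")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xCE11]))
    perms = rng.permuted(
        np.broadcast_to(_REF_LEVELS, (n_ref_probes, 6)).copy(), axis=1
    )
    jitter = rng.normal(0.0, _REF_JITTER_SD, size=perms.shape)
    means = np.clip(perms + jitter, 0.01, 0.99)
    probe_ids = tuple(f"cgREF{i:05d}" for i in range(n_ref_probes))
    return CellReference(probe_ids=probe_ids, cell_types=CELL_TYPES, means=means)


def _standardize(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=0)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate one cohort (beta matrix, detection p-values, phenotypes, truth).

    See the module docstring for the generative model.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    c = config
    n, p = c.n_samples, c.n_probes

    arch_seed = c.seed if c.architecture_seed is None else c.architecture_seed
    sample_names = (
        "pheno", "latent", "serum", "probe_noise", "cells", "detection", "batch",
    )
    arch_names = ("assign", "baseline", "effects")
    streams = {
        name: np.random.default_rng(child)
        for name, child in zip(
            sample_names, np.random.SeedSequence(int(c.seed)).spawn(len(sample_names))
        )
    }
    streams.update(
        {
            name: np.random.default_rng(child)
            for name, child in zip(
                arch_names,
                np.random.SeedSequence([int(arch_seed), 0xA2C4]).spawn(
                    len(arch_names)
                ),
            )
        }
    )

    # ---- demographics and smoking -------------------------------------------
    rp = streams["pheno"]
    age = rp.uniform(*c.age_range, size=n)
    sex = rp.binomial(1, 0.5, size=n)  # female=0, male=1
    smoking = rp.choice(len(SMOKING_LEVELS), size=n, p=_SMOKING_PROBS)

    # ---- latent chronic trait L (sample mean 0, sd 1) ------------------------
    rl = streams["latent"]
    z_age = _standardize(age)
    z_smk = (smoking - smoking.mean()) / max(smoking.std(ddof=0), 1e-12)
    l_raw = (
        c.age_effect * z_age
        + c.sex_effect * (sex - sex.mean())
        + c.smoking_effect * z_smk
        + rl.normal(0.0, 1.0, size=n)
    )
    latent = _standardize(l_raw)

    # ---- serum biomarker: log-normal readout of L + acute occasion noise ----
    rs = streams["serum"]
    f = c.chronic_variance_fraction
    chronic_part = np.sqrt(f) * latent
    acute = rs.normal(0.0, np.sqrt(1.0 - f), size=n)
    log_serum = c.serum_log_mean + c.serum_log_sd * (chronic_part + acute)
    serum = np.exp(log_serum)

    # ---- correlated phenotypes ----------------------------------------------
    def correlated(effect: float, rng: np.random.Generator) -> np.ndarray:
        noise = rng.normal(0.0, 1.0, size=n)
        if abs(effect) >= 1.0:
            raise ConfigurationError("phenotype effects must have |r| < 1")
        return effect * latent + np.sqrt(1.0 - effect**2) * noise

    bmi = 26.9 + 5.0 * correlated(c.bmi_effect, rp)
    bmi = np.clip(bmi, 14.0, 60.0)
    alcohol_units = np.exp(2.0 + 0.9 * correlated(c.alcohol_effect, rp))
    alcohol_units = np.round(alcohol_units, 1)
    dep_latent = correlated(c.deprivation_effect, rp)
    # rank 1..n, higher rank = less deprived
    deprivation_rank = (np.argsort(np.argsort(dep_latent)) + 1).astype(int)

    g_latent = correlated(c.cognitive_effect, rp)
    loading = 0.7
    resid_sd = np.sqrt(1.0 - loading**2)
    tests = {
        "logical_memory": (30.8, 7.9),
        "digit_symbol": (70.7, 16.6),
        "verbal_fluency": (40.6, 11.7),
    }
    cognitive = {
        name: mu + sd * (loading * g_latent + rp.normal(0.0, resid_sd, size=n))
        for name, (mu, sd) in tests.items()
    }

    # ---- batch assignment (uneven sizes, every batch nonempty) --------------
    rb = streams["batch"]
    weights = np.linspace(0.8, 1.2, c.n_batches)
    probs = weights / weights.sum()
    batch = rb.choice(c.n_batches, size=n, p=probs)
    # guarantee nonempty batches by reassigning from the largest
    for b in range(c.n_batches):
        if not np.any(batch == b):
            counts = np.bincount(batch, minlength=c.n_batches)
            donor = int(np.argmax(counts))
            idx = int(np.nonzero(batch == donor)[0][0])
            batch[idx] = b
    batch_labels = np.array([f"batch{b + 1:02d}" for b in batch])

    # ---- probe role assignment ----------------------------------------------
    ra = streams["assign"]
    probe_ids = np.array([f"cg{i:08d}" for i in range(p)])
    roles = ra.permutation(p)
    causal_idx = np.sort(roles[: c.n_causal])
    smoking_idx = np.sort(roles[c.n_causal : c.n_causal + c.n_smoking_probes])
    ct_lo = c.n_causal + c.n_smoking_probes
    celltype_idx = np.sort(roles[ct_lo : ct_lo + c.n_celltype_probes])

    # ---- beta matrix ---------------------------------------------------------
    rbase = streams["baseline"]
    reff = streams["effects"]
    rnoise = streams["probe_noise"]
    baseline = rbase.uniform(0.15, 0.85, size=p)
    # trait-responsive probes live in their dynamic (mid-beta) range so a
    # logit-scale effect is not attenuated by the sigmoid's flat tails
    responsive = np.concatenate([causal_idx, smoking_idx]).astype(int)
    baseline[responsive] = rbase.uniform(0.3, 0.7, size=responsive.size)
    base_logit = logit(baseline)

    def draw_effects(k: int, rng: np.random.Generator) -> np.ndarray:
        # near-homogeneous magnitudes (±10%): the causal set represents one
        # tier of trait-associated CpGs, each individually detectable
        mag = c.causal_effect_sd * rng.uniform(0.9, 1.1, size=k)
        sign = rng.choice([-1.0, 1.0], size=k)
        return mag * sign

    causal_eff = draw_effects(c.n_causal, reff)
    smoking_eff = draw_effects(c.n_smoking_probes, reff)

    logit_beta = np.tile(base_logit[:, None], (1, n))
    logit_beta += rnoise.normal(0.0, c.probe_noise_sd, size=(p, n))
    if c.n_causal:
        logit_beta[causal_idx] += causal_eff[:, None] * latent[None, :]
    if c.n_smoking_probes:
        logit_beta[smoking_idx] += smoking_eff[:, None] * z_smk[None, :]

    # ---- cell-composition probes --------------------------------------------
    rc = streams["cells"]
    base_reference = simulate_cell_reference(max(c.n_celltype_probes, 6), arch_seed)
    props = rc.dirichlet(np.asarray(c.dirichlet_concentration, float), size=n)
    ref_means = base_reference.means[: c.n_celltype_probes]
    # relabel reference rows with the matrix ids of the cell-type probes so
    # downstream deconvolution can match them
    reference = CellReference(
        probe_ids=tuple(probe_ids[celltype_idx]),
        cell_types=CELL_TYPES,
        means=ref_means,
    )
    if c.n_celltype_probes:
        mixture = np.clip(ref_means @ props.T, 1e-4, 1 - 1e-4)  # probes × samples
        ct_noise = rc.normal(0.0, c.celltype_noise_sd, size=mixture.shape)
        logit_beta[celltype_idx] = logit(mixture) + ct_noise

    beta_values = expit(logit_beta)

    # ---- detection p-values --------------------------------------------------
    rd = streams["detection"]
    detection_p = rd.uniform(0.0, 0.005, size=(p, n))
    if c.detection_fail_rate > 0:
        fails = rd.random(size=(p, n)) < c.detection_fail_rate
        detection_p[fails] = rd.uniform(0.02, 1.0, size=int(fails.sum()))

    sample_ids = [f"S{i:05d}" for i in range(n)]
    beta_df = pd.DataFrame(beta_values, index=probe_ids, columns=sample_ids)
    dp_df = pd.DataFrame(detection_p, index=probe_ids, columns=sample_ids)
    batch_series = pd.Series(batch_labels, index=sample_ids, name="batch")
    beta = BetaMatrix(values=beta_df, detection_p=dp_df, batch=batch_series)

    pheno = pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "batch": batch_labels,
            "smoking": pd.Categorical.from_codes(
                smoking, categories=list(SMOKING_LEVELS), ordered=True
            ),
            "serum_biomarker": serum,
            "alcohol_units": alcohol_units,
            "bmi": bmi,
            "deprivation_rank": deprivation_rank,
            **cognitive,
        },
        index=sample_ids,
    )

    truth = TruthTable(
        latent_chronic=pd.Series(latent, index=sample_ids, name="latent_chronic"),
        causal_probe_ids=tuple(probe_ids[causal_idx]),
        causal_effects=causal_eff,
        smoking_probe_ids=tuple(probe_ids[smoking_idx]),
        smoking_effects=smoking_eff,
        cell_proportions_true=pd.DataFrame(
            props, index=sample_ids, columns=list(CELL_TYPES)
        ),
        reference_used=reference,
    )
    return SyntheticCohort(beta=beta, phenotypes=pheno, truth=truth)
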