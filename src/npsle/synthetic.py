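"""Synthetic cohorts with a latent disease severity driving both behavior and
gene expression.

Each animal carries a latent severity in [0, 1] (controls near 0, cases
spread over the upper range). Severity shifts the group mean of each
behavioral subtest by a per-subtest effect size (Gaussian measurement noise,
truncated to the subtest's physical range — e.g. water-maze latency is capped
at the 60 s search limit) and raises the log2 expression of a planted
signature-gene set in an overdispersed (gamma-Poisson, i.e. negative
binomial) count model. The planted signature genes are named ``sig###`` so
downstream recovery can be checked against ground truth.

The Y-maze is modeled at the level of individual arm entries: a mouse never
re-enters the arm it is currently in, so a uniformly random choice between
the two remaining arms yields 50% spontaneous alternation in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .expression import CountMatrix

__all__ = [
    "SyntheticConfig",
    "SubtestSpec",
    "SUBTEST_SPECS",
    "generate_cohort",
    "planted_signature",
    "simulate_ymaze",
    "percent_alternation",
    "ppi_percent",
]

ARMS = ("A", "B", "C")


@dataclass(frozen=True)
class SubtestSpec:
    """Generative parameters for one behavioral subtest.

    ``effect`` is the shift of the group mean per unit latent severity (its
    sign encodes the direction of the deficit); measurements are truncated to
    [lo, hi].
    """

    baseline: float
    effect: float
    noise_sd: float
    lo: float
    hi: float


#: Default per-subtest generative parameters. Baselines and deficit
#: directions follow the behavioral phenotype of lupus-prone mice: longer
#: water-maze escape latency (60 s cap), reduced freezing to context (cue
#: response intact), elevated %PPI at the 12 kHz prepulse (impaired
#: adaptation; 4 and 20 kHz intact), shorter rotarod time. Y-maze
#: alternation, zero-maze open time, open-field distance and gait symmetry
#: are included as null (unaffected) subtests.
SUBTEST_SPECS: dict[str, SubtestSpec] = {
    "mwm_latency_d2": SubtestSpec(35.0, 20.0, 8.0, 0.0, 60.0),
    "mwm_latency_d3": SubtestSpec(28.0, 24.0, 8.0, 0.0, 60.0),
    "mwm_latency_d4": SubtestSpec(22.0, 28.0, 8.0, 0.0, 60.0),
    "mwm_latency_d5": SubtestSpec(18.0, 30.0, 8.0, 0.0, 60.0),
    "fc_context": SubtestSpec(45.0, -25.0, 8.0, 0.0, 100.0),
    "fc_cue": SubtestSpec(40.0, 0.0, 8.0, 0.0, 100.0),
    "ppi_4khz": SubtestSpec(55.0, 0.0, 10.0, 0.0, 200.0),
    "ppi_12khz": SubtestSpec(50.0, 30.0, 10.0, 0.0, 200.0),
    "ppi_20khz": SubtestSpec(60.0, 0.0, 10.0, 0.0, 200.0),
    "rotarod_d4": SubtestSpec(150.0, -60.0, 20.0, 0.0, 300.0),
    "rotarod_d5": SubtestSpec(170.0, -60.0, 20.0, 0.0, 300.0),
    "ymaze_alternation": SubtestSpec(75.0, 0.0, 8.0, 0.0, 100.0),
    "zeromaze_pct_open": SubtestSpec(25.0, 0.0, 6.0, 0.0, 100.0),
    "openfield_distance": SubtestSpec(30.0, 0.0, 5.0, 0.0, 200.0),
    "gait_symmetry": SubtestSpec(1.0, 0.0, 0.05, 0.0, 2.0),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of a synthetic cohort.

    The defaults emulate one RNA-seq age cohort: four control and four case
    animals, 2000 genes with a planted 18-gene signature, ~1e6 counts per
    library (3'-tag scale) with negative-binomial dispersion 0.1, and a
    severity coupling of 1.5 log2-fold per unit severity on signature genes.
    """

    n_per_group: int = 4
    n_genes: int = 2000
    signature_size: int = 18
    library_size_mean: float = 1.0e6
    library_size_cv: float = 0.2
    dispersion: float = 0.1
    coupling: float = 1.5
    behavior_effects: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_genes < 1 or self.signature_size < 0:
            raise ValueError("n_genes must be >= 1 and signature_size >= 0")
        if self.signature_size > self.n_genes:
            raise ValueError("signature_size must not exceed n_genes")
        if self.library_size_mean <= 0:
            raise ValueError("library_size_mean must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        unknown = (set(self.behavior_effects) | set(self.noise_sd)) - set(
            SUBTEST_SPECS
        )
        if unknown:
            raise ValueError(f"unknown subtests: {sorted(unknown)}")

    def subtest_spec(self, name: str) -> SubtestSpec:
        spec = SUBTEST_SPECS[name]
        changes = {}
        if name in self.behavior_effects:
            changes["effect"] = self.behavior_effects[name]
        if name in self.noise_sd:
            changes["noise_sd"] = self.noise_sd[name]
        return replace(spec, **changes) if changes else spec


def planted_signature(config: SyntheticConfig) -> list[str]:
    """Names of the planted signature genes for this configuration."""
    return [f"sig{i + 1:03d}" for i in range(config.signature_size)]


def _gene_names(config: SyntheticConfig) -> list[str]:
    sig = planted_signature(config)
    rest = [f"g{i + 1:05d}" for i in range(config.n_genes - config.signature_size)]
    return sig + rest


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[pd.DataFrame, CountMatrix, pd.Series]:
    """Generate one cohort: behavior battery, count matrix, latent severity.

    Returns ``(battery, counts, severity)``: an animals x subtests behavior
    table with a ``group`` column, a CountMatrix with one expression sample
    per animal, and the ground-truth severity per animal. Identical config
    (including seed) yields identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    animals = [f"ctrl_{i + 1}" for i in range(n)] + [f"case_{i + 1}" for i in range(n)]
    groups = pd.Series(["control"] * n + ["case"] * n, index=animals, name="group")

    # latent severity: controls tightly near 0 (not exactly 0, to avoid
    # degenerate ties), cases spread over the upper range
    sev_ctrl = np.clip(np.abs(rng.normal(0.0, 0.05, size=n)), 0.0, 1.0)
    sev_case = rng.beta(5.0, 2.0, size=n)
    severity = pd.Series(
        np.concatenate([sev_ctrl, sev_case]), index=animals, name="severity"
    )

    battery = pd.DataFrame(index=pd.Index(animals, name="animal_id"))
    battery["group"] = groups
    for name in SUBTEST_SPECS:
        spec = config.subtest_spec(name)
        mean = spec.baseline + spec.effect * severity.to_numpy()
        vals = rng.normal(mean, spec.noise_sd)
        battery[name] = np.clip(vals, spec.lo, spec.hi)

    genes = _gene_names(config)
    # relative abundances: heavy-tailed log-normal, as in bulk RNA-seq
    abundance = rng.lognormal(0.0, 1.5, size=config.n_genes)
    abundance /= abundance.sum()
    sigma = np.sqrt(np.log1p(config.library_size_cv**2))
    libsizes = rng.lognormal(
        np.log(config.library_size_mean) - sigma**2 / 2, sigma, size=len(animals)
    )

    fold = np.ones((config.n_genes, len(animals)))
    fold[: config.signature_size, :] = np.power(
        2.0, config.coupling * severity.to_numpy()
    )
    mu = abundance[:, None] * libsizes[None, :] * fold
    # gamma-Poisson mixture: var = mu + dispersion * mu^2
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=genes, columns=animals)
    return battery, CountMatrix(counts_df, groups), severity


def simulate_ymaze(n_entries: int, policy: str, seed=None) -> list[str]:
    """Simulate a Y-maze arm-entry sequence under an alternation policy.

    The mouse never immediately re-enters its current arm, so each step
    offers two arms. ``always_alternate`` picks the arm not visited in the
    last two entries (100% alternation), ``never_alternate`` returns to the
    arm visited two entries earlier (0%), and ``uniform_random`` chooses
    uniformly between the two available arms (50% in expectation).
    """
    if n_entries < 3:
        raise ValueError("need >= 3 entries for alternation to be defined")
    if policy not in ("always_alternate", "never_alternate", "uniform_random"):
        raise ValueError(f"unknown policy {policy!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    first = ARMS[rng.integers(3)]
    second = [a for a in ARMS if a != first][rng.integers(2)]
    seq = [first, second]
    while len(seq) < n_entries:
        options = [a for a in ARMS if a != seq[-1]]
        if policy == "always_alternate":
            nxt = next(a for a in options if a != seq[-2])
        elif policy == "never_alternate":
            nxt = seq[-2]
        else:
            nxt = options[rng.integers(2)]
        seq.append(nxt)
    return seq


def percent_alternation(seq: list[str]) -> float:
    """Percent spontaneous alternation of an arm-entry sequence.

    100 x (number of 3-entry windows visiting three distinct arms) divided by
    the number of possible alternations (length - 2).
    """
    if len(seq) < 3:
        raise ValueError("need >= 3 entries to score alternation")
    wins = sum(
        1 for i in range(len(seq) - 2) if len(set(seq[i : i + 3])) == 3
    )
    return 100.0 * wins / (len(seq) - 2)


def ppi_percent(paired_amplitude: float, baseline_amplitude: float) -> float:
    """%PPI: prepulse+pulse startle amplitude over pulse-alone baseline x 100.

    Lower values mean stronger inhibition of the startle response by the
    prepulse; 100 means no inhibition at all.
    """
    if baseline_amplitude <= 0:
        raise ValueError("baseline amplitude must be positive")
    if paired_amplitude < 0:
        raise ValueError("paired amplitude must be non-negative")
    return paired_amplitude / baseline_amplitude * 100.0
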