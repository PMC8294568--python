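"""Synthetic study-cohort generator with ground truth.

Emulates the study's raw inputs so every pipeline stage has a
parameter-recovery test:

* per-donor linear SCFA accumulation C(t) = C0 + (phi_control +
  phi_fiber) t at timepoints {0, 2, 4} h, measured in two replicate
  wells;
* replicate scatter as a multiplicative log-normal factor per well that
  scales the well's whole trajectory — the model of biological-replicate
  variation being dominated by inoculum (slurry) density, which scales
  baseline and production together. Its sigma is solved so the replicate
  pair-CV statistic reported by the QC stage matches a target (default
  23.5%);
* latent MMP types as whole-profile fiber preferences: inulin responders
  (high rates in all inulin columns, low in pectin columns) vs pectin
  responders, with wide bounded (uniform) between-donor spread — some
  donors of the "low" type produce almost nothing from that fiber;
* cellulose generated with phi_fiber = 0 (indistinguishable from
  control);
* a second visit with rate persistence rho: visit-2 rates are
  rho * visit-1 + (1 - rho) * a fresh draw from the donor's type;
* an OTU table with log-normal relative abundances, producer OTUs whose
  log-abundance is shifted upward in donors whose linked fiber:SCFA rate
  is above the cohort median, multinomial counts at variable depth, and
  a configurable fraction of shallow (<5,000-read) samples.

All randomness flows from one root seed through named substreams so
stages can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from mmpkit.data_io import SCFAS, Condition, ScfaSeries

FIBER_CONDITIONS = (Condition.INULIN, Condition.PECTIN, Condition.CELLULOSE)
MMP_COLUMNS = tuple(
    f"{fiber}:{scfa}" for fiber in ("inulin", "pectin") for scfa in SCFAS
)

# cohort-average net production rates, mM/h (acetate-dominant, as in
# typical fecal fermentations)
BASE_RATES = {
    "inulin:acetate": 4.0,
    "inulin:propionate": 2.0,
    "inulin:butyrate": 1.0,
    "pectin:acetate": 3.0,
    "pectin:propionate": 1.6,
    "pectin:butyrate": 0.8,
}


@dataclass
class MmpTypeSpec:
    """One latent phenotype: mean rate per fiber:SCFA column (mM/h) and a
    relative between-donor half-width.

    A donor of this type draws rate = mean * Uniform(1 - spread,
    1 + spread) per column: bounded heterogeneity (between-donor sd =
    spread/sqrt(3) * mean) without extreme outliers.
    """

    name: str
    mean_rates: dict[str, float]
    donor_spread: float = 0.9


def default_type_specs(
    high: float = 1.8, low: float = 0.2, donor_spread: float = 0.9
) -> list[MmpTypeSpec]:
    """Two fiber-preference phenotypes.

    Inulin responders run at ``high`` x the cohort base rate in every
    inulin column and ``low`` x in pectin columns; pectin responders are
    the mirror image. With the defaults, type means are separated by
    roughly 2 pooled between-donor standard deviations per column.
    """
    t1 = {
        c: (high if c.startswith("inulin") else low) * BASE_RATES[c]
        for c in MMP_COLUMNS
    }
    t2 = {
        c: (low if c.startswith("inulin") else high) * BASE_RATES[c]
        for c in MMP_COLUMNS
    }
    return [
        MmpTypeSpec("inulin responder", t1, donor_spread),
        MmpTypeSpec("pectin responder", t2, donor_spread),
    ]


@dataclass
class OtuSpec:
    """OTU-table generation parameters."""

    n_otus: int = 60
    log_abundance_sd: float = 1.0
    # otu index -> (fiber:scfa column, effect size in sd of the producer
    # OTU's own log-abundance)
    producer_links: dict[int, tuple[str, float]] = field(
        default_factory=lambda: {0: ("inulin:propionate", 2.0)}
    )
    # producer OTUs are modelled as prevalent, low-dispersion core taxa
    # (a dominant-organism profile); otherwise the planted shift would be
    # washed out by log-normal dispersion after compositional closure
    producer_log_mean: float = 1.0
    producer_log_sd: float = 0.6
    mean_depth: int = 20000
    depth_sd: int = 5000
    shallow_fraction: float = 0.0
    shallow_depth: int = 2000


@dataclass
class CohortConfig:
    """Everything the generator needs; ``seed`` is mandatory."""

    seed: int
    n_donors: int = 40
    type_specs: list[MmpTypeSpec] = field(default_factory=default_type_specs)
    control_rate_mean: dict[str, float] = field(
        default_factory=lambda: {"acetate": 0.8, "propionate": 0.4, "butyrate": 0.3}
    )
    control_rate_rel_sd: float = 0.3
    baseline_mM: dict[str, float] = field(
        default_factory=lambda: {"acetate": 15.0, "propionate": 5.0, "butyrate": 3.0}
    )
    replicate_noise_cv: float = 23.5  # target pair-CV statistic, percent
    timepoints_h: tuple[float, ...] = (0.0, 2.0, 4.0)
    n_replicates: int = 2
    visit2_persistence: float = 0.9
    otu_spec: OtuSpec = field(default_factory=OtuSpec)

    def validate(self) -> None:
        problems = []
        if self.seed is None:
            problems.append("seed is mandatory")
        if self.n_donors < 2:
            problems.append("n_donors must be >= 2")
        if not 0.0 <= self.visit2_persistence <= 1.0:
            problems.append("visit2_persistence must be in [0, 1]")
        if self.replicate_noise_cv < 0:
            problems.append("replicate_noise_cv must be >= 0")
        if self.n_replicates < 1:
            problems.append("n_replicates must be >= 1")
        if not 0.0 <= self.otu_spec.shallow_fraction <= 1.0:
            problems.append("shallow_fraction must be in [0, 1]")
        for spec in self.type_specs:
            if any(v < 0 for v in spec.mean_rates.values()):
                problems.append(f"type {spec.name!r} has negative mean rates")
            if not 0.0 <= spec.donor_spread < 1.0:
                problems.append(f"type {spec.name!r} donor_spread must be in [0, 1)")
        if problems:
            raise ValueError("invalid config: " + "; ".join(problems))


@dataclass
class SyntheticTruth:
    """Planted ground truth aligned with the emitted tables by ID."""

    type_labels: pd.Series  # donor -> type name
    true_rates: dict[int, pd.DataFrame]  # visit -> donors x MMP_COLUMNS (net phi)
    control_rates: pd.DataFrame  # donors x SCFAs
    producer_links: dict[int, tuple[str, float]]
    shallow_samples: list[str]


@dataclass
class SyntheticCohort:
    """Generator output bundle."""

    series: dict[int, list[ScfaSeries]]  # visit -> series
    otu_counts: pd.DataFrame  # donors x OTU ids
    taxonomy: dict[str, str]
    truth: SyntheticTruth
    config: CohortConfig


def lognormal_sigma_for_pair_cv(target_cv_pct: float) -> float:
    """Log-normal sigma whose expected replicate pair-CV equals the target.

    The QC statistic is 100 * sd(n-1) / mean over a pair, i.e.
    100 * sqrt(2) * |x1 - x2| / (x1 + x2) = 100 * sqrt(2) *
    |tanh(sigma (z1 - z2) / 2)| for x_i = m * exp(sigma z_i). Writing
    (z1 - z2)/sqrt(2) = z ~ N(0,1), the expectation
    100 sqrt(2) E|tanh(sigma z / sqrt(2))| is evaluated by Gauss-Hermite
    quadrature and inverted with Brent's method. (The naive
    sqrt(ln(1 + cv^2)) would undershoot the reported statistic because a
    pair's sample sd underestimates the population sd.)
    """
    if target_cv_pct == 0:
        return 0.0
    nodes, weights = np.polynomial.hermite_e.hermegauss(201)
    w = weights / np.sqrt(2 * np.pi)

    def expected_cv(sigma: float) -> float:
        return 100.0 * np.sqrt(2.0) * float(
            np.sum(w * np.abs(np.tanh(sigma * nodes / np.sqrt(2.0))))
        )

    return float(brentq(lambda s: expected_cv(s) - float(target_cv_pct), 1e-6, 5.0))


def _substreams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate SCFA tables (two visits), an OTU table, and ground truth.

    Byte-reproducible per seed: the same config yields identical tables.
    """
    config.validate()
    rngs = _substreams(config.seed, ("rates", "noise", "otus", "depths", "types"))
    n = config.n_donors
    donors = [f"D{i + 1:02d}" for i in range(n)]

    # latent types, balanced assignment then shuffled
    n_types = len(config.type_specs)
    type_idx = np.array([i % n_types for i in range(n)])
    rngs["types"].shuffle(type_idx)
    type_labels = pd.Series(
        [config.type_specs[i].name for i in type_idx], index=donors, name="type"
    )

    def draw_rates(rng: np.random.Generator) -> pd.DataFrame:
        rows = np.empty((n, len(MMP_COLUMNS)))
        for i, ti in enumerate(type_idx):
            spec = config.type_specs[ti]
            mu = np.array([spec.mean_rates[c] for c in MMP_COLUMNS])
            factor = rng.uniform(
                1.0 - spec.donor_spread, 1.0 + spec.donor_spread, len(MMP_COLUMNS)
            )
            rows[i] = mu * factor
        return pd.DataFrame(rows, index=donors, columns=list(MMP_COLUMNS))

    rates_v1 = draw_rates(rngs["rates"])
    fresh = draw_rates(rngs["rates"])
    rho = config.visit2_persistence
    rates_v2 = rho * rates_v1 + (1 - rho) * fresh
    ctrl_mu = np.array([config.control_rate_mean[s] for s in SCFAS])
    control = pd.DataFrame(
        np.maximum(
            rngs["rates"].normal(
                ctrl_mu, config.control_rate_rel_sd * ctrl_mu, size=(n, len(SCFAS))
            ),
            0.0,
        ),
        index=donors,
        columns=list(SCFAS),
    )

    sigma = lognormal_sigma_for_pair_cv(config.replicate_noise_cv)
    noise_rng = rngs["noise"]

    def make_series(rates: pd.DataFrame) -> list[ScfaSeries]:
        out: list[ScfaSeries] = []
        for donor in donors:
            for cond in (Condition.CONTROL, *FIBER_CONDITIONS):
                # one well per replicate; its density factor scales every
                # SCFA at every timepoint measured from that well
                well_mult = (
                    np.exp(sigma * noise_rng.standard_normal(config.n_replicates))
                    if sigma > 0
                    else np.ones(config.n_replicates)
                )
                for scfa in SCFAS:
                    phi_c = control.loc[donor, scfa]
                    if cond in (Condition.CONTROL, Condition.CELLULOSE):
                        phi_f = 0.0  # cellulose is indistinguishable from control
                    else:
                        phi_f = rates.loc[donor, f"{cond.value}:{scfa}"]
                    c0 = config.baseline_mM[scfa]
                    for rep in range(1, config.n_replicates + 1):
                        m = well_mult[rep - 1]
                        conc = {
                            t: m * (c0 + (phi_c + phi_f) * t)
                            for t in config.timepoints_h
                        }
                        out.append(ScfaSeries(donor, cond, scfa, rep, conc))
        return out

    series = {1: make_series(rates_v1), 2: make_series(rates_v2)}

    # OTU table: one sample per donor (baseline stool)
    spec = config.otu_spec
    otu_rng = rngs["otus"]
    otu_ids = [f"OTU{i + 1:03d}" for i in range(spec.n_otus)]
    log_ab = otu_rng.normal(0.0, spec.log_abundance_sd, size=(n, spec.n_otus))
    for otu_i, (column, effect_sd) in spec.producer_links.items():
        log_ab[:, otu_i] = otu_rng.normal(
            spec.producer_log_mean, spec.producer_log_sd, size=n
        )
        # threshold at the cohort mean: matches the z >= 0 rule that
        # defines the high/low phenotype downstream
        high = rates_v1[column] > rates_v1[column].mean()
        log_ab[high.to_numpy(), otu_i] += effect_sd * spec.producer_log_sd
    rel = np.exp(log_ab)
    rel /= rel.sum(axis=1, keepdims=True)

    depth_rng = rngs["depths"]
    depths = np.maximum(
        depth_rng.normal(spec.mean_depth, spec.depth_sd, size=n), 6000
    ).astype(int)
    n_shallow = int(round(spec.shallow_fraction * n))
    shallow_idx = depth_rng.choice(n, size=n_shallow, replace=False)
    depths[shallow_idx] = spec.shallow_depth
    counts = np.stack(
        [depth_rng.multinomial(d, p) for d, p in zip(depths, rel)]
    )
    otu_counts = pd.DataFrame(counts, index=donors, columns=otu_ids)

    families = ["Lachnospiraceae", "Bacteroidaceae", "Prevotellaceae",
                "Ruminococcaceae", "Bifidobacteriaceae", "Akkermansiaceae"]
    taxonomy = {}
    for i, otu in enumerate(otu_ids):
        fam = families[i % len(families)]
        genus = f"Genus{i % 7}" if i % 5 else "unassigned"
        taxonomy[otu] = (
            f"Bacteria;Phylum{i % 4};Class{i % 4};Order{i % 5};{fam};{genus};unassigned"
        )

    truth = SyntheticTruth(
        type_labels=type_labels,
        true_rates={1: rates_v1, 2: rates_v2},
        control_rates=control,
        producer_links=dict(spec.producer_links),
        shallow_samples=[donors[i] for i in sorted(shallow_idx)],
    )
    return SyntheticCohort(
        series=series,
        otu_counts=otu_counts,
        taxonomy=taxonomy,
        truth=truth,
        config=config,
    )


def generate_worked_examples() -> dict[str, object]:
    """Small deterministic fixtures used across the test suite.

    No randomness: every object is constructed explicitly.
    """
    two_donor_rows = pd.DataFrame(
        {
            "sample_id": ["H-Inul-00", "H-Inul-02", "H-Inul-04",
                          "K-Inul-00", "K-Inul-02", "K-Inul-04"],
            "replicate": [1, 1, 1, 1, 1, 1],
            "acetate": [10.0, 14.0, 18.0, 10.0, 12.0, 14.0],
            "propionate": [5.0, 7.0, 9.0, 5.0, 6.0, 7.0],
            "butyrate": [2.0, 3.0, 4.0, 2.0, 2.5, 3.0],
        }
    )
    otu_3x5 = pd.DataFrame(
        [[5, 0, 3, 1, 1], [2, 2, 2, 2, 2], [0, 0, 0, 0, 10]],
        index=["S1", "S2", "S3"],
        columns=[f"OTU{i}" for i in range(1, 6)],
    )
    contingency = np.array([[3, 1], [1, 3]])
    two_block = pd.DataFrame(
        [[2.0, 0.0], [2.0, 0.0], [0.0, 2.0], [0.0, 2.0]],
        index=["A", "B", "C", "D"],
        columns=["inulin:propionate", "pectin:propionate"],
    )
    return {
        "two_donor_scfa_table": two_donor_rows,
        "otu_3x5": otu_3x5,
        "contingency_3113": contingency,
        "two_block_mmp": two_block,
    }
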