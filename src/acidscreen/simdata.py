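"""Synthetic data with the statistical structure of a pH-stress screen.

Emulates a pooled genome-wide knockout viability screen run at three
extracellular pH conditions (7.4 / 6.9 / 6.63, set by the bicarbonate/CO2
system), harvested at day 11 with a day-5 passage bottleneck, sequenced as
sgRNA counts; plus growth plates generated from known biphasic Hill curves
and medium pH / O2 photometry time courses. Everything is seeded and
byte-reproducible, so downstream scoring and fitting can be tested against
planted ground truth without any external downloads.

Generative model for the screen
-------------------------------
* T0 guide abundance is log-normally skewed around a per-guide
  representation (cells per guide), emulating uneven library infection.
* Each guide grows exponentially at rate
  ``base_rate(condition) * multiplier(class, condition) ** efficacy``,
  where efficacy in [0.6, 1] reflects mixed edited/unedited lentiviral
  pools, and the class multiplier encodes the planted phenotype
  (neutral, core-essential, acid-essential, acid-dispensable).
* At the passage day the population is bottlenecked by multinomial
  resampling of the reseeded cell number from current abundances.
* Sequencing counts are negative binomial around abundance-proportional
  means at the requested depth, with a gamma-Poisson overdispersion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import chemlab
from .acidfit import BiphasicParams, biphasic_growth
from .screenz import CountMatrix

CONDITIONS = (7.4, 6.9, 6.63)

CLASSES = ("neutral", "core_essential", "acid_essential", "acid_dispensable")

DEFAULT_CLASS_FRACTIONS = {
    "neutral": 0.80,
    "core_essential": 0.10,
    "acid_essential": 0.05,
    "acid_dispensable": 0.05,
}

# growth-rate multipliers per class and condition (unitless, applied to the
# condition's base exponential rate): < 1 = knockout disadvantageous there
DEFAULT_FITNESS_EFFECT = {
    "neutral": {7.4: 1.0, 6.9: 1.0, 6.63: 1.0},
    "core_essential": {7.4: 0.5, 6.9: 0.5, 6.63: 0.5},
    "acid_essential": {7.4: 1.0, 6.9: 0.85, 6.63: 0.7},
    "acid_dispensable": {7.4: 1.0, 6.9: 1.15, 6.63: 1.3},
}

# base exponential growth rate per condition (1/day); acid slows growth
DEFAULT_BASE_RATE = {7.4: 0.69, 6.9: 0.48, 6.63: 0.35}


@dataclass
class ScreenSimConfig:
    """Design and noise parameters of the simulated screen."""

    n_genes: int = 2000
    guides_per_gene: int = 4
    class_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS))
    fitness_effect: dict = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_FITNESS_EFFECT.items()})
    base_rate: dict = field(default_factory=lambda: dict(DEFAULT_BASE_RATE))
    conditions: tuple = CONDITIONS
    n_replicates: int = 2
    representation: float = 675.0      # cells per guide at T0
    moi: float = 0.3                   # infection multiplicity (bookkeeping)
    days: float = 11.0
    passage_day: float = 5.0
    reseed_cells: float = 3e6
    depth: float = 500.0               # mean reads per guide
    dispersion: float = 0.1            # NB: var = mu + dispersion * mu^2
    library_skew_sd: float = 0.5       # log-scale SD of T0 guide abundance
    guide_efficacy_range: tuple = (0.6, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.guides_per_gene <= 0:
            raise ValueError("n_genes and guides_per_gene must be positive")
        if self.depth <= 0 or self.representation <= 0 or self.reseed_cells <= 0:
            raise ValueError("depth, representation and reseed_cells must be "
                             "positive")
        if self.dispersion < 0 or self.library_skew_sd < 0:
            raise ValueError("dispersion and library_skew_sd must be >= 0")
        if not np.isclose(sum(self.class_fractions.values()), 1.0):
            raise ValueError("class_fractions must sum to 1")
        lo, hi = self.guide_efficacy_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("guide_efficacy_range must lie within [0, 1]")
        if not 0 < self.passage_day < self.days:
            raise ValueError("passage_day must lie inside (0, days)")
        for cls in self.class_fractions:
            if cls not in self.fitness_effect:
                raise ValueError(f"no fitness_effect for class {cls!r}")


def _assign_classes(cfg: ScreenSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Exact class counts from the fractions (largest remainders), shuffled."""
    classes = [c for c in CLASSES if c in cfg.class_fractions]
    raw = np.array([cfg.class_fractions[c] * cfg.n_genes for c in classes])
    counts = np.floor(raw).astype(int)
    rem = cfg.n_genes - counts.sum()
    for i in np.argsort(-(raw - np.floor(raw)))[:rem]:
        counts[i] += 1
    labels = np.repeat(classes, counts)
    return rng.permutation(labels)


def _nb_counts(mean: np.ndarray, dispersion: float,
               rng: np.random.Generator) -> np.ndarray:
    """Negative binomial (gamma-Poisson) counts; Poisson when dispersion=0."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def expected_final_abundance(cfg: ScreenSimConfig, class_labels: np.ndarray,
                             efficacy: np.ndarray, condition: float) -> np.ndarray:
    """Closed-form per-guide expected relative abundance at harvest.

    Deterministic exponential growth with no bottleneck or sequencing
    sampling — the analytic expectation downstream directionality can be
    checked against.
    """
    mult = np.array([cfg.fitness_effect[c][condition] for c in class_labels])
    mult = np.repeat(mult, cfg.guides_per_gene)
    rate = cfg.base_rate[condition] * mult ** efficacy
    a = np.exp(rate * cfg.days)
    return a / a.sum()


def simulate_screen(cfg: ScreenSimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate a three-condition, two-replicate screen.

    Returns the count matrix (samples T0_r<i> and
    T11_ph<cond>_r<i>) and the ground truth table (gene, class, per-condition
    multiplier) needed to bench scoring recall and FDR.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rng_global, *rng_reps = [np.random.default_rng(s)
                             for s in ss.spawn(1 + cfg.n_replicates)]

    n_guides = cfg.n_genes * cfg.guides_per_gene
    gene_ids = np.array([f"g{i:05d}" for i in range(cfg.n_genes)])
    guide_ids = np.array([f"g{i:05d}_sg{j}" for i in range(cfg.n_genes)
                          for j in range(cfg.guides_per_gene)])
    gene_of_guide = np.repeat(gene_ids, cfg.guides_per_gene)

    class_labels = _assign_classes(cfg, rng_global)
    lo, hi = cfg.guide_efficacy_range
    efficacy = rng_global.uniform(lo, hi, size=n_guides)
    guide_mult = {
        cond: np.repeat(
            np.array([cfg.fitness_effect[c][cond] for c in class_labels]),
            cfg.guides_per_gene)
        for cond in cfg.conditions}

    total_reads = cfg.depth * n_guides
    columns: dict[str, np.ndarray] = {}
    for rep, rng in enumerate(rng_reps, start=1):
        # infected pool: log-normal library skew around the representation
        skew = rng.lognormal(0.0, cfg.library_skew_sd, size=n_guides) \
            if cfg.library_skew_sd > 0 else np.ones(n_guides)
        a0 = cfg.representation * skew
        columns[f"T0_r{rep}"] = _nb_counts(a0 / a0.sum() * total_reads,
                                           cfg.dispersion, rng)
        for cond in cfg.conditions:
            rate = cfg.base_rate[cond] * guide_mult[cond] ** efficacy
            a5 = a0 * np.exp(rate * cfg.passage_day)
            # passage bottleneck: multinomial reseed from current pool
            reseed = int(cfg.reseed_cells)
            a5 = rng.multinomial(reseed, a5 / a5.sum()).astype(float)
            a11 = a5 * np.exp(rate * (cfg.days - cfg.passage_day))
            tot = a11.sum()
            if tot <= 0:
                raise RuntimeError("population went extinct in simulation")
            name = f"T11_ph{cond:g}_r{rep}"
            columns[name] = _nb_counts(a11 / tot * total_reads,
                                       cfg.dispersion, rng)

    counts = pd.DataFrame({"gene": gene_of_guide, **columns},
                          index=pd.Index(guide_ids, name="guide"))
    from .screenz import parse_sample_name
    meta = pd.DataFrame([parse_sample_name(s) for s in columns],
                        index=pd.Index(list(columns), name="sample"))
    truth = pd.DataFrame({"gene": gene_ids, "class_label": class_labels})
    for cond in cfg.conditions:
        truth[f"mult_ph{cond:g}"] = [cfg.fitness_effect[c][cond]
                                     for c in class_labels]
    truth = truth.set_index("gene")
    return CountMatrix(counts=counts, meta=meta), truth


def simulate_growth_plate(params_by_group: dict[str, BiphasicParams],
                          ph_levels, n_reps: int = 3,
                          noise_cv: float = 0.05, seed: int = 0,
                          batch: int = 1) -> pd.DataFrame:
    """Generate an SRB-style growth plate from known biphasic curves.

    absorbance = G(pHe) * (1 + e), with e zero-mean normal of standard
    deviation ``noise_cv`` (multiplicative noise, truncated at zero).
    """
    ph_levels = np.asarray(ph_levels, dtype=float)
    if ph_levels.size < 2:
        raise ValueError("need at least 2 pH levels")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    well = 0
    for group in sorted(params_by_group):
        params = params_by_group[group]
        for rep in range(1, n_reps + 1):
            g = biphasic_growth(ph_levels, params)
            noise = rng.normal(0.0, noise_cv, size=ph_levels.size) \
                if noise_cv > 0 else np.zeros(ph_levels.size)
            y = np.maximum(g * (1.0 + noise), 0.0)
            for ph, val in zip(ph_levels, y):
                rows.append({"well": f"W{well:03d}", "group": group,
                             "pHe": ph, "absorbance": val,
                             "replicate": rep, "batch": batch})
                well += 1
    return pd.DataFrame(rows)


def bicarb_ph_levels(hco3_mM=(2.75, 5.5, 11, 22, 33, 44),
                     co2_pct: float = 5.0) -> np.ndarray:
    """pHe levels of the iso-osmolar six-point bicarbonate series."""
    return np.array([chemlab.hh_pH(h, co2_pct) for h in hco3_mM])


@dataclass
class PhotometrySimConfig:
    """Medium acidification / O2 depletion time-course parameters.

    Glycolytic acid production is itself pH sensitive (product inhibition
    of glycolysis at low pHi, which tracks pHe), modeled as a Hill term
    rising with pH; O2 consumption is constant until O2 runs out.
    """

    ocr: float = 0.012                 # O2 consumption rate, mM/h
    max_glycolytic_flux: float = 1.5   # H+ production, mM/h
    glyc_ph_half: float = 7.0          # pH of half-maximal glycolytic flux
    glyc_ph_hill: float = 2.0          # steepness of the pH sensitivity
    hepes_mM: float = 10.0
    mes_mM: float = 10.0
    o2_init_mM: float = 0.2            # air-equilibrated dissolved O2
    duration_h: float = 17.0
    dt: float = 0.01                   # hours
    seed: int = 0

    def validate(self) -> None:
        if min(self.ocr, self.max_glycolytic_flux, self.o2_init_mM) < 0:
            raise ValueError("rates and initial O2 must be >= 0")
        if self.dt <= 0 or self.duration_h <= 0:
            raise ValueError("dt and duration must be positive")


def glycolytic_acid_flux(pH, cfg: PhotometrySimConfig):
    """H+ production rate (mM/h) at a given medium pH."""
    pH = np.asarray(pH, dtype=float)
    t = 10.0 ** (cfg.glyc_ph_hill * (cfg.glyc_ph_half - pH))
    J = cfg.max_glycolytic_flux / (1.0 + t)
    return J if J.ndim else float(J)


def simulate_phot_timecourse(cfg: PhotometrySimConfig,
                             start_pH: float) -> pd.DataFrame:
    """Forward-Euler trajectory of sealed-well medium pH and O2.

    dpH/dt = -J_H(pH) / beta(pH) with beta from the HEPES/MES buffering
    capacity (bicarbonate-free assay medium); dO2/dt = -OCR, floored at
    zero. Columns: time_h, pH, o2_mM.
    """
    cfg.validate()
    if not 5.5 <= start_pH <= 8.5:
        raise ValueError("start_pH must be within [5.5, 8.5]")
    n = int(round(cfg.duration_h / cfg.dt)) + 1
    t = np.arange(n) * cfg.dt
    pH = np.empty(n)
    o2 = np.empty(n)
    pH[0], o2[0] = start_pH, cfg.o2_init_mM
    for i in range(1, n):
        beta = chemlab.buffering_capacity(cfg.hepes_mM, cfg.mes_mM, 0.0,
                                          pH[i - 1])
        j = glycolytic_acid_flux(pH[i - 1], cfg)
        dph = -j / beta if beta > 0 else 0.0
        pH[i] = pH[i - 1] + dph * cfg.dt
        o2[i] = max(o2[i - 1] - cfg.ocr * cfg.dt, 0.0)
    return pd.DataFrame({"time_h": t, "pH": pH, "o2_mM": o2})
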