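"""Synthetic study generator for the in vivo evolution pipeline.

Emulates a two-genotype gnotobiotic cohort (wild-type and Il10-deficient
mice monocolonized with a single E. coli strain), population-sequencing
variant tables with background mutations plus one planted inflammation-linked
selective sweep, fecal inflammation-marker (lipocalin-2) time series,
group-divergent feature matrices (NMR metabolome / Biolog-style AUC panels),
and small stoichiometric toy models with known ground truth.  Every generated
dataset carries its planted truth so downstream recovery tests are
self-validating.

Determinism contract: identical ``SimulationConfig`` (including seed) yields
byte-identical outputs.  Each object draws from its own labelled stream
derived from the master seed, so enlarging the cohort never perturbs
previously generated mice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import ConfigError, stream
from .fba import MetabolicModel, Reaction
from .stats import FeatureMatrix

NUCLEOTIDES = ("A", "C", "G", "T")

#: Genomic coordinate of the planted sweep, mirroring the intergenic
#: C>T variant upstream of mprA that rose to fixation in inflamed mice.
SWEEP_POSITION = 3_009_211


@dataclass(frozen=True)
class Mouse:
    mouse_id: str
    genotype: str  # "WT" | "KO"
    inoculum_id: str
    experiment_id: str


@dataclass(frozen=True)
class CohortDesign:
    """Mouse -> genotype / inoculum / experiment assignment.

    Parallelism calls key on ``inoculum_id``: experiment 1 mice share one
    inoculum, experiment 2 mice each receive an independent one, so mutations
    standing in a shared inoculum cannot be mistaken for parallel evolution.
    """

    mice: tuple[Mouse, ...]

    def __post_init__(self) -> None:
        ids = [m.mouse_id for m in self.mice]
        if len(set(ids)) != len(ids):
            raise ConfigError("duplicate mouse_id in cohort")

    @property
    def mouse_ids(self) -> list[str]:
        return [m.mouse_id for m in self.mice]

    def genotype_of(self, mouse_id: str) -> str:
        return self._index()[mouse_id].genotype

    def inoculum_of(self, mouse_id: str) -> str:
        return self._index()[mouse_id].inoculum_id

    def _index(self) -> dict[str, Mouse]:
        return {m.mouse_id: m for m in self.mice}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(m.mouse_id, m.genotype, m.inoculum_id, m.experiment_id) for m in self.mice],
            columns=["mouse_id", "genotype", "inoculum_id", "experiment_id"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CohortDesign":
        mice = tuple(
            Mouse(r.mouse_id, r.genotype, r.inoculum_id, r.experiment_id)
            for r in frame.itertuples()
        )
        return cls(mice)


@dataclass(frozen=True)
class SweepSpec:
    """Logistic selective-sweep trajectory planted in target-genotype mice."""

    locus_id: str = "mprA_upstream"
    target_genotype: str = "KO"
    midpoint_week: float = 5.0
    rate: float = 1.0  # per-week logistic slope
    final_frequency: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.final_frequency <= 1.0:
            raise ConfigError("final_frequency must be in [0, 1]")
        if self.rate <= 0:
            raise ConfigError("sweep rate must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_wt: int = 14
    n_ko: int = 11
    timepoints: tuple[float, ...] = (1, 4, 8, 12)
    n_background_loci: int = 200
    # freq = detection_threshold + (1-threshold) * Beta(a, b): bounded,
    # unimodal, most mass below 0.3 so null loci never mimic sweeps
    background_beta: tuple[float, float] = (1.5, 10.0)
    # marginal probability that a background locus is detected in a given
    # mouse at each sampled week; calibrated to the observed de-novo medians
    # (~87 at week 1 falling to ~36 at week 12 out of 200 loci)
    background_presence: Mapping[float, float] = field(
        default_factory=lambda: {1: 0.435, 4: 0.17, 8: 0.225, 12: 0.18}
    )
    background_persistence: float = 0.4  # P(still detected at next sampling)
    n_standing_per_inoculum: int = 10
    sweep: SweepSpec = field(default_factory=SweepSpec)
    sweep_noise_sd: float = 0.05
    detection_threshold: float = 0.05
    inflammation_baseline: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 100.0, "KO": 100.0}
    )  # marker units (ng lipocalin-2 per g feces)
    inflammation_slope: Mapping[str, float] = field(
        default_factory=lambda: {"WT": 0.0, "KO": 800.0}
    )  # marker units per week
    inflammation_cv: float = 0.1
    # per-mouse severity couples the inflammation rise with sweep timing and
    # attained frequency: severe mice sweep earlier and closer to fixation
    severity_sd: float = 0.25

    def __post_init__(self) -> None:
        if list(self.timepoints) != sorted(set(self.timepoints)):
            raise ConfigError("timepoints must be strictly increasing")
        if not 0 < self.detection_threshold < 1:
            raise ConfigError("detection_threshold must be in (0, 1)")


@dataclass
class MutationTables:
    """Per-mouse variant tables plus per-inoculum standing-variant sets."""

    calls: pd.DataFrame  # mouse_id, week, locus_id, position, ref, alt, frequency
    inoculum_calls: pd.DataFrame  # inoculum_id, locus_id, position, ref, alt, frequency
    sweep: SweepSpec
    background_loci: list[str]

    def calls_for(self, mouse_id: str, week: float) -> pd.DataFrame:
        c = self.calls
        return c[(c.mouse_id == mouse_id) & (c.week == week)].reset_index(drop=True)

    def inoculum_set(self, inoculum_id: str) -> pd.DataFrame:
        c = self.inoculum_calls
        return c[c.inoculum_id == inoculum_id].reset_index(drop=True)

    def write_tsv(self, path: str | Path) -> None:
        self.calls.to_csv(path, sep="\t", index=False)


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def sweep_expected_frequency(spec: SweepSpec, week: float) -> float:
    """Noise-free planted sweep frequency at ``week``."""
    return float(spec.final_frequency * _logistic(spec.rate * (week - spec.midpoint_week)))


def severity_factor(config: SimulationConfig, mouse_id: str) -> float:
    """Per-mouse latent severity shared by the sweep and the marker series."""
    rng = stream(config.seed, "severity", mouse_id)
    return float(np.clip(rng.normal(1.0, config.severity_sd), 0.5, 1.5))


def generate_cohort(config: SimulationConfig) -> CohortDesign:
    """Build the two-experiment cohort.

    Experiment 1 mice share a single inoculum; experiment 2 mice each get an
    independent inoculum (the design that makes parallelism interpretable).
    """
    if config.n_wt < 1 or config.n_ko < 1:
        raise ConfigError("n_wt and n_ko must both be >= 1")
    mice: list[Mouse] = []
    for genotype, n in (("WT", config.n_wt), ("KO", config.n_ko)):
        n_exp1 = n // 2
        for i in range(n):
            mouse_id = f"{genotype}_{i + 1:02d}"
            if i < n_exp1:
                mice.append(Mouse(mouse_id, genotype, "I_exp1", "Exp1"))
            else:
                mice.append(Mouse(mouse_id, genotype, f"I_{mouse_id}", "Exp2"))
    return CohortDesign(tuple(mice))


def _locus_alleles(seed: int, locus_id: str) -> tuple[str, str]:
    rng = stream(seed, "alleles", locus_id)
    ref = NUCLEOTIDES[rng.integers(4)]
    alt = NUCLEOTIDES[(NUCLEOTIDES.index(ref) + 1 + rng.integers(3)) % 4]
    return ref, alt


def _background_appearance_probs(config: SimulationConfig) -> list[float]:
    """Per-interval appearance probabilities hitting the marginal presences."""
    persist = config.background_persistence
    probs = []
    prev = 0.0
    for week in config.timepoints:
        marginal = float(config.background_presence.get(week, 0.2))
        if prev == 0.0:
            appear = marginal
        else:
            appear = (marginal - persist * prev) / (1.0 - prev)
        probs.append(float(np.clip(appear, 0.0, 1.0)))
        prev = marginal
    return probs


def generate_mutation_tables(
    config: SimulationConfig, cohort: CohortDesign
) -> MutationTables:
    """Simulate per-mouse, per-week variant tables.

    The table for each mouse contains (i) its inoculum's ancestral standing
    variants, which de-novo filtering must subtract, (ii) genotype-independent
    background mutations detected on and off across weeks, and (iii) in
    target-genotype mice only, the planted sweep rising along a noisy logistic
    to ``final_frequency``.  Calls below the detection threshold are not
    written, mirroring a variant caller's reporting floor.
    """
    if len(config.timepoints) == 0:
        raise ConfigError("timepoints must be non-empty")
    background_loci = [f"bgl_{i:04d}" for i in range(config.n_background_loci)]
    if config.sweep.locus_id in background_loci:
        raise ConfigError("sweep locus must not be a background locus")
    positions = {locus: 10_000 + i * 1_000 for i, locus in enumerate(background_loci)}
    alleles = {locus: _locus_alleles(config.seed, locus) for locus in background_loci}
    appear = _background_appearance_probs(config)
    a, b = config.background_beta
    thr = config.detection_threshold

    inoculum_rows: list[tuple] = []
    inocula = sorted({m.inoculum_id for m in cohort.mice})
    standing: dict[str, pd.DataFrame] = {}
    for k, inoc in enumerate(inocula):
        rng = stream(config.seed, "inoculum", inoc)
        rows = []
        for j in range(config.n_standing_per_inoculum):
            locus = f"anc_{inoc}_{j:02d}"
            pos = 4_000_000 + (k * config.n_standing_per_inoculum + j) * 500
            ref, alt = _locus_alleles(config.seed, locus)
            freq = float(rng.uniform(0.1, 1.0))
            rows.append((inoc, locus, pos, ref, alt, round(freq, 6)))
        standing[inoc] = pd.DataFrame(
            rows, columns=["inoculum_id", "locus_id", "position", "ref", "alt", "frequency"]
        )
        inoculum_rows.extend(rows)

    call_rows: list[tuple] = []
    for mouse in cohort.mice:
        rng = stream(config.seed, "mutations", mouse.mouse_id)
        # ancestral standing variants persist in the evolving population
        anc = standing[mouse.inoculum_id]
        for week in config.timepoints:
            for r in anc.itertuples():
                freq = float(np.clip(r.frequency + rng.normal(0.0, 0.05), thr, 1.0))
                call_rows.append(
                    (mouse.mouse_id, week, r.locus_id, r.position, r.ref, r.alt, round(freq, 6))
                )
        # background de-novo mutations, independent of genotype
        for locus in background_loci:
            present = False
            for wi, week in enumerate(config.timepoints):
                p = config.background_persistence if present else appear[wi]
                present = bool(rng.random() < p)
                if present:
                    freq = float(thr + (1.0 - thr) * rng.beta(a, b))
                    ref, alt = alleles[locus]
                    call_rows.append(
                        (mouse.mouse_id, week, locus, positions[locus], ref, alt, round(freq, 6))
                    )
        # planted sweep in target-genotype mice only
        if mouse.genotype == config.sweep.target_genotype:
            sev = severity_factor(config, mouse.mouse_id)
            midpoint = config.sweep.midpoint_week / sev
            # severe mice reach fixation, milder ones plateau at intermediate
            # frequency (the observed 7/11 fixed vs 4/11 intermediate split)
            attained = float(np.clip(0.85 + 0.6 * (sev - 1.0), 0.0, 1.0))
            final = config.sweep.final_frequency * attained
            for week in config.timepoints:
                mean = final * float(_logistic(config.sweep.rate * (week - midpoint)))
                freq = float(np.clip(mean + rng.normal(0.0, config.sweep_noise_sd), 0.0, 1.0))
                if freq >= thr:
                    call_rows.append(
                        (
                            mouse.mouse_id,
                            week,
                            config.sweep.locus_id,
                            SWEEP_POSITION,
                            "C",
                            "T",
                            round(freq, 6),
                        )
                    )

    calls = pd.DataFrame(
        call_rows,
        columns=["mouse_id", "week", "locus_id", "position", "ref", "alt", "frequency"],
    )
    inoculum_calls = pd.DataFrame(
        inoculum_rows,
        columns=["inoculum_id", "locus_id", "position", "ref", "alt", "frequency"],
    )
    return MutationTables(calls, inoculum_calls, config.sweep, background_loci)


def generate_inflammation_series(
    config: SimulationConfig, cohort: CohortDesign
) -> pd.DataFrame:
    """Per-mouse lipocalin-2-per-gram time series.

    KO mice rise linearly with week (slope scaled by the mouse's severity
    factor); WT mice stay flat around baseline.  Values are nonnegative.
    """
    if len(config.timepoints) == 0:
        raise ConfigError("timepoints must be non-empty")
    rows = []
    for mouse in cohort.mice:
        rng = stream(config.seed, "inflammation", mouse.mouse_id)
        base = float(config.inflammation_baseline[mouse.genotype])
        slope = float(config.inflammation_slope[mouse.genotype])
        sev = severity_factor(config, mouse.mouse_id)
        for week in config.timepoints:
            mean = base + slope * sev * week
            value = float(max(0.0, mean * (1.0 + rng.normal(0.0, config.inflammation_cv))))
            rows.append((mouse.mouse_id, week, round(value, 4)))
    return pd.DataFrame(rows, columns=["mouse_id", "week", "marker_per_gram"])


def generate_feature_matrix(
    config: SimulationConfig,
    cohort: CohortDesign,
    n_features: int,
    n_shifted: int,
    effect_size: float,
    label: str = "metabolome",
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Samples x features abundance matrix with ``n_shifted`` planted group shifts.

    Exactly the first ``n_shifted`` features have their KO-group mean moved by
    ``effect_size`` (in units of the within-group standard deviation, which is
    1); shift direction is drawn per feature (~70% higher-in-KO, echoing the
    42-up / 17-down split seen in real fecal metabolomes of inflamed mice).
    Returns the matrix and the ground-truth table of shifted features.
    """
    if n_shifted > n_features:
        raise ConfigError("n_shifted must be <= n_features")
    if effect_size < 0:
        raise ConfigError("effect_size must be nonnegative")
    sample_ids = cohort.mouse_ids
    groups = pd.Series(
        [cohort.genotype_of(s) for s in sample_ids], index=sample_ids, name="group"
    )
    ko_mask = (groups == "KO").to_numpy()
    columns = {}
    truth_rows = []
    for j in range(n_features):
        feature = f"{label}_f{j:03d}"
        rng = stream(config.seed, label, "feature", j)
        mu = float(rng.uniform(4.0, 8.0))
        values = rng.normal(mu, 1.0, size=len(sample_ids))
        if j < n_shifted and effect_size > 0:
            sign = 1.0 if rng.random() < 0.7 else -1.0
            values[ko_mask] += sign * effect_size
            truth_rows.append(
                (feature, "higher-in-KO" if sign > 0 else "higher-in-WT", sign * effect_size)
            )
        columns[feature] = np.clip(values, 0.0, None)
    data = pd.DataFrame(columns, index=sample_ids)
    truth = pd.DataFrame(truth_rows, columns=["feature_id", "direction", "shift"])
    return FeatureMatrix(data, groups), truth


def generate_growth_curves(
    config: SimulationConfig,
    sample_ids: Sequence[str],
    condition_ids: Sequence[str],
    n_replicates: int = 3,
    t_max_h: float = 36.0,
    dt_h: float = 0.25,
) -> pd.DataFrame:
    """Long-format logistic plate-reader OD curves (15-min sampling, 36 h)."""
    times = np.arange(0.0, t_max_h + dt_h / 2, dt_h)
    rows = []
    for sample in sample_ids:
        for condition in condition_ids:
            rng = stream(config.seed, "growth", sample, condition)
            cap = float(rng.uniform(0.6, 1.2))
            rate = float(rng.uniform(0.3, 0.6))
            lag = float(rng.uniform(4.0, 10.0))
            for rep in range(1, n_replicates + 1):
                noise = rng.normal(0.0, 0.005, size=times.size)
                od = 0.02 + cap / (1.0 + np.exp(-rate * (times - lag))) + noise
                od = np.clip(od, 0.0, None)
                rows.extend(
                    (sample, condition, f"rep{rep}", float(t), float(round(o, 5)))
                    for t, o in zip(times, od)
                )
    return pd.DataFrame(rows, columns=["sample", "condition", "replicate", "time_h", "od"])


# ---------------------------------------------------------------------------
# toy stoichiometric models
# ---------------------------------------------------------------------------

TOY_MODEL_NAMES = ("linear_chain", "branched", "blocked_target", "currency_hub")


def generate_toy_model(spec_name: str) -> MetabolicModel:
    """Small stoichiometric models with documented ground truth.

    ``linear_chain``   A -> B -> C -> biomass; B and C producible from A.
    ``branched``       adds an oxygen-requiring branch B + o2 -> D, so D is
                       producible only when oxygen uptake is allowed.
    ``blocked_target`` linear chain plus a metabolite T with no producing
                       reaction (a taurine analog): never producible.
    ``currency_hub``   chain A-B-C-D plus a high-degree cofactor h touching
                       eight metabolites, exercising degree-sum weighting.
    """
    if spec_name == "linear_chain":
        model = MetabolicModel(
            metabolites=["A", "B", "C"],
            reactions=[
                Reaction("EX_A", {"A": -1}, -1000, 1000),
                Reaction("R_AB", {"A": -1, "B": 1}, 0, 1000),
                Reaction("R_BC", {"B": -1, "C": 1}, 0, 1000),
                Reaction("BIOMASS", {"C": -1}, 0, 1000),
            ],
            biomass="BIOMASS",
            exchanges={"A": "EX_A"},
            notes={
                "sources": ["A"],
                "producible": {"B": "all", "C": "all"},
                "non_producible": [],
            },
        )
    elif spec_name == "branched":
        model = MetabolicModel(
            metabolites=["A", "B", "C", "D", "o2"],
            reactions=[
                Reaction("EX_A", {"A": -1}, -1000, 1000),
                Reaction("EX_o2", {"o2": -1}, -1000, 1000),
                Reaction("R_AB", {"A": -1, "B": 1}, 0, 1000),
                Reaction("R_BC", {"B": -1, "C": 1}, 0, 1000),
                Reaction("R_BD", {"B": -1, "o2": -1, "D": 1}, 0, 1000),
                Reaction("BIOMASS", {"C": -1}, 0, 1000),
            ],
            biomass="BIOMASS",
            exchanges={"A": "EX_A", "o2": "EX_o2"},
            notes={
                "sources": ["A"],
                "producible": {"C": "all", "D": "oxygen_only"},
                "non_producible": [],
            },
        )
    elif spec_name == "blocked_target":
        model = MetabolicModel(
            metabolites=["A", "B", "C", "T"],
            reactions=[
                Reaction("EX_A", {"A": -1}, -1000, 1000),
                Reaction("R_AB", {"A": -1, "B": 1}, 0, 1000),
                Reaction("R_BC", {"B": -1, "C": 1}, 0, 1000),
                Reaction("R_TB", {"T": -1, "B": 1}, 0, 1000),  # T consumed, never made
                Reaction("BIOMASS", {"C": -1}, 0, 1000),
            ],
            biomass="BIOMASS",
            exchanges={"A": "EX_A"},
            notes={
                "sources": ["A"],
                "producible": {"B": "all", "C": "all"},
                "non_producible": ["T"],
            },
        )
    elif spec_name == "currency_hub":
        peripherals = [f"P{i}" for i in range(1, 7)]
        reactions = [
            Reaction("EX_A", {"A": -1}, -1000, 1000),
            Reaction("R_AB", {"A": -1, "B": 1}, 0, 1000),
            Reaction("R_BC", {"B": -1, "C": 1}, 0, 1000),
            Reaction("R_CD", {"C": -1, "D": 1}, 0, 1000),
            Reaction("R_AH", {"A": -1, "h": 1}, 0, 1000),
            Reaction("R_HD", {"h": -1, "D": 1}, 0, 1000),
            Reaction("BIOMASS", {"D": -1}, 0, 1000),
        ]
        for i, p in enumerate(peripherals, start=1):
            reactions.append(Reaction(f"R_HP{i}", {"h": -1, p: 1}, 0, 1000))
        model = MetabolicModel(
            metabolites=["A", "B", "C", "D", "h"] + peripherals,
            reactions=reactions,
            biomass="BIOMASS",
            exchanges={"A": "EX_A"},
            notes={
                "sources": ["A"],
                "producible": {"D": "all"},
                "non_producible": [],
                "cofactor": "h",
                "peripheral_pair": ["A", "D"],
            },
        )
    else:
        raise ConfigError(f"unknown toy model: {spec_name!r}")
    model.validate()
    return model


def write_fixtures(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Emit every synthetic fixture (TSV/CSV/JSON) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    cohort = generate_cohort(config)
    cohort.write_tsv(out / "cohort.tsv")
    paths["cohort"] = out / "cohort.tsv"
    tables = generate_mutation_tables(config, cohort)
    tables.write_tsv(out / "variants.tsv")
    tables.inoculum_calls.to_csv(out / "inoculum_variants.tsv", sep="\t", index=False)
    paths["variants"] = out / "variants.tsv"
    paths["inoculum_variants"] = out / "inoculum_variants.tsv"
    inflammation = generate_inflammation_series(config, cohort)
    inflammation.to_csv(out / "inflammation.tsv", sep="\t", index=False)
    paths["inflammation"] = out / "inflammation.tsv"
    metabolome, truth = generate_feature_matrix(config, cohort, 77, 59, 2.5, "metabolome")
    metabolome.data.to_csv(out / "metabolome.csv")
    truth.to_csv(out / "metabolome_truth.csv", index=False)
    paths["metabolome"] = out / "metabolome.csv"
    for name in TOY_MODEL_NAMES:
        model = generate_toy_model(name)
        model.save_json(out / f"model_{name}.json")
        paths[f"model_{name}"] = out / f"model_{name}.json"
    return paths
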