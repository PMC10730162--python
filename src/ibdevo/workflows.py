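"""End-to-end convenience workflows shared by the analysis scripts and tests.

These compose the module operations into the study's main computations:
de-novo filtering of a simulated cohort, recovery of the planted sweep
(parallelism + locus scan + marker correlation), and the toy-model
path-linkage and producibility screens.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import fba, metabnet, stats, synthetic_data, variants


def simulate_denovo_calls(
    config: synthetic_data.SimulationConfig,
) -> tuple[synthetic_data.CohortDesign, pd.DataFrame]:
    """Simulate the cohort and return inoculum-subtracted, thresholded calls."""
    cohort = synthetic_data.generate_cohort(config)
    tables = synthetic_data.generate_mutation_tables(config, cohort)
    cfg = variants.VariantFilterConfig(config.detection_threshold)
    parts = []
    for mouse in cohort.mice:
        sample = tables.calls[tables.calls.mouse_id == mouse.mouse_id]
        parts.append(
            variants.subtract_inoculum(sample, tables.inoculum_set(mouse.inoculum_id))
        )
    de_novo = variants.apply_frequency_threshold(
        pd.concat(parts, ignore_index=True), cfg
    )
    return cohort, de_novo


def sweep_trajectory(
    config: synthetic_data.SimulationConfig,
    cohort: synthetic_data.CohortDesign,
    de_novo: pd.DataFrame,
) -> pd.DataFrame:
    """Focal-locus frequency per (mouse, week), absent calls reported as 0."""
    focal = de_novo[de_novo.locus_id == config.sweep.locus_id][
        ["mouse_id", "week", "frequency"]
    ]
    full = pd.MultiIndex.from_product(
        [cohort.mouse_ids, config.timepoints], names=["mouse_id", "week"]
    ).to_frame(index=False)
    return full.merge(focal, on=["mouse_id", "week"], how="left").fillna(
        {"frequency": 0.0}
    )


@dataclass
class SweepRecovery:
    sweep_locus: str
    is_parallel: bool
    n_supporting_inocula: int
    significant_loci: list[str]
    rho: float
    rho_p: float


def recover_sweep(config: synthetic_data.SimulationConfig) -> SweepRecovery:
    """Run the full genetic arm on one simulated cohort.

    Returns whether the planted locus is called parallel, which loci pass the
    BH-corrected week-12 locus scan, and the pooled Spearman correlation of
    the focal trajectory with the inflammation marker in target-genotype mice.
    """
    cohort, de_novo = simulate_denovo_calls(config)
    parallel = {
        r.locus_id: r for r in variants.detect_parallel_loci(de_novo, cohort)
    }
    focal = parallel.get(config.sweep.locus_id)
    final_week = config.timepoints[-1]
    groups = pd.Series(
        {m.mouse_id: m.genotype for m in cohort.mice}, name="group"
    )
    matrix = variants.locus_frequency_matrix(
        de_novo[de_novo.week == final_week], cohort.mouse_ids, groups=groups
    )
    scan = stats.scan_to_frame(stats.feature_scan(matrix))
    significant = scan[scan.adjusted_p < 0.05].feature_id.tolist()
    trajectory = sweep_trajectory(config, cohort, de_novo)
    marker = synthetic_data.generate_inflammation_series(config, cohort)
    rho, rho_p = stats.trajectory_correlation(
        trajectory, marker, scope="KO-only", cohort=cohort
    )
    return SweepRecovery(
        sweep_locus=config.sweep.locus_id,
        is_parallel=bool(focal is not None and focal.is_parallel),
        n_supporting_inocula=0 if focal is None else len(focal.supporting_inocula),
        significant_loci=significant,
        rho=rho,
        rho_p=rho_p,
    )


def toy_screen(
    spec_name: str, cfg: fba.FvaConfig | None = None
) -> tuple[fba.MetabolicModel, list[fba.ScreenResult]]:
    """Producibility screen of every non-source metabolite of a toy model."""
    model = synthetic_data.generate_toy_model(spec_name)
    cfg = cfg or fba.FvaConfig()
    sources = model.notes["sources"]
    targets = [
        m for m in model.metabolites if m not in sources and m != cfg.oxygen_id
    ]
    return model, fba.production_screen(model, cfg, sources, targets)


def toy_linkage(
    spec_name: str, params: metabnet.PathParams = metabnet.PathParams()
) -> tuple[pd.DataFrame, list[str]]:
    """Cross-dataset shortest-path linkage on a toy model, sources = model
    sources, targets = every other metabolite."""
    model = synthetic_data.generate_toy_model(spec_name)
    graph = metabnet.model_to_graph(model)
    sources = model.notes["sources"]
    targets = [m for m in model.metabolites if m not in sources]
    psets = {s: metabnet.pathway_set(graph, s, params) for s in sources}
    return metabnet.select_cross_pairs(psets, sources, targets, params)
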