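"""Growth-curve and plate phenotyping arithmetic.

The trapezoidal area under an optical-density curve (OD.hours) serves as the
proxy for cumulative growth or metabolic activity; fecal measurements are
normalized per gram of feces; metatranscriptomic expression uses the RPKM
proxy.  Panel-wide condition comparisons delegate to the stats layer so the
AUC screen and the metabolome screen share one inferential path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ValidationError
from . import stats as _stats


@dataclass
class GrowthCurve:
    sample_id: str
    condition_id: str
    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray  # optical density, >= 0
    replicate_id: str = "rep1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.size != self.od.size:
            raise ValidationError("times and od must have equal length")


@dataclass
class NormalizedMeasure:
    mouse_id: str
    week: float
    raw_value: float
    feces_weight: float  # grams
    value_per_gram: float


def auc_trapezoid(curve: GrowthCurve, blank: float | None = None) -> float:
    """Trapezoidal integral of OD over the recorded window (OD.hours).

    Optional blank subtraction is applied before integration with negative
    values floored at zero.  No extrapolation beyond the recorded times.
    """
    if curve.times.size < 2:
        raise ValidationError("AUC needs >= 2 timepoints")
    if not np.all(np.diff(curve.times) > 0):
        raise ValidationError("times must be strictly increasing")
    od = curve.od
    if blank is not None:
        od = np.clip(od - blank, 0.0, None)
    return float(np.trapezoid(od, curve.times))


def replicate_mean_auc(curves: list[GrowthCurve], blank: float | None = None) -> pd.DataFrame:
    """Mean AUC per (sample, condition) across replicates, with the count."""
    rows = [
        (c.sample_id, c.condition_id, c.replicate_id, auc_trapezoid(c, blank)) for c in curves
    ]
    per_rep = pd.DataFrame(rows, columns=["sample", "condition", "replicate", "auc"])
    out = (
        per_rep.groupby(["sample", "condition"])["auc"]
        .agg(mean_auc="mean", n_replicates="size")
        .reset_index()
    )
    out["n_replicates"] = out["n_replicates"].astype(int)
    return out


def per_gram(
    mouse_id: str, week: float, raw_value: float, feces_weight: float
) -> NormalizedMeasure:
    """Normalize a fecal measurement (marker mass, CFU) to per-gram units."""
    if feces_weight <= 0:
        raise ValidationError("feces_weight must be positive")
    return NormalizedMeasure(mouse_id, week, raw_value, feces_weight, raw_value / feces_weight)


def rpkm(read_count: float, gene_length_bp: float, total_mapped_reads: float) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length_bp <= 0 or total_mapped_reads <= 0:
        raise ValidationError("gene length and library size must be positive")
    return float(read_count * 1e9 / (gene_length_bp * total_mapped_reads))


def read_plate_csv(
    path: str | Path,
    layout: str = "long",
    plate_map: pd.DataFrame | None = None,
    time_unit: str = "hours",
) -> list[GrowthCurve]:
    """Read plate-reader curves from a long or wide CSV.

    Long layout: columns (sample, condition, replicate, time_h, od).  Wide
    layout: a time column plus one column per well, with ``plate_map``
    mapping well -> (sample, condition, replicate); time in hours or minutes.
    """
    frame = pd.read_csv(path)
    scale = 1.0 if time_unit == "hours" else 1.0 / 60.0
    curves: list[GrowthCurve] = []
    if layout == "long":
        for (sample, condition, rep), sub in frame.groupby(
            ["sample", "condition", "replicate"], sort=True
        ):
            sub = sub.sort_values("time_h")
            curves.append(
                GrowthCurve(str(sample), str(condition), sub["time_h"].to_numpy() * scale,
                            sub["od"].to_numpy(), str(rep))
            )
    elif layout == "wide":
        if plate_map is None:
            raise ValidationError("wide layout needs a plate map")
        time_col = frame.columns[0]
        times = frame[time_col].to_numpy(dtype=float) * scale
        wells = plate_map.set_index("well")
        for well in frame.columns[1:]:
            if well not in wells.index:
                continue
            meta = wells.loc[well]
            curves.append(
                GrowthCurve(str(meta["sample"]), str(meta["condition"]), times,
                            frame[well].to_numpy(dtype=float), str(meta.get("replicate", "rep1")))
            )
    else:
        raise ValidationError(f"unknown layout {layout!r}")
    return curves


def condition_compare(
    auc_matrix: _stats.FeatureMatrix, test: str = "rank-sum"
) -> list[_stats.ScanResult]:
    """Panel-wide group comparison of per-condition AUCs.

    Delegates to :func:`ibdevo.stats.feature_scan` so the AUC panel and the
    metabolome share one inferential path; a condition with lower KO values
    is flagged ``higher-in-WT`` (e.g., a collateral antibiotic sensitivity of
    inflammation-adapted bacteria).
    """
    return _stats.feature_scan(auc_matrix, test=test)
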