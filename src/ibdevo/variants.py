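"""De-novo mutation filtering, parallelism calls, persistence, locus matrices.

A variant table holds one row per mutation observation (mouse, week, locus,
position, ref, alt, frequency).  De-novo calls are obtained by subtracting
the standing variants of the founding inoculum, keyed by (position, alt) so
that distinct alternate alleles at one position remain distinct mutations.
A locus is called *parallel* when it is mutated in at least two mice founded
from different inocula — mutations shared through a common inoculum are not
evidence of repeated evolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import ValidationError
from .stats import FeatureMatrix
from .synthetic_data import CohortDesign

VARIANT_COLUMNS = ["mouse_id", "week", "locus_id", "position", "ref", "alt", "frequency"]


@dataclass(frozen=True)
class VariantFilterConfig:
    min_frequency: float = 0.05
    inclusive: bool = True  # detection floor: frequency >= min_frequency

    def __post_init__(self) -> None:
        if not 0 < self.min_frequency < 1:
            raise ValidationError("min_frequency must be in (0, 1)")


@dataclass
class ParallelCall:
    locus_id: str
    supporting_mice: list[str]
    supporting_inocula: set[str]

    @property
    def is_parallel(self) -> bool:
        return len(self.supporting_inocula) >= 2


def validate_calls(calls: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in VARIANT_COLUMNS if c not in calls.columns]
    if missing:
        raise ValidationError(f"variant table missing columns: {missing}")
    freq = calls["frequency"].astype(float)
    bad = calls.index[(freq < 0) | (freq > 1) | freq.isna()]
    if len(bad):
        raise ValidationError(f"frequency outside [0, 1] at rows {list(bad[:5])}")
    if (calls["position"].astype(int) < 1).any():
        raise ValidationError("positions must be 1-based (>= 1)")
    dup = calls.duplicated(subset=["mouse_id", "week", "position", "alt"])
    if dup.any():
        raise ValidationError(
            f"duplicate (mouse, week, position, alt) rows: {list(calls.index[dup][:5])}"
        )
    return calls


def read_variant_table(path: str | Path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a variant table (TSV) or the SNP/INS/DEL subset of a GenomeDiff.

    The GenomeDiff subset keeps only mutation records carrying a
    ``frequency=`` attribute; locus labels come from ``gene_name=`` /
    ``locus=`` attributes when present, else the position.
    """
    path = Path(path)
    if dialect == "tsv":
        try:
            calls = pd.read_csv(path, sep="\t")
        except Exception as exc:  # noqa: BLE001 - reported with filename
            raise ValidationError(f"cannot parse {path}: {exc}") from exc
        return validate_calls(calls)
    if dialect != "genomediff-subset":
        raise ValidationError(f"unknown dialect {dialect!r}")
    rows = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        kind = fields[0]
        if kind not in {"SNP", "INS", "DEL"}:
            continue
        attrs = dict(
            f.split("=", 1) for f in fields if "=" in f and not f.startswith("http")
        )
        if "frequency" not in attrs:
            continue
        try:
            position = int(fields[4])
            alt = fields[5] if kind != "DEL" else "-"
            frequency = float(attrs["frequency"])
        except (IndexError, ValueError) as exc:
            raise ValidationError(f"malformed GenomeDiff line {lineno}: {line!r}") from exc
        locus = attrs.get("gene_name", attrs.get("locus", f"pos_{position}"))
        rows.append(
            (
                attrs.get("mouse_id", "sample"),
                float(attrs.get("week", 0)),
                locus,
                position,
                attrs.get("ref_base", "."),
                alt,
                frequency,
            )
        )
    return validate_calls(pd.DataFrame(rows, columns=VARIANT_COLUMNS))


def _key(calls: pd.DataFrame) -> pd.Series:
    return calls["position"].astype(int).astype(str) + ":" + calls["alt"].astype(str)


def subtract_inoculum(sample_calls: pd.DataFrame, inoculum_calls: pd.DataFrame) -> pd.DataFrame:
    """Remove calls whose (position, alt) key occurs in the inoculum set.

    The same position with a *different* alternate allele is retained:
    distinct alleles are distinct mutations.  Frequencies are untouched.
    Idempotent; never increases the call count.
    """
    if len(sample_calls) == 0 or len(inoculum_calls) == 0:
        return sample_calls.reset_index(drop=True)
    ancestral = set(_key(inoculum_calls))
    keep = ~_key(sample_calls).isin(ancestral)
    return sample_calls[keep].reset_index(drop=True)


def apply_frequency_threshold(
    calls: pd.DataFrame, cfg: VariantFilterConfig = VariantFilterConfig()
) -> pd.DataFrame:
    """Detection-floor filter: frequency >= (or > when strict) min_frequency."""
    if len(calls) == 0:
        return calls
    freq = calls["frequency"].astype(float)
    keep = freq >= cfg.min_frequency if cfg.inclusive else freq > cfg.min_frequency
    return calls[keep].reset_index(drop=True)


def count_de_novo(
    calls: pd.DataFrame, sampled: list[tuple[str, float]] | None = None
) -> pd.DataFrame:
    """De-novo mutation counts per (mouse, week); zero rows emitted for
    sampled mouse-weeks with no calls."""
    counts = (
        calls.groupby(["mouse_id", "week"]).size().rename("n_mutations").reset_index()
        if len(calls)
        else pd.DataFrame(columns=["mouse_id", "week", "n_mutations"])
    )
    if sampled:
        frame = pd.DataFrame(sampled, columns=["mouse_id", "week"])
        counts = frame.merge(counts, on=["mouse_id", "week"], how="left").fillna(
            {"n_mutations": 0}
        )
    counts["n_mutations"] = counts["n_mutations"].astype(int)
    return counts


def detect_parallel_loci(calls: pd.DataFrame, cohort: CohortDesign) -> list[ParallelCall]:
    """Per-locus parallelism: mutated in >= 2 mice gavaged with different inocula.

    Any qualifying call marks the locus as mutated in that mouse (locus-level
    collapsing over positions within a gene or intergenic region).
    """
    known = set(cohort.mouse_ids)
    unknown = set(calls["mouse_id"]) - known
    if unknown:
        raise ValidationError(f"mice absent from cohort: {sorted(unknown)}")
    results = []
    for locus, sub in calls.groupby("locus_id", sort=True):
        mice = sorted(set(sub["mouse_id"]))
        inocula = {cohort.inoculum_of(m) for m in mice}
        results.append(ParallelCall(str(locus), mice, inocula))
    return results


def parallel_to_frame(results: list[ParallelCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.locus_id, len(r.supporting_mice), len(r.supporting_inocula), r.is_parallel)
            for r in results
        ],
        columns=["locus_id", "n_mice", "n_inocula", "is_parallel"],
    )


def persistence_table(calls: pd.DataFrame, final_week: float) -> pd.DataFrame:
    """Per mouse: fraction of final-week mutations already present at each
    earlier sampled week, keyed by (position, alt).

    An empty final-week set yields an undefined fraction, flagged rather than
    silently reported as 0/0.
    """
    weeks = sorted(calls["week"].unique())
    if final_week not in weeks:
        raise ValidationError(f"final week {final_week} absent from calls")
    if len(weeks) < 2:
        raise ValidationError("persistence needs >= 2 sampled weeks")
    earlier = [w for w in weeks if w < final_week]
    rows = []
    for mouse, sub in calls.groupby("mouse_id", sort=True):
        final = set(_key(sub[sub["week"] == final_week]))
        for week in earlier:
            present = set(_key(sub[sub["week"] == week]))
            if final:
                fraction = len(final & present) / len(final)
                rows.append((mouse, week, len(final), fraction, False))
            else:
                rows.append((mouse, week, 0, np.nan, True))
    return pd.DataFrame(
        rows, columns=["mouse_id", "week", "n_final", "fraction_present", "undefined"]
    )


def locus_frequency_matrix(
    calls: pd.DataFrame,
    mice: list[str],
    loci: list[str] | None = None,
    groups: pd.Series | None = None,
) -> FeatureMatrix | pd.DataFrame:
    """Mice x loci matrix of frequencies (absent -> 0; multiple calls in one
    locus aggregated by maximum frequency)."""
    if loci is None:
        loci = sorted(calls["locus_id"].unique()) if len(calls) else []
    if len(calls):
        agg = calls.groupby(["mouse_id", "locus_id"])["frequency"].max().unstack(fill_value=0.0)
    else:
        agg = pd.DataFrame()
    matrix = agg.reindex(index=mice, columns=loci, fill_value=0.0).fillna(0.0)
    if groups is not None:
        return FeatureMatrix(matrix, groups.reindex(mice))
    return matrix
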