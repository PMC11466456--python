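"""Cohort-level descriptors: scoliosis-onset kinetics, penetrance and qPCR
relative expression by the comparative-Ct method.

Penetrance at a timepoint t is the percentage of fish whose recorded onset
week is <= t among the fish still under observation at t (fish last seen
before t — deaths, removals — leave the denominator from then on).

Relative expression follows 2^-ddCt: per sample, replicate Ct values are
averaged, dCt = mean Ct(target) - mean Ct(reference); when a control group is
given, ddCt = dCt - mean dCt(control group) and fold = 2^-ddCt, otherwise
fold = 2^-dCt.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "OnsetRecord",
    "PenetranceCurve",
    "CtMeasurement",
    "RelativeExpression",
    "penetrance_curve",
    "penetrance",
    "relative_expression",
    "load_onset_csv",
    "load_ct_csv",
]


@dataclass(frozen=True)
class OnsetRecord:
    """One fish's scoliosis-onset record.

    ``onset_week`` is None for fish that never curved within the observation
    window; ``last_observed_week`` is the last week the fish was seen.
    """

    fish_id: str
    group: str
    onset_week: float | None
    last_observed_week: float

    def __post_init__(self) -> None:
        if self.onset_week is not None and self.onset_week > self.last_observed_week:
            raise ValueError(
                f"{self.fish_id}: onset week {self.onset_week} after last "
                f"observation {self.last_observed_week}"
            )


@dataclass
class PenetranceCurve:
    """Cumulative percentage of scoliotic fish per timepoint for one group."""

    group: str
    timepoints: np.ndarray
    cumulative_percent: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, float)
        self.cumulative_percent = np.asarray(self.cumulative_percent, float)
        if np.any((self.cumulative_percent < 0) | (self.cumulative_percent > 100)):
            raise ValueError("cumulative percentages outside [0, 100]")


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR threshold-cycle measurement."""

    sample_id: str
    group: str
    gene: str
    ct: float
    replicate: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.ct) or self.ct <= 0:
            raise ValueError(f"invalid Ct {self.ct} for {self.sample_id}/{self.gene}")


@dataclass
class RelativeExpression:
    """Per-sample relative expression of one target gene."""

    sample_id: str
    group: str
    gene: str
    delta_ct: float
    fold_change: float
    method: str  # "ddct" or "dct"

    def __post_init__(self) -> None:
        if self.fold_change <= 0:
            raise ValueError("fold change must be positive")


def penetrance_curve(
    records: list[OnsetRecord], timepoints: list[float]
) -> dict[str, PenetranceCurve]:
    """Cumulative scoliosis penetrance per group at each timepoint.

    At timepoint t the numerator is the number of fish with onset_week <= t.
    The denominator adds the fish still straight and under observation at t
    (last_observed_week >= t).  Never-curved fish that left observation
    before t (deaths, removals) are censored from the denominator; fish with
    a recorded onset stay counted permanently, because scoliosis does not
    revert — this keeps every curve non-decreasing.
    """
    if not records:
        raise ValueError("empty onset table")
    tps = np.asarray(sorted(timepoints), float)
    if not np.array_equal(tps, np.asarray(timepoints, float)):
        raise ValueError("timepoints must be sorted ascending")
    out: dict[str, PenetranceCurve] = {}
    for group in sorted({r.group for r in records}):
        grp = [r for r in records if r.group == group]
        pct = []
        for t in tps:
            n_curved = sum(
                1 for r in grp if r.onset_week is not None and r.onset_week <= t
            )
            n_straight_at_risk = sum(
                1
                for r in grp
                if r.last_observed_week >= t
                and (r.onset_week is None or r.onset_week > t)
            )
            denom = n_curved + n_straight_at_risk
            if denom == 0:
                pct.append(pct[-1] if pct else 0.0)
                continue
            pct.append(100.0 * n_curved / denom)
        out[group] = PenetranceCurve(
            group=group,
            timepoints=tps,
            cumulative_percent=np.asarray(pct),
            n_total=len(grp),
        )
    return out


def penetrance(records: list[OnsetRecord], at_week: float) -> dict[str, float]:
    """Scalar penetrance (%) per group at a single timepoint."""
    curves = penetrance_curve(records, [at_week])
    return {g: float(c.cumulative_percent[0]) for g, c in curves.items()}


def relative_expression(
    cts: list[CtMeasurement],
    target_gene: str,
    reference_gene: str,
    control_group: str | None = None,
) -> list[RelativeExpression]:
    """Relative expression of ``target_gene`` against ``reference_gene``.

    Replicate Ct values are averaged arithmetically per (sample, gene).  With
    a control group the comparative 2^-ddCt method is used; without one the
    per-sample 2^-dCt value is returned.
    """
    df = pd.DataFrame(
        [(m.sample_id, m.group, m.gene, m.ct) for m in cts],
        columns=["sample_id", "group", "gene", "ct"],
    )
    mean_ct = df.groupby(["sample_id", "group", "gene"])["ct"].mean().reset_index()
    wide = mean_ct.pivot_table(
        index=["sample_id", "group"], columns="gene", values="ct"
    )
    for gene in (target_gene, reference_gene):
        if gene not in wide.columns:
            raise ValueError(f"gene {gene!r} absent from the Ct table")
    missing_ref = wide.index[wide[reference_gene].isna()].tolist()
    missing_tgt = wide.index[wide[target_gene].isna()].tolist()
    if missing_ref or missing_tgt:
        bad = ", ".join(s for s, _ in (missing_ref + missing_tgt))
        raise ValueError(f"samples missing target or reference Ct: {bad}")

    delta_ct = wide[target_gene] - wide[reference_gene]
    if control_group is not None:
        in_ctrl = delta_ct.index.get_level_values("group") == control_group
        if not in_ctrl.any():
            raise ValueError(f"control group {control_group!r} has no samples")
        baseline = float(delta_ct[in_ctrl].mean())
        ddct = delta_ct - baseline
        folds = np.power(2.0, -ddct)
        method = "ddct"
    else:
        folds = np.power(2.0, -delta_ct)
        method = "dct"

    return [
        RelativeExpression(
            sample_id=str(sample),
            group=str(group),
            gene=target_gene,
            delta_ct=float(delta_ct.loc[(sample, group)]),
            fold_change=float(folds.loc[(sample, group)]),
            method=method,
        )
        for sample, group in delta_ct.index
    ]


def load_onset_csv(path: str | Path) -> list[OnsetRecord]:
    """Read an onset table: fish_id, group, onset_week (blank = never), last_observed_week."""
    df = pd.read_csv(path)
    required = ["fish_id", "group", "onset_week", "last_observed_week"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        OnsetRecord(
            fish_id=str(r.fish_id),
            group=str(r.group),
            onset_week=None if pd.isna(r.onset_week) else float(r.onset_week),
            last_observed_week=float(r.last_observed_week),
        )
        for r in df.itertuples()
    ]


def load_ct_csv(path: str | Path) -> list[CtMeasurement]:
    """Read a Ct table: sample_id, group, gene, replicate, ct."""
    df = pd.read_csv(path)
    required = ["sample_id", "group", "gene", "replicate", "ct"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        CtMeasurement(
            sample_id=str(r.sample_id),
            group=str(r.group),
            gene=str(r.gene),
            ct=float(r.ct),
            replicate=int(r.replicate),
        )
        for r in df.itertuples()
    ]
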