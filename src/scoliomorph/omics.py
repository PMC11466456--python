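"""Differential-expression and proteome table filtering, overlap and export.

Operates downstream of a DESeq2-style results table (feature id, log2 fold
change, raw p, adjusted p).  The standard deregulation criterion used
throughout is *strict*: adjusted p < 0.05 and |log2FC| > 0.75; boundary rows
are excluded.  Rows whose selected p column is missing (NA from DESeq2's
independent filtering) are excluded from both the up and down sets — the
conservative reading — with a configurable fallback to the raw p column for
processed proteome tables whose adjusted column may be absent.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureStats",
    "FilterCriteria",
    "DEGSummary",
    "OverlapResult",
    "read_feature_table",
    "filter_deg",
    "overlap",
    "crossref_targets",
    "volcano_export",
]


@dataclass(frozen=True)
class FeatureStats:
    """Differential statistics for one gene or protein."""

    feature_id: str
    log2fc: float
    pvalue: float | None = None
    padj: float | None = None
    mean_expr: float | None = None

    def __post_init__(self) -> None:
        for name, p in (("pvalue", self.pvalue), ("padj", self.padj)):
            if p is not None and not (0.0 <= p <= 1.0):
                raise ValueError(f"{self.feature_id}: {name}={p} outside [0, 1]")


@dataclass(frozen=True)
class FilterCriteria:
    """Deregulation thresholds (strict inequalities)."""

    padj_max: float = 0.05
    lfc_min: float = 0.75
    p_column: str = "padj"  # or "pvalue"

    def __post_init__(self) -> None:
        if not 0.0 < self.padj_max < 1.0:
            raise ValueError("padj_max must lie in (0, 1)")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be non-negative")
        if self.p_column not in ("padj", "pvalue"):
            raise ValueError("p_column must be 'padj' or 'pvalue'")


@dataclass
class DEGSummary:
    """Outcome of applying a FilterCriteria to a feature table."""

    n_up: int
    n_down: int
    up_ids: set[str]
    down_ids: set[str]
    criteria: FilterCriteria
    n_input: int

    def to_dict(self) -> dict:
        return {
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_input": self.n_input,
            "criteria": {
                "padj_max": self.criteria.padj_max,
                "lfc_min": self.criteria.lfc_min,
                "p_column": self.criteria.p_column,
            },
        }


@dataclass
class OverlapResult:
    """Two-set Venn decomposition of identifier sets."""

    n_a_only: int
    n_b_only: int
    n_both: int
    shared_ids: set[str]


def _normalize_id(s: str, case_insensitive: bool = False) -> str:
    s = str(s).strip()
    return s.lower() if case_insensitive else s


def read_feature_table(
    path: str | Path,
    id_column: str = "gene_id",
    lfc_column: str = "log2FoldChange",
    p_columns: dict[str, str] | None = None,
    sep: str | None = None,
) -> list[FeatureStats]:
    """Read a DESeq2-style (or processed-proteome) table into FeatureStats.

    ``p_columns`` maps internal names to file columns, default
    {"pvalue": "pvalue", "padj": "padj"}.  Blank or non-numeric p cells
    become missing (None), never zero.  Duplicate feature ids are rejected.
    Separator is sniffed from the extension when not given (.tsv -> tab).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    p_columns = p_columns or {"pvalue": "pvalue", "padj": "padj"}
    df = pd.read_csv(path, sep=sep)
    needed = [id_column, lfc_column] + list(p_columns.values())
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ids = df[id_column].astype(str).str.strip()
    dup = ids[ids.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"{path}: duplicate feature ids: {dup[:10]}")

    def _opt(v) -> float | None:
        v = pd.to_numeric(v, errors="coerce")
        return None if pd.isna(v) else float(v)

    records = []
    for i, row in df.iterrows():
        records.append(
            FeatureStats(
                feature_id=str(row[id_column]).strip(),
                log2fc=float(row[lfc_column]),
                pvalue=_opt(row[p_columns["pvalue"]]),
                padj=_opt(row[p_columns["padj"]]),
            )
        )
    return records


def filter_deg(
    table: list[FeatureStats], criteria: FilterCriteria = FilterCriteria()
) -> DEGSummary:
    """Split a feature table into up/down-regulated sets under strict thresholds.

    up:   p < padj_max  and  log2fc > +lfc_min
    down: p < padj_max  and  log2fc < -lfc_min

    Rows whose selected p column is missing belong to neither set.
    """
    up: set[str] = set()
    down: set[str] = set()
    for f in table:
        p = f.padj if criteria.p_column == "padj" else f.pvalue
        if p is None or not (p < criteria.padj_max):
            continue
        if f.log2fc > criteria.lfc_min:
            up.add(f.feature_id)
        elif f.log2fc < -criteria.lfc_min:
            down.add(f.feature_id)
    return DEGSummary(
        n_up=len(up),
        n_down=len(down),
        up_ids=up,
        down_ids=down,
        criteria=criteria,
        n_input=len(table),
    )


def overlap(
    a: set[str], b: set[str], case_insensitive: bool = False
) -> OverlapResult:
    """Exact two-set overlap on normalised identifiers."""
    an = {_normalize_id(x, case_insensitive) for x in a}
    bn = {_normalize_id(x, case_insensitive) for x in b}
    shared = an & bn
    return OverlapResult(
        n_a_only=len(an - bn),
        n_b_only=len(bn - an),
        n_both=len(shared),
        shared_ids=shared,
    )


def crossref_targets(
    deg_ids: set[str],
    target_list: set[str],
    direct_subset: set[str] | None = None,
    case_insensitive: bool = False,
) -> tuple[int, int]:
    """Count deregulated features present in a curated target list.

    Returns (n_in_targets, n_in_direct) after identifier normalisation; the
    direct subset defaults to empty.  An empty target list yields zero counts
    with a warning.
    """
    if not target_list:
        logger.warning("empty target list; cross-reference counts are zero")
        return (0, 0)
    dn = {_normalize_id(x, case_insensitive) for x in deg_ids}
    tn = {_normalize_id(x, case_insensitive) for x in target_list}
    sn = {_normalize_id(x, case_insensitive) for x in (direct_subset or set())}
    in_targets = dn & tn
    return (len(in_targets), len(in_targets & sn))


def volcano_export(
    table: list[FeatureStats],
    criteria: FilterCriteria,
    out_path: str | Path,
    plot_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write per-feature volcano coordinates and classes to CSV.

    x = log2fc, y = -log10(p) on the criteria's p column; class in
    {up, down, ns} consistent with :func:`filter_deg`.  Zero p-values are
    clamped to the smallest positive float with a warning.  If ``plot_path``
    is given a matplotlib rendering is written as well.
    """
    summary = filter_deg(table, criteria)
    tiny = np.nextafter(0.0, 1.0)
    rows = []
    n_clamped = 0
    for f in table:
        p = f.padj if criteria.p_column == "padj" else f.pvalue
        if p is None:
            y = np.nan
        else:
            if p == 0.0:
                p = tiny
                n_clamped += 1
            y = -np.log10(p)
        if f.feature_id in summary.up_ids:
            cls = "up"
        elif f.feature_id in summary.down_ids:
            cls = "down"
        else:
            cls = "ns"
        rows.append((f.feature_id, f.log2fc, y, cls))
    if n_clamped:
        logger.warning("clamped %d zero p-values to the smallest float", n_clamped)
    df = pd.DataFrame(rows, columns=["feature_id", "log2fc", "neg_log10_p", "class"])
    df.to_csv(out_path, index=False)
    if plot_path is not None:
        _render_volcano(df, criteria, plot_path)
    return df


def _render_volcano(df: pd.DataFrame, criteria: FilterCriteria, plot_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"up": "crimson", "down": "royalblue", "ns": "0.7"}
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, sub in df.groupby("class"):
        ax.scatter(sub["log2fc"], sub["neg_log10_p"], s=6, c=colors[cls], label=cls)
    ax.axhline(-np.log10(criteria.padj_max), ls="--", lw=0.6, c="k")
    for x in (criteria.lfc_min, -criteria.lfc_min):
        ax.axvline(x, ls="--", lw=0.6, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel(f"-log10({criteria.p_column})")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(plot_path, dpi=150)
    plt.close(fig)
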