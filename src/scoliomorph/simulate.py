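"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its parameters plus a seed: parametric
midlines with an analytic curvature function, tube masks around known curves,
vertebral landmark-line pairs constructed by rotation so the true Cobb angles
are known exactly, embryo landmark tables with known deflection angles,
onset cohorts with a stated penetrance, qPCR Ct tables with a planted fold
change, and differential-expression tables with planted up/down features.

Defaults mirror the cohort sizes and effect magnitudes of the zebrafish
scoliosis study this package models: a 252-fish onset cohort with 90%
penetrance over a 4-11 weeks-post-fertilisation onset window, a ~3.5-fold
target-gene induction assayed in duplicate against a reference gene, trunk
and brain transcriptome tables with 614/75 and 60/1 planted up/down genes
sharing 54 upregulated genes, a curated target list hitting 106 of the trunk
up-set (77 direct), and a 5706-protein proteome with 127 up / 45 down.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.ndimage import distance_transform_edt

from .cohort import CtMeasurement, OnsetRecord
from .geometry import (
    CobbMeasurement,
    EmbryoLandmarks,
    LandmarkLine,
    Point2D,
    Polyline,
    View,
    cobb_angle,
    rose_bin,
)
from .midline import BinaryMask

__all__ = [
    "MidlineSpec",
    "PlantedDEGSpec",
    "gen_midline",
    "gen_fish_mask",
    "gen_vertebral_lines",
    "gen_embryo_cohort",
    "gen_deg_table",
    "gen_paired_deg_tables",
    "gen_target_lists",
    "gen_onset_cohort",
    "gen_ct_table",
    "gen_proteome_table",
]


@dataclass
class MidlineSpec:
    """Parametric midline: shape family plus geometry and jitter parameters.

    ``scoliotic`` superposes 1-3 sine modes with random phases; ``amplitude``
    is the severity knob shared by all modes.
    """

    shape: str = "sine"  # straight | arc | sine | scoliotic
    length: float = 40.0
    amplitude: float = 2.0
    wavelength: float = 20.0
    radius: float = 10.0
    sweep_deg: float = 90.0
    n_source_points: int = 1000
    noise_sd: float = 0.0
    n_modes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("straight", "arc", "sine", "scoliotic"):
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.length <= 0 or self.n_source_points < 10 or self.noise_sd < 0:
            raise ValueError("invalid midline spec")


@dataclass
class PlantedDEGSpec:
    """Specification of a feature table with planted up/down features."""

    n_features: int = 20000
    n_up: int = 614
    n_down: int = 75
    lfc_up_range: tuple[float, float] = (0.8, 5.0)
    lfc_null_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_up + self.n_down > self.n_features:
            raise ValueError("more planted features than table rows")


def _graph_curve(y: Callable, dy: Callable, d2y: Callable, length: float):
    """Curvature machinery for a curve given as a graph y(x), x in [0, L]."""

    def kappa(x):
        return d2y(x) / (1.0 + dy(x) ** 2) ** 1.5

    def total_abs_turning():
        # |kappa| ds = |y''| / (1 + y'^2) dx
        val, _ = quad(
            lambda x: abs(d2y(x)) / (1.0 + dy(x) ** 2), 0.0, length, limit=500
        )
        return val

    return kappa, total_abs_turning


def gen_midline(spec: MidlineSpec) -> tuple[Polyline, Callable, float]:
    """Sample a parametric midline and report its analytic curvature truth.

    Returns ``(polyline, true_kappa, true_arc_integral)`` where ``true_kappa``
    maps the x-coordinate (or arc parameter, for arcs) to signed curvature
    and ``true_arc_integral`` is the exact/quadrature value of the integral
    of |kappa| ds over the curve.  Coordinate jitter (``noise_sd``) is added
    after the truth is recorded.
    """
    rng = np.random.default_rng(spec.seed)
    if spec.shape == "straight":
        x = np.linspace(0.0, spec.length, spec.n_source_points)
        xy = np.column_stack([x, np.zeros_like(x)])
        kappa = lambda s: 0.0 * np.asarray(s)  # noqa: E731
        truth = 0.0
    elif spec.shape == "arc":
        sweep = np.radians(spec.sweep_deg)
        t = np.linspace(0.0, sweep, spec.n_source_points)
        xy = np.column_stack(
            [spec.radius * np.sin(t), spec.radius * (1.0 - np.cos(t))]
        )
        kappa = lambda s: np.full_like(np.asarray(s, float), 1.0 / spec.radius)  # noqa: E731
        truth = sweep  # R * sweep / R
    elif spec.shape == "sine":
        w = 2.0 * np.pi / spec.wavelength
        A = spec.amplitude
        y = lambda x: A * np.sin(w * x)  # noqa: E731
        dy = lambda x: A * w * np.cos(w * x)  # noqa: E731
        d2y = lambda x: -A * w**2 * np.sin(w * x)  # noqa: E731
        kappa, tat = _graph_curve(y, dy, d2y, spec.length)
        truth = tat() if A > 0 else 0.0
        x = np.linspace(0.0, spec.length, spec.n_source_points)
        xy = np.column_stack([x, y(x)])
    else:  # scoliotic: low-order sine modes with random phases
        n_modes = int(rng.integers(1, spec.n_modes + 1))
        ks = rng.integers(1, 4, size=n_modes)  # mode numbers
        phases = rng.uniform(0, 2 * np.pi, size=n_modes)
        amps = spec.amplitude * rng.uniform(0.5, 1.0, size=n_modes) / n_modes
        ws = 2.0 * np.pi * ks / spec.length

        y = lambda x: sum(a * np.sin(w * x + p) for a, w, p in zip(amps, ws, phases))  # noqa: E731
        dy = lambda x: sum(a * w * np.cos(w * x + p) for a, w, p in zip(amps, ws, phases))  # noqa: E731
        d2y = lambda x: sum(-a * w**2 * np.sin(w * x + p) for a, w, p in zip(amps, ws, phases))  # noqa: E731
        kappa, tat = _graph_curve(y, dy, d2y, spec.length)
        truth = tat() if spec.amplitude > 0 else 0.0
        x = np.linspace(0.0, spec.length, spec.n_source_points)
        xy = np.column_stack([x, y(x)])

    if spec.noise_sd > 0:
        xy = xy + rng.normal(0.0, spec.noise_sd, size=xy.shape)
    return Polyline.from_xy(xy, view=View.LATERAL, unit="sim"), kappa, float(truth)


def gen_fish_mask(
    midline: Polyline, half_width: float = 5.0, image_size: tuple[int, int] | None = None
) -> BinaryMask:
    """Rasterise a tube of ``half_width`` pixels around a midline curve.

    Foreground = pixels whose Euclidean distance to the (densely sampled)
    curve is at most ``half_width``, built with a distance transform.  The
    curve must fit inside the image with a margin of at least ``half_width``.
    """
    xy = midline.xy
    margin = int(np.ceil(half_width)) + 2
    if image_size is None:
        w = int(np.ceil(xy[:, 0].max() - xy[:, 0].min())) + 2 * margin
        h = int(np.ceil(xy[:, 1].max() - xy[:, 1].min())) + 2 * margin
        offset = np.array([xy[:, 0].min() - margin, xy[:, 1].min() - margin])
        xy = xy - offset
        image_size = (h, w)
    else:
        h, w = image_size
        if (
            xy[:, 0].min() < half_width
            or xy[:, 1].min() < half_width
            or xy[:, 0].max() > w - 1 - half_width
            or xy[:, 1].max() > h - 1 - half_width
        ):
            raise ValueError("curve does not fit in the image with the tube margin")
    # dense resampling so the rasterised curve is 8-connected
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    n_dense = max(2, int(np.ceil(seg.sum() / 0.5)))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0, s[-1], n_dense)
    dx = np.interp(t, s, xy[:, 0])
    dyv = np.interp(t, s, xy[:, 1])
    grid = np.ones(image_size, dtype=bool)
    rows = np.clip(np.round(image_size[0] - 1 - dyv).astype(int), 0, image_size[0] - 1)
    cols = np.clip(np.round(dx).astype(int), 0, image_size[1] - 1)
    grid[rows, cols] = False  # curve pixels are the EDT zeros
    dist = distance_transform_edt(grid)
    return BinaryMask(pixels=dist <= half_width, scale=1.0)


def gen_vertebral_lines(
    true_angles: list[float], seed: int = 0, view: View = View.LATERAL
) -> list[CobbMeasurement]:
    """Landmark-line pairs whose Cobb angles equal ``true_angles`` exactly.

    For each angle theta, a randomly oriented base line is emitted together
    with a copy rotated by theta and randomly translated, so
    ``total_cobb`` over the output equals ``sum(true_angles)``.
    """
    rng = np.random.default_rng(seed)
    out: list[CobbMeasurement] = []
    for theta in true_angles:
        if not 0.0 <= theta <= 90.0:
            raise ValueError(f"Cobb angle {theta} outside [0, 90]")
        # keep theta acute w.r.t. the base orientation regardless of phi
        phi = rng.uniform(0, 2 * np.pi)
        d1 = np.array([np.cos(phi), np.sin(phi)])
        rot = np.radians(theta)
        d2 = np.array(
            [
                np.cos(phi) * np.cos(rot) - np.sin(phi) * np.sin(rot),
                np.sin(phi) * np.cos(rot) + np.cos(phi) * np.sin(rot),
            ]
        )
        o1 = rng.uniform(-50, 50, size=2)
        o2 = rng.uniform(-50, 50, size=2)
        top = LandmarkLine(
            Point2D(*o1), Point2D(*(o1 + 10 * d1)), label="top vertebra"
        )
        bottom = LandmarkLine(
            Point2D(*o2), Point2D(*(o2 + 10 * d2)), label="bottom vertebra"
        )
        out.append(
            CobbMeasurement(
                line_top=top,
                line_bottom=bottom,
                angle=cobb_angle(top, bottom),
                view=view,
            )
        )
    return out


def gen_embryo_cohort(
    n: int,
    mean_deg: float = 0.0,
    kappa_conc: float = 20.0,
    seed: int = 0,
    angles: list[float] | None = None,
) -> tuple[pd.DataFrame, list[EmbryoLandmarks], np.ndarray]:
    """Embryo landmark table with known deflection angles and rose counts.

    Angles are drawn from a von Mises distribution centred at ``mean_deg``
    (concentration ``kappa_conc``), or taken verbatim from ``angles``.
    Returns (landmark table, landmark objects, true 30-degree rose counts);
    the rose counts are the generator's own bookkeeping of the drawn angles.
    """
    rng = np.random.default_rng(seed)
    if angles is not None:
        theta = np.asarray(angles, float) % 360.0
    else:
        theta = np.degrees(rng.vonmises(np.radians(mean_deg), kappa_conc, size=n)) % 360.0
    rows, lms = [], []
    for i, a in enumerate(theta):
        eye = Point2D(0.0, 0.0)
        yolk = Point2D(1.0, 0.0)
        rad = np.radians(a)
        tail = Point2D(1.0 + np.cos(rad), np.sin(rad))
        lm = EmbryoLandmarks(eye, yolk, tail, embryo_id=f"emb{i:04d}")
        lms.append(lm)
        rows.append((lm.embryo_id, eye.x, eye.y, yolk.x, yolk.y, tail.x, tail.y))
    df = pd.DataFrame(
        rows, columns=["embryo_id", "eye_x", "eye_y", "yolk_x", "yolk_y", "tail_x", "tail_y"]
    )
    true_counts = rose_bin(theta).counts
    return df, lms, true_counts


def _planted_table(
    spec: PlantedDEGSpec, rng: np.random.Generator, prefix: str, up_ids=None
) -> tuple[pd.DataFrame, set[str], set[str]]:
    n_null = spec.n_features - spec.n_up - spec.n_down
    ids = [f"{prefix}{i:05d}" for i in range(spec.n_features)]
    if up_ids is not None:
        if len(up_ids) > spec.n_up:
            raise ValueError("forced up ids exceed n_up")
        ids[: len(up_ids)] = list(up_ids)
    lo, hi = spec.lfc_up_range
    lfc_up = rng.uniform(lo, hi, spec.n_up)
    lfc_down = -rng.uniform(lo, hi, spec.n_down)
    p_sig = rng.uniform(1e-12, 0.049, spec.n_up + spec.n_down)
    # nulls fail at least one criterion by construction: either small effect
    # with any p, or non-significant p with any effect
    small = rng.random(n_null) < 0.7
    lfc_null = np.where(
        small,
        rng.normal(0.0, spec.lfc_null_sd, n_null).clip(-0.74, 0.74),
        rng.uniform(0.8, 3.0, n_null) * rng.choice([-1, 1], n_null),
    )
    p_null = np.where(small, rng.uniform(0, 1, n_null), rng.uniform(0.051, 1.0, n_null))
    lfc = np.concatenate([lfc_up, lfc_down, lfc_null])
    padj = np.concatenate([p_sig, p_null])
    pval = padj * rng.uniform(0.1, 1.0, spec.n_features)  # raw p <= adjusted p
    # a realistic sprinkle of NA adjusted p among the nulls (independent filtering)
    na_mask = np.zeros(spec.n_features, bool)
    null_slice = np.arange(spec.n_up + spec.n_down, spec.n_features)
    na_mask[rng.choice(null_slice, size=n_null // 10, replace=False)] = True
    padj_col = padj.astype(object)
    padj_col[na_mask] = np.nan
    df = pd.DataFrame(
        {
            "gene_id": ids,
            "log2FoldChange": lfc,
            "pvalue": pval,
            "padj": padj_col.astype(float),
        }
    )
    df = df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
    up = set(ids[: spec.n_up])
    down = set(ids[spec.n_up : spec.n_up + spec.n_down])
    return df, up, down


def gen_deg_table(spec: PlantedDEGSpec) -> tuple[pd.DataFrame, set[str], set[str]]:
    """A DESeq2-style table with planted up/down features.

    Planted up features get log2FC > 0.75 and padj < 0.05, planted down the
    mirror image; null features fail at least one criterion by construction,
    so the standard strict filter recovers the planted sets exactly.
    Returns (table, true_up_ids, true_down_ids).
    """
    rng = np.random.default_rng(spec.seed)
    return _planted_table(spec, rng, prefix="gene")


def gen_paired_deg_tables(
    trunk_spec: PlantedDEGSpec | None = None,
    brain_spec: PlantedDEGSpec | None = None,
    n_shared_up: int = 54,
    seed: int = 0,
) -> dict:
    """Trunk and brain transcriptome tables with a forced up-set overlap.

    Defaults plant 614 up / 75 down genes in the trunk and 60 up / 1 down in
    the brain, with 54 of the brain's up genes shared with the trunk —
    the deregulation structure of the juvenile scoliotic-fish study this
    package models.  Returns a dict with both tables and all truth sets.
    """
    trunk_spec = trunk_spec or PlantedDEGSpec(n_features=20000, n_up=614, n_down=75, seed=seed)
    brain_spec = brain_spec or PlantedDEGSpec(n_features=20000, n_up=60, n_down=1, seed=seed + 1)
    if n_shared_up > min(trunk_spec.n_up, brain_spec.n_up):
        raise ValueError("shared up-set larger than a table's up-set")
    rng = np.random.default_rng(seed)
    trunk_df, trunk_up, trunk_down = _planted_table(trunk_spec, rng, prefix="gene")
    shared = set(rng.choice(sorted(trunk_up), size=n_shared_up, replace=False))
    brain_df, brain_up, brain_down = _planted_table(
        brain_spec, rng, prefix="bgene", up_ids=sorted(shared)
    )
    return {
        "trunk": trunk_df,
        "brain": brain_df,
        "trunk_up": trunk_up,
        "trunk_down": trunk_down,
        "brain_up": brain_up,
        "brain_down": brain_down,
        "shared_up": shared,
    }


def gen_target_lists(
    deg_up_ids: set[str],
    n_in_targets: int = 106,
    n_direct: int = 77,
    n_extra_targets: int = 500,
    seed: int = 0,
) -> tuple[set[str], set[str]]:
    """A curated target list hitting a known fraction of an up-set.

    Defaults plant 106 of the upregulated genes in the target list, 77 of
    them in the direct-target subset, mirroring a ciliogenesis-program
    target cross-reference.  Returns (targets, direct_targets).
    """
    if n_direct > n_in_targets or n_in_targets > len(deg_up_ids):
        raise ValueError("inconsistent target-list sizes")
    rng = np.random.default_rng(seed)
    hit = list(rng.choice(sorted(deg_up_ids), size=n_in_targets, replace=False))
    direct = set(rng.choice(hit, size=n_direct, replace=False))
    extras = {f"tgt{i:05d}" for i in range(n_extra_targets)}
    return set(hit) | extras, direct


def gen_proteome_table(
    n_proteins: int = 5706, n_up: int = 127, n_down: int = 45, seed: int = 0
) -> tuple[pd.DataFrame, set[str], set[str]]:
    """A processed-proteome table with planted enriched/depleted proteins.

    Defaults follow the adult-brain proteome of the modelled study: 5706
    detected proteins of which 127 are present in higher and 45 in lower
    quantity under the strict p < 0.05, |log2FC| > 0.75 criterion.  Planted
    rows pass under both the raw and the adjusted p column, so the
    reproduction is insensitive to that documented ambiguity.
    """
    spec = PlantedDEGSpec(n_features=n_proteins, n_up=n_up, n_down=n_down, seed=seed)
    rng = np.random.default_rng(seed)
    df, up, down = _planted_table(spec, rng, prefix="prot")
    df = df.rename(columns={"gene_id": "protein_id"})
    # planted rows must be significant on the raw p column too (they are:
    # pvalue <= padj by construction); make sure no null sneaks in on raw p
    null_sig = (
        (~df["protein_id"].isin(up | down))
        & (df["pvalue"] < 0.05)
        & (df["log2FoldChange"].abs() > 0.75)
    )
    df.loc[null_sig, "pvalue"] = rng.uniform(0.051, 1.0, int(null_sig.sum()))
    return df, up, down


def gen_onset_cohort(
    n: int = 252,
    penetrance: float = 0.9,
    onset_window: tuple[float, float] = (4.0, 11.0),
    last_observed_week: float = 16.0,
    group: str = "mutant",
    seed: int = 0,
) -> tuple[list[OnsetRecord], int]:
    """An onset cohort with binomial curvature assignment.

    Each fish curves with probability ``penetrance``; onset weeks are uniform
    in ``onset_window`` (weeks post-fertilisation).  Defaults emulate the
    modelled study's 252-fish incross cohort with 90% adult penetrance and a
    4-11 wpf onset window.  Returns (records, true number of curved fish).
    """
    if not 0.0 <= penetrance <= 1.0:
        raise ValueError("penetrance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    curved = rng.random(n) < penetrance
    onsets = rng.uniform(*onset_window, size=n)
    records = [
        OnsetRecord(
            fish_id=f"fish{i:04d}",
            group=group,
            onset_week=float(onsets[i]) if curved[i] else None,
            last_observed_week=last_observed_week,
        )
        for i in range(n)
    ]
    return records, int(curved.sum())


def gen_ct_table(
    true_fold: float = 3.5,
    n_per_group: int = 7,
    n_control: int = 5,
    noise_sd: float = 0.1,
    biological_sd: float = 0.0,
    n_replicates: int = 2,
    target_gene: str = "target",
    reference_gene: str = "reference",
    seed: int = 0,
) -> tuple[list[CtMeasurement], float]:
    """A qPCR Ct table with a planted fold change between two groups.

    The mutant group's target Ct is shifted by -log2(true_fold) cycles
    relative to control; technical replicate noise is Gaussian with
    ``noise_sd`` cycles, per-fish biological scatter with ``biological_sd``.
    Defaults emulate a ~3.5-fold induction assayed in duplicate in 7 mutant
    vs 5 control fish.  Returns (measurements, true_fold).
    """
    rng = np.random.default_rng(seed)
    out: list[CtMeasurement] = []
    base_ref, base_tgt = 18.0, 24.0
    for group, n_samples, shift in (
        ("control", n_control, 0.0),
        ("mutant", n_per_group, -np.log2(true_fold)),
    ):
        for i in range(n_samples):
            sid = f"{group}{i:02d}"
            sample_ref = base_ref + rng.normal(0, biological_sd) if biological_sd else base_ref
            sample_tgt = base_tgt + shift + (rng.normal(0, biological_sd) if biological_sd else 0.0)
            for rep in range(n_replicates):
                out.append(
                    CtMeasurement(sid, group, reference_gene, sample_ref + rng.normal(0, noise_sd), rep)
                )
                out.append(
                    CtMeasurement(sid, group, target_gene, sample_tgt + rng.normal(0, noise_sd), rep)
                )
    return out, true_fold
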