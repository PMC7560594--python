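"""Per-site geometric descriptors of abasic-site dynamics.

Implements the study-style descriptors computed on 13/15-bp duplex sections:

* extrahelicity — percentage of frames in which the lesion's C1' atom lies
  more than 14 Å from the facing nucleotide's C1' atom (not necessarily
  consecutive frames);
* orphan-base ejection — percentage of frames in which the distance between
  the mass-weighted nucleobase centres of mass of the orphan base and its
  would-be partner exceeds 10 Å (canonical B-DNA reference 6.8 Å);
* bend angle — a simplified section-curvature measure: the angle between
  least-squares axis fits through the first four and last four base-pair
  centres (C1' midpoints);
* phi correlation between two thresholded indicator series;
* equal-weight replicate aggregation with half-away-from-zero rounding.

All threshold comparisons are strict (">" / "<"): a frame exactly at
threshold counts as intrahelical / non-ejected / non-contact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structure import SelectionError, SiteSpec, Trajectory, select_atoms


@dataclass
class ThresholdConfig:
    """Classification thresholds (Å)."""

    extrahelical_c1p_threshold: float = 14.0
    ejection_com_threshold: float = 10.0
    canonical_com_reference: float = 6.8
    contact_cutoff: float = 6.0

    def __post_init__(self) -> None:
        for v in (self.extrahelical_c1p_threshold, self.ejection_com_threshold,
                  self.canonical_com_reference, self.contact_cutoff):
            if v <= 0:
                raise ValueError("thresholds must be positive")
        if self.ejection_com_threshold <= self.canonical_com_reference:
            raise ValueError(
                "ejection threshold must exceed the canonical COM reference"
            )


@dataclass
class DistanceSeries:
    values: np.ndarray
    descriptor_name: str
    atoms_used: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("a distance series is one value per frame")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("distances must be positive and finite")

    @property
    def n_frames(self) -> int:
        return self.values.size


@dataclass
class AngleSeries:
    values: np.ndarray
    descriptor_name: str = "bend_angle"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0) or np.any(self.values >= 180):
            raise ValueError("angles must lie in [0, 180)")

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def std(self) -> float:
        return float(self.values.std())


@dataclass
class PercentSummary:
    """Per-replicate percentages with the equal-weight "All" aggregate."""

    per_replicate: dict[str, float]
    all_mean: float
    all_std: float
    rounding: int = 1


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round with ties going away from zero (reporting convention)."""
    factor = 10 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


# ---------------------------------------------------------------------------
# Distance descriptors
# ---------------------------------------------------------------------------

def _single_c1p(traj: Trajectory, chain: str, resnum: int) -> int:
    idx = select_atoms(traj.topology, chain=chain, residue_number=resnum,
                       atom_name="C1'")
    if idx.size != 1:
        raise SelectionError(
            f"residue {chain}:{resnum} has {idx.size} C1' atoms (need 1)"
        )
    return int(idx[0])


def c1p_distance_series(traj: Trajectory, spec: SiteSpec) -> DistanceSeries:
    """Per-frame lesion-C1' to facing-C1' distance (extrahelicity input)."""
    i = _single_c1p(traj, *spec.lesion)
    j = _single_c1p(traj, *spec.facing)
    d = np.linalg.norm(traj.frames[:, i] - traj.frames[:, j], axis=1)
    return DistanceSeries(
        d, "c1p_distance",
        f"C1'({spec.lesion[0]}:{spec.lesion[1]})-"
        f"C1'({spec.facing[0]}:{spec.facing[1]})",
    )


def com_distance_series(
    traj: Trajectory,
    res_a: tuple[str, int],
    res_b: tuple[str, int],
    subset: str = "base",
) -> DistanceSeries:
    """Distance between mass-weighted centres of mass of two residues.

    ``subset`` selects the atoms entering each COM: "base" (nucleobase heavy
    atoms — the default, matching the ejection descriptor) or "heavy" (all
    heavy atoms of the residue).
    """
    if subset not in ("base", "heavy"):
        raise ValueError("subset must be 'base' or 'heavy'")
    idx = []
    for chain, resnum in (res_a, res_b):
        sel = select_atoms(
            traj.topology, chain=chain, residue_number=resnum,
            base_only=(subset == "base"), heavy_only=True,
            required=f"{subset} atoms of residue {chain}:{resnum}",
        )
        idx.append(sel)
    masses = [traj.topology.mass[i] for i in idx]
    coms = [
        np.einsum("fij,i->fj", traj.frames[:, i], m) / m.sum()
        for i, m in zip(idx, masses)
    ]
    d = np.linalg.norm(coms[0] - coms[1], axis=1)
    return DistanceSeries(
        d, "com_distance",
        f"{subset}-COM({res_a[0]}:{res_a[1]})-"
        f"COM({res_b[0]}:{res_b[1]})",
    )


# ---------------------------------------------------------------------------
# Threshold percentages
# ---------------------------------------------------------------------------

def percent_above(series: DistanceSeries, threshold: float) -> float:
    if series.n_frames == 0:
        raise ValueError("empty distance series")
    return 100.0 * float(np.count_nonzero(series.values > threshold)) \
        / series.n_frames


def extrahelicity_percent(series: DistanceSeries,
                          cfg: ThresholdConfig | None = None) -> float:
    """Percentage of frames with C1'-C1' distance strictly above 14 Å."""
    cfg = cfg or ThresholdConfig()
    return percent_above(series, cfg.extrahelical_c1p_threshold)


def ejection_fraction(series: DistanceSeries,
                      cfg: ThresholdConfig | None = None) -> float:
    """Percentage of frames with base-COM distance strictly above 10 Å."""
    cfg = cfg or ThresholdConfig()
    return percent_above(series, cfg.ejection_com_threshold)


# ---------------------------------------------------------------------------
# Bend angle (simplified axis fit; the study used a full helicoidal analysis)
# ---------------------------------------------------------------------------

def _pair_centers(traj: Trajectory, section: tuple) -> np.ndarray:
    """(n_frames, n_bp, 3) midpoints of paired C1' atoms along the section."""
    rng_a, rng_b = section
    n_bp = rng_a.length
    idx_a, idx_b = [], []
    for k in range(n_bp):
        res_a = rng_a.start + k
        res_b = rng_b.end - k
        idx_a.append(_single_c1p(traj, rng_a.chain, res_a))
        idx_b.append(_single_c1p(traj, rng_b.chain, res_b))
    return 0.5 * (traj.frames[:, idx_a] + traj.frames[:, idx_b])


def _fit_direction(points: np.ndarray) -> np.ndarray:
    """Least-squares line direction through points, oriented along progression."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    if d @ (points[-1] - points[0]) < 0:
        d = -d
    return d


def bend_angle_series(traj: Trajectory,
                      section: tuple | SiteSpec,
                      end_pairs: int = 4) -> AngleSeries:
    """Angle between axis fits through the two ends of a duplex section.

    Per frame, a least-squares line is fitted to the first ``end_pairs``
    base-pair centres (C1' midpoints) and another to the last ``end_pairs``;
    the bend is the angle between the two directions, both oriented along
    the 5'->3' progression of the first strand, in [0, 180).
    """
    if isinstance(section, SiteSpec):
        section = section.section
    n_bp = section[0].length
    if n_bp < 10:
        raise ValueError("bend angle needs a section of >= 10 bp")
    if end_pairs < 4:
        raise ValueError("need >= 4 base pairs per end segment")
    centers = _pair_centers(traj, section)
    angles = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        d1 = _fit_direction(centers[t, :end_pairs])
        d2 = _fit_direction(centers[t, -end_pairs:])
        cosang = float(np.clip(d1 @ d2, -1.0, 1.0))
        angles[t] = np.degrees(np.arccos(cosang))
    return AngleSeries(np.clip(angles, 0.0, np.nextafter(180.0, 0.0)))


# ---------------------------------------------------------------------------
# Indicator correlation and replicate aggregation
# ---------------------------------------------------------------------------

def correlate_indicators(
    series_a: DistanceSeries, threshold_a: float,
    series_b: DistanceSeries, threshold_b: float,
) -> float | None:
    """Phi coefficient of the two thresholded indicator series.

    Returns None when either indicator is constant (phi undefined).
    """
    if series_a.n_frames != series_b.n_frames:
        raise ValueError(
            f"length mismatch: {series_a.n_frames} vs {series_b.n_frames}"
        )
    a = series_a.values > threshold_a
    b = series_b.values > threshold_b
    n11 = int(np.count_nonzero(a & b))
    n10 = int(np.count_nonzero(a & ~b))
    n01 = int(np.count_nonzero(~a & b))
    n00 = int(np.count_nonzero(~a & ~b))
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    if denom == 0:
        return None
    return (n11 * n00 - n10 * n01) / math.sqrt(denom)


def aggregate_replicates(per_replicate: dict[str, float],
                         decimals: int = 1) -> PercentSummary:
    """Equal-weight mean over replicates, rounded last.

    Replicates in the emulated study have equal length, so the "All" value
    is the unweighted arithmetic mean of the per-replicate percentages,
    rounded half-away-from-zero to ``decimals``.
    """
    if not per_replicate:
        raise ValueError("no replicates to aggregate")
    values = np.array(list(per_replicate.values()), dtype=float)
    mean = round_half_away(float(values.mean()), decimals)
    std = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return PercentSummary(dict(per_replicate), mean,
                          round_half_away(std, decimals), decimals)
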