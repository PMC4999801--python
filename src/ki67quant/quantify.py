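"""Quantitative indicators: counts, positive percentage, coloring
strength, grading, and the statistical utilities for stability testing.

The proliferative index of a field is the positive percentage
100 * n_DAB / (n_DAB + n_hematoxylin).  DAB coloring strength is the
mean blue intensity I_b over DAB nuclei (darker brown = lower I_b =
stronger staining), and the positive level is the product of normalized
darkness (1 - I_b/255) and the positive fraction.  Section grading
averages the per-field percentages and maps the mean onto four ordinal
bands: [0,5] -> (-), (5,25] -> (+), (25,50] -> (++), (50,100] -> (+++);
(-)/(+) are low, (++) medium, (+++) high expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats

from .errors import DegenerateInputError, DomainError, InsufficientDataError
from .morphology import LabelledNuclei

_EIGHT = np.ones((3, 3), dtype=bool)

DEFAULT_BANDS = (5.0, 25.0, 50.0, 100.0)
GRADES = ("-", "+", "++", "+++")
LEVELS = {"-": "low", "+": "low", "++": "medium", "+++": "high"}


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus: geometry plus mean blue intensity."""

    id: int
    cls: str                      # "DAB" or "HEMATOXYLIN"
    area: int                     # px
    centroid: tuple[float, float]  # (row, col)
    circularity: float            # 4*pi*area / perimeter^2
    mean_Ib: float                # [0, 255]


@dataclass(frozen=True)
class FieldQuantification:
    """Counts and derived indicators for one visual field."""

    n_dab: int
    n_hema: int
    positive_percentage: float | None      # None when the field has no nuclei
    coloring_strength_Ib: float | None     # None when there are no DAB nuclei
    positive_level: float | None

    def as_dict(self) -> dict:
        return {
            "n_dab": self.n_dab,
            "n_hema": self.n_hema,
            "positive_percentage": self.positive_percentage,
            "coloring_strength_Ib": self.coloring_strength_Ib,
            "positive_level": self.positive_level,
        }


@dataclass(frozen=True)
class SectionGrade:
    """Averaged grade of one tissue section (typically five fields)."""

    field_percentages: tuple[float, ...]
    mean_percentage: float
    grade: str
    level: str

    def as_dict(self) -> dict:
        return {
            "field_percentages": list(self.field_percentages),
            "mean_percentage": self.mean_percentage,
            "grade": self.grade,
            "level": self.level,
        }


@dataclass(frozen=True)
class SampleSizeParams:
    """Paired-design sample-size inputs: allowable error delta (percentage
    points), sd of paired differences sigma_d, and alpha/beta error rates."""

    delta: float
    sigma_d: float
    alpha: float = 0.05
    beta: float = 0.10

    def __post_init__(self):
        if self.delta <= 0:
            raise DomainError("delta must be > 0")
        if self.sigma_d < 0:
            raise DomainError("sigma_d must be >= 0")
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise DomainError("alpha and beta must lie in (0, 1)")


def _perimeter_boundary_pixels(obj: np.ndarray) -> int:
    """Count object pixels with an 8-neighbor outside (border = outside)."""
    interior = ndi.binary_erosion(obj, structure=_EIGHT, border_value=0)
    return int(obj.sum() - interior.sum())


def scanline_object_order(
    labelled: dict[str, LabelledNuclei]
) -> list[tuple[str, int]]:
    """Deterministic global ordering of objects across class maps.

    Objects are ordered by the flat (row-major) index of their first
    pixel; ties across classes (impossible for disjoint maps) fall back
    to class name.  Global record id = 1 + position in this list.
    """
    entries = []
    for cls, ln in labelled.items():
        labels = ln.labels
        if ln.n_objects == 0:
            continue
        rows, cols = np.nonzero(labels)
        order = np.lexsort((cols, rows))
        seen = set()
        for i in order:
            lab = int(labels[rows[i], cols[i]])
            if lab not in seen:
                seen.add(lab)
                entries.append((int(rows[i]) * labels.shape[1] + int(cols[i]), cls, lab))
            if len(seen) == ln.n_objects:
                break
    entries.sort(key=lambda e: (e[0], e[1]))
    return [(cls, lab) for _, cls, lab in entries]


def build_nucleus_table(
    labelled: dict[str, LabelledNuclei],
    b_plane: np.ndarray,
) -> list[NucleusRecord]:
    """One record per labelled object across all nuclear classes.

    Ids are assigned in scanline order of each object's first pixel and
    are unique across classes; perimeter is the 8-connected boundary
    pixel count, from which circularity = 4*pi*area/perimeter^2.
    """
    b_plane = np.asarray(b_plane, dtype=np.float64)
    stats: dict[tuple[str, int], dict] = {}
    for cls, ln in labelled.items():
        labels = ln.labels
        if ln.n_objects == 0:
            continue
        idx = range(1, ln.n_objects + 1)
        areas = ndi.sum_labels(np.ones_like(labels), labels, index=idx)
        sums_b = ndi.sum_labels(b_plane, labels, index=idx)
        centroids = ndi.center_of_mass(np.ones_like(labels), labels, index=idx)
        slices = ndi.find_objects(labels)
        for lab in idx:
            sl = slices[lab - 1]
            if sl is None:
                continue
            per = _perimeter_boundary_pixels(labels[sl] == lab)
            area = int(areas[lab - 1])
            stats[(cls, lab)] = dict(
                cls=cls, area=area,
                centroid=(float(centroids[lab - 1][0]), float(centroids[lab - 1][1])),
                circularity=4.0 * math.pi * area / (per * per) if per > 0 else 0.0,
                mean_Ib=float(sums_b[lab - 1] / area),
            )
    return [
        NucleusRecord(id=i + 1, **stats[key])
        for i, key in enumerate(scanline_object_order(labelled))
    ]


def quantify_field(records: list[NucleusRecord]) -> FieldQuantification:
    """Counts, positive percentage, coloring strength and positive level.

    A field with no nuclei reports null percentage; a field with nuclei
    but no DAB reports percentage 0, null coloring strength, and
    positive level 0 (the product with a zero positive fraction).
    """
    dab = [r for r in records if r.cls == "DAB"]
    hema = [r for r in records if r.cls == "HEMATOXYLIN"]
    n_dab, n_hema = len(dab), len(hema)
    if n_dab + n_hema == 0:
        return FieldQuantification(0, 0, None, None, None)
    pct = 100.0 * n_dab / (n_dab + n_hema)
    if n_dab == 0:
        return FieldQuantification(n_dab, n_hema, pct, None, 0.0)
    strength = float(np.mean([r.mean_Ib for r in dab]))
    level = (1.0 - strength / 255.0) * (pct / 100.0)
    return FieldQuantification(n_dab, n_hema, pct, strength, level)


def grade_from_percentage(
    p: float, bands: tuple[float, ...] = DEFAULT_BANDS
) -> tuple[str, str]:
    """Map a positive percentage onto the four-band ordinal grade.

    Bands are contiguous half-open intervals, upper-inclusive:
    [0, 5] -> (-), (5, 25] -> (+), (25, 50] -> (++), (50, 100] -> (+++).
    """
    if not (0.0 <= p <= 100.0):
        raise DomainError(f"percentage {p} outside [0, 100]")
    for upper, grade in zip(bands, GRADES):
        if p <= upper:
            return grade, LEVELS[grade]
    return GRADES[-1], LEVELS[GRADES[-1]]


def grade_section(
    field_quants: list[FieldQuantification],
    bands: tuple[float, ...] = DEFAULT_BANDS,
) -> SectionGrade:
    """Grade of the mean per-field positive percentage (order-invariant).

    Fields with null percentage (no nuclei) are excluded; if all fields
    are null the section cannot be graded.
    """
    pcts = [q.positive_percentage for q in field_quants if q.positive_percentage is not None]
    if not pcts:
        raise InsufficientDataError("no field with a defined positive percentage")
    mean_pct = float(np.mean(pcts))
    grade, level = grade_from_percentage(mean_pct, bands)
    return SectionGrade(tuple(pcts), mean_pct, grade, level)


def required_sample_size(params: SampleSizeParams) -> int:
    """Minimum paired-sample count N = ceil(((z_{1-a/2}+z_{1-b}) * sigma_d / delta)^2).

    z are standard-normal quantiles; N is floored at 1.
    """
    z = stats.norm.ppf(1.0 - params.alpha / 2.0) + stats.norm.ppf(1.0 - params.beta)
    n = math.ceil((z * params.sigma_d / params.delta) ** 2)
    return max(1, n)


def paired_t_test(x, y) -> tuple[float, float]:
    """Paired t statistic and two-tailed p for consistency checking.

    t = mean(d) / (sd(d)/sqrt(n)) with sample sd (n-1 divisor),
    p from the t distribution with n-1 degrees of freedom.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("x and y must be 1-d sequences of equal length")
    n = x.size
    if n < 2:
        raise DomainError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("paired differences have zero variance")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def evaluate_detections(
    pred_labels: np.ndarray, truth_labels: np.ndarray
) -> tuple[float, float, float]:
    """FAR / FRR / accuracy of a predicted object map against ground truth.

    Objects are matched one-to-one greedily by descending pixel IoU with
    a match threshold of IoU >= 0.5.  Both rates are referenced to the
    ground-truth object count, so accuracy = 100 - FAR - FRR:

    - FAR (false accept): 100 * unmatched predictions / n_truth
      (spurious or over-segmented detections);
    - FRR (false reject): 100 * unmatched truths / n_truth
      (missed or under-segmented nuclei).
    """
    pred = np.asarray(pred_labels)
    truth = np.asarray(truth_labels)
    if pred.shape != truth.shape:
        raise DomainError("prediction and truth label maps must share a shape")
    truth_ids = np.unique(truth)
    truth_ids = truth_ids[truth_ids > 0]
    if truth_ids.size == 0:
        raise DomainError("ground truth contains no objects")
    pred_ids = np.unique(pred)
    pred_ids = pred_ids[pred_ids > 0]
    n_truth = truth_ids.size

    pred_area = {int(i): int((pred == i).sum()) for i in pred_ids}
    truth_area = {int(i): int((truth == i).sum()) for i in truth_ids}
    both = (pred > 0) & (truth > 0)
    pairs, counts = np.unique(
        np.stack([pred[both], truth[both]]), axis=1, return_counts=True
    )
    candidates = []
    for (pi, ti), inter in zip(pairs.T, counts):
        union = pred_area[int(pi)] + truth_area[int(ti)] - int(inter)
        iou = inter / union
        if iou >= 0.5:
            candidates.append((iou, int(pi), int(ti)))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_p, used_t = set(), set()
    for iou, pi, ti in candidates:
        if pi in used_p or ti in used_t:
            continue
        used_p.add(pi)
        used_t.add(ti)
    far = 100.0 * (pred_ids.size - len(used_p)) / n_truth
    frr = 100.0 * (n_truth - len(used_t)) / n_truth
    return far, frr, 100.0 - far - frr
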