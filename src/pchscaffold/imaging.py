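"""Nucleus / chromocenter image quantification.

Implements DAPI-based segmentation of nuclei and pericentric
heterochromatin (PCH) foci, the percent-in-PCH intensity ratio
``100 * (S_PCH x n x I_PCH) / (S_N x I_N)``, linear standard-curve
calibration of expression levels, the four expression classes, k-means
chromatin-compaction classes, copies-per-nucleus to molar conversion,
tissue scaling by relative abundance, and BH-corrected pairwise tests.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.cluster.vq import kmeans2
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as sk_label
from statsmodels.stats.multitest import multipletests

from .synthio import StandardCurve, _rng


# ---------------------------------------------------------------------------
# domain types


@dataclass
class PCHQuant:
    """Per-nucleus PCH quantification.

    ``s_n``/``i_n``: nucleus area (pixels) and mean intensity; ``n``:
    focus count; per-focus areas and mean intensities; ``pct_in_pch``:
    percent of total channel intensity inside the foci, per channel.
    """

    s_n: int
    i_n: float
    n: int
    focus_areas: np.ndarray
    focus_means: np.ndarray
    pct_in_pch: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.focus_areas = np.asarray(self.focus_areas, dtype=int)
        self.focus_means = np.asarray(self.focus_means, dtype=float)
        if len(self.focus_areas) != self.n:
            raise ValueError("n must equal the number of foci")
        if self.focus_areas.sum() > self.s_n:
            raise ValueError("total focus area exceeds the nucleus")
        for v in self.pct_in_pch.values():
            if not 0.0 <= v <= 100.0:
                raise ValueError("percentages must lie in [0, 100]")


@dataclass
class CompactionProfile:
    """Chromatin compaction classes from voxel-intensity clustering.

    Class 1 is the lowest-intensity (interchromatin) class; the class
    index increases with mean DAPI intensity up to the densest
    heterochromatin.  ``pct_intensity`` is each class's share of total
    DAPI intensity and sums to 100.
    """

    class_map: np.ndarray
    voxel_counts: np.ndarray
    pct_intensity: np.ndarray
    class_means: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.voxel_counts = np.asarray(self.voxel_counts, dtype=int)
        self.pct_intensity = np.asarray(self.pct_intensity, dtype=float)
        self.class_means = np.asarray(self.class_means, dtype=float)
        if abs(self.pct_intensity.sum() - 100.0) > 1e-6:
            raise ValueError("class intensity percentages must sum to 100")
        if (np.diff(self.class_means) < 0).any():
            raise ValueError("class index must increase with intensity")

    @property
    def k(self) -> int:
        return len(self.voxel_counts)


EXPRESSION_BINS = (
    # (label, low, high, closed_right): concentration bins in uM
    ("I", 2.0, 3.0, True),     # endogenous 2-3 uM, closed interval
    ("II", 10.0, 30.0, False),  # nominal 20 uM
    ("III", 30.0, 50.0, False),  # nominal 40 uM
)


@dataclass
class ExpressionClass:
    """Expression class of a nucleus and its calibrated concentration."""

    label: str
    concentration: float

    def __post_init__(self) -> None:
        if self.label not in {"I", "II", "III", "IV", "unclassified"}:
            raise ValueError(f"unknown class label {self.label!r}")


# ---------------------------------------------------------------------------
# segmentation


def segment_nucleus(dapi: np.ndarray) -> np.ndarray:
    """Binary nucleus mask from a single-channel DAPI image.

    Global histogram threshold, then the largest connected foreground
    component with holes filled.  Works on 2-D and 3-D images.  The
    threshold is the lowest cut of a three-class Otsu so that bright
    chromocenter foci cannot pull the cut above the nucleoplasm level; on
    effectively two-level images this falls back to the two-class Otsu.
    """
    img = np.asarray(dapi, dtype=float)
    if img.ndim not in (2, 3):
        raise ValueError("expected a 2-D or 3-D single-channel image")
    if np.ptp(img) == 0:
        raise ValueError("image has no contrast; empty foreground")
    try:
        thr = threshold_multiotsu(img, classes=3)[0]
    except ValueError:
        thr = threshold_otsu(img)
    fg = img > thr
    if not fg.any():
        raise ValueError("empty foreground after thresholding")
    labels = sk_label(fg)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == sizes.argmax()
    return ndimage.binary_fill_holes(mask)


def segment_pch(dapi: np.ndarray, nucleus_mask: np.ndarray,
                min_area: int = 5, k_sd: float = 2.0) -> np.ndarray:
    """Label map of PCH foci inside the nucleus.

    Foci are connected components of voxels brighter than
    ``mean + k_sd * sd`` of the intra-nuclear intensity, with at least
    ``min_area`` pixels.  Zero foci is a valid outcome.
    """
    img = np.asarray(dapi, dtype=float)
    mask = np.asarray(nucleus_mask, dtype=bool)
    if img.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    inside = img[mask]
    if inside.size == 0:
        raise ValueError("empty nucleus mask")
    thr = inside.mean() + k_sd * inside.std()
    bright = (img > thr) & mask
    labels = sk_label(bright)
    out = np.zeros_like(labels, dtype=np.uint16)
    nxt = 1
    for lab in range(1, labels.max() + 1):
        region = labels == lab
        if region.sum() >= min_area:
            out[region] = nxt
            nxt += 1
    return out


def percent_in_compartment(channel: np.ndarray, focus_map: np.ndarray,
                           nucleus_mask: np.ndarray) -> float:
    """Percent of total nuclear intensity lying inside the PCH foci.

    Computed per focus as area x mean intensity and summed — the
    heterogeneous-focus generalization of ``S_PCH x n x I_PCH`` — then
    divided by ``S_N x I_N``.
    """
    img = np.asarray(channel, dtype=float)
    foci = np.asarray(focus_map)
    mask = np.asarray(nucleus_mask, dtype=bool)
    if img.shape != foci.shape or img.shape != mask.shape:
        raise ValueError("channel, focus map and mask shapes differ")
    if not mask.any():
        raise ValueError("empty nucleus mask")
    s_n = int(mask.sum())
    i_n = float(img[mask].mean())
    numer = 0.0
    for lab in np.unique(foci[foci > 0]):
        region = foci == lab
        numer += region.sum() * img[region].mean()
    pct = 100.0 * numer / (s_n * i_n)
    return float(min(max(pct, 0.0), 100.0))


def quantify_nucleus(channels: Mapping[str, np.ndarray],
                     focus_map: np.ndarray,
                     nucleus_mask: np.ndarray) -> PCHQuant:
    """Bundle nucleus/focus geometry and percent-in-PCH for all channels."""
    dapi = np.asarray(channels["dapi"], dtype=float)
    mask = np.asarray(nucleus_mask, dtype=bool)
    labs = np.unique(focus_map[focus_map > 0])
    areas = np.array([(focus_map == lab).sum() for lab in labs], dtype=int)
    means = np.array([dapi[focus_map == lab].mean() for lab in labs])
    pct = {name: percent_in_compartment(img, focus_map, mask)
           for name, img in channels.items()}
    return PCHQuant(s_n=int(mask.sum()), i_n=float(dapi[mask].mean()),
                    n=len(labs), focus_areas=areas, focus_means=means,
                    pct_in_pch=pct)


# ---------------------------------------------------------------------------
# calibration


def fit_standard_curve(curve: StandardCurve) -> StandardCurve:
    """Ordinary least-squares line through the standard measurements."""
    res = stats.linregress(curve.levels, curve.readings)
    return StandardCurve(curve.levels, curve.readings,
                         slope=float(res.slope),
                         intercept=float(res.intercept),
                         r2=float(res.rvalue ** 2),
                         provenance=curve.provenance)


def invert_to_quantity(curve: StandardCurve, reading: float) -> float:
    """Known quantity implied by a reading: (reading - intercept)/slope."""
    if curve.slope is None:
        raise ValueError("fit the curve before inverting")
    if curve.slope == 0:
        raise ZeroDivisionError("flat standard curve cannot be inverted")
    return float((reading - curve.intercept) / curve.slope)


def assign_expression_class(concentration_uM: float) -> ExpressionClass:
    """Expression class from calibrated nuclear concentration (uM).

    Bins: I = [2, 3] (endogenous), II = [10, 30), III = [30, 50),
    IV = >= 50; concentrations in the gaps are unclassified.
    """
    c = float(concentration_uM)
    if c < 0:
        raise ValueError("concentration must be >= 0")
    if c >= 50.0:
        return ExpressionClass("IV", c)
    for label, low, high, closed in EXPRESSION_BINS:
        if low <= c < high or (closed and c == high):
            return ExpressionClass(label, c)
    return ExpressionClass("unclassified", c)


def compaction_classify(dapi: np.ndarray, nucleus_mask: np.ndarray,
                        k: int = 7, seed: int = 0,
                        n_restarts: int = 10) -> CompactionProfile:
    """k-means chromatin-compaction classes of intra-nuclear DAPI voxels.

    Cluster centres are sorted ascending so class 1 is the DNA-poor
    interchromatin class and class ``k`` the densest heterochromatin.
    Deterministic per seed; the best of ``n_restarts`` initializations
    (lowest within-class sum of squares) is kept.  A constant-intensity
    nucleus collapses to a single class with a warning.
    """
    img = np.asarray(dapi, dtype=float)
    mask = np.asarray(nucleus_mask, dtype=bool)
    vox = img[mask]
    if vox.size < k:
        raise ValueError("fewer masked voxels than classes")
    if np.ptp(vox) == 0:
        warnings.warn("constant intensity; single-class profile",
                      stacklevel=2)
        class_map = np.zeros(img.shape, dtype=np.int16)
        class_map[mask] = 1
        return CompactionProfile(class_map, np.array([vox.size]),
                                 np.array([100.0]),
                                 np.array([vox.mean()]), degenerate=True)

    rng = _rng(seed, "compaction_classify")
    best = None
    for _ in range(n_restarts):
        centres, assign = kmeans2(vox, k, minit="++",
                                  seed=rng.integers(2 ** 31 - 1))
        inertia = float(np.sum((vox - centres[assign]) ** 2))
        if best is None or inertia < best[0]:
            best = (inertia, centres, assign)
    _, centres, assign = best
    order = np.argsort(centres)
    rank = np.empty_like(order)
    rank[order] = np.arange(1, k + 1)
    classes = rank[assign]

    class_map = np.zeros(img.shape, dtype=np.int16)
    class_map[mask] = classes
    counts = np.array([(classes == c).sum() for c in range(1, k + 1)])
    sums = np.array([vox[classes == c].sum() for c in range(1, k + 1)])
    means = np.array([vox[classes == c].mean() if (classes == c).any()
                      else np.nan for c in range(1, k + 1)])
    pct = 100.0 * sums / sums.sum()
    return CompactionProfile(class_map, counts, pct, means)


# ---------------------------------------------------------------------------
# abundance


def abundance_from_blot(band_intensity: float, curve: StandardCurve,
                        n_nuclei: int, molecular_weight: float,
                        nuclear_volume: float = 4.0e-13) -> float:
    """Nuclear concentration (uM) from a calibrated blot band.

    The band reading is inverted through the ng standard curve; the mass
    is converted to moles via the molecular weight (Da) and divided by
    the total nuclear volume ``n_nuclei * nuclear_volume`` (litres;
    default 4.0e-13 L ~ 400 um^3 per nucleus).
    """
    if n_nuclei <= 0 or molecular_weight <= 0 or nuclear_volume <= 0:
        raise ValueError("n_nuclei, molecular weight and volume must be > 0")
    mass_ng = invert_to_quantity(curve, band_intensity)
    moles = mass_ng * 1e-9 / molecular_weight
    return float(moles / (n_nuclei * nuclear_volume) * 1e6)


def tissue_scale(reference_conc_uM: float, reference_tissue: str,
                 ppm_table: Mapping[str, float]) -> dict:
    """Scale a reference-tissue concentration across tissues by ppm ratio.

    ``conc_t = reference_conc * ppm_t / ppm_ref``; returns the per-tissue
    map plus its mean and median.
    """
    if reference_tissue not in ppm_table:
        raise KeyError(f"reference tissue {reference_tissue!r} missing")
    ppm_ref = float(ppm_table[reference_tissue])
    if ppm_ref <= 0:
        raise ValueError("reference ppm must be > 0")
    conc = {t: float(reference_conc_uM) * float(p) / ppm_ref
            for t, p in ppm_table.items()}
    vals = np.array(list(conc.values()))
    return {"per_tissue": conc, "mean": float(vals.mean()),
            "median": float(np.median(vals))}


# ---------------------------------------------------------------------------
# group tests


def grouped_tests(values_by_group: Mapping[str, Sequence[float]],
                  correction: str = "BH") -> pd.DataFrame:
    """All pairwise unpaired t-tests across groups, optionally BH-adjusted.

    Benjamini-Hochberg step-up adjustment is applied across the whole
    pairwise family.  Returns one row per pair with raw and adjusted
    p-values.
    """
    if correction not in ("none", "BH"):
        raise ValueError("correction must be 'none' or 'BH'")
    groups = {g: np.asarray(v, dtype=float)
              for g, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
    rows = []
    for ga, gb in itertools.combinations(sorted(groups), 2):
        a, b = groups[ga], groups[gb]
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 \
                and a.mean() == b.mean():
            pval = 1.0
        else:
            pval = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
        rows.append({"group_a": ga, "group_b": gb, "p": pval})
    df = pd.DataFrame(rows)
    if correction == "BH":
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adj"] = df["p"]
    return df
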