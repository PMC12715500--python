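"""Downstream quantification of condensate partition proteomics.

Starting from a DIA protein-group intensity matrix this module applies
the standard label-free steps (detection filtering, log2 transform,
per-sample median normalization, downshifted-Gaussian imputation),
classifies proteins by their pellet/supernatant partition behaviour,
quantifies how an added scaffold condensate shifts the pellet
composition, and estimates neutral masses from native-MS charge-state
series.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthio import IntensityMatrix, _rng

if TYPE_CHECKING:  # pragma: no cover
    from .synthio import AnnotationTable

PROTON_MASS = 1.00728  # Da


# ---------------------------------------------------------------------------
# domain types


@dataclass
class PartitionResult:
    """Pellet/supernatant partition classes after phase separation.

    ``p_and_s``: detected in both pellet and supernatant; ``p_only`` /
    ``s_only``: exclusive to one fraction.  The three sets are pairwise
    disjoint and union to all proteins passing the replicate rule in at
    least one group.
    """

    p_and_s: set[str]
    p_only: set[str]
    s_only: set[str]
    group_means: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        sets = [self.p_and_s, self.p_only, self.s_only]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("partition classes overlap")

    @property
    def universe(self) -> set[str]:
        return self.p_and_s | self.p_only | self.s_only

    def to_dict(self) -> dict:
        return {"p_and_s": sorted(self.p_and_s),
                "p_only": sorted(self.p_only),
                "s_only": sorted(self.s_only),
                "n_p_and_s": len(self.p_and_s),
                "n_p_only": len(self.p_only),
                "n_s_only": len(self.s_only)}


@dataclass
class CompositionShift:
    """Pellet composition change upon adding scaffold condensates.

    ``retained`` = in both pellets, ``excluded`` = lost from the
    comparison pellet, ``recruited`` = gained in the comparison pellet.
    """

    retained: set[str]
    excluded: set[str]
    recruited: set[str]
    reference_label: str = "reference"
    comparison_label: str = "comparison"

    def __post_init__(self) -> None:
        sets = [self.retained, self.excluded, self.recruited]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("composition-shift classes overlap")

    def to_dict(self) -> dict:
        return {"reference": self.reference_label,
                "comparison": self.comparison_label,
                "n_retained": len(self.retained),
                "n_excluded": len(self.excluded),
                "n_recruited": len(self.recruited),
                "retained": sorted(self.retained),
                "excluded": sorted(self.excluded),
                "recruited": sorted(self.recruited)}


@dataclass
class ChargeSeries:
    """A native-MS charge-state series and its inferred neutral mass."""

    peaks_mz: np.ndarray
    charges: np.ndarray
    mass: float
    residual: float  # relative spread of the per-peak mass estimates

    def __post_init__(self) -> None:
        self.peaks_mz = np.asarray(self.peaks_mz, dtype=float)
        self.charges = np.asarray(self.charges, dtype=int)
        if self.mass <= 0:
            raise ValueError("mass must be positive")
        dz = np.diff(self.charges)
        if len(dz) and not (dz == -1).all():
            raise ValueError("charges must descend consecutively with m/z")

    def to_dict(self) -> dict:
        return {"peaks_mz": self.peaks_mz.tolist(),
                "charges": self.charges.tolist(),
                "mass_da": float(self.mass),
                "residual": float(self.residual)}


# ---------------------------------------------------------------------------
# matrix-level operations


def detection_filter(matrix: IntensityMatrix,
                     min_samples: int = 3) -> IntensityMatrix:
    """Drop proteins observed in fewer than ``min_samples`` samples."""
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    observed = matrix.values.notna().sum(axis=1)
    out = matrix.copy()
    out.values = matrix.values.loc[observed >= min_samples]
    return out


def replicate_presence(matrix: IntensityMatrix, group_label: str,
                       min_reps: int = 2) -> set[str]:
    """Ids non-missing in at least ``min_reps`` replicates of a group."""
    cols = matrix.sample_ids(group_label)
    counts = matrix.values[cols].notna().sum(axis=1)
    return set(counts.index[counts >= min_reps])


def log2_median_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """log2-transform and subtract each sample's median observed value.

    Requires a raw-scale matrix with positive intensities; missing cells
    stay missing and every column median is exactly zero afterwards.
    """
    if matrix.scale != "raw":
        raise ValueError("expected a raw-scale matrix")
    vals = matrix.values.to_numpy(dtype=float)
    if np.nanmin(vals, initial=np.inf) <= 0:
        raise ValueError("raw intensities must be positive")
    log2 = np.log2(vals)
    med = np.nanmedian(log2, axis=0)
    out = matrix.copy()
    out.values = pd.DataFrame(log2 - med, index=matrix.values.index,
                              columns=matrix.values.columns)
    out.scale = "log2"
    return out


def impute_downshift(matrix: IntensityMatrix, width: float = 0.3,
                     shift: float = 1.8, seed: int = 0) -> IntensityMatrix:
    """Downshifted-Gaussian imputation of missing log2 intensities.

    Each missing cell is drawn from
    ``Normal(mu_col - shift * sd_col, (width * sd_col)^2)`` using the
    column's observed mean and standard deviation — the label-free
    convention of drawing imputed values from the low-abundance tail.
    Observed cells are untouched; output is reproducible per seed.
    """
    if matrix.scale != "log2":
        raise ValueError("imputation expects a log2-scale matrix")
    vals = matrix.values.to_numpy(dtype=float).copy()
    rng = _rng(seed, "impute_downshift")
    for j, col in enumerate(matrix.values.columns):
        x = vals[:, j]
        obs = x[~np.isnan(x)]
        n_missing = int(np.isnan(x).sum())
        if n_missing == 0:
            continue
        if len(obs) < 2:
            raise ValueError(
                f"column {col!r} has fewer than 2 observed values")
        mu, sd = obs.mean(), obs.std(ddof=1)
        draw = rng.normal(mu - shift * sd, width * sd, n_missing)
        x[np.isnan(x)] = draw
    out = matrix.copy()
    out.values = pd.DataFrame(vals, index=matrix.values.index,
                              columns=matrix.values.columns)
    return out


# ---------------------------------------------------------------------------
# set-level classification


def partition_classify(hc_ids: set[str], s_ids: set[str],
                       p_ids: set[str],
                       group_means: pd.DataFrame | None = None
                       ) -> PartitionResult:
    """Classify proteins by pellet/supernatant detection pattern."""
    s, p = set(s_ids), set(p_ids)
    hc = set(hc_ids)
    if not (s <= hc and p <= hc):
        import warnings
        warnings.warn("supernatant/pellet ids not within the source "
                      "fraction universe", stacklevel=2)
    return PartitionResult(p_and_s=s & p, p_only=p - s, s_only=s - p,
                           group_means=group_means)


def composition_shift(pellet_ref: set[str], pellet_cmp: set[str],
                      reference_label: str = "HC_P",
                      comparison_label: str = "HC_MBD2_P"
                      ) -> CompositionShift:
    """Retained / excluded / recruited sets between two pellet proteomes."""
    a, b = set(pellet_ref), set(pellet_cmp)
    return CompositionShift(retained=a & b, excluded=a - b, recruited=b - a,
                            reference_label=reference_label,
                            comparison_label=comparison_label)


def domain_fraction(ids: set[str], annotations: "AnnotationTable",
                    domain: str) -> float:
    """Fraction of ``ids`` carrying a coiled-coil or zinc-finger domain."""
    col = {"cc": "has_cc", "znf": "has_znf"}.get(domain)
    if col is None:
        raise ValueError("domain must be 'cc' or 'znf'")
    if not ids:
        raise ValueError("domain fraction undefined for an empty id set")
    flags = annotations.df.set_index("protein_id")[col]
    missing = set(ids) - set(flags.index)
    if missing:
        raise KeyError(f"unannotated ids: {sorted(missing)[:10]}")
    return float(flags.loc[sorted(ids)].mean())


def functional_partition_summary(class_ids: set[str],
                                 reference_pellet: set[str],
                                 shift: CompositionShift) -> dict:
    """Exclusion/retention tally of a functional class of proteins.

    The denominator is the class members detected in the reference pellet;
    counts and percentages (one decimal, plus round-half-up integers) say
    how many were excluded from, or retained in, the comparison pellet.
    """
    detected = set(class_ids) & set(reference_pellet)
    if not detected:
        return {"n_class_detected": 0, "undefined": True}
    n_exc = len(detected & shift.excluded)
    n_ret = len(detected & shift.retained)
    n = len(detected)

    def pct(x: int) -> float:
        return round(100.0 * x / n, 1)

    def approx(p: float) -> int:
        return int(math.floor(p + 0.5))  # round half up, for "~x%" rendering

    return {"n_class_detected": n, "n_excluded": n_exc,
            "n_retained": n_ret,
            "pct_excluded": pct(n_exc), "pct_retained": pct(n_ret),
            "pct_excluded_approx": approx(pct(n_exc)),
            "pct_retained_approx": approx(pct(n_ret)),
            "undefined": False}


# ---------------------------------------------------------------------------
# group statistics


def _student_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance (Student) unpaired t-test."""
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def compare_group_metric(set_a: set[str], set_b: set[str],
                         source, metric: str) -> dict:
    """Unpaired two-sample t-test on a per-protein metric.

    ``metric`` is ``disorder_fraction`` (from an annotation table) or
    ``mean_log2_abundance`` (row mean of a log2 intensity matrix).
    """
    if len(set_a) < 2 or len(set_b) < 2:
        raise ValueError("both groups need >= 2 proteins")
    if metric == "disorder_fraction":
        series = source.df.set_index("protein_id")["disorder_fraction"]
    elif metric == "mean_log2_abundance":
        if source.scale != "log2":
            raise ValueError("metric needs a log2-scale matrix")
        series = source.values.mean(axis=1, skipna=True)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    missing = (set_a | set_b) - set(series.index)
    if missing:
        raise KeyError(f"metric unavailable for {sorted(missing)[:10]}")
    a = series.loc[sorted(set_a)].to_numpy(dtype=float)
    b = series.loc[sorted(set_b)].to_numpy(dtype=float)
    _, pval = _student_t(a, b)
    return {"mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "p_two_sided": pval}


def differential_abundance(matrix: IntensityMatrix, group_a: str,
                           group_b: str,
                           member_ids: Iterable[str] | None = None,
                           alpha: float = 0.05) -> pd.DataFrame:
    """Per-protein unpaired t-tests between two sample groups.

    ``log2_fc`` is mean(group_b) - mean(group_a); significance is the raw
    two-sided Student p-value against ``alpha`` (no multiple-testing
    correction at this step).  Zero within-group variance in both groups
    leaves p undefined (NaN) with ``flagged`` set.
    """
    if matrix.scale != "log2":
        raise ValueError("differential abundance expects log2 data")
    cols_a = matrix.sample_ids(group_a)
    cols_b = matrix.sample_ids(group_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    ids = list(member_ids) if member_ids is not None else matrix.proteins
    missing = set(ids) - set(matrix.proteins)
    if missing:
        raise KeyError(f"ids not in matrix: {sorted(missing)[:10]}")
    rows = []
    for pid in ids:
        a = matrix.values.loc[pid, cols_a].to_numpy(dtype=float)
        b = matrix.values.loc[pid, cols_b].to_numpy(dtype=float)
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError(
                f"missing values for {pid!r}; impute before testing")
        fc = float(b.mean() - a.mean())
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            rows.append({"protein_id": pid, "log2_fc": fc, "p": np.nan,
                         "significant": False, "flagged": True})
            continue
        _, pval = _student_t(a, b)
        rows.append({"protein_id": pid, "log2_fc": fc, "p": pval,
                     "significant": bool(pval < alpha), "flagged": False})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# native mass spectrometry


def mass_from_charge_series(peaks_mz: Sequence[float],
                            z_search: Sequence[int] = range(1, 151),
                            tolerance: float = 0.005) -> ChargeSeries:
    """Neutral mass from a consecutive charge-state peak series.

    Ascending m/z peaks are assigned consecutive descending positive
    charges ``z, z-1, ...``; the assignment minimizing the relative spread
    of the implied neutral masses ``M_i = z_i * (mz_i - m_proton)`` wins.
    Raises if no assignment brings the relative spread under ``tolerance``.
    """
    mz = np.asarray(peaks_mz, dtype=float)
    if len(mz) < 2:
        raise ValueError("need >= 2 peaks")
    if (np.diff(mz) <= 0).any():
        raise ValueError("peaks must be strictly ascending in m/z")
    n = len(mz)
    best = None
    for z_top in z_search:
        if z_top < n:  # lowest charge z_top - n + 1 must stay >= 1
            continue
        z = np.arange(z_top, z_top - n, -1)
        masses = z * (mz - PROTON_MASS)
        mean = masses.mean()
        spread = (masses.max() - masses.min()) / mean
        if best is None or spread < best[0]:
            best = (float(spread), z, float(mean))
    if best is None or best[0] > tolerance:
        raise ValueError("no consecutive charge assignment fits the peaks")
    spread, z, mean = best
    return ChargeSeries(mz, z, mean, spread)


def synthesize_charge_peaks(mass: float, z_top: int,
                            n_peaks: int) -> np.ndarray:
    """Noiseless m/z peaks of ``mass`` at charges z_top..z_top-n_peaks+1.

    Inverse of :func:`mass_from_charge_series`; used for round-trip
    checks and jitter simulations.
    """
    if mass <= 0:
        raise ValueError("mass must be positive")
    if z_top - n_peaks + 1 < 1:
        raise ValueError("charges must stay positive")
    z = np.arange(z_top, z_top - n_peaks, -1)
    return np.sort(mass / z + PROTON_MASS)


def oligomer_order(mass: float, monomer_mass: float
                   ) -> tuple[int, float, bool]:
    """Oligomeric order = round(mass / monomer mass).

    Returns ``(order, ratio, ambiguous)`` where ``ambiguous`` marks
    ratios farther than 0.25 from the nearest integer.
    """
    if mass <= 0 or monomer_mass <= 0:
        raise ValueError("masses must be positive")
    ratio = mass / monomer_mass
    order = int(round(ratio))
    ambiguous = abs(ratio - order) > 0.25 or order == 0
    return max(order, 1) if order == 0 else order, ratio, ambiguous
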