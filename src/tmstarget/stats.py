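"""Dose extraction and the statistical battery for the method comparison.

Per subject and targeting method the dose metric is the median |E| over
the L-DLPFC gray-matter voxel mask.  Across the cohort the doses are
compared with a Friedman test (rank-based, within-subject), post hoc
pairwise Wilcoxon signed-rank tests with Holm step-down adjustment, and
a Bartlett test of homogeneity of variances; the dose-response analysis
is a Pearson correlation between the treatment-target dose and the
CDRS-R change in completers.  A one-sample t summary from (mean, sd, n)
supports the motor-threshold sanity check against the 135 V/m adult
reference.  All tests are two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.ndimage import map_coordinates

from .targeting import RoiMask

__all__ = [
    "METHODS",
    "StatsReport",
    "median_roi_dose",
    "interpolate_volume",
    "friedman_test",
    "pairwise_wilcoxon_holm",
    "holm_adjust",
    "bartlett_test",
    "pearson_dose_response",
    "t_summary",
    "run_stats_battery",
]

METHODS = ["5cm", "F3", "DST", "OPT"]


def interpolate_volume(volume: np.ndarray, affine: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a voxel volume at world-space points (mm)."""
    inv = np.linalg.inv(affine)
    ijk = np.atleast_2d(points) @ inv[:3, :3].T + inv[:3, 3]
    return map_coordinates(volume, ijk.T, order=1, mode="nearest")


def median_roi_dose(volume: np.ndarray, mask: RoiMask, affine: np.ndarray | None = None) -> float:
    """Median |E| (V/m) over mask voxel centres.

    ``volume`` is an |E| lattice; if its affine differs from the mask's,
    values are trilinearly interpolated at the mask voxel centres.
    """
    if mask.n_voxels == 0:
        raise ValueError("empty mask")
    if affine is None or np.allclose(affine, mask.affine):
        if volume.shape != mask.data.shape:
            raise ValueError("volume and mask grids differ; pass the volume affine")
        vals = volume[mask.data]
    else:
        vals = interpolate_volume(volume, affine, mask.voxel_centers)
    return float(np.median(vals))


def friedman_test(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square over an n x k within-subject dose matrix.

    Average ranks for ties; chi-square approximation with k-1 df.
    Identical columns give chi2 = 0 (p = 1).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a complete n x k matrix with n, k >= 2")
    if np.isnan(m).any():
        raise ValueError("matrix must be complete")
    if np.allclose(m, m[:, [0]]):
        return 0.0, 1.0
    chi2, p = sps.friedmanchisquare(*(m[:, j] for j in range(m.shape[1])))
    return float(chi2), float(p)


def holm_adjust(pvals: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (n - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def _wilcoxon_pair(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p; zero differences dropped (Wilcoxon's
    treatment), exact null for n <= 25 without ties."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    if len(d) == 0:
        import warnings

        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    n = len(d)
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    return float(sps.wilcoxon(d, method=method, correction=(method == "approx")).pvalue)


def pairwise_wilcoxon_holm(matrix: np.ndarray, labels: list[str] | None = None) -> pd.DataFrame:
    """All pairwise Wilcoxon signed-rank tests with Holm adjustment."""
    m = np.asarray(matrix, dtype=float)
    if m.shape[0] < 2:
        raise ValueError("need n >= 2 subjects")
    k = m.shape[1]
    labels = labels or [f"col{j}" for j in range(k)]
    pairs = list(combinations(range(k), 2))
    raw = np.array([_wilcoxon_pair(m[:, i], m[:, j]) for i, j in pairs])
    adj = holm_adjust(raw)
    return pd.DataFrame(
        {
            "pair": [f"{labels[i]} vs {labels[j]}" for i, j in pairs],
            "p_raw": raw,
            "p_holm": adj,
        }
    )


def bartlett_test(columns: list[np.ndarray] | np.ndarray) -> tuple[float, float]:
    """Bartlett K^2 statistic and p for homogeneity of variances."""
    if isinstance(columns, np.ndarray) and columns.ndim == 2:
        columns = [columns[:, j] for j in range(columns.shape[1])]
    if len(columns) < 2 or any(len(c) < 2 for c in columns):
        raise ValueError("need >= 2 groups with n >= 2 each")
    if any(np.var(np.asarray(c, float), ddof=1) == 0 for c in columns):
        raise ValueError(
            "a group has zero variance; Bartlett's statistic is undefined "
            "(add variability or drop the degenerate group)"
        )
    k2, p = sps.bartlett(*columns)
    return float(k2), float(p)


def pearson_dose_response(doses: np.ndarray, cdrs_changes: np.ndarray) -> tuple[float, float]:
    """Pearson r (t-based two-sided p) between dose and symptom change."""
    x = np.asarray(doses, float)
    y = np.asarray(cdrs_changes, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in dose or outcome")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def t_summary(mean: float, sd: float, n: int, mu0: float) -> tuple[float, float]:
    """One-sample t test from summary statistics, two-sided p (df = n-1)."""
    if n < 2:
        raise ValueError("need n >= 2")
    if sd <= 0:
        raise ValueError("sd must be positive")
    t = (mean - mu0) / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


@dataclass
class StatsReport:
    friedman_chi2: float
    friedman_p: float
    pairwise: pd.DataFrame
    bartlett_k2: float
    bartlett_p: float
    pearson_r_magnitude: float | None = None
    pearson_p_magnitude: float | None = None
    pearson_r_normal: float | None = None
    pearson_p_normal: float | None = None
    t_motor: float | None = None
    p_motor: float | None = None

    def to_dict(self) -> dict:
        d = {
            "friedman_chi2": self.friedman_chi2,
            "friedman_p": self.friedman_p,
            "pairwise_wilcoxon_holm": self.pairwise.to_dict(orient="records"),
            "bartlett_k2": self.bartlett_k2,
            "bartlett_p": self.bartlett_p,
        }
        for k in ("pearson_r_magnitude", "pearson_p_magnitude", "pearson_r_normal",
                  "pearson_p_normal", "t_motor", "p_motor"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


def run_stats_battery(
    dose_table: pd.DataFrame,
    methods: list[str] = METHODS,
    dose_response: tuple[np.ndarray, np.ndarray] | None = None,
    normal_response: tuple[np.ndarray, np.ndarray] | None = None,
    motor_summary: tuple[float, float, int, float] | None = None,
) -> StatsReport:
    """Run the full battery on a per-subject dose table (columns = methods)."""
    m = dose_table[methods].to_numpy(dtype=float)
    chi2, p_f = friedman_test(m)
    pw = pairwise_wilcoxon_holm(m, labels=methods)
    k2, p_b = bartlett_test(m)
    rep = StatsReport(
        friedman_chi2=chi2, friedman_p=p_f, pairwise=pw,
        bartlett_k2=k2, bartlett_p=p_b,
    )
    if dose_response is not None:
        rep.pearson_r_magnitude, rep.pearson_p_magnitude = pearson_dose_response(*dose_response)
    if normal_response is not None:
        rep.pearson_r_normal, rep.pearson_p_normal = pearson_dose_response(*normal_response)
    if motor_summary is not None:
        rep.t_motor, rep.p_motor = t_summary(*motor_summary)
    return rep
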