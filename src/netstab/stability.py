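"""Inter-session stability statistics.

Lin's concordance correlation coefficient (CCC) quantifies the agreement of
paired measurements against the 45-degree identity line:

    rho_c = 2*cov(x, y) / (var(x) + var(y) + (mu_y - mu_x)^2)

with population (1/n) moments. It factors into precision times accuracy,
rho_c = chi_a * rho, where rho is the Pearson correlation and

    chi_a = 2 / (w + 1/w + v^2),  w = sd_y/sd_x,  v^2 = (mu_y-mu_x)^2/(sd_x*sd_y),

so chi_a <= 1 penalizes location and scale shifts that plain correlation
ignores. The sample counterpart r_c uses the same form with sample
statistics (any common normalization cancels, so r_c == rho_c).

Applied here per subject: the CCC between the two sessions' voxel values of
a standardized+smoothed metric map within a network mask, and the Spearman
rank correlation between the two sessions' internetwork Fisher-z blocks.
Multiplicity is handled by a Bonferroni-adjusted alpha for the CCC family
and Benjamini-Hochberg FDR for the Spearman family; magnitudes are labelled
on the Dancey-Reidy scale (weak < .40, moderate .40-.69, strong .70-.99,
perfect 1.00).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import MetricMap

__all__ = [
    "CCCResult",
    "StabilityRecord",
    "AggregateRow",
    "ccc",
    "voxel_ccc",
    "bonferroni_alpha",
    "spearman_stability",
    "fdr_correct",
    "label_strength",
    "aggregate",
]


@dataclass
class CCCResult:
    """Lin's CCC with its accuracy/precision decomposition and CI."""

    rho_c: float
    precision_rho: float
    accuracy_chi: float
    location_v2: float
    scale_omega: float
    mu_x: float
    mu_y: float
    var_x: float
    var_y: float
    cov_xy: float
    n: int
    ci_low: float
    ci_high: float
    alpha: float


@dataclass
class StabilityRecord:
    """One stability estimate: a subject x network x metric CCC, or a
    subject x network-pair Spearman coefficient."""

    subject_id: str
    unit: str               # network, or "DMN/SN"-style pair
    measure: str            # metric name for CCC; pair name repeated for Spearman
    estimate: float
    p_value: float = np.nan
    corrected: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            self.label = label_strength(self.estimate)


@dataclass
class AggregateRow:
    unit: str
    measure: str
    mean: float
    sd: float
    min: float
    max: float
    n_subjects: int
    single_subject: bool = False


def ccc(x: np.ndarray, y: np.ndarray, alpha: float = 0.00026) -> CCCResult:
    """Lin's concordance correlation coefficient between paired vectors.

    Moments use population (1/n) normalization. The confidence interval
    follows Lin's asymptotic method: Fisher z-transform of r_c, normal
    standard error, back-transformed; ``alpha`` defaults to the
    Bonferroni-adjusted 0.05/192 of a 16-subject x 4-metric x 3-network
    family.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")

    mu_x, mu_y = x.mean(), y.mean()
    var_x = ((x - mu_x) ** 2).mean()
    var_y = ((y - mu_y) ** 2).mean()
    cov_xy = ((x - mu_x) * (y - mu_y)).mean()

    if var_x == 0 and var_y == 0:
        raise ValueError("CCC undefined: both inputs are constant")
    if var_x == 0 or var_y == 0:
        # degenerate: no covariation possible; concordance collapses to 0
        rho_c, rho, chi_a = 0.0, 0.0, 0.0
        omega = np.inf if var_x == 0 else 0.0
        v2 = np.inf
        ci_low = ci_high = np.nan
        return CCCResult(rho_c, rho, chi_a, v2, omega, mu_x, mu_y,
                         var_x, var_y, cov_xy, n, ci_low, ci_high, alpha)

    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)
    rho_c = 2.0 * cov_xy / (var_x + var_y + (mu_y - mu_x) ** 2)
    rho = cov_xy / (sd_x * sd_y)
    omega = sd_y / sd_x
    v2 = (mu_y - mu_x) ** 2 / (sd_x * sd_y)
    chi_a = 2.0 / (omega + 1.0 / omega + v2)

    ci_low, ci_high = _lin_ci(rho_c, rho, v2, n, alpha)
    return CCCResult(rho_c, rho, chi_a, v2, omega, mu_x, mu_y,
                     var_x, var_y, cov_xy, n, ci_low, ci_high, alpha)


def _lin_ci(rc: float, r: float, v2: float, n: int, alpha: float) -> tuple[float, float]:
    """Lin (1989) asymptotic CI on the Fisher-z scale, back-transformed."""
    if n < 4 or abs(rc) >= 1.0 or r == 0:
        return np.nan, np.nan
    # u = (mu_y - mu_x) / sqrt(sd_x * sd_y), hence u^2 equals the location shift v^2
    u2 = v2
    se2 = (
        (1 - r**2) * rc**2 / ((1 - rc**2) * r**2)
        + 4 * rc**3 * (1 - rc) * u2 / (r * (1 - rc**2) ** 2)
        - 2 * rc**4 * u2**2 / (r**2 * (1 - rc**2) ** 2)
    ) / (n - 2)
    if se2 <= 0:
        return np.nan, np.nan
    z = np.arctanh(rc)
    half = stats.norm.ppf(1 - alpha / 2) * np.sqrt(se2)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def sample_ccc(x: np.ndarray, y: np.ndarray) -> float:
    """Sample counterpart r_c computed with n-1 statistics.

    Algebraically identical to the population form — the normalization
    cancels between numerator and denominator except through the squared
    mean difference, which is normalization-free — kept as an independent
    code path for cross-checking.
    """
    x = np.asarray(x, dtype=np.float64).ravel()
    y = np.asarray(y, dtype=np.float64).ravel()
    sx2 = x.var(ddof=1)
    sy2 = y.var(ddof=1)
    r = stats.pearsonr(x, y).statistic
    # r*sx*sy is the sample covariance; rescale to the 1/n population moments
    n = x.size
    scale = (n - 1) / n
    return float(
        2.0 * r * np.sqrt(sx2 * sy2) * scale
        / (sx2 * scale + sy2 * scale + (y.mean() - x.mean()) ** 2)
    )


def voxel_ccc(
    map_s1: MetricMap,
    map_s2: MetricMap,
    network_mask: np.ndarray,
    alpha: float = 0.00026,
) -> CCCResult:
    """Subject-level voxel-based CCC of a metric between two sessions.

    Pairs the two sessions' values voxel-by-voxel over the network mask,
    dropping voxels flagged with the sentinel in either session.
    """
    if map_s1.values.shape != map_s2.values.shape:
        raise ValueError("session maps must share a grid")
    if map_s1.metric_name != map_s2.metric_name:
        raise ValueError("session maps must hold the same metric")
    network_mask = np.asarray(network_mask).astype(bool)
    if network_mask.shape != map_s1.values.shape:
        raise ValueError("network mask shape mismatch")
    usable = network_mask & map_s1.valid_mask() & map_s2.valid_mask()
    if usable.sum() < 10:
        raise ValueError(f"only {int(usable.sum())} usable voxels (< 10)")
    return ccc(map_s1.values[usable], map_s2.values[usable], alpha=alpha)


def bonferroni_alpha(base_alpha: float = 0.05, n_tests: int = 1) -> float:
    """Bonferroni-adjusted per-test significance level: base_alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return base_alpha / n_tests


def spearman_stability(
    block_s1: np.ndarray,
    block_s2: np.ndarray,
    method: str = "t",
) -> tuple[float, float]:
    """Spearman rank correlation between two sessions' connectivity blocks.

    Average ranks on ties; two-sided p-value from the t-approximation
    (``method="t"``), or by exact enumeration of all pairings
    (``method="exact"``, n <= 10 only — chosen over the approximation when
    a handful of connectivity values make the t reference dubious).
    """
    x = np.asarray(block_s1, dtype=np.float64).ravel()
    y = np.asarray(block_s2, dtype=np.float64).ravel()
    if x.shape != y.shape or x.size < 5:
        raise ValueError("blocks must have equal length >= 5")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant connectivity block")
    res = stats.spearmanr(x, y)
    rho = float(res.statistic)
    if method == "t":
        return rho, float(res.pvalue)
    if method == "exact":
        return rho, _exact_spearman_p(x, y, rho)
    raise ValueError(f"unknown method {method!r}")


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p over all n! pairings (n <= 10)."""
    n = x.size
    if n > 10:
        raise ValueError("exact enumeration limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum() * ((ry - ry.mean()) ** 2).sum())
    count = total = 0
    chunk: list[tuple[int, ...]] = []

    def flush(chunk: list[tuple[int, ...]]) -> int:
        perms = np.array(chunk)
        rhos = (rx_c @ (ry[perms] - ry.mean()).T) / denom
        return int((np.abs(rhos) >= abs(rho_obs) - 1e-12).sum())

    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        total += 1
        if len(chunk) == 100_000:
            count += flush(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
    return count / total


def fdr_correct(p_values: np.ndarray, q: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns (reject flags, adjusted p-values); adjusted p's are monotone
    nondecreasing in raw-p rank order.
    """
    p = np.asarray(p_values, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def label_strength(coefficient: float) -> str:
    """Dancey-Reidy label for a correlation-scale coefficient.

    Applied to the magnitude after half-even rounding to 2 decimals (the
    scale is defined on printed 2-decimal values): weak < .40, moderate
    .40-.69, strong .70-.99, perfect 1.00. Negative coefficients keep
    their sign in reports; only the magnitude is labelled.
    """
    if not -1.0 <= coefficient <= 1.0 + 1e-12:
        raise ValueError("coefficient must lie in [-1, 1]")
    m = abs(round(float(coefficient), 2))
    if m >= 1.0:
        return "perfect"
    if m >= 0.70:
        return "strong"
    if m >= 0.40:
        return "moderate"
    return "weak"


def aggregate(records: list[StabilityRecord]) -> list[AggregateRow]:
    """Group stability records by (unit, measure) and summarize.

    Mean, SD (n-1 denominator), min, max per group, at full precision;
    rounding to the 2 printed decimals happens only at report time. A
    single-record group gets SD 0 with a flag.
    """
    if not records:
        raise ValueError("no records to aggregate")
    df = pd.DataFrame(
        {
            "unit": [r.unit for r in records],
            "measure": [r.measure for r in records],
            "estimate": [r.estimate for r in records],
        }
    )
    rows = []
    for (unit, measure), grp in df.groupby(["unit", "measure"], sort=False):
        vals = grp["estimate"].to_numpy()
        single = vals.size == 1
        rows.append(
            AggregateRow(
                unit=unit,
                measure=measure,
                mean=float(vals.mean()),
                sd=0.0 if single else float(vals.std(ddof=1)),
                min=float(vals.min()),
                max=float(vals.max()),
                n_subjects=int(vals.size),
                single_subject=single,
            )
        )
    return rows
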