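"""Feature-validity statistics for the two-group cohort.

Per feature: an independent-samples t-test (Welch by default, pooled
Student's as an option) with Bonferroni correction over the 14 features,
Cohen's d with the convention d = (mean_control - mean_T2DM) / pooled SD,
and a histogram distribution-difference statistic (half the L1 distance
between the two groups' normalized histograms — the discrete total
variation distance).

The accompanying voice-information model quantifies how much acoustic
evidence the recording protocol yields per screening decision.  Knowing a
person's disease status is one binary outcome, I_same = log2(2) = 1 bit;
a cohort of N people each contributing 14 features recorded twice carries
I = log2(14 * 2 * N) bits, so the required per-unit discrimination is the
ratio eta(N) = 1 / (log2(N) + C) with C = log2(28), displayed and
evaluated (by convention of the source model) at two decimals, C = 4.81.
A feature's distribution-difference statistic should exceed eta(N) for the
feature to carry enough group information at that cohort scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import VDT2Error
from .features import FEATURE_NAMES, GROUP_CONTROL, GROUP_T2DM

__all__ = [
    "ValidityRow",
    "DistributionDiff",
    "InfoModel",
    "group_ttest",
    "bonferroni",
    "cohens_d",
    "distribution_diff",
    "info_eta",
    "meets_threshold",
    "validity_report",
]

#: Number of acoustic features, the Bonferroni family size.
N_FEATURES = 14
#: Recordings per vowel per person in the protocol.
RECORDINGS_PER_PERSON = 2


@dataclass
class ValidityRow:
    feature: str
    p_raw: float
    p_bonf: float
    cohens_d: float


@dataclass
class DistributionDiff:
    """Shared-grid histograms of the two groups and their difference.

    ``tv`` is half the L1 distance between the per-bin proportions, in
    [0, 1]; ``degenerate`` flags an all-equal pooled sample (tv = 0 by
    convention).
    """

    bin_edges: np.ndarray
    f_control: np.ndarray
    f_t2dm: np.ndarray
    tv: float
    degenerate: bool = False


def group_ttest(x_control, x_t2dm, variant: str = "welch") -> float:
    """Two-sided independent-samples t-test p-value.

    ``variant`` selects Welch's unequal-variance test (default; group sizes
    and spreads differ) or Student's pooled test.  Two constant groups with
    equal means return p = 1 by convention.
    """
    x_control = np.asarray(x_control, dtype=float)
    x_t2dm = np.asarray(x_t2dm, dtype=float)
    if len(x_control) < 2 or len(x_t2dm) < 2:
        raise VDT2Error("each group needs at least 2 values")
    if variant not in ("welch", "student"):
        raise VDT2Error(f"unknown t-test variant {variant!r}")
    if x_control.std() == 0 and x_t2dm.std() == 0:
        return 1.0 if x_control.mean() == x_t2dm.mean() else 0.0
    res = sps.ttest_ind(x_control, x_t2dm, equal_var=(variant == "student"))
    return float(res.pvalue)


def bonferroni(p_raw: float, m: int = N_FEATURES) -> float:
    """Family-wise corrected p-value: min(1, m * p_raw)."""
    if not 0.0 <= p_raw <= 1.0:
        raise VDT2Error("p_raw must be in [0, 1]")
    return min(1.0, m * p_raw)


def cohens_d(x_control, x_t2dm) -> float:
    """Standardized mean difference, control minus T2DM over pooled SD.

    Positive when the control group is higher (e.g. meanF0), negative for
    measures elevated in patients (jitter/shimmer).
    """
    x1 = np.asarray(x_control, dtype=float)
    x2 = np.asarray(x_t2dm, dtype=float)
    n1, n2 = len(x1), len(x2)
    if n1 < 2 or n2 < 2:
        raise VDT2Error("each group needs at least 2 values")
    pooled_var = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (
        n1 + n2 - 2
    )
    if pooled_var == 0:
        raise VDT2Error("zero pooled SD: Cohen's d undefined")
    return float((x1.mean() - x2.mean()) / np.sqrt(pooled_var))


def distribution_diff(x_control, x_t2dm, n_bins: int = 20) -> DistributionDiff:
    """Histogram total-variation statistic on a shared equal-width grid.

    Both samples are binned over the pooled [min, max] range; the statistic
    is half the L1 distance between the per-group bin proportions.
    """
    x1 = np.asarray(x_control, dtype=float)
    x2 = np.asarray(x_t2dm, dtype=float)
    if len(x1) == 0 or len(x2) == 0:
        raise VDT2Error("both groups must be nonempty")
    if n_bins < 2:
        raise VDT2Error("n_bins must be >= 2")
    pooled = np.concatenate([x1, x2])
    lo, hi = pooled.min(), pooled.max()
    if lo == hi:
        edges = np.linspace(lo - 0.5, hi + 0.5, n_bins + 1)
        flat = np.histogram(x1, bins=edges)[0] / len(x1)
        return DistributionDiff(edges, flat, flat, tv=0.0, degenerate=True)
    edges = np.linspace(lo, hi, n_bins + 1)
    f1 = np.histogram(x1, bins=edges)[0] / len(x1)
    f2 = np.histogram(x2, bins=edges)[0] / len(x2)
    tv = 0.5 * float(np.abs(f1 - f2).sum())
    return DistributionDiff(edges, f1, f2, tv=tv)


def _info_constant(exact_constant: bool) -> float:
    c = np.log2(N_FEATURES * RECORDINGS_PER_PERSON)  # log2(28)
    return float(c) if exact_constant else round(float(c), 2)


@dataclass
class InfoModel:
    """Voice-information quantities at group size N."""

    n: int
    i_same: float
    i_diabetes: float
    eta: float


def info_eta(n: int, exact_constant: bool = False) -> float:
    """Information-efficiency ratio eta(N) = 1 / (log2(N) + C).

    By default C is the conventional two-decimal constant 4.81
    (= round(log2(28), 2)), which reproduces the reference percentages
    eta(1) = 20.79% and eta(50) = 9.57%; ``exact_constant=True`` keeps
    C = log2(28) at full precision.
    """
    if not float(n).is_integer() or n < 1:
        raise VDT2Error("group size N must be an integer >= 1")
    c = _info_constant(exact_constant)
    return 1.0 / (np.log2(n) + c)


def info_model(n: int, exact_constant: bool = False) -> InfoModel:
    c = _info_constant(exact_constant)
    return InfoModel(
        n=int(n),
        i_same=1.0,
        i_diabetes=float(np.log2(n) + c),
        eta=info_eta(n, exact_constant),
    )


def meets_threshold(diff: DistributionDiff, n: int) -> bool:
    """Whether a feature's distribution difference reaches the
    information-model threshold eta(N)."""
    return diff.tv >= info_eta(n)


def validity_report(
    cohort: pd.DataFrame,
    variant: str = "welch",
    n_bins: int = 20,
    group_size: int | None = None,
    per_vowel: bool = False,
    group_col: str = "group",
) -> pd.DataFrame:
    """Per-feature validity table for a two-group cohort.

    One row per feature (pooled over vowels by default; ``per_vowel=True``
    yields one row per (vowel, feature)): raw and Bonferroni-corrected
    (m = 14) t-test p-values, Cohen's d, the distribution-difference
    statistic ``tv`` and — when ``group_size`` is given — the eta(N)
    threshold and verdict.
    """
    groups = set(cohort[group_col].unique())
    if not {GROUP_T2DM, GROUP_CONTROL} <= groups:
        raise VDT2Error(
            f"cohort must contain both {GROUP_T2DM!r} and {GROUP_CONTROL!r} rows"
        )

    def one_block(df: pd.DataFrame, extra: dict) -> list[dict]:
        ctrl = df[df[group_col] == GROUP_CONTROL]
        t2dm = df[df[group_col] == GROUP_T2DM]
        out = []
        for feat in FEATURE_NAMES:
            x1, x2 = ctrl[feat].to_numpy(), t2dm[feat].to_numpy()
            p = group_ttest(x1, x2, variant)
            diff = distribution_diff(x1, x2, n_bins)
            row = {
                **extra,
                "feature": feat,
                "p_raw": p,
                "p_bonf": bonferroni(p, N_FEATURES),
                "cohens_d": cohens_d(x1, x2),
                "tv": diff.tv,
            }
            if group_size is not None:
                row["eta"] = info_eta(group_size)
                row["meets_threshold"] = meets_threshold(diff, group_size)
            out.append(row)
        return out

    rows: list[dict] = []
    if per_vowel:
        for vowel, block in cohort.groupby("vowel"):
            rows.extend(one_block(block, {"vowel": vowel}))
    else:
        rows.extend(one_block(cohort, {}))
    return pd.DataFrame(rows)
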