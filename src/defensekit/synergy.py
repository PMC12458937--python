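"""Synergy statistics for pairs of co-encoded defense systems.

Two complementary definitions are implemented:

* the **epistatic coefficient** epsilon on plating efficiencies,
  ``|log10 EOP_both| - |log10 EOP_a| - |log10 EOP_b|``, zeroed when the
  wild-type strain shows no meaningful protection (mean WT EOP >= 1e-2).
  For EOPs <= 1 this equals ``log10(EOP_a * EOP_b / EOP_both)``: epsilon is 0
  exactly when the two systems multiply, positive when their combination
  protects super-multiplicatively;

* the **AUC synergy call** on liquid growth curves: baseline-subtracted
  areas under the OD600 curve, with synergy declared when the AUC of the
  strain carrying both systems strictly exceeds the sum of the single-system
  AUCs (the expected additive value).

Reporter-dye normalization (propidium iodide, resazurin: RLU/OD600 with an
OD floor), pointwise t confidence bands for replicate curves, the one-sided
Welch t-test with a normality pre-check, and one-way ANOVA with all-vs-control
(Dunnett) correction round out the statistical machinery.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import DEFAULTS

logger = logging.getLogger("defensekit")


# ---------------------------------------------------------------------------
# Epistatic coefficient
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EpistasisResult:
    epsilon: float
    components: tuple[float, float, float]  # (eop_both, eop_a, eop_b)
    zeroed: bool
    wt_mean_eop: float
    #: the epsilon value the formula would give, kept for diagnostics even
    #: when the zeroing rule applies
    epsilon_raw: float = float("nan")
    #: set when any input EOP was a censored bound; the sign records whether
    #: the true epsilon is at least (+1) or at most (-1) the reported value
    bound_direction: int = 0


def epistatic_coefficient(
    eop_both: float,
    eop_a: float,
    eop_b: float,
    wt_mean_eop: float,
    wt_eop_threshold: float = DEFAULTS["synergy"]["epsilon_wt_eop_threshold"],
    both_censored: bool = False,
) -> EpistasisResult:
    """Interaction strength between two defense systems from their EOPs.

    epsilon = |log10 eop_both| - |log10 eop_a| - |log10 eop_b|, set to 0
    (``zeroed``) when ``wt_mean_eop >= wt_eop_threshold`` — i.e. when the
    strain carrying both systems shows no meaningful reduction in plaque
    formation, no interaction is scored.  ``both_censored`` marks
    ``eop_both`` as an upper bound, which makes the reported epsilon a lower
    bound (``bound_direction=+1``).
    """
    for name, v in (("eop_both", eop_both), ("eop_a", eop_a), ("eop_b", eop_b),
                    ("wt_mean_eop", wt_mean_eop)):
        if not (v > 0):
            raise ValueError(f"{name} must be positive, got {v!r}")
    raw = (
        abs(math.log10(eop_both))
        - abs(math.log10(eop_a))
        - abs(math.log10(eop_b))
    )
    direction = 1 if both_censored else 0
    if wt_mean_eop >= wt_eop_threshold:
        return EpistasisResult(
            0.0, (eop_both, eop_a, eop_b), True, wt_mean_eop, raw, direction
        )
    return EpistasisResult(
        raw, (eop_both, eop_a, eop_b), False, wt_mean_eop, raw, direction
    )


# ---------------------------------------------------------------------------
# Growth curves and AUC synergy
# ---------------------------------------------------------------------------


class AUCSynergyCall(NamedTuple):
    auc_both: float
    auc_a: float
    auc_b: float
    expected_additive: float
    synergy: bool


def baseline_subtract(curve: Sequence[float]) -> np.ndarray:
    """Subtract the optical density at the start from every data point."""
    arr = np.asarray(curve, dtype=float)
    if arr.size == 0:
        raise ValueError("empty curve")
    return arr - arr[..., :1] if arr.ndim > 1 else arr - arr[0]


def area_under_curve(curve: Sequence[float], time_min: Sequence[float]) -> float:
    """Trapezoid-rule AUC of a (baseline-subtracted) curve, in OD600·hour."""
    y = np.asarray(curve, dtype=float)
    t = np.asarray(time_min, dtype=float)
    if y.shape != t.shape:
        raise ValueError(f"curve length {y.shape} != time length {t.shape}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_min must be strictly increasing")
    return float(np.trapezoid(y, t) / 60.0)


def call_auc_synergy(auc_both: float, auc_a: float, auc_b: float) -> AUCSynergyCall:
    """Synergy iff AUC(both) strictly exceeds AUC(a) + AUC(b); ties are not
    synergy."""
    expected = auc_a + auc_b
    return AUCSynergyCall(auc_both, auc_a, auc_b, expected, auc_both > expected)


def normalize_reporter(
    fluorescence_rlu: Sequence[float],
    od600: Sequence[float],
    floor_od: float = DEFAULTS["synergy"]["reporter_od_floor"],
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize a reporter-dye signal to OD600 with a denominator floor.

    Returns ``(rlu / max(od, floor_od), flagged)`` where ``flagged`` marks the
    points whose OD fell below the floor (e.g. after lysis) and were clamped.
    """
    rlu = np.asarray(fluorescence_rlu, dtype=float)
    od = np.asarray(od600, dtype=float)
    if rlu.shape != od.shape:
        raise ValueError("fluorescence and OD series differ in length")
    flagged = od < floor_od
    return rlu / np.maximum(od, floor_od), flagged


def replicate_band(
    replicates: Sequence[Sequence[float]], level: float = 0.95
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise mean and symmetric t confidence band across replicate curves.

    With n replicates the half-width at each time point is
    ``t_{1-(1-level)/2, n-1} * sd / sqrt(n)``.
    """
    arr = np.asarray(replicates, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError(
            "need >= 2 replicates on a shared grid; plot the raw curve instead"
        )
    n = arr.shape[0]
    mean = arr.mean(axis=0)
    sd = arr.std(axis=0, ddof=1)
    tcrit = stats.t.ppf(0.5 + level / 2.0, df=n - 1)
    half = tcrit * sd / math.sqrt(n)
    return mean, mean - half, mean + half


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------


class OneSidedTestResult(NamedTuple):
    statistic: float
    p_value: float
    normality_p: tuple[float, float]


def one_sided_greater_test(
    x: Sequence[float], y: Sequence[float]
) -> OneSidedTestResult:
    """Welch unpaired t-test of mean(x) > mean(y), with a normality pre-check.

    Shapiro-Wilk is run on each sample and its p-values are reported; a
    failed check (p < 0.05) emits a warning but never silently switches the
    test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # Shapiro warns for tiny n / ties
        px = float(stats.shapiro(x).pvalue) if len(set(x)) > 1 else 1.0
        py = float(stats.shapiro(y).pvalue) if len(set(y)) > 1 else 1.0
    if min(px, py) < 0.05:
        warnings.warn(
            f"normality check failed (Shapiro p = {px:.3g}, {py:.3g}); "
            "t-test reported anyway",
            stacklevel=2,
        )
    res = stats.ttest_ind(x, y, equal_var=False, alternative="greater")
    return OneSidedTestResult(float(res.statistic), float(res.pvalue), (px, py))


def anova_multcomp(
    groups: Mapping[str, Sequence[float]],
    control: str,
    method: str = DEFAULTS["synergy"]["multcomp_method"],
    alpha: float = DEFAULTS["synergy"]["alpha"],
) -> tuple[float, float, pd.DataFrame]:
    """One-way ANOVA plus all-vs-control comparisons with FWER correction.

    Returns ``(F, p_anova, table)`` where ``table`` has one row per
    non-control group with columns ``group, statistic, p_unadjusted,
    p_adjusted, significant``.  ``method`` is ``"dunnett"`` (default; the
    natural choice when every group is compared to one control) or
    ``"holm"`` (Welch pairwise t-tests with Holm step-down).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if control not in groups:
        raise KeyError(f"control group {control!r} not among {sorted(groups)}")
    samples = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in samples.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    f_stat, p_anova = stats.f_oneway(*samples.values())

    names = [k for k in samples if k != control]
    ctrl = samples[control]
    if method == "dunnett":
        res = stats.dunnett(*[samples[k] for k in names], control=ctrl)
        n_total = sum(len(v) for v in samples.values())
        df = n_total - len(samples)
        p_unadj = 2.0 * stats.t.sf(np.abs(res.statistic), df=df)
        table = pd.DataFrame(
            {
                "group": names,
                "statistic": res.statistic,
                "p_unadjusted": p_unadj,
                "p_adjusted": res.pvalue,
            }
        )
    elif method == "holm":
        from statsmodels.stats.multitest import multipletests

        stats_, praw = [], []
        for k in names:
            r = stats.ttest_ind(samples[k], ctrl, equal_var=False)
            stats_.append(float(r.statistic))
            praw.append(float(r.pvalue))
        _, padj, _, _ = multipletests(praw, alpha=alpha, method="holm")
        table = pd.DataFrame(
            {
                "group": names,
                "statistic": stats_,
                "p_unadjusted": praw,
                "p_adjusted": padj,
            }
        )
    else:
        raise ValueError(f"unknown multiple-comparison method {method!r}")
    table["significant"] = table["p_adjusted"] < alpha
    return float(f_stat), float(p_anova), table
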