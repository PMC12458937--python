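"""Titers, efficiency of plating (EOP), plaque-size fold change, and
protection classification from spot-dilution plaque assays.

A titer is quantified from the most dilute spot whose plaque count falls in a
countable window (default 3-100 plaques).  Spots that cleared the lawn without
distinct plaques ("lysis halos") are quantified from the most dilute
halo-positive spot with the count taken as >= 1 and flagged.  All-zero series
yield a censored estimate reported as a limit of detection.

EOP is the ratio of the test-strain titer to the reference-strain titer;
log-protection is -log10(EOP), i.e. the orders of magnitude by which the
defense system reduces the phage titer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import DEFAULTS

logger = logging.getLogger("defensekit")


@dataclass(frozen=True)
class TiterEstimate:
    """A phage titer in PFU/ml, possibly censored below the detection limit."""

    value_pfu_per_ml: float | None
    censored: bool
    lod_pfu_per_ml: float
    lysis_halo_quantified: bool = False
    #: plaque count and dilution factor of the spot actually quantified
    counted_plaques: float | None = None
    counted_dilution: float | None = None

    def __post_init__(self) -> None:
        if self.censored:
            if self.value_pfu_per_ml is not None:
                raise ValueError("censored titer must not carry a value")
        elif not (self.value_pfu_per_ml and self.value_pfu_per_ml > 0):
            raise ValueError("uncensored titer must be positive")


@dataclass(frozen=True)
class EOPResult:
    """Efficiency of plating relative to a reference strain.

    When the test titer is censored, ``eop`` is an *upper bound*
    (``censored_eop`` True) and ``log_protection`` the corresponding lower
    bound.
    """

    eop: float
    censored_eop: bool
    log_protection: float
    sfc: float | None = None
    lysis_halo_quantified: bool = False


def estimate_titer(
    rows: pd.DataFrame,
    count_window: tuple[int, int] | None = None,
) -> TiterEstimate:
    """Estimate a titer from one phage x strain x replicate dilution series.

    ``rows`` needs columns ``dilution_factor, spot_volume_ml, plaque_count,
    is_halo``.  titer = count / (spot_volume_ml * dilution_factor) at the most
    dilute spot with a count inside ``count_window``; if no spot is in the
    window but plaques were seen, the most dilute spot with >= 1 plaque is
    used; if only halos, the most dilute halo-positive spot with count >= 1
    (flagged); if everything is zero, a censored estimate at
    lod = 1 / (spot_volume_ml * lowest dilution).
    """
    if count_window is None:
        lo, hi = DEFAULTS["plaque"]["count_window"]
    else:
        lo, hi = count_window
    if len(rows) == 0:
        raise ValueError("empty dilution series")
    dil = rows["dilution_factor"].to_numpy(dtype=float)
    if len(np.unique(dil)) != len(dil):
        dupes = sorted({d for d in dil if (dil == d).sum() > 1})
        raise ValueError(f"conflicting duplicate dilutions: {dupes}")

    order = np.argsort(dil)  # most dilute first
    counts = rows["plaque_count"].to_numpy(dtype=float)[order]
    halos = rows["is_halo"].to_numpy(dtype=bool)[order]
    vols = rows["spot_volume_ml"].to_numpy(dtype=float)[order]
    dil = dil[order]

    countable = ~halos & (counts >= lo) & (counts <= hi)
    if countable.any():
        i = int(np.argmax(countable))
        return TiterEstimate(
            float(counts[i] / (vols[i] * dil[i])), False, _lod(vols, dil),
            counted_plaques=float(counts[i]), counted_dilution=float(dil[i]),
        )
    positive = ~halos & (counts >= 1)
    if positive.any():
        i = int(np.argmax(positive))
        return TiterEstimate(
            float(counts[i] / (vols[i] * dil[i])), False, _lod(vols, dil),
            counted_plaques=float(counts[i]), counted_dilution=float(dil[i]),
        )
    if halos.any():
        i = int(np.argmax(halos))
        return TiterEstimate(
            float(1.0 / (vols[i] * dil[i])), False, _lod(vols, dil),
            lysis_halo_quantified=True,
            counted_plaques=1.0, counted_dilution=float(dil[i]),
        )
    return TiterEstimate(None, True, _lod(vols, dil))


def _lod(vols: np.ndarray, dil: np.ndarray) -> float:
    # one plaque at the least dilute (largest dilution_factor) spot: the
    # lowest dilution examined sets the detection limit
    i = int(np.argmax(dil))
    return float(1.0 / (vols[i] * dil[i]))


def efficiency_of_plating(
    test: TiterEstimate, reference: TiterEstimate, sfc: float | None = None
) -> EOPResult:
    """EOP = test titer / reference titer, with censoring propagated.

    A censored test titer yields an upper-bound EOP of lod/reference and a
    lower-bound log-protection.  A censored reference is an error: there is
    no valid denominator.
    """
    if reference.censored:
        raise ValueError("reference titer is censored; EOP has no denominator")
    ref = reference.value_pfu_per_ml
    if test.censored:
        eop = test.lod_pfu_per_ml / ref
        return EOPResult(eop, True, -math.log10(eop), sfc=sfc)
    eop = test.value_pfu_per_ml / ref
    return EOPResult(
        eop,
        False,
        -math.log10(eop),
        sfc=sfc,
        lysis_halo_quantified=test.lysis_halo_quantified or reference.lysis_halo_quantified,
    )


def size_fold_change(
    test_radii_mm: Sequence[float],
    reference_radii_mm: Sequence[float],
    metric: str = "radius",
) -> float:
    """Plaque size fold change: mean test radius / mean reference radius.

    ``metric='area'`` compares mean squared radii instead.
    """
    if not len(test_radii_mm) or not len(reference_radii_mm):
        raise ValueError("radius lists must be non-empty")
    t = np.asarray(test_radii_mm, dtype=float)
    r = np.asarray(reference_radii_mm, dtype=float)
    if (t <= 0).any() or (r <= 0).any():
        raise ValueError("plaque radii must be positive")
    if metric == "area":
        t, r = t**2, r**2
    elif metric != "radius":
        raise ValueError(f"unknown SFC metric {metric!r}")
    return float(t.mean() / r.mean())


def classify_protection(
    log_protection: float,
    is_lower_bound: bool = False,
    threshold: float = DEFAULTS["plaque"]["protection_log_threshold"],
) -> bool:
    """True iff the titer reduction strictly exceeds 10^threshold-fold.

    A censored lower bound that already exceeds the threshold also counts as
    protection; a bound at or below it does not (indeterminate -> False).
    """
    del is_lower_bound  # a bound > threshold is conclusive either way
    return log_protection > threshold


def classify_modest_protection(
    eop: float | None = None,
    sfc: float | None = None,
    eop_threshold: float = DEFAULTS["plaque"]["modest_eop_threshold"],
    sfc_threshold: float = DEFAULTS["plaque"]["modest_sfc_threshold"],
) -> bool:
    """"At least modest protection": EOP < 0.01 or SFC < 0.5 (disjunction)."""
    if eop is None and sfc is None:
        raise ValueError("need at least one of eop, sfc")
    if eop is not None and eop < eop_threshold:
        return True
    if sfc is not None and sfc < sfc_threshold:
        return True
    return False


def eop_table(
    assays: pd.DataFrame,
    reference_strain: str,
    count_window: tuple[int, int] | None = None,
) -> pd.DataFrame:
    """Per phage x strain protection summary from a long assay table.

    Titers and EOPs are computed per replicate, then aggregated: geometric
    mean for EOP (it lives on a log scale), arithmetic mean for SFC.
    Replicates with a censored test titer make the aggregated EOP an upper
    bound (``eop_censored`` True).  Output columns: phage, strain, eop,
    eop_censored, sfc, log_protection, protected, modest_protection.
    """
    rows = []
    for (phage, strain), grp in assays.groupby(["phage", "strain"], sort=True):
        if strain == reference_strain:
            continue
        eops, censored, sfcs, halo = [], False, [], False
        for rep, sub in grp.groupby("replicate"):
            ref_rows = assays[
                (assays["phage"] == phage)
                & (assays["strain"] == reference_strain)
                & (assays["replicate"] == rep)
            ]
            if len(ref_rows) == 0:
                raise ValueError(
                    f"no reference rows for phage {phage!r} replicate {rep}"
                )
            test_t = estimate_titer(sub, count_window)
            ref_t = estimate_titer(ref_rows, count_window)
            res = efficiency_of_plating(test_t, ref_t, sfc=_replicate_sfc(sub, ref_rows))
            eops.append(res.eop)
            censored = censored or res.censored_eop
            halo = halo or res.lysis_halo_quantified
            if res.sfc is not None:
                sfcs.append(res.sfc)
        eop = float(np.exp(np.mean(np.log(eops))))
        sfc = float(np.mean(sfcs)) if sfcs else None
        logp = -math.log10(eop)
        rows.append(
            {
                "phage": phage,
                "strain": strain,
                "eop": eop,
                "eop_censored": censored,
                "sfc": sfc,
                "log_protection": logp,
                "protected": classify_protection(logp, is_lower_bound=censored),
                "modest_protection": classify_modest_protection(eop=eop, sfc=sfc),
                "lysis_halo_quantified": halo,
            }
        )
    return pd.DataFrame(rows)


def _replicate_sfc(test_rows: pd.DataFrame, ref_rows: pd.DataFrame) -> float | None:
    t = [r for v in test_rows["plaque_radii_mm"] if isinstance(v, list) for r in v]
    r = [x for v in ref_rows["plaque_radii_mm"] if isinstance(v, list) for x in v]
    if t and r:
        return size_fold_change(t, r)
    return None
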