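"""Central configuration: every threshold the pipeline applies, with defaults.

Defaults are the values used throughout the analyses (protection thresholds,
clustering identity/coverage, island grouping distance, direct-repeat scanner
bounds).  A YAML file with the same (possibly nested) keys overrides them.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path
from typing import Any, Mapping

import yaml

logger = logging.getLogger("defensekit")

#: Package-wide defaults.  Keys mirror the module that consumes them.
DEFAULTS: dict[str, Any] = {
    "plaque": {
        # countable plaque window for choosing the quantified dilution
        "count_window": [3, 100],
        # strict log10 titer-reduction threshold for "protection"
        "protection_log_threshold": 1.0,
        # "at least modest protection" thresholds (disjunction)
        "modest_eop_threshold": 0.01,
        "modest_sfc_threshold": 0.5,
        # plaque size fold change on radii ("radius") or areas ("area")
        "sfc_metric": "radius",
    },
    "synergy": {
        # WT mean EOP at or above which epsilon is zeroed
        "epsilon_wt_eop_threshold": 1e-2,
        # OD600 floor for reporter-dye normalization
        "reporter_od_floor": 0.01,
        # confidence level of replicate bands
        "band_level": 0.95,
        # all-vs-control family-wise correction: "dunnett" or "holm"
        "multcomp_method": "dunnett",
        "alpha": 0.05,
    },
    "islands": {
        "identity_threshold": 0.90,
        "coverage_threshold": 0.80,
        "min_flank_orfs": 10,
        "max_content_diff": 3,
        # count gene content as a set ("set") or multiset ("multiset")
        "content_mode": "set",
        "neighborhood_flank": 50,
    },
    "mge": {
        "min_repeat_len": 16,
        "max_repeat_len": 20,
        "max_mismatch": 1,
        "max_span": 200_000,
        # anchor window: last N nt of the tRNA plus M nt past its 3' end
        "anchor_window_in_trna": 25,
        "anchor_window_past_end": 5,
        "bidirectional": False,
        # mobility-classification keyword vocabulary (case-insensitive,
        # matched on whole words so "rep" does not hit "repressor")
        "integrase_keywords": [
            "integrase",
            "recombinase",
            "tyrosine recombinase",
            "serine recombinase",
        ],
        "excisionase_keywords": ["excisionase", "alpa"],
        "replication_keywords": ["rep", "rolling circle", "replication initiator"],
    },
}


def defaults() -> dict[str, Any]:
    """Return a deep copy of the default configuration."""
    return copy.deepcopy(DEFAULTS)


def _merge(base: dict[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Load configuration, overlaying a YAML file (if given) on the defaults."""
    cfg = defaults()
    if path is None:
        return cfg
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, Mapping):
        raise ValueError(f"config file {path} must contain a mapping at top level")
    return _merge(cfg, user)


def log_filter(operation: str, threshold: Any, n_in: int, n_out: int) -> None:
    """Structured log line for every filter/threshold application."""
    logger.info(
        "filter operation=%s threshold=%r n_in=%d n_out=%d",
        operation,
        threshold,
        n_in,
        n_out,
    )
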