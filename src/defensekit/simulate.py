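"""Seeded generators emulating the data each analysis stage consumes.

Every generator is a pure function of its configuration (master seed
included) and returns machine-readable ground truth alongside the data, so
downstream recovery tests can be scored without re-reading configs.  Each
generator draws from its own pseudorandom substream derived from the master
seed by a fixed integer label, so adding one generator never perturbs the
others.

* :func:`simulate_plaque_assay` — Poisson spot counts across ten-fold
  dilution series under known true titers and plating efficiencies
  (3 ul spots, triplicates).
* :func:`simulate_growth` — OD600 curves from a minimal
  susceptible/infected/phage ODE with logistic host growth, adsorption,
  lysis and burst, sampled every 10 min.  Defense systems scale the
  adsorption rate by (1 - efficacy); the two-system strain uses
  a (1-e_A)(1-e_B)/gamma, so gamma = 1 encodes exactly multiplicative
  (additive-on-AUC) protection and gamma > 1 encodes ground-truth synergy.
  This is not a mechanistic model of any particular phage; it exists to
  give the AUC machinery curves with controllable interaction structure.
* :func:`simulate_genome_with_elements` — random genomes carrying tRNA
  genes with integrated elements flanked by 16-20 nt direct repeats
  (configurable mismatches), cargo genes exercising every mobility class,
  and decoy repeats each violating exactly one scanner constraint.
* :func:`simulate_island_table` — defense-island tables with planted
  family structure and ORF protein sequences at controlled identity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GeneRecord, GeneTable, GrowthCurveSet
from . import mge as _mge

logger = logging.getLogger("defensekit")

# fixed substream labels (never reorder)
_LABEL_PLAQUE, _LABEL_GROWTH, _LABEL_GENOME, _LABEL_ISLANDS = 1, 2, 3, 4

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
_NT = np.array(list("ACGT"))


def _rng(seed: int, label: int, attempt: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, label, attempt])


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_NT, size=n))


# ---------------------------------------------------------------------------
# Plaque assays
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PlaqueSimConfig:
    """Spot-dilution assay design: ten-fold series, 3 ul spots, triplicate."""

    seed: int = 0
    phage: str = "HK022"
    reference_strain: str = "reference"
    true_titer_pfu_ml: float = 1e10
    #: strain -> true efficiency of plating relative to the reference
    true_eops: tuple[tuple[str, float], ...] = (("defended", 1e-4),)
    dilutions: tuple[float, ...] = tuple(10.0 ** -k for k in range(1, 10))
    spot_volume_ml: float = 0.003
    replicates: int = 3

    def validate(self) -> None:
        if self.true_titer_pfu_ml <= 0 or self.spot_volume_ml <= 0:
            raise ValueError("titer and spot volume must be positive")
        if any(not (0 < d <= 1) for d in self.dilutions):
            raise ValueError("dilution factors must be in (0, 1]")
        if any(e <= 0 for _, e in self.true_eops):
            raise ValueError("true EOPs must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


def simulate_plaque_assay(config: PlaqueSimConfig) -> tuple[pd.DataFrame, dict]:
    """Poisson spot counts: count ~ Poisson(titer * eop * dilution * volume).

    Returns a long assay table (readable by the plaque module) and a truth
    record with the exact titer and EOPs.
    """
    config.validate()
    rng = _rng(config.seed, _LABEL_PLAQUE)
    strains = [(config.reference_strain, 1.0), *config.true_eops]
    rows = []
    for strain, eop in strains:
        for rep in range(1, config.replicates + 1):
            for dil in config.dilutions:
                lam = config.true_titer_pfu_ml * eop * dil * config.spot_volume_ml
                rows.append(
                    {
                        "phage": config.phage,
                        "strain": strain,
                        "replicate": rep,
                        "dilution_factor": dil,
                        "spot_volume_ml": config.spot_volume_ml,
                        "plaque_count": int(rng.poisson(lam)),
                        "is_halo": False,
                        "plaque_radii_mm": None,
                    }
                )
    truth = {
        "true_titer_pfu_ml": config.true_titer_pfu_ml,
        "true_eops": dict(config.true_eops),
        "reference_strain": config.reference_strain,
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Growth curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GrowthSimConfig:
    """Parameters of the susceptible/infected/phage growth model.

    Rates are per hour; OD-to-cell conversion links MOI and burst to optical
    density.  ``gamma`` is the ground-truth interaction: the two-system
    strain adsorbs at a (1-e_A)(1-e_B)/gamma.
    """

    seed: int = 0
    phage: str = "phage"
    growth_rate_per_h: float = 1.4
    carrying_capacity_od: float = 1.2
    cells_per_ml_per_od: float = 8e8
    adsorption_ml_per_pfu_h: float = 3e-9
    burst_size: float = 10.0
    lysis_rate_per_h: float = 1.0
    efficacy_a: float = 0.5
    efficacy_b: float = 0.4
    gamma: float = 1.0
    mois: tuple[float, ...] = (0.1, 1.0, 10.0)
    initial_od: float = 0.1
    sample_every_min: float = 10.0
    duration_min: float = 500.0
    noise_sd: float = 0.01
    replicates: int = 3
    dt_min: float = 0.5

    def validate(self) -> None:
        if not (0 <= self.efficacy_a <= 1 and 0 <= self.efficacy_b <= 1):
            raise ValueError("efficacies must lie in [0, 1]")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        for name in (
            "growth_rate_per_h", "carrying_capacity_od", "cells_per_ml_per_od",
            "burst_size", "lysis_rate_per_h", "initial_od",
            "sample_every_min", "duration_min", "dt_min",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.adsorption_ml_per_pfu_h < 0 or self.noise_sd < 0:
            raise ValueError("adsorption and noise must be non-negative")


#: the four strain genotypes the growth generator produces
GROWTH_STRAINS = ("none", "A", "B", "AB")


def effective_adsorption(config: GrowthSimConfig, strain: str) -> float:
    """Adsorption rate of each genotype under the configured efficacies."""
    a = config.adsorption_ml_per_pfu_h
    if strain == "none":
        return a
    if strain == "A":
        return a * (1 - config.efficacy_a)
    if strain == "B":
        return a * (1 - config.efficacy_b)
    if strain == "AB":
        return a * (1 - config.efficacy_a) * (1 - config.efficacy_b) / config.gamma
    raise ValueError(f"unknown strain {strain!r}")


def _sip_rhs(state: np.ndarray, r: float, k: float, a_eff: float,
             delta: float, beta: float, c: float) -> np.ndarray:
    s, i, p = state
    infect = a_eff * p * s
    return np.array(
        [
            r * s * (1.0 - (s + i) / k) - infect,
            infect - delta * i,
            c * (beta * delta * i - infect),
        ]
    )


def integrate_infection(
    config: GrowthSimConfig, a_eff: float, moi: float
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic OD600 trajectory for one genotype at one MOI.

    Fixed-step classical 4th-order Runge-Kutta at ``dt_min`` steps; any
    transient negative population is clipped to zero.  Returns
    (time_min at the sampling grid, OD600 = susceptible + infected).
    """
    r = config.growth_rate_per_h
    k = config.carrying_capacity_od
    delta = config.lysis_rate_per_h
    beta = config.burst_size
    c = config.cells_per_ml_per_od
    dt_h = config.dt_min / 60.0
    n_steps = int(round(config.duration_min / config.dt_min))
    sample_every = int(round(config.sample_every_min / config.dt_min))

    state = np.array(
        [config.initial_od, 0.0, moi * c * config.initial_od], dtype=float
    )
    times = [0.0]
    od = [state[0] + state[1]]
    clipped = False
    for step in range(1, n_steps + 1):
        k1 = _sip_rhs(state, r, k, a_eff, delta, beta, c)
        k2 = _sip_rhs(state + 0.5 * dt_h * k1, r, k, a_eff, delta, beta, c)
        k3 = _sip_rhs(state + 0.5 * dt_h * k2, r, k, a_eff, delta, beta, c)
        k4 = _sip_rhs(state + dt_h * k3, r, k, a_eff, delta, beta, c)
        state = state + dt_h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if (state < 0).any():
            clipped = True
            state = np.clip(state, 0.0, None)
        if step % sample_every == 0:
            times.append(step * config.dt_min)
            od.append(state[0] + state[1])
    if clipped:
        logger.debug("integration clipped a negative population to zero")
    return np.asarray(times), np.asarray(od)


def simulate_growth(config: GrowthSimConfig) -> tuple[list[GrowthCurveSet], dict]:
    """Replicate OD600 curves for the four genotypes at each configured MOI.

    Replicates share the deterministic trajectory and differ only in i.i.d.
    Gaussian measurement noise.  The truth record carries gamma, whether
    the interaction is synergistic (gamma > 1), and every effective
    adsorption rate.
    """
    config.validate()
    rng = _rng(config.seed, _LABEL_GROWTH)
    curves: list[GrowthCurveSet] = []
    a_effs = {s: effective_adsorption(config, s) for s in GROWTH_STRAINS}
    for strain in GROWTH_STRAINS:
        for moi in config.mois:
            t, od = integrate_infection(config, a_effs[strain], moi)
            reps = od[None, :] + rng.normal(
                0.0, config.noise_sd, size=(config.replicates, od.size)
            )
            curves.append(
                GrowthCurveSet(
                    strain=strain, phage=config.phage, moi=float(moi),
                    time_min=t, od600=reps,
                )
            )
    truth = {
        "gamma": config.gamma,
        "synergy": config.gamma > 1.0,
        "effective_adsorption": a_effs,
    }
    return curves, truth


# ---------------------------------------------------------------------------
# Genomes with integrated elements
# ---------------------------------------------------------------------------

#: cargo product sets exercising each mobility class
_MARKER_PROFILES = {
    "active": (
        ("site-specific integrase", False),
        ("AlpA family excisionase", False),
        ("Rep rolling circle replication initiator protein", False),
    ),
    "immobilized": (("phage integrase fragment", True),),
    "unclassified": (("tyrosine recombinase XerC-like", False),),
    "plain": (),
}
_FILLER_PRODUCTS = (
    "hypothetical protein",
    "DNA methyltransferase",
    "YprA family helicase",
    "ATP-dependent helicase",
    "DUF1998 domain-containing protein",
)
_DECOY_KINDS = ("too_short", "too_far", "two_mismatch", "no_trna")
_TRNA_LEN = 76


@dataclass(frozen=True)
class ElementSpec:
    """One element to plant: DR length/mismatches, interior span, cargo."""

    dr_length: int = 18
    dr_mismatches: int = 0
    span: int = 8000
    n_cargo: int = 8
    marker_profile: str = "active"
    strand: str = "+"

    def validate(self) -> None:
        if not (10 <= self.dr_length <= 30):
            raise ValueError("dr_length must lie in [10, 30]")
        if self.dr_mismatches < 0 or self.dr_mismatches > 2:
            raise ValueError("dr_mismatches must be 0-2")
        if self.span < 600 or self.n_cargo < 0:
            raise ValueError("span must be >= 600 and n_cargo >= 0")
        if self.marker_profile not in _MARKER_PROFILES:
            raise ValueError(f"unknown marker profile {self.marker_profile!r}")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class GenomeSimConfig:
    seed: int = 0
    replicon_id: str = "synthetic_chromosome"
    length: int = 50_000
    elements: tuple[ElementSpec, ...] = (ElementSpec(),)
    decoys: tuple[str, ...] = ()
    #: span bound the decoy "too_far" is planted just beyond; scan with
    #: max_span equal to this value
    scan_max_span: int = 20_000
    max_retries: int = 20

    def validate(self) -> None:
        for spec in self.elements:
            spec.validate()
            if spec.span >= self.scan_max_span:
                raise ValueError("element span must be below scan_max_span")
        for kind in self.decoys:
            if kind not in _DECOY_KINDS:
                raise ValueError(f"unknown decoy kind {kind!r}")


def _mutate_repeat(rng: np.random.Generator, repeat: str, n_sub: int) -> str:
    """Substitute ``n_sub`` positions, placed so that every window of >= 16
    columns of the repeat still contains all substitutions (no exact core of
    length >= 16 survives)."""
    k = len(repeat)
    lo, hi = max(1, k - 16), min(k - 2, 15)
    positions = rng.choice(np.arange(lo, hi + 1), size=n_sub, replace=False)
    out = list(repeat)
    for pos in positions:
        choices = [b for b in "ACGT" if b != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def _differing(rng: np.random.Generator, avoid: str) -> str:
    """A random base-wise different string of the same length as ``avoid``."""
    out = []
    for ch in avoid:
        choices = [b for b in "ACGT" if b != ch]
        out.append(choices[rng.integers(len(choices))])
    return "".join(out)


def _cargo_genes(
    rng: np.random.Generator, span: int, n_cargo: int, profile: str, prefix: str
) -> list[tuple[int, int, str, bool, str]]:
    """Lay out cargo genes inside [0, span): (start, end, product, pseudo, id)."""
    markers = list(_MARKER_PROFILES[profile])
    genes = []
    cursor = 40
    for i in range(n_cargo):
        glen = int(rng.integers(150, 400))
        if cursor + glen + 40 > span:
            break
        if markers:
            product, pseudo = markers.pop(0)
        else:
            product = _FILLER_PRODUCTS[int(rng.integers(len(_FILLER_PRODUCTS)))]
            pseudo = False
        genes.append((cursor, cursor + glen, product, pseudo, f"{prefix}_g{i}"))
        cursor += glen + int(rng.integers(20, 60))
    return genes


def _repeat_scaffold(
    rng: np.random.Generator, k: int, n_mut: int, span: int
) -> tuple[str, str, str]:
    """tRNA + interior + distal repeat + extension guard, in reading
    orientation.

    The direct repeat is the last ``k`` nt of the tRNA; the distal copy sits
    ``span`` nt past the tRNA 3' end with ``n_mut`` central substitutions.
    The two interior characters flanking each copy are forced to differ
    between the copies' contexts, so neither copy can be extended into a
    longer repeat within a one-substitution budget.
    """
    trna = _random_dna(rng, _TRNA_LEN)
    repeat = trna[-k:]
    distal = _mutate_repeat(rng, repeat, n_mut) if n_mut else repeat
    interior = list(_random_dna(rng, span))
    # leftward-extension guard: chars just before the distal copy must
    # differ from the chars just before the anchor copy (inside the tRNA)
    interior[-2:] = _differing(rng, trna[-k - 2: -k])
    interior = "".join(interior)
    # rightward-extension guard: chars just after the distal copy must
    # differ from the chars just after the anchor copy (interior start)
    guard = _differing(rng, interior[:2])
    return trna, interior, trna + interior + distal + guard


def _element_block(
    rng: np.random.Generator, spec: ElementSpec, idx: int
) -> tuple[str, list[GeneRecord], dict]:
    """Build one tRNA + element + distal-repeat block in reading orientation,
    then reverse-complement it for minus-strand specs.  Coordinates in the
    returned features/truth are relative to the block."""
    k = spec.dr_length
    trna, interior, block = _repeat_scaffold(rng, k, spec.dr_mismatches,
                                             spec.span)
    cargo = _cargo_genes(rng, spec.span, spec.n_cargo, spec.marker_profile,
                         f"elem{idx}")
    features = [
        GeneRecord(
            gene_id=f"trna_{idx}", start=0, end=_TRNA_LEN, strand="+",
            product="tRNA-Phe", feature_type="tRNA",
        )
    ]
    for start, end, product, pseudo, gid in cargo:
        features.append(
            GeneRecord(
                gene_id=gid, start=_TRNA_LEN + start, end=_TRNA_LEN + end,
                strand="+", product=product, is_pseudo=pseudo,
            )
        )
    truth = {
        "trna_id": f"trna_{idx}",
        "anchor_span": (_TRNA_LEN - k, _TRNA_LEN),
        "distal_span": (_TRNA_LEN + spec.span, _TRNA_LEN + spec.span + k),
        "element_span": (_TRNA_LEN, _TRNA_LEN + spec.span),
        "dr_length": k,
        "mismatches": spec.dr_mismatches,
        "strand": spec.strand,
        "marker_profile": spec.marker_profile,
        "n_cargo": len(cargo),
        "repeat_seq": trna[-k:],
    }
    if spec.strand == "-":
        block, features, truth = _flip_block(block, features, truth)
    return block, features, truth


def _flip_block(block: str, features: list[GeneRecord], truth: dict):
    n = len(block)
    flipped = _mge.reverse_complement(block)
    feats = [
        replace(
            f, start=n - f.end, end=n - f.start,
            strand="-" if f.strand == "+" else "+",
        )
        for f in features
    ]

    def flip_span(span):
        return (n - span[1], n - span[0])

    new_truth = dict(truth)
    for key in ("anchor_span", "distal_span", "element_span"):
        new_truth[key] = flip_span(truth[key])
    return flipped, feats, new_truth


def _decoy_block(
    rng: np.random.Generator, kind: str, idx: int, scan_max_span: int
) -> tuple[str, list[GeneRecord], dict]:
    if kind == "no_trna":
        k = 18
        copy = _random_dna(rng, k)
        gap = _random_dna(rng, 300)
        block = copy + gap + copy + _random_dna(rng, 40)
        truth = {"kind": kind, "spans": [(0, k), (k + 300, 2 * k + 300)],
                 "repeat_seq": copy}
        return block, [], truth

    if kind == "too_short":
        k, span, n_mut = 14, 2000, 0
    elif kind == "two_mismatch":
        k, span, n_mut = 18, 2000, 2
    elif kind == "too_far":
        k, span, n_mut = 18, scan_max_span + 500, 0
    else:  # pragma: no cover
        raise ValueError(kind)
    trna, _, block = _repeat_scaffold(rng, k, n_mut, span)
    features = [
        GeneRecord(
            gene_id=f"decoy_trna_{idx}", start=0, end=_TRNA_LEN, strand="+",
            product="tRNA-Leu", feature_type="tRNA",
        )
    ]
    truth = {
        "kind": kind,
        "trna_id": f"decoy_trna_{idx}",
        "anchor_span": (_TRNA_LEN - k, _TRNA_LEN),
        "distal_span": (_TRNA_LEN + span, _TRNA_LEN + span + k),
        "dr_length": k,
        "mismatches": n_mut,
        "repeat_seq": trna[-k:],
    }
    return block, features, truth


def _assemble_genome(
    config: GenomeSimConfig, rng: np.random.Generator
) -> tuple[GeneTable, dict]:
    segments: list[str] = []
    features: list[GeneRecord] = []
    planted: list[dict] = []
    decoys: list[dict] = []
    cursor = 0

    def push(seq: str) -> int:
        nonlocal cursor
        segments.append(seq)
        start = cursor
        cursor += len(seq)
        return start

    push(_random_dna(rng, 1000))
    blocks = [("element", i, spec) for i, spec in enumerate(config.elements)]
    blocks += [("decoy", i, kind) for i, kind in enumerate(config.decoys)]
    for btype, idx, payload in blocks:
        if btype == "element":
            block, feats, truth = _element_block(rng, payload, idx)
        else:
            block, feats, truth = _decoy_block(rng, payload, idx,
                                               config.scan_max_span)
        offset = push(block)
        for f in feats:
            features.append(replace(f, start=f.start + offset, end=f.end + offset))
        shifted = dict(truth)
        for key in ("anchor_span", "distal_span", "element_span"):
            if key in shifted:
                a, b = shifted[key]
                shifted[key] = (a + offset, b + offset)
        if "spans" in shifted:
            shifted["spans"] = [(a + offset, b + offset) for a, b in shifted["spans"]]
        push(_random_dna(rng, 800 + int(rng.integers(400))))
        (planted if btype == "element" else decoys).append(shifted)
    if cursor < config.length:
        push(_random_dna(rng, config.length - cursor))
    sequence = "".join(segments)
    table = GeneTable(
        replicon_id=config.replicon_id, genes=features, sequence=sequence
    )
    truth = {"elements": planted, "decoys": decoys, "length": len(sequence),
             "scan_max_span": config.scan_max_span}
    return table, truth


def _truth_matches_scan(table: GeneTable, truth: dict, config: GenomeSimConfig
                        ) -> bool:
    """Verify the planted elements are the *only* anchored repeats the scan
    geometry admits; accidental background repeats count as collisions."""
    trnas = [g for g in table.genes if g.feature_type in ("tRNA", "tmRNA")]
    hits = _mge.find_trna_anchored_repeats(
        table.sequence, trnas, max_span=config.scan_max_span
    )
    # only elements inside the scanner's constraint envelope are expected
    expected = {
        (e["trna_id"], tuple(e["anchor_span"]), tuple(e["distal_span"]),
         e["mismatches"])
        for e in truth["elements"]
        if 16 <= e["dr_length"] <= 20
        and e["mismatches"] <= 1
        and e["element_span"][1] - e["element_span"][0] <= config.scan_max_span
    }
    got = {
        (h.trna_id, h.anchor_span, h.distal_span, h.mismatches) for h in hits
    }
    return got == expected


def simulate_genome_with_elements(
    config: GenomeSimConfig,
) -> tuple[GeneTable, dict]:
    """Generate an annotated genome with planted DR-flanked elements.

    Returns an annotated :class:`GeneTable` (sequence included; write it out
    with :func:`defensekit.io.write_gff3`) and the truth record listing every
    planted element and decoy.  If an accidental background repeat collides
    with the planted geometry, the genome is regenerated from the next
    substream, up to ``max_retries`` times, with a warning.
    """
    config.validate()
    for attempt in range(config.max_retries):
        rng = _rng(config.seed, _LABEL_GENOME, attempt)
        table, truth = _assemble_genome(config, rng)
        if _truth_matches_scan(table, truth, config):
            if attempt:
                warnings.warn(
                    f"regenerated genome {attempt} time(s) after repeat "
                    "collisions",
                    stacklevel=2,
                )
            return table, truth
    raise RuntimeError(
        f"could not plant elements without collisions in "
        f"{config.max_retries} attempts"
    )


# ---------------------------------------------------------------------------
# Island tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IslandSimConfig:
    seed: int = 0
    n_families: int = 4
    islands_per_family: int = 5
    content_size: int = 10
    perturbations_per_island: int = 1
    decoy_pool: int = 30
    protein_length: int = 80
    #: per-member divergence cap from the prototype; pairwise within-family
    #: identity is then guaranteed >= 1 - 2 * max_divergence
    max_divergence: float = 0.025
    #: islands planted closer than 10 ORFs to a contig end, to exercise the
    #: edge filter
    edge_islands: int = 0

    def validate(self) -> None:
        if self.perturbations_per_island >= self.content_size:
            raise ValueError("perturbations must be < content_size")
        if min(self.n_families, self.islands_per_family, self.content_size,
               self.protein_length) < 1:
            raise ValueError("sizes must be positive")
        if not (0 <= self.max_divergence <= 0.025):
            raise ValueError("max_divergence must keep >= 95% within identity")


@dataclass(frozen=True)
class SimulatedIslands:
    """Planted island families with ORF proteins and ground-truth labels."""

    proteins: dict[str, str]  # orf id -> amino-acid sequence
    island_orfs: dict[str, list[str]]  # island id -> orf ids
    truth_family: dict[str, str]  # island id -> planted family label
    truth_prototype: dict[str, str]  # orf id -> planted prototype label
    edge_island_ids: tuple[str, ...] = ()


def _mutate_protein(rng: np.random.Generator, seq: str, max_divergence: float
                    ) -> str:
    out = list(seq)
    cap = int(max_divergence * len(seq))
    n_mut = int(rng.integers(0, cap + 1))
    if n_mut:
        for pos in rng.choice(len(seq), size=n_mut, replace=False):
            choices = _AA[_AA != out[pos]]
            out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def simulate_island_table(config: IslandSimConfig) -> SimulatedIslands:
    """Plant island families with disjoint core contents.

    Each family has a core set of ``content_size`` ORF prototypes (disjoint
    across families, so planted inter-family content distance is
    2 * content_size); each island applies ``perturbations_per_island``
    single-element edits — dropping a core member or gaining a decoy
    prototype — so two islands of one family differ by at most twice that
    number.  ORF proteins of the same prototype are >= 95% identical;
    different prototypes are unrelated random sequences.
    """
    config.validate()
    rng = _rng(config.seed, _LABEL_ISLANDS)
    n_proto = config.n_families * config.content_size + config.decoy_pool
    prototypes = {
        f"proto{p:03d}": "".join(rng.choice(_AA, size=config.protein_length))
        for p in range(n_proto)
    }
    proto_ids = sorted(prototypes)
    core_of = {
        f: proto_ids[f * config.content_size: (f + 1) * config.content_size]
        for f in range(config.n_families)
    }
    decoy_ids = proto_ids[config.n_families * config.content_size:]

    proteins: dict[str, str] = {}
    island_orfs: dict[str, list[str]] = {}
    truth_family: dict[str, str] = {}
    truth_prototype: dict[str, str] = {}
    edge_ids: list[str] = []
    n_islands = 0
    for fam in range(config.n_families):
        for j in range(config.islands_per_family):
            island_id = f"island{n_islands:03d}"
            n_islands += 1
            content = list(core_of[fam])
            for _ in range(config.perturbations_per_island):
                if rng.random() < 0.5 and len(content) > 1:
                    content.pop(int(rng.integers(len(content))))
                else:
                    extra = decoy_ids[int(rng.integers(len(decoy_ids)))]
                    if extra not in content:
                        content.append(extra)
            orf_ids = []
            for proto in content:
                orf_id = f"{island_id}_{proto}"
                proteins[orf_id] = _mutate_protein(
                    rng, prototypes[proto], config.max_divergence
                )
                truth_prototype[orf_id] = proto
                orf_ids.append(orf_id)
            island_orfs[island_id] = orf_ids
            truth_family[island_id] = f"family{fam}"
            if len(edge_ids) < config.edge_islands and j == 0:
                edge_ids.append(island_id)
    return SimulatedIslands(
        proteins=proteins,
        island_orfs=island_orfs,
        truth_family=truth_family,
        truth_prototype=truth_prototype,
        edge_island_ids=tuple(edge_ids),
    )
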