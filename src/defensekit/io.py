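"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are **0-based half-open** internally.  The 1-based
inclusive conventions of GenBank and GFF3 exist only at the parsing/writing
boundary.  Compound (join) locations are collapsed to their min-start/max-end
envelope with a warning: only gene order and span matter downstream.
"""

from __future__ import annotations

import csv
import io as _stdio
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("defensekit")

#: feature types treated as genes when parsing annotations
GENE_FEATURE_TYPES = ("CDS", "tRNA", "tmRNA", "rRNA", "ncRNA")


class FormatError(ValueError):
    """A file could not be parsed; the message names the offending element."""


# ---------------------------------------------------------------------------
# Gene tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneRecord:
    """One gene on a replicon, in 0-based half-open coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    product: str = ""
    is_pseudo: bool = False
    feature_type: str = "CDS"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid span [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")


@dataclass
class GeneTable:
    """Ordered genes of one replicon, optionally with its sequence."""

    replicon_id: str
    genes: list[GeneRecord]
    sequence: str | None = None

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end, g.gene_id))
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene ids on {self.replicon_id}: {dupes}")
        if self.sequence is not None:
            n = len(self.sequence)
            for g in self.genes:
                if g.end > n:
                    raise ValueError(
                        f"gene {g.gene_id} extends past the end of "
                        f"{self.replicon_id} (length {n})"
                    )

    def __len__(self) -> int:
        return len(self.genes)

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(f"gene {gene_id!r} not found on {self.replicon_id}")

    def index_of(self, gene_id: str) -> int:
        for i, g in enumerate(self.genes):
            if g.gene_id == gene_id:
                return i
        raise KeyError(f"gene {gene_id!r} not found on {self.replicon_id}")


def _is_pseudo(qualifiers: dict) -> bool:
    return "pseudo" in qualifiers or "pseudogene" in qualifiers


def _from_genbank(path: Path, need_sequence: bool) -> GeneTable:
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise FormatError(f"{path}: no GenBank records found")
    if len(records) > 1:
        raise FormatError(
            f"{path}: multiple replicons ({[r.id for r in records]}); "
            "split the file or pass one replicon per call"
        )
    rec = records[0]
    genes: list[GeneRecord] = []
    counter = 0
    for feat in rec.features:
        if feat.type not in GENE_FEATURE_TYPES:
            continue
        loc = feat.location
        if loc is None:
            raise FormatError(f"{path}: feature {feat.type} without a location")
        if getattr(loc, "parts", None) and len(loc.parts) > 1:
            warnings.warn(
                f"{path}: compound location for {feat.type} collapsed to its envelope",
                stacklevel=2,
            )
        start, end = int(loc.start), int(loc.end)
        strand = "-" if loc.strand == -1 else "+"
        quals = feat.qualifiers
        gene_id = (
            quals.get("locus_tag", [None])[0]
            or quals.get("gene", [None])[0]
            or quals.get("protein_id", [None])[0]
            or f"{feat.type}_{counter}"
        )
        counter += 1
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                start=start,
                end=end,
                strand=strand,
                product=quals.get("product", [""])[0],
                is_pseudo=_is_pseudo(quals),
                feature_type=feat.type,
            )
        )
    seq = str(rec.seq) if (need_sequence or len(rec.seq)) else None
    return GeneTable(replicon_id=rec.id, genes=genes, sequence=seq)


def _from_gff3(path: Path, fasta: Path | None, need_sequence: bool) -> GeneTable:
    if need_sequence and fasta is None:
        raise FormatError(f"{path}: sequence required but no FASTA file given")
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - gffutils error text varies
        raise FormatError(f"{path}: malformed GFF3 ({exc})") from exc

    genes: list[GeneRecord] = []
    seqids: set[str] = set()
    counter = 0
    for ftype in GENE_FEATURE_TYPES:
        for feat in db.features_of_type(ftype):
            seqids.add(feat.seqid)
            gene_id = (
                feat.attributes.get("ID", [None])[0]
                or feat.attributes.get("locus_tag", [None])[0]
                or f"{ftype}_{counter}"
            )
            counter += 1
            pseudo = (
                feat.attributes.get("pseudo", ["false"])[0].lower() == "true"
                or "pseudogene" in feat.attributes
            )
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    # GFF3 is 1-based inclusive
                    start=feat.start - 1,
                    end=feat.end,
                    strand="-" if feat.strand == "-" else "+",
                    product=feat.attributes.get("product", [""])[0],
                    is_pseudo=pseudo,
                    feature_type=ftype,
                )
            )
    if len(seqids) > 1:
        raise FormatError(f"{path}: multiple replicons ({sorted(seqids)})")
    replicon_id = seqids.pop() if seqids else path.stem

    sequence = None
    if fasta is not None:
        seqs = list(SeqIO.parse(str(fasta), "fasta"))
        if not seqs:
            raise FormatError(f"{fasta}: no FASTA records found")
        match = [r for r in seqs if r.id == replicon_id]
        if genes and not match:
            raise FormatError(
                f"{fasta}: no sequence for replicon {replicon_id!r}"
            )
        rec = match[0] if match else seqs[0]
        replicon_id = rec.id
        sequence = str(rec.seq)
    return GeneTable(replicon_id=replicon_id, genes=genes, sequence=sequence)


def read_annotations(
    path: str | Path,
    fasta: str | Path | None = None,
    require_sequence: bool = False,
) -> GeneTable:
    """Read gene annotations from GenBank, or GFF3 plus an optional FASTA.

    The format is chosen by extension (``.gb/.gbk/.gbff/.genbank`` vs
    ``.gff/.gff3``).  Coordinates are converted to 0-based half-open,
    pseudogene qualifiers map to :attr:`GeneRecord.is_pseudo`, and compound
    locations collapse to their envelope with a warning.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
        return _from_genbank(path, require_sequence)
    if suffix in (".gff", ".gff3"):
        return _from_gff3(path, Path(fasta) if fasta else None, require_sequence)
    raise FormatError(f"{path}: unrecognized annotation format {suffix!r}")


def write_gff3(table: GeneTable, path: str | Path, fasta: str | Path | None = None) -> None:
    """Write a GeneTable as GFF3 (and its sequence as FASTA, if requested)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for g in table.genes:
            attrs = [f"ID={g.gene_id}"]
            if g.product:
                attrs.append(f"product={g.product}")
            if g.is_pseudo:
                attrs.append("pseudo=true")
            fh.write(
                "\t".join(
                    [
                        table.replicon_id,
                        "defensekit",
                        g.feature_type,
                        str(g.start + 1),  # back to 1-based inclusive
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    if fasta is not None:
        if table.sequence is None:
            raise ValueError("GeneTable has no sequence to write")
        rec = SeqRecord(Seq(table.sequence), id=table.replicon_id, description="")
        SeqIO.write([rec], str(fasta), "fasta")


# ---------------------------------------------------------------------------
# Plaque-assay tables
# ---------------------------------------------------------------------------

ASSAY_COLUMNS = [
    "phage",
    "strain",
    "replicate",
    "dilution_factor",
    "spot_volume_ml",
    "plaque_count",
]
#: sentinel accepted in the plaque_count column for confluent lysis halos
HALO_SENTINEL = "lawn"


def _parse_radii(value) -> list[float] | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or value == "":
        return None
    if isinstance(value, (list, tuple)):
        radii = [float(v) for v in value]
    else:
        radii = [float(v) for v in str(value).split(";") if v.strip()]
    if any(r <= 0 for r in radii):
        raise ValueError(f"non-positive plaque radius in {value!r}")
    return radii


def read_assay_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format plaque-assay table (CSV or TSV, auto-detected).

    Returns a DataFrame with columns ``phage, strain, replicate,
    dilution_factor, spot_volume_ml, plaque_count, is_halo, plaque_radii_mm``.
    ``plaque_count`` is NaN where the spot was a confluent lysis halo
    (``is_halo`` True).  Zero counts are preserved, never dropped.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"plaque_count": str})
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    raw = df["plaque_count"].astype(str).str.strip().str.lower()
    is_halo = raw.eq(HALO_SENTINEL)
    counts = pd.to_numeric(raw.mask(is_halo), errors="coerce")
    bad_count = ~is_halo & (counts.isna() | (counts < 0) | (counts % 1 != 0))
    bad_dil = (df["dilution_factor"] <= 0) | (df["dilution_factor"] > 1)
    bad = bad_count | bad_dil
    if bad.any():
        rows = [int(i) for i in df.index[bad][:20]]
        raise ValueError(
            f"{path}: invalid plaque_count/dilution_factor in rows {rows} "
            "(counts must be non-negative integers or 'lawn'; 0 < dilution <= 1)"
        )
    out = df.copy()
    out["plaque_count"] = counts
    out["is_halo"] = is_halo.to_numpy()
    out["replicate"] = out["replicate"].astype(int)
    if (out["replicate"] < 1).any():
        raise ValueError(f"{path}: replicate numbers must be >= 1")
    if "plaque_radii_mm" in out.columns:
        out["plaque_radii_mm"] = out["plaque_radii_mm"].map(_parse_radii)
    else:
        out["plaque_radii_mm"] = None
    out = out.sort_values(
        ["phage", "strain", "replicate", "dilution_factor"],
        ascending=[True, True, True, False],
        kind="stable",
    ).reset_index(drop=True)
    canonical = ASSAY_COLUMNS + ["is_halo", "plaque_radii_mm"]
    extras = [c for c in out.columns if c not in canonical]
    return out[canonical + extras]


def write_assay_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write an assay table so that :func:`read_assay_table` round-trips it."""
    out = df.copy()
    counts = []
    for cnt, halo in zip(out["plaque_count"], out.get("is_halo", [False] * len(out))):
        counts.append(HALO_SENTINEL if halo else str(int(cnt)))
    out["plaque_count"] = counts
    if "plaque_radii_mm" in out.columns:
        out["plaque_radii_mm"] = out["plaque_radii_mm"].map(
            lambda v: ";".join(f"{x:g}" for x in v) if isinstance(v, list) else ""
        )
    out = out.drop(columns=["is_halo"], errors="ignore")
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Plate-reader time series
# ---------------------------------------------------------------------------


@dataclass
class GrowthCurveSet:
    """Replicate OD600 (and optional fluorescence) time series for one
    condition (strain x phage x MOI x dye).

    ``od600`` has shape (n_replicates, n_timepoints) on the shared
    ``time_min`` grid; ``fluorescence_rlu`` is None or the same shape.
    """

    strain: str
    phage: str
    moi: float
    time_min: "np.ndarray"
    od600: "np.ndarray"
    fluorescence_rlu: "np.ndarray | None" = None
    dye: str = "none"

    def __post_init__(self) -> None:
        import numpy as np

        self.time_min = np.asarray(self.time_min, dtype=float)
        self.od600 = np.atleast_2d(np.asarray(self.od600, dtype=float))
        if self.od600.shape[1] != self.time_min.shape[0]:
            raise ValueError(
                f"od600 has {self.od600.shape[1]} points per replicate but "
                f"time grid has {self.time_min.shape[0]}"
            )
        if self.fluorescence_rlu is not None:
            self.fluorescence_rlu = np.atleast_2d(
                np.asarray(self.fluorescence_rlu, dtype=float)
            )
            if self.fluorescence_rlu.shape != self.od600.shape:
                raise ValueError("fluorescence and od600 shapes differ")
        if self.moi < 0:
            raise ValueError("MOI must be non-negative")

    @property
    def n_replicates(self) -> int:
        return self.od600.shape[0]


def write_growth_curves(curves: Sequence[GrowthCurveSet], path: str | Path) -> None:
    """Write growth-curve sets as a long-format CSV (one row per reading)."""
    rows = []
    for cs in curves:
        for rep in range(cs.n_replicates):
            for j, t in enumerate(cs.time_min):
                row = {
                    "strain": cs.strain,
                    "phage": cs.phage,
                    "moi": cs.moi,
                    "dye": cs.dye,
                    "replicate": rep + 1,
                    "time_min": t,
                    "od600": cs.od600[rep, j],
                }
                if cs.fluorescence_rlu is not None:
                    row["fluorescence_rlu"] = cs.fluorescence_rlu[rep, j]
                rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_growth_curves(path: str | Path) -> list[GrowthCurveSet]:
    """Read back a long-format plate CSV into GrowthCurveSets."""
    import numpy as np

    df = pd.read_csv(path, sep=None, engine="python")
    required = {"strain", "phage", "moi", "replicate", "time_min", "od600"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if "dye" not in df.columns:
        df = df.assign(dye="none")
    out = []
    for (strain, phage, moi, dye), grp in df.groupby(
        ["strain", "phage", "moi", "dye"], sort=True
    ):
        reps = sorted(grp["replicate"].unique())
        time = np.sort(grp["time_min"].unique())
        od = np.empty((len(reps), len(time)))
        rlu = (
            np.empty_like(od) if "fluorescence_rlu" in grp.columns else None
        )
        for i, rep in enumerate(reps):
            sub = grp[grp["replicate"] == rep].sort_values("time_min")
            if len(sub) != len(time):
                raise FormatError(
                    f"{path}: replicate {rep} of {strain}/{phage} not on the "
                    "shared time grid"
                )
            od[i] = sub["od600"].to_numpy()
            if rlu is not None:
                rlu[i] = sub["fluorescence_rlu"].to_numpy()
        out.append(
            GrowthCurveSet(
                strain=strain, phage=phage, moi=float(moi),
                time_min=time, od600=od, fluorescence_rlu=rlu, dye=dye,
            )
        )
    return out


# ---------------------------------------------------------------------------
# BED output for element calls
# ---------------------------------------------------------------------------


def write_elements_bed(calls: Iterable, path: str | Path) -> None:
    """Write element calls as BED6 (0-based half-open, so spans go unchanged).

    Columns: chrom, start, end, name=element id, score=repeat mismatch count,
    strand=tRNA strand.  An empty call list yields an empty file.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for call in calls:
            start, end = call.span
            fh.write(
                f"{call.replicon_id}\t{start}\t{end}\t{call.element_id}\t"
                f"{call.mismatches}\t{call.strand}\n"
            )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read back a BED6 file written by :func:`write_elements_bed`."""
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(path, sep="\t", header=None, names=cols)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=cols)
    return df
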