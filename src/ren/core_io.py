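"""Domain types and file readers/writers shared by every pipeline stage.

Coordinate convention: 0-based half-open (BED native) everywhere in memory.
Methylation is stored as a fraction in [0, 1] in memory and rendered as
percent in reports.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("ren")


def setup_logging(quiet: bool = False) -> None:
    """Configure the package logger: info-level audit trail, or warnings only."""
    level = logging.WARNING if quiet else logging.INFO
    logging.basicConfig(format="%(name)s %(levelname)s: %(message)s")
    log.setLevel(level)


class Stage(str, enum.Enum):
    """Disease stage of a myeloma sample (control = healthy plasma-B pool)."""

    MGUS = "MGUS"
    SMM = "SMM"
    MM = "MM"
    CONTROL = "CONTROL"


class Subgroup(str, enum.Enum):
    """Molecular subgroup: IgH translocations, hyperdiploidy D1/D2, or control."""

    T4_14 = "T4_14"
    T11_14 = "T11_14"
    T14_16 = "T14_16"
    T14_20 = "T14_20"
    D1 = "D1"
    D2 = "D2"
    CONTROL = "CONTROL"


#: Accepted sample-sheet spellings for each subgroup.
SUBGROUP_LABELS: dict[str, Subgroup] = {
    "t(4;14)": Subgroup.T4_14,
    "t(11;14)": Subgroup.T11_14,
    "t(14;16)": Subgroup.T14_16,
    "t(14;20)": Subgroup.T14_20,
    **{m.value: m for m in Subgroup},
    "control": Subgroup.CONTROL,
}

STAGE_LABELS: dict[str, Stage] = {
    **{s.value: s for s in Stage},
    "control": Stage.CONTROL,
}

DISEASE_STAGES = (Stage.MGUS, Stage.SMM, Stage.MM)
DISEASE_SUBGROUPS = (
    Subgroup.T4_14,
    Subgroup.T11_14,
    Subgroup.T14_16,
    Subgroup.T14_20,
    Subgroup.D1,
    Subgroup.D2,
)


class Mark(str, enum.Enum):
    """Chromatin feature tracks consumed by the integration stage."""

    H3K4me1 = "H3K4me1"
    H3K4me3 = "H3K4me3"
    H3K27ac = "H3K27ac"
    H3K36me3 = "H3K36me3"
    H3K27me3 = "H3K27me3"
    BRD4 = "BRD4"
    MED1 = "MED1"
    CTCF = "CTCF"
    DHS = "DHS"
    MAF = "MAF"


class Assay(str, enum.Enum):
    PYRO = "PYRO"
    QPCR = "QPCR"
    VIABILITY = "VIABILITY"


@dataclass(frozen=True)
class SampleRecord:
    sample_id: str
    stage: Stage
    subgroup: Subgroup

    def __post_init__(self) -> None:
        if (self.stage == Stage.CONTROL) != (self.subgroup == Subgroup.CONTROL):
            raise ValueError(
                f"sample {self.sample_id!r}: stage==CONTROL iff subgroup==CONTROL "
                f"(got stage={self.stage.value}, subgroup={self.subgroup.value})"
            )


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must be > start, got [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Overlapping base pairs with another interval (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class CpGSite:
    """A single CpG with per-group methylation fractions."""

    interval: GenomicInterval
    methylation: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for group, frac in self.methylation.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(
                    f"CpG {self.interval.chrom}:{self.interval.start}: methylation "
                    f"fraction for {group!r} out of [0,1]: {frac}"
                )


@dataclass
class DMR:
    """Differentially methylated region with per-group median methylation (%)."""

    id: str
    interval: GenomicInterval
    gene: str
    region_class: str = "intergenic"  # promoter | body | intergenic
    n_cpg: int = 1
    median_methylation: dict[str, float] = field(default_factory=dict)
    dm_vs_control: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_cpg < 1:
            raise ValueError(f"DMR {self.id}: n_cpg must be >= 1")


@dataclass
class PeakSet:
    """Scored peaks for one mark in one cell line; signal is a -log10 p score."""

    mark: Mark
    cell_line: str
    peaks: list[tuple[GenomicInterval, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for iv, signal in self.peaks:
            if signal < 0:
                raise ValueError(f"peak signal must be >= 0, got {signal}")
        self.peaks.sort(key=lambda p: (p[0].chrom, p[0].start))

    def intervals(self) -> list[GenomicInterval]:
        return [iv for iv, _ in self.peaks]


@dataclass
class PerturbationTable:
    """Long-format assay table: (condition, replicate, key, value) rows.

    key meaning depends on the assay: CpG index (PYRO, value = % methylation),
    gene name (QPCR, value = Ct), or concentration in uM (VIABILITY,
    value = viability fraction).
    """

    assay: Assay
    data: pd.DataFrame  # columns: condition, replicate, key, value

    def __post_init__(self) -> None:
        required = {"condition", "replicate", "key", "value"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"perturbation table missing columns {sorted(missing)}")
        if (self.data["replicate"] < 1).any():
            raise ValueError("replicate numbers must be >= 1")
        vals = self.data["value"]
        if self.assay == Assay.PYRO and ((vals < 0) | (vals > 100)).any():
            raise ValueError("PYRO values must lie in [0, 100] percent")
        if self.assay == Assay.VIABILITY and (vals < 0).any():
            raise ValueError("VIABILITY values must be >= 0")


@dataclass
class ExpressionMatrix:
    """log2 expression intensities (genes x samples) with sample metadata."""

    genes: list[str]
    samples: list[SampleRecord]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if any(not g for g in self.genes):
            raise ValueError("missing gene symbol")
        if len(set(self.genes)) != len(self.genes):
            dup = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValueError(f"duplicate gene symbol(s): {dup}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id in cohort")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.genes, columns=[s.sample_id for s in self.samples]
        )

    def sample_index(
        self, stage: Stage | None = None, subgroup: Subgroup | None = None
    ) -> np.ndarray:
        """Column indices of samples matching the given stage/subgroup."""
        keep = np.ones(len(self.samples), dtype=bool)
        if stage is not None:
            keep &= np.array([s.stage == stage for s in self.samples])
        if subgroup is not None:
            keep &= np.array([s.subgroup == subgroup for s in self.samples])
        return np.flatnonzero(keep)

    def gene_values(
        self, gene: str, stage: Stage | None = None, subgroup: Subgroup | None = None
    ) -> np.ndarray:
        if gene not in self.genes:
            raise KeyError(f"unknown gene {gene!r}")
        row = self.genes.index(gene)
        return self.values[row, self.sample_index(stage, subgroup)]


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read a TSV sample sheet with columns sample_id, stage, subgroup."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "stage", "subgroup"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        stage_label, subgroup_label = row["stage"], row["subgroup"]
        if stage_label not in STAGE_LABELS:
            raise ValueError(f"unknown stage label {stage_label!r}")
        if subgroup_label not in SUBGROUP_LABELS:
            raise ValueError(f"unknown subgroup label {subgroup_label!r}")
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                stage=STAGE_LABELS[stage_label],
                subgroup=SUBGROUP_LABELS[subgroup_label],
            )
        )
    return records


def read_expression(
    matrix_path: str | Path, sample_sheet_path: str | Path
) -> ExpressionMatrix:
    """Read a genes-x-samples log2 TSV matrix plus its sample sheet.

    The first matrix column holds gene symbols; every remaining column name
    must appear in the sheet. Samples in the sheet but absent from the matrix
    are dropped (a sheet may describe a larger cohort).
    """
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = {s.sample_id: s for s in read_sample_sheet(sample_sheet_path)}
    missing = [c for c in df.columns if c not in sheet]
    if missing:
        raise ValueError(f"matrix sample(s) absent from sample sheet: {missing}")
    samples = [sheet[c] for c in df.columns]
    matrix = ExpressionMatrix(list(df.index), samples, df.to_numpy(dtype=float))
    log.info(
        "read expression matrix %s: %d genes x %d samples",
        matrix_path,
        len(matrix.genes),
        len(matrix.samples),
    )
    return matrix


def _parse_coord(token: str, path: str | Path, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: non-integer coordinate {token!r}"
        ) from None


def read_intervals(
    path: str | Path, mark: Mark | str | None = None, cell_line: str = ""
) -> PeakSet | list[GenomicInterval]:
    """Read BED3+ or narrowPeak intervals (0-based half-open, returned sorted).

    With ``mark`` given a :class:`PeakSet` is returned; narrowPeak rows carry
    their signalValue column as the peak signal, plain BED rows signal 0.
    """
    intervals: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 columns")
            chrom = fields[0]
            start = _parse_coord(fields[1], path, lineno)
            end = _parse_coord(fields[2], path, lineno)
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-." else "."
            signal = 0.0
            if len(fields) >= 10:  # narrowPeak: signalValue is column 7
                signal = float(fields[6])
            intervals.append((GenomicInterval(chrom, start, end, strand), signal))
    intervals.sort(key=lambda p: (p[0].chrom, p[0].start))
    if mark is None:
        return [iv for iv, _ in intervals]
    return PeakSet(mark=Mark(mark), cell_line=cell_line, peaks=intervals)


def read_cpg_methylation(path: str | Path, group: str) -> list[CpGSite]:
    """Read a bedGraph-like 4-column file of per-CpG methylation for one group.

    The value column may be a fraction in [0,1] or a percent in [0,100]; if any
    value exceeds 1 the whole file is treated as percent.
    """
    rows: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            chrom = fields[0]
            start = _parse_coord(fields[1], path, lineno)
            end = _parse_coord(fields[2], path, lineno)
            value = float(fields[3])
            if value < 0 or value > 100:
                raise ValueError(
                    f"{path}:{lineno}: methylation value {value} out of [0, 100]"
                )
            rows.append((GenomicInterval(chrom, start, end), value))
    is_percent = any(v > 1 for _, v in rows)
    scale = 0.01 if is_percent else 1.0
    sites = [CpGSite(iv, {group: v * scale}) for iv, v in rows]
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    log.info("read %d CpG sites for group %s from %s", len(sites), group, path)
    return sites


def merge_cpg_groups(per_group: Mapping[str, Sequence[CpGSite]]) -> list[CpGSite]:
    """Merge per-group CpG lists into sites carrying one fraction per group."""
    merged: dict[GenomicInterval, CpGSite] = {}
    for group, sites in per_group.items():
        for site in sites:
            tgt = merged.setdefault(site.interval, CpGSite(site.interval, {}))
            tgt.methylation.update({group: site.methylation[group]})
    out = list(merged.values())
    out.sort(key=lambda s: (s.interval.chrom, s.interval.start))
    return out


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    rows = []
    for rec in records:
        if dataclasses.is_dataclass(rec):
            d = dataclasses.asdict(rec)
        elif isinstance(rec, Mapping):
            d = dict(rec)
        else:
            raise TypeError(f"cannot serialize record of type {type(rec)}")
        rows.append(
            {k: (v.value if isinstance(v, enum.Enum) else v) for k, v in d.items()}
        )
    return pd.DataFrame(rows)


def write_report(records, path: str | Path, columns: Sequence[str] | None = None) -> Path:
    """Write records as a TSV with deterministic column order.

    Floats are rendered with 6 significant digits so a write/read round-trip
    preserves values to that precision. An empty record list yields a
    header-only file (``columns`` must then be given).
    """
    df = _records_to_frame(records)
    if df.empty and columns is not None:
        df = pd.DataFrame(columns=list(columns))
    elif columns is not None:
        df = df[list(columns)]
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    log.info("wrote %d records to %s", len(df), path)
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Sequence[str] | None = None) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")
    return path


def load_config(path: str | Path) -> dict:
    """Load a structured key-value (YAML) config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
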