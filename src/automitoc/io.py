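"""Readers and writers for the on-disk artifacts of the pipeline.

The canonical interchange formats are plain TSV (probe-major L2R matrix,
probe/sample annotation tables, estimates table) and 3+-column BED for
exclusion regions. Missing L2R cells are written as the literal ``NA``.
All readers validate rather than coerce: duplicated identifiers, malformed
numbers and out-of-range fractions raise instead of propagating silently.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "IntensityMatrix",
    "ProbeAnnotation",
    "SampleAnnotation",
    "RegionSet",
    "MtEstimates",
    "read_l2r_matrix",
    "write_l2r_matrix",
    "read_probe_annotation",
    "read_sample_annotation",
    "read_bed",
    "write_estimates",
    "read_estimates",
]


class FormatError(ValueError):
    """A file does not conform to the documented dialect."""


class ValidationError(ValueError):
    """A parsed value violates a domain invariant (range, uniqueness...)."""


# canonical chromosome labels: autosomes "1".."22", "X", "Y", "XY", "MT".
# The table mixes array (PLINK numeric) and sequencing ("chr" prefixed)
# conventions because annotation files in the wild do.
_CHROM_ALIASES = {
    "M": "MT", "MT": "MT", "26": "MT",
    "X": "X", "23": "X",
    "Y": "Y", "24": "Y",
    "XY": "XY", "25": "XY",
}
_AUTOSOMES = {str(i) for i in range(1, 23)}

_SEX_ALIASES = {
    "female": "female", "f": "female", "2": "female",
    "male": "male", "m": "male", "1": "male",
    "unknown": "unknown", "u": "unknown", "0": "unknown",
    "na": "unknown", "": "unknown", "nan": "unknown",
}


def normalize_chromosome(label: object) -> str:
    """Map a chromosome label to the canonical set ("1".."22", "X", "Y",
    "XY", "MT"); e.g. "chrM", "M" and "26" all become "MT"."""
    s = str(label).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s in _AUTOSOMES:
        return s
    if s.upper() in _CHROM_ALIASES:
        return _CHROM_ALIASES[s.upper()]
    raise ValidationError(f"unrecognized chromosome label: {label!r}")


@dataclass
class IntensityMatrix:
    """Probes x samples matrix of log2-ratio (L2R) intensities.

    Missing cells are stored as NaN in ``values``; ``missing_mask`` is the
    boolean view of those cells. Downstream arithmetic only ever uses
    non-missing entries.
    """

    probe_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray  # float64, NaN where missing

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for name, ids in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                raise ValidationError(f"duplicate {name} IDs")

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe_ids) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        try:
            return np.array([lookup[p] for p in probe_ids], dtype=int)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"unknown probe id {e.args[0]!r}") from None

    def select_probes(self, probe_ids) -> "IntensityMatrix":
        idx = self.probe_index(probe_ids)
        return IntensityMatrix(self.probe_ids[idx], self.sample_ids.copy(),
                               self.values[idx].copy())

    def select_samples_mask(self, keep: np.ndarray) -> "IntensityMatrix":
        keep = np.asarray(keep, dtype=bool)
        return IntensityMatrix(self.probe_ids.copy(), self.sample_ids[keep],
                               self.values[:, keep].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.probe_ids, name="probe_id"),
                            columns=list(self.sample_ids))


@dataclass
class ProbeAnnotation:
    """Per-probe genomic metadata: chromosome (canonical label), 1-based
    position, minor allele frequency, call rate and GC fraction of the
    probe's flanking window."""

    df: pd.DataFrame  # index probe_id; chromosome, position, maf, call_rate, gc_fraction

    REQUIRED = ("chromosome", "position", "maf", "call_rate", "gc_fraction")

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValidationError("duplicate probe IDs in annotation")
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise FormatError(f"probe annotation missing columns: {missing}")
        self.df = self.df.copy()
        self.df["chromosome"] = [normalize_chromosome(c) for c in self.df["chromosome"]]
        maf = self.df["maf"].to_numpy(dtype=float)
        if np.any((maf < 0) | (maf > 0.5)):
            bad = self.df.index[(maf < 0) | (maf > 0.5)][0]
            raise ValidationError(f"maf outside [0, 0.5] for probe {bad!r}")
        for col, hi in (("call_rate", 1.0), ("gc_fraction", 1.0)):
            v = self.df[col].to_numpy(dtype=float)
            if np.any((v < 0) | (v > hi)):
                bad = self.df.index[(v < 0) | (v > hi)][0]
                raise ValidationError(f"{col} outside [0, {hi}] for probe {bad!r}")

    def loc(self, probe_ids) -> pd.DataFrame:
        return self.df.loc[list(probe_ids)]

    def is_autosomal(self, probe_ids) -> np.ndarray:
        chrom = self.df.loc[list(probe_ids), "chromosome"]
        return chrom.isin(_AUTOSOMES).to_numpy()

    def is_mitochondrial(self, probe_ids) -> np.ndarray:
        chrom = self.df.loc[list(probe_ids), "chromosome"]
        return (chrom == "MT").to_numpy()


@dataclass
class SampleAnnotation:
    """Per-sample covariates: sex ("female"/"male"/"unknown"), age in years
    (NaN allowed) and any extra named real-valued columns."""

    df: pd.DataFrame  # index sample_id; sex, age, extras

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            raise ValidationError("duplicate sample IDs in annotation")
        self.df = self.df.copy()
        if "sex" not in self.df.columns:
            self.df["sex"] = "unknown"
        norm = []
        for v in self.df["sex"]:
            key = str(v).strip().lower()
            if key not in _SEX_ALIASES:
                raise ValidationError(f"malformed sex value {v!r}")
            norm.append(_SEX_ALIASES[key])
        self.df["sex"] = norm
        if "age" not in self.df.columns:
            self.df["age"] = np.nan
        try:
            self.df["age"] = pd.to_numeric(self.df["age"])
        except (TypeError, ValueError) as e:
            raise ValidationError(f"malformed age column: {e}") from None

    def female_indicator(self, sample_ids) -> np.ndarray:
        """1.0 female, 0.0 male, NaN unknown — the fixed sign convention for
        all sex correlations in the pipeline."""
        sex = self.df.loc[list(sample_ids), "sex"].to_numpy()
        out = np.full(len(sex), np.nan)
        out[sex == "female"] = 1.0
        out[sex == "male"] = 0.0
        return out

    def age(self, sample_ids) -> np.ndarray:
        return self.df.loc[list(sample_ids), "age"].to_numpy(dtype=float)


@dataclass
class RegionSet:
    """Genomic intervals, 0-based half-open, on canonical chromosome labels."""

    intervals: list = field(default_factory=list)  # (chromosome, start, end)

    def __post_init__(self) -> None:
        norm = []
        for chrom, start, end in self.intervals:
            start, end = int(start), int(end)
            if start >= end:
                raise FormatError(f"interval start >= end: {chrom}:{start}-{end}")
            norm.append((normalize_chromosome(chrom), start, end))
        self.intervals = norm

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chromosomes, positions) -> np.ndarray:
        """Membership of 1-based positions in the 0-based half-open intervals:
        position p is inside (c, s, e) iff s < p <= e."""
        chromosomes = np.asarray(chromosomes, dtype=object)
        positions = np.asarray(positions, dtype=np.int64)
        hit = np.zeros(len(positions), dtype=bool)
        for chrom, start, end in self.intervals:
            hit |= (chromosomes == chrom) & (positions > start) & (positions <= end)
        return hit


@dataclass
class MtEstimates:
    """Final per-sample mtDNA-CN estimates.

    ``mtdna_cn`` is standardized (mean 0, population SD 1 over retained
    samples); ``raw_mt_pc`` is the unstandardized score the estimator
    produced (top MT principal component, or the MT median in legacy mode).
    """

    sample_ids: np.ndarray
    raw_mt_pc: np.ndarray
    mtdna_cn: np.ndarray
    n_mt_probes_used: int
    sign_flipped: bool = False
    alignment_covariate: str = "none"  # {"sex", "age", "none"}
    estimator: str = "pca"  # {"pca", "median"}
    region_label: str = "MT"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample_id": list(self.sample_ids),
            "mtdna_cn": self.mtdna_cn,
            "raw_mt_pc": self.raw_mt_pc,
            "n_mt_probes_used": self.n_mt_probes_used,
        })


# ---------------------------------------------------------------------------
# readers / writers


def read_l2r_matrix(path) -> IntensityMatrix:
    """Read a probe-major L2R matrix TSV (first column ``probe_id``,
    remaining headers sample IDs, cells decimal or ``NA``)."""
    with open(path, "rt") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "probe_id":
            raise FormatError(f"{path}: first column header must be 'probe_id'")
        sample_ids = header[1:]
        if len(set(sample_ids)) != len(sample_ids):
            raise FormatError(f"{path}: duplicated sample ID in header")
        probe_ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise FormatError(f"{path}:{lineno}: expected {len(header)} fields, "
                                  f"got {len(fields)}")
            probe_ids.append(fields[0])
            row = np.empty(len(sample_ids))
            for j, cell in enumerate(fields[1:]):
                if cell == "NA":
                    row[j] = np.nan
                else:
                    try:
                        row[j] = float(cell)
                    except ValueError:
                        raise FormatError(
                            f"{path}:{lineno}: non-numeric cell {cell!r} in row "
                            f"{fields[0]!r}, column {sample_ids[j]!r}") from None
            rows.append(row)
    if len(set(probe_ids)) != len(probe_ids):
        raise FormatError(f"{path}: duplicated probe ID")
    values = np.vstack(rows) if rows else np.empty((0, len(sample_ids)))
    return IntensityMatrix(np.array(probe_ids, dtype=object),
                           np.array(sample_ids, dtype=object), values)


def write_l2r_matrix(path, matrix: IntensityMatrix) -> None:
    """Write the matrix in the dialect ``read_l2r_matrix`` reads; missing
    cells become ``NA``; floats use repr precision so the round trip is
    bit-exact."""
    with open(path, "wt") as fh:
        fh.write("probe_id\t" + "\t".join(str(s) for s in matrix.sample_ids) + "\n")
        for pid, row in zip(matrix.probe_ids, matrix.values):
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(pid) + "\t" + "\t".join(cells) + "\n")


def read_probe_annotation(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chromosome": str})
    if "probe_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'probe_id'")
    missing = [c for c in ProbeAnnotation.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {missing}")
    return ProbeAnnotation(df.set_index("probe_id"))


def write_probe_annotation(path, probes: ProbeAnnotation) -> None:
    probes.df.rename_axis("probe_id").to_csv(path, sep="\t")


def read_sample_annotation(path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "sex": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    return SampleAnnotation(df.set_index("sample_id"))


def write_sample_annotation(path, samples: SampleAnnotation) -> None:
    samples.df.rename_axis("sample_id").to_csv(path, sep="\t")


def read_bed(path) -> RegionSet:
    """Read a 3+-column BED file (0-based half-open intervals)."""
    intervals = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: BED line has <3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer BED coordinates") from None
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            intervals.append((fields[0], start, end))
    return RegionSet(intervals)


_ESTIMATE_COLUMNS = ("sample_id", "mtdna_cn", "raw_mt_pc", "n_mt_probes_used")


def write_estimates(path, estimates: MtEstimates) -> None:
    """Write the estimates TSV (sample_id, mtdna_cn, raw_mt_pc,
    n_mt_probes_used) at repr float precision."""
    with open(path, "wt") as fh:
        fh.write("\t".join(_ESTIMATE_COLUMNS) + "\n")
        for sid, cn, raw in zip(estimates.sample_ids, estimates.mtdna_cn,
                                estimates.raw_mt_pc):
            fh.write(f"{sid}\t{float(cn)!r}\t{float(raw)!r}\t"
                     f"{estimates.n_mt_probes_used}\n")


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in _ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns: {missing}")
    return df
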