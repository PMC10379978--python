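"""Input/output, validation, configuration and logging.

All external inputs to the pipeline pass through this module: fragment-count
matrices (features x samples, TSV), gene models (GFF3 or a 5-column TSV that
also carries the allele pairing of the haplotype-resolved assembly), the
sample sheet describing the pooled-library stress design, term->gene
annotation maps, and plain gene lists.  Everything downstream consumes the
validated containers returned here.

Counts are kept as plain pandas DataFrames (features as index, samples as
columns, integer dtype); gene models and sample metadata are small frozen
dataclasses.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HaplodynError",
    "FormatError",
    "ValidationError",
    "ConfigurationError",
    "PipelineStageError",
    "SampleMeta",
    "GeneModel",
    "TREATMENTS",
    "TIME_POINTS",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_models",
    "write_gene_models",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_term_map",
    "read_gene_list",
    "attach_library_sizes",
    "models_by_id",
    "write_json",
    "get_logger",
    "configure_logging",
]

TREATMENTS = ("control", "NaCl", "PEG")
TIME_POINTS = (0, 24, 48, 72)


class HaplodynError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(HaplodynError):
    """A file could not be parsed (malformed line, wrong column count...)."""


class ValidationError(HaplodynError):
    """Parsed content violates an invariant (duplicates, bad labels...)."""


class ConfigurationError(HaplodynError):
    """Inconsistent or impossible configuration values."""


class PipelineStageError(HaplodynError):
    """A pipeline stage failed; carries the stage name for context."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


# ---------------------------------------------------------------------------
# logging
# ---------------------------------------------------------------------------

_LOGGER_NAME = "haplodyn"


def get_logger(child: str | None = None) -> logging.Logger:
    name = _LOGGER_NAME if child is None else f"{_LOGGER_NAME}.{child}"
    return logging.getLogger(name)


def configure_logging(verbose: bool = False) -> None:
    """Route package logs to stderr; ``verbose`` lowers the level to DEBUG."""
    logger = logging.getLogger(_LOGGER_NAME)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleMeta:
    """One pooled RNA-seq library.

    treatment is one of control/NaCl/PEG; time_h is hours of continuous
    treatment (0 exists only for control).  library_size (total assigned
    fragments) is unset until the sheet is bound to a count matrix.
    """

    sample_id: str
    treatment: str
    time_h: int
    library_size: int | None = None

    def __post_init__(self):
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown treatment {self.treatment!r}; "
                f"expected one of {TREATMENTS}"
            )
        if self.time_h not in TIME_POINTS:
            raise ValidationError(
                f"sample {self.sample_id!r}: time {self.time_h} h not in {TIME_POINTS}"
            )
        if self.library_size is not None and self.library_size <= 0:
            raise ValidationError(f"sample {self.sample_id!r}: non-positive library size")


@dataclass(frozen=True)
class GeneModel:
    """A gene with its (optional) pair of haplotype-resolved alleles."""

    gene_id: str
    chromosome: str
    length_bp: int
    allele_a_id: str | None = None
    allele_b_id: str | None = None

    def __post_init__(self):
        if self.length_bp < 1:
            raise ValidationError(f"gene {self.gene_id!r}: length_bp must be >= 1")
        has_a, has_b = self.allele_a_id is not None, self.allele_b_id is not None
        if has_a != has_b:
            raise ValidationError(f"gene {self.gene_id!r}: allele pair incomplete")
        if has_a and self.allele_a_id == self.allele_b_id:
            raise ValidationError(f"gene {self.gene_id!r}: alleles must be distinct")

    @property
    def has_alleles(self) -> bool:
        return self.allele_a_id is not None


def models_by_id(models: Iterable[GeneModel]) -> dict[str, GeneModel]:
    out: dict[str, GeneModel] = {}
    for m in models:
        if m.gene_id in out:
            raise ValidationError(f"duplicate gene id {m.gene_id!r}")
        out[m.gene_id] = m
    return out


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def read_count_matrix(path: str | Path, id_kind: str = "gene") -> pd.DataFrame:
    """Read a features x samples fragment-count TSV.

    First header cell is arbitrary; '#' lines are ignored; cells must be
    nonnegative integers.  Returns a DataFrame with the feature ids as index
    (named after ``id_kind``) and sample ids as columns.
    """
    path = Path(path)
    header: list[str] | None = None
    ids: list[str] = []
    rows: list[list[int]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if header is None:
                if len(cells) < 2:
                    raise FormatError(f"{path}:{lineno}: header needs >= 2 columns")
                header = cells[1:]
                continue
            if len(cells) != len(header) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header) + 1} columns, got {len(cells)}"
                )
            ids.append(cells[0])
            try:
                values = [int(c) for c in cells[1:]]
            except ValueError as exc:
                raise ValidationError(f"{path}:{lineno}: non-integer count ({exc})") from None
            if any(v < 0 for v in values):
                raise ValidationError(f"{path}:{lineno}: negative count for {cells[0]!r}")
            rows.append(values)
    if header is None:
        raise FormatError(f"{path}: empty count matrix (no header line)")
    if len(set(header)) != len(header):
        dupes = sorted({s for s in header if header.count(s) > 1})
        raise ValidationError(f"{path}: duplicated sample ids {dupes}")
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupe = next(i for i in ids if i in seen or seen.add(i))  # type: ignore[func-returns-value]
        raise ValidationError(f"{path}: duplicated {id_kind} id {dupe!r}")
    mat = pd.DataFrame(rows, index=pd.Index(ids, name=f"{id_kind}_id"), columns=header, dtype=np.int64)
    return mat


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index_label=counts.index.name or "feature_id")


def validate_count_matrix(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates or counts.columns.has_duplicates:
        raise ValidationError("count matrix has duplicated row or column ids")
    vals = counts.to_numpy()
    if not np.issubdtype(vals.dtype, np.integer):
        if not np.allclose(vals, np.round(vals)):
            raise ValidationError("count matrix contains non-integer values")
    if (vals < 0).any():
        raise ValidationError("count matrix contains negative values")


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def _merged_interval_length(intervals: Sequence[tuple[int, int]]) -> int:
    """Total covered length of 1-based inclusive intervals after merging."""
    total = 0
    cur_start = cur_end = None
    for start, end in sorted(intervals):
        if cur_end is None:
            cur_start, cur_end = start, end
        elif start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part or "=" not in part:
            continue
        key, value = part.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def _read_gff3(path: Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}  # id -> {chrom, span}
    tx_parent: dict[str, str] = {}  # transcript id -> gene id
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cells)}")
            chrom, _src, ftype, start_s, end_s, _score, _strand, _phase, attrs_s = cells
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end < start:
                raise ValidationError(f"{path}:{lineno}: end < start")
            attrs = _parse_gff3_attributes(attrs_s)
            if ftype == "gene":
                if "ID" not in attrs:
                    raise FormatError(f"{path}:{lineno}: gene feature missing ID attribute")
                gid = attrs["ID"]
                if gid in genes:
                    raise ValidationError(f"{path}: duplicated gene id {gid!r}")
                genes[gid] = {"chrom": chrom, "span": (start, end)}
                order.append(gid)
            elif ftype in ("mRNA", "transcript"):
                if "ID" not in attrs or "Parent" not in attrs:
                    raise FormatError(f"{path}:{lineno}: transcript missing ID or Parent")
                tx_parent[attrs["ID"]] = attrs["Parent"]
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: exon missing Parent")
                for p in parent.split(","):
                    tx_exons.setdefault(p, []).append((start, end))
    models = []
    for gid in order:
        info = genes[gid]
        tx_lengths = [
            _merged_interval_length(exons)
            for tx, exons in tx_exons.items()
            if tx_parent.get(tx) == gid or tx == gid  # exons may hang off the gene itself
        ]
        span = info["span"]
        length = max(tx_lengths) if tx_lengths else span[1] - span[0] + 1
        models.append(GeneModel(gid, info["chrom"], length))
    return models


_TSV_MODEL_COLUMNS = ("gene_id", "chromosome", "length_bp", "allele_a_id", "allele_b_id")


def _read_models_tsv(path: Path) -> list[GeneModel]:
    models = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if cells[0] == "gene_id":  # optional header
                continue
            if len(cells) not in (3, 5):
                raise FormatError(f"{path}:{lineno}: expected 3 or 5 columns, got {len(cells)}")
            try:
                length = int(cells[2])
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-integer length") from None
            allele_a = allele_b = None
            if len(cells) == 5 and cells[3] not in ("", ".") and cells[4] not in ("", "."):
                allele_a, allele_b = cells[3], cells[4]
            models.append(GeneModel(cells[0], cells[1], length, allele_a, allele_b))
    _check_model_uniqueness(models, path)
    return models


def _check_model_uniqueness(models: Sequence[GeneModel], path: Path | None = None) -> None:
    where = f"{path}: " if path else ""
    gene_ids = [m.gene_id for m in models]
    if len(set(gene_ids)) != len(gene_ids):
        raise ValidationError(f"{where}duplicated gene ids in gene models")
    allele_ids = [a for m in models for a in (m.allele_a_id, m.allele_b_id) if a is not None]
    if len(set(allele_ids)) != len(allele_ids):
        raise ValidationError(f"{where}allele ids are not unique across gene models")


def read_gene_models(path: str | Path, format: str | None = None) -> list[GeneModel]:
    """Read gene models from GFF3 or the 5-column TSV.

    GFF3 gene length is the merged-exon length of the longest transcript,
    falling back to the 1-based inclusive gene span when no exons are given.
    """
    path = Path(path)
    if format is None:
        format = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "tsv"
    if format == "gff3":
        models = _read_gff3(path)
        _check_model_uniqueness(models, path)
        return models
    if format == "tsv":
        return _read_models_tsv(path)
    raise ConfigurationError(f"unknown gene-model format {format!r}")


def write_gene_models(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(_TSV_MODEL_COLUMNS) + "\n")
        for m in models:
            fh.write(
                f"{m.gene_id}\t{m.chromosome}\t{m.length_bp}\t"
                f"{m.allele_a_id or '.'}\t{m.allele_b_id or '.'}\n"
            )


# ---------------------------------------------------------------------------
# sample sheet
# ---------------------------------------------------------------------------


def validate_design(samples: Sequence[SampleMeta]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids in sample sheet")
    conditions = [(s.treatment, s.time_h) for s in samples]
    if len(set(conditions)) != len(conditions):
        dupe = next(c for c in conditions if conditions.count(c) > 1)
        raise ValidationError(f"duplicate condition {dupe} (pooled design: one library each)")
    control_times = {s.time_h for s in samples if s.treatment == "control"}
    for s in samples:
        if s.treatment != "control" and s.time_h not in control_times:
            raise ValidationError(
                f"treated sample {s.sample_id!r} at {s.time_h} h has no control at that time"
            )


def read_sample_sheet(path: str | Path) -> list[SampleMeta]:
    """Read the sample sheet TSV (columns sample_id, treatment, time_h)."""
    path = Path(path)
    samples = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if cells[0] == "sample_id":
                continue
            if len(cells) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 columns")
            try:
                time_h = int(cells[2])
            except ValueError:
                raise ValidationError(f"{path}:{lineno}: non-integer time") from None
            samples.append(SampleMeta(cells[0], cells[1], time_h))
    validate_design(samples)
    return samples


def write_sample_sheet(samples: Iterable[SampleMeta], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\ttreatment\ttime_h\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.treatment}\t{s.time_h}\n")


def attach_library_sizes(samples: Sequence[SampleMeta], counts: pd.DataFrame) -> list[SampleMeta]:
    """Bind samples to a count matrix: set library_size = column sum.

    Every sample must be a column of ``counts``.
    """
    missing = [s.sample_id for s in samples if s.sample_id not in counts.columns]
    if missing:
        raise ValidationError(f"samples absent from count matrix: {missing}")
    sums = counts.sum(axis=0)
    return [replace(s, library_size=int(sums[s.sample_id])) for s in samples]


# ---------------------------------------------------------------------------
# annotation maps, gene lists, JSON
# ---------------------------------------------------------------------------


def read_term_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV term_id<TAB>gene_id -> {term: set of genes}."""
    path = Path(path)
    out: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cells = line.split("\t")
            if len(cells) < 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            out.setdefault(cells[0], set()).add(cells[1])
    return out


def read_gene_list(path: str | Path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def write_json(obj: Mapping, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
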