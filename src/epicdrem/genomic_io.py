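"""Readers, writers and core containers for the genomic file formats the
pipeline touches.

Every coordinate inside the package is 0-based half-open (the BED
convention): ``start`` is the first base of a region and ``end`` is one past
the last. GTF-like TSS tables, which are 1-based inclusive on disk, are
converted on read. bedGraph tracks are interpreted as step functions;
overlapping bedGraph intervals are rejected as malformed input.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as _bio_motifs

__all__ = [
    "GenomicRegion",
    "GeneAnnotation",
    "PWM",
    "ExpressionSeries",
    "read_regions",
    "write_regions",
    "read_pwms",
    "read_expression",
    "write_expression",
    "read_tss_table",
    "read_bedgraph",
    "read_fasta",
    "write_fasta",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class GenomicRegion:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    id: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in region {self}")
        if self.end <= self.start:
            raise ValueError(
                f"zero- or negative-length region {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicRegion") -> bool:
        """True iff the two regions share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with one or more annotated transcription start sites.

    ``tss_list`` holds 0-based positions; the 5'-most TSS (minimum on the +
    strand, maximum on the - strand) anchors promoter and association
    windows downstream.
    """

    gene_id: str
    chrom: str
    strand: str
    tss_list: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.tss_list:
            raise ValueError(f"gene {self.gene_id} has no TSS")
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )


@dataclass(frozen=True)
class PWM:
    """Position weight matrix: per-position base probabilities for a motif.

    ``matrix`` has shape (motif_length, 4) in A, C, G, T order. Rows are
    probability distributions after pseudocount regularization.
    """

    tf_name: str
    matrix: np.ndarray
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"PWM {self.tf_name}: matrix must be L x 4 with L >= 1")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"PWM {self.tf_name}: rows must sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def motif_length(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    @classmethod
    def from_counts(
        cls, tf_name: str, counts: np.ndarray, pseudocount: float = 0.01
    ) -> "PWM":
        """Build a PWM from a count (or unnormalized frequency) matrix.

        The pseudocount is added per cell before row renormalization, which
        keeps every probability strictly positive so that log-ratio binding
        energies stay finite.
        """
        c = np.asarray(counts, dtype=float)
        if c.ndim != 2 or c.shape[1] != 4:
            raise ValueError(f"PWM {tf_name}: counts must be L x 4")
        if (c < 0).any():
            raise ValueError(f"PWM {tf_name}: negative counts")
        if (c.sum(axis=1) == 0).any():
            raise FormatError(f"PWM {tf_name}: row of all zeros")
        c = c + pseudocount
        return cls(tf_name, c / c.sum(axis=1, keepdims=True), pseudocount)


@dataclass
class ExpressionSeries:
    """A gene x time matrix of log2 expression over an ordered time course."""

    gene_ids: list[str]
    time_points: list[str]
    values: np.ndarray
    reference_time: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.time_points)):
            raise ValueError("expression matrix shape does not match labels")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids in expression series")
        if self.reference_time not in self.time_points:
            raise ValueError(
                f"reference time {self.reference_time!r} not among time points"
            )
        if np.isnan(self.values).any():
            raise ValueError("missing values in expression matrix")

    @property
    def reference_index(self) -> int:
        return self.time_points.index(self.reference_time)

    def log2fc_vs_reference(self) -> np.ndarray:
        """Per-gene log2 fold change of each time point against the reference."""
        return self.values - self.values[:, [self.reference_index]]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in expression series") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.time_points)


# ---------------------------------------------------------------------------
# BED / bedGraph


def read_regions(path: str | Path, min_fields: int = 3) -> list[GenomicRegion]:
    """Read a BED file into :class:`GenomicRegion` records, in file order.

    Parameters
    ----------
    path:
        BED3+ file; track/browser/comment lines are skipped.
    min_fields:
        Minimum number of tab-separated columns each data line must carry.
    """
    regions: list[GenomicRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < max(min_fields, 3):
                raise FormatError(
                    f"{path}:{lineno}: expected >= {max(min_fields, 3)} fields, "
                    f"got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: float | None = None
            if len(fields) > 4 and fields[4] not in {".", ""}:
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                regions.append(
                    GenomicRegion(fields[0], start, end, id=name, score=score, strand=strand)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return regions


def write_regions(regions: Iterable[GenomicRegion], path: str | Path) -> None:
    """Write regions as BED; emits the minimal number of columns needed."""
    with open(path, "w") as fh:
        for r in regions:
            fields = [r.chrom, str(r.start), str(r.end)]
            if r.id is not None or r.score is not None or r.strand != ".":
                fields.append(r.id if r.id is not None else ".")
            if r.score is not None or r.strand != ".":
                fields.append(f"{r.score:g}" if r.score is not None else ".")
            if r.strand != ".":
                fields.append(r.strand)
            fh.write("\t".join(fields) + "\n")


def read_bedgraph(path: str | Path) -> dict[str, np.ndarray]:
    """Read a bedGraph step-function track.

    Returns a mapping ``chrom -> (starts, ends, values)`` stacked as a
    ``(3, n)`` float array, sorted by start. Overlapping intervals on one
    chromosome are an input error: a bedGraph is a partial step function.
    """
    rows: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph line") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            rows.setdefault(fields[0], []).append((start, end, value))
    out: dict[str, np.ndarray] = {}
    for chrom, ivs in rows.items():
        ivs.sort()
        arr = np.array(ivs, dtype=float).T
        if (arr[1, :-1] > arr[0, 1:]).any():
            raise ValueError(f"{path}: overlapping bedGraph intervals on {chrom}")
        out[chrom] = arr
    return out


# ---------------------------------------------------------------------------
# Motifs


def read_pwms(path: str | Path, pseudocount: float = 0.01) -> list[PWM]:
    """Read motifs from a JASPAR-style or MEME-style text file.

    The format is sniffed: a ``MEME version`` header selects the MEME
    letter-probability parser, otherwise the file is handed to Biopython's
    JASPAR reader. Counts (or probabilities) are regularized with
    ``pseudocount`` per cell and renormalized per position.
    """
    text = Path(path).read_text()
    if "MEME version" in text:
        return _read_meme(text, pseudocount, str(path))
    if not text.lstrip().startswith(">"):
        raise FormatError(f"{path}: unrecognized motif format")
    try:
        records = _bio_motifs.parse(_io.StringIO(text), "jaspar")
    except Exception as exc:  # Biopython raises bare ValueError/KeyError
        raise FormatError(f"{path}: failed to parse JASPAR motifs: {exc}") from exc
    pwms = []
    for rec in records:
        counts = np.array([rec.counts[b] for b in _BASES], dtype=float).T
        name = rec.name or rec.matrix_id
        pwms.append(PWM.from_counts(name, counts, pseudocount))
    return pwms


def _read_meme(text: str, pseudocount: float, label: str) -> list[PWM]:
    pwms: list[PWM] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"motif_{len(pwms)}"
            # advance to the letter-probability matrix header
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{label}: motif {name} lacks a probability matrix")
                i += 1
            if i == len(lines):
                raise FormatError(f"{label}: motif {name} lacks a probability matrix")
            i += 1
            rows: list[list[float]] = []
            while i < len(lines):
                stripped = lines[i].strip()
                fields = stripped.split()
                if len(fields) == 4:
                    try:
                        rows.append([float(x) for x in fields])
                    except ValueError:
                        break
                    i += 1
                else:
                    break
            if not rows:
                raise FormatError(f"{label}: empty matrix for motif {name}")
            pwms.append(PWM.from_counts(name, np.array(rows), pseudocount))
        else:
            i += 1
    if not pwms:
        raise FormatError(f"{label}: no MOTIF blocks found")
    return pwms


def write_pwms_jaspar(pwms: Sequence[PWM], path: str | Path, scale: int = 100) -> None:
    """Write PWMs as JASPAR count blocks (probabilities scaled to ``scale``)."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.tf_name}\t{p.tf_name}\n")
            counts = np.round(p.matrix * scale).astype(int)
            for bi, base in enumerate(_BASES):
                vals = "  ".join(str(v) for v in counts[:, bi])
                fh.write(f"{base}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# Expression


def read_expression(
    path: str | Path, reference_time: str | None = None
) -> ExpressionSeries:
    """Read a gene x time TSV of log2 expression.

    First column holds gene ids; the header row holds time-point labels in
    course order. ``reference_time`` defaults to the first column.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except ValueError as exc:
        raise FormatError(f"{path}: cannot parse expression table: {exc}") from exc
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups}")
    values = df.to_numpy(dtype=float)  # raises on non-numeric cells
    if np.isnan(values).any():
        raise FormatError(f"{path}: non-numeric or missing expression values")
    times = [str(c) for c in df.columns]
    return ExpressionSeries(
        gene_ids=[str(g) for g in df.index],
        time_points=times,
        values=values,
        reference_time=reference_time if reference_time is not None else times[0],
    )


def write_expression(expr: ExpressionSeries, path: str | Path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# TSS tables


def read_tss_table(path: str | Path, one_based: bool = False) -> list[GeneAnnotation]:
    """Read a TSS table: gene_id, chrom, strand, comma-separated TSS positions.

    With ``one_based=True`` (GTF-like provenance) positions are shifted to
    the internal 0-based convention on read.
    """
    genes: list[GeneAnnotation] = []
    offset = 1 if one_based else 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                tss = tuple(int(x) - offset for x in fields[3].split(","))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad TSS list") from exc
            genes.append(GeneAnnotation(fields[0], fields[1], fields[2], tss))
    return genes


def write_tss_table(genes: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.gene_id}\t{g.chrom}\t{g.strand}\t"
                + ",".join(str(t) for t in g.tss_list)
                + "\n"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an upper-cased chrom -> sequence dict.

    Genomes at the scale this pipeline targets fit comfortably in memory;
    sequence access everywhere else in the package goes through this dict.
    """
    seqs: dict[str, list[str]] = {}
    name: str | None = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValueError(f"{path}: duplicate sequence {name}")
                seqs[name] = []
            else:
                if name is None:
                    raise FormatError(f"{path}: sequence data before header")
                seqs[name].append(line.upper())
    if not seqs:
        raise FormatError(f"{path}: empty FASTA")
    return {k: "".join(v) for k, v in seqs.items()}


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(genome: dict[str, str], region: GenomicRegion) -> str:
    """Extract the sequence under ``region``, validating bounds."""
    if region.chrom not in genome:
        raise KeyError(f"region {region} on unknown chromosome {region.chrom}")
    seq = genome[region.chrom]
    if region.end > len(seq):
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds "
            f"chromosome length {len(seq)}"
        )
    return seq[region.start : region.end]
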