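"""Readers and writers for every external format the pipeline touches.

Supported formats: ENCODE narrowPeak (10 columns), BED6 gene bodies,
GTF-lite ("gene" features only), BED tag intervals, TSV expression matrix +
TSV sample metadata, JASPAR PFM motif text, and FASTA.

Internally everything is 0-based half-open; GTF (1-based inclusive) is
converted on read.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .types import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    PWM,
    Peak,
    PeakSet,
    SampleMeta,
    TagSet,
)


class FormatError(ValueError):
    """A malformed input file; the message names the offending line/cell."""


def _fields(line: str) -> list[str]:
    return line.rstrip("\n").split("\t") if "\t" in line else line.split()


# ---------------------------------------------------------------------------
# Peaks (narrowPeak)
# ---------------------------------------------------------------------------

def load_peaks(path: str | Path, label: str) -> PeakSet:
    """Read an ENCODE narrowPeak file into a :class:`PeakSet`.

    The summit is ``start + column 10`` (the summit offset); an offset of
    ``-1`` falls back to the interval midpoint (floor).
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = _fields(line)
            if len(f) < 10:
                raise FormatError(
                    f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(f)}"
                )
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, score, strand = f[3], float(f[4]), f[5]
                offset = int(f[9])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            if offset == -1:
                summit = (start + end) // 2
            else:
                summit = start + offset
            try:
                peak = Peak(GenomicInterval(chrom, start, end, strand), summit, name, score)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            peaks.append(peak)
    return PeakSet(label, peaks)


def write_peaks(peakset: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as 10-column narrowPeak (summit as offset from start)."""
    with open(path, "w") as fh:
        for p in peakset:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        str(int(p.score)),
                        p.interval.strand,
                        "0",
                        "-1",
                        "-1",
                        str(p.summit - p.start),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Genes (BED6 / GTF-lite)
# ---------------------------------------------------------------------------

def load_genes(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 or GTF-lite (``gene`` features).

    Format is sniffed from the extension (``.gtf``/``.gff``) falling back to
    BED6.  Duplicate gene ids are rejected; strand is required.
    """
    path = Path(path)
    if path.suffix.lower() in (".gtf", ".gff"):
        genes = _load_genes_gtf(path)
    else:
        genes = _load_genes_bed(path)
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise FormatError(f"{path}: duplicate gene id {g.gene_id!r}")
        seen.add(g.gene_id)
    return genes


def _load_genes_bed(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _fields(line)
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 requires 6 columns")
            chrom, start, end, name, _score, strand = f[:6]
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            try:
                iv = GenomicInterval(chrom, int(start), int(end), strand)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            genes.append(GeneModel(name, iv))
    return genes


def _load_genes_gtf(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: GTF requires 9 columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = f[:9]
            if feature != "gene":
                continue
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: missing or invalid strand {strand!r}")
            gene_id = None
            for attr in attrs.strip().strip(";").split(";"):
                parts = attr.strip().split(None, 1)
                if len(parts) == 2 and parts[0] == "gene_id":
                    gene_id = parts[1].strip().strip('"')
            if not gene_id:
                raise FormatError(f"{path}:{lineno}: no gene_id attribute")
            try:
                # GTF is 1-based inclusive -> 0-based half-open
                iv = GenomicInterval(chrom, int(start) - 1, int(end), strand)
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            genes.append(GeneModel(gene_id, iv))
    return genes


def write_genes_bed(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.gene_id}\t0\t{g.strand}\n"
            )


# ---------------------------------------------------------------------------
# Tags (BED intervals -> fragment midpoints)
# ---------------------------------------------------------------------------

def load_tags(path: str | Path, label: str) -> TagSet:
    """Read aligned-tag BED intervals; the tag position is the midpoint."""
    positions: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = _fields(line)
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED requires >= 3 columns")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
            except ValueError as e:
                raise FormatError(f"{path}:{lineno}: {e}") from None
            positions.setdefault(chrom, []).append((start + end) // 2)
    return TagSet(label, positions)


def write_tags(tags: TagSet, path: str | Path, read_length: int = 1) -> None:
    """Write tag positions as BED; midpoint of each written interval round-trips."""
    half = read_length // 2
    with open(path, "w") as fh:
        for chrom in sorted(tags.positions):
            for pos in tags.positions[chrom]:
                fh.write(f"{chrom}\t{pos - half}\t{pos - half + read_length}\n")


# ---------------------------------------------------------------------------
# Expression matrix + metadata
# ---------------------------------------------------------------------------

def load_expression(path_values: str | Path, path_meta: str | Path) -> ExpressionMatrix:
    """Read a genes x samples log2 TSV and its sample metadata TSV.

    The values TSV has a header row of sample labels and gene ids in the
    first column.  The metadata TSV needs columns label/stage/induced/
    replicate.  NA values and duplicate gene rows are errors.
    """
    df = pd.read_csv(path_values, sep="\t", index_col=0, comment="#")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path_values}: duplicate gene row {dup!r}")
    for col in df.columns:
        bad = df[col].isna()
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = bad | coerced.isna()
            df[col] = coerced
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path_values}: value at gene {gene!r}, sample {col!r} "
                "is missing or not numeric"
            )
    meta = pd.read_csv(path_meta, sep="\t", comment="#")
    required = {"label", "stage", "induced", "replicate"}
    if not required.issubset(meta.columns):
        raise FormatError(f"{path_meta}: metadata needs columns {sorted(required)}")
    meta_by_label = {}
    for _, row in meta.iterrows():
        induced = row["induced"]
        if isinstance(induced, str):
            induced = induced.strip().lower() in ("true", "1", "yes")
        meta_by_label[str(row["label"])] = SampleMeta(
            label=str(row["label"]),
            stage=str(row["stage"]),
            induced=bool(induced),
            replicate=int(row["replicate"]),
        )
    samples = []
    for col in df.columns:
        if str(col) not in meta_by_label:
            raise FormatError(f"{path_meta}: sample {col!r} has no metadata row")
        samples.append(meta_by_label[str(col)])
    return ExpressionMatrix(list(df.index.astype(str)), samples, df.to_numpy(dtype=float))


def write_expression(
    m: ExpressionMatrix, path_values: str | Path, path_meta: str | Path
) -> None:
    df = pd.DataFrame(m.values, index=m.gene_ids, columns=m.sample_labels)
    df.index.name = "gene_id"
    df.to_csv(path_values, sep="\t", float_format="%.6g")
    meta = pd.DataFrame(
        [
            {"label": s.label, "stage": s.stage, "induced": s.induced, "replicate": s.replicate}
            for s in m.samples
        ]
    )
    meta.to_csv(path_meta, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Motifs (JASPAR PFM)
# ---------------------------------------------------------------------------

def load_motifs(
    path: str | Path,
    background: Sequence[float] | None = None,
    pseudocount: float = 0.5,
) -> list[PWM]:
    """Read JASPAR-format PFMs (A/C/G/T count rows) into :class:`PWM` objects."""
    with open(path) as fh:
        text = fh.read()
    try:
        records = bio_motifs.parse(_io.StringIO(text), "jaspar")
        parsed = [
            (m.matrix_id or m.name, np.array([m.counts[b] for b in "ACGT"], dtype=float))
            for m in records
        ]
    except Exception as e:
        raise FormatError(f"{path}: cannot parse JASPAR PFM: {e}") from None
    if not parsed:
        raise FormatError(f"{path}: no motifs found")
    return [
        PWM(motif_id, counts, background=background, pseudocount=pseudocount)
        for motif_id, counts in parsed
    ]


def write_motifs(pwms: Iterable[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id}\t{pwm.motif_id}\n")
            for i, base in enumerate("ACGT"):
                vals = " ".join(f"{v:.0f}" for v in pwm.counts[i])
                fh.write(f"{base}  [ {vals} ]\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Output TSVs with provenance header
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, config_hash: str = "", seed: int | None = None,
                index: bool = False) -> None:
    """Write a TSV with a comment header recording config hash and seed."""
    with open(path, "w") as fh:
        fh.write(f"# regstage config={config_hash} seed={seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
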