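"""Readers/writers for the standard formats plus quantification primitives.

Containers
----------
:class:`ExpressionMatrix`
    genes x samples abundance table (raw counts or TPM) with the sample
    design attached.
:class:`MetaboliteMatrix`
    metabolites x seed-samples intensity table with one class label per
    metabolite (eleven-class vocabulary).
:class:`GeneModel`
    one gene locus with 1-based inclusive GFF3 coordinates and the
    summed-exon length used for TPM normalisation.

Primitives
----------
``counts_to_tpm``     length-normalised transcripts-per-million
``filter_expressed``  the "TPM > 3 in at least one sample" expression filter
``zscore_rows``       per-feature standardisation with optional clipping
"""

from __future__ import annotations

import re
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import GROUP_ORDER, SEED_STAGE_DAF, SampleDesign, validate_design
from .errors import ParameterError, ParseError, ValidationError
from .reference import METABOLITE_CLASSES

_SAMPLE_ID_RE = re.compile(r"^(?P<group>.+)_r(?P<rep>\d+)$")


def _design_from_ids(sample_ids: Sequence[str]) -> list[SampleDesign]:
    """Infer a SampleDesign list from `<group>_r<rep>` column names."""
    design = []
    for sid in sample_ids:
        m = _SAMPLE_ID_RE.match(sid)
        if not m or m.group("group") not in GROUP_ORDER:
            raise ValidationError(
                f"cannot infer sample design from column {sid!r}; "
                "pass an explicit design"
            )
        group = m.group("group")
        design.append(
            SampleDesign(sid, group, int(m.group("rep")), SEED_STAGE_DAF.get(group))
        )
    return design


class ExpressionMatrix:
    """Genes x samples abundance table with design metadata.

    Parameters
    ----------
    values : DataFrame
        Feature x sample table of non-negative reals; index holds the
        feature ids, columns the sample ids.
    design : list of SampleDesign, optional
        One entry per column, in column order. Inferred from
        ``<group>_r<rep>`` column names when omitted.
    unit : {"counts", "TPM"}
    lengths : Series, optional
        Per-feature length in bp (carried along for TPM conversion).
    """

    def __init__(
        self,
        values: pd.DataFrame,
        design: list[SampleDesign] | None = None,
        unit: str = "counts",
        lengths: pd.Series | None = None,
    ) -> None:
        if unit not in ("counts", "TPM"):
            raise ParameterError(f"unknown unit {unit!r}")
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        vals = values.astype(float)
        if not np.issubdtype(vals.to_numpy().dtype, np.number):
            raise ValidationError("non-numeric values in expression table")
        if (vals.to_numpy() < 0).any():
            raise ValidationError("negative values in expression table")
        if design is None:
            design = _design_from_ids(list(values.columns))
        if len(design) != values.shape[1]:
            raise ValidationError("design length does not match column count")
        if [s.sample_id for s in design] != list(values.columns):
            raise ValidationError("design sample ids do not match columns")
        validate_design(design)
        self.values = vals
        self.design = design
        self.unit = unit
        self.lengths = None if lengths is None else lengths.astype(float)

    # -- convenience -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def groups(self) -> list[str]:
        """Distinct groups in canonical order."""
        present = {s.group for s in self.design}
        return [g for g in GROUP_ORDER if g in present]

    def group_means(self) -> pd.DataFrame:
        """Feature x group table of replicate means, groups in stage order."""
        cols = {}
        for g in self.groups:
            ids = [s.sample_id for s in self.design if s.group == g]
            cols[g] = self.values[ids].mean(axis=1)
        return pd.DataFrame(cols)

    def subset(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.values.index]
        if missing:
            raise ValidationError(f"unknown feature ids: {missing[:5]}")
        lengths = None if self.lengths is None else self.lengths.loc[list(feature_ids)]
        return ExpressionMatrix(
            self.values.loc[list(feature_ids)], self.design, self.unit, lengths
        )

    def select_samples(self, predicate) -> "ExpressionMatrix":
        keep = [s for s in self.design if predicate(s)]
        ids = [s.sample_id for s in keep]
        return ExpressionMatrix(self.values[ids], keep, self.unit, self.lengths)


class MetaboliteMatrix:
    """Metabolites x seed-samples intensity table with class labels."""

    def __init__(
        self,
        values: pd.DataFrame,
        class_labels: pd.Series,
        design: list[SampleDesign] | None = None,
    ) -> None:
        if values.index.has_duplicates:
            raise ValidationError("duplicate metabolite ids")
        vals = values.astype(float)
        if (vals.to_numpy() < 0).any():
            raise ValidationError("negative metabolite intensities")
        labels = class_labels.reindex(values.index)
        if labels.isna().any():
            raise ValidationError("missing class label for some metabolites")
        bad = sorted(set(labels) - set(METABOLITE_CLASSES))
        if bad:
            raise ValidationError(f"class labels outside the 11-class vocabulary: {bad}")
        if design is None:
            design = _design_from_ids(list(values.columns))
        if [s.sample_id for s in design] != list(values.columns):
            raise ValidationError("design sample ids do not match columns")
        validate_design(design)
        self.values = vals
        self.class_labels = labels
        self.design = design

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    def group_means(self) -> pd.DataFrame:
        present = {s.group for s in self.design}
        cols = {}
        for g in [g for g in GROUP_ORDER if g in present]:
            ids = [s.sample_id for s in self.design if s.group == g]
            cols[g] = self.values[ids].mean(axis=1)
        return pd.DataFrame(cols)

    def class_counts(self) -> pd.Series:
        return self.class_labels.value_counts()


@dataclass(frozen=True)
class GeneModel:
    """One gene locus; GFF3-style 1-based inclusive coordinates."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.start < 1:
            raise ValidationError(f"gene {self.gene_id}: 1-based start must be >= 1")
        if self.strand not in "+-":
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.length_bp < 1:
            raise ValidationError(f"gene {self.gene_id}: length must be positive")


# ---------------------------------------------------------------------------
# TSV readers / writers
# ---------------------------------------------------------------------------

def read_counts(path: str | Path, design: list[SampleDesign] | None = None) -> ExpressionMatrix:
    """Read a gene-level count table (TSV, first column = gene id).

    An optional ``length_bp`` column (right after the id column) is
    stored as per-gene lengths for TPM conversion.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    lengths = None
    if "length_bp" in df.columns:
        lengths = df.pop("length_bp")
    arr = df.apply(pd.to_numeric, errors="coerce")
    if arr.isna().any().any():
        bad = arr.index[arr.isna().any(axis=1)].tolist()
        raise ValidationError(f"non-numeric count values for features {bad[:5]}")
    return ExpressionMatrix(arr, design=design, unit="counts", lengths=lengths)


def write_counts(em: ExpressionMatrix, path: str | Path) -> None:
    out = em.values.copy()
    if em.lengths is not None:
        out.insert(0, "length_bp", em.lengths)
    out.to_csv(path, sep="\t", index_label="gene_id")


def read_metabolites(path: str | Path, design: list[SampleDesign] | None = None) -> MetaboliteMatrix:
    """Read a metabolite intensity table (TSV with a ``class`` column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "class" not in df.columns:
        raise ParseError("metabolite table lacks a 'class' column")
    labels = df.pop("class")
    arr = df.apply(pd.to_numeric, errors="coerce")
    if arr.isna().any().any():
        raise ValidationError("non-numeric metabolite intensities")
    return MetaboliteMatrix(arr, labels, design=design)


def write_metabolites(mm: MetaboliteMatrix, path: str | Path) -> None:
    out = mm.values.copy()
    out.insert(0, "class", mm.class_labels)
    out.to_csv(path, sep="\t", index_label="metabolite_id")


def read_lengths(path: str | Path) -> pd.Series:
    """Read a two-column gene-id / length TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].astype(float)


# ---------------------------------------------------------------------------
# FASTA / GFF3
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a genome FASTA into a contig-id -> uppercase sequence map."""
    genome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in genome:
            raise ValidationError(f"duplicate contig id {rec.id!r}")
        genome[rec.id] = str(rec.seq).upper()
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta-2line" if width == 0 else "fasta")


def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs = {}
    for item in field.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            continue
        k, v = item.split("=", 1)
        attrs[k.strip()] = v.strip()
    return attrs


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene models; ``ID`` of ``gene`` features becomes gene_id.

    Exon lines (via their mRNA Parent) define the summed-exon
    ``length_bp``; genes without exons fall back to the gene span.
    """
    genes: dict[str, dict] = {}
    mrna_to_gene: dict[str, str] = {}
    exon_len: dict[str, int] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields")
            contig, _src, ftype, start_s, end_s, _score, strand, _phase, attr_s = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise ParseError(f"{path}:{lineno}: end < start ({end} < {start})")
            if start < 1:
                raise ParseError(f"{path}:{lineno}: GFF3 coordinates are 1-based")
            attrs = _parse_gff_attributes(attr_s)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise ParseError(f"{path}:{lineno}: gene feature without ID")
                if gid in genes:
                    raise ValidationError(f"duplicate gene ID {gid!r} at line {lineno}")
                if strand not in "+-":
                    raise ParseError(f"{path}:{lineno}: gene strand must be + or -")
                genes[gid] = dict(contig=contig, start=start, end=end, strand=strand)
                order.append(gid)
            elif ftype == "mRNA":
                mid, parent = attrs.get("ID"), attrs.get("Parent")
                if mid and parent:
                    mrna_to_gene[mid] = parent
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent:
                    gid = mrna_to_gene.get(parent, parent)
                    exon_len[gid] = exon_len.get(gid, 0) + (end - start + 1)
    models = []
    for gid in order:
        g = genes[gid]
        length = exon_len.get(gid, g["end"] - g["start"] + 1)
        models.append(GeneModel(gid, g["contig"], g["start"], g["end"], g["strand"], length))
    return models


def write_gff3(annotation: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene -> mRNA -> single-exon models (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation:
            base = f"{g.contig}\tseedregnet\t"
            coord = f"\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
            fh.write(base + "gene" + coord + f"ID={g.gene_id}\n")
            fh.write(base + "mRNA" + coord + f"ID={g.gene_id}.1;Parent={g.gene_id}\n")
            fh.write(base + "exon" + coord + f"ID={g.gene_id}.1.exon1;Parent={g.gene_id}.1\n")


# ---------------------------------------------------------------------------
# Quantification primitives
# ---------------------------------------------------------------------------

def counts_to_tpm(
    counts: ExpressionMatrix, lengths: Mapping[str, float] | pd.Series | None = None
) -> ExpressionMatrix:
    """Convert raw counts to transcripts per million.

    Per sample: ``rate_g = count_g / length_kb_g`` and
    ``TPM_g = 1e6 * rate_g / sum(rates)``.  Each non-degenerate column
    sums to one million; all-zero columns remain all-zero.
    """
    if counts.unit != "counts":
        raise ParameterError("counts_to_tpm expects a counts-unit matrix")
    if lengths is None:
        lengths = counts.lengths
    if lengths is None:
        raise ParameterError("no gene lengths supplied or attached to the matrix")
    lens = pd.Series(lengths, dtype=float)
    missing = [g for g in counts.feature_ids if g not in lens.index]
    if missing:
        raise ValidationError(f"missing gene length for {missing[:5]}")
    lens = lens.loc[counts.feature_ids]
    if (lens <= 0).any():
        bad = lens.index[lens <= 0].tolist()
        raise ValidationError(f"non-positive gene length for {bad[:5]}")
    rate = counts.values.div(lens / 1000.0, axis=0)
    colsum = rate.sum(axis=0)
    tpm = rate.div(colsum.where(colsum > 0, 1.0), axis=1) * 1e6
    tpm.loc[:, colsum == 0] = 0.0
    return ExpressionMatrix(tpm, counts.design, unit="TPM", lengths=lens)


def filter_expressed(
    tpm: ExpressionMatrix, threshold: float = 3.0, min_samples: int = 1
) -> ExpressionMatrix:
    """Keep features with TPM strictly above `threshold` in >= `min_samples` samples."""
    if tpm.unit != "TPM":
        raise ParameterError("filter_expressed expects a TPM matrix")
    if min_samples > tpm.n_samples:
        raise ParameterError(
            f"min_samples={min_samples} exceeds sample count {tpm.n_samples}"
        )
    keep = (tpm.values > threshold).sum(axis=1) >= min_samples
    lengths = None if tpm.lengths is None else tpm.lengths[keep]
    return ExpressionMatrix(tpm.values.loc[keep], tpm.design, "TPM", lengths)


def zscore_rows(m: pd.DataFrame, clip: float | None = None) -> pd.DataFrame:
    """Standardise each row to mean 0 / sd 1 (sample sd, ddof=1).

    Zero-variance rows map to all-zeros.  With `clip`, values are
    truncated to [-clip, clip] afterwards (as in -4..4 / -2..2 heatmap
    scales).
    """
    if m.shape[1] < 2:
        raise ParameterError("zscore_rows needs at least 2 columns")
    arr = m.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[np.repeat(sd == 0, arr.shape[1], axis=1)] = 0.0
    if clip is not None:
        if clip <= 0:
            raise ParameterError("clip must be positive")
        z = np.clip(z, -clip, clip)
    return pd.DataFrame(z, index=m.index, columns=m.columns)
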