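"""Strand-aware promoter extraction and PWM scanning.

Promoters are the 2 kb immediately upstream of the transcription start
site (approximated by the 5' end of the gene model, respecting strand);
minus-strand promoters are reverse-complemented so every promoter
sequence reads 5'->3' relative to its gene.

Binding sites are called with a log2-odds position weight matrix scan
(pseudocount 0.25, uniform background by default) thresholded on the
*relative score*::

    rel = (score - min_possible) / (max_possible - min_possible)

Windows on both strands with rel >= threshold (default 0.85) are
reported.  Windows containing N are unscorable (-inf).
"""

from __future__ import annotations

import logging
from collections.abc import Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .errors import ParameterError, ParseError, ValidationError
from .io import GeneModel

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PROMOTER_LENGTH = 2000
DEFAULT_REL_THRESHOLD = 0.85
DEFAULT_PSEUDOCOUNT = 0.25


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """Encode ACGTN as 0..4 (4 = unscorable)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass(frozen=True)
class PromoterSequence:
    """A promoter oriented 5'->3' relative to its gene.

    ``gff_start``/``gff_end`` are 1-based inclusive genomic coordinates
    of the promoter interval (on the forward genome strand); for a
    zero-length (fully truncated) promoter ``gff_end = gff_start - 1``.
    """

    gene_id: str
    contig: str
    gff_start: int
    gff_end: int
    strand: str
    sequence: str
    truncated: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PositionWeightMatrix:
    """A TF binding model as a 4 x width count matrix (rows A,C,G,T)."""

    tf_id: str
    counts: np.ndarray
    family: str = ""
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != 4:
            raise ParameterError("counts must be a 4 x width matrix")
        if self.width < 1:
            raise ParameterError("PWM width must be >= 1")
        if (self.counts < 0).any():
            raise ParameterError("PWM counts must be non-negative")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ParameterError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    def log_odds(self) -> np.ndarray:
        """4 x width log2-odds matrix with pseudocount-smoothed frequencies."""
        smoothed = self.counts + self.pseudocount
        freqs = smoothed / smoothed.sum(axis=0, keepdims=True)
        bg = np.asarray(self.background, dtype=float)[:, None]
        return np.log2(freqs / bg)

    def score_range(self) -> tuple[float, float]:
        lo_matrix = self.log_odds()
        return float(lo_matrix.min(axis=0).sum()), float(lo_matrix.max(axis=0).sum())

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.counts.argmax(axis=0))

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            self.tf_id, self.counts[::-1, ::-1].copy(), self.family,
            self.pseudocount, self.background,
        )


@dataclass(frozen=True)
class MotifHit:
    """One PWM occurrence within a promoter (0-based promoter offsets)."""

    gene_id: str
    tf_id: str
    offset: int
    strand: str
    score: float
    relative_score: float
    width: int = 0


# ---------------------------------------------------------------------------
# Promoter extraction
# ---------------------------------------------------------------------------

def extract_promoters(
    annotation: Sequence[GeneModel],
    genome: Mapping[str, str],
    length: int = DEFAULT_PROMOTER_LENGTH,
) -> list[PromoterSequence]:
    """Extract the `length` bp upstream of each gene's TSS, strand-aware.

    Plus-strand gene starting at s (1-based): promoter covers
    [max(1, s-length), s-1].  Minus-strand gene ending at e: promoter
    covers [e+1, min(contig_len, e+length)], reverse-complemented.
    Promoters shorter than `length` (TSS near a contig edge) are
    flagged ``truncated``; at the very edge a zero-length record is
    returned.
    """
    if length < 1:
        raise ParameterError("promoter length must be >= 1")
    promoters = []
    for gene in annotation:
        if gene.contig not in genome:
            raise ValidationError(
                f"gene {gene.gene_id}: contig {gene.contig!r} absent from genome"
            )
        contig = genome[gene.contig]
        if gene.strand == "+":
            start = max(1, gene.start - length)
            end = gene.start - 1
            seq = contig[start - 1 : end]
            if end < start:  # TSS at position 1
                start, end, seq = 1, 0, ""
        else:
            start = gene.end + 1
            end = min(len(contig), gene.end + length)
            seq = reverse_complement(contig[start - 1 : end])
            if end < start:  # TSS at the contig's last base
                start, end, seq = gene.end + 1, gene.end, ""
        promoters.append(
            PromoterSequence(
                gene.gene_id, gene.contig, start, end, gene.strand,
                seq.upper(), truncated=len(seq) < length,
            )
        )
    return promoters


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def _window_scores(encoded: np.ndarray, lodds: np.ndarray) -> np.ndarray:
    """Scores of every window of an encoded sequence under a log-odds matrix.

    Windows containing N (code 4) score -inf.
    """
    w = lodds.shape[1]
    n_win = encoded.shape[0] - w + 1
    if n_win <= 0:
        return np.empty(0)
    lookup = np.vstack([lodds, np.full((1, w), -np.inf)])
    scores = np.zeros(n_win)
    for j in range(w):
        scores += lookup[encoded[j : j + n_win], j]
    return scores


def scan_pwm(
    promoter: PromoterSequence,
    pwm: PositionWeightMatrix,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
) -> list[MotifHit]:
    """Scan one promoter with one PWM on both strands.

    Returns all windows with relative score >= `rel_threshold`, sorted
    by offset (offsets are 0-based positions of the window start within
    the promoter sequence as given, for both strands).
    """
    if not 0.0 <= rel_threshold <= 1.0:
        raise ParameterError("rel_threshold must lie in [0, 1]")
    w = pwm.width
    if len(promoter) < w:
        return []
    lo, hi = pwm.score_range()
    span = hi - lo
    if span <= 0:  # completely uninformative matrix: every window is maximal
        span = 1.0
    encoded = encode_sequence(promoter.sequence)
    hits: list[MotifHit] = []
    for strand, lodds in (("+", pwm.log_odds()), ("-", pwm.reverse_complement().log_odds())):
        scores = _window_scores(encoded, lodds)
        rel = (scores - lo) / span
        for off in np.nonzero(rel >= rel_threshold)[0]:
            hits.append(
                MotifHit(
                    promoter.gene_id, pwm.tf_id, int(off), strand,
                    float(scores[off]), float(rel[off]), w,
                )
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def batch_window_scores(
    mat: np.ndarray, lodds: np.ndarray, dtype: type = np.float64
) -> np.ndarray:
    """Window scores for every row of an encoded sequence matrix.

    `mat` holds codes 0..4 (4 = N/padding, scoring -inf); rows are
    padded sequences of equal width.  Returns (n_rows, n_windows).
    """
    w = lodds.shape[1]
    n_win = mat.shape[1] - w + 1
    if n_win <= 0:
        return np.empty((mat.shape[0], 0))
    lookup = np.vstack([lodds, np.full((1, w), -np.inf)]).astype(dtype)
    scores = np.zeros((mat.shape[0], n_win), dtype=dtype)
    for j in range(w):
        scores += lookup[mat[:, j : j + n_win], j]
    return scores


def encode_promoter_matrix(promoters: Sequence[PromoterSequence]) -> np.ndarray:
    """Stack promoters into one padded code matrix (padding code 4)."""
    if not promoters:
        return np.empty((0, 0), dtype=np.int8)
    width = max(len(p) for p in promoters)
    mat = np.full((len(promoters), width), 4, dtype=np.int8)
    for i, p in enumerate(promoters):
        if len(p):
            mat[i, : len(p)] = encode_sequence(p.sequence)
    return mat


def tfbs_presence(
    promoters: Sequence[PromoterSequence],
    motif_library: Sequence[PositionWeightMatrix],
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
) -> pd.DataFrame:
    """Binary TF x gene map: 1 iff the TF's motif hits the gene's promoter.

    Equivalent to running :func:`scan_pwm` on every (promoter, motif)
    pair; the scan is batched over promoters for speed.
    """
    if not 0.0 <= rel_threshold <= 1.0:
        raise ParameterError("rel_threshold must lie in [0, 1]")
    seen = set()
    for p in promoters:
        if p.gene_id in seen:
            raise ValidationError(f"duplicate promoter for gene {p.gene_id!r}")
        seen.add(p.gene_id)
    mat = encode_promoter_matrix(promoters)
    tf_ids = []
    rows = []
    for pwm in motif_library:
        if pwm.counts.size == 0:
            logger.warning("TF %s has no usable motif; row omitted", pwm.tf_id)
            continue
        tf_ids.append(pwm.tf_id)
        lo, hi = pwm.score_range()
        span = hi - lo if hi > lo else 1.0
        cut = lo + rel_threshold * span
        margin = 1e-4  # float32 fast path; borderline rows rescored exactly
        hit = np.zeros(len(promoters), dtype=bool)
        border = np.zeros(len(promoters), dtype=bool)
        if mat.shape[1] >= pwm.width:
            for lodds in (pwm.log_odds(), pwm.reverse_complement().log_odds()):
                s32 = batch_window_scores(mat, lodds, dtype=np.float32)
                hit |= (s32 >= cut + margin).any(axis=1)
                border |= (s32 >= cut - margin).any(axis=1)
            for i in np.nonzero(border & ~hit)[0]:
                hit[i] = bool(scan_pwm(promoters[i], pwm, rel_threshold))
        rows.append(hit.astype(int))
    return pd.DataFrame(rows, index=tf_ids, columns=[p.gene_id for p in promoters], dtype=int)


# ---------------------------------------------------------------------------
# MEME-minimal I/O
# ---------------------------------------------------------------------------

def write_meme(motifs_list: Sequence[PositionWeightMatrix], path: str | Path) -> None:
    """Write motifs in MEME minimal format (counts normalised to frequencies)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for pwm in motifs_list:
            nsites = pwm.counts.sum(axis=0)
            total = int(round(float(nsites.max()))) if pwm.counts.size else 0
            freqs = pwm.counts / np.where(nsites == 0, 1.0, nsites)
            fh.write(f"MOTIF {pwm.tf_id} {pwm.family or pwm.tf_id}\n")
            fh.write(
                f"letter-probability matrix: alphlength= 4 w= {pwm.width} "
                f"nsites= {max(total, 1)} E= 0\n"
            )
            for col in freqs.T:
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path: str | Path, nsites_default: int = 20) -> list[PositionWeightMatrix]:
    """Read MEME minimal motifs back into count PWMs.

    Frequencies are rescaled by the recorded ``nsites`` to recover a
    count matrix.  Families are carried in the motif's alternate name
    on the MOTIF line (which the minimal parser drops, so it is read
    directly).
    """
    families: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("MOTIF"):
                parts = line.split()
                if len(parts) >= 3:
                    families[parts[1]] = parts[2]
    out = []
    with open(path) as fh:
        try:
            records = bio_motifs.parse(fh, "minimal")
        except Exception as exc:  # noqa: BLE001 - surface as our parse error
            raise ParseError(f"cannot parse MEME file {path}: {exc}") from exc
        for m in records:
            nsites = getattr(m, "num_occurrences", 0) or nsites_default
            counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
            total = counts.sum(axis=0)
            freqs = counts / np.where(total == 0, 1.0, total)
            out.append(
                PositionWeightMatrix(
                    m.name, freqs * float(nsites), family=families.get(m.name, "")
                )
            )
    return out


def write_promoters_fasta(promoters: Sequence[PromoterSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in promoters:
            fh.write(
                f">{p.gene_id} {p.contig}:{p.gff_start}-{p.gff_end}({p.strand})"
                f"{' truncated' if p.truncated else ''}\n{p.sequence}\n"
            )


def write_hits_tsv(hits: Sequence[MotifHit], path: str | Path) -> None:
    """BED-like TSV of hits with 0-based half-open promoter offsets."""
    rows = [
        dict(
            gene_id=h.gene_id, tf_id=h.tf_id, start=h.offset,
            end=h.offset + h.width, strand=h.strand, score=h.score,
            relative_score=h.relative_score,
        )
        for h in hits
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
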