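"""Synthetic multi-omics fixtures with planted, recoverable ground truth.

The generator emulates the study design end to end: a small genome with
one-transcript gene models, TF binding motifs planted in target-gene
promoters, a 4-stage x 4-replicate seed time course plus 4 tissues x 3
replicates of gene-level counts, and a seed metabolome tagged with the
eleven-class compound vocabulary.

Ground truth has three layers, all recorded in a :class:`TruthSet`:

* **temporal archetypes** — every gene and metabolite follows one of
  three stage profiles (early / mid / late peak), the structure that
  k-means co-clustering should recover;
* **planted motifs** — each regulated gene's 2 kb promoter carries its
  regulator's consensus (half of them reverse-complemented), and all
  other promoters are scrubbed of chance hits so the PWM scanner's
  presence map has no false positives by construction;
* **planted edges** — each TF/target pair shares a latent Gaussian
  factor with loading ``sqrt(edge_effect)`` inside the replicate noise,
  so their expression correlation survives noise while non-regulated
  (decoy) pairs share no latent component.

Counts are Poisson draws around log-normal means (multiplicative
replicate noise of sd ``noise_sd`` on the log scale).
"""

from __future__ import annotations

import json
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    SEED_GROUPS,
    TISSUE_GROUPS,
    SampleDesign,
    validate_design,
)
from .errors import DesignError, ParameterError, SizingError, ValidationError
from .io import (
    ExpressionMatrix,
    GeneModel,
    MetaboliteMatrix,
    write_counts,
    write_fasta,
    write_gff3,
    write_metabolites,
)
from .motifs import (
    ALPHABET,
    PositionWeightMatrix,
    batch_window_scores,
    write_meme,
)
from .reference import METABOLITE_CLASS_COUNTS, METABOLITE_CLASSES

ARCHETYPES = ("early", "mid", "late")

#: raw stage profiles over (T1..T4), unit-normalised before use
_ARCHETYPE_RAW = {
    "early": (1.0, 0.4, 0.1, 0.0),
    "mid": (0.1, 1.0, 0.9, 0.2),
    "late": (0.0, 0.2, 0.5, 1.0),
}

#: baseline log-level of the four mature tissues per archetype
_TISSUE_LEVELS = {
    "early": (0.20, 0.10, 0.30, 0.15),
    "mid": (0.10, 0.25, 0.10, 0.05),
    "late": (0.35, 0.05, 0.20, 0.40),
}

TF_FAMILIES = (
    "bHLH", "MYB", "B3", "C2H2", "HD-ZIP",
    "bZIP", "NAC", "GATA", "G2-like", "WRKY",
)


def archetype_profile(archetype: str) -> dict[str, float]:
    """Unit-norm stage profile plus tissue baselines, as group -> level."""
    raw = np.asarray(_ARCHETYPE_RAW[archetype], dtype=float)
    stage = raw / np.linalg.norm(raw)
    prof = dict(zip(SEED_GROUPS, stage))
    prof.update(zip(TISSUE_GROUPS, _TISSUE_LEVELS[archetype]))
    return prof


@dataclass(frozen=True)
class MotifPlacement:
    """One planted consensus occurrence within a target promoter."""

    gene_id: str
    tf_id: str
    offset: int
    strand: str


@dataclass
class TruthSet:
    """Everything the generator planted, for downstream recovery checks."""

    archetype_of_feature: dict[str, str] = field(default_factory=dict)
    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    motif_placements: list[MotifPlacement] = field(default_factory=list)
    tf_families: dict[str, str] = field(default_factory=dict)
    gene_lengths: dict[str, int] = field(default_factory=dict)
    tf_ids: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    metabolite_ids: list[str] = field(default_factory=list)

    @property
    def structural_gene_ids(self) -> list[str]:
        tfs = set(self.tf_ids)
        return [g for g in self.gene_ids if g not in tfs]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "archetype_of_feature": self.archetype_of_feature,
            "planted_edges": sorted(self.planted_edges),
            "motif_placements": [asdict(p) for p in self.motif_placements],
            "tf_families": self.tf_families,
            "gene_lengths": self.gene_lengths,
            "tf_ids": self.tf_ids,
            "gene_ids": self.gene_ids,
            "metabolite_ids": self.metabolite_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            archetype_of_feature=d["archetype_of_feature"],
            planted_edges={tuple(e) for e in d["planted_edges"]},
            motif_placements=[MotifPlacement(**p) for p in d["motif_placements"]],
            tf_families=d["tf_families"],
            gene_lengths={k: int(v) for k, v in d["gene_lengths"].items()},
            tf_ids=d["tf_ids"],
            gene_ids=d["gene_ids"],
            metabolite_ids=d["metabolite_ids"],
        )


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic study.

    Defaults mirror the emulated design: 300 genes of which 30 are TFs,
    20 planted regulatory edges of latent-correlation strength 0.98,
    2 kb promoters, and log-scale replicate noise of sd 0.25.
    """

    n_genes: int = 300
    n_tfs: int = 30
    n_metabolites: int = 100
    n_planted_edges: int | None = None
    n_contigs: int = 3
    contig_length: int | None = None
    promoter_length: int = 2000
    motif_width: int = 10
    edge_effect: float = 0.98
    decoy_corr_max: float = 0.3
    noise_sd: float = 0.25
    amplitude: float = 1.0
    gene_length_range: tuple[int, int] = (900, 3000)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_contigs < 1 or self.n_metabolites < 0:
            raise ParameterError("n_genes, n_contigs must be positive")
        if not 0 <= self.n_tfs < self.n_genes:
            raise ParameterError("need 0 <= n_tfs < n_genes")
        if not 0 < self.edge_effect <= 1:
            raise ParameterError("edge_effect must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.promoter_length < self.motif_width:
            raise ParameterError("promoter must be at least as long as the motif")
        if self.n_planted_edges is None:
            n_struct = self.n_genes - self.n_tfs
            self.n_planted_edges = 0 if self.n_tfs == 0 else min(20, n_struct // 3)
        if self.n_tfs == 0 and self.n_planted_edges:
            raise ParameterError("cannot plant edges without TFs")
        if self.n_planted_edges > self.n_genes - self.n_tfs:
            raise ParameterError("more planted edges than structural genes")

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.rng_seed, stream])


# ---------------------------------------------------------------------------
# Ground truth (archetypes, families, edges) -- no sequence involved
# ---------------------------------------------------------------------------

def generate_truth(cfg: GeneratorConfig) -> TruthSet:
    """Assign archetypes, TF families, gene lengths and planted edges."""
    rng = cfg._rng(0)
    tf_ids = [f"TF{i:04d}" for i in range(1, cfg.n_tfs + 1)]
    sg_ids = [f"G{i:04d}" for i in range(1, cfg.n_genes - cfg.n_tfs + 1)]
    truth = TruthSet(tf_ids=tf_ids, gene_ids=tf_ids + sg_ids)
    for i, tf in enumerate(tf_ids):
        truth.archetype_of_feature[tf] = ARCHETYPES[i % 3]
        truth.tf_families[tf] = TF_FAMILIES[i % len(TF_FAMILIES)]
    for i, g in enumerate(sg_ids):
        truth.archetype_of_feature[g] = ARCHETYPES[i % 3]
    lo, hi = cfg.gene_length_range
    for g in truth.gene_ids:
        truth.gene_lengths[g] = int(rng.integers(lo, hi + 1))
    # planted edges: regulator and target share an archetype so the edge
    # is consistent with the co-cluster constraint of the inference step
    pool = {a: [g for g in sg_ids if truth.archetype_of_feature[g] == a] for a in ARCHETYPES}
    for a in pool:
        rng.shuffle(pool[a])
    assert cfg.n_planted_edges is not None
    attempts = 0
    while len(truth.planted_edges) < cfg.n_planted_edges:
        attempts += 1
        if attempts > 100 * cfg.n_planted_edges:
            raise SizingError("cannot place the requested number of edges")
        tf = tf_ids[int(rng.integers(len(tf_ids)))]
        targets = pool[truth.archetype_of_feature[tf]]
        if not targets:
            continue
        truth.planted_edges.add((tf, targets.pop()))
    return truth


# ---------------------------------------------------------------------------
# Genome, annotation and motifs
# ---------------------------------------------------------------------------

def _random_consensi(rng: np.random.Generator, n: int, width: int, min_dist: int = 3) -> list[str]:
    """Pairwise-distant consensus strings (Hamming >= min_dist, incl. revcomps).

    Shift-by-one overlaps must also differ in >= 2 positions: a scan
    window overlapping a planted consensus by width-1 protected bases
    would otherwise match a different motif regardless of how its one
    free base is rewritten, making the promoter scrub impossible.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}

    def revcomp(s: str) -> str:
        return "".join(comp[c] for c in reversed(s))

    def dist(a: str, b: str) -> int:
        return sum(x != y for x, y in zip(a, b))

    def compatible(a: str, b: str) -> bool:
        if dist(a, b) < min_dist:
            return False
        # shifted overlaps of width-1 on either side
        return dist(a[1:], b[:-1]) >= 2 and dist(a[:-1], b[1:]) >= 2

    chosen: list[str] = []
    guard = 0
    while len(chosen) < n:
        guard += 1
        if guard > 10000:
            raise SizingError("cannot draw sufficiently distinct motif consensi")
        cand = "".join(ALPHABET[i] for i in rng.integers(0, 4, size=width))
        ok = all(
            compatible(cand, other) and compatible(cand, revcomp(other))
            for other in chosen
        )
        if ok and dist(cand, revcomp(cand)) >= min_dist:
            chosen.append(cand)
    return chosen


def _consensus_pwm(tf_id: str, family: str, consensus: str) -> PositionWeightMatrix:
    counts = np.ones((4, len(consensus)))
    for j, base in enumerate(consensus):
        counts[ALPHABET.index(base), j] = 12.0
    return PositionWeightMatrix(tf_id, counts, family=family)


def _scrub_promoters(
    prom: np.ndarray,
    pwms: Sequence[PositionWeightMatrix],
    allowed: set[tuple[int, int]],
    protected: dict[int, list[tuple[int, int]]],
    rel_threshold: float,
    rng: np.random.Generator,
    max_passes: int = 40,
) -> None:
    """Remove chance motif hits from non-target promoters, in place.

    `allowed` holds (tf_index, gene_index) pairs whose hits are planted;
    `protected` maps gene_index -> promoter intervals that must never be
    rewritten (the planted placements).  After the first full pass only
    rewritten promoter rows are rescanned.
    """
    if not len(pwms):
        return
    # scrub in float32 with a conservative margin: anything a float64
    # scan could call a hit is removed (over-scrubbing is harmless)
    lodds_all = []
    for pwm in pwms:
        lo, hi = pwm.score_range()
        cut = lo + rel_threshold * ((hi - lo) if hi > lo else 1.0) - 1e-4
        lodds_all.append((pwm.log_odds(), pwm.reverse_complement().log_odds(), cut))
    wmax = max(p.width for p in pwms)
    P = prom.shape[1]

    def rewrite(g_idx: int, off: int, w: int) -> None:
        keep = protected.get(g_idx, [])
        for pos in range(off, off + w):
            if any(a <= pos < b for a, b in keep):
                continue
            prom[g_idx, pos] = rng.integers(0, 4)

    # full first pass over all promoters
    spans: list[tuple[int, int, int]] = []  # (gene, rewrite start, rewrite end)
    for m_idx, (lf, lr, cut) in enumerate(lodds_all):
        w = pwms[m_idx].width
        for lodds in (lf, lr):
            scores = batch_window_scores(prom, lodds, dtype=np.float32)
            for g_idx, off in zip(*np.nonzero(scores >= cut)):
                if (m_idx, int(g_idx)) in allowed:
                    continue
                rewrite(int(g_idx), int(off), w)
                spans.append((int(g_idx), int(off), int(off) + w))

    # subsequent passes rescan only the neighbourhoods of rewrites
    for _ in range(max_passes):
        if not spans:
            return
        regions = sorted(
            {(g, max(0, a - wmax + 1), min(P, b - 1 + wmax)) for g, a, b in spans}
        )
        width = max(rb - ra for _, ra, rb in regions)
        sub = np.full((len(regions), width), 4, dtype=np.int8)
        for i, (g, ra, rb) in enumerate(regions):
            sub[i, : rb - ra] = prom[g, ra:rb]
        spans = []
        for m_idx, (lf, lr, cut) in enumerate(lodds_all):
            w = pwms[m_idx].width
            for lodds in (lf, lr):
                scores = batch_window_scores(sub, lodds, dtype=np.float32)
                for i, off in zip(*np.nonzero(scores >= cut)):
                    g, ra, _rb = regions[i]
                    if (m_idx, g) in allowed:
                        continue
                    goff = ra + int(off)
                    rewrite(g, goff, w)
                    spans.append((g, goff, goff + w))
    raise SizingError("could not scrub chance motif hits from promoters")


def generate_genome(
    cfg: GeneratorConfig, truth: TruthSet | None = None
) -> tuple[dict[str, str], list[GeneModel], list[PositionWeightMatrix], TruthSet]:
    """Generate genome sequence, gene models, motifs, and planted placements.

    Every regulated gene's promoter carries its regulator's consensus
    (half of the placements reverse-complemented); all other promoters
    are scrubbed of chance hits above the default scan threshold.
    """
    if truth is None:
        truth = generate_truth(cfg)
    rng = cfg._rng(1)
    n_genes = len(truth.gene_ids)
    gene_index = {g: i for i, g in enumerate(truth.gene_ids)}
    tf_index = {tf: i for i, tf in enumerate(truth.tf_ids)}

    consensi = _random_consensi(rng, cfg.n_tfs, cfg.motif_width)
    pwms = [
        _consensus_pwm(tf, truth.tf_families[tf], consensi[i])
        for i, tf in enumerate(truth.tf_ids)
    ]

    # -- promoter matrix in promoter orientation (5'->3' of each gene)
    P = cfg.promoter_length
    prom = rng.integers(0, 4, size=(n_genes, P), dtype=np.int8)
    comp_code = np.array([3, 2, 1, 0], dtype=np.int8)
    allowed: set[tuple[int, int]] = set()
    protected: dict[int, list[tuple[int, int]]] = {}
    truth.motif_placements.clear()
    for tf, gene in sorted(truth.planted_edges):
        m_idx, g_idx = tf_index[tf], gene_index[gene]
        w = pwms[m_idx].width
        off = int(rng.integers(0, P - w + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        encoded = np.array([ALPHABET.index(c) for c in consensi[m_idx]], dtype=np.int8)
        if strand == "-":
            encoded = comp_code[encoded][::-1]
        prom[g_idx, off : off + w] = encoded
        allowed.add((m_idx, g_idx))
        protected.setdefault(g_idx, []).append((off, off + w))
        truth.motif_placements.append(MotifPlacement(gene, tf, off, strand))
    _scrub_promoters(prom, pwms, allowed, protected, rel_threshold=0.85, rng=rng)

    # -- lay genes out over contigs: [promoter][gene] (+) or [gene][promoter] (-)
    gap, margin = 100, 200
    per_contig = -(-n_genes // cfg.n_contigs)
    contig_names = [f"chr{c + 1}" for c in range(cfg.n_contigs)]
    layouts: dict[str, list] = {c: [] for c in contig_names}
    annotation: list[GeneModel] = []
    for i, g in enumerate(truth.gene_ids):
        contig = contig_names[i // per_contig]
        layouts[contig].append((g, i))
    genome: dict[str, str] = {}
    base_chars = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    for contig in contig_names:
        pos = margin  # 0-based cursor
        pieces: list[tuple[int, np.ndarray]] = []
        for g, i in layouts[contig]:
            glen = truth.gene_lengths[g]
            strand = "+" if i % 2 == 0 else "-"
            if strand == "+":
                prom_start0 = pos
                gene_start0 = pos + P
                gene_end0 = gene_start0 + glen - 1
                prom_genomic = prom[i]
            else:
                gene_start0 = pos
                gene_end0 = pos + glen - 1
                prom_start0 = gene_end0 + 1
                prom_genomic = comp_code[prom[i]][::-1]
            pieces.append((prom_start0, prom_genomic))
            annotation.append(
                GeneModel(g, contig, gene_start0 + 1, gene_end0 + 1, strand, glen)
            )
            pos += P + glen + gap
        total = pos + margin
        if cfg.contig_length is not None:
            if total > cfg.contig_length:
                raise SizingError(
                    f"contig {contig} needs {total} bp but contig_length="
                    f"{cfg.contig_length}"
                )
            total = cfg.contig_length
        arr = rng.integers(0, 4, size=total, dtype=np.int8)
        for start0, seq_codes in pieces:
            arr[start0 : start0 + P] = seq_codes
        genome[contig] = base_chars[arr].tobytes().decode("ascii")
    return genome, annotation, pwms, truth


# ---------------------------------------------------------------------------
# Expression and metabolome
# ---------------------------------------------------------------------------

def _group_profiles(truth_features: Sequence[str], archetypes: Mapping[str, str],
                    groups: Sequence[str], amplitude: float) -> np.ndarray:
    profs = {a: archetype_profile(a) for a in ARCHETYPES}
    out = np.empty((len(truth_features), len(groups)))
    for i, f in enumerate(truth_features):
        a = archetypes.get(f)
        if a is None:
            raise ValidationError(f"feature {f!r} has no archetype in the truth set")
        out[i] = [amplitude * profs[a][g] for g in groups]
    return out


def generate_expression(
    cfg: GeneratorConfig,
    design: list[SampleDesign],
    truth: TruthSet,
    *,
    poisson: bool = True,
) -> ExpressionMatrix:
    """Integer count matrix over `design` with planted correlation structure.

    Expected log-abundance follows each feature's archetype profile;
    planted TF/target pairs additionally share a latent factor of
    loading ``sqrt(edge_effect)`` inside the per-sample log-normal
    noise, and counts are Poisson draws around the resulting mean.
    Gene lengths from the truth set are attached to the returned matrix.
    """
    validate_design(design)
    rng = cfg._rng(2)
    genes = truth.gene_ids
    n, s = len(genes), len(design)
    sample_groups = [d.group for d in design]
    mu = _group_profiles(genes, truth.archetype_of_feature, sample_groups, cfg.amplitude)
    baseline = rng.uniform(np.log(100.0), np.log(2000.0), size=n)[:, None]

    U = rng.standard_normal((n, s))
    Z = rng.standard_normal((max(len(truth.tf_ids), 1), s))
    rho = cfg.edge_effect
    noise = U.copy()
    gene_index = {g: i for i, g in enumerate(genes)}
    tf_index = {tf: i for i, tf in enumerate(truth.tf_ids)}
    for tf in truth.tf_ids:
        i = gene_index[tf]
        noise[i] = np.sqrt(rho) * Z[tf_index[tf]] + np.sqrt(1 - rho) * U[i]
    for tf, target in sorted(truth.planted_edges):
        i = gene_index[target]
        noise[i] = np.sqrt(rho) * Z[tf_index[tf]] + np.sqrt(1 - rho) * U[i]

    lam = np.exp(baseline + mu + cfg.noise_sd * noise)
    counts = rng.poisson(lam) if poisson else np.rint(lam)
    values = pd.DataFrame(counts.astype(float), index=genes,
                          columns=[d.sample_id for d in design])
    lengths = pd.Series({g: truth.gene_lengths[g] for g in genes}, dtype=float)
    return ExpressionMatrix(values, design, unit="counts", lengths=lengths)


def generate_metabolome(
    cfg: GeneratorConfig, design: list[SampleDesign], truth: TruthSet
) -> MetaboliteMatrix:
    """Seed-sample metabolite intensities with archetype structure.

    Class labels are drawn from the eleven-class vocabulary with the
    published class frequencies.  Tissue samples are rejected: the
    metabolome covers seeds only.
    """
    validate_design(design)
    bad = [d.sample_id for d in design if not d.is_seed]
    if bad:
        raise DesignError(f"metabolome design must contain seed samples only; got {bad[:4]}")
    rng = cfg._rng(3)
    ids = [f"M{i:04d}" for i in range(1, cfg.n_metabolites + 1)]
    truth.metabolite_ids = ids
    for i, m in enumerate(ids):
        truth.archetype_of_feature[m] = ARCHETYPES[i % 3]
    weights = np.array([METABOLITE_CLASS_COUNTS[c] for c in METABOLITE_CLASSES], float)
    weights /= weights.sum()
    labels = rng.choice(len(METABOLITE_CLASSES), size=cfg.n_metabolites, p=weights)
    class_labels = pd.Series(
        [METABOLITE_CLASSES[i] for i in labels], index=ids, dtype=object
    )
    groups = [d.group for d in design]
    mu = _group_profiles(ids, truth.archetype_of_feature, groups, cfg.amplitude)
    baseline = rng.uniform(np.log(1e4), np.log(1e6), size=len(ids))[:, None]
    noise = rng.standard_normal((len(ids), len(design)))
    values = np.exp(baseline + mu + cfg.noise_sd * noise)
    df = pd.DataFrame(values, index=ids, columns=[d.sample_id for d in design])
    return MetaboliteMatrix(df, class_labels, design)


# ---------------------------------------------------------------------------
# Fixture bundle
# ---------------------------------------------------------------------------

def write_fixture_bundle(
    outdir: str | Path,
    genome: Mapping[str, str],
    annotation: Sequence[GeneModel],
    motifs: Sequence[PositionWeightMatrix],
    counts: ExpressionMatrix,
    metabolites: MetaboliteMatrix,
    truth: TruthSet,
) -> dict[str, int]:
    """Write the six-file fixture bundle; returns a file -> record-count manifest."""
    out = Path(outdir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(genome, out / "genome.fasta")
        write_gff3(annotation, out / "genes.gff3")
        write_counts(counts, out / "counts.tsv")
        write_metabolites(metabolites, out / "metabolites.tsv")
        write_meme(motifs, out / "motifs.meme")
        truth.to_json(out / "truth.json")
    except OSError as exc:
        raise OSError(f"cannot write fixture bundle under {out}: {exc}") from exc
    return {
        "genome.fasta": len(genome),
        "genes.gff3": len(annotation),
        "counts.tsv": counts.values.shape[0],
        "metabolites.tsv": metabolites.values.shape[0],
        "motifs.meme": len(motifs),
        "truth.json": len(truth.archetype_of_feature),
    }
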