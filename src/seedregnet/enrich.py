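"""Pathway over-representation analysis of cluster gene sets.

One-sided upper-tail hypergeometric test per pathway::

    p = P(X >= overlap),  X ~ Hypergeom(N=|universe|, K=|set ∩ universe|,
                                        n=|cluster|)

with Benjamini-Hochberg FDR across the tested sets.  The universe
should be the expressed genes (post expression filter), the standard
ORA background for co-expression panels.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from pathlib import Path

from scipy import stats

from .errors import ParseError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    pathway_id: str
    pathway_size_in_universe: int
    cluster_size: int
    overlap: int
    p_value: float
    fdr: float
    gene_ids_overlapping: tuple[str, ...]


def hypergeom_enrich(
    cluster_genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
) -> list[EnrichmentResult]:
    """Test each gene set for over-representation in the cluster.

    Gene sets are intersected with the universe before testing; sets
    with an empty intersection are dropped.  Results are sorted by
    p-value ascending.
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    cluster = set(cluster_genes)
    outside = cluster - uni
    if outside:
        raise ValidationError(
            f"cluster genes outside the universe: {sorted(outside)[:5]}"
        )
    N, n = len(uni), len(cluster)
    tested = []
    for name, members in gene_sets.items():
        in_uni = set(members) & uni
        if not in_uni:
            logger.info("gene set %s has no members in the universe; dropped", name)
            continue
        K = len(in_uni)
        hits = tuple(sorted(cluster & in_uni))
        k = len(hits)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        tested.append((name, K, k, min(p, 1.0), hits))
    if not tested:
        return []
    pvals = [t[3] for t in tested]
    fdrs = stats.false_discovery_control(pvals, method="bh")
    results = [
        EnrichmentResult(name, K, n, k, p, float(min(f, 1.0)), hits)
        for (name, K, k, p, hits), f in zip(tested, fdrs)
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


# ---------------------------------------------------------------------------
# GMT I/O
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file into pathway -> member-gene lists.

    Duplicate members within a set are deduplicated (order preserved);
    sets left empty are dropped with a warning; a duplicated set name
    is an error.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"gene set {name!r} listed twice (line {lineno})")
            members = list(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                logger.warning("gene set %s is empty; dropped", name)
                continue
            sets[name] = members
    return sets


def write_gmt(gene_sets: Mapping[str, Iterable[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for name, members in gene_sets.items():
            desc = descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")
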