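"""Published bookkeeping tables for the O. violaceus seed study.

Two small tables from the source study are used as fixed inputs:

* the class breakdown of the annotated seed metabolites (eleven classes:
  ten named compound classes plus an unclassified remainder), and
* the copy-number table of the structural genes of the dihydroxy
  fatty-acid (diOH-FA) ``discontinuous elongation`` pathway, in which
  every gene retains two whole-genome-duplication copies except FAE1,
  which has three, one of which (the clade-I copy) is transcriptionally
  silent in every sampled tissue.

These drive simple arithmetic checks and supply realistic class
frequencies to the synthetic metabolome generator.
"""

from __future__ import annotations

from collections.abc import Mapping

#: annotated metabolite counts per class in O. violaceus seeds
METABOLITE_CLASS_COUNTS: dict[str, int] = {
    "phenolic acids": 161,
    "lipids": 154,
    "flavonoids": 140,
    "amino acids and derivatives": 85,
    "alkaloids": 75,
    "organic acids": 75,
    "nucleotides and derivatives": 55,
    "terpenoids": 43,
    "lignans and coumarins": 39,
    "tannins": 7,
    "others": 169,
}

#: the eleven-class vocabulary used to tag metabolites
METABOLITE_CLASSES: tuple[str, ...] = tuple(METABOLITE_CLASS_COUNTS)

#: WGD copy numbers of the diOH-FA structural genes
DIOH_FA_COPY_NUMBERS: dict[str, int] = {
    "FAE1": 3,
    "FAD2": 2,
    "KCR": 2,
    "HACD": 2,
    "ECR": 2,
}

#: copies silent in all sampled tissues (the clade-I FAE1 copy)
DIOH_FA_UNEXPRESSED_COPIES: dict[str, int] = {"FAE1": 1}


def total_annotated_metabolites(
    class_counts: Mapping[str, int] = METABOLITE_CLASS_COUNTS,
) -> int:
    """Total annotated metabolites implied by the per-class counts."""
    return int(sum(class_counts.values()))


def expressed_structural_gene_count(
    copy_numbers: Mapping[str, int] = DIOH_FA_COPY_NUMBERS,
    unexpressed: Mapping[str, int] = DIOH_FA_UNEXPRESSED_COPIES,
) -> int:
    """Number of expressed diOH-FA structural-gene copies.

    Applies the expression filter to the copy table: total copies minus
    copies never observed above the expression threshold in any sample.
    This is the structural-gene node count of the multi-tissue
    regulatory network.
    """
    total = sum(copy_numbers.values())
    silent = 0
    for gene, n in unexpressed.items():
        if gene not in copy_numbers:
            raise KeyError(f"unexpressed copy of unknown gene {gene!r}")
        if n > copy_numbers[gene]:
            raise ValueError(f"more silent copies than copies for {gene!r}")
        silent += n
    return int(total - silent)
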