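"""Sample design for the seed time course and mature tissues.

The experimental layout is a 4-stage seed development time course
(T1..T4, spanning roughly 21-63 days after flowering) with four
biological replicates per stage, plus four mature tissues (flower,
leaf, root, stem) with three replicates each.  The metabolome covers
the 16 seed samples only; the transcriptome covers all 28 samples.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DesignError

SEED_GROUPS: tuple[str, ...] = ("T1", "T2", "T3", "T4")
TISSUE_GROUPS: tuple[str, ...] = ("flower", "leaf", "root", "stem")
GROUP_ORDER: tuple[str, ...] = SEED_GROUPS + TISSUE_GROUPS

#: days after flowering of each seed stage midpoint
SEED_STAGE_DAF: dict[str, int] = {"T1": 21, "T2": 35, "T3": 47, "T4": 63}


@dataclass(frozen=True)
class SampleDesign:
    """One sequenced sample: group (stage or tissue), replicate, and time point."""

    sample_id: str
    group: str
    replicate: int
    days_after_flowering: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUP_ORDER:
            raise DesignError(
                f"unknown group {self.group!r} for sample {self.sample_id!r}; "
                f"expected one of {GROUP_ORDER}"
            )
        if self.replicate < 1:
            raise DesignError(f"replicate must be >= 1 for sample {self.sample_id!r}")

    @property
    def is_seed(self) -> bool:
        return self.group in SEED_GROUPS


def seed_design(n_replicates: int = 4) -> list[SampleDesign]:
    """The 4 x 4 seed time-course design (16 samples by default)."""
    return [
        SampleDesign(f"{g}_r{i}", g, i, SEED_STAGE_DAF[g])
        for g in SEED_GROUPS
        for i in range(1, n_replicates + 1)
    ]


def tissue_design(n_replicates: int = 3) -> list[SampleDesign]:
    """The 4 tissue x 3 replicate design (12 samples by default)."""
    return [
        SampleDesign(f"{g}_r{i}", g, i, None)
        for g in TISSUE_GROUPS
        for i in range(1, n_replicates + 1)
    ]


def full_design() -> list[SampleDesign]:
    """Seed stages plus mature tissues: the 28-sample transcriptome design."""
    return seed_design() + tissue_design()


def validate_design(design: list[SampleDesign]) -> None:
    """Check uniqueness of sample ids and (group, replicate) pairs."""
    if not design:
        raise DesignError("empty sample design")
    ids = [s.sample_id for s in design]
    if len(set(ids)) != len(ids):
        raise DesignError("duplicate sample ids in design")
    pairs = [(s.group, s.replicate) for s in design]
    if len(set(pairs)) != len(pairs):
        raise DesignError("duplicate (group, replicate) pairs in design")
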