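"""Gene signatures and ordered time-course references.

A signature is a named pair of gene sets: genes up-regulated in the state of
interest and (optionally) genes down-regulated. A time-course reference is an
ordered series of signatures, one per timepoint of a differentiation course,
each typically the top-k differentially expressed genes of that timepoint's
population versus a naive reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["GeneSignature", "TimecourseReference"]


@dataclass
class GeneSignature:
    name: str
    up_genes: frozenset = field(default_factory=frozenset)
    down_genes: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.up_genes = frozenset(self.up_genes)
        self.down_genes = frozenset(self.down_genes)
        if not self.up_genes:
            raise ValueError(f"signature {self.name!r} has an empty up set")
        overlap = self.up_genes & self.down_genes
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: up and down sets overlap "
                f"({sorted(overlap)[:5]}...)"
            )

    @property
    def size(self) -> int:
        return len(self.up_genes) + len(self.down_genes)

    def restrict_to(self, genes) -> tuple["GeneSignature", int]:
        """Drop genes absent from ``genes``; return (signature, n_dropped).

        Raises if no up gene survives.
        """
        pool = set(genes)
        up = self.up_genes & pool
        down = self.down_genes & pool
        dropped = self.size - len(up) - len(down)
        if not up:
            raise ValueError(
                f"signature {self.name!r}: no up gene present in the matrix"
            )
        return GeneSignature(self.name, up, down), dropped


@dataclass
class TimecourseReference:
    """Ordered timepoints, each carrying the gene signature of that stage."""

    days: list[float]
    signatures: list[GeneSignature]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.signatures):
            raise ValueError("days and signatures must have equal length")
        if len(self.days) < 2:
            raise ValueError("a time-course needs at least two timepoints")
        for a, b in zip(self.days, self.days[1:]):
            if not b > a:
                raise ValueError("timepoint days must be strictly increasing")

    @property
    def n_timepoints(self) -> int:
        return len(self.days)

    def __iter__(self):
        return iter(zip(self.days, self.signatures))
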