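"""Core domain types: the target-gene model and cleavage geometry.

The package analyses retroelements that integrate into a short multicopy
target gene (the motivating case is a U2 snRNA gene of ~190 nt).  Two
coordinates on the target describe an integration event:

* ``insertion_site`` — the 1-based position of the last target base 5' of
  the bottom-strand cleavage.  The target sequence downstream of an
  element therefore starts at ``insertion_site + 1`` (nt 39 for U2).
* the top-strand cut, expressed relative to the bottom cut as a signed
  ``top_offset``.  A positive offset duplicates ``top_offset`` target
  bases on both sides of the element (a target site duplication), zero
  gives a blunt junction, and a negative offset deletes ``|top_offset|``
  target bases immediately 5' of the bottom cut.

Coordinates are 0-based half-open internally; report writers convert to
1-based closed intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._seq import check_dna


@dataclass(frozen=True)
class TargetGeneModel:
    """Reference target gene with its functional 5' region.

    Parameters
    ----------
    name : str
        Label used in reports.
    sequence : str
        Target gene sequence (ACGTN).
    functional_5prime_len : int
        Length of the 5' region whose intactness defines a functional
        gene copy (50 nt for U2: the nucleotides required for splicing
        are concentrated there).
    insertion_site : int
        1-based position of the last target base 5' of the bottom-strand
        cut (38 for U2: downstream fragments start at nt 39).
    """

    name: str
    sequence: str
    functional_5prime_len: int = 50
    insertion_site: int = 38

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("target gene sequence must be non-empty")
        check_dna(self.sequence, "target gene sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not 1 <= self.insertion_site < len(self.sequence):
            raise ValueError(
                f"insertion_site {self.insertion_site} outside target "
                f"sequence of length {len(self.sequence)}"
            )
        if self.functional_5prime_len > len(self.sequence):
            raise ValueError("functional_5prime_len exceeds target length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CleavageGeometry:
    """Relative geometry of the two target-strand cuts.

    ``bottom_cut`` is the 1-based target coordinate of the bottom-strand
    cleavage (normally the model's ``insertion_site``); ``top_offset`` is
    the top-strand cut position minus the bottom-strand cut position.
    ``bottom_cut`` may be ``None`` on inferred geometries whose junctions
    could not be placed on the target model (TSD called from sequence
    evidence alone).
    """

    bottom_cut: int | None
    top_offset: int

    @property
    def tsd_len(self) -> int:
        return self.top_offset if self.top_offset > 0 else 0

    @property
    def deletion_len(self) -> int:
        return -self.top_offset if self.top_offset < 0 else 0


@dataclass
class GeneLocus:
    """One emitted target-gene locus (0-based half-open genome interval)."""

    contig: str
    start: int
    end: int

    def as_1based(self) -> tuple[int, int]:
        return self.start + 1, self.end
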