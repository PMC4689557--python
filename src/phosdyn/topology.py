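"""Duplex topology: sequences, step enumeration, and the facing-phosphate map.

A B-DNA duplex of length L is represented with both strands written 5'->3'.
Bases are numbered continuously 1..L on strand 1 and L+1..2L on strand 2, so
that base j pairs base 2L+1-j (for L=12 this is the conventional N1..N24
dodecamer numbering).  A *step* is a phosphodiester linkage identified by the
strand and the duplex number of its 5' base; the *facing* step of a strand-1
step at 5' position i is the strand-2 step at 5' position 2L-i, i.e. the
phosphate directly across the two strands within the same complementary
dinucleotide NpN.NpN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "COMPLEMENT",
    "StepIdentity",
    "DuplexTopology",
    "build_topology",
    "reverse_complement",
    "facing_step",
    "enumerate_complementary_steps",
]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement of an ACGT string."""
    try:
        return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))
    except KeyError as exc:
        raise ValueError(f"non-ACGT base {exc.args[0]!r} in sequence") from exc


@dataclass(frozen=True, order=True)
class StepIdentity:
    """One phosphate linkage, keyed by strand and the duplex number of its 5' base."""

    strand: int  # 1 or 2
    pos5: int  # duplex numbering (1..L-1 on strand 1, L+1..2L-1 on strand 2)
    dinucleotide: str = field(compare=False, default="")

    def label(self) -> str:
        """Residue-style label, e.g. ``C2pG3``."""
        a, b = (self.dinucleotide + "??")[:2]
        return f"{a}{self.pos5}p{b}{self.pos5 + 1}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label()


@dataclass(frozen=True)
class DuplexTopology:
    """A fully complementary B-DNA duplex.

    Parameters
    ----------
    name : str
        Label for the duplex (e.g. ``"Oligo 4"``).
    strand1, strand2 : str
        Base sequences written 5'->3'.  ``strand2`` must be the reverse
        complement of ``strand1``.
    """

    name: str
    strand1: str
    strand2: str

    def __post_init__(self) -> None:
        s1, s2 = self.strand1.upper(), self.strand2.upper()
        object.__setattr__(self, "strand1", s1)
        object.__setattr__(self, "strand2", s2)
        for seq in (s1, s2):
            for i, b in enumerate(seq):
                if b not in COMPLEMENT:
                    raise ValueError(f"non-ACGT base {b!r} at position {i + 1}")
        if len(s1) < 4:
            raise ValueError("duplex length must be >= 4 base pairs")
        if s2 != reverse_complement(s1):
            raise ValueError(
                f"strand2 {s2!r} is not the reverse complement of strand1 {s1!r}"
            )

    @property
    def length(self) -> int:
        """Number of base pairs L."""
        return len(self.strand1)

    def base(self, pos: int) -> str:
        """Base letter at duplex position ``pos`` (1..2L)."""
        L = self.length
        if 1 <= pos <= L:
            return self.strand1[pos - 1]
        if L + 1 <= pos <= 2 * L:
            return self.strand2[pos - L - 1]
        raise ValueError(f"position {pos} outside 1..{2 * L}")

    def paired_base(self, pos: int) -> int:
        """Duplex number of the Watson-Crick partner of base ``pos``."""
        return 2 * self.length + 1 - pos

    def step(self, strand: int, pos5: int) -> StepIdentity:
        """The step on ``strand`` whose 5' base has duplex number ``pos5``."""
        L = self.length
        lo, hi = (1, L - 1) if strand == 1 else (L + 1, 2 * L - 1)
        if strand not in (1, 2):
            raise ValueError(f"strand must be 1 or 2, got {strand}")
        if not lo <= pos5 <= hi:
            raise ValueError(
                f"step 5' position {pos5} outside strand-{strand} range {lo}..{hi}"
            )
        dinuc = self.base(pos5) + self.base(pos5 + 1)
        return StepIdentity(strand=strand, pos5=pos5, dinucleotide=dinuc)

    def steps(self, strand: int, exclude_terminal: bool = True) -> list[StepIdentity]:
        """All steps of one strand, optionally dropping the two terminal steps."""
        L = self.length
        lo, hi = (1, L - 1) if strand == 1 else (L + 1, 2 * L - 1)
        if exclude_terminal:
            lo, hi = lo + 1, hi - 1
        return [self.step(strand, i) for i in range(lo, hi + 1)]

    def all_steps(self, exclude_terminal: bool = True) -> list[StepIdentity]:
        return self.steps(1, exclude_terminal) + self.steps(2, exclude_terminal)

    def is_terminal(self, step: StepIdentity) -> bool:
        L = self.length
        return step.pos5 in (1, L - 1, L + 1, 2 * L - 1)


def build_topology(strand1: str, name: str = "duplex") -> DuplexTopology:
    """Build a fully complementary duplex from its first strand (5'->3')."""
    s1 = strand1.upper()
    for i, b in enumerate(s1):
        if b not in COMPLEMENT:
            raise ValueError(f"non-ACGT base {b!r} at position {i + 1}")
    return DuplexTopology(name=name, strand1=s1, strand2=reverse_complement(s1))


def facing_step(topology: DuplexTopology, step: StepIdentity) -> StepIdentity:
    """The step directly across the duplex from ``step``.

    For a strand-1 step at 5' position i the facing strand-2 step sits at
    5' position 2L-i; the map is an involution.
    """
    L = topology.length
    # validate membership (raises if outside range)
    step = topology.step(step.strand, step.pos5)
    other = 2 if step.strand == 1 else 1
    return topology.step(other, 2 * L - step.pos5)


def enumerate_complementary_steps(
    topology: DuplexTopology, exclude_terminal: bool = True
) -> list[tuple[StepIdentity, StepIdentity]]:
    """All complementary (facing) step pairs, keyed by the strand-1 member.

    Returns L-3 pairs with terminal exclusion (the central-base-pair
    convention) and L-1 without.
    """
    return [
        (s, facing_step(topology, s)) for s in topology.steps(1, exclude_terminal)
    ]


#: The four dodecamers of the study sequence (5' half of the 601 positioning
#: sequence), usable as ready-made topologies.
STUDY_DODECAMERS: dict[str, str] = {
    "Oligo 1": "TCGTAGCAAGCT",
    "Oligo 2": "GCTCTAGCACCG",
    "Oligo 3": "CCGCTTAAACGC",
    "Oligo 4": "CGCACGTACGCG",
}


def study_topologies() -> list[DuplexTopology]:
    """Topologies for the four study dodecamers, in order."""
    return [build_topology(seq, name) for name, seq in STUDY_DODECAMERS.items()]
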