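"""Reference sequences for mtDNA variant coordinates.

All coordinates in this package are 1-based, matching the m-dot notation
(m.3915G>A) used throughout the mitochondrial literature. The reference is
pluggable: analyses of real data load the 16,569 bp rCRS coordinate system,
while tests and the cohort simulator use short toy references.

The packaged reference ``rcrs_like_synthetic.fa`` is a *synthetic* stand-in
for the rCRS (NC_012920): a pseudo-random 16,569 nt sequence in which the
bases at the positions this package documents (common polymorphic sites and
the codons of the worked annotation examples) are set to their published
rCRS values. It provides the correct coordinate system and the correct local
codon context for those sites, nothing more; analyses of real data should
load the true NC_012920 FASTA instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

#: Length of the revised Cambridge Reference Sequence (NC_012920).
RCRS_LENGTH = 16569


@dataclass(frozen=True)
class ReferenceSequence:
    """A named nucleotide reference with 1-based coordinate access."""

    name: str
    bases: str
    circular: bool = True

    def __post_init__(self) -> None:
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise ValueError(f"reference contains non-nucleotide symbols: {sorted(bad)}")
        if not self.bases:
            raise ValueError("reference sequence is empty")

    @property
    def length(self) -> int:
        return len(self.bases)

    def base_at(self, position: int) -> str:
        """Return the base at a 1-based position."""
        if not 1 <= position <= self.length:
            raise ValueError(
                f"position {position} outside reference {self.name!r} (1..{self.length})"
            )
        return self.bases[position - 1]

    def slice(self, start: int, end: int) -> str:
        """Bases of the closed 1-based interval [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"bad interval {start}..{end} on {self.name!r}")
        return self.bases[start - 1 : end]


def read_fasta(path: Union[str, Path], circular: bool = True) -> ReferenceSequence:
    """Read the first record of a FASTA file as a reference sequence."""
    record = next(SeqIO.parse(str(path), "fasta"))
    return ReferenceSequence(name=record.id, bases=str(record.seq).upper(), circular=circular)


def write_fasta(path: Union[str, Path], records: Iterable[tuple[str, str]]) -> None:
    """Write (name, sequence) pairs as 70-column wrapped FASTA."""
    seq_records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=70)
        writer.write_file(seq_records)


def load_packaged_reference() -> ReferenceSequence:
    """Load the packaged synthetic rCRS-like reference (see module docstring)."""
    with resources.files("mitoscan.data").joinpath("rcrs_like_synthetic.fa").open("r") as fh:
        record = next(SeqIO.parse(fh, "fasta"))
    return ReferenceSequence(name=record.id, bases=str(record.seq).upper(), circular=True)


def toy_reference(length: int = 2000, seed: int = 7, name: str = "toy") -> ReferenceSequence:
    """Deterministic pseudo-random reference for simulations and tests."""
    import numpy as np

    rng = np.random.default_rng(seed)
    bases = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
    return ReferenceSequence(name=name, bases=bases, circular=True)
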