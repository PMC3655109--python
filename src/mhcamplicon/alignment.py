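"""Equal-length, in-frame nucleotide allele alignments.

All downstream statistics (divergence, dN/dS, recombination, trees) operate on
an :class:`Alignment`: a list of same-length ACGT sequences read in frame 0.
The MHC amplicons this package targets are gap-free PCR products of one exon,
so no gap handling is provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

STOP_CODONS = {"TAA", "TAG", "TGA"}


def has_inframe_stop(seq: str) -> bool:
    return any(seq[i : i + 3] in STOP_CODONS for i in range(0, len(seq) - 2, 3))


@dataclass
class Alignment:
    """Aligned nucleotide sequences with stable identifiers.

    Parameters
    ----------
    ids : list of str
        One unique label per sequence.
    seqs : list of str
        Uppercase ACGT sequences, all the same length.
    offset : int
        Added to 1-based codon indices when reporting site positions in an
        external residue-numbering frame.
    """

    ids: list[str]
    seqs: list[str]
    offset: int = 0
    _codons: list[list[str]] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if not self.seqs:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        self.seqs = [s.upper() for s in self.seqs]
        for s in self.seqs:
            bad = set(s) - set("ACGT")
            if bad:
                raise ValueError(f"non-ACGT characters {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0])

    def require_codons(self) -> None:
        """Raise unless the alignment is in-frame and stop-free."""
        if self.length % 3 != 0:
            raise ValueError(f"length {self.length} not divisible by 3")
        for sid, s in zip(self.ids, self.seqs):
            if has_inframe_stop(s):
                raise ValueError(f"in-frame stop codon in {sid}")

    def codons(self) -> list[list[str]]:
        if self._codons is None:
            self._codons = [
                [s[i : i + 3] for i in range(0, len(s), 3)] for s in self.seqs
            ]
        return self._codons

    def translate(self) -> list[str]:
        self.require_codons()
        return [str(Seq(s).translate()) for s in self.seqs]

    @classmethod
    def from_fasta(cls, path, offset: int = 0) -> "Alignment":
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        if not ids:
            raise ValueError(f"no sequences in {path}")
        return cls(ids, seqs, offset=offset)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, s in zip(self.ids, self.seqs):
                fh.write(f">{sid}\n{s}\n")
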