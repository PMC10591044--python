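"""Reference-sequence access.

All coordinates handed to :meth:`Reference.fetch` are 0-based half-open;
this is the only layer where conversion from the 1-based VCF convention
happens (callers pass ``position - 1``).
"""

from __future__ import annotations

from typing import Iterable, Mapping

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N passes through)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


class Reference:
    """Minimal random-access interface over a genome."""

    def contig_names(self) -> list[str]:
        raise NotImplementedError

    def length(self, contig: str) -> int:
        raise NotImplementedError

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Sequence of ``contig[start:end]`` (0-based half-open, clipped)."""
        raise NotImplementedError

    # -- conveniences shared by all implementations ---------------------

    def base_at(self, contig: str, position: int) -> str:
        """Base at a 1-based position."""
        return self.fetch(contig, position - 1, position)

    def window(self, contig: str, position: int, flank: int) -> tuple[str, int]:
        """Sequence of ``flank`` bases either side of a 1-based position.

        Returns ``(seq, offset)`` where ``offset`` is the index of the
        focal base inside ``seq`` (smaller than ``flank`` only when the
        window was clipped at the contig start).
        """
        start = max(0, position - 1 - flank)
        end = min(self.length(contig), position + flank)
        return self.fetch(contig, start, end), position - 1 - start

    def trinucleotide(self, contig: str, position: int) -> str | None:
        """Trinucleotide centered on a 1-based position, or None at a contig end."""
        if position < 2 or position > self.length(contig) - 1:
            return None
        return self.fetch(contig, position - 2, position + 1)


class InMemoryReference(Reference):
    """Reference backed by plain strings (synthetic genomes, fixtures)."""

    def __init__(self, sequences: Mapping[str, str] | Iterable[tuple[str, str]]):
        self._seqs = dict(sequences)
        for name, seq in self._seqs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")

    def contig_names(self) -> list[str]:
        return list(self._seqs)

    def length(self, contig: str) -> int:
        return len(self._seqs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        seq = self._seqs[contig]
        return seq[max(0, start):max(0, end)]

    def sequence(self, contig: str) -> str:
        return self._seqs[contig]


class FastaReference(Reference):
    """Reference backed by an indexed FASTA file (via pyfaidx)."""

    def __init__(self, path: str):
        import pyfaidx

        self._fasta = pyfaidx.Fasta(path, sequence_always_upper=True)

    def contig_names(self) -> list[str]:
        return list(self._fasta.keys())

    def length(self, contig: str) -> int:
        return len(self._fasta[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        end = min(end, self.length(contig))
        if start >= end:
            return ""
        return str(self._fasta[contig][max(0, start):end])

    def sequence(self, contig: str) -> str:
        return str(self._fasta[contig][:])


def as_reference(obj) -> Reference:
    """Coerce a Reference, mapping of sequences, or FASTA path to a Reference."""
    if isinstance(obj, Reference):
        return obj
    if isinstance(obj, (str, bytes)):
        return FastaReference(obj)
    if isinstance(obj, Mapping):
        return InMemoryReference(obj)
    raise TypeError(f"cannot interpret {type(obj).__name__} as a reference")
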