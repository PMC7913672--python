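"""Reference and read I/O.

Reads the reference amplicon from FASTA, streams structured reads (insert +
optional UMI) from FASTQ, and provides the small sequence utilities the rest
of the pipeline builds on.

Conventions
-----------
* All user-facing coordinates are 1-based and fully closed ("position 33"
  means the 33rd nucleotide).  0-based offsets exist only inside functions
  and are never serialised.
* RNA input (``U``) is normalised to the DNA alphabet (``T``) at the
  boundary; every downstream module works on ``A/C/G/T`` only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import FormatError, ValidationError

__all__ = [
    "ReferenceAmplicon",
    "StructuredRead",
    "UmiSpec",
    "normalize_sequence",
    "read_reference",
    "read_structured_fastq",
    "write_structured_fastq",
    "count_umi_run",
]

_DNA = frozenset("ACGT")
_INSERT_ALPHABET = frozenset("ACGTN")


def normalize_sequence(sequence: str) -> str:
    """Uppercase a nucleotide string and map RNA ``U`` to DNA ``T``.

    Idempotent: applying it twice gives the same result.
    """
    return sequence.upper().replace("U", "T")


@dataclass(frozen=True)
class ReferenceAmplicon:
    """A target amplicon sequence with its annotated m6A candidate positions.

    ``modified_positions`` are 1-based indices of residues annotated (or
    suspected) to carry m6A; each must point at an ``A`` in the normalised
    sequence.
    """

    name: str
    sequence: str
    modified_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        seq = normalize_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValidationError("reference sequence is empty")
        bad = set(seq) - _DNA
        if bad:
            raise ValidationError(
                f"reference contains non-ACGT characters after normalisation: {sorted(bad)}"
            )
        positions = tuple(int(p) for p in self.modified_positions)
        object.__setattr__(self, "modified_positions", positions)
        for p in positions:
            if not 1 <= p <= len(seq):
                raise ValidationError(
                    f"modified position {p} outside reference (length {len(seq)})"
                )
            if seq[p - 1] != "A":
                raise ValidationError(
                    f"modified position {p} is {seq[p - 1]!r}, not an A"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def a_positions(self) -> tuple[int, ...]:
        """1-based positions of every adenosine in the reference."""
        return tuple(i + 1 for i, b in enumerate(self.sequence) if b == "A")

    @property
    def c_positions(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, b in enumerate(self.sequence) if b == "C")


@dataclass(frozen=True)
class UmiSpec:
    """Where the unique molecular identifier sits inside the raw read.

    The two library preparations this pipeline targets differ: adapter
    ligation on synthetic oligos carries no UMI, while targeted RT primers
    embed a 7-nt UMI that ends up trailing the insert in the sequenced read.
    """

    placement: str = "none"  # "none" | "trailing" | "leading"
    length: int = 7

    def __post_init__(self) -> None:
        if self.placement not in ("none", "trailing", "leading"):
            raise ValidationError(f"unknown UMI placement {self.placement!r}")
        if self.placement != "none" and self.length < 1:
            raise ValidationError("UMI length must be >= 1")

    @classmethod
    def none(cls) -> "UmiSpec":
        return cls(placement="none", length=0)

    @classmethod
    def amplicon(cls) -> "UmiSpec":
        """The targeted-RT-primer layout: trailing 7-nt UMI."""
        return cls(placement="trailing", length=7)

    def split(self, sequence: str, qualities: str) -> tuple[str, str | None, str]:
        """Split a raw read into (insert, umi, insert_qualities)."""
        if self.placement == "none":
            return sequence, None, qualities
        n = self.length
        if len(sequence) < n:
            raise FormatError(
                f"read of length {len(sequence)} shorter than UMI length {n}"
            )
        if self.placement == "trailing":
            return sequence[:-n], sequence[-n:], qualities[:-n]
        return sequence[n:], sequence[:n], qualities[n:]

    def join(self, insert: str, umi: str | None, qualities: str) -> tuple[str, str]:
        """Inverse of :meth:`split`; UMI bases get the maximum quality."""
        if self.placement == "none" or umi is None:
            return insert, qualities
        pad = "I" * len(umi)
        if self.placement == "trailing":
            return insert + umi, qualities + pad
        return umi + insert, pad + qualities


@dataclass
class StructuredRead:
    """A sequenced read split into insert and (optional) UMI.

    Base qualities are carried verbatim (Phred+33 ASCII) but never
    interpreted by the pipeline.
    """

    read_id: str
    insert: str
    umi: str | None = None
    qualities: str = ""

    def __post_init__(self) -> None:
        if not self.qualities:
            self.qualities = "I" * len(self.insert)
        bad = set(self.insert) - _INSERT_ALPHABET
        if bad:
            raise ValidationError(
                f"read {self.read_id}: insert contains {sorted(bad)}"
            )


def read_reference(
    path: str | Path, modified_positions: Iterable[int] = ()
) -> ReferenceAmplicon:
    """Load the first FASTA record as the reference amplicon.

    U is normalised to T and every annotated position is validated to be an
    adenosine of the normalised sequence.
    """
    path = Path(path)
    try:
        record = next(SeqIO.parse(str(path), "fasta"), None)
    except (ValueError, FileNotFoundError) as exc:
        raise FormatError(f"cannot parse FASTA {path}: {exc}") from exc
    if record is None:
        raise FormatError(f"FASTA file {path} contains no records")
    return ReferenceAmplicon(
        name=record.id,
        sequence=str(record.seq),
        modified_positions=tuple(modified_positions),
    )


def read_structured_fastq(
    path: str | Path, umi_spec: UmiSpec | None = None
) -> Iterator[StructuredRead]:
    """Stream FASTQ records as :class:`StructuredRead`, splitting off the UMI.

    Raises :class:`FormatError` naming the (1-based) record index on a
    truncated or inconsistent record.
    """
    spec = umi_spec or UmiSpec.none()
    path = Path(path)
    parser = SeqIO.parse(str(path), "fastq")
    index = 0
    while True:
        index += 1
        try:
            record = next(parser)
        except StopIteration:
            return
        except ValueError as exc:
            raise FormatError(f"FASTQ record {index} in {path}: {exc}") from exc
        seq = normalize_sequence(str(record.seq))
        quals = "".join(
            chr(q + 33) for q in record.letter_annotations["phred_quality"]
        )
        insert, umi, insert_quals = spec.split(seq, quals)
        yield StructuredRead(
            read_id=record.id, insert=insert, umi=umi, qualities=insert_quals
        )


def write_structured_fastq(
    reads: Iterable[StructuredRead], path: str | Path, umi_spec: UmiSpec | None = None
) -> int:
    """Write reads to FASTQ, re-joining insert and UMI per ``umi_spec``.

    Returns the number of records written.
    """
    spec = umi_spec or UmiSpec.none()
    records = []
    for read in reads:
        seq, quals = spec.join(read.insert, read.umi, read.qualities)
        rec = SeqRecord(Seq(seq), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in quals]
        records.append(rec)
    return SeqIO.write(records, str(Path(path)), "fastq")


def count_umi_run(primer_sequence: str) -> int:
    """Length of the longest run of consecutive ``N`` in a primer sequence.

    Targeted RT primers encode their UMI as a run of N's between the adapter
    and the target-binding part; this recovers its length.
    """
    best = 0
    for char, group in itertools.groupby(primer_sequence.upper()):
        if char == "N":
            best = max(best, sum(1 for _ in group))
    return best
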