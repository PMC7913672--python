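import pytest

from noseq import ReferenceAmplicon, StructuredRead
from noseq.sim import demo_reference

# The synthetic 53-mer test oligo as it would arrive from an RNA supplier
# (RNA alphabet, m6A written as plain A at position 33).
RNA_53MER = "AUAGGGGAAUGGGCCGUUCAUCUGCUAAAAGGACUGCUUUUGGGGCUUGUAGU"
DNA_53MER = RNA_53MER.replace("U", "T")


@pytest.fixture
def ref53() -> ReferenceAmplicon:
    return demo_reference()


@pytest.fixture
def fasta_53mer(tmp_path):
    path = tmp_path / "ref.fasta"
    path.write_text(f">oligo_53mer\n{RNA_53MER}\n")
    return path


def make_read(insert: str, read_id: str = "r", umi: str | None = None) -> StructuredRead:
    return StructuredRead(read_id=read_id, insert=insert, umi=umi)


def fully_deaminated(sequence: str) -> str:
    """Complete A->I (read G) and C->U (read T) conversion of a DNA string."""
    return sequence.replace("A", "G").replace("C", "T")
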