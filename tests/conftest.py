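import pytest

from barcauth import synthetic
from barcauth.seqio import SequenceRecord


@pytest.fixture
def field_table():
    """The packaged 38-sample field-collection character table."""
    return synthetic.table5_characters()


@pytest.fixture
def write_fasta(tmp_path):
    def _write(seqs, name="input.fasta", meta=True):
        path = tmp_path / name
        with open(path, "w") as fh:
            for i, item in enumerate(seqs, start=1):
                if isinstance(item, SequenceRecord):
                    extra = f" species={item.species.replace(' ', '_')}" if meta else ""
                    fh.write(f">{item.id}{extra}\n{item.sequence}\n")
                else:
                    fh.write(f">seq{i}\n{item}\n")
        return path

    return _write
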