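import numpy as np
import pytest

from pldscale import PLDSequence


@pytest.fixture
def fasta_file(tmp_path):
    """Factory writing a FASTA file from (id, residues) pairs."""

    def _write(records, name="seqs.fasta"):
        path = tmp_path / name
        path.write_text("".join(f">{rid}\n{res}\n" for rid, res in records))
        return path

    return _write


@pytest.fixture
def random_sequence():
    """Factory for random sequences over a given alphabet."""

    def _make(length, seed, alphabet="ACDEFGHIKLMNPQRSTVWY", seq_id="rand"):
        rng = np.random.default_rng(seed)
        letters = rng.choice(list(alphabet), size=length)
        return PLDSequence(id=seq_id, residues="".join(letters))

    return _make
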