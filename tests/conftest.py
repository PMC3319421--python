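import pytest

from sptax.datasets import EXAMPLE_READS, EXAMPLE_SP, example_anchored_reads
from sptax.io_formats import SPRecord


@pytest.fixture(scope="session")
def example_sp() -> SPRecord:
    return EXAMPLE_SP


@pytest.fixture()
def example_reads():
    return dict(EXAMPLE_READS)


@pytest.fixture()
def anchored_example():
    return example_anchored_reads()


@pytest.fixture()
def fasta_file(tmp_path):
    def _write(records, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rid, seq in records:
                fh.write(f">{rid}\n{seq}\n")
        return path

    return _write


@pytest.fixture()
def sp_table_file(tmp_path):
    def _write(rows, name="sp.tsv"):
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write("# peptide\tec\n")
            for peptide, ec in rows:
                fh.write(f"{peptide}\t{ec}\n")
        return path

    return _write
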