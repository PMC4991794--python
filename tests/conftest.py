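import textwrap

import pytest

SAM_HEADER = "@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:chr1\tLN:100000\n"


def make_sam(tmp_path, records, name="reads.sam", header=SAM_HEADER):
    """Write a minimal SAM file from (qname, flag, rname, pos1, cigar) tuples."""
    path = tmp_path / name
    with open(path, "w") as fh:
        fh.write(header)
        for qname, flag, rname, pos1, cigar in records:
            fh.write(f"{qname}\t{flag}\t{rname}\t{pos1}\t255\t{cigar}\t*\t0\t0\t*\t*\n")
    return path


@pytest.fixture
def sam_factory(tmp_path):
    def _make(records, name="reads.sam"):
        return make_sam(tmp_path, records, name=name)

    return _make


@pytest.fixture
def gff3_file(tmp_path):
    path = tmp_path / "ann.gff3"
    path.write_text(
        textwrap.dedent(
            """\
            ##gff-version 3
            chr1\tsrc\tCDS\t101\t200\t.\t+\t0\tID=SCO0001
            chr1\tsrc\tCDS\t301\t900\t.\t-\t0\tID=SCO0002
            """
        )
    )
    return path
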