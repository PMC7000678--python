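import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from neuston_phylogeo.io_formats import NucleotideSequence, SequenceSet
from neuston_phylogeo.popgen_stats import HaplotypeTable


@pytest.fixture
def write_fasta_file(tmp_path):
    """Write records to a temporary FASTA file; returns its path."""

    def _write(records, name="test.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for rec_id, residues in records:
                fh.write(f">{rec_id}\n{residues}\n")
        return path

    return _write


@pytest.fixture
def write_group_file(tmp_path):
    def _write(entries, name="groups.tsv"):
        path = tmp_path / name
        with open(path, "w") as fh:
            fh.write("id\tclade\thabitat\n")
            for sid, clade, habitat in entries:
                fh.write(f"{sid}\t{clade}\t{habitat}\n")
        return path

    return _write


def make_alignment(rows, ids=None):
    ids = ids or [f"s{i + 1}" for i in range(len(rows))]
    return SequenceSet(
        [NucleotideSequence(i, r) for i, r in zip(ids, rows)], is_alignment=True
    )


def make_table(vectors, counts=None):
    """Haplotype table straight from residue vectors (unit counts default)."""
    counts = counts or [1] * len(vectors)
    haps = [
        (f"H{i + 1}", v, [f"m{i}_{j}" for j in range(c)], c)
        for i, (v, c) in enumerate(zip(vectors, counts))
    ]
    return HaplotypeTable(haps, n=sum(counts), analyzed_sites=len(vectors[0]))
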