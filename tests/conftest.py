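import numpy as np
import pandas as pd
import pytest

from spliceatlas.junction_data import JunctionCountTable


def make_sheet(sample_ids, dataset="DS1", cell_types=None, condition="healthy"):
    n = len(sample_ids)
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "dataset": [dataset] * n,
            "cell_type": cell_types or ["B"] * n,
            "condition": [condition] * n,
            "donor": [f"d{i}" for i in range(n)],
        }
    )


@pytest.fixture
def sheet4():
    return make_sheet(["s1", "s2", "s3", "s4"])


@pytest.fixture
def toy_table(sheet4):
    counts = pd.DataFrame(
        {
            "s1": [30, 70, 5],
            "s2": [40, 60, 2],
            "s3": [0, 0, 0],
            "s4": [12, 20, 1],
        },
        index=pd.Index(
            ["chr1:100:200:+", "chr1:100:300:+", "chr1:250:300:+"], name="junction"
        ),
        dtype=np.int64,
    )
    return JunctionCountTable(counts, sheet4)


TOY_GFF3 = """##gff-version 3
chr1\ttoy\tgene\t100\t500\t.\t+\t.\tID=geneA
chr1\ttoy\tmRNA\t100\t500\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\ttoy\texon\t100\t199\t.\t+\t.\tID=geneA.t1.e1;Parent=geneA.t1
chr1\ttoy\texon\t250\t299\t.\t+\t.\tID=geneA.t1.e2;Parent=geneA.t1
chr1\ttoy\texon\t400\t500\t.\t+\t.\tID=geneA.t1.e3;Parent=geneA.t1
chr1\ttoy\tmRNA\t100\t500\t.\t+\t.\tID=geneA.t2;Parent=geneA
chr1\ttoy\texon\t100\t199\t.\t+\t.\tID=geneA.t2.e1;Parent=geneA.t2
chr1\ttoy\texon\t400\t500\t.\t+\t.\tID=geneA.t2.e2;Parent=geneA.t2
chrM\ttoy\tgene\t1\t900\t.\t+\t.\tID=geneM
chrM\ttoy\tmRNA\t1\t900\t.\t+\t.\tID=geneM.t1;Parent=geneM
chrM\ttoy\texon\t1\t400\t.\t+\t.\tID=geneM.t1.e1;Parent=geneM.t1
chrM\ttoy\texon\t600\t900\t.\t+\t.\tID=geneM.t1.e2;Parent=geneM.t1
"""


@pytest.fixture
def toy_gff3(tmp_path):
    p = tmp_path / "toy.gff3"
    p.write_text(TOY_GFF3)
    return p
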