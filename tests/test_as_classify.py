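"""Alternative-splicing-type calls from junction geometry plus annotation."""

import pytest

from spliceatlas.annotation_model import GeneModel, Transcript
from spliceatlas.as_classify import (
    classify_a3ss,
    classify_a5ss,
    classify_afe_ale,
    classify_all,
    classify_mxe,
    classify_se,
)
from spliceatlas.junction_data import Junction


def J(start, end, strand="+", chrom="chr1"):
    return Junction(chrom, start, end, strand)


SE_GENE = GeneModel(
    "g", "chr1", "+",
    (
        Transcript("t1", ((600, 699), (1000, 1099), (1200, 1299), (1400, 1499), (1700, 1799))),
        Transcript("t2", ((600, 699), (1000, 1099), (1400, 1499), (1700, 1799))),
    ),
)
SE_TRIAD = [J(1100, 1199), J(1300, 1399), J(1100, 1399)]


class TestSE:
    def test_exact_triad(self):
        dpsi = {j.key: d for j, d in zip(SE_TRIAD, (0.2, 0.2, 0.3))}
        ev = classify_se(SE_TRIAD, dpsi, SE_GENE)
        assert ev and ev[0]["exon"] == [1200, 1299]

    def test_needs_two_qualifying_junctions(self):
        dpsi = {j.key: d for j, d in zip(SE_TRIAD, (0.2, 0.05, 0.05))}
        assert classify_se(SE_TRIAD, dpsi, SE_GENE) is None

    def test_no_skip_junction_no_call(self):
        triad = SE_TRIAD[:2]
        dpsi = {j.key: 0.3 for j in triad}
        assert classify_se(triad, dpsi, SE_GENE) is None


class TestMXE:
    up = [J(1100, 1199), J(1100, 1399)]
    down = [J(1300, 1699), J(1500, 1699)]

    def test_two_cluster_pair(self):
        dpsi = {j.key: 0.3 for j in self.up + self.down}
        hits = classify_mxe({"lcU": self.up, "lcD": self.down}, dpsi)
        assert set(hits) == {"lcU", "lcD"}

    def test_single_cluster_gene_no_call(self):
        dpsi = {j.key: 0.3 for j in self.up}
        assert classify_mxe({"lcU": self.up}, dpsi) is None

    def test_upstream_without_shared_start_no_call(self):
        up = [J(1100, 1199), J(1120, 1399)]
        dpsi = {j.key: 0.3 for j in up + self.down}
        assert classify_mxe({"lcU": up, "lcD": self.down}, dpsi) is None


A5_GENE_PLUS = GeneModel(
    "g", "chr1", "+",
    (
        Transcript("t1", ((600, 699), (1000, 1149), (1400, 1499), (1700, 1799))),
        Transcript("t2", ((600, 699), (1000, 1199), (1400, 1499), (1700, 1799))),
    ),
)
A5_JUNCS = [J(1150, 1399), J(1200, 1399)]


class TestAltSS:
    def test_a5ss_plus(self):
        dpsi = {j.key: 0.3 for j in A5_JUNCS}
        assert classify_a5ss(A5_JUNCS, dpsi, A5_GENE_PLUS)
        assert classify_a3ss(A5_JUNCS, dpsi, A5_GENE_PLUS) is None

    def test_same_geometry_on_minus_is_a3ss(self):
        gene = GeneModel("g", "chr1", "-", A5_GENE_PLUS.transcripts)
        juncs = [J(1150, 1399, "-"), J(1200, 1399, "-")]
        dpsi = {j.key: 0.3 for j in juncs}
        assert classify_a3ss(juncs, dpsi, gene)
        assert classify_a5ss(juncs, dpsi, gene) is None

    def test_shared_start_on_plus_is_a3ss(self):
        gene = GeneModel(
            "g", "chr1", "+",
            (
                Transcript("t1", ((600, 699), (1000, 1099), (1300, 1499), (1700, 1799))),
                Transcript("t2", ((600, 699), (1000, 1099), (1350, 1499), (1700, 1799))),
            ),
        )
        juncs = [J(1100, 1299), J(1100, 1349)]
        dpsi = {j.key: 0.3 for j in juncs}
        assert classify_a3ss(juncs, dpsi, gene)
        assert classify_a5ss(juncs, dpsi, gene) is None

    def test_unknown_strand_not_classified(self):
        gene = GeneModel("g", "chr1", ".", A5_GENE_PLUS.transcripts)
        juncs = [J(1150, 1399, "."), J(1200, 1399, ".")]
        dpsi = {j.key: 0.3 for j in juncs}
        assert classify_a5ss(juncs, dpsi, gene) is None

    def test_alternates_must_share_one_exon_interval(self):
        # donor-adjacent positions fall in two different exons: no call
        gene = GeneModel(
            "g", "chr1", "+",
            (
                Transcript("t1", ((1000, 1099), (2000, 2099), (2400, 2499))),
                Transcript("t2", ((1400, 1499), (2000, 2099), (2400, 2499))),
            ),
        )
        juncs = [J(1100, 1999), J(1500, 1999)]
        dpsi = {j.key: 0.3 for j in juncs}
        assert classify_a5ss(juncs, dpsi, gene) is None


AFE_GENE = GeneModel(
    "g", "chr1", "+",
    (
        Transcript("t1", ((1000, 1099), (2000, 2099), (2400, 2499))),
        Transcript("t2", ((1400, 1499), (2000, 2099), (2400, 2499))),
    ),
)


class TestAfeAle:
    def test_afe_junctions(self):
        juncs = [J(1100, 1999), J(1500, 1999)]
        dpsi = {j.key: 0.3 for j in juncs}
        afe, ale = classify_afe_ale(juncs, dpsi, AFE_GENE)
        assert afe and len(afe) == 2 and ale is None

    def test_internal_junction_neither(self):
        # flanks only the internal exon (2000,2099)
        juncs = [J(1600, 1999)]
        dpsi = {j.key: 0.3 for j in juncs}
        afe, ale = classify_afe_ale(juncs, dpsi, AFE_GENE)
        assert afe is None and ale is None

    def test_exon_first_in_one_transcript_last_in_another(self):
        gene = GeneModel(
            "g", "chr1", "+",
            (
                Transcript("t1", ((100, 199), (500, 599))),
                Transcript("t2", ((500, 599), (900, 999))),
            ),
        )
        juncs = [J(200, 499), J(600, 899)]
        dpsi = {j.key: 0.3 for j in juncs}
        afe, ale = classify_afe_ale(juncs, dpsi, gene)
        # exon (500,599) is last of t1 and first of t2: both sets hit
        assert afe and ale


class TestClassifyAll:
    def test_union_and_unknown(self):
        genes = {"g": SE_GENE}
        lc_junctions = {"lc1": SE_TRIAD, "lc2": [J(5000, 5100), J(5000, 5200)]}
        dpsi = {j.key: 0.3 for j in SE_TRIAD}
        dpsi.update({"chr1:5000:5100:+": 0.3, "chr1:5000:5200:+": 0.3})
        out = classify_all(lc_junctions, dpsi, {"lc1": "g", "lc2": None}, genes)
        assert out["lc1"].types == {"SE"}
        assert out["lc2"].types == frozenset() and out["lc2"].label == "unknown"

    def test_multi_label_allowed(self):
        # SE triad whose upstream flanking exon is also a first exon
        gene = GeneModel(
            "g", "chr1", "+",
            (
                Transcript("t1", ((1000, 1099), (1200, 1299), (1400, 1499), (1700, 1799))),
                Transcript("t2", ((1000, 1099), (1400, 1499), (1700, 1799))),
            ),
        )
        dpsi = {j.key: d for j, d in zip(SE_TRIAD, (0.2, 0.2, 0.3))}
        out = classify_all({"lc": SE_TRIAD}, dpsi, {"lc": "g"}, {"g": gene})
        assert {"SE", "AFE"} <= out["lc"].types

    def test_pure_function_order_independent(self):
        genes = {"g": SE_GENE}
        dpsi = {j.key: 0.3 for j in SE_TRIAD}
        a = classify_all({"lc": SE_TRIAD}, dpsi, {"lc": "g"}, genes)
        b = classify_all({"lc": list(reversed(SE_TRIAD))}, dpsi, {"lc": "g"}, genes)
        assert a["lc"].types == b["lc"].types
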