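import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from refstab.ct_io import (
    AssayDesign,
    CtMatrix,
    CtMatrixError,
    EfficiencyTable,
    check_stemloop_primer,
    ct_to_quantity,
    efficiency_from_percent,
    read_ct_table,
    read_efficiency_table,
    write_ct_table,
)
from refstab.published import ASSAY_DESIGNS

from conftest import make_ct


WIDE = """sample_id,colony,body_part,day,G1,G2
s1,c1,head,0D,20.0,25.0
s2,c1,head,1D,21.0,24.0
s3,c2,thorax_abdomen,0D,22.5,23.0
"""

LONG_ROWS = [
    ("s1", "c1", "head", "0D", "G1", 20.0),
    ("s2", "c1", "head", "1D", "G1", 21.0),
    ("s3", "c2", "thorax_abdomen", "0D", "G1", 22.5),
    ("s1", "c1", "head", "0D", "G2", 25.0),
    ("s2", "c1", "head", "1D", "G2", 24.0),
    ("s3", "c2", "thorax_abdomen", "0D", "G2", 23.0),
]


def _long_text(rows) -> str:
    head = "sample_id\tcolony\tbody_part\tday\tgene\tct\n"
    return head + "\n".join("\t".join(map(str, r)) for r in rows) + "\n"


class TestReadCtTable:
    def test_wide_shape_and_metadata(self):
        mat = read_ct_table(io.StringIO(WIDE), layout="wide")
        assert mat.genes == ["G1", "G2"]
        assert mat.samples == ["s1", "s2", "s3"]
        assert list(mat.meta["day"].cat.categories) == ["0D", "1D"]
        assert mat.ct.loc["G1", "s3"] == 22.5

    def test_long_equals_wide_even_shuffled(self):
        wide = read_ct_table(io.StringIO(WIDE), layout="wide")
        rows = [LONG_ROWS[i] for i in (3, 0, 5, 2, 1, 4)]
        long = read_ct_table(io.StringIO(_long_text(rows)), layout="long")
        pd.testing.assert_frame_equal(
            wide.ct.sort_index(), long.ct.sort_index(), check_like=True
        )
        cols = ["colony", "body_part", "day"]
        assert wide.meta[cols].astype(str).equals(
            long.meta.loc[wide.meta.index, cols].astype(str)
        )

    def test_duplicate_cell_rejected(self):
        rows = LONG_ROWS + [("s1", "c1", "head", "0D", "G1", 20.0)]
        with pytest.raises(CtMatrixError, match="duplicate cell"):
            read_ct_table(io.StringIO(_long_text(rows)), layout="long")

    def test_missing_metadata_column(self):
        text = WIDE.replace("sample_id,colony,", "sample_id,")
        with pytest.raises(CtMatrixError, match="colony"):
            read_ct_table(io.StringIO(text), layout="wide")

    def test_non_numeric_ct(self):
        with pytest.raises(CtMatrixError, match="non-numeric"):
            read_ct_table(io.StringIO(WIDE.replace("22.5", "oops")), "wide")

    def test_ct_out_of_range(self):
        with pytest.raises(CtMatrixError, match="out of range"):
            read_ct_table(io.StringIO(WIDE.replace("22.5", "46.0")), "wide")

    def test_round_trip(self, tmp_path):
        mat = read_ct_table(io.StringIO(WIDE), layout="wide")
        path = str(tmp_path / "ct.tsv")
        write_ct_table(mat, path)
        back = read_ct_table(path, layout="wide")
        pd.testing.assert_frame_equal(mat.ct, back.ct)
        assert mat.meta.astype(str).equals(back.meta.astype(str))


class TestEfficiency:
    @pytest.mark.parametrize(
        "pct,expected", [(113.3, 2.133), (100.0, 2.0), (104.0, 2.04)]
    )
    def test_percent_to_factor(self, pct, expected):
        assert efficiency_from_percent(pct) == pytest.approx(expected)

    @pytest.mark.parametrize("pct", [0.0, -5.0, 151.0])
    def test_implausible_rejected(self, pct):
        with pytest.raises(ValueError):
            efficiency_from_percent(pct)

    def test_default_is_doubling(self):
        assert EfficiencyTable()["anything"] == 2.0

    def test_table_parsing(self):
        eff = read_efficiency_table(io.StringIO("gene,efficiency_percent\nG1,113.3\n"))
        assert eff["G1"] == pytest.approx(2.133)
        assert eff["G2"] == 2.0


class TestCtToQuantity:
    def test_min_ct_maps_to_one_and_doubling(self, toy_ct):
        q = ct_to_quantity(toy_ct)
        assert q.loc["G1"].max() == 1.0
        # one cycle above the per-gene minimum halves the quantity at E = 2
        assert q.loc["G1", "s0"] == 1.0 and q.loc["G1", "s1"] == 0.5

    def test_non_doubling_efficiency(self):
        mat = make_ct({"G1": [20.0, 22.0], "G2": [20.0, 20.0]})
        q = ct_to_quantity(mat, EfficiencyTable({"G1": 2.133}))
        assert q.loc["G1"].iloc[1] == pytest.approx(2.133 ** -2, abs=5e-5)
        assert q.loc["G1"].iloc[1] == pytest.approx(0.2198, abs=1e-4)

    def test_monotone_decreasing_in_ct(self):
        rng = np.random.default_rng(1)
        ct_vals = rng.uniform(18, 35, 12)
        mat = make_ct({"G1": ct_vals.tolist(), "G2": [20.0] * 12})
        q = ct_to_quantity(mat)
        order = np.argsort(ct_vals)
        assert (np.diff(q.loc["G1"].to_numpy()[order]) < 0).all()

    def test_per_gene_additive_shift_cancels(self, toy_ct):
        q0 = ct_to_quantity(toy_ct)
        shifted = toy_ct.ct.copy()
        shifted.loc["G1"] += 3.0
        q1 = ct_to_quantity(CtMatrix(shifted, toy_ct.meta.copy()))
        pd.testing.assert_frame_equal(q0, q1)

    def test_missing_propagates_and_all_missing_errors(self):
        mat = make_ct({"G1": [20.0, np.nan, 22.0], "G2": [20.0, 21.0, 20.0]})
        q = ct_to_quantity(mat)
        assert np.isnan(q.loc["G1"].iloc[1]) and q.loc["G1"].notna().sum() == 2
        bad = make_ct({"G1": [np.nan, np.nan], "G2": [20.0, 21.0]})
        with pytest.raises(CtMatrixError, match="no observed"):
            ct_to_quantity(bad)


class TestStemloopPrimer:
    @pytest.mark.parametrize(
        "gene,offset", [("miR-193-3p", 0), ("miR-7-3p", 1), ("U6", 0), ("miR-2788-3p", 1)]
    )
    def test_published_designs_anneal(self, gene, offset):
        res = check_stemloop_primer(ASSAY_DESIGNS[gene])
        assert res == {"ok": True, "offset": offset}

    def test_all_published_designs_pass(self):
        assert all(
            check_stemloop_primer(d)["ok"] for d in ASSAY_DESIGNS.values()
        )

    def test_mismatched_primer_fails(self):
        d = AssayDesign(
            gene="x",
            mirna_seq=ASSAY_DESIGNS["miR-193-3p"].mirna_seq,
            stemloop_primer="GTCGTATCCAGTGCAGGGTCCGAGGTGGGGGG",
        )
        assert check_stemloop_primer(d) == {"ok": False, "offset": None}

    def test_too_short_errors(self):
        d = AssayDesign(gene="x", mirna_seq="ACGUAC", stemloop_primer="ACGTACGT")
        with pytest.raises(ValueError, match="7 nt"):
            check_stemloop_primer(d)

    def test_markup_stripped_and_alphabet_enforced(self):
        d = AssayDesign(
            gene="x", mirna_seq="ACGUACGU", stemloop_primer="ACGTACGT",
            probe="(FAM)ACGT(MGB)",
        )
        assert d.probe == "ACGT"
        with pytest.raises(ValueError, match="non-ACGU"):
            AssayDesign(gene="x", mirna_seq="ACGT", stemloop_primer="ACGTACGT")


@settings(deadline=None, derandomize=True, max_examples=50)
@given(pct=st.floats(min_value=0.1, max_value=150.0, allow_nan=False))
def test_efficiency_factor_in_valid_band(pct):
    e = efficiency_from_percent(pct)
    assert 1.0 < e <= 2.5
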