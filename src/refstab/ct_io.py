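"""Reading, validation and transformation of Ct tables.

The quantification cycle (Ct) is the PCR cycle at which a well's
fluorescence crosses the detection threshold; it is inversely
log-proportional to the starting template amount.  Every downstream
stability algorithm in this package consumes either raw Ct values or the
efficiency-transformed relative quantities produced here.

A :class:`CtMatrix` couples a genes x samples table of Ct values with
per-sample metadata (colony, body part, sampling day).  Missing wells are
represented as NaN and are carried, not imputed; each algorithm declares
its own missing-data policy.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "CtMatrix",
    "EfficiencyTable",
    "AssayDesign",
    "CT_RANGE",
    "META_COLUMNS",
    "read_ct_table",
    "write_ct_table",
    "read_efficiency_table",
    "efficiency_from_percent",
    "ct_to_quantity",
    "check_stemloop_primer",
]

#: Plausible Ct range: the qPCR program runs 40 cycles; 45 leaves headroom
#: for instruments that extrapolate slightly past the last cycle.
CT_RANGE = (0.0, 45.0)

#: Mandatory per-sample metadata columns, in canonical order.
META_COLUMNS = ("sample_id", "colony", "body_part", "day")


class CtMatrixError(ValueError):
    """Raised when a Ct table violates a structural invariant."""


@dataclass
class CtMatrix:
    """Genes x samples Ct values plus per-sample metadata.

    Parameters
    ----------
    ct
        DataFrame indexed by gene name with one column per ``sample_id``.
        Missing wells are NaN.
    meta
        DataFrame indexed by ``sample_id`` with columns ``colony``,
        ``body_part`` and ``day``.  Level order is first-appearance order
        unless the columns are already ordered categoricals.
    """

    ct: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.ct = self.ct.astype(float)
        self.ct.index.name = None
        self.ct.columns.name = None
        if self.ct.shape[0] < 2 or self.ct.shape[1] < 2:
            raise CtMatrixError(
                f"need at least 2 genes and 2 samples, got {self.ct.shape}"
            )
        if self.ct.index.has_duplicates:
            raise CtMatrixError("duplicate gene names")
        if self.ct.columns.has_duplicates:
            raise CtMatrixError("duplicate sample ids")
        if not self.ct.columns.equals(pd.Index(self.meta.index)):
            raise CtMatrixError("metadata sample ids do not match Ct columns")
        missing_meta = [c for c in META_COLUMNS[1:] if c not in self.meta.columns]
        if missing_meta:
            raise CtMatrixError(f"missing metadata columns: {missing_meta}")
        vals = self.ct.to_numpy(float)
        present = ~np.isnan(vals)
        lo, hi = CT_RANGE
        bad = present & ((vals <= lo) | (vals > hi))
        if bad.any():
            g, s = np.argwhere(bad)[0]
            raise CtMatrixError(
                f"Ct out of range ({lo}, {hi}]: gene {self.ct.index[g]!r}, "
                f"sample {self.ct.columns[s]!r}, value {vals[g, s]}"
            )
        # freeze metadata level order: first appearance unless already ordered
        for col in META_COLUMNS[1:]:
            if not isinstance(self.meta[col].dtype, pd.CategoricalDtype):
                levels = pd.unique(self.meta[col])
                self.meta[col] = pd.Categorical(
                    self.meta[col], categories=levels, ordered=True
                )

    @property
    def genes(self) -> list[str]:
        return list(self.ct.index)

    @property
    def samples(self) -> list[str]:
        return list(self.ct.columns)

    def subset_genes(self, genes: Iterable[str]) -> "CtMatrix":
        genes = list(genes)
        missing = set(genes) - set(self.ct.index)
        if missing:
            raise CtMatrixError(f"unknown genes: {sorted(missing)}")
        return CtMatrix(self.ct.loc[genes].copy(), self.meta.copy())

    def subset_samples(self, mask: pd.Series) -> "CtMatrix":
        keep = self.meta.index[mask.reindex(self.meta.index).fillna(False)]
        return CtMatrix(self.ct[keep].copy(), self.meta.loc[keep].copy())

    def stratify(self, column: str = "body_part") -> dict[str, "CtMatrix"]:
        """Split the dataset into independent strata (body parts)."""
        out = {}
        for level in self.meta[column].cat.categories:
            mask = self.meta[column] == level
            if mask.sum() >= 2:
                out[str(level)] = self.subset_samples(mask)
        return out


@dataclass
class EfficiencyTable:
    """Per-gene amplification factor E (fold increase per cycle).

    A perfectly efficient PCR doubles the template each cycle (E = 2).
    Genes absent from the table default to 2.0.
    """

    efficiencies: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for gene, e in self.efficiencies.items():
            if not e > 1.0 or e > 2.5:
                raise ValueError(f"efficiency for {gene!r} outside (1, 2.5]: {e}")

    def __getitem__(self, gene: str) -> float:
        return float(self.efficiencies.get(gene, 2.0))


@dataclass
class AssayDesign:
    """Sequences of one stem-loop RT-qPCR assay.

    ``probe`` may carry reporter/quencher annotations such as ``(FAM)`` or
    ``(MGB)``; they are stripped before validation.
    """

    gene: str
    mirna_seq: str
    stemloop_primer: str
    probe: str = ""
    forward_primer: str = ""

    def __post_init__(self) -> None:
        self.mirna_seq = _validate_seq(self.mirna_seq, "ACGU", "miRNA")
        self.stemloop_primer = _validate_seq(
            self.stemloop_primer, "ACGT", "stem-loop primer"
        )
        if self.probe:
            self.probe = _validate_seq(_strip_markup(self.probe), "ACGT", "probe")
        if self.forward_primer:
            self.forward_primer = _validate_seq(
                self.forward_primer, "ACGT", "forward primer"
            )


def _strip_markup(seq: str) -> str:
    out, depth = [], 0
    for ch in seq:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        elif depth == 0:
            out.append(ch)
    return "".join(out)


def _validate_seq(seq: str, alphabet: str, what: str) -> str:
    seq = seq.strip().upper()
    if not seq:
        raise ValueError(f"empty {what} sequence")
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"{what} contains non-{alphabet} symbols: {sorted(bad)}")
    return seq


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def _sniff_sep(first_line: str) -> str:
    return "\t" if first_line.count("\t") >= first_line.count(",") else ","


def _as_text(stream) -> TextIO:
    if isinstance(stream, (str,)):
        import os

        if os.path.exists(stream) or "\n" not in stream:
            return open(stream, "r", encoding="utf-8")
        return io.StringIO(stream)
    return stream


def read_ct_table(stream, layout: str = "wide") -> CtMatrix:
    """Read a delimited Ct table in ``wide`` or ``long`` layout.

    Wide: one row per sample with columns ``sample_id, colony, body_part,
    day`` followed by one column per gene.  Long: columns ``sample_id,
    colony, body_part, day, gene, ct``.  The delimiter (comma or tab) is
    sniffed from the header line.

    Raises
    ------
    CtMatrixError
        On duplicate (gene, sample) cells, non-numeric Ct, or missing
        mandatory metadata columns.
    """
    fh = _as_text(stream)
    text = fh.read()
    sep = _sniff_sep(text.splitlines()[0] if text else "")
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype={"sample_id": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise CtMatrixError(f"missing mandatory metadata columns: {missing}")

    if layout == "wide":
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise CtMatrixError(f"duplicate cell: sample {dup!r} appears twice")
        gene_cols = [c for c in df.columns if c not in META_COLUMNS]
        meta = df[list(META_COLUMNS)].set_index("sample_id")
        ct = df.set_index("sample_id")[gene_cols].T
        ct = _coerce_numeric(ct)
        return CtMatrix(ct, meta)

    if layout == "long":
        if "gene" not in df.columns or "ct" not in df.columns:
            raise CtMatrixError("long layout requires 'gene' and 'ct' columns")
        if df.duplicated(subset=["sample_id", "gene"]).any():
            row = df[df.duplicated(subset=["sample_id", "gene"])].iloc[0]
            raise CtMatrixError(
                f"duplicate cell: sample {row['sample_id']!r}, gene {row['gene']!r}"
            )
        meta = (
            df[list(META_COLUMNS)]
            .drop_duplicates(subset="sample_id")
            .set_index("sample_id")
        )
        genes = list(pd.unique(df["gene"]))
        samples = list(meta.index)
        ct = df.pivot(index="gene", columns="sample_id", values="ct")
        ct = _coerce_numeric(ct.reindex(index=genes, columns=samples))
        ct.columns.name = None
        ct.index.name = None
        return CtMatrix(ct, meta)

    raise ValueError(f"unknown layout {layout!r}; expected 'wide' or 'long'")


def _coerce_numeric(ct: pd.DataFrame) -> pd.DataFrame:
    try:
        return ct.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise CtMatrixError(f"non-numeric Ct value: {exc}") from exc


def write_ct_table(mat: CtMatrix, stream, sep: str = "\t") -> None:
    """Write a CtMatrix in wide layout (round-trips through read_ct_table)."""
    close = False
    if isinstance(stream, str):
        stream, close = open(stream, "w", encoding="utf-8"), True
    try:
        wide = mat.meta.reset_index()
        wide = pd.concat([wide, mat.ct.T.reset_index(drop=True)], axis=1)
        wide.to_csv(stream, sep=sep, index=False)
    finally:
        if close:
            stream.close()


def read_efficiency_table(stream) -> EfficiencyTable:
    """Read a two-column (gene, efficiency_percent) delimited table."""
    fh = _as_text(stream)
    text = fh.read()
    sep = _sniff_sep(text.splitlines()[0] if text else "")
    df = pd.read_csv(io.StringIO(text), sep=sep)
    gene_col, pct_col = df.columns[:2]
    eff = {
        str(row[gene_col]): efficiency_from_percent(float(row[pct_col]))
        for _, row in df.iterrows()
    }
    return EfficiencyTable(eff)


# ---------------------------------------------------------------------------
# Ct -> relative quantity
# ---------------------------------------------------------------------------

def efficiency_from_percent(pct: float) -> float:
    """Convert a percent efficiency to the amplification factor E = 1 + pct/100.

    100% efficiency means perfect doubling, E = 2.  Values outside
    (0, 150] are rejected as implausible assays.
    """
    if not pct > 0:
        raise ValueError(f"efficiency percent must be > 0, got {pct}")
    if pct > 150:
        raise ValueError(f"implausible efficiency percent {pct} (> 150)")
    return 1.0 + pct / 100.0


def ct_to_quantity(
    mat: CtMatrix, eff: EfficiencyTable | None = None
) -> pd.DataFrame:
    """Transform Ct to relative quantities Q = E**(minCt - Ct), per gene.

    Each gene's most abundant sample (minimum Ct) gets quantity 1; every
    extra cycle divides the quantity by that gene's amplification factor.
    Missing Ct propagates as missing Q.

    Parameters
    ----------
    mat
        Input Ct matrix.
    eff
        Per-gene efficiencies; ``None`` assumes perfect doubling (E = 2)
        for every gene.

    Returns
    -------
    DataFrame of quantities, same index/columns as ``mat.ct``, values in
    (0, 1] with per-gene maximum exactly 1.
    """
    if eff is None:
        eff = EfficiencyTable()
    q = pd.DataFrame(index=mat.ct.index, columns=mat.ct.columns, dtype=float)
    for gene in mat.ct.index:
        row = mat.ct.loc[gene]
        if row.isna().all():
            raise CtMatrixError(f"gene {gene!r} has no observed Ct values")
        e = eff[gene]
        q.loc[gene] = np.power(e, row.min() - row)
    return q


def log2_quantity(q: pd.DataFrame) -> pd.DataFrame:
    """log2 of a quantity matrix (the scale NormFinder operates on)."""
    return np.log2(q)


# ---------------------------------------------------------------------------
# Stem-loop primer QC
# ---------------------------------------------------------------------------

def check_stemloop_primer(design: AssayDesign) -> dict:
    """Check that a stem-loop RT primer's 3' end anneals to the miRNA 3' end.

    A stem-loop RT primer extends the ~22 nt miRNA into an amplifiable
    cDNA; its 3'-terminal six bases must be the reverse complement (in
    DNA) of the miRNA's 3'-terminal hexamer, or of the hexamer ending one
    base earlier (some designs skip the terminal base).

    Returns
    -------
    dict with keys ``ok`` (bool) and ``offset`` (0 or 1 when ok, else None).
    """
    if len(design.mirna_seq) < 7 or len(design.stemloop_primer) < 7:
        raise ValueError("sequences shorter than 7 nt")
    primer_end = design.stemloop_primer[-6:]
    for offset in (0, 1):
        stop = len(design.mirna_seq) - offset
        hexamer = design.mirna_seq[stop - 6 : stop]
        expected = str(Seq(hexamer.replace("U", "T")).reverse_complement())
        if primer_end == expected:
            return {"ok": True, "offset": offset}
    return {"ok": False, "offset": None}
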