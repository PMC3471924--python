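"""Readers, writers and container types for all pipeline inputs.

Formats are deliberately plain: tab-separated UTF-8 text with ``.`` decimals
for matrices, metadata, ortholog tables, cohort tables and micronucleus count
tables; GMT (with an optional ``+``/``-`` suffix dialect for per-gene
directions) for gene sets.  Mouse gene symbols are title case, human symbols
upper case; cross-species comparisons must go through an
:class:`OrthologTable` (or explicit case-folding), never raw equality.

The package also ships transcriptions of the printed cancer-outcome-associated
(COA) gene tables, the early low-dose gene-function overlap counts, and the
low-dose "thresholded" gene fold-change table, accessible through
:func:`load_fixture_table`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ldsig")

STRAINS = ("sensitive", "resistant")
TISSUES = ("mammary", "blood")
DOSES = ("sham", "LD", "HD", "LD+HD")
TIMES = ("baseline", "early", "late")
CELL_CLASSES = ("RET", "NCE")

META_COLUMNS = ("strain", "tissue", "dose", "time", "replicate")

_FIXTURE_FILES = {
    "table2_baseline_coa": "table2_baseline_coa.tsv",
    "table3_ld1month_coa": "table3_ld1month_coa.tsv",
    "table1_early_ld_overlaps": "table1_early_ld_overlaps.tsv",
    "table4_thresholded": "table4_thresholded.tsv",
}


class ParseError(ValueError):
    """Raised when an input file violates the expected dialect."""


# ---------------------------------------------------------------------------
# container types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """A log2 gene x sample expression matrix with per-sample design factors.

    Parameters
    ----------
    gene_ids
        Unique gene symbols, one per matrix row.
    values
        Real matrix of shape ``(len(gene_ids), n_samples)`` in log2 intensity
        units; all entries must be finite.
    sample_meta
        One row per sample (index = sample id, same order as matrix columns)
        with columns ``strain``, ``tissue``, ``dose``, ``time``,
        ``replicate``.
    """

    gene_ids: list[str]
    values: np.ndarray
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = sorted({g for g in self.gene_ids if self.gene_ids.count(g) > 1})
            raise ValueError(f"duplicate gene symbol(s): {', '.join(dup)}")
        if self.values.ndim != 2 or self.values.shape[0] != len(self.gene_ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} gene ids"
            )
        if self.values.shape[1] != len(self.sample_meta):
            raise ValueError(
                f"matrix has {self.values.shape[1]} columns but metadata has "
                f"{len(self.sample_meta)} rows"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        missing = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing:
            raise ValueError(f"sample metadata missing column(s): {missing}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sample_meta.index)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def select(self, **factors) -> np.ndarray:
        """Boolean sample mask for exact-match factor filters.

        ``study.select(strain="sensitive", dose="LD")`` selects the columns
        whose metadata matches every given factor; a tuple/list/set value
        matches any of its elements.
        """
        mask = np.ones(self.n_samples, dtype=bool)
        for key, val in factors.items():
            if key not in self.sample_meta.columns:
                raise KeyError(f"unknown sample factor {key!r}")
            col = self.sample_meta[key].to_numpy()
            if isinstance(val, (list, tuple, set, frozenset)):
                mask &= np.isin(col, list(val))
            else:
                mask &= col == val
        return mask


@dataclass
class GeneSet:
    """A named gene set, optionally with per-member direction signs."""

    name: str
    members: set[str]
    description: str = ""
    directions: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.members = set(self.members)
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if self.directions is not None:
            extra = set(self.directions) - self.members
            if extra:
                raise ValueError(
                    f"gene set {self.name!r}: directions keyed by non-members {sorted(extra)}"
                )
            bad = {g: s for g, s in self.directions.items() if s not in (-1, 0, 1)}
            if bad:
                raise ValueError(f"gene set {self.name!r}: invalid direction signs {bad}")


@dataclass
class OrthologTable:
    """Mouse symbol -> deduplicated list of human symbols."""

    pairs: dict[str, list[str]]

    def __post_init__(self) -> None:
        clean: dict[str, list[str]] = {}
        for mouse, humans in self.pairs.items():
            if not mouse:
                raise ValueError("empty mouse symbol in ortholog table")
            uniq = list(dict.fromkeys(humans))
            if not all(uniq):
                raise ValueError(f"empty human symbol mapped from {mouse!r}")
            clean[mouse] = uniq
        self.pairs = clean

    def __contains__(self, mouse: str) -> bool:
        return mouse in self.pairs

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class MNRecord:
    """Per-animal micronucleus count for one cell class at one time point."""

    animal_id: str
    strain: str
    dose: str
    time_point: str
    cell_class: str
    cells_scored: int
    mn_cells: int

    def __post_init__(self) -> None:
        if self.cells_scored <= 0:
            raise ValueError(f"{self.animal_id}: cells_scored must be positive")
        if not 0 <= self.mn_cells <= self.cells_scored:
            raise ValueError(
                f"{self.animal_id}: mn_cells {self.mn_cells} outside "
                f"[0, {self.cells_scored}]"
            )
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(f"{self.animal_id}: unknown cell class {self.cell_class!r}")


# ---------------------------------------------------------------------------
# expression study I/O
# ---------------------------------------------------------------------------


def read_expression_study(matrix_path: str | Path, meta_path: str | Path) -> ExpressionStudy:
    """Read a TSV expression matrix plus its sample-metadata table.

    The matrix has a header row of sample ids and a first column of gene
    symbols; the metadata table is keyed by sample id.  Sample order follows
    the matrix header.  Errors name the offending row/column.
    """
    matrix = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype={0: str})
    for col in matrix.columns:
        bad = pd.to_numeric(matrix[col], errors="coerce")
        nan_here = bad.isna() & matrix[col].notna()
        if nan_here.any():
            row = matrix.index[nan_here.to_numpy().nonzero()[0][0]]
            raise ParseError(
                f"non-numeric value in {matrix_path} at gene {row!r}, sample {col!r}"
            )
        matrix[col] = bad
    meta = pd.read_csv(meta_path, sep="\t", index_col=0, dtype=str)
    meta["replicate"] = meta["replicate"].astype(int)
    missing = [s for s in matrix.columns if s not in meta.index]
    if missing:
        raise ParseError(f"missing metadata for sample(s): {missing}")
    meta = meta.loc[list(matrix.columns)]
    return ExpressionStudy(
        gene_ids=list(matrix.index), values=matrix.to_numpy(float), sample_meta=meta
    )


def write_expression_study(
    study: ExpressionStudy, matrix_path: str | Path, meta_path: str | Path
) -> None:
    mat = pd.DataFrame(study.values, index=study.gene_ids, columns=study.sample_ids)
    mat.index.name = "gene"
    mat.to_csv(matrix_path, sep="\t", float_format="%.10g")
    meta = study.sample_meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------


def read_gene_sets(path: str | Path, directed: bool = False) -> list[GeneSet]:
    """Parse a GMT file into gene sets.

    Standard dialect: ``name<TAB>description<TAB>member...``.  With
    ``directed=True``, a trailing ``+`` or ``-`` on each member encodes a
    per-gene direction sign (members without a suffix get ``0``, meaning the
    gene is reported in both directions).
    """
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, desc, *raw_members = fields
            members: list[str] = []
            directions: dict[str, int] = {}
            for tok in raw_members:
                if not tok:
                    continue
                if directed and tok[-1] in "+-":
                    sym, sign = tok[:-1], (1 if tok[-1] == "+" else -1)
                elif directed:
                    sym, sign = tok, 0
                else:
                    sym, sign = tok, None
                members.append(sym)
                if sign is not None:
                    directions[sym] = sign
            sets.append(
                GeneSet(
                    name=name,
                    description=desc,
                    members=set(members),
                    directions=directions if directed else None,
                )
            )
    return sets


def write_gene_sets(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            if gs.directions is not None:
                toks = [
                    f"{g}{'+' if gs.directions.get(g, 0) > 0 else '-' if gs.directions.get(g, 0) < 0 else ''}"
                    for g in sorted(gs.members)
                ]
            else:
                toks = sorted(gs.members)
            fh.write("\t".join([gs.name, gs.description, *toks]) + "\n")


# ---------------------------------------------------------------------------
# ortholog tables
# ---------------------------------------------------------------------------


def read_ortholog_table(path: str | Path) -> OrthologTable:
    """Read a two-column TSV (mouse_symbol, human_symbol); multiple rows per
    mouse symbol are allowed and collected into a deduplicated list."""
    pairs: dict[str, list[str]] = {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: ortholog table needs two columns")
    for mouse, human in zip(df.iloc[:, 0], df.iloc[:, 1]):
        pairs.setdefault(str(mouse), []).append(str(human))
    return OrthologTable(pairs=pairs)


def write_ortholog_table(table: OrthologTable, path: str | Path) -> None:
    rows = [
        {"mouse_symbol": m, "human_symbol": h}
        for m, humans in table.pairs.items()
        for h in humans
    ]
    pd.DataFrame(rows, columns=["mouse_symbol", "human_symbol"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------


def read_cohort(expression_path: str | Path, followup_path: str | Path):
    """Read a patient cohort: gene x patient TSV plus a (time, event) table.

    Returns a :class:`ldsig.survival.SurvivalCohort`.
    """
    from .survival import SurvivalCohort

    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    fu = pd.read_csv(followup_path, sep="\t", index_col=0)
    missing = [p for p in expr.columns if p not in fu.index]
    if missing:
        raise ParseError(f"missing follow-up for patient(s): {missing}")
    fu = fu.loc[list(expr.columns)]
    return SurvivalCohort(
        patient_ids=list(expr.columns),
        gene_ids=list(expr.index),
        expression=expr.to_numpy(float),
        time=fu["time"].to_numpy(float),
        event=fu["event"].to_numpy(int).astype(bool),
    )


def write_cohort(cohort, expression_path: str | Path, followup_path: str | Path) -> None:
    expr = pd.DataFrame(cohort.expression, index=cohort.gene_ids, columns=cohort.patient_ids)
    expr.index.name = "gene"
    expr.to_csv(expression_path, sep="\t", float_format="%.10g")
    fu = pd.DataFrame(
        {"time": cohort.time, "event": cohort.event.astype(int)}, index=cohort.patient_ids
    )
    fu.index.name = "patient_id"
    fu.to_csv(followup_path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# micronucleus count tables
# ---------------------------------------------------------------------------

_MN_COLUMNS = [
    "animal_id",
    "strain",
    "dose",
    "time_point",
    "cell_class",
    "cells_scored",
    "mn_cells",
]


def read_mn_records(path: str | Path) -> list[MNRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MN_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: MN table missing column(s) {missing}")
    return [
        MNRecord(
            animal_id=row.animal_id,
            strain=row.strain,
            dose=row.dose,
            time_point=row.time_point,
            cell_class=row.cell_class,
            cells_scored=int(row.cells_scored),
            mn_cells=int(row.mn_cells),
        )
        for row in df.itertuples()
    ]


def write_mn_records(records: Sequence[MNRecord], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in records], columns=_MN_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# packaged fixtures of the printed tables
# ---------------------------------------------------------------------------


def load_fixture_table(name: str) -> pd.DataFrame:
    """Load one of the packaged printed-table transcriptions.

    Available names: ``table2_baseline_coa`` (55 baseline-signature COA genes,
    57 rows with two genes listed under two categories),
    ``table3_ld1month_coa`` (36 one-month low-dose COA genes),
    ``table1_early_ld_overlaps`` (overlap counts of the 313 early low-dose
    genes with three annotation sets), ``table4_thresholded`` (per-gene
    low/high-dose log2 fold changes for the low-dose "thresholded" genes).
    """
    try:
        fname = _FIXTURE_FILES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURE_FILES)}"
        ) from None
    with resources.files("ldsig.fixtures").joinpath(fname).open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    if name.endswith("_coa"):
        df["lower_in_above_median"] = df["lower_in_above_median"].astype(bool)
        _validate_coa_table(df)
    return df


def _validate_coa_table(df: pd.DataFrame) -> None:
    if not ((df["p_value"] > 0) & (df["p_value"] < 1)).all():
        raise ValueError("COA fixture p-values must lie in (0, 1)")
    flag_counts = df.groupby("gene")["lower_in_above_median"].nunique()
    inconsistent = flag_counts[flag_counts > 1]
    if len(inconsistent):
        raise ValueError(
            f"inconsistent direction flag for gene(s): {list(inconsistent.index)}"
        )


def summarize_coa_fixture(table: pd.DataFrame) -> dict:
    """Summary counts of a COA fixture table.

    Returns ``n_rows``, ``n_unique_genes`` (deduplicated by symbol across
    categories), ``n_inverse_genes`` (unique symbols flagged as expressed at
    lower levels in the above-median patient group), per-category row counts
    (not deduplicated), and ``min_p`` / ``max_p`` over all rows.
    """
    if len(table) == 0:
        raise ValueError("empty COA table")
    per_cat = table["category"].value_counts().to_dict()
    uniq = table.drop_duplicates("gene")
    return {
        "n_rows": int(len(table)),
        "n_unique_genes": int(len(uniq)),
        "n_inverse_genes": int(uniq["lower_in_above_median"].sum()),
        "per_category_row_counts": {k: int(v) for k, v in per_cat.items()},
        "min_p": float(table["p_value"].min()),
        "max_p": float(table["p_value"].max()),
    }
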