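"""Cell-barcode/UMI counting of validated read pairs, stratified by mismatch.

Each surviving pair contributes its corrected cell barcode, UMI, and the
mismatch count of its R2 target hit.  Distinct UMIs are counted per cell at
every mismatch budget 0..M; a (cell, UMI) group's stratum is the minimum
mismatch among its reads, so counts are non-decreasing in the budget.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import scipy.io
import scipy.sparse as sp

from spikecap.design import ReadAnatomy
from spikecap.readproc import ReadPair, ReadRecord

__all__ = [
    "Whitelist",
    "FeatureCountMatrix",
    "GEXMatrix",
    "CountSummary",
    "MTXFormatError",
    "extract_cell_umi",
    "correct_barcode",
    "count_features",
    "write_counts",
    "read_counts",
    "merge_with_gex",
]


class MTXFormatError(ValueError):
    """Malformed MatrixMarket input; message carries the offending line."""


class Whitelist:
    """A set of valid cell barcodes of uniform length with 1-mismatch correction.

    Correction follows the standard droplet convention: an observed barcode is
    kept if it is a member, corrected to a member at Hamming distance 1 when
    that member is unique, and discarded otherwise.
    """

    def __init__(self, barcodes: Iterable[str]):
        ordered: list[str] = []
        seen: set[str] = set()
        for bc in barcodes:
            bc = bc.strip().upper()
            if not bc:
                continue
            if bc in seen:
                raise ValueError(f"duplicate whitelist barcode: {bc}")
            seen.add(bc)
            ordered.append(bc)
        if not ordered:
            raise ValueError("whitelist is empty")
        lengths = {len(bc) for bc in ordered}
        if len(lengths) != 1:
            raise ValueError(f"whitelist barcode lengths differ: {sorted(lengths)}")
        self.barcodes: tuple[str, ...] = tuple(ordered)
        self.barcode_len: int = len(ordered[0])
        self._members = seen
        # neighbor -> member; ambiguous neighbors collapse to None
        self._neighbors: dict[str, Optional[str]] = {}
        for member in ordered:
            for i in range(self.barcode_len):
                for base in "ACGT":
                    if base == member[i]:
                        continue
                    neighbor = member[:i] + base + member[i + 1 :]
                    if neighbor in self._neighbors:
                        self._neighbors[neighbor] = None
                    else:
                        self._neighbors[neighbor] = member

    def __len__(self) -> int:
        return len(self.barcodes)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self._members

    def correct(self, raw: str) -> Optional[str]:
        """Exact member, unique 1-mismatch member, or ``None``."""
        if len(raw) != self.barcode_len:
            raise ValueError(
                f"barcode length {len(raw)} != whitelist length {self.barcode_len}"
            )
        if raw in self._members:
            return raw
        return self._neighbors.get(raw)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "Whitelist":
        with open(path) as handle:
            return cls(line for line in handle)

    def to_file(self, path: Union[str, Path]) -> None:
        with open(path, "w") as handle:
            for bc in self.barcodes:
                handle.write(bc + "\n")


def correct_barcode(raw: str, whitelist: Whitelist) -> Optional[str]:
    """Functional alias for :meth:`Whitelist.correct`."""
    return whitelist.correct(raw)


def extract_cell_umi(r1: ReadRecord, anatomy: ReadAnatomy) -> Optional[tuple[str, str]]:
    """Cell barcode and UMI from the R1 prefix, or ``None`` if too short."""
    need = anatomy.cell_barcode_len + anatomy.umi_len
    if len(r1) < need:
        return None
    return (
        r1.seq[: anatomy.cell_barcode_len],
        r1.seq[anatomy.cell_barcode_len : need],
    )


@dataclass
class CountSummary:
    """Conservation bookkeeping: pairs in = counted + discarded + skipped."""

    pairs_in: int = 0
    pairs_counted: int = 0
    pairs_barcode_discarded: int = 0
    pairs_skipped_short: int = 0

    def as_dict(self) -> dict:
        return {
            "pairs_in": self.pairs_in,
            "pairs_counted": self.pairs_counted,
            "pairs_barcode_discarded": self.pairs_barcode_discarded,
            "pairs_skipped_short": self.pairs_skipped_short,
        }


@dataclass
class FeatureCountMatrix:
    """Per-cell distinct-UMI counts of one target at mismatch budgets 0..M.

    ``counts_by_budget[m, c]`` counts UMIs in cell ``c`` whose best read hit
    has at most ``m`` mismatches (cumulative, hence monotone in ``m``).
    """

    feature_name: str
    cells: tuple[str, ...]
    counts_by_budget: np.ndarray  # shape (max_budget + 1, n_cells), int

    def __post_init__(self) -> None:
        self.counts_by_budget = np.asarray(self.counts_by_budget, dtype=np.int64)
        if self.counts_by_budget.ndim != 2:
            raise ValueError("counts_by_budget must be 2-D (budgets x cells)")
        if self.counts_by_budget.shape[1] != len(self.cells):
            raise ValueError("counts_by_budget width != number of cells")
        if (self.counts_by_budget < 0).any():
            raise ValueError("negative counts")
        if (np.diff(self.counts_by_budget, axis=0) < 0).any():
            raise ValueError("counts not monotone in mismatch budget")

    @property
    def max_budget(self) -> int:
        return self.counts_by_budget.shape[0] - 1

    def counts_at(self, budget: int) -> np.ndarray:
        if not 0 <= budget <= self.max_budget:
            raise ValueError(f"budget {budget} not in [0, {self.max_budget}]")
        return self.counts_by_budget[budget]

    def stratum_names(self) -> list[str]:
        names = [f"{self.feature_name}_pm"]
        names += [f"{self.feature_name}_mm{m}" for m in range(1, self.max_budget + 1)]
        return names


def count_features(
    pairs: Iterable[tuple[ReadPair, int]],
    anatomy: ReadAnatomy,
    whitelist: Optional[Whitelist],
    max_budget: int = 5,
    summary: Optional[CountSummary] = None,
    feature_name: str = "target",
) -> FeatureCountMatrix:
    """Count distinct UMIs per corrected cell at each budget 0..``max_budget``.

    ``pairs`` yields ``(pair, mismatches)`` where ``mismatches`` is the R2
    target-hit mismatch count.  Duplicated reads of a (cell, UMI) molecule
    collapse to one count; the group keeps its minimum mismatch (best
    evidence).  With ``whitelist=None`` every observed barcode is its own
    cell (test-only mode, no correction).
    """
    if max_budget < 0:
        raise ValueError("max_budget must be >= 0")
    best_mm: dict[tuple[str, str], int] = {}
    for pair, mismatches in pairs:
        if summary is not None:
            summary.pairs_in += 1
        extracted = extract_cell_umi(pair.r1, anatomy)
        if extracted is None:
            if summary is not None:
                summary.pairs_skipped_short += 1
            continue
        raw_cb, umi = extracted
        if whitelist is not None:
            cell = whitelist.correct(raw_cb)
            if cell is None:
                if summary is not None:
                    summary.pairs_barcode_discarded += 1
                continue
        else:
            cell = raw_cb
        if summary is not None:
            summary.pairs_counted += 1
        key = (cell, umi)
        mm = int(mismatches)
        if key not in best_mm or mm < best_mm[key]:
            best_mm[key] = mm

    cells = tuple(sorted({cell for cell, _ in best_mm}))
    index = {cell: i for i, cell in enumerate(cells)}
    counts = np.zeros((max_budget + 1, len(cells)), dtype=np.int64)
    for (cell, _umi), mm in best_mm.items():
        if mm <= max_budget:
            counts[mm:, index[cell]] += 1
    return FeatureCountMatrix(
        feature_name=feature_name, cells=cells, counts_by_budget=counts
    )


@dataclass
class GEXMatrix:
    """Sparse features x cells unique-molecule count matrix with sidecars."""

    features: tuple[str, ...]
    barcodes: tuple[str, ...]
    matrix: sp.csr_matrix  # features x cells

    def __post_init__(self) -> None:
        self.features = tuple(self.features)
        self.barcodes = tuple(self.barcodes)
        self.matrix = sp.csr_matrix(self.matrix)
        if self.matrix.shape != (len(self.features), len(self.barcodes)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with "
                f"{len(self.features)} features x {len(self.barcodes)} barcodes"
            )
        if self.matrix.nnz and self.matrix.data.min() < 0:
            raise ValueError("negative matrix entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.matrix.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.matrix > 0).sum(axis=0)).ravel()

    def mito_fraction(self, prefix: str = "MT-") -> Optional[np.ndarray]:
        """Per-cell mitochondrial fraction, or ``None`` if no feature matches."""
        mask = np.array([f.startswith(prefix) for f in self.features])
        if not mask.any():
            return None
        totals = self.cell_totals().astype(float)
        mito = np.asarray(self.matrix[mask].sum(axis=0)).ravel().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito / np.maximum(totals, 1e-300), 0.0)
        return frac

    def subset_cells(self, keep: np.ndarray) -> "GEXMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        return GEXMatrix(
            features=self.features,
            barcodes=tuple(self.barcodes[i] for i in idx),
            matrix=self.matrix[:, idx],
        )


# ---------------------------------------------------------------------------
# MatrixMarket I/O (CellRanger-style directory: matrix.mtx + sidecars)
# ---------------------------------------------------------------------------

def write_gex(gex: GEXMatrix, outdir: Union[str, Path]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(outdir / "matrix.mtx"), sp.coo_matrix(gex.matrix), field="integer"
    )
    (outdir / "barcodes.tsv").write_text("".join(b + "\n" for b in gex.barcodes))
    (outdir / "features.tsv").write_text("".join(f + "\n" for f in gex.features))


def read_gex(indir: Union[str, Path]) -> GEXMatrix:
    indir = Path(indir)
    mtx_path = indir / "matrix.mtx"
    with open(mtx_path) as handle:
        first = handle.readline()
    if not first.startswith("%%MatrixMarket"):
        raise MTXFormatError(
            f"{mtx_path}: line 1: expected '%%MatrixMarket' header, got {first.strip()!r}"
        )
    try:
        matrix = sp.csr_matrix(scipy.io.mmread(str(mtx_path)))
    except ValueError as exc:
        raise MTXFormatError(f"{mtx_path}: {exc}") from exc
    barcodes = (indir / "barcodes.tsv").read_text().split()
    features = (indir / "features.tsv").read_text().split()
    if matrix.shape != (len(features), len(barcodes)):
        raise MTXFormatError(
            f"{mtx_path}: matrix is {matrix.shape} but sidecars give "
            f"{len(features)} features x {len(barcodes)} barcodes"
        )
    return GEXMatrix(features=tuple(features), barcodes=tuple(barcodes), matrix=matrix)


def write_counts(matrix: FeatureCountMatrix, outdir: Union[str, Path]) -> None:
    """Write one feature row per budget stratum (``<name>_pm``, ``<name>_mm1``…).

    Rows hold the cumulative counts at each budget, so the raw MTX preserves
    the full stratification and round-trips losslessly.
    """
    gex = GEXMatrix(
        features=tuple(matrix.stratum_names()),
        barcodes=matrix.cells,
        matrix=sp.csr_matrix(matrix.counts_by_budget),
    )
    write_gex(gex, outdir)


def read_counts(indir: Union[str, Path], feature_name: Optional[str] = None) -> FeatureCountMatrix:
    gex = read_gex(indir)
    if feature_name is None:
        if not gex.features or not gex.features[0].endswith("_pm"):
            raise MTXFormatError(
                f"{indir}: first feature {gex.features[:1]} is not a '_pm' stratum"
            )
        feature_name = gex.features[0][: -len("_pm")]
    return FeatureCountMatrix(
        feature_name=feature_name,
        cells=gex.barcodes,
        counts_by_budget=np.asarray(gex.matrix.todense()),
    )


def merge_with_gex(
    gex: GEXMatrix, fc: FeatureCountMatrix, budget: int = 1
) -> GEXMatrix:
    """Append the target's budget-``budget`` counts as one feature row.

    Rows are aligned on the GEX barcode order; cells absent from ``fc`` get 0.
    Zero barcode overlap is a hard error (it suggests a whitelist mismatch).
    """
    counts = fc.counts_at(budget)
    fc_index = {cell: i for i, cell in enumerate(fc.cells)}
    overlap = sum(1 for bc in gex.barcodes if bc in fc_index)
    if overlap == 0:
        raise ValueError(
            "no barcode overlap between gene-expression matrix and feature "
            "counts; check that both used the same whitelist"
        )
    row = np.zeros(len(gex.barcodes), dtype=np.int64)
    for j, bc in enumerate(gex.barcodes):
        i = fc_index.get(bc)
        if i is not None:
            row[j] = counts[i]
    stacked = sp.vstack([gex.matrix, sp.csr_matrix(row)])
    return GEXMatrix(
        features=gex.features + (fc.feature_name,),
        barcodes=gex.barcodes,
        matrix=stacked,
    )
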