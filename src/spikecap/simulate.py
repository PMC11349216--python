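"""Ground-truth read simulator for the spike-in capture pipeline.

Generates paired 5' reads with the statistical structure the method assumes:
three cell populations with high / low / zero target expression, a dominant
non-specific-priming read class carrying the feature barcode but a random
insert, PCR duplicates, and i.i.d. substitution errors.  Every run emits a
per-cell and per-read truth ledger so downstream modules can be scored
without any external data.

Read layout (true capture):
    R1 = cell barcode + UMI + TSO + sense target prefix (to read length)
    R2 = spacer1 + feature barcode + spacer2 + antisense target (the library
         bottom strand read from just after the Read2N adaptor)
Non-specific pairs keep the same layout with the target segments replaced by
random sequence (optionally by a mutated "homolog" copy of the target).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from spikecap.design import GSPDesign, ReadAnatomy, TargetGene, reverse_complement
from spikecap.quant import FeatureCountMatrix, Whitelist
from spikecap.readproc import ReadRecord, write_fastq

__all__ = [
    "SimConfig",
    "SimGroundTruth",
    "SimResult",
    "simulate_run",
    "simulate_gex",
    "evaluate_counts",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

POPULATIONS = ("high", "low", "zero")


@dataclass(frozen=True)
class SimConfig:
    """Simulation knobs.

    ``population_means`` are emulation constants for the high/low/zero
    expression populations (the zero mean is forced to 0); they are not
    measured values.  ``nonspecific_fraction`` is the fraction of oligo-tag
    read pairs whose insert is unrelated to the target.
    """

    n_cells_per_population: Union[int, tuple[int, int, int]] = 50
    population_means: tuple[float, float, float] = (20.0, 4.0, 0.0)
    nonspecific_fraction: float = 0.99
    reads_per_molecule: float = 3.0
    error_rate: float = 0.0
    read_len: int = 100
    seed: int = 0
    homolog_mode: bool = False
    homolog_mismatches: tuple[int, int] = (3, 8)
    overdispersion: Optional[float] = None  # neg-binomial shape; None = Poisson

    def __post_init__(self) -> None:
        if not 0.0 <= self.nonspecific_fraction < 1.0:
            raise ValueError("nonspecific_fraction must be in [0, 1)")
        if any(m < 0 for m in self.population_means[:2]):
            raise ValueError("population means must be >= 0")
        if self.population_means[2] != 0.0:
            raise ValueError("zero-population mean must be 0")
        if self.reads_per_molecule < 1.0:
            raise ValueError("reads_per_molecule must be >= 1")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")

    @property
    def cells_per_population(self) -> tuple[int, int, int]:
        n = self.n_cells_per_population
        if isinstance(n, int):
            return (n, n, n)
        return tuple(int(x) for x in n)  # type: ignore[return-value]


@dataclass
class SimGroundTruth:
    """Truth ledger: one row per cell and one row per read."""

    cells: pd.DataFrame  # barcode, population, true_molecules
    reads: pd.DataFrame  # read_id, read_class, cell_barcode, umi, r1_errors, r2_errors

    def true_counts(self) -> pd.Series:
        """Per-cell true molecule count indexed by barcode."""
        return self.cells.set_index("barcode")["true_molecules"]

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
        self.reads.to_csv(outdir / "truth_reads.tsv", sep="\t", index=False)


@dataclass
class SimResult:
    r1: list[ReadRecord]
    r2: list[ReadRecord]
    truth: SimGroundTruth
    whitelist: Whitelist

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fastq(self.r1, outdir / "sim_R1.fastq")
        write_fastq(self.r2, outdir / "sim_R2.fastq")
        self.whitelist.to_file(outdir / "whitelist.txt")
        self.truth.write(outdir)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _distinct_barcodes(rng: np.random.Generator, n: int, length: int) -> list[str]:
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        bc = _random_seq(rng, length)
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def _inject_errors(rng: np.random.Generator, seq: str, error_rate: float) -> tuple[str, int]:
    """Substitute each base independently with probability ``error_rate``."""
    if error_rate <= 0.0:
        return seq, 0
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < error_rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii"), int(hits.size)


def _mutate(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    """Plant exactly ``n_mut`` substitutions at distinct positions."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    for i in rng.choice(arr.size, size=min(n_mut, arr.size), replace=False):
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def _molecule_counts(
    rng: np.random.Generator, cfg: SimConfig, mean: float, n_cells: int
) -> np.ndarray:
    if mean == 0.0:
        return np.zeros(n_cells, dtype=np.int64)
    if cfg.overdispersion is not None:
        shape = cfg.overdispersion
        lam = rng.gamma(shape, mean / shape, size=n_cells)
        return rng.poisson(lam)
    return rng.poisson(mean, size=n_cells)


def simulate_run(
    cfg: SimConfig,
    design: GSPDesign,
    target: TargetGene,
    anatomy: ReadAnatomy,
) -> SimResult:
    """Generate a full paired-read run plus its ground truth.

    Deterministic under a fixed ``cfg.seed`` (byte-identical FASTQ output).
    """
    if design.anchor_interval is None:
        raise ValueError("design must be located on the target (anchor_interval)")
    offset = anatomy.r1_insert_offset
    if cfg.read_len < offset + 1:
        raise ValueError(
            f"read_len {cfg.read_len} too short for anatomy prefix of {offset} nt"
        )
    rng = np.random.default_rng(cfg.seed)
    anchor_end = design.anchor_interval[1]
    r1_insert_full = target.sequence[: cfg.read_len - offset]
    r2_antisense_full = reverse_complement(target.sequence[:anchor_end])

    n_by_pop = cfg.cells_per_population
    n_cells = sum(n_by_pop)
    barcodes = _distinct_barcodes(rng, n_cells, anatomy.cell_barcode_len)
    populations = [
        pop for pop, n in zip(POPULATIONS, n_by_pop) for _ in range(n)
    ]

    # Plan true molecules per cell.
    molecules: list[tuple[int, str]] = []  # (cell index, umi)
    cell_mols = np.concatenate(
        [
            _molecule_counts(rng, cfg, mean, n)
            for mean, n in zip(cfg.population_means, n_by_pop)
        ]
    )
    for ci in range(n_cells):
        for _ in range(int(cell_mols[ci])):
            molecules.append((ci, _random_seq(rng, anatomy.umi_len)))

    true_umis_per_cell = [set() for _ in range(n_cells)]
    for ci, umi in molecules:
        true_umis_per_cell[ci].add(umi)

    # Build reads molecule by molecule, then add non-specific pairs.
    planned: list[tuple[str, int, str, str, str]] = []
    # (read_class, cell index, umi, r1_insert, r2_insert)
    for ci, umi in molecules:
        spacer1 = _random_seq(rng, design.spacer1_len)
        spacer2 = _random_seq(rng, design.spacer2_len)
        r2_payload = spacer1 + design.feature_barcode + spacer2 + r2_antisense_full
        n_reads = 1 + rng.poisson(cfg.reads_per_molecule - 1.0)
        for _ in range(int(n_reads)):
            planned.append(("true_capture", ci, umi, r1_insert_full, r2_payload))

    n_true = len(planned)
    f = cfg.nonspecific_fraction
    n_nonspecific = int(round(n_true * f / (1.0 - f))) if f > 0 else 0
    if n_true == 0 and f > 0:
        # Still emit a contaminant-only run sized by the cell count.
        n_nonspecific = 100 * n_cells
    insert_len = cfg.read_len - offset
    for _ in range(n_nonspecific):
        ci = int(rng.integers(n_cells))
        umi = _random_seq(rng, anatomy.umi_len)
        spacer1 = _random_seq(rng, design.spacer1_len)
        spacer2 = _random_seq(rng, design.spacer2_len)
        if cfg.homolog_mode:
            lo, hi = cfg.homolog_mismatches
            k = int(rng.integers(lo, hi + 1))
            r1_ins = _mutate(rng, r1_insert_full, k)
            r2_ins = _mutate(rng, r2_antisense_full, k)
        else:
            r1_ins = _random_seq(rng, insert_len)
            r2_ins = _random_seq(rng, len(r2_antisense_full))
        r2_payload = spacer1 + design.feature_barcode + spacer2 + r2_ins
        planned.append(("nonspecific", ci, umi, r1_ins, r2_payload))

    order = rng.permutation(len(planned))
    r1_records: list[ReadRecord] = []
    r2_records: list[ReadRecord] = []
    read_rows: list[dict] = []
    for out_idx, src_idx in enumerate(order):
        read_class, ci, umi, r1_ins, r2_payload = planned[src_idx]
        read_id = f"sim:{out_idx:07d}"
        r1_seq = (barcodes[ci] + umi + anatomy.tso + r1_ins)[: cfg.read_len]
        r2_seq = r2_payload[: cfg.read_len]
        r1_seq, r1_err = _inject_errors(rng, r1_seq, cfg.error_rate)
        r2_seq, r2_err = _inject_errors(rng, r2_seq, cfg.error_rate)
        r1_records.append(ReadRecord(read_id, r1_seq, "I" * len(r1_seq)))
        r2_records.append(ReadRecord(read_id, r2_seq, "I" * len(r2_seq)))
        read_rows.append(
            {
                "read_id": read_id,
                "read_class": read_class,
                "cell_barcode": barcodes[ci],
                "umi": umi,
                "r1_errors": r1_err,
                "r2_errors": r2_err,
            }
        )

    cells = pd.DataFrame(
        {
            "barcode": barcodes,
            "population": populations,
            "true_molecules": [len(s) for s in true_umis_per_cell],
        }
    )
    truth = SimGroundTruth(cells=cells, reads=pd.DataFrame(read_rows))
    return SimResult(
        r1=r1_records,
        r2=r2_records,
        truth=truth,
        whitelist=Whitelist(barcodes),
    )


def simulate_gex(
    barcodes: Sequence[str],
    n_genes: int = 60,
    n_mito_genes: int = 5,
    mean_total: float = 5000.0,
    seed: int = 0,
):
    """A small companion gene-expression matrix for integration tests.

    Gene means are log-normal; per-cell counts are Poisson.  A handful of
    ``MT-`` prefixed genes provide a mitochondrial fraction.  This is a test
    scaffold, not a transcriptome model.
    """
    from spikecap.quant import GEXMatrix
    import scipy.sparse as sp

    rng = np.random.default_rng(seed)
    names = [f"GENE{i:03d}" for i in range(n_genes - n_mito_genes)] + [
        f"MT-G{i}" for i in range(n_mito_genes)
    ]
    weights = rng.lognormal(0.0, 1.0, size=n_genes)
    weights /= weights.sum()
    counts = rng.poisson(
        np.outer(weights, np.full(len(barcodes), mean_total))
    ).astype(np.int64)
    return GEXMatrix(
        features=tuple(names),
        barcodes=tuple(barcodes),
        matrix=sp.csr_matrix(counts),
    )


def evaluate_counts(
    truth: SimGroundTruth, fc: FeatureCountMatrix, budget: int = 1
) -> dict:
    """Score recovered counts against the truth ledger.

    Returns per-population mean recovered counts, mean absolute per-cell
    error, Spearman correlation between recovered and true molecule counts
    over all cells, and false positives in the zero population.
    """
    from scipy.stats import spearmanr

    recovered_by_cell = dict(zip(fc.cells, fc.counts_at(budget)))
    cells = truth.cells
    recovered = np.array(
        [recovered_by_cell.get(bc, 0) for bc in cells["barcode"]], dtype=float
    )
    true = cells["true_molecules"].to_numpy(dtype=float)

    metrics: dict = {"budget": budget}
    for pop in POPULATIONS:
        mask = (cells["population"] == pop).to_numpy()
        metrics[f"mean_recovered_{pop}"] = (
            float(recovered[mask].mean()) if mask.any() else float("nan")
        )
    metrics["mean_abs_error"] = float(np.abs(recovered - true).mean())
    if np.ptp(true) > 0 and np.ptp(recovered) > 0:
        rho = float(spearmanr(recovered, true).statistic)
    elif np.array_equal(true, recovered):
        rho = 1.0
    else:
        rho = float("nan")
    metrics["spearman"] = rho
    zero_mask = (cells["population"] == "zero").to_numpy()
    metrics["zero_population_false_positives"] = int((recovered[zero_mask] > 0).sum())
    return metrics
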