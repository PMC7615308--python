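"""Simulation of genotype-determined junction-spanning reads.

Each simulated cell draws a Poisson read count whose mean is the requested
``depth`` scaled by the genotype's total isoform output relative to a
two-allele wild-type reference. Each read then picks an isoform with the
genotype's expected -KTS fraction and becomes a splice-gapped alignment
whose gap sits exactly on the corresponding donor/acceptor pair. An
optional error channel perturbs the donor-side gap coordinate by 1-3 nt,
yielding reads the classifier must reject as ambiguous.

Randomness derives from a single top-level seed; one child stream is
spawned per cell (via ``numpy`` seed sequences), so output is bit-identical
for identical arguments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignio import AlignedReadRecord
from .genotypes import GenotypeModel
from .junctions import Call, JunctionSpec

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulatedCellTruth:
    """Ground truth for one simulated cell."""

    cell_id: str
    genotype: str
    true_minus_fraction: float
    n_reads: int
    n_plus: int
    n_minus: int


def _random_barcode(rng: np.random.Generator, k: int = 12) -> str:
    return "".join(rng.choice(_BASES, size=k))


def _junction_read(
    spec: JunctionSpec,
    isoform: Call,
    left_anchor: int,
    right_anchor: int,
    shift: int,
) -> tuple[int, tuple[tuple[str, int], ...]]:
    """Genomic start and blocks of one junction read; ``shift`` perturbs the
    donor-side gap edge (error model)."""
    gstart, gend = spec.gap_interval(isoform)
    if spec.strand == "+":
        gstart += shift
    else:
        gend += shift
    start = gstart - left_anchor
    blocks = (("M", left_anchor), ("N", gend - gstart), ("M", right_anchor))
    return start, blocks


def simulate_cells(
    model: GenotypeModel,
    n_cells: int,
    depth: float = 50.0,
    error_rate: float = 0.0,
    spec: JunctionSpec | None = None,
    seed: int = 0,
    with_umi: bool = True,
    anchor_range: tuple[int, int] = (10, 30),
) -> tuple[list[AlignedReadRecord], pd.DataFrame]:
    """Simulate per-cell junction reads for one genotype.

    Parameters
    ----------
    model:
        Genotype with per-allele isoform output rates.
    n_cells:
        Number of cells (>= 1).
    depth:
        Expected junction reads per cell for a two-WT-allele reference
        genotype with unit budgets; the actual per-cell mean is scaled by
        the genotype's total output.
    error_rate:
        Per-read probability (< 0.5) that the donor-side gap coordinate is
        perturbed by +-1..3 nt, making the read uninformative downstream.
    anchor_range:
        Inclusive range of simulated anchor lengths on each side of the
        gap; the lower bound must be >= ``spec.min_anchor`` so error-free
        reads always pass the anchor filter.

    Returns
    -------
    (records, truth):
        Alignment records and a per-cell truth table (one row per cell,
        including cells that drew zero reads).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    spec = spec or JunctionSpec()
    if anchor_range[0] < spec.min_anchor:
        raise ValueError(
            f"anchor_range lower bound {anchor_range[0]} is below "
            f"spec.min_anchor {spec.min_anchor}"
        )

    rate_plus, rate_minus = model.emission_rates()
    total = rate_plus + rate_minus
    if total == 0.0:
        warnings.warn(
            f"genotype {model.name} has no expression; simulating zero reads",
            stacklevel=2,
        )
    lam = depth * total / 2.0  # two unit-budget WT alleles define depth
    minus_frac = model.minus_fraction

    root = np.random.SeedSequence(seed)
    cell_seeds = root.spawn(n_cells)
    records: list[AlignedReadRecord] = []
    truth_rows = []
    seen_barcodes: set[str] = set()
    for i, ss in enumerate(cell_seeds):
        rng = np.random.default_rng(ss)
        barcode = _random_barcode(rng)
        while barcode in seen_barcodes:  # vanishingly rare at 12 nt
            barcode = _random_barcode(rng)
        seen_barcodes.add(barcode)
        n = int(rng.poisson(lam)) if lam > 0 else 0
        n_minus = int(rng.binomial(n, minus_frac)) if n else 0
        isoforms = np.array(
            [Call.MINUS_KTS] * n_minus + [Call.PLUS_KTS] * (n - n_minus), dtype=object
        )
        rng.shuffle(isoforms)
        for j, iso in enumerate(isoforms):
            left, right = rng.integers(anchor_range[0], anchor_range[1] + 1, size=2)
            shift = 0
            if error_rate > 0 and rng.random() < error_rate:
                shift = int(rng.choice([-3, -2, -1, 1, 2, 3]))
            start, blocks = _junction_read(spec, iso, int(left), int(right), shift)
            records.append(
                AlignedReadRecord(
                    read_id=f"{barcode}:{j:06d}",
                    cell=barcode,
                    umi="".join(rng.choice(_BASES, size=10)) if with_umi else None,
                    chrom=spec.chrom,
                    strand=spec.strand,
                    start=start,
                    blocks=blocks,
                    mapq=60,
                )
            )
        truth_rows.append(
            {
                "cell": barcode,
                "genotype": model.name,
                "true_minus_fraction": minus_frac if total > 0 else np.nan,
                "n_reads": n,
                "n_plus": n - n_minus,
                "n_minus": n_minus,
            }
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["cell", "genotype", "true_minus_fraction", "n_reads", "n_plus", "n_minus"],
    )
    return records, truth


def simulate_population(
    groups: dict[str, tuple[GenotypeModel, int]],
    depth: float = 50.0,
    error_rate: float = 0.0,
    spec: JunctionSpec | None = None,
    seed: int = 0,
    with_umi: bool = True,
) -> tuple[list[AlignedReadRecord], pd.DataFrame]:
    """Simulate several genotype groups into one pooled read set.

    ``groups`` maps a group label to ``(model, n_cells)``; the truth table
    gains a ``group`` column. Each group gets an independent child stream
    of ``seed``.
    """
    root = np.random.SeedSequence(seed)
    child = {name: s for name, s in zip(sorted(groups), root.spawn(len(groups)))}
    records: list[AlignedReadRecord] = []
    tables = []
    for name in groups:  # preserve caller ordering
        model, n_cells = groups[name]
        sub_seed = int(child[name].generate_state(1)[0] % (2**31))
        recs, truth = simulate_cells(
            model, n_cells, depth, error_rate, spec, seed=sub_seed, with_umi=with_umi
        )
        truth.insert(0, "group", name)
        records.extend(recs)
        tables.append(truth)
    return records, pd.concat(tables, ignore_index=True)
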