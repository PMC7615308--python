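"""Classification of junction-spanning reads at the Wt1 exon-9 donors and
per-cell isoform quantification.

The canonical exon-9 donor produces -KTS transcripts; an alternative donor
9 nt further into the intron (in transcription direction) appends the nine
coding nucleotides of the KTS tripeptide, producing +KTS transcripts. Both
junctions share the exon-10 acceptor, so a splice-gapped read pinpoints the
isoform by the donor-side coordinate of its gap.

Coordinates are 0-based half-open throughout; a splice gap is the interval
``[first intronic base, first exonic base after the intron)`` in genomic
order. On the minus strand the donor lies at the genomically-high end of the
intron and the +KTS donor sits ``alt_offset`` nt *left* of the canonical
one; :class:`JunctionSpec` handles both orientations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .alignio import AlignedReadRecord


class Call(str, Enum):
    """Per-read isoform call."""

    PLUS_KTS = "PLUS_KTS"
    MINUS_KTS = "MINUS_KTS"
    AMBIGUOUS = "AMBIGUOUS"
    NON_JUNCTION = "NON_JUNCTION"


@dataclass(frozen=True)
class JunctionSpec:
    """Genomic definition of the -KTS/+KTS donor pair and shared acceptor.

    Parameters
    ----------
    donor_minus:
        0-based genomic coordinate of the first intronic base of the
        canonical (-KTS) junction.
    alt_offset:
        Length in nt of the donor extension producing +KTS (9 nt = the KTS
        tripeptide).
    acceptor:
        0-based genomic coordinate of the first base of exon 10 (first base
        in transcription direction; on the minus strand this is the
        genomically-highest exon-10 base).
    min_anchor, min_mapq:
        Read filters: minimum aligned bases on each side of the gap and
        minimum mapping quality for an informative call.
    allow_contiguous_plus:
        When true, an ungapped read whose aligned span covers the whole
        9-nt extension counts as +KTS evidence. Off by default: such reads
        cannot exclude an unspliced (intronic) origin.
    """

    gene_id: str = "Wt1"
    chrom: str = "chr2"
    strand: str = "+"
    donor_minus: int = 1000
    alt_offset: int = 9
    acceptor: int = 2000
    min_anchor: int = 6
    min_mapq: int = 20
    allow_contiguous_plus: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.alt_offset <= 0:
            raise ValueError("alt_offset must be > 0")
        if self.min_anchor < 1:
            raise ValueError("min_anchor must be >= 1")
        if self.strand == "+" and not self.donor_minus + self.alt_offset < self.acceptor:
            raise ValueError("on + strand need donor_minus + alt_offset < acceptor")
        if self.strand == "-" and not self.donor_minus - self.alt_offset > self.acceptor:
            raise ValueError("on - strand need donor_minus - alt_offset > acceptor")

    # -- gap geometry ---------------------------------------------------------

    def gap_interval(self, isoform: str) -> tuple[int, int]:
        """Genomic half-open interval of the splice gap for ``"MINUS_KTS"``
        or ``"PLUS_KTS"``."""
        if isoform == Call.MINUS_KTS or isoform == "MINUS_KTS":
            donor = self.donor_minus
        elif isoform == Call.PLUS_KTS or isoform == "PLUS_KTS":
            donor = (
                self.donor_minus + self.alt_offset
                if self.strand == "+"
                else self.donor_minus - self.alt_offset
            )
        else:
            raise ValueError(f"no gap interval for {isoform!r}")
        if self.strand == "+":
            return donor, self.acceptor
        # minus strand: intron runs genomically from just after the acceptor
        # up to and including the donor base
        return self.acceptor + 1, donor + 1

    def _acceptor_edge_matches(self, gstart: int, gend: int) -> bool:
        if self.strand == "+":
            return gend == self.acceptor
        return gstart == self.acceptor + 1

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "chrom": self.chrom,
            "strand": self.strand,
            "donor_minus": self.donor_minus,
            "alt_offset": self.alt_offset,
            "acceptor": self.acceptor,
            "min_anchor": self.min_anchor,
            "min_mapq": self.min_mapq,
            "allow_contiguous_plus": self.allow_contiguous_plus,
        }

    @classmethod
    def from_json(cls, source) -> "JunctionSpec":
        if isinstance(source, dict):
            d = source
        elif hasattr(source, "read"):
            d = json.load(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        return cls(**d)


@dataclass(frozen=True)
class IsoformCall:
    """One read's isoform call, with the cell/UMI context needed for
    counting."""

    read_id: str
    cell: str
    call: Call
    umi: str | None = None


def classify_read(r: AlignedReadRecord, spec: JunctionSpec) -> Call:
    """Classify one alignment against the donor pair.

    A read is informative (PLUS_KTS or MINUS_KTS) iff it carries exactly one
    splice gap whose acceptor edge matches exon 10 and whose donor edge
    matches the corresponding donor, with both flanking anchors >=
    ``min_anchor`` and mapq >= ``min_mapq``. A gap reaching the acceptor
    from any other donor-side coordinate — or an informative gap failing the
    anchor/mapq filters — is AMBIGUOUS. Everything else (wrong chromosome,
    no gap, gaps not touching the acceptor) is NON_JUNCTION.
    """
    if r.chrom != spec.chrom:
        return Call.NON_JUNCTION

    gaps = r.gaps()
    if not gaps:
        if spec.allow_contiguous_plus:
            # the 9-nt extension, inclusive genomic bounds
            if spec.strand == "+":
                ext_lo, ext_hi = spec.donor_minus, spec.donor_minus + spec.alt_offset - 1
            else:
                ext_lo, ext_hi = spec.donor_minus - spec.alt_offset + 1, spec.donor_minus
            if r.start <= ext_lo and r.end > ext_hi and r.mapq >= spec.min_mapq:
                return Call.PLUS_KTS
        return Call.NON_JUNCTION

    at_acceptor = [g for g in gaps if spec._acceptor_edge_matches(g[0], g[1])]
    if len(at_acceptor) != 1:
        # no acceptor-anchored gap, or more than one (implausible structure);
        # multi-gap reads are evaluated only through their acceptor gap
        return Call.NON_JUNCTION

    gstart, gend, left, right = at_acceptor[0]
    minus_gap = spec.gap_interval(Call.MINUS_KTS)
    plus_gap = spec.gap_interval(Call.PLUS_KTS)
    if (gstart, gend) == minus_gap:
        candidate = Call.MINUS_KTS
    elif (gstart, gend) == plus_gap:
        candidate = Call.PLUS_KTS
    else:
        return Call.AMBIGUOUS  # reaches the acceptor from an unexpected donor
    if left < spec.min_anchor or right < spec.min_anchor or r.mapq < spec.min_mapq:
        return Call.AMBIGUOUS
    return candidate


def classify_reads(
    records: list[AlignedReadRecord], spec: JunctionSpec
) -> list[IsoformCall]:
    """Classify a batch of alignments, carrying cell and UMI through."""
    return [
        IsoformCall(r.read_id, r.cell, classify_read(r, spec), r.umi) for r in records
    ]


COUNT_COLUMNS = ["cell", "n_plus", "n_minus", "n_ambiguous"]


def count_cells(
    calls: list[IsoformCall],
    dedup_umi: bool = True,
    cell_labels: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Tally informative units per cell barcode.

    NON_JUNCTION calls never count. With ``dedup_umi`` on, reads sharing a
    (cell, UMI) pair collapse to a single unit whose call is the majority
    call among them (ties -> AMBIGUOUS); reads without a UMI each count as
    their own unit. ``cell_labels`` (indexed or keyed by ``cell``) is merged
    onto the output when given; labelled cells with no junction reads appear
    with zero counts.
    """
    units: dict[str, dict[Call, int]] = {}

    def bump(cell: str, call: Call) -> None:
        units.setdefault(cell, {c: 0 for c in Call})[call] += 1

    if dedup_umi:
        grouped: dict[tuple[str, str], list[Call]] = {}
        for c in calls:
            if c.call is Call.NON_JUNCTION:
                continue
            if c.umi is None:
                bump(c.cell, c.call)
            else:
                grouped.setdefault((c.cell, c.umi), []).append(c.call)
        for (cell, _), members in grouped.items():
            counts = pd.Series(members).value_counts()
            top = counts.max()
            winners = [c for c in counts.index if counts[c] == top]
            bump(cell, winners[0] if len(winners) == 1 else Call.AMBIGUOUS)
    else:
        for c in calls:
            if c.call is not Call.NON_JUNCTION:
                bump(c.cell, c.call)

    rows = [
        {
            "cell": cell,
            "n_plus": tally[Call.PLUS_KTS],
            "n_minus": tally[Call.MINUS_KTS],
            "n_ambiguous": tally[Call.AMBIGUOUS],
        }
        for cell, tally in units.items()
    ]
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    if cell_labels is not None:
        labels = cell_labels.reset_index() if cell_labels.index.name == "cell" else cell_labels
        df = labels.merge(df, on="cell", how="outer")
        for col in ("n_plus", "n_minus", "n_ambiguous"):
            df[col] = df[col].fillna(0).astype(int)
    return df.sort_values("cell", ignore_index=True)


@dataclass(frozen=True)
class RatioEstimate:
    """Per-cell (or pooled) -KTS fraction of informative units with a 95%
    binomial confidence interval; ``defined`` is False when there are no
    informative units."""

    minus_fraction: float
    ci_low: float
    ci_high: float
    n_informative: int
    defined: bool = True


_CI_METHODS = {"wilson": "wilson", "clopper_pearson": "beta"}


def estimate_ratio(
    n_minus: int, n_plus: int, ci_method: str = "wilson", alpha: float = 0.05
) -> RatioEstimate:
    """Estimate the -KTS fraction ``n_minus / (n_minus + n_plus)``.

    ``ci_method`` is ``"wilson"`` (score interval) or ``"clopper_pearson"``
    (exact tail inversion).
    """
    if ci_method not in _CI_METHODS:
        raise ValueError(f"ci_method must be one of {sorted(_CI_METHODS)}")
    n = n_minus + n_plus
    if n == 0:
        return RatioEstimate(float("nan"), float("nan"), float("nan"), 0, defined=False)
    lo, hi = proportion_confint(n_minus, n, alpha=alpha, method=_CI_METHODS[ci_method])
    return RatioEstimate(n_minus / n, float(lo), float(hi), n)


def add_ratio_columns(
    counts: pd.DataFrame, ci_method: str = "wilson", alpha: float = 0.05
) -> pd.DataFrame:
    """Append minus_fraction / ci_low / ci_high / n_informative columns to a
    per-cell counts table (vectorised)."""
    if ci_method not in _CI_METHODS:
        raise ValueError(f"ci_method must be one of {sorted(_CI_METHODS)}")
    out = counts.copy()
    n = (counts["n_minus"] + counts["n_plus"]).to_numpy()
    k = counts["n_minus"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n > 0, k / np.maximum(n, 1), np.nan)
    lo = np.full(len(out), np.nan)
    hi = np.full(len(out), np.nan)
    pos = n > 0
    if pos.any():
        lo_pos, hi_pos = proportion_confint(
            k[pos], n[pos], alpha=alpha, method=_CI_METHODS[ci_method]
        )
        lo[pos] = lo_pos
        hi[pos] = hi_pos
    out["n_informative"] = n
    out["minus_fraction"] = frac
    out["ci_low"] = lo
    out["ci_high"] = hi
    return out


def aggregate_groups(counts: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    """Summarise per-cell counts by label combination.

    Returns one row per observed key combination with the number of cells,
    mean informative units per cell for each isoform, and the pooled -KTS
    fraction ``sum(n_minus) / sum(n_minus + n_plus)`` (equal to the
    n-weighted mean of per-cell fractions).
    """
    missing = [k for k in keys if k not in counts.columns]
    if missing:
        raise KeyError(f"grouping keys not in counts table: {missing}")
    grouped = counts.groupby(list(keys), sort=True, observed=True)
    rows = []
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        n_minus = int(sub["n_minus"].sum())
        n_plus = int(sub["n_plus"].sum())
        informative = n_minus + n_plus
        rows.append(
            dict(zip(keys, key))
            | {
                "n_cells": len(sub),
                "mean_minus_per_cell": sub["n_minus"].mean(),
                "mean_plus_per_cell": sub["n_plus"].mean(),
                "mean_ambiguous_per_cell": sub["n_ambiguous"].mean(),
                "pooled_minus_fraction": n_minus / informative if informative else float("nan"),
                "n_informative": informative,
            }
        )
    return pd.DataFrame(rows)
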