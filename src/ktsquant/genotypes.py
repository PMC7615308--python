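"""Allele-level model of Wt1 KTS isoform output.

*Wt1* produces two major isoforms through competing 5' splice donors at the
end of exon 9: the canonical donor yields -KTS transcripts, while an
alternative donor 9 nt downstream inserts the Lys-Thr-Ser tripeptide (+KTS).
A wild-type allele emits a mixture of both; a Frasier-type allele (intron-9
donor mutation) can only produce -KTS; a null allele emits nothing.

The compensation switch models the observation that losing the +KTS splice
choice does not lower total transcript output: a Frasier allele then
redirects its full expression budget into -KTS, so a Frasier/Frasier cell
produces the same total as wild-type but twice the -KTS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum


class AlleleKind(str, Enum):
    """Functional class of a Wt1 allele with respect to KTS splicing."""

    WT = "WT"
    FRASIER = "FRASIER"  # +KTS donor abolished; -KTS only
    NULL = "NULL"  # whole-locus knockout; no output


@dataclass(frozen=True)
class Allele:
    """One Wt1 allele.

    Parameters
    ----------
    kind:
        Functional class (WT, FRASIER or NULL).
    expression_budget:
        Expected junction-read output of this allele, in units where a
        wild-type allele contributes 1.0. Must be non-negative.
    """

    kind: AlleleKind
    expression_budget: float = 1.0

    def __post_init__(self) -> None:
        if self.expression_budget < 0:
            raise ValueError(
                f"expression_budget must be >= 0, got {self.expression_budget}"
            )

    def rates(self, wt_plus_fraction: float, compensation: bool) -> tuple[float, float]:
        """Expected (+KTS, -KTS) output of this allele.

        Without compensation a Frasier allele loses the +KTS share of its
        budget outright; with compensation the whole budget is rerouted to
        the -KTS donor.
        """
        b = self.expression_budget
        if self.kind is AlleleKind.WT:
            return b * wt_plus_fraction, b * (1.0 - wt_plus_fraction)
        if self.kind is AlleleKind.FRASIER:
            return 0.0, b if compensation else b * (1.0 - wt_plus_fraction)
        return 0.0, 0.0


@dataclass
class GenotypeModel:
    """Diploid genotype with per-allele isoform output rates.

    ``wt_plus_fraction`` is the probability that a transcript from a WT
    allele takes the +KTS donor (default 0.5, i.e. balanced isoform output).
    ``compensation`` holds the total output of a Frasier/Frasier genotype
    equal to wild-type, doubling its -KTS share.
    """

    alleles: tuple[Allele, Allele]
    wt_plus_fraction: float = 0.5
    compensation: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.alleles = tuple(self.alleles)  # type: ignore[assignment]
        if len(self.alleles) != 2:
            raise ValueError("a diploid genotype needs exactly 2 alleles")
        if not 0.0 <= self.wt_plus_fraction <= 1.0:
            raise ValueError(
                f"wt_plus_fraction must be in [0, 1], got {self.wt_plus_fraction}"
            )
        if not self.name:
            self.name = "/".join(a.kind.value for a in self.alleles)

    def emission_rates(self) -> tuple[float, float]:
        """Expected (+KTS, -KTS) junction-read output per cell, in WT-allele
        budget units."""
        plus = minus = 0.0
        for a in self.alleles:
            p, m = a.rates(self.wt_plus_fraction, self.compensation)
            plus += p
            minus += m
        return plus, minus

    @property
    def total_rate(self) -> float:
        p, m = self.emission_rates()
        return p + m

    @property
    def minus_fraction(self) -> float:
        """Expected -KTS fraction of informative reads; 0.0 for a silent
        genotype (no output at all)."""
        p, m = self.emission_rates()
        return m / (p + m) if p + m > 0 else 0.0

    @property
    def is_silent(self) -> bool:
        return self.total_rate == 0.0

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_string(
        cls,
        genotype: str,
        wt_plus_fraction: float = 0.5,
        compensation: bool = False,
        name: str = "",
    ) -> "GenotypeModel":
        """Parse a genotype such as ``"WT/WT"`` or ``"FRASIER/NULL"``."""
        parts = genotype.strip().split("/")
        if len(parts) != 2:
            raise ValueError(f"genotype must be 'A/B', got {genotype!r}")
        alleles = tuple(Allele(AlleleKind(p.upper())) for p in parts)
        return cls(alleles, wt_plus_fraction, compensation, name or genotype)

    @classmethod
    def from_json(cls, source) -> "GenotypeModel":
        """Load from a JSON mapping (dict, path or file-like)."""
        if isinstance(source, dict):
            d = source
        elif hasattr(source, "read"):
            d = json.load(source)
        else:
            with open(source) as fh:
                d = json.load(fh)
        alleles = tuple(
            Allele(AlleleKind(a["kind"]), a.get("expression_budget", 1.0))
            for a in d["alleles"]
        )
        return cls(
            alleles,
            d.get("wt_plus_fraction", 0.5),
            d.get("compensation", False),
            d.get("name", ""),
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "alleles": [
                {"kind": a.kind.value, "expression_budget": a.expression_budget}
                for a in self.alleles
            ],
            "wt_plus_fraction": self.wt_plus_fraction,
            "compensation": self.compensation,
        }


def wildtype(**kw) -> GenotypeModel:
    """WT/WT genotype (balanced +KTS/-KTS output by default)."""
    return GenotypeModel.from_string("WT/WT", **kw)


def plus_kts_ko(compensation: bool = True, **kw) -> GenotypeModel:
    """Frasier-type +KTS knockout: both alleles -KTS-only, compensated by
    default so total output matches wild-type."""
    return GenotypeModel.from_string("FRASIER/FRASIER", compensation=compensation, **kw)


def plus_kts_ko_over_null(compensation: bool = True, **kw) -> GenotypeModel:
    """Compound heterozygote with a single -KTS-encoding allele over a
    whole-locus null (the low-dose end of the -KTS allelic series)."""
    return GenotypeModel.from_string("FRASIER/NULL", compensation=compensation, **kw)
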