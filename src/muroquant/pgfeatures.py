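"""Peptidoglycan summary statistics from muropeptide molar percentages.

Implements the standard muropeptide-profile summary used for whole-sacculus
composition tables: per-oligomer molar percentages, the overall crosslink
percentage (crosslinked bonds per 100 muropeptide species,
dimers% + 2*trimers% + 3*tetramers%), and the mean glycan chain length in
disaccharide units (100 / anhydro-muropeptide percentage, since every glycan
strand terminates in exactly one 1,6-anhydro-MurNAc).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .murolib import MuropeptideRecord

ORDER_FIELDS = ("monomers_pct", "dimers_pct", "trimers_pct", "tetramers_pct")


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching tabular presentation."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OligomerAbundance:
    """Molar percentages per oligomer order plus the anhydro-species percentage."""

    monomers_pct: float
    dimers_pct: float
    trimers_pct: float
    tetramers_pct: float
    anhydro_pct: float

    def validate(self, tolerance: float = 0.05) -> "OligomerAbundance":
        """Check non-negativity and that the four oligomer classes sum to 100.

        The tolerance (default 0.05) accommodates inputs quoted at two
        decimals. Returns self so it can be chained.
        """
        values = [getattr(self, f) for f in ORDER_FIELDS] + [self.anhydro_pct]
        if any(v < 0 for v in values):
            raise ValueError("abundances must be non-negative")
        total = sum(getattr(self, f) for f in ORDER_FIELDS)
        if abs(total - 100.0) > tolerance:
            raise ValueError(
                f"oligomer percentages sum to {total:.4f}, not 100 +/- {tolerance}"
            )
        return self


@dataclass(frozen=True)
class PGFeatureSummary:
    """The summary statistic set computed from an :class:`OligomerAbundance`."""

    abundance: OligomerAbundance
    crosslink_pct: float
    higher_order_pct: float
    chain_length: float

    def to_table(self, ndigits: int = 2) -> dict[str, float]:
        """Report-style dict, rounded half-up to ``ndigits`` decimals."""
        ab = self.abundance
        return {
            "Monomers": round_half_up(ab.monomers_pct, ndigits),
            "Dimers": round_half_up(ab.dimers_pct, ndigits),
            "Trimers": round_half_up(ab.trimers_pct, ndigits),
            "Tetramers": round_half_up(ab.tetramers_pct, ndigits),
            "Crosslinks": round_half_up(self.crosslink_pct, ndigits),
            "Anhydro muropeptide": round_half_up(ab.anhydro_pct, ndigits),
            "Chain length": round_half_up(self.chain_length, ndigits),
        }


def oligomer_percentages(
    quant: pd.DataFrame,
    library: Sequence[MuropeptideRecord],
    count_termini: bool = False,
) -> OligomerAbundance:
    """Sum molar percentages by oligomer order and anhydro status.

    Each quant row must resolve by name to a library record supplying the
    oligomer order and anhydro count. An anhydro-containing species counts
    once toward ``anhydro_pct`` regardless of how many anhydro termini it
    carries, unless ``count_termini`` weights it by that number.
    """
    by_name: Mapping[str, MuropeptideRecord] = {r.name: r for r in library}
    order_sums = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0}
    anhydro = 0.0
    for _, row in quant.iterrows():
        name = row["name"]
        try:
            record = by_name[name]
        except KeyError:
            raise KeyError(f"quant species {name!r} not found in library") from None
        pct = float(row["molar_percent"])
        order_sums[record.composition.n_subunits] += pct
        n_anh = record.composition.n_anhydro
        if n_anh >= 1:
            anhydro += pct * (n_anh if count_termini else 1)
    return OligomerAbundance(
        monomers_pct=order_sums[1],
        dimers_pct=order_sums[2],
        trimers_pct=order_sums[3],
        tetramers_pct=order_sums[4],
        anhydro_pct=anhydro,
    )


def crosslink_percentage(abundance: OligomerAbundance) -> float:
    """Crosslinked bonds per 100 muropeptide species: D + 2T + 3Q."""
    return (
        abundance.dimers_pct
        + 2.0 * abundance.trimers_pct
        + 3.0 * abundance.tetramers_pct
    )


def mean_chain_length(anhydro_pct: float) -> float:
    """Mean glycan strand length (disaccharide units) = 100 / anhydro percentage."""
    if anhydro_pct <= 0:
        raise ValueError("chain length undefined for anhydro percentage <= 0")
    return 100.0 / anhydro_pct


def summarize_abundance(abundance: OligomerAbundance) -> PGFeatureSummary:
    return PGFeatureSummary(
        abundance=abundance,
        crosslink_pct=crosslink_percentage(abundance),
        higher_order_pct=abundance.trimers_pct + abundance.tetramers_pct,
        chain_length=mean_chain_length(abundance.anhydro_pct),
    )


def summarize(
    quant: pd.DataFrame,
    library: Sequence[MuropeptideRecord],
    count_termini: bool = False,
) -> PGFeatureSummary:
    """Full summary from a quant table plus the library that names it."""
    return summarize_abundance(oligomer_percentages(quant, library, count_termini))


_ABUNDANCE_ALIASES = {
    "monomers": "monomers_pct",
    "dimers": "dimers_pct",
    "trimers": "trimers_pct",
    "tetramers": "tetramers_pct",
    "anhydro": "anhydro_pct",
    "anhydro muropeptide": "anhydro_pct",
    "anhydro muropeptides": "anhydro_pct",
}


def abundance_from_csv(path) -> OligomerAbundance:
    """Read a two-column ``feature,value`` CSV into an OligomerAbundance."""
    df = pd.read_csv(path, header=None, names=["feature", "value"], comment="#")
    # tolerate a header row
    if str(df.iloc[0, 0]).strip().lower() == "feature":
        df = df.iloc[1:]
    fields: dict[str, float] = {}
    for _, row in df.iterrows():
        key = str(row["feature"]).strip().lower()
        if key in _ABUNDANCE_ALIASES:
            fields[_ABUNDANCE_ALIASES[key]] = float(row["value"])
    missing = {
        "monomers_pct", "dimers_pct", "trimers_pct", "tetramers_pct", "anhydro_pct"
    } - set(fields)
    if missing:
        raise ValueError(f"abundance CSV missing features: {sorted(missing)}")
    return OligomerAbundance(**fields)
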