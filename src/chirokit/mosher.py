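"""Modified Mosher (MTPA ester) Δδ analysis.

A secondary alcohol is esterified with both (R)- and (S)-MTPA chloride and
the proton shifts of the two esters compared: Δδ = δ_S − δ_R.  In the
Ohtani model the MTPA plane splits the molecule into two branches; protons
on one side move upfield in one ester and downfield in the other, so the
sign pattern of Δδ across the branches fixes the carbinol center's R/S
configuration.  Branch membership ("side" A or B) is supplied by the user
from the drawn structure; by convention side A is the branch that carries
negative Δδ for an R center.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

__all__ = [
    "ProtonShiftRecord",
    "MosherTable",
    "ConfigurationCall",
    "delta_delta",
    "assign_configuration",
]

#: |Δδ| below this (ppm) is treated as zero — under 2-decimal shift resolution.
ZERO_DELTA_PPM = 0.005


@dataclass(frozen=True)
class ProtonShiftRecord:
    """One proton's shifts in the (S)- and (R)-MTPA esters (ppm)."""

    label: str
    side: str  # "A" | "B"
    delta_s: float
    delta_r: float

    def __post_init__(self) -> None:
        if self.side not in ("A", "B"):
            raise ValueError(f"side must be 'A' or 'B', got {self.side!r}")
        for name, v in (("delta_S", self.delta_s), ("delta_R", self.delta_r)):
            if not (-1.0 < v < 16.0):
                raise ValueError(f"{name} = {v} ppm outside the plausible (-1, 16) range")

    @property
    def dd(self) -> float:
        return self.delta_s - self.delta_r


@dataclass(frozen=True)
class MosherTable:
    """All assigned protons around one esterified stereocenter."""

    stereocenter: str
    protons: Sequence[ProtonShiftRecord]

    def __post_init__(self) -> None:
        labels = [p.label for p in self.protons]
        if len(set(labels)) != len(labels):
            raise ValueError("proton labels must be unique")
        sides = {p.side for p in self.protons}
        if sides != {"A", "B"}:
            raise ValueError("both sides A and B must carry at least one proton")

    def swapped(self) -> "MosherTable":
        """Table with the two ester columns exchanged (negates every Δδ)."""
        return MosherTable(
            self.stereocenter,
            [
                ProtonShiftRecord(p.label, p.side, p.delta_r, p.delta_s)
                for p in self.protons
            ],
        )


@dataclass(frozen=True)
class ConfigurationCall:
    """Outcome of the sign-pattern vote.

    ``configuration`` is "R", "S", or None when the call is withheld
    (consistency below threshold) or undecidable (tie); ``consistency`` is
    the fraction of informative protons whose Δδ sign matches the winning
    hypothesis.
    """

    stereocenter: str
    configuration: Optional[str]
    consistency: float
    fraction_r: float
    fraction_s: float
    delta_deltas: Dict[str, float]
    reason: str = ""

    @property
    def decided(self) -> bool:
        return self.configuration is not None


def delta_delta(table: MosherTable) -> Dict[str, float]:
    """Per-proton Δδ = δ_S − δ_R in ppm."""
    return {p.label: p.dd for p in table.protons}


def assign_configuration(
    table: MosherTable,
    min_consistency: float = 0.8,
    zero_threshold: float = ZERO_DELTA_PPM,
) -> ConfigurationCall:
    """Call the stereocenter configuration from the Δδ sign pattern.

    Hypothesis R predicts Δδ < 0 on side A and Δδ > 0 on side B; hypothesis
    S predicts the reverse.  Each proton with |Δδ| ≥ ``zero_threshold``
    votes for whichever hypothesis its sign supports; near-zero protons are
    uninformative and count against both hypotheses' fractions.  The call
    is the better-supported hypothesis, withheld when its fraction is below
    ``min_consistency`` and undecidable on an exact tie.
    """
    dd = delta_delta(table)
    n = len(table.protons)
    votes_r = 0
    votes_s = 0
    for p in table.protons:
        if abs(p.dd) < zero_threshold:
            continue  # unmatched for both hypotheses
        expected_r = -1 if p.side == "A" else +1
        if (p.dd > 0) == (expected_r > 0):
            votes_r += 1
        else:
            votes_s += 1
    frac_r, frac_s = votes_r / n, votes_s / n
    if votes_r == votes_s:
        return ConfigurationCall(
            table.stereocenter, None, max(frac_r, frac_s), frac_r, frac_s, dd,
            reason="tie between R and S hypotheses",
        )
    config, best = ("R", frac_r) if votes_r > votes_s else ("S", frac_s)
    if best < min_consistency:
        return ConfigurationCall(
            table.stereocenter, None, best, frac_r, frac_s, dd,
            reason=f"consistency {best:.2f} below threshold {min_consistency:.2f}",
        )
    return ConfigurationCall(table.stereocenter, config, best, frac_r, frac_s, dd)
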