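"""Conformer ensembles and Boltzmann statistical weights.

Each conformer carries a relative Gibbs free energy ΔG (kcal/mol, zero for
the most stable), an optional dihedral-class label (θ1 ≈ 0° vs 180°
rotamer families) and the electronic transitions computed for it.  The
weight of conformer i is

    g_i = exp(−ΔG_i / RT) / Σ_j exp(−ΔG_j / RT)

and spectral averaging consumes these weights.  A hard ΔG cutoff
(conventionally 4 kcal/mol) discards high-energy conformers before
weighting, and class-mixture reweighting imposes externally chosen totals
on the rotamer families (e.g. 40:60 for the θ1 = 0°:180° split).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "EV_NM",
    "TransitionRecord",
    "ConformerRecord",
    "Ensemble",
    "boltzmann_weights",
    "select_conformers",
    "class_mixture_weights",
]

#: Gas constant in kcal·mol⁻¹·K⁻¹.
GAS_CONSTANT_KCAL = 1.98720425e-3

#: Energy–wavelength conversion, eV·nm.
EV_NM = 1239.84193


@dataclass(frozen=True)
class TransitionRecord:
    """One electronic excited state: energy (eV) and rotatory strength.

    Rotatory strengths are in the conventional 10⁻⁴⁰ cgs units
    (erg·esu·cm/Gauss); either sign is meaningful.
    """

    energy_ev: float
    rotatory_strength: float

    def __post_init__(self) -> None:
        if not self.energy_ev > 0:
            raise ValueError(f"excitation energy must be positive, got {self.energy_ev}")
        if not np.isfinite(self.rotatory_strength):
            raise ValueError("rotatory strength must be finite")

    @classmethod
    def from_wavelength(cls, wavelength_nm: float, rotatory_strength: float) -> "TransitionRecord":
        return cls(EV_NM / wavelength_nm, rotatory_strength)

    @property
    def wavelength_nm(self) -> float:
        return EV_NM / self.energy_ev


@dataclass(frozen=True)
class ConformerRecord:
    identifier: str
    delta_g: float  # relative Gibbs free energy, kcal/mol, >= 0
    theta1_class: Optional[str] = None  # "0" | "180" | None
    transitions: Sequence[TransitionRecord] = ()

    def __post_init__(self) -> None:
        if self.delta_g < 0:
            raise ValueError(f"relative Gibbs energy must be >= 0, got {self.delta_g}")


@dataclass(frozen=True)
class Ensemble:
    """A set of conformers sharing a temperature (K)."""

    conformers: Sequence[ConformerRecord]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError("ensemble must contain at least one conformer")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        ids = [c.identifier for c in self.conformers]
        if len(set(ids)) != len(ids):
            raise ValueError("conformer identifiers must be unique")
        n_zero = sum(1 for c in self.conformers if c.delta_g == 0.0)
        if n_zero == 0:
            raise ValueError("exactly one conformer must sit at ΔG = 0 (the reference)")

    def __len__(self) -> int:
        return len(self.conformers)

    def ids(self) -> List[str]:
        return [c.identifier for c in self.conformers]


class WeightVector(dict):
    """conformer identifier → statistical weight; sums to 1."""

    def __init__(self, weights: Mapping[str, float]):
        total = sum(weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {total}, not 1")
        if any(w < 0 for w in weights.values()):
            raise ValueError("weights must be non-negative")
        super().__init__(weights)


def boltzmann_weights(ensemble: Ensemble) -> WeightVector:
    """Statistical weights from relative Gibbs free energies.

    g_i = exp(−ΔG_i/RT) / Σ_j exp(−ΔG_j/RT), RT in kcal/mol.
    """
    rt = GAS_CONSTANT_KCAL * ensemble.temperature
    dg = np.array([c.delta_g for c in ensemble.conformers])
    w = np.exp(-dg / rt)
    w /= w.sum()
    return WeightVector(dict(zip(ensemble.ids(), w.tolist())))


def select_conformers(ensemble: Ensemble, cutoff: float = 4.0) -> Ensemble:
    """Keep conformers with ΔG ≤ cutoff (boundary inclusive).

    The ΔG = 0 reference always survives, so the result is never empty;
    weights computed on the survivors renormalize to 1.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    kept = [c for c in ensemble.conformers if c.delta_g <= cutoff]
    return Ensemble(kept, ensemble.temperature)


def class_mixture_weights(
    ensemble: Ensemble, class_totals: Mapping[str, float]
) -> WeightVector:
    """Impose fixed totals on dihedral classes, Boltzmann-split within each.

    ``class_totals`` maps θ1-class labels to fractions summing to 1.  Within
    each class the conformers carry Boltzmann weights renormalized so the
    class sums to its stated total; classes with total 0 contribute nothing
    (and may be empty).
    """
    total = sum(class_totals.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"class totals sum to {total}, not 1")
    members: Dict[str, List[ConformerRecord]] = {k: [] for k in class_totals}
    for c in ensemble.conformers:
        if c.theta1_class is None:
            raise ValueError(f"conformer {c.identifier!r} has no dihedral-class label")
        if c.theta1_class not in class_totals:
            raise ValueError(
                f"conformer {c.identifier!r} has class {c.theta1_class!r} "
                f"absent from the mixture {sorted(class_totals)}"
            )
        members[c.theta1_class].append(c)
    rt = GAS_CONSTANT_KCAL * ensemble.temperature
    weights: Dict[str, float] = {}
    for cls, frac in class_totals.items():
        group = members[cls]
        if not group:
            if frac > 0:
                raise ValueError(f"class {cls!r} has no members but total {frac}")
            continue
        w = np.exp(-np.array([c.delta_g for c in group]) / rt)
        w *= frac / w.sum()
        for c, wi in zip(group, w.tolist()):
            weights[c.identifier] = wi
    return WeightVector(weights)
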