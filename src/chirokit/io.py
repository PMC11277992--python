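"""Readers, writers and run configuration.

File formats (all plain text):

* ensemble TSV — conformer header rows ``conformer_id  dG_kcal_mol
  theta1_class`` interleaved with transition rows ``conformer_id  E_eV
  R_cgs40`` (or ``lambda_nm`` instead of ``E_eV``); a JSON mirror carries
  the same content.
* spectrum CSV — two columns ``lambda_nm, delta_epsilon``; ``#`` comment
  header lines carry provenance and, for scaled spectra, the λ_peak used.
* Mosher CSV — columns ``proton, side, delta_S_ppm, delta_R_ppm``.

All writers emit full precision (wavelengths to 4 decimals, Δε to 6
significant figures) so read(write(x)) round-trips numerically to 1e-9.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple, Union

import numpy as np
import yaml

from .conformers import Ensemble, ConformerRecord, TransitionRecord, EV_NM
from .ecd import SpectrumGrid
from .mosher import MosherTable, ProtonShiftRecord

__all__ = [
    "RunConfig",
    "read_ensemble",
    "write_ensemble",
    "read_spectrum",
    "write_spectrum",
    "read_mosher",
    "write_mosher",
]

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file; message carries the file and line number."""


@dataclass
class RunConfig:
    """All tunable parameters of a modeling run, YAML round-trippable."""

    temperature: float = 298.15     # K
    cutoff: float = 4.0             # kcal/mol
    zeta: float = 0.36              # eV
    uv_shift: float = 4.0           # nm
    grid_start: float = 190.0       # nm
    grid_stop: float = 400.0        # nm
    grid_step: float = 1.0          # nm
    window: Tuple[float, float] = (200.0, 400.0)
    reference_band: float = 290.0   # nm
    min_consistency: float = 0.8
    seed: int = 0
    adducts: Dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("temperature", "cutoff", "zeta", "grid_step"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_yaml(self, path: PathLike) -> None:
        data = asdict(self)
        data["window"] = list(self.window)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "window" in data:
            data["window"] = tuple(data["window"])
        return cls(**data)


# ---------------------------------------------------------------- ensembles

_ENSEMBLE_HEADER = ["conformer_id", "dG_kcal_mol", "theta1_class"]
_TRANSITION_HEADER_EV = ["conformer_id", "E_eV", "R_cgs40"]
_TRANSITION_HEADER_NM = ["conformer_id", "lambda_nm", "R_cgs40"]


def write_ensemble(ensemble: Ensemble, path: PathLike) -> None:
    """Write an ensemble as TSV (or JSON when the suffix is .json)."""
    path = Path(path)
    if path.suffix == ".json":
        payload = {
            "temperature_K": ensemble.temperature,
            "conformers": [
                {
                    "id": c.identifier,
                    "dG_kcal_mol": c.delta_g,
                    "theta1_class": c.theta1_class,
                    "transitions": [
                        {"E_eV": t.energy_ev, "R_cgs40": t.rotatory_strength}
                        for t in c.transitions
                    ],
                }
                for c in ensemble.conformers
            ],
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return
    lines = [f"# temperature_K\t{ensemble.temperature!r}"]
    lines.append("\t".join(_ENSEMBLE_HEADER + _TRANSITION_HEADER_EV[1:]))
    for c in ensemble.conformers:
        lines.append(f"{c.identifier}\t{c.delta_g!r}\t{c.theta1_class or ''}\t\t")
        for t in c.transitions:
            lines.append(
                f"{c.identifier}\t\t\t{t.energy_ev!r}\t{t.rotatory_strength!r}"
            )
    path.write_text("\n".join(lines) + "\n")


def _fail(path: Path, lineno: int, msg: str) -> None:
    raise FormatError(f"{path}:{lineno}: {msg}")


def read_ensemble(path: PathLike) -> Ensemble:
    """Read an ensemble TSV/JSON written by :func:`write_ensemble`."""
    path = Path(path)
    if path.suffix == ".json":
        payload = json.loads(path.read_text())
        conformers = [
            ConformerRecord(
                c["id"],
                float(c["dG_kcal_mol"]),
                c.get("theta1_class"),
                tuple(
                    TransitionRecord(float(t["E_eV"]), float(t["R_cgs40"]))
                    for t in c.get("transitions", [])
                ),
            )
            for c in payload["conformers"]
        ]
        return Ensemble(conformers, float(payload.get("temperature_K", 298.15)))

    temperature = 298.15
    order: List[str] = []
    dg: Dict[str, float] = {}
    cls: Dict[str, Optional[str]] = {}
    trans: Dict[str, List[TransitionRecord]] = {}
    use_nm = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            parts = line[1:].split("\t")
            if parts and parts[0].strip() == "temperature_K":
                temperature = float(parts[1])
            continue
        cells = line.split("\t")
        if cells[0] == "conformer_id":
            use_nm = "lambda_nm" in cells
            continue
        if len(cells) < 5:
            cells += [""] * (5 - len(cells))
        cid = cells[0].strip()
        if not cid:
            _fail(path, lineno, "missing conformer_id")
        if cells[1].strip():  # conformer header row
            if cid in dg:
                _fail(path, lineno, f"duplicated conformer id {cid!r}")
            try:
                dg[cid] = float(cells[1])
            except ValueError:
                _fail(path, lineno, f"non-numeric dG {cells[1]!r}")
            cls[cid] = cells[2].strip() or None
            order.append(cid)
            trans[cid] = []
        else:  # transition row
            if cid not in dg:
                _fail(path, lineno, f"transition row for unknown conformer {cid!r}")
            try:
                x, r = float(cells[3]), float(cells[4])
            except ValueError:
                _fail(path, lineno, f"non-numeric transition cells {cells[3:5]!r}")
            e_ev = EV_NM / x if use_nm else x
            trans[cid].append(TransitionRecord(e_ev, r))
    if not order:
        _fail(path, 0, "no conformers found")
    conformers = [
        ConformerRecord(cid, dg[cid], cls[cid], tuple(trans[cid])) for cid in order
    ]
    return Ensemble(conformers, temperature)


# ----------------------------------------------------------------- spectra

def write_spectrum(spectrum: SpectrumGrid, path: PathLike) -> None:
    path = Path(path)
    lines = [f"# provenance={spectrum.provenance}"]
    if spectrum.scale_peak_nm is not None:
        lines.append(f"# scaled=true lambda_peak_nm={spectrum.scale_peak_nm:.4f}")
    lines.append("lambda_nm,delta_epsilon")
    for wl, v in zip(spectrum.wavelengths, spectrum.values):
        lines.append(f"{wl:.4f},{v:.6g}")
    path.write_text("\n".join(lines) + "\n")


def read_spectrum(path: PathLike) -> SpectrumGrid:
    path = Path(path)
    provenance = "experimental"
    scale_peak: Optional[float] = None
    wl: List[float] = []
    vals: List[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line[1:].split():
                if token.startswith("provenance="):
                    provenance = token.split("=", 1)[1]
                elif token.startswith("lambda_peak_nm="):
                    scale_peak = float(token.split("=", 1)[1])
            continue
        if line.startswith("lambda_nm"):
            continue
        cells = line.split(",")
        if len(cells) != 2:
            _fail(path, lineno, f"expected 2 columns, got {len(cells)}")
        try:
            wl.append(float(cells[0]))
            vals.append(float(cells[1]))
        except ValueError:
            _fail(path, lineno, f"non-numeric cells {cells!r}")
    if not wl:
        _fail(path, 0, "no data rows")
    return SpectrumGrid(np.array(wl), np.array(vals), provenance, scale_peak)


# ------------------------------------------------------------------ Mosher

_MOSHER_HEADER = ["proton", "side", "delta_S_ppm", "delta_R_ppm"]


def write_mosher(table: MosherTable, path: PathLike) -> None:
    path = Path(path)
    lines = [f"# stereocenter={table.stereocenter}", ",".join(_MOSHER_HEADER)]
    for p in table.protons:
        lines.append(f"{p.label},{p.side},{p.delta_s!r},{p.delta_r!r}")
    path.write_text("\n".join(lines) + "\n")


def read_mosher(path: PathLike) -> MosherTable:
    path = Path(path)
    stereocenter = "?"
    protons: List[ProtonShiftRecord] = []
    header_seen = False
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "stereocenter=" in line:
                stereocenter = line.split("stereocenter=", 1)[1].strip()
            continue
        cells = [c.strip() for c in line.split(",")]
        if cells[0] == "proton":
            if cells != _MOSHER_HEADER:
                _fail(path, lineno, f"expected header {_MOSHER_HEADER}, got {cells}")
            header_seen = True
            continue
        if len(cells) != 4:
            _fail(path, lineno, f"expected 4 columns, got {len(cells)}")
        try:
            rec = ProtonShiftRecord(cells[0], cells[1], float(cells[2]), float(cells[3]))
        except ValueError as exc:
            _fail(path, lineno, str(exc))
        protons.append(rec)
    if not header_seen:
        _fail(path, 0, "missing header row")
    try:
        return MosherTable(stereocenter, tuple(protons))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
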