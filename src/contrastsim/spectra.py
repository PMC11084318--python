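"""Polychromatic X-ray spectra: containers, file I/O and a tube model.

A :class:`Spectrum` is a relative photon-fluence histogram on a uniform energy
grid capped at the tube peak kilovoltage (kVp).  Spectra can be loaded from
two-column text files or generated with a simple tube model: a Kramers
continuum ``S(E) ~ (kVp - E)/E`` hardened by exponential filtration through an
elemental filter, plus characteristic K-lines for rhodium anodes.  The model
is a deliberately light-weight approximation of published tube spectra; the
bundled fixtures are calibrated (via the filter thickness) so their
fluence-weighted mean energies match the beam qualities the pipeline
simulates: 20 keV for the 35 kVp Rh/Rh mammographic beam and 51 keV for the
100 kVp W/Al radiographic beam.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np

from .materials import ELEMENT_DENSITIES, element

__all__ = [
    "Spectrum",
    "SpectrumFormatError",
    "SpectrumStatisticError",
    "load_spectrum",
    "save_spectrum",
    "mean_energy",
    "generate_bremsstrahlung",
    "fixture_spectrum",
    "FIXTURE_TUBES",
]

DEFAULT_STEP = 0.5  # keV
DEFAULT_E_MIN = 5.0  # keV

# Rhodium characteristic lines (K-alpha, K-beta), keV, and their fluence as a
# fraction of the filtered continuum fluence.
RH_K_LINES: Tuple[Tuple[float, float], ...] = ((20.2, 0.18), (22.7, 0.045))
RH_K_EDGE = 23.2199


class SpectrumFormatError(ValueError):
    """Raised for malformed spectrum files."""


class SpectrumStatisticError(ValueError):
    """Raised for statistics of degenerate (all-zero) spectra."""


@dataclass(frozen=True)
class Spectrum:
    """Relative photon fluence per energy bin (uniform grid, bin centers)."""

    energies: np.ndarray
    fluence: np.ndarray
    kvp: float
    label: str = ""

    def __post_init__(self) -> None:
        e, f = self.energies, self.fluence
        if len(e) != len(f) or len(e) == 0:
            raise ValueError("energies and fluence must be equal-length, non-empty")
        if np.any(e <= 0) or np.any(e > self.kvp + 1e-9):
            raise ValueError("bin energies must lie in (0, kvp]")
        if np.any(f < 0) or not np.any(f > 0):
            raise ValueError("fluence must be >= 0 with at least one positive bin")
        if len(e) > 1 and np.ptp(np.diff(e)) > 1e-9:
            raise ValueError("energy grid must be uniform")

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())

    def normalized(self) -> "Spectrum":
        return replace(self, fluence=self.fluence / self.total_fluence)

    def mean_energy(self) -> float:
        return mean_energy(self)


def mean_energy(spectrum: Spectrum) -> float:
    """Fluence-weighted mean energy, sum(S*E)/sum(S), in keV."""
    total = spectrum.fluence.sum()
    if total <= 0:
        raise SpectrumStatisticError("spectrum has zero total fluence")
    return float((spectrum.fluence * spectrum.energies).sum() / total)


def _uniform_grid(kvp: float, step: float, e_min: float) -> np.ndarray:
    n = int(np.floor((kvp - e_min) / step + 1e-9)) + 1
    return e_min + step * np.arange(n)


def load_spectrum(path, step: float = DEFAULT_STEP, kvp: Optional[float] = None,
                  label: str = "") -> Spectrum:
    """Load a two-column (energy keV, relative fluence) text spectrum.

    Rows may be unordered; a header line and ``#`` comments are tolerated.  A
    ``# kvp: <value>`` comment sets the peak kilovoltage, otherwise the maximum
    energy is used.  Input already on a uniform grid is kept as-is; otherwise
    fluence is deposited into the nearest bin of a uniform ``step`` grid.
    """
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "kvp" in line.lower() and ":" in line:
                try:
                    kvp = float(line.split(":", 1)[1])
                except ValueError:
                    pass
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise SpectrumFormatError(f"bad row in {path}: {raw!r}")
        try:
            e, f = float(parts[0]), float(parts[1])
        except ValueError:
            if not rows:  # tolerate a single non-numeric header line
                continue
            raise SpectrumFormatError(f"non-numeric row in {path}: {raw!r}")
        if f < 0:
            raise SpectrumFormatError(f"negative fluence in {path}: {raw!r}")
        rows.append((e, f))
    if not rows:
        raise SpectrumFormatError(f"no data rows in {path}")
    rows.sort()
    e_in = np.array([r[0] for r in rows])
    f_in = np.array([r[1] for r in rows])
    if kvp is None:
        kvp = float(e_in[-1])
    uniform = len(e_in) == 1 or (
        len(e_in) > 1 and np.ptp(np.diff(e_in)) <= 1e-9 and not np.any(np.diff(e_in) == 0)
    )
    if uniform:
        return Spectrum(e_in, f_in, kvp=kvp, label=label or str(path))
    grid = _uniform_grid(kvp, step, e_min=min(DEFAULT_E_MIN, float(e_in[0])))
    fluence = np.zeros_like(grid)
    idx = np.clip(np.round((e_in - grid[0]) / step).astype(int), 0, len(grid) - 1)
    np.add.at(fluence, idx, f_in)
    return Spectrum(grid, fluence, kvp=kvp, label=label or str(path))


def save_spectrum(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column tab-separated text with a kvp header."""
    lines = [f"# kvp: {spectrum.kvp:g}", f"# label: {spectrum.label}",
             "energy_keV\trelative_fluence"]
    for e, f in zip(spectrum.energies, spectrum.fluence):
        lines.append(f"{e:.6g}\t{f:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")


def generate_bremsstrahlung(kvp: float, anode: str = "W",
                            filtration: Sequence[Tuple[str, float]] = (),
                            step: float = DEFAULT_STEP,
                            e_min: float = DEFAULT_E_MIN,
                            label: str = "") -> Spectrum:
    """Generate a filtered Kramers spectrum, normalized to unit total fluence.

    ``filtration`` is a sequence of (element symbol, thickness mm).  A rhodium
    anode adds its characteristic K-lines when the tube voltage exceeds the
    rhodium K-shell binding energy.
    """
    if not 20.0 <= kvp <= 150.0:
        raise ValueError("kvp must lie within [20, 150] kV")
    grid = _uniform_grid(kvp, step, e_min)
    fluence = np.maximum((kvp - grid) / grid, 0.0)  # clamp endpoint round-off
    for sym, t_mm in filtration:
        el = element(sym)  # raises FormulaError when data are missing
        rho = ELEMENT_DENSITIES.get(sym)
        if rho is None:
            raise ValueError(f"no bulk density known for filter element {sym}")
        mu = el.mu_rho_at(grid) * rho  # 1/cm
        fluence = fluence * np.exp(-mu * t_mm / 10.0)
    if anode == "Rh" and kvp > RH_K_EDGE:
        continuum = fluence.sum()
        for line_e, frac in RH_K_LINES:
            i = int(round((line_e - grid[0]) / step))
            fluence[i] += frac * continuum
    spectrum = Spectrum(grid, fluence, kvp=kvp,
                        label=label or f"{anode} {kvp:g} kVp")
    return spectrum.normalized()


# Fixture tube settings.  Filter thicknesses of the two simulation beams were
# calibrated once (scripts in the repository) so the fluence-weighted mean
# energies equal 20.0 keV (35 kVp Rh/Rh) and 51.0 keV (100 kVp W/Al); the
# radiographic-survey beams use a fixed 2.5 mm Al total filtration.
FIXTURE_TUBES = {
    "rh_rh_35kvp": dict(kvp=35.0, anode="Rh", filtration=(("Rh", 0.31841062422018),)),
    "w_al_100kvp": dict(kvp=100.0, anode="W", filtration=(("Al", 5.19324864408650),)),
    "w_al_46kvp": dict(kvp=46.0, anode="W", filtration=(("Al", 2.5),)),
    "w_al_80kvp": dict(kvp=80.0, anode="W", filtration=(("Al", 2.5),)),
    "w_al_95kvp": dict(kvp=95.0, anode="W", filtration=(("Al", 2.5),)),
}


def fixture_spectrum(name: str) -> Spectrum:
    """Load a bundled fixture spectrum by name (see ``FIXTURE_TUBES``)."""
    if name not in FIXTURE_TUBES:
        raise KeyError(f"unknown fixture spectrum {name!r}; "
                       f"choose from {sorted(FIXTURE_TUBES)}")
    ref = resources.files("contrastsim.data").joinpath(f"spectra/{name}.tsv")
    with resources.as_file(ref) as path:
        return load_spectrum(path, label=name)


def spectrum_for_kvp(kvp: float) -> Spectrum:
    """Bundled fixture spectrum matching an acquisition kVp."""
    by_kvp = {35.0: "rh_rh_35kvp", 100.0: "w_al_100kvp", 46.0: "w_al_46kvp",
              80.0: "w_al_80kvp", 95.0: "w_al_95kvp"}
    if float(kvp) not in by_kvp:
        raise KeyError(f"no bundled fixture spectrum for {kvp} kVp")
    return fixture_spectrum(by_kvp[float(kvp)])
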