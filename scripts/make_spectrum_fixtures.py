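"""Regenerate the bundled fixture spectra from the frozen tube settings.

The two simulation beams carry filter thicknesses calibrated (once, with
scipy.optimize.brentq against the tube model) so that their fluence-weighted
mean energies equal 20.0 keV (35 kVp Rh/Rh) and 51.0 keV (100 kVp W/Al); the
thicknesses are frozen in ``contrastsim.spectra.FIXTURE_TUBES``.  Run from the
repository root:

    python scripts/make_spectrum_fixtures.py
"""

from pathlib import Path

from contrastsim.spectra import FIXTURE_TUBES, generate_bremsstrahlung, save_spectrum


def main() -> None:
    out_dir = Path(__file__).resolve().parents[1] / "src/contrastsim/data/spectra"
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, tube in FIXTURE_TUBES.items():
        spectrum = generate_bremsstrahlung(label=name, **tube)
        save_spectrum(spectrum, out_dir / f"{name}.tsv")
        print(f"{name}: mean energy {spectrum.mean_energy():.3f} keV, "
              f"{len(spectrum.energies)} bins")


if __name__ == "__main__":
    main()
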