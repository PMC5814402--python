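"""Define the measurement scenario and persist its inputs.

Writes the run configuration, the chromophore extinction spectrum, the
pump-beam spectrum and the ground-truth CRI table for the pump-on /
pump-off, eleven-wavelength protein scenario under results/scenario/.
The heavy image simulation itself happens inside the pipeline driver
(02_recover_cri.py), which reads the configuration written here.

Run:  python analysis/01_simulate_scenario.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from holocri.pipeline import RunConfig
from holocri.synthesize import medium_cri_from_scenario

OUT = Path("results/scenario")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(seed=2026, save_images=False)
    cfg.to_yaml(OUT / "config.yaml")

    eps = cfg.extinction_spectrum()
    pd.DataFrame({"wavelength_nm": eps.wavelengths_nm,
                  "epsilon_M_cm": eps.epsilon}).to_csv(
        OUT / "extinction_spectrum.csv", index=False, float_format="%.10g")
    pump = cfg.pump_spectrum()
    pd.DataFrame({"wavelength_nm": pump.wavelengths_nm,
                  "spectral_density_W_m2_nm": pump.spectral_density}).to_csv(
        OUT / "pump_spectrum.csv", index=False, float_format="%.10g")

    sc = cfg.scenario()
    rows = []
    for state in ("pump-off", "pump-on"):
        for wl in sc.wavelengths_nm:
            ci = medium_cri_from_scenario(sc, state, float(wl))
            rows.append({"state": state, "wavelength_nm": float(wl),
                         "n_true": ci.n, "kappa_true": ci.kappa})
    truth = pd.DataFrame(rows)
    truth.to_csv(OUT / "ground_truth_cri.csv", index=False,
                 float_format="%.12g")

    print(f"scenario: {len(sc.wavelengths_nm)} wavelengths x 2 states, "
          f"sphere {sc.sphere.diameter_um:.0f} um, grid "
          f"{sc.grid.n_pixels} px @ {sc.grid.pixel_pitch_um} um")
    print(f"pG density {sc.rho_pG_off*1e3:.2f} mM (pump off) / "
          f"{sc.rho_pG_on*1e3:.2f} mM (pump on)")
    kmax = truth.kappa_true.max()
    print(f"peak in-band kappa {kmax:.2e} at "
          f"{truth.loc[truth.kappa_true.idxmax(), 'wavelength_nm']:.0f} nm; "
          f"pump integrated irradiance {pump.total_irradiance:.0f} W/m^2")
    print(f"wrote config + spectra + truth table under {OUT}/")


if __name__ == "__main__":
    main()
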