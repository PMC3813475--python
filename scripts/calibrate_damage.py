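"""Calibrate the Arrhenius frequency factor to the clinical operating point.

The activation energy is fixed at the published liver value (2.577e5 J/mol).
The frequency factor A is chosen so that, on the standard one-fiber regimen
with default tissue constants, the Ω = 1 damage boundary coincides with a
peak temperature of ~52.5 °C — the threshold the peak-temperature model and
the damage integral agree on for this procedure.  With first-order kinetics Ω
is linear in A, so A* = target / Ω_{A=1} evaluated at the 52.5 °C peak
isotherm.  The result is frozen as ``littherm.dose.DEFAULT_FREQUENCY_FACTOR``.

Run:  python scripts/calibrate_damage.py
"""

import numpy as np

from littherm.dose import DamageModelParams, arrhenius_omega
from littherm.phantom import (
    ApplicatorGeometry,
    LaserRegimen,
    TissueParams,
    solve_pennes,
)

TARGET_PEAK_C = 52.5


def main() -> None:
    series = solve_pennes(
        TissueParams(), [ApplicatorGeometry()], LaserRegimen(), dt=1.0
    )
    peak = series.frames.max(axis=0)
    # Ω with A = 1 (Ω scales linearly in A)
    unit = DamageModelParams(frequency_factor=1.0)
    omega_unit = arrhenius_omega(series.frames, series.times, unit)
    band = (peak >= TARGET_PEAK_C - 0.5) & (peak <= TARGET_PEAK_C + 0.5)
    a_star = 1.0 / np.median(omega_unit[band])
    print(f"voxels in {TARGET_PEAK_C}±0.5 °C peak band: {band.sum()}")
    print(f"calibrated frequency factor A = {a_star:.3e} 1/s")

    cal = DamageModelParams(frequency_factor=float(a_star))
    omega = omega_unit * a_star
    boundary = (omega >= 0.8) & (omega <= 1.25)
    print(
        "peak T on the Ω≈1 boundary: "
        f"median {np.median(peak[boundary]):.2f} °C, "
        f"range {peak[boundary].min():.2f}-{peak[boundary].max():.2f} °C"
    )


if __name__ == "__main__":
    main()
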