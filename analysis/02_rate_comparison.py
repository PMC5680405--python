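#!/usr/bin/env python
"""Stage 2 — GDNF distribution at 0.1, 1, 3 and 5 uL/min.

Simulates one 0.105 mL infusion per rate and tabulates the C_norm = 0.5
radius, minimal Peclet number, high-concentration and total distribution
volumes, the homogeneity ratio, and — for delivery of the projected
0.13 mL per catheter — the infusion time and infusate volume cleared.

Writes results/rate_comparison.csv and per-rate profile CSVs.
"""

from pathlib import Path

from cedsim.experiments import run_rate_comparison
from cedsim.solver import ConcentrationProfile

RESULTS = Path(__file__).resolve().parent.parent / "results"
PROFILE_STRIDE = 6  # thin the saved radial grid; full resolution stays in memory


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    result = run_rate_comparison()
    result.table.to_csv(
        RESULTS / "rate_comparison.csv", index=False, float_format="%.10g"
    )
    for rate, profile in result.profiles.items():
        thinned = ConcentrationProfile(
            radii=profile.radii[::PROFILE_STRIDE],
            times=profile.times,
            values=profile.values[:, ::PROFILE_STRIDE],
            phases=list(profile.phases),
        )
        thinned.to_csv(RESULTS / f"profile_rate_{rate:g}.csv")

    print(result.table.round(4).to_string(index=False))
    table = result.table.set_index("rate_ul_min")
    print()
    print(
        "homogeneity rises from "
        f"{table.loc[0.1, 'homogeneity_ratio']:.0%} at 0.1 uL/min to "
        f"{table.loc[5.0, 'homogeneity_ratio']:.0%} at 5 uL/min: convection"
    )
    print("dominates at CED rates (Pe >> 1) and squares off the profile,")
    print("while at 0.1 uL/min diffusion broadens and dilutes the front.")
    print(
        "infusate cleared while delivering 0.13 mL: "
        + ", ".join(
            f"{table.loc[q, 'lost_volume_ml']:.3f} mL at {q:g} uL/min"
            for q in (1.0, 3.0, 5.0)
        )
    )


if __name__ == "__main__":
    main()
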