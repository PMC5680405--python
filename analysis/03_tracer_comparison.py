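#!/usr/bin/env python
"""Stage 3 — how well does the MRI tracer Gd-DTPA predict GDNF spread?

Simulates the same 5 uL/min, 0.105 mL infusion for r-metHuGDNF (30.4 kDa)
and Gd-DTPA (938 Da; ~6-fold larger effective diffusivity) and compares
their distribution volumes at the C_norm = 0.1 threshold immediately after
the infusion and 2 h later, with elimination off (it affects both species
equally over this window).

Writes results/tracer_comparison.csv.
"""

from pathlib import Path

from cedsim.experiments import run_tracer_comparison

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    comparison = run_tracer_comparison()
    frame = comparison.to_frame()
    frame.to_csv(RESULTS / "tracer_comparison.csv", index=False, float_format="%.10g")

    print(frame.round(3).to_string(index=False))
    r0, r2 = comparison.ratio[0], comparison.ratio[-1]
    g_drug = comparison.vd_drug[-1] / comparison.vd_drug[0]
    g_tracer = comparison.vd_tracer[-1] / comparison.vd_tracer[0]
    print()
    print(f"Vd ratio (tracer/drug): {r0:.2f} at T=0, {r2:.2f} at T=2 h")
    print(f"2-h Vd growth: {g_drug:.2f}-fold for the drug, {g_tracer:.2f}-fold for the tracer")
    print("during infusion bulk flow carries both species alike, so the tracer")
    print("is most faithful immediately post-infusion; afterwards its faster")
    print("diffusion makes it overpredict the drug's coverage.")


if __name__ == "__main__":
    main()
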