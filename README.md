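# cedsim

Modelling toolkit for **convection-enhanced delivery (CED)** of
r-metHuGDNF (glial cell line-derived neurotrophic factor, a ~30.4 kDa
Parkinson's disease drug candidate) into the human putamen, with the MRI
contrast agent Gd-DTPA as its imaging surrogate.

CED drives drug through brain tissue by pressure-driven bulk flow from a
catheter tip, reaching far beyond what diffusion alone can cover. The
questions this package addresses, for scientists planning or interpreting
intraputamenal infusions:

* how fast is GDNF cleared from the striatum, and by what route;
* how does the infusion rate shape the concentration profile — how uniform
  is the covered volume, and how much drug is lost during the infusion;
* what distribution *shape* (sphere vs reflux cylinder) best fits the
  posterior dorsal putamen without overflowing it;
* how faithfully does a small MRI tracer predict the protein's coverage.

## Model

With an isotropic target, negligible binding and a spherically symmetric
source of radius $r'_0$, interstitial fluid continuity gives the radial
velocity $v_r = Q / (4\pi\phi r^2)$ and the normalized interstitial
concentration $C = C_\mathrm{ISF}/C_0$ obeys

$$
\frac{\partial C}{\partial t}
  = \frac{D}{\lambda^2}\,\frac{1}{r^2}\frac{\partial}{\partial r}
    \!\left(r^2 \frac{\partial C}{\partial r}\right)
  - v_r \frac{\partial C}{\partial r} - kC ,
$$

where $Q$ is the volumetric infusion rate, $\phi$ tissue porosity, $D$ the
free diffusivity, $\lambda$ tortuosity, and $k$ a first-order elimination
rate. After the pump stops the same equation runs with $v_r = 0$. The
convection/diffusion balance is summarised by the Peclet number
$Pe = Q / (4\pi\phi (D/\lambda^2) r)$.

Around that PDE core the package provides: two-compartment PK fitting and
the interstitial-bulk-flow clearance estimate ($k = Q_\mathrm{ISF}/V_\mathrm{ISF}$);
the closed-form infusion-phase loss
$A_\mathrm{Loss}(t) = Q C_0 (V_d/V_i)\,(t - (1-e^{-kt})/k)$; distribution
volumes $V_d = \tfrac{4}{3}\pi r^3$ at concentration thresholds; and
sphere/cylinder coverage models of the putamen target. A synthetic-data
module generates the striatal PK study design the fitting stage expects.

## Worked example

```python
from cedsim import (InfusionProtocol, TissueModel, get_molecule,
                    solve_infusion, summarize_distribution)

tissue = TissueModel()                      # phi=0.3, k=3.72e-2/h, Vd/Vi=3.87
gdnf = get_molecule("r-metHuGDNF")
protocol = InfusionProtocol(rate=5.0, infusion_volume=0.105)  # uL/min, mL

profile = solve_infusion(protocol, tissue, gdnf)
s = summarize_distribution(profile, protocol, tissue, gdnf)
print(f"r(C=0.5) = {s.r_half:.3f} cm, Pe_min = {s.peclet_min:.0f}, "
      f"homogeneity = {s.homogeneity_ratio:.0%}")
```

prints

```
r(C=0.5) = 0.450 cm, Pe_min = 183, homogeneity = 67%
```

i.e. a 5 uL/min infusion of 0.105 mL pushes a near-square front to ~0.45 cm
(the mass-conserving advective limit), transport is convection-dominated
($Pe \gg 1$), and two-thirds of the covered volume sits within 5% of the
infusate concentration. The full analysis sequence lives in `analysis/`:

```bash
python analysis/01_fit_elimination_kinetics.py   # k10 fit vs ISF-flux route, t1/2 ~ 19 h
python analysis/02_rate_comparison.py            # profiles & homogeneity at 0.1-5 uL/min
python analysis/03_tracer_comparison.py          # Gd-DTPA vs GDNF Vd at T=0 and T=2 h
python analysis/04_target_geometry.py            # sphere vs cylinder in the putamen box
```

Each writes its tables under `results/`. A `cedsim` command-line interface
exposes the same stages (`cedsim rate-compare --config run.yaml`, `cedsim
pk-fit data.csv`, `cedsim synth`, ...).

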