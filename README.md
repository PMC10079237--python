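# wpcf

Spatial statistics for point patterns whose points carry both categorical
and continuous labels — typified by multiplex images of tumours in which
each cell has a type (vessel, tumour, stromal, necrotic, macrophage) and
macrophages additionally carry a continuous phenotype `p ∈ [0, 1]` from
anti-tumour (M1, `p ≈ 0`) to pro-tumour (M2, `p ≈ 1`).

The package provides, for researchers analysing such data or building
simulation models of it:

* the **cross pair correlation function** with an exact border correction,

  `g_QQ'(r) = (1 / N_Q N_Q') Σ_i Σ_j (A / A_r(x_i)) Θ(Q,q_i) Θ(Q',q_j) I_r(|x_i−x_j|)`,

  where annuli `[r, r+dr)` are centred on source points, targets are
  counted, and `A_r(x_i)` is the annulus area inside the observation
  window; `g = 1` means no correlation, `> 1` clustering, `< 1` exclusion;

* the **weighted pair correlation function (wPCF)**, which generalises the
  source indicator to a weight `w_p(P, p_i) = max(1 − |P − p_i|/ΔP, 0)`
  measuring how close a continuous mark is to a target value `P`:

  `wPCF(r, P, Q') = (1 / W_P N_Q') Σ_i Σ_j (A / A_r(x_i)) w_p(P, p_i) Θ(Q',q_j) I_r(|x_i−x_j|)`,

  with `W_P = Σ_i w_p(P, p_i)`. The result is a surface over `(P, r)` that
  reads as a continuum of cross-PCFs, one per phenotype;

* an **off-lattice agent-based model** of a growing tumour in vascularised
  tissue: overdamped cell mechanics, five reaction–diffusion fields
  (oxygen, CSF-1, CXCL12, TGF-β, EGF), CSF-1–dependent macrophage
  extravasation, TGF-β–driven phenotype conversion, phenotype-dependent
  chemotaxis and tumour-cell killing. Depending on macrophage parameters
  the model reproduces the three Es of immunoediting — Equilibrium,
  Escape (perivascular niches and tumour cells reaching vessels) and
  Elimination;

* a **classification pipeline**: the *PCF signature*
  `{wPCF(r,p,B), wPCF(r,p,T), g_BT(r)}` of a snapshot is flattened into a
  38,773-entry vector (default grids: 191 radial bins × 101 phenotype
  values), reduced with PCA, and classified into the three Es with an
  RBF-kernel SVM; time series of signatures trace trajectories through the
  reduced space.

## Worked example: recovering a known phenotype–distance law

200 crosses (category B) sit on the line y = 1 of a 2×2 square; 1000
circles (category M) are uniformly random with mark equal to their
distance from the line. The wPCF should therefore peak along `P = r`:

```python
import numpy as np
from wpcf import RadialBinning, wpcf
from wpcf.fixtures import LinePatternSpec, make_line_pattern

cloud = make_line_pattern(LinePatternSpec(variant="linear", seed=1))
binning = RadialBinning(dr=0.05, n_bins=17)
surface = wpcf(cloud, "B", binning)
for k in (4, 8, 12, 16):
    r = binning.inner_radii[k]
    ridge = surface.P_grid[np.nanargmax(surface.values[:, k])]
    peak = np.nanmax(surface.values[:, k])
    print(f"r = {r:.2f}: wPCF peaks at P = {ridge:.2f} (value {peak:.1f})")
```

```
r = 0.20: wPCF peaks at P = 0.12 (value 3.7)
r = 0.40: wPCF peaks at P = 0.35 (value 2.4)
r = 0.60: wPCF peaks at P = 0.57 (value 2.9)
r = 0.80: wPCF peaks at P = 0.76 (value 3.5)
```

At every distance the surface peaks within the kernel half-width
(ΔP = 0.2) of the constructed law, and the peak values ≈ 2–4 indicate
strong clustering of the matching marks relative to spatial randomness.

Simulating an Elimination regime (strong extravasation, moderate
chemotaxis) and labelling the snapshots:

```python
from wpcf.abm import ABMParams, run
from wpcf.pipeline import auto_label

snapshots = run(ABMParams(chi_c_m=1.5, c_half=0.3), t_end=150, snapshot_every=50, seed=0)
for s in snapshots:
    print(f"t = {s.time:5.1f} h  tumour {s.count('T'):3d}  macrophages {s.count('M'):3d}  -> {auto_label(s)}")
```

```
t =   0.0 h  tumour  30  macrophages   0  -> Equilibrium
t =  50.0 h  tumour  81  macrophages  77  -> Equilibrium
t = 100.0 h  tumour  11  macrophages 160  -> Equilibrium
t = 150.0 h  tumour   0  macrophages 169  -> Elimination
```

The tumour grows while macrophages are recruited, is then overwhelmed by
the M1 infiltrate, and is fully eliminated by 150 h.

A command-line interface mirrors the library
(`wpcf fixtures`, `wpcf pcf`, `wpcf abm run`, `wpcf sweep`,
`wpcf signature`, `wpcf model`, `wpcf plot`); every run writes a JSON
manifest with the parameters and seed needed to reproduce it.

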