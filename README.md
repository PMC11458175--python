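# subdki

Robust mapping of diffusional mean kurtosis from multi-shell,
multi-diffusion-time diffusion-weighted MRI, via the anomalous
sub-diffusion signal model.

## The problem

Diffusional kurtosis imaging (DKI) quantifies non-Gaussian water diffusion
in tissue through the quadratic signal model

```
S(b) ≈ S0 · exp(−b·D_DKI + b²·D_DKI²·K_DKI / 6)
```

but the quadratic form is only valid for b ≲ 2000–3000 s/mm², the fit is
noise-sensitive, and it cannot pool data acquired at different diffusion
times. The sub-diffusion (continuous-time random walk) framework instead
models the powder-averaged signal as

```
S(q, Δ̄) = S0 · E_β(−D_β q² Δ̄^β),     b = q² Δ̄,   Δ̄ = Δ − δ/3
```

where `E_β` is the single-parameter Mittag-Leffler function, `β ∈ (0, 1]`
the fractional order, and `D_β` (mm²/s^β) the anomalous diffusion
coefficient. Mean kurtosis and diffusivity then follow in closed form:

```
D_SUB = D_β Δ̄^(β−1)        D* = D_SUB / Γ(1+β)
K*    = 6 Γ²(1+β) / Γ(1+2β) − 3
```

`K*` depends on `β` alone and is diffusion-time independent. Because the
model is valid at arbitrarily high b and its objective sums observations
over any number of diffusion times, two short acquisitions at distinct Δ
yield a more robust kurtosis map than a long single-Δ protocol. The
package targets researchers analysing multi-diffusion-time DWI (e.g. the
Connectome-style two-Δ protocol: Δ = 19/49 ms, δ = 8 ms, 8 b-shells per Δ)
and anyone designing reduced b-value sampling schemes for fast kurtosis
mapping.

## What's inside

| module | contents |
| --- | --- |
| `subdki.mittleff` | accurate `E_β(z)` on the negative real axis (Taylor series + spectral-integral quadrature) |
| `subdki.models` | forward signals, `K*`/`D*`/`D_SUB` closed forms, acquisition schemes, bval/bvec/timing serialization |
| `subdki.fitting` | powder averaging, bounded trust-region NLLS fits (sub-diffusion joint multi-Δ, DKI comparator), voxelwise volume mapping |
| `subdki.simulate` | noise model σ = 1/(SNR·√N_DIR) and the Monte-Carlo experiments: diffusion-time count, Δ1/Δ2 grid, b-subset optimisation, DKI time-dependence |
| `subdki.stats` | R² of kurtosis recovery, pooled region statistics, tissue contrast, scan–rescan voxelwise ICC |
| `subdki.volume_io` | NIfTI + sidecar I/O, provenance-stamped map writing, antipodal direction downsampling |
| `subdki.phantom` | synthetic two-tissue phantom and scan–rescan generators |
| `subdki.cli` | `subdki fit / simulate / optimize-b / icc / make-fixtures` |

## Worked example

Simulate one voxel on the two-diffusion-time Connectome scheme at SNR 20
from a white-matter-like truth (D_β = 3·10⁻⁴ mm²/s^0.75, β = 0.75,
K* = 0.8125), then fit it back:

```python
import subdki as sk

scheme = sk.connectome_scheme()                    # b=0 + 8 shells per Δ
truth = sk.SubDiffParams(d_beta=3e-4, beta=0.75)
signal = sk.simulate_signal(truth, scheme,
                            sigma=sk.noise_sigma(20, 64), rng=7)
fit = sk.fit_subdiffusion(signal, scheme)
p = fit.params
print(f"D_beta = {p.d_beta:.4e} mm^2/s^beta")
print(f"beta   = {p.beta:.4f}")
print(f"K*     = {sk.k_star(p.beta):.4f}")
print(f"D*(19 ms) = {p.d_star((19 - 8/3) * 1e-3):.4e} mm^2/s")
```

prints

```
D_beta = 2.9678e-04 mm^2/s^beta
beta   = 0.7447
K*     = 0.8310
D*(19 ms) = 9.2451e-04 mm^2/s
```

i.e. the fitted fractional order 0.745 (truth 0.75) maps to a mean
kurtosis of 0.83 (truth 0.8125) and a 19-ms diffusivity of
0.92·10⁻³ mm²/s — one noisy 17-volume measurement pins kurtosis to a few
percent. The same fit runs voxelwise over a 4-D volume with
`sk.fit_volume(...)` or from the shell:

```
subdki make-fixtures --snr 20 --out work/
subdki fit --dwi work/phantom.nii --bval work/phantom.bval \
    --bvec work/phantom.bvec --timing work/phantom_timing.csv \
    --out work/maps
```

which writes `Dbeta.nii`, `beta.nii`, `Kstar.nii`, `Dstar_*.nii`,
`rmse.nii` and a provenance JSON.

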