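# dwifit

Self-supervised, physics-informed fitting of diffusion MRI signal
models: the diffusion tensor (DTI), the diffusion kurtosis model (DKI)
and Watson-NODDI.

## The problem

Diffusion MRI measures, in every voxel, signals S = [S₁ … Sₙ] along
encoding directions **v**ᵢ at b-values bᵢ.  Microstructural parameter
maps are obtained by inverting a forward model f(P, **v**ᵢ, bᵢ) per
voxel — conventionally with linearized least squares (fast but noisy)
or exhaustive nonlinear search (accurate but hours-slow for
multi-compartment models).  dwifit instead trains a small convolutional
network G to map the measured volumes directly to parameter maps,
P̂ = G(S), and optimizes the network by minimizing the masked
discrepancy between the measured signals and the signals the forward
model re-synthesizes from P̂:

    L = (1/n) Σᵢ MSE over masked voxels of (Sᵢ, f(G(S), vᵢ, bᵢ))

No reference parameter maps are needed (self-supervision), the physics
enters through f (tensor, kurtosis, or Watson-NODDI forward model), and
because one network serves all voxels the estimates are regularized
across voxels — which denoises relative to independent per-voxel fits.
Keeping dropout active at inference and averaging l = 20 passes
(MC dropout) gives a further-stabilized estimate plus a per-voxel
uncertainty map from the spread of the passes.

The package also contains everything needed to test the method without
any data downloads: classical estimators (OLS tensor fit, IWLS kurtosis
fit, brute-force NODDI grid search) as baselines and oracles, a
multi-tensor phantom simulator with known ground truth, the standard
scalar maps (FA, MD, AD, V1, MK, AK, RK, ODI) and the evaluation
statistics (masked MAE with outlier-exclusion rules, angular error,
SSIM on standardized images).

For whom: researchers fitting microstructure models who want fast,
denoised parameter maps from sub-sampled acquisitions, and developers
who want a transparent, dependency-light reference implementation of
self-supervised model fitting (the autodiff/NN core is plain numpy).

## Worked example

Simulate a 12³-voxel multi-tensor phantom at SNR 10, keep 2 b=0 and 30
b=1000 s/mm² volumes (sub-sampled regime), fit it with OLS and with the
self-supervised network, and compare both FA maps against the
noise-free ground truth:

```bash
cat > sim.yaml <<EOF
grid: [12, 12, 12]
snr: 10.0
seed: 42
EOF
cat > net.yaml <<EOF
model: tensor
M: 0
N: 7
c1: 32
c2: 64
c3: 64
p: 0.05
EOF
cat > train.yaml <<EOF
stage1_blocks: 1500
stage2_blocks: 500
block_size: 8
EOF

dwifit simulate --out-dir phantom --spec-yaml sim.yaml --n-b0 2 --n-dwi 30
dwifit fit --dwi phantom/dwi.nii.gz --bval phantom/dwi.bval \
  --bvec phantom/dwi.bvec --brain-mask phantom/brain_mask.nii.gz \
  --model dti --method ols --out-dir fit_ols
dwifit fit --dwi phantom/dwi.nii.gz --bval phantom/dwi.bval \
  --bvec phantom/dwi.bvec --brain-mask phantom/brain_mask.nii.gz \
  --model dti --method selfsup --net-yaml net.yaml --train-yaml train.yaml \
  --seed 7 --out-dir fit_selfsup
dwifit evaluate --result fit_ols/fa.nii.gz \
  --reference phantom/truth_fa.nii.gz \
  --mask phantom/tissue_mask.nii.gz --out-csv eval.csv
dwifit evaluate --result fit_selfsup/fa.nii.gz \
  --reference phantom/truth_fa.nii.gz \
  --mask phantom/tissue_mask.nii.gz --out-csv eval.csv
```

Output of the two `evaluate` calls:

```
mae: 0.070268
ssim: 0.847107
mae: 0.0537674
ssim: 0.900372
```

The first pair is OLS against the ground truth (FA mean absolute error
0.070, SSIM 0.847); the second is the self-supervised MC-dropout fit
(FA MAE 0.054, SSIM 0.900): at this noise level and volume count the
network fit is clearly more accurate, reproducing the method's central
claim.  `fit_selfsup/` additionally contains the per-voxel uncertainty
maps (`params_uncertainty.nii.gz`, the standard deviation over the 20
dropout inferences) and a reusable checkpoint (`checkpoint.npz`) that
can be transferred to another subject via `--pretrained` /
`--finetune`.

The same `fit` command handles the other models (`--model dki` with
`--loss cwls` for the constrained weighted kurtosis fit; `--model
noddi`; `--method iwls|grid` for the classical baselines).

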