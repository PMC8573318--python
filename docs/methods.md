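# Methods

`epactive` estimates the posterior density of spatially varying cardiac
tissue excitability from multi-lead ECG, using a Gaussian-process (GP)
surrogate of the posterior over a low-dimensional generative latent space,
trained by Bayesian active learning. This note records the model, the
numerical choices, and what the synthetic test bed does and does not
establish.

## Forward model

Transmembrane potential u and recovery current v follow the two-variable
Aliev–Panfilov (AP) reaction–diffusion model

    du/dt = d · (−L u) − c·u(u−θ)(u−1) − u·v + I_stim
    dv/dt = ε(u,v)·(−v − c·u(u−θ−1)),   ε = e0 + μ1·v/(u+μ2)

with the standard constants c = 8, e0 = 0.002, μ1 = 0.2, μ2 = 0.3. The
per-node excitability θ ∈ [0, 0.5] is the estimand: θ ≈ 0.15 is healthy,
θ ∈ [0.4, 0.5] marks infarcted (inexcitable) tissue.

The spatial operator is a weighted graph Laplacian L on a symmetric
k-nearest-neighbor graph (k = 6) over the node cloud, with inverse-square-
distance edge weights rescaled to unit mean degree; the diffusion
coefficient is a single scalar d (anisotropy is out of scope). Time
stepping is explicit forward Euler. Defaults — d = 4, dt = 0.01 model
units, horizon t_end = 60, stimulus 3.0 for 2.0 time units on an apical
pacing *region* (apex node plus its graph neighbors) — were chosen so
that a uniformly healthy ventricle fully captures (last activation ≈ 21
units, complete action potential inside the horizon) and so that a
quarter-step reference integration agrees to < 1% relative L2 error. The
step obeys dt < 2/(d·λ_max) with λ_max the top Laplacian eigenvalue;
violating it raises before integration starts.

A property worth knowing: under the fixed AP constants, plane-wave
propagation fails for uniform θ ≳ 0.2 at any diffusion strength we
tested — slow fronts are extinguished by recovery-current build-up. That
is the physiology that makes high-θ regions visible in the ECG (they
simply do not activate), and it means "activation delay grows with θ"
holds only inside the propagating regime (θ ≲ 0.19); above it, capture is
lost rather than delayed.

## Measurement model

ECG is the linear map Y(t) = H·u(t). The synthetic transfer matrix places
120 electrodes on a cylinder at 1.2× the node-cloud extent; each row is
the inverse squared electrode-to-node distance, normalized to unit sum,
then referenced against the average lead (Wilson-central-terminal style).
Referencing matters: without it the far-field rows are nearly identical
(effective rank ≈ 1) and the ECG is location-blind; with it the effective
rank rises to ≈ 5 and the inverse problem becomes identifiable.
Observation noise is white Gaussian at a prescribed SNR (20 dB by
default), and σ_e² records the injected per-sample variance.

## Likelihood scale

The latent log-posterior is

    log π(z|Y) = −½ ( ‖Y − M(E[p_β(θ|z)])‖² / σ_eff² + ‖z‖² ),

where M composes the decoder expectation, the AP simulation and the lead
field. The effective variance σ_eff² is a modeling choice because the ECG
residual samples are far from independent: treating all ~12,000 samples
as iid (σ_eff² = σ_e²) collapses the latent posterior to a numerical
near-delta (width far below any workable grid or proposal scale), while
the default `total` scaling (σ_eff² = σ_e² × sample count, i.e. the
exponent is the mean squared residual in noise-floor units) yields an
identifiable posterior with spread of 0.1–0.5 latent units — the regime
in which posterior-*shape* estimation, KDE summaries and the 0.22
acceptance-rate protocol are all meaningful. A `per_lead` intermediate is
available. This is a free parameter of the method, set once from
identifiability measurements on the fixture and exposed as
`LogPosterior(noise_scale=...)`.

## Generative model

Excitability fields are embedded by a VAE: encoder and decoder are
three-layer fully connected networks (512 + 512 softplus hidden units; a
2-D latent code with mean and log-variance heads), trained by Adam
(lr 1e-3, batch 64, up to 100 epochs, early stopping on a 10% validation
split) on a corpus of binary injured/healthy fields from random region
growing (defaults: 10,000 fields, region sizes uniform over 2–40% of
nodes, injured θ = 0.5, healthy θ = 0.15, plus U[0, 0.001] noise). The
decoder likelihood is Gaussian with mean sigmoid-squashed to [0, 0.5] and
a *fixed small variance* (0.1², the scale of the healthy/injured gap).
With a unit-variance likelihood at desk-scale node counts the
reconstruction term is smaller than the latent information cost and
training posterior-collapses; the small fixed variance restores a useful
code. Only the decoder expectation is used downstream. The implementation
is plain NumPy (hand-written backprop): at this network size that is fast
and bit-reproducible under a fixed seed.

The learned code behaves as expected: the latent radius tracks
abnormal-region size (rank correlation ≈ 0.9) and training fields
reconstruct with median Dice ≈ 0.93. Reconstruction degrades below
regions of ~15 nodes (5% of the fixture), which bounds the smallest
abnormality the pipeline can localize — see Limitations.

## GP surrogate and active learning

The GP over the 2-D latent log-posterior uses a zero mean and the
anisotropic Matérn 5/2 kernel; labels are never standardized because
exp(GP) is treated as a log-normal process whose pointwise variance

    Var(z) = (exp σ² − 1)·exp(2μ + σ²)

and entropy  μ + ½ + ln(√(2π)·σ)  are the acquisition functions (the
entropy is implemented in the standard log-normal form; it differs from a
"ln(2πσ)" variant only by the constant ½ln(2π), which cannot change an
argmax). A GP upper-confidence-bound μ + κσ (κ = 2) is the regular
Bayesian-active-learning baseline. Acquisition argmaxes are taken on a
60×60 grid over [−3.5, 3.5]² (which covers > 99.9% of the latent prior
mass) with L-BFGS refinement from the best three cells; for the
log-normal variance the argmax is computed on the log scale because the
natural-scale value under/overflows float64. Inference uses Cholesky
factorization with escalating jitter; hyperparameters (per-dimension
length scales in [0.05, 10], amplitude², noise variance in [1e-8, 0.1])
are refit after every new training point by 5-start bounded L-BFGS on the
evidence, never accepting a decrease. The amplitude bound must reach the
squared label scale — unstandardized log-posterior labels are large — so
its upper bound is 1e14.

The loop starts from a 3×3 design on [−2, 2]², then iterates select →
simulate → update → refit until the KL divergence between the current
normalized density exp(μ(z)) on the grid and the average of the previous
five such densities falls below 1e-3 (at least six iterations; cap 500).

## MCMC baselines

Random-walk Metropolis–Hastings with an isotropic Gaussian proposal whose
variance is tuned by bisection on cheap surrogate chains to a 0.22 ± 0.03
acceptance rate. The protocol runs two chains (10,000 steps at full
scale; shorter in the desk benchmark), discards the first 20%, keeps
every second sample, and pools; Geweke (first 10% vs last 50%) and
Gelman–Rubin diagnostics are computed per dimension on the post-burn-in
chains. Chains are initialized jittered around the surrogate's best
training points rather than from prior draws: prior-drawn starts
intermittently freeze delayed-acceptance chains on local maxima of the
surrogate (observed acceptance ≈ 0.01 over a whole chain), and the
surrogate's labels are available at zero simulation cost.

Two-stage sampling is standard delayed acceptance: candidates are
screened by the MH ratio of the surrogate density exp(GP mean), and
survivors pay one exact simulation with the correction ratio that
preserves the exact stationary law. The fraction of proposals reaching
stage 2 is close to the surrogate-chain acceptance at the tuned proposal
but exceeds it when the surrogate is smoother than the exact posterior
(the chain lives where the surrogate's local ratios are mild): measured
stage-2 fractions on the fixture range from ≈ 0.3 (multi-segment cases)
to ≈ 0.55 (single-segment case), i.e. simulation reductions of 45–70%.

## Summaries and metrics

Latent summaries use Gaussian KDE with Scott's-rule bandwidth (mode on a
200×200 refined grid); field summaries push latent samples through the
decoder expectation (mean/std per node; mode field decodes the KDE mode).
KL between sample sets is the sampled KDE estimator (draw from the p-KDE,
average log p/q). Field accuracy uses Dice at threshold 0.3 (midway
between healthy 0.15 and the lowest test severity 0.4), RMSE, and Pearson
correlation; vector summary errors use the Euclidean norm.

## Synthetic test bed and problem sizes

The fixture is an LV-like half-ellipsoidal shell (300 nodes by default;
200 in property tests) with approximate AHA 17-segment labels from
long-axis thirds and circumferential sectors. Benchmark cases place
severity-0.45 abnormalities on contiguous multi-segment regions
({1,2,7}, {8,9,14}, {4,5,10}; 15–25% of nodes) — single segments at this
resolution (~6% of nodes) sit at the identifiability limit and are used
only in the dedicated single-segment recovery check (segment 1, the
largest basal segment).

Problem sizes are scaled to a desk: the test suite trains the VAE on a
4,000-field corpus (60 epochs) and runs 2×1,500-step reference chains;
the acceptance script uses the full 10,000-field corpus and 2×2,000-step
two-stage chains. The 2×10,000 protocol remains the (protocol-defined)
denominator of computation-reduction figures.

What passing these tests shows: the machinery — forward model, generative
embedding, GP surrogate, acquisitions, delayed acceptance, summaries — is
internally correct against closed-form and brute-force oracles, and the
end-to-end pipeline localizes moderate abnormalities on clean synthetic
geometry. What it does not show: performance on image-derived anatomies,
heterogeneous/non-transmural scar, model mismatch beyond the
severity-vs-training gap, or real ECG noise structure.

## Known limitations

- Abnormalities below ~5% of nodes are at the edge of what the 2-D latent
  code can localize; posterior peaks for such cases are narrow (σ ≈ 0.1
  latent units) and the grid-based KL stopping rule can fire while the
  surrogate is still oversmoothed, so single-segment recovery varies
  across noise realizations.
- The acquisition-count ordering between UCB and the log-normal
  acquisitions depends on the label scale: with large unstandardized
  log-posterior ranges, κσ dominates UCB early and makes it nearly as
  exploratory as the log-normal variance, eroding the expected
  UCB-needs-more-steps gap.
- On the multi-segment benchmark the log-normal *variance* acquisition
  yields the least accurate surrogate density of the three rules
  (sampled KL to the direct-MCMC reference ≈ 2 vs ≈ 0.2 for the entropy
  rule): its argmax objective 2μ + log σ² is doubly exploitative at
  this label scale, leaving interpolation bumps in sparsely sampled
  mid-range regions that the surrogate-sampling chains then visit. The
  entropy acquisition does not show this pathology.
- The graph-Laplacian AP model is phenomenological; time is in model
  units with no millisecond calibration, and the lead field is a
  monopole-distance surrogate, not a boundary-element torso model.
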