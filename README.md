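# thermospike

Temperature dependence of spike generation in a Connor–Stevens model
neuron: full-factorial Q10 parameter sweeps scored for firing-rate
robustness (RMSD), energetic cost and information transfer, a grid-based
elementary-effects sensitivity analysis with dimensional-stacking
visualization, genetic-algorithm RMSD minimization, reverse-engineering
of a sigmoidal mechanotransduction stage, and an analysis pipeline for
(synthetic) intracellular receptor-neuron recordings.

## What it does

The spike generator is a single-compartment Connor–Stevens model
(transient Na⁺, delayed-rectifier K⁺, A-type K⁺, leak) defined at
18 °C. Temperature scaling acts on nine Q10 coefficients — one per peak
conductance (range [1.2, 2.0]) and one per gating variable's opening and
closing rates (range [2.0, 4.0]) — plus a Nernst factor on the reversal
potentials. For each of the 4⁹ = 262,144 Q10 combinations the f-I curve
(12 step currents, 0.05–0.60 µA/mm², 100 ms stimuli, dt = 0.01 ms RK4)
is simulated at 18 and 28 °C and summarized by:

- **RMSD** — RMS firing-rate difference across currents, normalized by
  the mean cold rate;
- square-root fits `f = A·√(I − I0)` and the Q10s of slope and
  threshold;
- **energy measures** — Na⁺ load per spike, charge-separation
  efficiency, and resting-potential costs from the fixed point of the
  membrane equation;
- **Fisher information** — closed-form averages for Poisson/Gaussian
  rate noise, whose Q10 is `Q10(A)⁴`.

Per-parameter *impact scores* (normalized medians of neighboring-grid
differences) rank what controls each observable, and dimensional
stacking renders the full nine-dimensional grid as one image with
high-impact parameters on the large-scale axes. A transduction sigmoid
(sound intensity → receptor current) is fitted per model so that the
composed rate-level curve matches a representative receptor response at
each temperature.

`thermospike.synth` generates recording-like datasets (9 neurons,
8 intensities at 32–88 dB SPL, 5 trials, two temperatures, sigmoidal
rate-level structure with known parameter Q10s, trial noise, stylized
AP waveforms), and `thermospike.analysis` recovers rate-level sigmoids,
Q10 statistics with box-plot/rank-test conventions, AP-width Q10s and
adaptation ratios from them.

## CLI

```sh
thermospike sweep --steps 2 --out runs/smoke      # 512-model smoke sweep
thermospike all --steps 2 --out runs/full         # sweep -> impacts -> stack -> transduce -> synth -> analyze
thermospike minimize --seed 0                     # GA minimization of the RMSD
thermospike impacts --sweep-dir runs/smoke        # impact scores of a saved sweep
thermospike stack --sweep-dir runs/smoke --observable rmsd --out stack.png
thermospike info --a 1 --fmin 1 --fmax 2          # closed-form mean Fisher information
thermospike synth --out data/ --seed 1            # synthetic recordings
thermospike analyze --data data/ --out report/
```

Pipeline configuration can also be given as YAML (`thermospike all
--config cfg.yaml`); defaults reproduce the published setting
(18/28 °C, 4-step grid, N = 12 currents, dt = 0.01 ms).

## Layout

| module | role |
| --- | --- |
| `thermospike.model` | model equations, temperature scaling, simulation, spike detection, f-I curves |
| `thermospike._engine` | numba RK4 kernels (single-trace and batched sweep; shared derivative) |
| `thermospike.sweep` | Q10 grid, RMSD, factorial sweep, perturbed references, genetic algorithm |
| `thermospike.sensitivity` | impact scores, dimensional stacking |
| `thermospike.energetics` | Na⁺ load/spike, charge separation, resting potential and costs |
| `thermospike.information` | mean Fisher information closed forms, capacity bound |
| `thermospike.transduction` | representative responses, composed rate-level curves, sigmoid inversion |
| `thermospike.synth` | synthetic recording generator with ground truth |
| `thermospike.analysis` | spike extraction, sigmoid fits, Q10 statistics, waveform metrics |
| `thermospike.cli` | pipeline orchestration and `thermospike` console script |
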