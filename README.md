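# dermapattern

Computational analyses of periodic pattern formation in embryonic skin —
how an array of hair-follicle primordia emerges from interacting BMP, FGF,
and WNT signalling and from the self-organisation of motile dermal
mesenchymal cells. The package is written for developmental and systems
biologists who want to re-run, probe, or extend the quantitative parts of
that analysis: signed network inference from perturbation screens, Turing
linear stability analysis, PDE simulation of both patterning mechanisms,
windowed cell-trajectory statistics, transcript half-life estimation, and
particle image velocimetry.

## The analyses

**Signed network inference.** Six-hour pathway stimulation/inhibition
experiments give per-gene fold changes; a gene is called regulated when
*p* < 0.05 and the ratio is ≥ 1.8-fold (or ≤ 1/1.8). Gene-level edges are
collapsed onto five species — BMP, WNT, WNT inhibitor, BMP inhibitor, FGF —
giving a 5×5 sign matrix *M* with entries in {−1, 0, +1}.

**Turing stability.** The linearization `du/dt = J u + diag(d) ∇²u` has,
for a spatial mode of wavenumber *k*, growth rate
`λ(k) = max Re eig(J − k² diag(d))`. Diffusion-driven instability means
λ(0) < 0 while λ(k) > 0 in a finite band; the peak k* predicts the pattern
wavelength 2π/k*. `turing.scan_parameters` samples magnitudes, decays and
diffusivities log-uniformly over the sign structure *M* and reports how
often the network supports instability.

**Two pattern-forming mechanisms.** `rd.simulate_rd` integrates the
network with saturating kinetics (`φ(x) = s·tanh(x/s)` preserves J at the
steady state); `chemotaxis.simulate_chemotaxis` integrates the
volume-filling Keller–Segel model

    ∂ρ/∂t = D_ρ ∇²ρ − ∇·( χ₀ (1 − ρ/ρ_max) ρ ∇c )
    ∂c/∂t = D_c ∇²c + α ρ − (δ + bmp) c + sources

in which moving cells themselves are the patterning agents. Shipped
scenarios reproduce the study's perturbations: attractant-loaded bead
sources, BMP-driven erosion of pre-formed condensates, and the cut-edge
experiment that separates the mechanisms (reaction–diffusion foci align
along an inhibitor-sink edge; chemotactic aggregates keep their distance
from a truncated edge).

**Trajectory statistics.** Tracked cells are classed *condensate* (the
track ends inside a condensate ROI; tracking halts on entry) or
*intercondensate*. Each track is cut into 6-h windows counted backward
from entry (or track end), recording the Euclidean angle to the future
condensate centre (0–180°), Euclidean and accumulated distances, and
persistence = Euclidean/accumulated. Directionality is tested with a
one-sample KS test against Uniform(0°, 180°); group contrasts use
Kruskal–Wallis followed by Bonferroni-corrected Mann–Whitney U tests.

**Half-life screen.** After transcription blockade, normalized abundance
follows `exp(−k t)`; `t½ = ln2/k` is fit by log-linear regression through
the origin, and candidates must have t½ ≤ 90 min, encode extracellular
proteins, and be expressed in skin.

**PIV.** Patchwise displacement fields by normalized cross-correlation
with 3-point Gaussian subpixel refinement, temporal path integration, and
radial-inflow readouts over rasterized nuclear-reporter movies.

Every input the pipeline consumes can be generated by
`dermapattern.synthetic` with known ground truth: biased-random-walk
trajectories with a late-onset attraction switch, fold-change tables drawn
from a known sign matrix, exponential decay series, and rendered movies.

## Worked example

The numbered scripts under `analysis/` run the full story; each prints its
findings and writes tables under `results/`. For example:

```
$ python analysis/02_dispersion.py
two-species exemplar: Turing=True, k*=0.528, peak growth 0.334/h, band (0.244, 0.917)
five-species scan: 3/1000 draws Turing-unstable (0.30%)
```

The activator–inhibitor exemplar is unstable to modes with wavenumber
0.24–0.92, fastest at k* = 0.528, i.e. an expected spot spacing of
2π/k* ≈ 11.9 length units — and simulating the same model
(`analysis/03_simulate_patterns.py`) gives an emerged wavelength of 12.6,
5.6% off the linear prediction. The five-species network's sign structure
supports Turing instability in a small pocket of parameter space, matching
its qualitative capability without fine-tuning.

```
$ python analysis/05_track_analysis.py
condensate vs intercondensate Euclidean angles (median corrected p over 20 datasets):
  0-6 h    p = 1.9e-22   (median angles 4 deg vs 88 deg)
  6-12 h   p = 0.0437   (median angles 70 deg vs 95 deg)
  12-18 h  p = 0.274   (median angles 73 deg vs 94 deg)
-> directed movement appears only in the final 6 h before entry
bias-0 null: 49/50 datasets consistent with uniform angles (KS, alpha=0.05)
```

On synthetic tracks whose attraction switches on 6 h before condensate
entry, the pipeline recovers exactly the published structure: strongly
oriented movement (median angle ≈ 4°) only in the last window, and a clean
uniform null when the generator has no bias.

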