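# unghost

Simulation and removal of translational-motion ghosting artifacts in 2-D MRI,
via an iterative, magnitude-preserving, support-constrained phase-correction
of k-space.

## The problem

MRI acquires its raw data in the spatial-frequency domain (k-space), one
phase-encode line at a time, over seconds to minutes. If the patient moves
between line acquisitions, each line sees the object in a different position.
For in-plane translations `(p(k_y), q(k_y))`, the shift theorem turns this
into a line-dependent linear phase error:

    S'(k_x, k_y) = exp(-i 2π (k_x p(k_y) + k_y q(k_y)) / N) · S(k_x, k_y)

The magnitude of k-space is untouched — only the phase is inconsistent — and
the reconstructed image shows displaced, replicated copies of the anatomy
("ghosts") along the phase-encode direction. This matters most where motion
is unavoidable and soft-tissue detail is the point, e.g. pelvic imaging.

## The method

Because the corruption is a pure phase error, `|S'|` equals the motion-free
magnitude exactly. The correction keeps `|S'|` as a hard constraint and
recovers a consistent phase by alternating projections
(error-reduction / Gerchberg–Saxton style):

1. `G_1 = S'`; reconstruct the image by inverse FFT and segment the region of
   interest `R` that contains all true signal (threshold, active contour, or
   level set — or an oracle mask in simulation).
2. Support projection: zero every pixel outside `R`, transform back to
   k-space: `G'_j`.
3. Phase update: `φ' = arg G'_j − arg G_j` (wrapped to `(−π, π]`).
4. Magnitude replacement: `G_{j+1} = exp(i·arg G'_j)·|S'|`; repeat from 2
   until the fraction of image energy outside `R` stops decreasing.

This iteration provably never increases the support-violation energy, and a
motion-free input is a fixed point. Since support + magnitude determine the
image only up to a global translation, all quality metrics register images
by the best integer circular shift before comparing.

A synthetic-phantom generator (disk, multi-ellipse, head-like, pelvis-like
analytic models with exact oracle supports) makes the whole pipeline testable
without clinical data.

## Worked example

```sh
unghost end-to-end --size 128 --model disk --trajectory-model step \
    --amplitude-px 4 --onset 0.5 --axis x --roi-method oracle \
    --out-dir demo
cat demo/report.json
```

prints (exactly, the pipeline is deterministic):

```json
{
  "ghost_ratio_corrected": 0.0002521802813119158,
  "ghost_ratio_corrupted": 0.022725045794605964,
  "iterations_run": 50,
  "nrmse_corrected": 0.14483711435526236,
  "nrmse_corrupted": 0.21120321106818069,
  "registration_shift": [0, -1],
  "relative_reduction": 0.3142286349590301
}
```

Reading: the abrupt 4-pixel shift halfway through the acquisition put 2.3% of
the image energy outside the true object support (`ghost_ratio_corrupted`);
after 50 iterations the correction pushed that to 0.03%, and the registered
normalized root-mean-square error against the ground-truth phantom dropped
from 0.211 to 0.145 — a 31.4% reduction. `registration_shift` is the global
integer translation absorbed before comparison.

The same pipeline is available stage by stage (`unghost phantom generate`,
`unghost simulate corrupt`, `unghost roi extract`, `unghost correct run`,
`unghost evaluate`) and as a library (`unghost.correct`,
`unghost.run_end_to_end`, ...). Images travel as NIfTI-1 or PNG, complex
k-space as a two-channel NIfTI or raw complex64 file with a JSON sidecar,
trajectories and convergence histories as CSV.

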