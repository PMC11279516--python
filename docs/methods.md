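# Methods

This note records the model implemented by `sddseg`, the parameters that
matter, the synthetic scenes the tests run on, and the design choices made
where the method's published description leaves room.

## Pipeline

1. **Denoising** (`preprocess`).  Non-local means with patch size 7,
   search window 21 (pixels).  The filtering strength `h` defaults to
   0.8·σ̂, with σ̂ the wavelet/MAD noise estimate in intensity levels, so a
   noise-free image passes through unchanged and noisier inputs are
   smoothed harder.  The stage can be disabled (`denoise.enabled`).
   Output is re-quantized to the integer level set so all downstream
   histogram arithmetic stays on unambiguous bins.

2. **Candidate discovery** (`sdd`).  The intensity histogram (256 bins;
   one bin per level at 8 bit) is smoothed with a Gaussian of σ = 2 bins —
   raw counts make the slope-difference derivative cross zero spuriously;
   σ = 0 disables it — then max-normalized to `P(n)`.  Least-squares line
   slopes over the `W = 5` points on each side of `n` give
   `s(n) = a_L(n) − a_R(n)`; `ds/dn` is taken by central differences; the
   first/last `W` bins are undefined and excluded.  Candidates are the
   + → − zero crossings of `ds/dn` with `s > 0`, refined to sub-bin
   position by linear interpolation and reported as the nearest integer
   level (ties take the lower level).  A relative floor of 1e-9 of the
   curve maximum keeps float-level wiggle around exact zero from
   producing crossings.  `W` and σ are configurable; 5 and 2 localize
   peaks at 256 bins while suppressing bin noise.

   The method's published account computes `P(n)` from the gradient image
   yet binarizes the intensity image without stating the mapping between
   the two; `sdd.domain` therefore selects the interpretation.  The
   default `intensity` discovers candidates directly on the intensity
   histogram (a threshold must ultimately be an intensity cut);
   `gradient` discovers them on the gradient-magnitude histogram (Sobel,
   1/8-normalized, edge-replicated) and maps a candidate to an intensity
   level by its fractional histogram position.  All quantitative checks
   use the intensity domain.

3. **Range selection**.  Auto mode spans the candidate set
   (A = smallest, B = largest candidate); manual mode takes user limits
   and drops candidates outside.

4. **Threshold selection** (`entropy`).  For a cut `t`, the class
   distributions are renormalized *within* each class before their
   Shannon entropies are summed (`0·log 0 ≡ 0`).  Renormalization is
   essential: with global probabilities the sum is constant in `t` and
   cannot drive a search.  The figure of merit rewards cuts that leave
   both classes spread over many levels and collapses when one class is
   stranded on a few.  The search narrows over indices into the sorted
   candidate list — compare `H(mid)` and `H(mid+1)`, keep the better
   half, ties move right — and the selected threshold is the entropy
   argmax over every candidate the search evaluated.  For a unimodal
   entropy sequence this is exactly the narrowing endpoint and the global
   maximum (the oracle tests assert this); when background structure
   makes the sequence multi-modal the endpoint alone can stop on a minor
   local bump, and the evaluated-set argmax is the package's guard
   against that failure mode.  `entropy.exhaustive` scores every
   candidate instead; `entropy.search_space = "levels"` searches raw
   levels in `[A, B]` for sensitivity analysis.  Degenerate cuts (one
   class empty) score −inf.  Entropies are reported in raw bits; the
   trace also carries a max-normalized column for plotting, since
   published traces appear normalized to 1 without a stated convention.

5. **Binarization and clean-up** (`segment`).  Dark polarity
   (`mask = intensity < t`) by default, for bright-field images where
   particles absorb/scatter.  Clean-up order: hole filling (optional),
   then component filters by minimum area (default 9 px), optional
   maximum area, and optional convexity — solidity = area / convex-hull
   area below `convexity_min` drops the component.  The sequence is
   idempotent.  Two profiles encode the use cases: `particles` fills
   holes (holes inside an isolated particle are segmentation noise);
   `aggregates` does not, because pores between aggregated particles are
   real structure that the method is valued for preserving.  The
   convexity constraint is opt-in: its published mention gives no
   definition or threshold, and the solidity-ratio form implemented here
   is documented as this package's formalization.  Contours come from
   Moore boundary tracing (ordered, closed, 8-connected, deterministic)
   or optionally from Canny on the mask/masked intensity with hysteresis
   thresholds derived from Otsu on the gradient magnitude.

## Baselines

"Histogram thresholding" is pinned to Otsu's between-class-variance
criterion and "dynamic thresholding" to a per-pixel threshold of local
Gaussian-weighted mean (block 51 px) minus offset (5 levels) — standard
readings, since the published comparisons name neither implementation nor
parameters.  The Otsu threshold is returned such that the dark class is
exactly `{n < t}`, which makes it coincide with an exhaustive scan of the
criterion over all cut points (tested against that oracle).

## Counting and scores

Counting accuracy `100·(1 − |c − c_truth|/c_truth)` scores against a known
simulated truth; relative error `100·|c − c_manual|/c_manual` against a
manual reference.  Percentages are rounded half-up to two decimals.  Grid
counting tiles the image from a configurable origin with cells of about
one particle diameter; partial border tiles participate with their actual
area, and a cell counts when foreground covers strictly more than
`coverage_frac` (default 0.5) of it.  Because the count depends on grid
alignment (unstated in the protocol), a 3×3 origin sweep reporting
min/median/max is available.

## Synthetic scenes

The generator emulates the difficult features of real test images; it
makes no attempt at physics-based TEM simulation (no CTF, no multislice,
no 3-D projection), so passing tests demonstrate robustness to the
modeled difficulties — uneven and sharply varying background, noise,
merging, distractors — not to unmodeled optics.

All scenes are deterministic in their seed: placement, intensities and
noise derive from one `numpy` generator, and rendering twice is
bit-identical.  Truth labels mark each particle's footprint (its disk at
full radius) noise-free; the truth is unaffected by background structure.

- **`uneven_1028`** — the benchmark design: 1028 circular particles,
  radii uniform in [4, 10] px, per-particle intensities uniform in
  [40, 120] of 255, on a 1600×1600 canvas.  Background: base 180, smooth
  low-order polynomial ramp of amplitude ±30, plus one sharp dark ring
  (shift −40, radii 260–420) placed where the ramp is near zero so the
  ring's intensity band (~132–148) falls in the gap between the particle
  band and the main background mass.  That placement realizes the
  designed failure mode of global histogram thresholding: the
  between-class-variance optimum is pulled above the ring, flooding it
  and merging the particles inside, while the entropy criterion —
  which penalizes the concentrated ring mass folded into the particle
  class — keeps the cut below the ring.  Gaussian noise σ = 6 levels
  (a moderate, realistic level for dose-limited imaging; the NLM stage
  must earn its keep).  Dart-throwing placement with minimum center
  separation 0.9·(r₁+r₂) permits slight overlaps, reproducing the known
  failure mode of closely spaced particles merging — the method's
  residual ~5% undercount on this scene comes almost entirely from that.
  Canvas and radii were sized so that ~1000 resolvable particles fit at
  ~6% area coverage.

- **`cryo_aggregate`** — touching particles (r ≈ 6 px, spacing 1.7·r) in
  designed aggregates: one annular aggregate whose interior is a large
  enclosed pore, and two hexagonal-packed blobs with small pores punched
  inside; textured background (Gaussian-correlated speckle, σ 8 levels,
  scale 3 px) over base 150 emulating salt-crystal texture, noise σ = 7.
  Contrast is deliberately low (particle band 70–105).

- **`cell_uptake`** — 120 isolated particles plus three membrane-like
  ribbons: smooth random curves with persistent curvature, stroke width
  5 px, intensity 60 — squarely inside the particle intensity range, so
  no intensity cut can reject them and only the shape (solidity < 0.5)
  can.  Ribbons are kept clear of particles (dilated keep-out region) so
  the convexity filter's effect can be measured without merge ambiguity.

## Numerical choices and degenerate inputs

- Histogram bin identity: all intensity math on integer levels; RGB input
  collapses by Rec. 601 luma, rounded.
- Gradient: Sobel/8 with edge replication — on a linear ramp the response
  equals the per-pixel slope; constant images are rejected downstream as
  degenerate ("no gradient" / "structureless").
- Candidate ties on adjacent bins resolve to the lower level; entropy
  ties in the search move right (strict "higher than" comparison), and
  final selection ties resolve to the lower level.
- Images smaller than 8×8, empty masks, empty partitions, constant
  images, and unplaceable particle densities raise informative errors
  rather than propagating NaNs.

## Problem sizes

The quantitative suite runs the full benchmark at its native 1600×1600 /
1028-particle size (a few tens of seconds end to end); the robustness
scenes are 768×768.  Unit and property tests use 16–384 px fixtures
generated in-process; nothing is read from disk.

## Known limitations

- Touching particles are not split (no watershed); the benchmark's
  residual undercount is exactly this effect, as in the method's
  published account.
- A single global intensity cut is selected; the hinted two-threshold
  band segmentation (lower limit A separating particle sub-populations)
  is noted but not implemented.
- The entropy figure of merit can be multi-modal over candidates on
  heavily structured backgrounds; the evaluated-set argmax mitigates but
  does not eliminate the gap to exhaustive scoring (which
  `entropy.exhaustive` provides).
- Grid counts depend on alignment within ± a few percent (use the sweep).
- The generator's disks are ideal circles; elongated or faceted particles
  are outside the tested envelope.
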