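# Methods

## Coordinate frames and geometry

The laboratory frame is right-handed with **x** along the incident beam of
the first scan, **y** the laboratory vertical and **z** the goniometer
rotation axis (horizontal). A mesh scan rasters the holder over a grid
whose `u` axis runs along **z** and whose `v` axis runs along **y**; the
grid pitch equals the beam size (default 10 µm). A sample point `p` given
in the goniometer-zero frame is observed at laboratory position
`R(−ω)·p` in a scan at goniometer angle ω, where `R` is the right-handed
rotation about **z**. With the two scans separated by Ω this forward model
is inverted exactly by

    y = y₁,  x = (y₁ cos Ω − y₂) / sin Ω,  z = (z₁ + z₂) / 2,

which is degenerate at Ω ≡ 0 (mod 180°); in practice |Ω| ≥ 5° and accuracy
improves towards 90° (the 1/sin Ω factor amplifies vertical-centroid error
at small angles). The sign convention (which of the two scans "leads") is
not observable from a single scan; it is fixed package-wide by the forward
model above and pinned by round-trip tests against the simulator.

The detector is modelled flat, orthogonal to the beam, offset only by the
beam centre — the minimal model compatible with the Ewald construction.
A spot at detector position with unit sample-to-spot direction û maps to
the reciprocal-space node

    q = (û − b̂) / λ,      |q| = 2 sin θ / λ,

which lies on the Ewald sphere by construction. No Lorentz/polarisation or
parallax corrections are applied; spot positions are the only input used.

## Periodicity detection and its Rayleigh calibration

For a set of nodes the search scans an isotropic set of unit directions
(spherical-Fibonacci layout over one hemisphere, default n = 2500 —
antipodal directions are redundant, and the Fibonacci lattice avoids polar
clustering). Per direction:

1. project all nodes onto the direction (coordinates in Å⁻¹);
2. histogram with bin width 0.002 Å⁻¹ over the data range padded 5 %;
3. normalise: h = (H − p)/√p with p a Gaussian moving average
   (σ = 10 bins); bins where p falls below 0.5 counts carry no evidence
   and are set to zero;
4. FFT; the magnitude scaled by √(2/n_bins) makes each component
   unit-Rayleigh under the null that counts are independent (for a
   zero-mean unit-variance white h, the real and imaginary parts of
   DFT component k each have variance n/2).

Component k corresponds to a direct-space period f = k/(n_bins·bin_width)
Å. The DC term, the Nyquist term, and low frequencies attenuated by the
moving-average subtraction (Gaussian transfer exp(−2π²σ²(k/n)²) above
0.002) are masked — with the defaults this hides periods below ≈ 28 Å and
above 250 Å (Nyquist for 0.002 Å⁻¹ bins). Within this band the unit scale
makes the printed thresholds meaningful: P(score > 7) = e^(−49/2) ≈
2×10⁻¹¹ and P(score > 5) = e^(−25/2) ≈ 4×10⁻⁶.

The top 10 coarse directions are refined by Nelder–Mead on (θ, φ)
(initial step 0.5°, ≤ 40 evaluations), followed by a **lattice-consistency
polish**: a few Gauss–Newton steps minimising the wrapped phase residuals
(q·û)·f − round(·) of inlier nodes over the two direction angles and the
period. The polish converges to machine precision on exact lattice data
and sharpens direction and period far beyond the histogram-bin and
simplex-step scales; the refined direction is rescored through the full
pipeline and kept only if the score does not drop. Peak frequencies are
additionally interpolated to sub-bin accuracy by a parabolic fit through
the peak magnitude and its neighbours. Directions whose refined score
exceeds 7 become plane vectors v = f·û; near-parallel results (< 2°) are
deduplicated keeping the best score, because parallel detections are the
same family or its harmonics and carry no independent evidence. Fewer
than 50 nodes returns an empty list — not an error.

The whole coarse scan is vectorised (one matmul, one shared-length batched
FFT per chunk of directions; each direction keeps its own span and
Rayleigh scale, shorter spans acting as zero padding), giving the
n_dirs·(N + n_bins log n_bins) complexity profile; the acceptance suite
checks the N→2N runtime ratio stays below the O(N log N) bound.

## Crystal maps

Cell score: Σ intensity/(background+1) over the cell's spots — a declared
proxy, linear in intensity and discounted by local background (the real
per-image scoring engine is upstream of this package's scope). Cells with
score 0 are "no diffraction".

**Multi-pattern flag.** An image containing one lattice is almost fully
explained by one plane family: after a reduced plane search
(500 directions, top 4, ≤ 200 nodes) nearly every node projects within
0.25 periods of a family plane. With two superimposed patterns the other
lattice's nodes are uniform in phase, so ≥ (1−w)/2 of the nodes fall in
the outer phase band whatever the mixing fraction w; each family is also
evaluated at twice its period so that detecting a half-period harmonic
does not penalise a single lattice. A cell is flagged (label 999) when the
minimum outer-band fraction exceeds 0.1, or when a well-populated image
(≥ 120 nodes) yields no accepted family at all — the signature of two
patterns diluting each other. Cells with < 20 spots are never flagged
(insufficient evidence). A difference-vector clustering criterion was
evaluated first and abandoned: on Ewald-slice patterns the 2D spot set is
only locally periodic and the cluster statistics did not separate single
from superimposed patterns.

**Segmentation.** Diffracting, single-pattern cells are vertices of a
graph with edges between 4-adjacent cells whose patterns agree; pattern
similarity is the fraction of the *larger* spot list matched one-to-one
within 4 px (greedy nearest-neighbour). Normalising by the larger list is
deliberate: an overlap cell whose spots are the union of a weak neighbour
pattern with a stronger one scores low against that neighbour instead of
trivially high. Connected components become regions, labelled 1..K by
descending integrated score. Region centroids are score-weighted cell
centres; 4-adjacent 999 cells are included at half weight — the overlap
zone belongs partly to the crystal, and excluding it entirely biases the
centroid (and hence the depth triangulation) by up to ~1.5 cells. The
recommended aperture is the smallest of {10, 20, 30, 50} µm at least as
large as the smaller region extent (the largest if none fits). Region
node pools deduplicate spot positions rounded to the nearest pixel:
neighbouring cells of one crystal record the same reflections, and
duplicated nodes would scale the normalised histogram by √m and destroy
the Rayleigh calibration.

**Pair candidates.** The rotation-axis (u) coordinate of a crystal is
invariant between scans, so all cross-scan region pairs whose u centroids
agree within 1.5 cells are geometrically possible; each candidate carries
the provisionally triangulated position.

## Cross-scan identity and matching

`check()` projects the target region's nodes onto a rotated plane vector,
rebuilds histogram/normalisation/spectrum exactly as in the search (the
span comes from the target nodes; frequency alignment is by physical
units), and returns the best score within ±1.5 Fourier bins of the
expected frequency |v|. The window is small because sub-bin interpolation
and the polish localise the source frequency to well under a bin; a wider
window only grows the accidental-match cross-section. Scan-1 vectors are
rotated forward (into the scan-2 frame), scan-2 vectors backward, and the
pair decision uses the maximum score over all combinations in both
directions: matched ⇔ max > 5. One region may match several partners;
all passing pairs are reported with their scores rather than forced into
an assignment. Matched pairs are ranked by the combined integrated
diffraction score of their two regions — the order in which collection
should visit positions.

Residual false matches are dominated not by Rayleigh fluctuations but by
genuine partial periodicities: projections of a 3D lattice onto an
arbitrary axis form a three-frequency quasi-periodic set, and occasionally
(≈ 0.3 % per check at these conditions) a random direction/period lands
on a near-commensurate combination of the other crystal's basis. The
benchmark counts these per evaluated candidate; the operating point keeps
them at the percent level, consistent with the occasional spurious
position that downstream data-set clustering would reject.

## The simulator

A virtual holder with n crystals: unit cells uniform in 50–100 Å
(angles 85–95°), random orientations, sizes 10–30 µm, intensities
exponential with a per-crystal scale, positions rejection-sampled with
≥ 30 µm separation inside a disc around the rotation axis sized so the
whole footprint stays on the grid at every angle (default grid 32×28
cells at 10 µm). Reciprocal-lattice points within a resolution cutoff
(d_min = 2.5 Å) are excited when within ε = 0.002 Å⁻¹ of the Ewald
sphere — a binary stand-in for mosaicity and bandwidth on still images —
and projected to the flat detector (λ = 1 Å, 150 mm, 75 µm pixels,
2048²). A crystal's spots appear in every grid cell its projected
bounding box overlaps, with intensities scaled by the fractional overlap
area: this grades the heat map towards crystal edges the way real scans
fade out, and is what allows score-weighted centroids to localise
crystals to a fraction of a grid step. Cells covered by several crystals
receive merged spot lists; every cell gets 5 uniform noise spots;
noise-only cells score 0 (the upstream scorer's real/noise decision is
emulated, not modelled). Everything derives from one RNG seed and is
byte-reproducible.

What the simulator does **not** emulate — and what passing tests therefore
do not show about real data: physically meaningful intensities (structure
factors, Lorentz/polarisation, partiality profiles), detector noise and
pixel defects, mosaic spot broadening (spots sit at exact geometric
positions; real centroiding error ~1 px would add phase jitter),
radiation damage across the scan, salt rings, and preferred orientation.
Identical spot patterns repeat across a crystal's cells, which real beam
profiles would modulate.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| `n_directions` | 2500 | — | coarse isotropic direction set |
| `bin_width` | 0.002 | Å⁻¹ | projection histogram resolution; Nyquist period 250 Å |
| `smooth_sigma_bins` | 10 | bins | moving-average scale; masks periods ≲ 28 Å |
| `plane_threshold` | 7.0 | Rayleigh units | plane-vector acceptance (tail 2×10⁻¹¹) |
| `match_threshold` | 5.0 | Rayleigh units | pair decision (tail 4×10⁻⁶) |
| `window_bins` | 1.5 | bins | check() frequency window around |v| |
| `top_k` | 10 | — | coarse candidates refined |
| `min_nodes` | 50 | — | evidence floor for the plane search |
| `similarity_threshold` | 0.4 | — | cell-linking threshold |
| `match_radius_px` | 4 | px | spot-matching radius |
| `pairing_tolerance_cells` | 1.5 | cells | rotation-axis agreement for candidates |
| `epsilon` | 0.002 | Å⁻¹ | simulator excitation tolerance |
| `apertures_um` | 10/20/30/50 | µm | available beam sizes |

All are config-exposed (YAML blocks `segmentation`, `planes`, `matching`,
`simulation`).

## Numerical choices and degenerate inputs

Histogram spans are padded 5 % so boundary bins are not clipped; a span
narrower than one bin is widened to one bin. The smoothed level is floored
at 0.5 counts before division. Ties in region ranking break by centroid
lexicographic order. Empty scans segment to an empty list; plane search
on < 50 nodes and check() on < 50 nodes return empty/0 rather than raise;
check() raises only for expected frequencies beyond Nyquist, and
match_pair skips such vectors. Triangulation refuses Ω ≡ 0 (mod 180°) and
rotation-axis gaps beyond tolerance. Parabolic peak interpolation is
clamped to ±half a bin and skipped when the three-point stencil is not
concave.

## Benchmark problem sizes

The bundled benchmarks run 20 double-mesh simulations of 5–15 crystals at
α ∈ {30°, 60°, 90°} for the end-to-end check, 50 single-crystal seeds
(cells 40–150 Å) for plane recovery, 200 lattice-free node sets for the
null, and N = 500 vs 1000 nodes for the scaling ratio; the acceptance
script uses the same machinery at reduced repetition counts. The position
criterion is assessed as the fraction of recovered pairs within half a
grid step (≥ 90 %): crystals truncated by overlap (999) zones retain an
irreducible centroid bias of order one cell that any map-based centring
shares.

## Known limitations

Matching degrades for poorly diffracting crystals (few nodes) and for
periods outside the 28–250 Å band fixed by the histogram defaults; very
large unit cells need a smaller `bin_width`. At small inter-scan angles
the depth coordinate amplifies centroid noise by 1/sin Ω. Crystals much
larger than the beam violate the point-crystal footprint model, and the
identity check inherits the physical limitation that two crystals in an
accidental twin-like orientation relationship with commensurate periods
cannot be distinguished from one crystal.
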