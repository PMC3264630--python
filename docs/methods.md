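# Methods

## Scope and model

`slidecache` models the server- and client-side mathematics of a
region-on-demand whole-slide viewer: a tiled multi-resolution pyramid, a
rectangular region instruction set, an affine pan/zoom viewport, a
multi-resolution prefetch cache with promotion and re-anchoring, and
slide-anchored annotations. It deliberately models no hardware concerns:
no touch recognition (gestures arrive as explicit `ManipulationEvent`
records), no rendering, no network transport or latency, and no
concurrency — asynchronous block loading is represented by a
deterministic priority queue so that behaviour is exactly reproducible.

## Coordinate and resampling conventions

* Pixels are addressed 0-based from the top-left; regions are half-open
  `[x, x+w) × [y, y+h)`.
* A level at magnification `m` of a slide scanned at `M₀` has size
  `ceil(W·m/M₀) × ceil(H·m/M₀)`.
* Nearest-neighbour resampling uses half-pixel centres: target pixel `g`
  of a `T`-pixel axis samples source index `⌊(g+0.5)·S/T⌋` of an
  `S`-pixel axis. This makes requests at a stored magnification
  bit-identical to the stored tiles, keeps abutting requests stitchable
  bit-exactly, and is the convention pinned by the test oracles.
* Pixels outside the slide are white (255,255,255), the viewer's blank
  background, and responses always have exactly the requested size.
* A non-stored magnification is synthesised from the stored level with
  the smallest magnification ≥ the request. The stored intermediate
  levels themselves are produced in software with the same operator.

## Viewport mathematics

The transform group is translations plus uniform positive scalings in
homogeneous 3×3 form; rotation is intentionally unsupported, which keeps
axis-aligned rectangles axis-aligned and lets circle annotations project
to circles. Scaling about a focal point `p` is the composition
`T(p)·S(s)·T(−p)`, so `p` is a fixed point. A gesture sequence composes
by matrix product in application order; prefix products give the
intermediate display states. Composition equalities are asserted at an
absolute tolerance of 1e-9 (screen-scale magnitudes in double precision
leave ~1e-12 of rounding headroom).

`uncovered_screen_region` reports the screen rectangles that held
content before a manipulation but not after — what must be refetched. It
intersects with the slide's current projection, so areas that are
legitimately off-slide (blank) are not reported as needing fill.

## The cache

Defaults: 9×12 cells of 256 px around a 1024×768 screen, anchored so the
central 3×4 block (rows 4–6, columns 5–8, 1-based) coincides with the
screen. The per-cell resolution pattern is stored verbatim as
configuration (it is graded — 100% centre, then 25/12.5/6.25% toward the
edge — but it is *not* a pure function of Chebyshev distance from the
centre block, so no formula is used). Its sum is 26.375 cell-equivalents
of 108, hence a fill loads 24.4213% of the naive cost (75.58% less).

A cell with area fraction `f` is fetched as a square block of
`round(256·√f)` px per side (256, 128, 91, 64 for the four pattern
values) at the correspondingly reduced magnification, via the same zoom
mechanism the region server exposes, then enlarged by nearest neighbour
for display. Because 12.5% has no integer isotropic block size, the
request is rounded to 91 px while the savings accounting uses the
nominal pattern fractions; this keeps requests realisable and the
pattern's arithmetic exact. A full-resolution promotion counts its cell
area toward both the loaded and the naive counters (the naive strategy
pays the same for that cell), preserving `loaded ≤ naive` within a
session; savings between *strategies* are measured by replaying the same
trace under the graded and the all-full-resolution pattern.

Load order is a deterministic queue: central cells first, then rings
outward (row-major within a ring) — the reproducible stand-in for
asynchronous per-block display. Visibility uses strict rectangle overlap
(an abutting cell is not visible). Re-anchoring triggers exactly when
the screen rectangle is no longer contained in the grid's screen
footprint (containment tolerance 1e-6 px); this is the reading of the
reload rule consistent with its purpose — never showing unloaded
background. A zoom-in only expands the footprint and thus never
reloads; newly visible blurred cells are promoted in place, at the
grid's own magnification frame. The grid's magnification is set from the
viewport scale at (re)anchor time, clamped to the base power.

With default geometry the margin is 1024 px horizontally and 768 px
vertically, so any *single* pan up to one full screen in each axis is
absorbed without reload — the property the randomized coverage tests
assert. A sufficiently adversarial sequence of small pans can promote
many peripheral cells between reloads and erode the saving; the
simulator's accounting makes this visible rather than hiding it.

## Annotations

Geometry lives in base-slide pixels (the anchoring invariant), including
radii and extents — so a shape's slide-frame size is zoom-invariant and
its screen size scales with the viewport factor. Editing deltas arrive
in screen pixels and are divided by the viewport scale; extents are
clamped at 1 base px instead of inverting. The session state machine
allows one annotation in editing mode; manipulation events arriving
while editing are ignored (gesture control is halted), while
structurally impossible directives (begin while editing, commit while
navigating) are errors that name the offending trace line. Labels are
free text, attached at commit; the projection includes a label anchor at
the shape's bottom edge for any renderer. Persistence is a JSON list in
stable id order; duplicate ids are rejected at load.

## Synthetic slides

The generator emulates what matters for this engine about an H&E scan:
structure at several spatial scales. It composes a low-frequency
pink/eosin wash (bilinear-enlarged coarse noise), clusters of dark
purple nucleus-like ellipses (2.5–9 px radii, ~1 cluster per 80k px),
and per-pixel Gaussian grain (σ=5). The grain guarantees that 2×
down-then-up-sampling changes ≥1% of pixels, so blur/promotion tests are
meaningful. It does **not** model stain variation, scanner optics, JPEG
artefacts, or tissue morphology — passing tests demonstrate the engine's
geometry and accounting, not diagnostic image quality. Output is a pure
function of (size, magnification, seed).

Default study sizes: unit tests use a 1024×768 base slide (every grid
cell off the small slide is white-filled and counted at its nominal
fraction, which the accounting treats identically); the end-to-end
acceptance measurements use a 4096×3072 slide at 40× — large enough that
the full 9×12 grid at base magnification lies on-slide.

## Design choices where the design was open

* Table-driven pattern rather than a distance formula (see above);
  pattern, grid shape, cell size and screen size are all configuration,
  so other screens (e.g. 1920×1080) are expressible.
* Peripheral cells are fetched through the generic zoom mechanism rather
  than from a fixed pyramid level, so any fraction is servable exactly.
* The on-disk pyramid is a transparent DZI-like layout (`pyramid.json`
  plus one PNG per tile) rather than a proprietary container.
* The HTTP surface is omitted; the library API and the `slidecache`
  CLI (`synth`, `build`, `region`, `simulate`, `annotate`) expose the
  same contract.

## Known limitations

* No network/latency model: "savings" are pixel counts, a proxy for
  bandwidth and memory, not measured download time.
* Magnification synthesis is nearest-neighbour only (no smoothing), by
  design — bit-exactness is the tested contract.
* The cache promotes at the grid's anchored magnification; a long
  zoom-in sequence without panning keeps serving from that frame until a
  re-anchor occurs.
* Human-factors claims (usability, perceived speed) are out of scope and
  not simulated.
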