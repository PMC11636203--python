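# Methods

## The measurement problem

A camera watches a tunnel at a hive entrance; each bee carries a circular
fiducial tag on its thorax. Every frame in which a tag is read produces a
detection record (ID, time, position, orientation). Bees move fast, crawl
upside down, and loiter, so the detection stream is sparse and noisy; the
analysis must infer discrete behaviors (exits, entries, trips) from it.

## Event segmentation

Within one tag ID, consecutive detections separated by at most
`gap_seconds` (default 60 s, **inclusive** boundary: a gap of exactly 60 s
stays in the event) belong to the same event; a longer gap starts a new one.
Streams of different IDs never interact. The rule has two consequences used
throughout:

- every trip duration (entry start − exit end) strictly exceeds
  `gap_seconds`, because otherwise the two events would have been one;
- absences shorter than the window (most cleansing flights) are
  fundamentally unresolvable — the out and back traversals merge into one
  low-displacement event.

The streaming implementation is checked against an exhaustive oracle that
enumerates every contiguous partition of a stream and keeps the unique one
whose within-block gaps are ≤ the window and whose boundary gaps exceed it.

## Direction classification

The classifier is deliberately simple and declared as this package's own
reconstruction (no published criterion exists for the original field
system): project the displacement from an event's first to its last
detection onto the tunnel axis, signed positive toward the hive-side image
edge. At or beyond `displacement_threshold_frac × axis length` (default
0.25, i.e. 200 px of the 800-px axis) the event is an *enter*; at or beyond
the negative threshold an *exit*; otherwise, or with fewer than
`min_detections_for_direction` (default 2) detections, *unknown*. Tag
orientation is recorded and carried through but not used — a bee can walk
backwards with a fixed heading, so position change is the safer signal.
The rule is antisymmetric (reversing a trajectory swaps enter/exit) and
translation-invariant, and both properties are tested.

The tunnel axis is taken from `hive_side` (left/right → x, top/bottom → y);
the default field of view is 800×320 px with the hive on the left.

## Trip extraction

Unknown events are discarded *before* pairing — in field data roughly half
of events are unknown, and interleaving them would break nearly every
exit/enter adjacency. Among the remaining classified events of one ID in
time order, each enter is paired with the **latest** unpaired exit before it
(earlier exits are failed exits); enters without a preceding exit are failed
entries. Each event joins at most one trip and trips are disjoint per ID.

Duration is `enter.t_start − exit.t_end` (last sighting leaving → first
sighting returning): the closest observable proxy for time outside the hive.
The start-to-start alternative would add the outbound tunnel transit and is
not used. Statistics: mean and median over raw seconds; mode over durations
rounded to whole seconds with ties going to the smallest value; histogram in
`bin_minutes` bins (default 1 min). The report also counts trips under a
configurable cutoff (default 2 h, the conventional bound for plausible
foraging trips) and prints the direct detections-per-event quotient.

## Synthetic traffic

The simulator is first-class, tested code; it defines the study conditions
under which the pipeline's guarantees are stated.

Per bee, activities are scheduled inside a daily window (07:00–19:00; bees
fly in daylight) with exponential gaps targeting `activities_per_bee_day`
(default 6) and a 90-s minimum separation so distinct activities never merge
into one event. The default behavior mix is 50% foraging trips, 15%
cleansing flights, 5% orientation flights, 10% failed exits, 10% failed
entries, 10% loitering — declared assumptions, since no field
characterization of these proportions exists.

- **Foraging-trip durations**: log-normal with mode 120 s and raw mean
  ≈ 18.6 min (μ = 6.2752, σ = 1.2198), truncated below 90 s because the
  grouping window makes shorter excursions unobservable as trips; the short-
  excursion regime is covered by cleansing flights instead.
- **Orientation flights**: uniform 250–300 s. **Cleansing flights**: uniform
  5–60 s. **Failed exits/entries**: partial traversals (30–60% of the axis)
  that turn back, producing low-net-displacement events. **Loitering**:
  10–60 s random-walk clusters near the tunnel middle.
- **Traversals**: straight-line runs along the tunnel axis at
  `traversal_speed_px_s` (default 400 px/s ⇒ 2 s per 800-px crossing),
  sampled at `frame_rate` (default 15 Hz, the capture system's cap), with
  Gaussian jitter in the cross axis; no curvature model. Each in-view frame
  is detected with probability `p_frame_detect` (default 0.15, giving ~4–5
  detections per traversal, matching the sparse field regime), and an entire
  traversal is missed with `p_traversal_missed` (default 0.10; bees crawling
  upside down).

Ground truth records, per excursion, the moment the bee leaves the field of
view outward and the moment it reappears, plus whether each traversal was
detectable. Recovery counts an excursion when a same-ID trip overlaps it and
matches its duration within a tolerance; with perfect detection the
pipeline's duration error is bounded by two frame intervals (one per
endpoint), and at the default 15 Hz geometry it is exactly zero because the
crossing time is an integer number of frames.

**Common random numbers.** Every stochastic draw — schedules, durations,
per-frame uniforms — is made from one seeded generator regardless of the
detection probabilities, which enter only as comparison thresholds. Two runs
differing only in `p_frame_detect` therefore see identical traffic with
nested detection sets, so recovery degrades monotonically along a
probability ladder by construction, not merely in expectation. Identical
(scenario, seed) pairs give byte-identical logs.

**What the simulator does not emulate:** camera optics and image clutter
(no frames are synthesized), tag misreads/ID confusion, curved or stalled
trajectories inside the tunnel, weather- or time-of-day-dependent activity
rates, and colony demography. Passing recovery benchmarks therefore show the
*log-to-trips* chain is correct under the stated traffic model — they say
nothing about detector performance on real imagery.

## Circular tag family

The 10×10 cell-role grid ships as a versioned text file
(`src/hivegate/data/tag_layout_circle44.txt`) and is the single source of
truth: an outer data ring (trimmed by ignored corner cells into a raster
circle), a fixed white ring, a fixed black ring, and a 4×4 inner data block
— 44 data cells in total, matching a 44-bit family. The file is a synthetic
transcription satisfying those constraints, not a copy of any published
family; bit significance is raster-scan order of the data cells, MSB first.
Real-family codewords enter only through the detector adapter, which carries
its own ordering.

Rendering maps cells to an 8-bit raster (white = bit 1); decoding samples
each data cell's center pixel and thresholds at mid-gray, raising an error
inside a ±10% ambiguity band. Physical tag geometry follows the deployed
design: 2 mm printed square, 2.6 mm concentric cut circle (ratio 1.3; the
circle must clear the farthest used cell corner, checked geometrically),
yellow forward stripe. Sheets place tags on a grid whose pitch keeps cut
circles at least 0.1 mm apart (the cutting machine's precision).

**Ink bleed.** Cheap printers spread black into white cells, sometimes
obscuring them entirely; the fix is to morphologically dilate bright pixels
before detection (`dilate_white`, default 3×3, disable-able). Because
center-sample decoding only fails when a cell is fully swallowed, the test
fixture uses heavy bleed (2-px erosion) on a codeword whose 1-bits form the
solid inner block, which a 5×5 dilation regrows exactly (morphological
opening of a 12-px square is the identity).

**Detector adapter.** Detection is behind a narrow protocol (raster in,
id/x/y/θ out) so any tag-detection binding can be injected; all log-based
analysis runs without one. The shipped `GridTemplateDetector` cross-
correlates the binarized frame with the border-ring template (FFT) and
decodes at correlation peaks — a reference implementation for axis-aligned
rendered frames (no rotation, perspective or lighting handling), used to
test the contract end-to-end.

## Numerical and format choices

- Log dialect: headered CSV, naive local ISO-8601 timestamps (the field
  hardware has no timezone handling), floats written in shortest
  round-trip form so `parse ∘ write` is the identity; lenient parsing skips
  and reports malformed lines, strict parsing aborts with the line number.
- Colony allocation: thousands digit of the tag ID (1000–1999 → worker01,
  …, 6000–6999 → queen); IDs outside every range map to a sentinel rather
  than an error.
- Empty inputs yield empty outputs or explicitly flagged undefined
  statistics (None / "—"), never NaNs.
- Problem sizes in tests and the acceptance script (e.g. 4 bee-days of
  default traffic, 500 perfect-detection excursions, 200 excursions per
  ladder step, 1,000 oracle streams, 100 codewords) were chosen as the
  smallest scales at which the checked properties are meaningful.

## Known limitations

- The enter/exit rule ignores orientation and cannot separate a slow partial
  traversal from loitering; field data will contain many unknown events.
- Duration statistics are conditional on recovery: trips lost to missed
  traversals bias nothing, but asymmetric detection failure between exits
  and entries would.
- The reference detector requires known scale and axis alignment; field
  imagery needs a real tag-detection binding behind the adapter.
- The shipped layout is a constraint-faithful stand-in; codewords rendered
  with it are not interchangeable with any published family's IDs.
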