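# hivegate

Tools for analyzing honey-bee traffic at a hive entrance monitored by a
camera reading fiducial tags glued to each bee's thorax.

Automated entrance monitors log one line per tag sighting — tag ID,
timestamp, in-frame position, tag orientation — as bees walk through a
tunnel under the camera. Turning that stream into biology takes four steps,
all implemented here:

1. **Parse** detection logs (a headered CSV dialect; strict or lenient).
2. **Segment** each tag's detections into *events*: consecutive sightings at
   most 60 s apart belong to the same event, a longer silence starts a new
   one. This makes one minute the shortest resolvable absence.
3. **Classify** each event as *enter*, *exit* or *unknown* from its net
   displacement along the tunnel axis (threshold: 25% of the 800-px axis by
   default), signed toward the hive-side image edge.
4. **Pair** events into *trips*: an exit followed by the consecutive entry
   of the same bee, after discarding unknown events, failed exits and failed
   entries. Trip duration = first sighting on return − last sighting while
   leaving, and a report gives counts, category percentages, per-ID tallies
   and duration statistics (mean, median, mode at 1-s resolution, minute
   histogram).

Because field data is noisy and scarce, the package also ships

- a **traffic simulator** with ground truth — foraging trips (log-normal
  durations, mode ≈ 2 min), cleansing flights (5–60 s), orientation flights
  (250–300 s), failed exits/entries and loitering, with per-frame detection
  failure and wholly-missed traversals — so every pipeline stage is testable
  without hardware, and
- a **circular tag toolkit**: a 10×10 cell-role layout with 44 data bits,
  raster rendering and decoding, printable sheets (2 mm tags, 2.6 mm
  magenta cut circles, yellow orientation stripe; SVG/PNG/PDF), the
  white-pixel dilation pre-pass that rescues tags degraded by printer ink
  bleed, and a narrow detector-adapter contract with a reference detector
  for rendered frames.

## Worked example

```python
from hivegate import TrafficScenario, build_report, extract_trips, segment
from hivegate.simulate import simulate_traffic

detections, truth = simulate_traffic(TrafficScenario(seed=42))
events = segment(detections)
trips = extract_trips(events)
print(build_report(detections, events, trips, colony_label="worker05").to_text())
```

prints

```
Colony report: worker05
  detections:            15743
  events:                1624
  detections per event:  9.69
  enter / exit / unknown: 34.67% / 35.96% / 29.37%
  trips:                 451
  trips < 2 h:           424
  trip duration mean:    2604.22 s (43 min 24 s)
  trip duration median:  596.94 s (9 min 57 s)
  trip duration mode:    252.00 s (4 min 12 s)
```

Four simulated days of one colony yielded 15,743 sightings that collapse to
1,624 events; roughly a third of events cannot be given a direction (bees
loitering, aborted exits/entries, traversals seen only partially). 451
exit→enter pairs survive as trips; the duration distribution is strongly
right-skewed (median 10 min, mean 43 min), as expected when a few long
foraging trips sit on a bulk of short ones. The ground truth held 832 true
excursions: cleansing flights shorter than the grouping window are
unresolvable in principle, and imperfect per-frame detection loses some of
the remainder — exactly the gap the simulator exists to quantify.

The `examples/` directory holds this script plus recovery benchmarking
(`recovery_benchmark.py`) and tag rendering/decoding
(`render_and_decode_tags.py`).

## Command line

```sh
hivegate simulate --seed 1 --out log.csv --truth truth.json
hivegate analyze log.csv --out results/       # report + spreadsheet + figures
hivegate plot-events log.csv --tag-id 5000    # per-event trajectory panels
hivegate render-tags --ids 5000-5099 --out sheet.svg
```

`analyze` writes `report.json`/`report.txt`, `Events_by_ID.csv`/`.xlsx`, and
the two histogram figures (detections/events/trips per ID; trips per
duration range in minutes).

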